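"""Multiexponential TCF fits, spectral densities and Wigner rotation.

The real part of each correlation channel is fitted with

    G(τ) ≈ Σ_k A_k exp(−τ/τ_k),   A_k ≥ 0, τ_k > 0,  k = 1..3 by default,

whose two-sided Fourier transform gives the spectral density

    J(ω) = Σ_k 2 A_k τ_k / (1 + ω² τ_k²)

and the sine-transform companion L(ω) = Σ_k 2 A_k τ_k² ω / (1 + ω² τ_k²)
entering the slow oscillation of the transverse magnetization.  The quality
gate is the relative mismatch between the integrals of the data and the fit
over the available lag range (warned above 2%), not the number of components.

Spectral densities in a frame tilted by β from the uniaxial PAS follow from
the rank-2 Wigner small-d matrix:  J_nn(ω; β) = Σ_m [d²_{m,n}(β)]² J′_{|m|}(ω).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

PS = 1e-12  # timescales are stored in ps; spectral densities use seconds

INTEGRAL_MISMATCH_WARN = 0.02


@dataclass
class MultiExpFit:
    amplitudes: np.ndarray    # (k,) (rad/s)^2, >= 0
    timescales: np.ndarray    # (k,) ps, > 0
    residual: float           # RMS of fit residuals
    integral_mismatch: float  # |∫fit − ∫data| / ∫data

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.timescales = np.asarray(self.timescales, dtype=float)
        if np.any(self.amplitudes < 0) or np.any(self.timescales <= 0):
            raise ValueError("amplitudes must be >= 0 and timescales > 0")

    def __call__(self, tau_ps) -> np.ndarray:
        tau_ps = np.asarray(tau_ps, dtype=float)
        return np.sum(
            self.amplitudes[:, None] * np.exp(-tau_ps[None, :] / self.timescales[:, None]),
            axis=0,
        )


class FitConvergenceError(RuntimeError):
    def __init__(self, best_residual):
        super().__init__(
            f"multiexponential fit failed to converge (best residual {best_residual})"
        )
        self.best_residual = best_residual


def _model(tau, *params):
    k = len(params) // 2
    a = np.asarray(params[:k])
    t = np.asarray(params[k:])
    return np.sum(a[:, None] * np.exp(-tau[None, :] / t[:, None]), axis=0)


def fit_multiexponential(
    tau: np.ndarray,
    g: np.ndarray,
    n_exp: int = 3,
    n_starts: int = 8,
    seed: int = 0,
) -> MultiExpFit:
    """Non-negative least-squares multiexponential fit with multistart.

    Initial timescales are log-spaced over [lag spacing, lag range], jittered
    per start by a seeded RNG; the lowest-residual solution is kept, ties
    broken by the smaller timescale sum.
    """
    tau = np.asarray(tau, dtype=float)
    g = np.asarray(g, dtype=float)
    if len(tau) < 10:
        raise ValueError("need at least 10 lag points to fit")
    if not np.isfinite(g[0]) or g[0] <= 0:
        raise ValueError("G(0) must be positive to fit a decaying TCF")
    ok = np.isfinite(g)
    tau, g = tau[ok], g[ok]

    dt = tau[1] - tau[0]
    span = max(tau[-1], 2 * dt)
    rng = np.random.default_rng(seed)
    scale = g[0]
    best = None
    best_key = None
    for start in range(n_starts):
        t0 = np.geomspace(dt, span, n_exp)
        if start > 0:
            t0 = t0 * np.exp(rng.normal(0, 0.7, size=n_exp))
        t0 = np.clip(t0, dt * 2e-3, 4.9 * span)
        a0 = np.full(n_exp, scale / n_exp)
        p0 = np.concatenate([a0, t0])
        # timescales capped at 5x the lag range: slower components are not
        # resolvable from the available lags and would destabilize tau'
        bounds = (
            np.concatenate([np.zeros(n_exp), np.full(n_exp, dt * 1e-3)]),
            np.concatenate([np.full(n_exp, np.inf), np.full(n_exp, 5.0 * span)]),
        )
        try:
            popt, _ = curve_fit(_model, tau, g, p0=p0, bounds=bounds, maxfev=20000)
        except RuntimeError:
            continue
        resid = float(np.sqrt(np.mean((_model(tau, *popt) - g) ** 2)))
        key = (round(resid / max(scale, 1e-300), 12), float(np.sum(popt[n_exp:])))
        if best_key is None or key < best_key:
            best_key = key
            best = popt
    if best is None:
        raise FitConvergenceError(np.inf)

    a, t = best[:n_exp], best[n_exp:]
    order = np.argsort(t)
    a, t = a[order], t[order]
    fit_curve = _model(tau, *best)
    integral_data = np.trapezoid(g, tau)
    integral_fit = np.trapezoid(fit_curve, tau)
    mismatch = abs(integral_fit - integral_data) / abs(integral_data) \
        if integral_data != 0 else np.inf
    if mismatch > INTEGRAL_MISMATCH_WARN:
        warnings.warn(
            f"TCF fit integral mismatch {mismatch:.1%} exceeds "
            f"{INTEGRAL_MISMATCH_WARN:.0%}; consider more components"
        )
    resid = float(np.sqrt(np.mean((fit_curve - g) ** 2)))
    return MultiExpFit(a, t, resid, float(mismatch))


def fit_triexponential(tau, g, n_starts: int = 8, seed: int = 0) -> MultiExpFit:
    """Three-component fit (the default used throughout the analysis)."""
    return fit_multiexponential(tau, g, n_exp=3, n_starts=n_starts, seed=seed)


def spectral_density(fit: MultiExpFit, omega: float | np.ndarray) -> np.ndarray | float:
    """J(ω) = Σ_k 2 A_k τ_k / (1 + ω²τ_k²), ω in rad/s, τ in seconds."""
    omega = np.asarray(omega, dtype=float)
    t = fit.timescales * PS
    val = np.sum(
        2.0 * fit.amplitudes[:, None] * t[:, None]
        / (1.0 + (omega.ravel()[None, :] * t[:, None]) ** 2),
        axis=0,
    ).reshape(omega.shape)
    return float(val) if val.shape == () else val


def companion_l(fit: MultiExpFit, omega: float | np.ndarray) -> np.ndarray | float:
    """Sine-transform companion L(ω) = Σ_k 2 A_k τ_k² ω / (1 + ω²τ_k²)."""
    omega = np.asarray(omega, dtype=float)
    t = fit.timescales * PS
    val = np.sum(
        2.0 * fit.amplitudes[:, None] * t[:, None] ** 2 * omega.ravel()[None, :]
        / (1.0 + (omega.ravel()[None, :] * t[:, None]) ** 2),
        axis=0,
    ).reshape(omega.shape)
    return float(val) if val.shape == () else val


def integrated_correlation_time(fit: MultiExpFit) -> float:
    """Amplitude-weighted mean timescale τ′ = Σ A_k τ_k / Σ A_k, in ps."""
    total = fit.amplitudes.sum()
    if total <= 0:
        raise ValueError("zero total amplitude: integrated time undefined")
    return float(np.dot(fit.amplitudes, fit.timescales) / total)


# ---------------------------------------------------------------------------
# Wigner rotation
# ---------------------------------------------------------------------------

_M_ORDER = np.array([2, 1, 0, -1, -2])


def _didx(m: int) -> int:
    return 2 - m


def wigner_d2(beta: float) -> np.ndarray:
    """Rank-2 Wigner small-d matrix d²_{m,n}(β), Condon–Shortley convention.

    Returned as a 5×5 array indexed by (2−m, 2−n) for m, n = 2..−2.
    Rows and columns are orthonormal: Σ_m [d²_{m,n}]² = 1.
    """
    c, s = np.cos(beta), np.sin(beta)
    d = np.full((5, 5), np.nan)
    d[_didx(2), _didx(2)] = ((1 + c) / 2) ** 2
    d[_didx(2), _didx(1)] = -s * (1 + c) / 2
    d[_didx(2), _didx(0)] = np.sqrt(3.0 / 8.0) * s * s
    d[_didx(2), _didx(-1)] = -s * (1 - c) / 2
    d[_didx(2), _didx(-2)] = ((1 - c) / 2) ** 2
    d[_didx(1), _didx(1)] = (1 + c) * (2 * c - 1) / 2
    d[_didx(1), _didx(0)] = -np.sqrt(3.0 / 8.0) * 2.0 * s * c
    d[_didx(1), _didx(-1)] = (1 - c) * (2 * c + 1) / 2
    d[_didx(0), _didx(0)] = (3 * c * c - 1) / 2
    for m in range(2, -3, -1):
        for n in range(2, -3, -1):
            if np.isnan(d[_didx(m), _didx(n)]):
                if not np.isnan(d[_didx(n), _didx(m)]):
                    d[_didx(m), _didx(n)] = (-1) ** (m - n) * d[_didx(n), _didx(m)]
                elif not np.isnan(d[_didx(-n), _didx(-m)]):
                    d[_didx(m), _didx(n)] = d[_didx(-n), _didx(-m)]
                elif not np.isnan(d[_didx(-m), _didx(-n)]):
                    d[_didx(m), _didx(n)] = (-1) ** (m - n) * d[_didx(-m), _didx(-n)]
    return d


def rotation_weights(beta: float) -> np.ndarray:
    """w[n, |m|]: weight of J′_{|m|} in J_nn(β), n = 0..2, with ±m folded.

    w[n, q] = Σ_{m: |m| = q} [d²_{m,n}(β)]²;  Σ_q w[n, q] = 1 for every n.
    """
    d = wigner_d2(beta)
    w = np.zeros((3, 3))
    for n in range(3):
        col = d[:, _didx(n)]
        for i, m in enumerate(_M_ORDER):
            w[n, abs(m)] += col[i] ** 2
    return w


def rotate_spectral_density(
    j_pas: np.ndarray, beta: float, n: int | None = None
) -> np.ndarray:
    """Tilted-frame J_nn(ω; β) from PAS values J′_{|m|}(ω).

    ``j_pas`` has shape (3, ...) for |m| = 0, 1, 2 (negative m equal by
    symmetry).  With ``n=None`` all three n channels are returned, shape
    (3, ...).
    """
    j_pas = np.asarray(j_pas)
    if j_pas.shape[0] != 3:
        raise ValueError("j_pas must supply |m| = 0, 1, 2 along the first axis")
    w = rotation_weights(beta)
    rotated = np.tensordot(w, j_pas, axes=(1, 0))
    return rotated if n is None else rotated[n]
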