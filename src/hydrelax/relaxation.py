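"""Orientation-dependent relaxation observables from spectral densities.

For a like-spin-1/2 pair under Redfield theory, with the spectral densities
J_nn(ω; β) of the dipolar spatial functions in a frame tilted by β from the
uniaxial PAS (two-sided transform convention):

    R₁    = ⅛ J₁,₁(ω₀) + ½ J₂,₂(2ω₀)
    R₂    = 3/16 J₀,₀(0) + 5/16 J₁,₁(ω₀) + ⅛ J₂,₂(2ω₀)        (Δ = 0 limit)
    R_⊥   = 3/16 J₀,₀(0) + 3/16 J₁,₁(ω₀) + ⅛ J₂,₂(2ω₀)

In extreme narrowing with isotropic J these coincide (R₁ = R₂ = (3/2) b² τ_c
for a rigid pair with coupling b = (μ0/4π)γ²ħ/r³), reproducing the familiar
bulk-water T₁ ≈ T₂.  A nonzero residual coupling Δ = 3·2π·d_IS splits the
transverse evolution: when 4Δ² − J₁,₁(ω₀)² > 0 the magnetization decays at
R_⊥ while oscillating at ¼√(4Δ² − J₁,₁²); otherwise the decay is
multiexponential.  The RDC scales with orientation as Δ(β) = Δ_PAS·P₂(cos β)
and vanishes at the magic angle 54.74°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hydrelax.fitting import (
    MultiExpFit,
    companion_l,
    integrated_correlation_time,
    rotate_spectral_density,
    spectral_density,
)


@dataclass
class AnalysisConfig:
    larmor_frequency: float = 400e6       # Hz; omega0 = 2*pi*nu0
    beta_grid_deg: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 90.1, 5.0)
    )
    block_length: float = 100.0           # ps
    inter_cutoff: float = 20.0            # Å (10 Å for bulk-only systems)
    first_layer_cutoff: float = 3.5       # Å
    second_layer_cutoff: float = 7.0      # Å
    n_bootstrap: int = 1000
    seed: int = 0
    n_exp: int = 3

    def __post_init__(self):
        if self.larmor_frequency <= 0:
            raise ValueError("Larmor frequency must be positive")
        b = np.asarray(self.beta_grid_deg, dtype=float)
        if np.any(b < 0) or np.any(b > 180):
            raise ValueError("beta grid must lie in [0, 180] degrees")
        self.beta_grid_deg = b

    @property
    def omega0(self) -> float:
        return 2.0 * np.pi * self.larmor_frequency


@dataclass
class RelaxationProfile:
    beta_deg: np.ndarray
    r1: np.ndarray                 # 1/s
    r2: np.ndarray                 # 1/s
    r_perp: np.ndarray             # 1/s
    oscillation: np.ndarray        # 1/s; NaN in the multiexponential regime
    oscillatory: np.ndarray        # bool per beta
    slow_cosine: np.ndarray        # 1/s
    delta_pas: float               # rad/s
    omega0: float
    selection: str = ""
    kind: str = ""

    @property
    def t1(self) -> np.ndarray:
        return _safe_inverse(self.r1)

    @property
    def t2(self) -> np.ndarray:
        return _safe_inverse(self.r2)

    @property
    def g_r1(self) -> float:
        return anisotropy_fraction(self.r1)

    @property
    def g_r2(self) -> float:
        return anisotropy_fraction(self.r2)


def _safe_inverse(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    out = np.full_like(r, np.inf)
    ok = r > 1e-12
    out[ok] = 1.0 / r[ok]
    return out


def _check_j(*values):
    for v in values:
        if np.any(np.asarray(v) < 0):
            raise ValueError("spectral densities must be non-negative")


def r1_rate(j11_w0: float, j22_2w0: float) -> float:
    """Longitudinal rate from J₁,₁(ω₀) and J₂,₂(2ω₀)."""
    _check_j(j11_w0, j22_2w0)
    return j11_w0 / 8.0 + j22_2w0 / 2.0


def r2_rate(j00_0: float, j11_w0: float, j22_2w0: float) -> float:
    """Transverse rate in the vanishing-RDC limit."""
    _check_j(j00_0, j11_w0, j22_2w0)
    return 3.0 / 16.0 * j00_0 + 5.0 / 16.0 * j11_w0 + j22_2w0 / 8.0


def r_perp(
    j00_0: float, j11_w0: float, j22_2w0: float, delta: float,
    require_regime: bool = True,
) -> float:
    """Decay rate of the oscillating transverse evolution (RDC present).

    Valid in the positive-discriminant regime 4Δ² ≥ J₁,₁(ω₀)²; equals the
    Δ = 0 transverse rate minus ⅛ J₁,₁(ω₀) (the share of J₁,₁ that feeds the
    oscillation instead of the decay), hence reduces to it exactly when
    J₁,₁(ω₀) = 0.
    """
    _check_j(j00_0, j11_w0, j22_2w0)
    if require_regime and 4.0 * delta**2 - j11_w0**2 < 0:
        raise ValueError(
            "negative discriminant 4Δ² − J₁,₁²: the transverse evolution is "
            "multiexponential; use transverse_evolution instead"
        )
    return 3.0 / 16.0 * j00_0 + 3.0 / 16.0 * j11_w0 + j22_2w0 / 8.0


@dataclass
class OscillationResult:
    value: float          # 1/s; NaN when multiexponential
    regime: str           # "oscillatory" | "multiexponential"
    discriminant: float   # 4Δ² − J₁,₁²


def oscillation_factor(delta: float, j11_w0: float) -> OscillationResult:
    """¼√(4Δ² − J₁,₁(ω₀)²) and the evolution regime."""
    disc = 4.0 * delta**2 - j11_w0**2
    if disc < 0:
        return OscillationResult(np.nan, "multiexponential", disc)
    return OscillationResult(0.25 * np.sqrt(disc), "oscillatory", disc)


def slow_cosine_rate(l11_w0: float, l22_2w0: float) -> float:
    """⅛ [L₁,₁(ω₀) + 2 L₂,₂(2ω₀)], the slow oscillation of the transverse decay."""
    return (l11_w0 + 2.0 * l22_2w0) / 8.0


def transverse_evolution(
    t: np.ndarray,
    r_perp_rate: float,
    oscillation: float,
    slow_rate: float,
    slow_cutoff_ratio: float = 1e-3,
    discriminant: float | None = None,
) -> np.ndarray:
    """Product-form transverse magnetization M(t)/M(0).

    exp(−R_⊥ t) · cos(Ω t) · cos(ω_slow t), with the slow cosine replaced by 1
    when its rate is below ``slow_cutoff_ratio`` × R_⊥.  In the
    multiexponential regime (negative discriminant) the oscillation is the
    analytic continuation cosh(¼√(J₁,₁² − 4Δ²) t).
    """
    t = np.asarray(t, dtype=float)
    decay = np.exp(-r_perp_rate * t)
    if discriminant is not None and discriminant < 0:
        osc = np.cosh(0.25 * np.sqrt(-discriminant) * t)
    else:
        osc = np.cos(oscillation * t) if np.isfinite(oscillation) else 1.0
    if r_perp_rate > 0 and abs(slow_rate) < slow_cutoff_ratio * r_perp_rate:
        slow = 1.0
    else:
        slow = np.cos(slow_rate * t)
    return decay * osc * slow


def anisotropy_fraction(r: np.ndarray) -> float:
    """g(R) = 1 − R_min/R_max over the orientation grid."""
    r = np.asarray(r, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two orientations")
    if np.any(r <= 0):
        raise ValueError("all rates must be positive")
    return float(1.0 - r.min() / r.max())


def delta_of_beta(delta_pas: float, beta_deg: np.ndarray) -> np.ndarray:
    """Δ(β) = Δ_PAS · P₂(cos β); zero at the magic angle."""
    c = np.cos(np.radians(np.asarray(beta_deg, dtype=float)))
    return delta_pas * (3.0 * c * c - 1.0) / 2.0


def relaxation_profile(
    fits: list[MultiExpFit],
    delta_pas: float,
    omega0: float,
    beta_deg: np.ndarray,
    selection: str = "",
    kind: str = "",
) -> RelaxationProfile:
    """Full β profile of R₁, R₂, R_⊥, oscillation and slow-cosine rates.

    ``fits`` holds the PAS-frame TCF fits for m = 0, 1, 2.  For every β the
    PAS spectral densities are Wigner-rotated before entering the rate
    expressions; the residual coupling scales as Δ_PAS·P₂(cos β).
    """
    if len(fits) != 3:
        raise ValueError("need fits for m = 0, 1, 2")
    beta_deg = np.asarray(beta_deg, dtype=float)
    # PAS-frame J and L at the three frequencies that enter the rates
    j_pas = np.array(
        [
            [spectral_density(f, w) for f in fits]
            for w in (0.0, omega0, 2.0 * omega0)
        ]
    )  # shape (freq, m)
    l_pas = np.array(
        [[companion_l(f, w) for f in fits] for w in (omega0, 2.0 * omega0)]
    )

    n_b = len(beta_deg)
    r1 = np.empty(n_b)
    r2 = np.empty(n_b)
    rp = np.empty(n_b)
    osc = np.empty(n_b)
    oscillatory = np.empty(n_b, dtype=bool)
    slow = np.empty(n_b)
    deltas = delta_of_beta(delta_pas, beta_deg)
    for i, b in enumerate(np.radians(beta_deg)):
        j00_0 = rotate_spectral_density(j_pas[0], b, n=0)
        j11_w0 = rotate_spectral_density(j_pas[1], b, n=1)
        j22_2w0 = rotate_spectral_density(j_pas[2], b, n=2)
        l11_w0 = rotate_spectral_density(l_pas[0], b, n=1)
        l22_2w0 = rotate_spectral_density(l_pas[1], b, n=2)
        r1[i] = r1_rate(j11_w0, j22_2w0)
        r2[i] = r2_rate(j00_0, j11_w0, j22_2w0)
        rp[i] = r_perp(j00_0, j11_w0, j22_2w0, deltas[i], require_regime=False)
        res = oscillation_factor(deltas[i], j11_w0)
        osc[i] = res.value
        oscillatory[i] = res.regime == "oscillatory"
        slow[i] = slow_cosine_rate(l11_w0, l22_2w0)
    return RelaxationProfile(
        beta_deg=beta_deg, r1=r1, r2=r2, r_perp=rp,
        oscillation=osc, oscillatory=oscillatory, slow_cosine=slow,
        delta_pas=delta_pas, omega0=omega0, selection=selection, kind=kind,
    )


def combine_contributions(profiles: list[RelaxationProfile], selection: str = "") -> RelaxationProfile:
    """Sum additive relaxation contributions (negligible cross-correlations).

    Rates and residual couplings add.  The oscillation factor and regime are
    re-evaluated from the combined Δ and the combined J₁,₁(ω₀; β), the latter
    recovered exactly as 8·(R₂ − R_⊥) of the summed profiles.
    """
    if not profiles:
        raise ValueError("no profiles to combine")
    ref = profiles[0]
    for p in profiles[1:]:
        if len(p.beta_deg) != len(ref.beta_deg) or np.max(
            np.abs(p.beta_deg - ref.beta_deg)
        ) > 1e-9 or abs(p.omega0 - ref.omega0) > 1e-6:
            raise ValueError("profiles must share the beta grid and omega0")
    r1 = np.sum([p.r1 for p in profiles], axis=0)
    r2 = np.sum([p.r2 for p in profiles], axis=0)
    rp = np.sum([p.r_perp for p in profiles], axis=0)
    slow = np.sum([p.slow_cosine for p in profiles], axis=0)
    delta_pas = float(np.sum([p.delta_pas for p in profiles]))
    # J11(omega0; beta) = 8 (R2 - R_perp) for each contribution, additive
    j11 = 8.0 * (r2 - rp)
    deltas = delta_of_beta(delta_pas, ref.beta_deg)
    osc = np.empty_like(r1)
    oscillatory = np.empty(len(r1), dtype=bool)
    for i in range(len(r1)):
        res = oscillation_factor(deltas[i], j11[i])
        osc[i] = res.value
        oscillatory[i] = res.regime == "oscillatory"
    return RelaxationProfile(
        beta_deg=ref.beta_deg.copy(), r1=r1, r2=r2, r_perp=rp,
        oscillation=osc, oscillatory=oscillatory, slow_cosine=slow,
        delta_pas=delta_pas, omega0=ref.omega0,
        selection=selection or ref.selection, kind="all",
    )


@dataclass
class UniaxialityReport:
    ratio_f1: float
    ratio_f2: float
    f0_mean: complex
    warning: bool
    note: str = ""


def check_uniaxial_symmetry(
    f_means: np.ndarray, threshold: float = 0.1
) -> UniaxialityReport:
    """Azimuthal-residual diagnostic of the uniaxial-symmetry assumption.

    For a truly uniaxial environment the ensemble means of F₁ and F₂ vanish;
    reported are |⟨F₁⟩|/|⟨F₀⟩| and |⟨F₂⟩|/|⟨F₀⟩| with a warning above the
    threshold.  When ⟨F₀⟩ ≈ 0 absolute values are reported instead.
    """
    f_means = np.asarray(f_means).reshape(3)
    if np.all(f_means == 0):
        raise ValueError("empty input: no F means supplied")
    f0 = abs(f_means[0])
    note = ""
    if f0 < 1e-12 * max(abs(f_means[1]), abs(f_means[2]), 1e-300):
        r1, r2 = abs(f_means[1]), abs(f_means[2])
        note = "⟨F0⟩ ≈ 0: absolute |⟨F1⟩|, |⟨F2⟩| reported instead of ratios"
    else:
        r1, r2 = abs(f_means[1]) / f0, abs(f_means[2]) / f0
    return UniaxialityReport(
        ratio_f1=float(r1), ratio_f2=float(r2), f0_mean=complex(f_means[0]),
        warning=bool(max(r1, r2) > threshold), note=note,
    )
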