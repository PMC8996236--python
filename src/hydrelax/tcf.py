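"""Ensemble-averaged time-correlation functions of the dipolar F_m.

Two estimators are provided, both evaluated in the uniaxial PAS and both with
the squared magnitude of the all-water ensemble mean |⟨F_m⟩|² subtracted as a
time-independent baseline (the residual coupling survives in the baseline, not
in the decaying part):

* unrestricted — the trajectory is sliced into fixed blocks (default 100 ps)
  and each pair contributes a single time origin per block, the block start:
  G′_mm(τ) = ⟨F_m(t₀) F_m*(t₀+τ)⟩ − |⟨F_m⟩_all|², averaged over pairs and
  blocks.  Selections are static (block-start snapshot).

* restricted — every admissible origin in the whole trajectory contributes,
  but (t, t+τ) is counted only when the whole interval lies inside a single
  first-layer residence interval of the pair's home molecule.  Molecules that
  stay longer therefore carry proportionally more weight.

F series arrays are complex with shape (3, n_pairs, n_frames) for m = 0, 1, 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft


@dataclass
class TCFSet:
    tau: np.ndarray            # (L,) ps
    g: np.ndarray              # (3, L) complex, (rad/s)^2, baseline-subtracted
    baseline: np.ndarray       # (3,) |<F_m>_all|^2
    n_pairs: int
    n_origins: np.ndarray      # (L,) accumulated origin count per lag
    selection: str = ""
    kind: str = ""
    mode: str = "unrestricted"

    def __post_init__(self):
        if self.n_pairs <= 0:
            raise ValueError("TCFSet requires n_pairs > 0")

    def real(self) -> np.ndarray:
        return self.g.real

    def to_frame(self):
        """Columnar table: τ, Re/Im G′_mm, n_origins."""
        import pandas as pd

        data = {"tau_ps": self.tau}
        for m in range(3):
            data[f"re_g{m}{m}"] = self.g[m].real
            data[f"im_g{m}{m}"] = self.g[m].imag
        data["n_origins"] = self.n_origins
        return pd.DataFrame(data)


def _check_series(f_series: np.ndarray) -> np.ndarray:
    f_series = np.asarray(f_series)
    if f_series.ndim != 3 or f_series.shape[0] != 3:
        raise ValueError("F series must have shape (3, n_pairs, n_frames)")
    return f_series


def tcf_unrestricted(
    block_series: list[np.ndarray],
    baseline_all: np.ndarray,
    dt: float,
    selection: str = "",
    kind: str = "",
) -> TCFSet:
    """Single-origin-per-block TCF averaged over pairs and blocks.

    ``block_series`` holds one (3, n_pairs, n_frames_block) array per block;
    pair membership may differ between blocks.  The lag grid runs to one frame
    short of the shortest block (lags at or beyond the block length are not
    computable from a single origin).
    """
    if not block_series:
        raise ValueError("no blocks supplied")
    blocks = [_check_series(b) for b in block_series]
    if any(b.shape[1] == 0 for b in blocks):
        raise ValueError("no pairs in selection")
    if any(b.shape[2] < 2 for b in blocks):
        raise ValueError("each block needs at least 2 frames")
    baseline_all = np.asarray(baseline_all, dtype=float).reshape(3)
    L = min(b.shape[2] for b in blocks)
    acc = np.zeros((3, L), dtype=complex)
    counts = np.zeros(L, dtype=np.int64)
    n_pairs = 0
    for b in blocks:
        # one origin per pair per block: t0 = block start
        acc += (b[:, :, :1] * np.conj(b[:, :, :L])).sum(axis=1)
        counts += b.shape[1]
        n_pairs += b.shape[1]
    g = acc / counts[None, :] - baseline_all[:, None]
    return TCFSet(
        tau=np.arange(L) * dt,
        g=g,
        baseline=baseline_all,
        n_pairs=n_pairs,
        n_origins=counts,
        selection=selection,
        kind=kind,
        mode="unrestricted",
    )


def _autocorr_sums(x: np.ndarray, max_lag: int) -> np.ndarray:
    """s[j] = Σ_t x(t) x*(t+j), j = 0..max_lag, via zero-padded FFT."""
    n = x.shape[-1]
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    X = fft(x, n=nfft, axis=-1)
    c = ifft(X * np.conj(X), axis=-1)[..., : max_lag + 1]
    # ifft(|X|^2)[j] = Σ_t x(t+j) x*(t); we want its conjugate
    return np.conj(c)


def tcf_restricted(
    f_series: np.ndarray,
    frame_intervals: list[list[tuple[int, int]]],
    baseline_all: np.ndarray,
    dt: float,
    max_lag: int | None = None,
    selection: str = "",
    kind: str = "",
) -> TCFSet:
    """All-origin TCF restricted to residence intervals.

    ``frame_intervals[p]`` lists the inclusive (start, stop) frame intervals
    during which pair ``p``'s home molecule resides in the first hydration
    layer.  A lag contributes only where an interval is long enough; lags with
    zero admissible origins are reported as NaN.
    """
    f_series = _check_series(f_series)
    n_pairs = f_series.shape[1]
    if len(frame_intervals) != n_pairs:
        raise ValueError("need one interval list per pair")
    longest = max((b - a for ivals in frame_intervals for a, b in ivals), default=-1)
    if longest < 0:
        raise ValueError("empty union of residence intervals")
    if max_lag is None:
        max_lag = longest
    max_lag = min(max_lag, longest)
    baseline_all = np.asarray(baseline_all, dtype=float).reshape(3)

    acc = np.zeros((3, max_lag + 1), dtype=complex)
    counts = np.zeros(max_lag + 1, dtype=np.int64)
    for p, ivals in enumerate(frame_intervals):
        for a, b in ivals:
            seg = f_series[:, p, a : b + 1]
            n = seg.shape[-1]
            lag = min(max_lag, n - 1)
            acc[:, : lag + 1] += _autocorr_sums(seg, lag)
            counts[: lag + 1] += n - np.arange(lag + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(counts > 0, acc / np.maximum(counts, 1), np.nan + 0j)
    g = g - baseline_all[:, None]
    return TCFSet(
        tau=np.arange(max_lag + 1) * dt,
        g=g,
        baseline=baseline_all,
        n_pairs=n_pairs,
        n_origins=counts,
        selection=selection,
        kind=kind,
        mode="restricted",
    )


def tcf_sliding(
    f_series: np.ndarray,
    baseline_all: np.ndarray,
    dt: float,
    max_lag: int | None = None,
    selection: str = "",
    kind: str = "",
) -> TCFSet:
    """Whole-trajectory sliding-origin TCF (restricted estimator, trivial mask)."""
    f_series = _check_series(f_series)
    n = f_series.shape[2]
    full = [[(0, n - 1)] for _ in range(f_series.shape[1])]
    out = tcf_restricted(
        f_series, full, baseline_all, dt, max_lag=max_lag,
        selection=selection, kind=kind,
    )
    out.mode = "sliding"
    return out


def average_tcf_over_blocks(tcfs: list[TCFSet]) -> TCFSet:
    """Unweighted mean of per-block TCFs on an identical lag grid."""
    if not tcfs:
        raise ValueError("no TCFs to average")
    ref = tcfs[0]
    for t in tcfs[1:]:
        if len(t.tau) != len(ref.tau) or np.max(np.abs(t.tau - ref.tau)) > 1e-12:
            raise ValueError("lag grids differ between blocks")
    g = np.mean([t.g for t in tcfs], axis=0)
    return TCFSet(
        tau=ref.tau.copy(),
        g=g,
        baseline=ref.baseline.copy(),
        n_pairs=sum(t.n_pairs for t in tcfs),
        n_origins=np.sum([t.n_origins for t in tcfs], axis=0),
        selection=ref.selection,
        kind=ref.kind,
        mode=ref.mode,
    )
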