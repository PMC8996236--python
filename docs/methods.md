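# Methods

## Model

`hydrelax` treats each ¹H–¹H pair as an isolated pair of identical spin-1/2
nuclei whose dipole–dipole coupling is a small, time-dependent perturbation
(Redfield regime: correlation times much shorter than the inverse coupling,
and much shorter than the inverse residual coupling for the longitudinal
equations). The coupling is decomposed into spatial functions
F_m = C·Y₂ᵐ(θ′,φ′)/r³ with the orthonormal rank-2 spherical harmonics
(Condon–Shortley phase) and C = −√(24π/5)(μ0/4π)γ²ħ. The fundamental
constants are pinned at γ_H = 2.675221900 × 10⁸ rad s⁻¹ T⁻¹ and
ħ = 1.0545718 × 10⁻³⁴ J s (CODATA 2014) so that C reproduces
−2.93083474 × 10⁻²⁴ m³/s bit-for-bit to nine significant digits; later
CODATA revisions move the ninth digit.

The motional environment of water around an elongated solute is assumed
uniaxial on average. The symmetry axis z′ is the eigenvector of the
smallest eigenvalue of the solute's inertia tensor; x′ and y′ are arbitrary
up to right-handedness, which is legitimate exactly because of the assumed
azimuthal symmetry (the package reports |⟨F₁⟩|/|⟨F₀⟩| and |⟨F₂⟩|/|⟨F₀⟩| as
an azimuthal-residual diagnostic, warning above 0.1). Per analysis block
the PAS comes from the eigendecomposition of the block-mean inertia tensor:
averaging tensors is well defined, averaging eigenvectors is not.
Eigenvector sign is fixed by continuity with the previous block (first
block: positive dot with lab +z); the F_m are even rank, so physics is
sign-independent and the convention only serves reproducibility.

## Correlation functions and their two estimators

Both estimators subtract |⟨F_m⟩|² computed over **all** water as the
time-independent baseline; the mean that is subtracted is the residual
coupling, which is treated separately. Hydration-layer means over a block
are not stationary (molecules escape), so per-selection baselines would be
ill-defined; the all-water ensemble is the stationary reference.

* **Unrestricted**: the trajectory is cut into fixed blocks (default
  100 ps); selections are frozen at the block-start frame, and each pair
  contributes a single time origin per block (the block start). This is the
  estimator used for all tabulated selections and for the segment
  bootstrap.
* **Restricted**: every (t, t+τ) window fully inside a first-layer
  residence interval of the pair's home molecule contributes. Long
  residents therefore carry proportionally more weight — this is a
  deliberate property of the estimator, not a bug — and no bootstrap is
  attempted because the whole trajectory is one sample.

The baseline form of the restricted estimator is an open design point; the
package subtracts the same all-water |⟨F_m⟩|² as the unrestricted mode, for
the same stationarity reason.

Residence intervals are maximal runs of consecutive frames with the
any-atom minimum-image distance to the solute < 3.5 Å; endpoints are
inclusive, and a single-frame visit yields a zero-length interval usable
only at τ = 0. Spherical cutoffs (defaults 20 Å solute systems, 10 Å bulk)
limit intermolecular pair enumeration, frozen at the block start. RDCs are
considered reliable only for intramolecular pairs: dipolar couplings decay
as r⁻³ but their lattice sum does not, so a cutoff biases intermolecular
RDCs; results for other kinds are flagged.

## Fits, spectral densities, rotation

The real part of each channel is fitted with a non-negative
multiexponential (three components by default, more via configuration)
using bounded least squares with eight log-spaced, seeded multistarts;
the lowest residual wins, ties broken toward the smaller timescale sum.
Timescales are capped at five times the available lag range: slower
components are unresolvable and, because the non-negativity constraint
rectifies tail noise into spurious slow amplitude, an uncapped fit can
corrupt the amplitude-weighted time τ′ = ΣAτ/ΣA. The quality gate is the
relative mismatch of the integrals of data and fit over the lag range
(warning above 2%), which is insensitive to how the decay is partitioned
among components.

Spectral densities use the two-sided transform convention
J(ω) = Σ 2Aτ/(1+ω²τ²), with the sine-transform companion
L(ω) = Σ 2Aτ²ω/(1+ω²τ²) entering the slow cosine of the transverse
evolution. Tilted-frame densities follow from the rank-2 Wigner small-d
matrix, J_nn(ω;β) = Σ_m [d²_{m,n}(β)]² J′_{|m|}(ω); the implementation is
the closed-form table and the test oracle is exp(−iβJ_y) in the spin-2
basis. The rates are the like-spin Redfield combinations

    R₁ = ⅛ J₁,₁(ω₀) + ½ J₂,₂(2ω₀)
    R₂ = 3/16 J₀,₀(0) + 5/16 J₁,₁(ω₀) + ⅛ J₂,₂(2ω₀)      (Δ = 0)
    R_⊥ = R₂ − ⅛ J₁,₁(ω₀)

normalized to the F_m convention above (isotropic rigid pair:
G′_mm(0) = (6/5)b², b = (μ0/4π)γ²ħ/r³, extreme narrowing
R₁ = R₂ = (3/2)b²τ_c, which reproduces bulk-water T₁ ≈ 3.4 s at
τ_c = 2.45 ps and r = 1.5139 Å). With a nonzero residual coupling,
Δ(β) = 3·2π·d_IS·P₂(cos β), the transverse evolution is oscillatory with
frequency ¼√(4Δ² − J₁,₁²) while that discriminant is positive — the ⅛J₁,₁
share of R₂ feeds the oscillation rather than the decay, hence the R_⊥
expression — and multiexponential otherwise; the numerical evolution uses
the analytic continuation cosh(¼√(J₁,₁² − 4Δ²)t). d_IS = ⟨F₀⟩/(√6·2π) is
anchored by two printed checks: a fully aligned rigid pair gives
|d_IS| = 34.6 kHz, and d_IS = 85 Hz gives an oscillation factor of
0.80 × 1000/s.

## Bootstrap

Trajectory segments (default 100 ps) are resampled with replacement,
their raw correlation functions and couplings averaged, and the statistic
(fit → J → rate) applied to the average — not averaged over per-segment
statistics. 95% CIs are the 2.5/97.5 percentiles of 1000 replicates (means
reported). Segments are correlated through slow solute motion but are
treated as independent; this is a documented approximation, adequate when
water correlation times are far below the segment length. The PAS itself
is not bootstrapped.

## Synthetic generators and what they do (not) show

The rotor generators integrate overdamped rotational Brownian motion on
the unit sphere with a first-order Euler step: a rotation by an angle
drawn from N(0, √(4D_r dt)) about a random perpendicular axis, preceded,
for the biased rotor, by the drift 2kD_r dt (u·ẑ)(ẑ − (u·ẑ)u) of the
aligning potential U(θ) = −k cos²θ (k in units of kT), then
renormalization. The free rotor has exactly exponential rank-2 TCFs
exp(−6D_r τ); the biased rotor's stationary density is ∝ exp(k cos²θ)
with ⟨P₂⟩ available by quadrature. The constraint dt·D_r < 0.01 keeps the
integrator bias on correlation times below ~1%; the residual O(dt) bias on
⟨P₂⟩ is visible at dt = 0.05 ps and negligible at dt = 0.01 ps, which the
tests use. Defaults mirror the conditions the analysis is meant for:
100 fs frame spacing, D_r = 0.068 ps⁻¹ (τ = 2.45 ps, bulk-water-like),
r_HH = 1.5139 Å (rigid 4-site water geometry).

For the oracle suites the TCF is estimated with all sliding origins (FFT
autocorrelation, streamed over vector chunks): the single-origin block
estimator is faithful to the production analysis but at desk-scale ensemble
sizes its rectified tail noise biases τ′ upward by several percent, whereas
the sliding estimator recovers τ′ within 1% at the suite's problem size
(500 vectors × 1 ns at 10 fs).

The generators emulate the *statistical* structure the analysis assumes —
exponential rank-2 TCFs, uniaxial bias, residence/escape logic in the toy
rod system — not real hydration water: there is no translational
diffusion coupled to rotation, no hydrogen-bond kinetics, no exchange, and
intermolecular coupling statistics are not modeled quantitatively. Passing
oracles therefore validate the estimator chain and unit conventions, not
the fidelity of any particular force field or water model.

## Numerical choices and degenerate inputs

- Minimum-image components lie in (−L/2, L/2]; orthorhombic boxes only,
  cutoffs above half the smallest box edge are rejected.
- Near-degenerate smallest inertia eigenvalues (within 0.1%) trigger an
  ill-defined-axis warning rather than an error.
- G(0) ≤ 0, empty selections, zero total fit amplitude, and rates ≤ 0 in
  the anisotropy fraction are hard errors; lags with no admissible
  restricted origins are reported as NaN and skipped by the fit.
- Division by rates below 10⁻¹² 1/s yields infinite relaxation times
  rather than raising.
- The slow transverse cosine is replaced by 1 when its rate is below
  10⁻³ × R_⊥ (configurable), matching its negligible size in practice.
- Problem sizes in the test suite (ensembles of 24–500 vectors, 0.2–1 ns)
  were chosen so that each oracle's sampling noise sits well inside its
  stated tolerance; the bootstrap-coverage check uses 100 independent
  meta-replicates of a 24-vector ensemble.

## Known limitations

- Like-spin pairs only; intermolecular couplings are approximations within
  an isolated-pair theory, and cross-correlations between pairs are
  neglected throughout.
- Intermolecular RDCs under a spherical cutoff are unreliable by
  construction and flagged, not corrected (no Ewald-type lattice summation).
- The restricted estimator's weighting toward long residents means its
  rates are not population averages; restricted and unrestricted results
  bracket the observable for exchanging water.
- No proton exchange, no spin-lock (T₁ρ) observables, no sub-frame
  (librational) dynamics: couplings are sampled at the frame interval and
  faster motion enters only through its effect on the sampled geometry.
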