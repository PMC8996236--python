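"""Dipolar spatial functions F_m and residual (secular) dipolar couplings.

For a pair of identical spin-1/2 nuclei at separation r with orientation
(θ′, φ′) in the uniaxial principal axis system, the dipole–dipole coupling
decomposes into spatial functions

    F_m = C · Y₂ᵐ(θ′, φ′) / r³ ,   m = 0, ±1, ±2,   [rad/s, r in metres]

with the orthonormal rank-2 spherical harmonics (∫|Y₂ᵐ|² dΩ = 1) and the
prefactor C = −√(24π/5)·(μ0/4π)·γ_H²·ħ = −2.93083474 × 10⁻²⁴ m³/s.  Only
m = 0, 1, 2 are stored; negative orders follow from F_{−m} = (−1)^m F_m*.

The time-and-ensemble average of the secular (m = 0) component is the
residual dipolar coupling, reported as d_IS = ⟨F₀⟩/(√6·2π) in Hz; the
transverse evolution contains it through Δ = 3·2π·d_IS (rad/s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Fundamental constants (CODATA 2014), pinned for bit-reproducibility of C.
GAMMA_H = 2.675221900e8       # proton gyromagnetic ratio, rad s^-1 T^-1
HBAR = 1.0545718e-34          # J s
MU0_OVER_4PI = 1.0e-7         # T m / A

ANGSTROM = 1e-10
MAGIC_ANGLE_DEG = np.degrees(np.arccos(1.0 / np.sqrt(3.0)))  # 54.7356...


@dataclass(frozen=True)
class PhysicalConstants:
    C: float                 # m^3/s, dipolar spatial prefactor (< 0)
    gamma_H: float
    hbar: float
    mu0_over_4pi: float


def dipolar_constant() -> PhysicalConstants:
    """Evaluate C = −√(24π/5)·(μ0/4π)·γ_H²·ħ from fundamental constants."""
    C = -np.sqrt(24.0 * np.pi / 5.0) * MU0_OVER_4PI * GAMMA_H**2 * HBAR
    return PhysicalConstants(C=C, gamma_H=GAMMA_H, hbar=HBAR, mu0_over_4pi=MU0_OVER_4PI)


_C = dipolar_constant().C


def y2m(m: int, theta, phi):
    """Orthonormal rank-2 spherical harmonic Y₂ᵐ(θ, φ), |m| ≤ 2.

    Condon–Shortley phase; normalization ∫|Y₂ᵐ|² dΩ = 1.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    c, s = np.cos(theta), np.sin(theta)
    if m == 0:
        return np.sqrt(5.0 / (16.0 * np.pi)) * (3.0 * c * c - 1.0) + 0j
    if abs(m) == 1:
        val = -np.sqrt(15.0 / (8.0 * np.pi)) * s * c * np.exp(1j * phi)
        return val if m == 1 else -np.conj(val)
    if abs(m) == 2:
        val = np.sqrt(15.0 / (32.0 * np.pi)) * s * s * np.exp(2j * phi)
        return val if m == 2 else np.conj(val)
    raise ValueError(f"|m| must be <= 2, got {m}")


def y2m_cartesian(unit_vector: np.ndarray) -> np.ndarray:
    """Y₂ᵐ for m = 0, 1, 2 from a unit vector (…, 3) → complex (3, …)."""
    v = np.asarray(unit_vector, dtype=float)
    norm = np.sqrt(np.einsum("...i,...i->...", v, v))
    if np.any(np.abs(norm - 1.0) > 1e-8):
        raise ValueError("input vectors must be unit length (|v| = 1 within 1e-8)")
    x, y, z = v[..., 0], v[..., 1], v[..., 2]
    xy = x + 1j * y
    return np.stack(
        [
            np.sqrt(5.0 / (16.0 * np.pi)) * (3.0 * z * z - 1.0) + 0j,
            -np.sqrt(15.0 / (8.0 * np.pi)) * z * xy,
            np.sqrt(15.0 / (32.0 * np.pi)) * xy * xy,
        ]
    )


def f_m(r_angstrom, theta, phi) -> np.ndarray:
    """Dipolar spatial functions F_m (m = 0, 1, 2) in rad/s.

    ``r_angstrom`` is the internuclear distance in Å (converted to metres
    internally); angles are the PAS-frame spherical coordinates.
    """
    r = np.asarray(r_angstrom, dtype=float)
    if np.any(r < 0.5):
        raise ValueError("internuclear distance below 0.5 Å is unphysical")
    inv_r3 = 1.0 / (r * ANGSTROM) ** 3
    return np.stack([_C * y2m(m, theta, phi) * inv_r3 for m in (0, 1, 2)])


def f_m_from_vectors(vectors_angstrom: np.ndarray) -> np.ndarray:
    """F_m for displacement vectors (…, 3) in Å, PAS frame → complex (3, …)."""
    v = np.asarray(vectors_angstrom, dtype=float)
    r = np.sqrt(np.einsum("...i,...i->...", v, v))
    if np.any(r < 0.5):
        raise ValueError("internuclear distance below 0.5 Å is unphysical")
    y = y2m_cartesian(v / r[..., None])
    return _C * y / (r * ANGSTROM) ** 3


@dataclass
class ResidualCoupling:
    d_is: float          # Hz
    delta: float         # rad/s, Δ = 3·2π·d_IS
    selection: str
    reliable: bool = True

    def __post_init__(self):
        expected = 3.0 * 2.0 * np.pi * self.d_is
        if abs(self.delta - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError("Delta must equal 3·2π·d_IS")


def secular_rdc(f0_values: np.ndarray, selection: str = "", kind: str = "intra") -> ResidualCoupling:
    """Residual coupling from the ensemble-and-time mean of F₀ (PAS frame).

    Intermolecular couplings are long-ranged, so their RDC cannot be estimated
    reliably under a spherical cutoff; such results carry ``reliable=False``.
    """
    f0_values = np.asarray(f0_values)
    if f0_values.size == 0:
        raise ValueError("empty selection: no F0 values to average")
    mean_f0 = float(np.mean(f0_values).real)
    d_is = mean_f0 / (np.sqrt(6.0) * 2.0 * np.pi)
    return ResidualCoupling(
        d_is=d_is,
        delta=3.0 * 2.0 * np.pi * d_is,
        selection=selection,
        reliable=(kind == "intra"),
    )
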