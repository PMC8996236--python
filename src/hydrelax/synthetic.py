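"""Synthetic generators with closed-form oracles.

Three kinds of inputs emulate the statistical structure the analysis assumes:

* a free rotational-diffusion ensemble of unit vectors whose rank-2
  orientational TCFs decay as exp(−6 D_r τ) — the isotropic-water stand-in;
* a uniaxially biased rotor (overdamped Langevin on the sphere in the
  potential U(θ) = −k cos²θ, thermal units) whose stationary density is
  ∝ exp(k cos²θ), giving a nonzero ⟨P₂⟩ and hence a residual coupling that
  can be checked against Boltzmann quadrature;
* a toy rod + water system exercising the structure/trajectory readers,
  hydration-layer logic, residence tracking and the PAS construction.

Every generator takes an explicit seed and the Euler step on the sphere
enforces dt·D_r < 0.01 so the discretization bias on correlation times stays
below the ~1% level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import quad

from hydrelax.dipolar import f_m_from_vectors

R_HH_DEFAULT = 1.5139  # Å, H–H distance of a rigid 4-site water geometry


@dataclass
class RotorEnsembleSpec:
    n_vectors: int = 500
    D_r: float = 0.068          # 1/ps (bulk-water-like: tau_2 = 1/(6 D_r) ≈ 2.45 ps)
    k: float = 0.0              # aligning potential strength, units of kT
    r_hh: float = R_HH_DEFAULT  # Å
    dt: float = 0.01            # ps
    n_steps: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.D_r < 0:
            raise ValueError("D_r must be non-negative")
        if self.n_vectors < 1:
            raise ValueError("need at least one vector")
        if self.dt * self.D_r >= 0.01:
            raise ValueError(
                f"dt*D_r = {self.dt * self.D_r:.3g} >= 0.01: time step too coarse "
                "for the Euler sphere integrator"
            )


def _init_orientations(spec: RotorEnsembleSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw initial vectors from the stationary density ∝ exp(k cos²θ)."""
    n = spec.n_vectors
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    if spec.k != 0.0:
        # rejection sampling on cosθ; azimuth stays uniform
        kmax = np.exp(max(spec.k, 0.0))
        c = np.empty(n)
        filled = 0
        while filled < n:
            cand = rng.uniform(-1, 1, size=2 * n)
            acc = rng.uniform(0, kmax, size=2 * n) < np.exp(spec.k * cand**2)
            take = cand[acc][: n - filled]
            c[filled : filled + len(take)] = take
            filled += len(take)
        s = np.sqrt(1 - c**2)
        phi = rng.uniform(0, 2 * np.pi, size=n)
        u = np.column_stack([s * np.cos(phi), s * np.sin(phi), c])
    return u


def _step(u, rng, sigma, drift_coeff):
    """One Euler step: optional drift down the potential, then a random
    rotation about a perpendicular axis, then renormalization."""
    if drift_coeff != 0.0:
        uz = u[:, 2:3]
        u = u + drift_coeff * uz * (np.array([0.0, 0.0, 1.0]) - uz * u)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
    a = rng.normal(size=u.shape)
    a -= np.einsum("ij,ij->i", a, u)[:, None] * u
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    ang = rng.normal(0.0, sigma, size=(len(u), 1))
    u = u * np.cos(ang) + np.cross(a, u) * np.sin(ang)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u


def _simulate(spec: RotorEnsembleSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    u = _init_orientations(spec, rng)
    out = np.empty((spec.n_steps + 1, spec.n_vectors, 3), dtype=np.float32)
    out[0] = u
    sigma = np.sqrt(4.0 * spec.D_r * spec.dt)
    drift = 2.0 * spec.k * spec.D_r * spec.dt
    for t in range(1, spec.n_steps + 1):
        u = _step(u, rng, sigma, drift)
        out[t] = u
    return out


def simulate_free_rotor(spec: RotorEnsembleSpec) -> np.ndarray:
    """Isotropic rotational Brownian motion; returns (n_steps+1, n_vectors, 3).

    Rank-2 orientational TCFs of the output decay as exp(−6 D_r τ); the
    long-run orientation distribution is uniform on the sphere.
    """
    if spec.k != 0.0:
        raise ValueError("free rotor requires k = 0 (use simulate_uniaxial_rotor)")
    return _simulate(spec)


def simulate_uniaxial_rotor(spec: RotorEnsembleSpec) -> np.ndarray:
    """Rotor in the aligning potential U(θ) = −k cos²θ (k in kT units).

    Overdamped Langevin on the sphere; stationary density ∝ exp(k cos²θ),
    initial conditions drawn from it, so the series is stationary from t = 0.
    """
    if spec.k <= 0.0:
        raise ValueError("uniaxial rotor requires k > 0 (use simulate_free_rotor)")
    return _simulate(spec)


def boltzmann_order_parameter(k: float) -> float:
    """⟨P₂(cos θ)⟩ over the stationary density ∝ exp(k cos²θ), by quadrature."""
    if not np.isfinite(k):
        raise ValueError("k must be finite")
    num = quad(lambda x: 0.5 * (3 * x * x - 1) * np.exp(k * x * x), -1, 1)[0]
    den = quad(lambda x: np.exp(k * x * x), -1, 1)[0]
    return num / den


def make_pair_series(orientations: np.ndarray, r_hh: float = R_HH_DEFAULT) -> np.ndarray:
    """Dipolar F_m series for rigid pairs at fixed separation.

    ``orientations`` is (n_frames, n_vectors, 3) of unit vectors (PAS frame);
    returns complex (3, n_vectors, n_frames).
    """
    o = np.asarray(orientations, dtype=float)
    f = f_m_from_vectors(o * r_hh)          # (3, n_frames, n_vectors)
    return np.ascontiguousarray(np.swapaxes(f, 1, 2))


# ---------------------------------------------------------------------------
# toy rod + water system
# ---------------------------------------------------------------------------

_WATER_GEOM = np.array(
    [
        [0.0, 0.0, 0.0],                 # O
        [0.75695, 0.58588, 0.0],         # H
        [-0.75695, 0.58588, 0.0],        # H
    ]
)


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def build_toy_system(
    n_free: int = 8,
    n_tethered: int = 4,
    rod_length: float = 20.0,
    n_frames: int = 50,
    dt: float = 0.1,
    box_edge: float = 40.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
):
    """Rigid rod of point masses plus tethered and free water-like molecules.

    The rod (alternating C/H sites, 1 Å spacing, aligned near z) tumbles
    slowly; ``n_tethered`` waters jitter harmonically within 3.5 Å of rod
    sites, ``n_free`` waters random-walk through the box.  Returns
    ``(topology, trajectory)`` and, when ``out_dir`` is given, writes
    ``toy.pdb`` and ``toy.traj`` in the package's own formats.
    """
    from hydrelax.trajectory import Trajectory, read_structure, write_trajectory

    rng = np.random.default_rng(seed)
    box = np.full(3, box_edge)
    center = box / 2.0

    n_rod = int(rod_length) + 1
    rod_local = np.column_stack(
        [np.zeros(n_rod), np.zeros(n_rod), np.linspace(-rod_length / 2, rod_length / 2, n_rod)]
    )
    rod_elements = ["C" if i % 2 == 0 else "H" for i in range(n_rod)]

    # anchor sites and initial offsets for tethered waters
    anchor_idx = rng.choice(n_rod, size=n_tethered, replace=False)
    tether_dirs = rng.normal(size=(n_tethered, 3))
    tether_dirs[:, 2] = 0.3 * tether_dirs[:, 2]
    tether_dirs /= np.linalg.norm(tether_dirs, axis=1, keepdims=True)
    # free waters start on a coarse lattice (no overlaps) and jitter gently
    grid = np.arange(4.0, box_edge - 4.0, 6.0)
    lattice = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
    lattice = lattice[np.linalg.norm(lattice - center, axis=1) > rod_length / 2 + 5.0]
    free_pos = lattice[rng.choice(len(lattice), size=n_free, replace=False)].astype(float)

    n_waters = n_tethered + n_free
    n_atoms = n_rod + 3 * n_waters
    coords = np.empty((n_frames, n_atoms, 3))
    times = np.arange(n_frames) * dt

    axis_angle = 0.0
    water_rots = [_random_rotation(rng) for _ in range(n_waters)]
    for f in range(n_frames):
        # slow tumble: small rotation about the x axis, ~0.2°/frame
        axis_angle += np.radians(0.2)
        ca, sa = np.cos(axis_angle), np.sin(axis_angle)
        R = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
        rod = rod_local @ R.T + center
        coords[f, :n_rod] = rod
        for w in range(n_waters):
            # slow random reorientation of the rigid water
            water_rots[w] = water_rots[w] @ _random_rotation_small(rng, 0.15)
            geom = _WATER_GEOM @ water_rots[w].T
            if w < n_tethered:
                site = rod[anchor_idx[w]]
                wobble = rng.normal(0, 0.15, size=3)
                o_pos = site + tether_dirs[w] * 2.4 + wobble
            else:
                free_pos[w - n_tethered] += rng.normal(0, 0.1, size=3)
                o_pos = np.mod(free_pos[w - n_tethered], box_edge)
            coords[f, n_rod + 3 * w : n_rod + 3 * w + 3] = o_pos + geom

    lines = []
    serial = 1
    for i, el in enumerate(rod_elements):
        lines.append(_pdb_line(serial, el + str(i + 1), "ROD", 1, coords[0, i], el))
        serial += 1
    for w in range(n_waters):
        base = n_rod + 3 * w
        for j, (nm, el) in enumerate([("O", "O"), ("H1", "H"), ("H2", "H")]):
            lines.append(
                _pdb_line(serial, nm, "HOH", 2 + w, coords[0, base + j], el)
            )
            serial += 1
    pdb_text = "\n".join(lines) + "\nEND\n"

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pdb_path = out_dir / "toy.pdb"
        pdb_path.write_text(pdb_text)
        topology = read_structure(pdb_path)
        trajectory = Trajectory(topology, times, coords, np.tile(box, (n_frames, 1)))
        write_trajectory(trajectory, out_dir / "toy.traj")
        return topology, trajectory

    import tempfile
    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
        fh.write(pdb_text)
        tmp = fh.name
    topology = read_structure(tmp)
    Path(tmp).unlink()
    trajectory = Trajectory(topology, times, coords, np.tile(box, (n_frames, 1)))
    return topology, trajectory


def _random_rotation_small(rng, scale: float) -> np.ndarray:
    v = rng.normal(0, scale, size=3)
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.eye(3)
    k = v / angle
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _pdb_line(serial, name, resname, resseq, xyz, element) -> str:
    return (
        f"ATOM  {serial:>5} {name:<4} {resname:<4}A{resseq:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2}"
    )
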