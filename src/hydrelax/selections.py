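"""Spin-pair enumeration, hydration-layer classification and residence tracking.

Layer criterion (any-atom): a water molecule whose minimum-image distance from
any of its sites to any solute atom is < 3.5 Å belongs to the first hydration
layer; ∈ [3.5, 7.0) Å to the second; otherwise it is unclassified bulk-side
water (layer 0).  The thresholds bracket the first peaks of the water–solute
radial distribution functions for collagen-like peptides.

Pair kinds: ``intra`` joins the two hydrogens of one water, ``inter`` joins
hydrogens of distinct waters within a spherical cutoff, ``pept_H`` joins a
water hydrogen with a solute hydrogen within the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hydrelax.trajectory import Topology, Trajectory, minimum_image_vector

FIRST_LAYER_CUTOFF = 3.5   # Å
SECOND_LAYER_CUTOFF = 7.0  # Å


@dataclass
class SpinPairSet:
    kind: str                       # intra | inter | pept_H
    pairs: np.ndarray               # (n_pairs, 2) atom indices
    selection: str = "all_water"
    cutoff: float | None = None
    molecule_ids: np.ndarray | None = None  # home water molecule per pair

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        key = {tuple(sorted(p)) for p in self.pairs}
        if len(key) != len(self.pairs):
            raise ValueError("duplicate unordered spin pairs")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class ResidenceRecord:
    molecule_id: int
    layers: np.ndarray                       # per-frame layer code 1/2/0
    intervals: list[tuple[float, float]]     # (t_start, t_end) ps, layer-1 runs
    frame_intervals: list[tuple[int, int]] = field(default_factory=list)  # inclusive


def _min_water_peptide_distance(
    water_coords: np.ndarray, peptide_coords: np.ndarray, box: np.ndarray
) -> float:
    d = minimum_image_vector(water_coords[:, None, :], peptide_coords[None, :, :], box)
    return float(np.sqrt(np.einsum("...i,...i->...", d, d)).min())


def hydration_layer(
    water_coords: np.ndarray, peptide_coords: np.ndarray, box: np.ndarray
) -> int:
    """Layer code for one water molecule: 1, 2 or 0 (beyond both shells)."""
    if len(peptide_coords) == 0:
        raise ValueError("empty peptide selection")
    dmin = _min_water_peptide_distance(np.atleast_2d(water_coords), peptide_coords, box)
    if dmin < FIRST_LAYER_CUTOFF:
        return 1
    if dmin < SECOND_LAYER_CUTOFF:
        return 2
    return 0


def layer_series(trajectory: Trajectory, frames: range | None = None) -> dict[int, np.ndarray]:
    """Per-frame layer code for every water molecule (molecule_id → array)."""
    top = trajectory.topology
    pep = top.peptide_atoms()
    waters = top.water_molecules()
    frames = frames if frames is not None else range(trajectory.n_frames)
    out = {mol: np.empty(len(frames), dtype=int) for mol in waters}
    for j, i in enumerate(frames):
        coords = trajectory.coordinates[i]
        box = trajectory.boxes[i]
        pcoords = coords[pep]
        for mol, idx in waters.items():
            out[mol][j] = hydration_layer(coords[idx], pcoords, box)
    return out


def initial_layer_assignment(
    trajectory: Trajectory, frame_index: int = 0
) -> dict[int, int]:
    """Static layer assignment from a single (block-start) frame."""
    if trajectory.n_frames < 1:
        raise ValueError("block must contain at least one frame")
    series = layer_series(trajectory, frames=range(frame_index, frame_index + 1))
    return {mol: int(v[0]) for mol, v in series.items()}


def residence_intervals(trajectory: Trajectory, molecule_id: int) -> ResidenceRecord:
    """Maximal runs of consecutive frames with layer = 1 for one molecule.

    Frame endpoints are inclusive; a single-frame visit yields a zero-length
    interval (usable only for τ = 0).
    """
    series = layer_series(trajectory)[molecule_id]
    return residence_record_from_layers(series, trajectory.times, molecule_id)


def residence_record_from_layers(
    layers: np.ndarray, times: np.ndarray, molecule_id: int = -1
) -> ResidenceRecord:
    layers = np.asarray(layers)
    in1 = layers == 1
    frame_ivals: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(in1):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            frame_ivals.append((start, i - 1))
            start = None
    if start is not None:
        frame_ivals.append((start, len(in1) - 1))
    t_ivals = [(float(times[a]), float(times[b])) for a, b in frame_ivals]
    return ResidenceRecord(molecule_id, layers, t_ivals, frame_ivals)


def enumerate_pairs(
    kind: str,
    topology: Topology,
    reference_coords: np.ndarray,
    box: np.ndarray,
    cutoff: float | None = None,
    selection_molecules: set[int] | None = None,
    selection: str = "all_water",
) -> SpinPairSet:
    """Enumerate ¹H–¹H spin pairs of a given kind at reference coordinates.

    ``inter`` and ``pept_H`` require a spherical cutoff on the minimum-image
    H–H distance (membership frozen at the reference frame, e.g. the block
    start); ``intra`` takes exactly one pair per water and ignores the cutoff.
    ``selection_molecules`` restricts the home water molecule; for ``inter``
    a pair is kept if either member water belongs to the selection.
    """
    box = np.asarray(box, dtype=float)
    if kind in ("inter", "pept_H"):
        if cutoff is None:
            raise ValueError(f"kind={kind!r} requires a cutoff")
        if cutoff > box.min() / 2.0:
            raise ValueError(
                f"cutoff {cutoff} Å exceeds half the smallest box edge "
                f"({box.min() / 2:.2f} Å); minimum image invalid"
            )
    water_h = topology.water_hydrogens()
    mols = sorted(water_h)
    in_sel = (lambda m: True) if selection_molecules is None else (
        lambda m: m in selection_molecules
    )

    pairs: list[tuple[int, int]] = []
    home: list[int] = []
    if kind == "intra":
        for mol in mols:
            if in_sel(mol):
                h = water_h[mol]
                pairs.append((int(h[0]), int(h[1])))
                home.append(mol)
    elif kind == "inter":
        h_idx = np.array([i for mol in mols for i in water_h[mol]])
        h_mol = np.array([mol for mol in mols for _ in water_h[mol]])
        coords = reference_coords[h_idx]
        for a in range(len(h_idx)):
            d = minimum_image_vector(coords[a], coords[a + 1:], box)
            dist = np.sqrt(np.einsum("ij,ij->i", d, d))
            for off in np.nonzero(dist < cutoff)[0]:
                b = a + 1 + off
                if h_mol[a] == h_mol[b]:
                    continue
                if in_sel(int(h_mol[a])) or in_sel(int(h_mol[b])):
                    pairs.append((int(h_idx[a]), int(h_idx[b])))
                    home.append(int(h_mol[a]) if in_sel(int(h_mol[a])) else int(h_mol[b]))
    elif kind == "pept_H":
        pep_h = topology.peptide_hydrogens()
        for mol in mols:
            if not in_sel(mol):
                continue
            for hw in water_h[mol]:
                d = minimum_image_vector(reference_coords[hw], reference_coords[pep_h], box)
                dist = np.sqrt(np.einsum("ij,ij->i", d, d))
                for j in np.nonzero(dist < cutoff)[0]:
                    pairs.append((int(hw), int(pep_h[j])))
                    home.append(mol)
    else:
        raise ValueError(f"unknown pair kind {kind!r}")

    return SpinPairSet(
        kind=kind,
        pairs=np.array(pairs, dtype=int).reshape(-1, 2),
        selection=selection,
        cutoff=None if kind == "intra" else cutoff,
        molecule_ids=np.array(home, dtype=int),
    )


def pair_vectors(
    trajectory: Trajectory, pair_set: SpinPairSet, frames: range | None = None
) -> np.ndarray:
    """Minimum-image H–H displacement vectors (n_frames, n_pairs, 3) in Å."""
    frames = frames if frames is not None else range(trajectory.n_frames)
    out = np.empty((len(frames), pair_set.n_pairs, 3))
    a = pair_set.pairs[:, 0]
    b = pair_set.pairs[:, 1]
    for j, i in enumerate(frames):
        coords = trajectory.coordinates[i]
        out[j] = minimum_image_vector(coords[a], coords[b], trajectory.boxes[i])
    return out
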