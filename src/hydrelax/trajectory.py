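"""Structure/trajectory data model, readers and periodic-boundary geometry.

Units are Å for lengths, ps for times and amu for masses throughout.  Only
orthorhombic boxes are supported.  Water is identified by a residue-name
whitelist and must carry exactly two hydrogens per molecule (3-site or rigid
4-site models; the virtual 4th site is read, assigned zero mass and ignored by
all analysis stages).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

WATER_RESIDUES = ("HOH", "WAT", "TIP4", "SPC", "TIP3", "SOL", "T4P")

#: residue names assigned to the solute without a warning
_PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HYP",
    "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR",
    "VAL", "ROD",
}

_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "F": 18.998, "CL": 35.45, "NA": 22.99,
    "K": 39.098, "MG": 24.305, "CA": 40.078, "FE": 55.845,
    # virtual / massless interaction sites of 4-site waters
    "M": 0.0, "EP": 0.0, "X": 0.0,
}


class StructureParseError(ValueError):
    """Raised when a structure file record cannot be parsed."""


@dataclass
class Topology:
    """Atom table with molecule grouping.

    group is ``"water"`` or ``"peptide"``; molecule ids are dense integers,
    one per residue.
    """

    elements: list[str]
    masses: np.ndarray           # amu
    residue_ids: np.ndarray
    molecule_ids: np.ndarray
    groups: np.ndarray           # array of "water"/"peptide"
    atom_names: list[str] = field(default_factory=list)
    residue_names: list[str] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def water_molecules(self) -> dict[int, np.ndarray]:
        """Map molecule_id -> atom indices for each water molecule."""
        out: dict[int, np.ndarray] = {}
        water = self.groups == "water"
        for mol in np.unique(self.molecule_ids[water]):
            out[int(mol)] = np.nonzero(self.molecule_ids == mol)[0]
        return out

    def water_hydrogens(self) -> dict[int, np.ndarray]:
        """Map water molecule_id -> its two hydrogen atom indices."""
        out = {}
        for mol, idx in self.water_molecules().items():
            h = idx[[self.elements[i] == "H" for i in idx]]
            out[mol] = h
        return out

    def peptide_atoms(self) -> np.ndarray:
        return np.nonzero(self.groups == "peptide")[0]

    def peptide_hydrogens(self) -> np.ndarray:
        pep = self.peptide_atoms()
        return pep[[self.elements[i] == "H" for i in pep]]

    def validate_waters(self) -> None:
        for mol, idx in self.water_molecules().items():
            if len(idx) not in (3, 4):
                raise ValueError(
                    f"water molecule {mol} has {len(idx)} sites; expected 3 or 4"
                )
            n_h = sum(self.elements[i] == "H" for i in idx)
            if n_h != 2:
                raise ValueError(
                    f"water molecule {mol} has {n_h} hydrogens; expected exactly 2"
                )


@dataclass
class Frame:
    time: float                # ps
    coordinates: np.ndarray    # (n_atoms, 3) Å
    box: np.ndarray            # (3,) orthorhombic edges, Å

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates in frame")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive orthorhombic edge lengths")


@dataclass
class Trajectory:
    topology: Topology
    times: np.ndarray          # (n_frames,) ps
    coordinates: np.ndarray    # (n_frames, n_atoms, 3) Å
    boxes: np.ndarray          # (n_frames, 3) Å
    time_tolerance: float = 1e-6

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.n_frames > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > self.time_tolerance:
                raise ValueError("frame times must be evenly spaced")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def sampling_interval(self) -> float:
        """ps between consecutive frames (0.1 ps = 100 fs default in practice)."""
        if self.n_frames < 2:
            raise ValueError("sampling interval undefined for a single frame")
        return float(self.times[1] - self.times[0])

    def frame(self, i: int) -> Frame:
        return Frame(self.times[i], self.coordinates[i], self.boxes[i])


def _element_from_record(name: str, element_field: str) -> str:
    el = element_field.strip().upper()
    if not el:
        stripped = name.strip().lstrip("0123456789")
        el = stripped[:2].upper() if stripped[:2].upper() in _MASSES else stripped[:1].upper()
    if el in ("EPW", "MW", "EP", "M", "LP"):
        return "M"
    return el


def read_structure(path: str | Path, water_residues: tuple[str, ...] = WATER_RESIDUES) -> Topology:
    """Parse a PDB file into a :class:`Topology`.

    Atoms are grouped into molecules by residue; residues on the water
    whitelist form water molecules, everything else is assigned to the solute
    ("peptide") group — with a warning for residue names outside the standard
    amino-acid set.  Unparseable ATOM records raise with the offending line
    number.
    """
    path = Path(path)
    elements, names, resnames = [], [], []
    res_keys: list[tuple[str, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise StructureParseError(
                    f"{path.name}:{lineno}: truncated ATOM record (needs coordinate columns)"
                )
            try:
                name = line[12:16]
                resname = line[17:21].strip()
                chain = line[21]
                resseq = int(line[22:26])
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError as exc:
                raise StructureParseError(
                    f"{path.name}:{lineno}: unparseable ATOM record: {exc}"
                ) from None
            element = _element_from_record(name, line[76:78] if len(line) >= 78 else "")
            elements.append(element)
            names.append(name.strip())
            resnames.append(resname)
            res_keys.append((chain, resseq, resname))
    if not elements:
        raise StructureParseError(f"{path.name}: no ATOM/HETATM records found")

    mol_ids = np.empty(len(elements), dtype=int)
    seen: dict[tuple, int] = {}
    for i, key in enumerate(res_keys):
        if key not in seen:
            seen[key] = len(seen)
        mol_ids[i] = seen[key]

    groups = np.empty(len(elements), dtype=object)
    warned: set[str] = set()
    for i, rn in enumerate(resnames):
        if rn.upper() in water_residues:
            groups[i] = "water"
        else:
            groups[i] = "peptide"
            if rn.upper() not in _PROTEIN_RESIDUES and rn not in warned:
                warnings.warn(f"unknown residue name {rn!r}: assigned to group 'peptide'")
                warned.add(rn)

    masses = np.array([_MASSES.get(el, 0.0) for el in elements])
    for i, el in enumerate(elements):
        if el not in _MASSES:
            warnings.warn(f"unknown element {el!r} for atom {i}; mass set to 0")

    top = Topology(
        elements=elements,
        masses=masses,
        residue_ids=np.array([k[1] for k in res_keys]),
        molecule_ids=mol_ids,
        groups=groups,
        atom_names=names,
        residue_names=resnames,
    )
    top.validate_waters()
    return top


# ---------------------------------------------------------------------------
# plain-text trajectory format
#
#   line 1:            <natoms> <dt_ps>
#   per frame:         <time_ps>
#                      <Lx> <Ly> <Lz>
#                      natoms lines of  x y z   (Å, 1e-3 Å precision)
# ---------------------------------------------------------------------------

def _read_text_trajectory(path: Path, n_atoms_expected: int):
    with open(path) as fh:
        header = fh.readline().split()
        n_atoms, _dt = int(header[0]), float(header[1])
        if n_atoms != n_atoms_expected:
            raise ValueError(
                f"trajectory atom count {n_atoms} does not match topology ({n_atoms_expected})"
            )
        times, coords, boxes = [], [], []
        while True:
            line = fh.readline()
            if not line.strip():
                break
            times.append(float(line))
            boxes.append([float(x) for x in fh.readline().split()])
            xyz = np.empty((n_atoms, 3))
            for i in range(n_atoms):
                row = fh.readline().split()
                if len(row) < 3:
                    raise ValueError(
                        f"frame {len(times) - 1}: expected {n_atoms} coordinate rows, "
                        f"got {i}"
                    )
                xyz[i] = [float(x) for x in row[:3]]
            coords.append(xyz)
    return np.array(times), np.array(coords), np.array(boxes)


def _read_dcd_trajectory(path: Path, n_atoms_expected: int, dt_ps: float | None):
    from MDAnalysis.coordinates.DCD import DCDReader

    reader = DCDReader(str(path))
    if reader.n_atoms != n_atoms_expected:
        raise ValueError(
            f"trajectory atom count {reader.n_atoms} does not match topology "
            f"({n_atoms_expected})"
        )
    times, coords, boxes = [], [], []
    for ts in reader:
        times.append(ts.time)
        coords.append(ts.positions.copy())
        boxes.append(ts.dimensions[:3].copy())
    times = np.asarray(times, dtype=float)
    if dt_ps is not None:
        times = np.arange(len(times)) * dt_ps
    return times, np.array(coords, dtype=float), np.array(boxes, dtype=float)


def read_trajectory(path: str | Path, topology: Topology, dt_ps: float | None = None) -> Trajectory:
    """Read coordinate frames (plain-text ``.traj``/``.txt`` or binary DCD).

    The sampling interval is inferred from the first two frame times; for DCD
    files an explicit ``dt_ps`` overrides the (often unit-ambiguous) embedded
    timestamps.
    """
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        times, coords, boxes = _read_dcd_trajectory(path, topology.n_atoms, dt_ps)
    else:
        times, coords, boxes = _read_text_trajectory(path, topology.n_atoms)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("non-monotonic frame times")
    return Trajectory(topology, times, coords, boxes)


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write the plain-text trajectory format (1e-3 Å round-trip precision)."""
    path = Path(path)
    dt = trajectory.sampling_interval if trajectory.n_frames > 1 else 0.0
    with open(path, "w") as fh:
        fh.write(f"{trajectory.topology.n_atoms} {dt:.6f}\n")
        for i in range(trajectory.n_frames):
            fh.write(f"{trajectory.times[i]:.6f}\n")
            fh.write(" ".join(f"{x:.4f}" for x in trajectory.boxes[i]) + "\n")
            for row in trajectory.coordinates[i]:
                fh.write(f"{row[0]:.4f} {row[1]:.4f} {row[2]:.4f}\n")


def minimum_image_vector(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement from ``a`` to ``b`` in an orthorhombic box.

    Each component lies in (−L/2, L/2]; broadcasts over leading axes.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    half = box / 2.0
    return half - np.mod(half - d, box)


def unwrap_group(coordinates: np.ndarray, box: np.ndarray, reference_index: int = 0) -> np.ndarray:
    """Re-join a molecule split across periodic boundaries.

    Every atom is placed at its minimum image relative to ``reference_index``.
    Adequate for solutes smaller than half the box in each direction.
    """
    ref = coordinates[..., reference_index, :][..., None, :]
    return ref + minimum_image_vector(ref, coordinates, box)
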