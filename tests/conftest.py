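import numpy as np
import pytest

from hydrelax.synthetic import RotorEnsembleSpec, build_toy_system, simulate_free_rotor


@pytest.fixture(scope="session")
def small_free_rotor():
    """A modest free-rotor ensemble reused across tests (τ_c ≈ 2.45 ps)."""
    spec = RotorEnsembleSpec(n_vectors=200, D_r=0.068, dt=0.02, n_steps=10_000, seed=11)
    return spec, simulate_free_rotor(spec)


@pytest.fixture(scope="session")
def toy_system(tmp_path_factory):
    out = tmp_path_factory.mktemp("toy")
    topology, trajectory = build_toy_system(
        n_free=6, n_tethered=3, rod_length=20.0, n_frames=60, dt=0.1, seed=3,
        out_dir=out,
    )
    return topology, trajectory, out


def make_pdb(text: str, tmp_path, name="test.pdb"):
    p = tmp_path / name
    p.write_text(text)
    return p


def pdb_atom(serial, name, resname, resseq, x, y, z, element):
    return (
        f"ATOM  {serial:>5} {name:<4} {resname:<4}A{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}"
    )


@pytest.fixture
def three_waters_pdb(tmp_path):
    lines = []
    s = 1
    for i in range(3):
        x = 5.0 * i
        lines.append(pdb_atom(s, "O", "HOH", i + 1, x, 0, 0, "O")); s += 1
        lines.append(pdb_atom(s, "H1", "HOH", i + 1, x + 0.76, 0.59, 0, "H")); s += 1
        lines.append(pdb_atom(s, "H2", "HOH", i + 1, x - 0.76, 0.59, 0, "H")); s += 1
    return make_pdb("\n".join(lines) + "\nEND\n", tmp_path, name="waters.pdb")


@pytest.fixture
def gly_water_pdb(tmp_path):
    lines = [
        pdb_atom(1, "N", "GLY", 1, 0, 0, 0, "N"),
        pdb_atom(2, "H", "GLY", 1, 0.5, 0.8, 0, "H"),
        pdb_atom(3, "CA", "GLY", 1, 1.4, 0, 0, "C"),
        pdb_atom(4, "C", "GLY", 1, 2.2, 1.2, 0, "C"),
        pdb_atom(5, "O", "GLY", 1, 3.4, 1.2, 0, "O"),
        pdb_atom(6, "O", "HOH", 2, 8, 0, 0, "O"),
        pdb_atom(7, "H1", "HOH", 2, 8.76, 0.59, 0, "H"),
        pdb_atom(8, "H2", "HOH", 2, 7.24, 0.59, 0, "H"),
    ]
    return make_pdb("\n".join(lines) + "\nEND\n", tmp_path, name="gly_water.pdb")


def exponential_tcf(amplitudes, timescales, tau):
    amplitudes = np.asarray(amplitudes, dtype=float)
    timescales = np.asarray(timescales, dtype=float)
    return np.sum(
        amplitudes[:, None] * np.exp(-tau[None, :] / timescales[:, None]), axis=0
    )
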