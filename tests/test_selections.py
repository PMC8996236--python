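import numpy as np
import pytest

from hydrelax.selections import (
    SpinPairSet,
    enumerate_pairs,
    hydration_layer,
    initial_layer_assignment,
    layer_series,
    residence_intervals,
    residence_record_from_layers,
)
from hydrelax.trajectory import Trajectory, read_structure

BOX = np.array([40.0, 40.0, 40.0])


def water_at(origin):
    """3-site water geometry placed with its O at `origin`."""
    geom = np.array([[0, 0, 0], [0.757, 0.586, 0], [-0.757, 0.586, 0.0]])
    return geom + np.asarray(origin, dtype=float)


class TestHydrationLayer:
    peptide = np.array([[20.0, 20.0, 20.0]])

    @pytest.mark.parametrize("dist,layer", [(3.0, 1), (5.0, 2), (8.0, 0), (3.49, 1), (6.99, 2)])
    def test_threshold_classification(self, dist, layer):
        w = water_at([20.0 + dist, 19.414, 20.0])  # O–H geometry shifts min distance
        # place so the *minimum* distance over water sites equals dist: use O only
        w = np.array([[20.0 + dist, 20.0, 20.0]])
        assert hydration_layer(w, self.peptide, BOX) == layer

    def test_any_atom_criterion_uses_closest_site(self):
        # O beyond 3.5 Å but one H within
        w = np.array([[24.2, 20, 20], [23.2, 20, 20], [24.9, 20, 20.0]])
        assert hydration_layer(w, self.peptide, BOX) == 1

    def test_periodic_image_counts(self):
        w = np.array([[1.0, 20.0, 20.0]])
        pep = np.array([[38.5, 20.0, 20.0]])
        assert hydration_layer(w, pep, BOX) == 1  # 2.5 Å across the boundary

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValueError):
            hydration_layer(np.zeros((1, 3)), np.zeros((0, 3)), BOX)

    def test_partition_is_exhaustive(self, toy_system):
        _, traj, _ = toy_system
        series = layer_series(traj, frames=range(3))
        for s in series.values():
            assert set(np.unique(s)) <= {0, 1, 2}


class TestStaticAssignment:
    def _traj_with_moving_water(self, tmp_path):
        from conftest import make_pdb, pdb_atom

        lines = [pdb_atom(1, "C", "ROD", 1, 20, 20, 20, "C"),
                 pdb_atom(2, "C", "ROD", 1, 21, 20, 20, "C")]
        s = 3
        for j, w in enumerate([water_at([23, 20, 20])]):
            for nm, el, xyz in zip(["O", "H1", "H2"], ["O", "H", "H"], w):
                lines.append(pdb_atom(s, nm, "HOH", 2 + j, *xyz, el)); s += 1
        top = read_structure(make_pdb("\n".join(lines), tmp_path, "move.pdb"))
        coords = np.empty((4, top.n_atoms, 3))
        for f in range(4):
            coords[f, :2] = [[20, 20, 20], [21, 20, 20]]
            coords[f, 2:] = water_at([23 + 4 * f, 20, 20])  # drifts out of layer 1
        return Trajectory(top, np.arange(4) * 0.1, coords, np.tile(BOX, (4, 1)))

    def test_assignment_from_first_frame_only(self, tmp_path):
        traj = self._traj_with_moving_water(tmp_path)
        assign = initial_layer_assignment(traj, 0)
        (layer,) = assign.values()
        assert layer == 1  # still 1 even though the molecule leaves later

    def test_different_reference_frames_differ(self, tmp_path):
        traj = self._traj_with_moving_water(tmp_path)
        later = initial_layer_assignment(traj, 3)
        (layer,) = later.values()
        assert layer == 0

    def test_all_bulk_toy_gives_empty_first_layer(self, tmp_path):
        traj = self._traj_with_moving_water(tmp_path)
        assign = initial_layer_assignment(traj, 2)  # at 11 Å: beyond both shells
        assert 1 not in assign.values()


class TestResidenceIntervals:
    def test_series_1101_pattern(self):
        times = np.arange(4) * 0.1
        rec = residence_record_from_layers([1, 1, 0, 1], times)
        assert rec.intervals == [(0.0, 0.1), pytest.approx((0.30000000000000004, 0.30000000000000004))]
        assert rec.frame_intervals == [(0, 1), (3, 3)]

    def test_always_resident_single_full_interval(self):
        rec = residence_record_from_layers([1] * 7, np.arange(7) * 0.5)
        assert rec.frame_intervals == [(0, 6)]
        assert rec.intervals == [(0.0, 3.0)]

    def test_never_resident_empty(self):
        rec = residence_record_from_layers([0, 2, 0], np.arange(3) * 0.1)
        assert rec.intervals == []

    def test_trajectory_level_api(self, toy_system):
        _, traj, _ = toy_system
        layers = layer_series(traj)
        tethered = [m for m, s in layers.items() if np.all(s == 1)]
        assert tethered, "toy system should keep tethered waters in layer 1"
        rec = residence_intervals(traj, tethered[0])
        assert rec.frame_intervals == [(0, traj.n_frames - 1)]


class TestEnumeratePairs:
    def _two_water_topology(self, tmp_path, sep=3.0):
        from conftest import make_pdb, pdb_atom

        lines = []
        s = 1
        for j, origin in enumerate([[10, 10, 10], [10 + sep, 10, 10]]):
            for nm, el, xyz in zip(["O", "H1", "H2"], ["O", "H", "H"], water_at(origin)):
                lines.append(pdb_atom(s, nm, "HOH", j + 1, *xyz, el)); s += 1
        top = read_structure(make_pdb("\n".join(lines), tmp_path, "two.pdb"))
        coords = np.array([water_at([10, 10, 10]), water_at([10 + sep, 10, 10])]).reshape(6, 3)
        return top, coords

    def test_intra_and_inter_combinatorics(self, tmp_path):
        top, coords = self._two_water_topology(tmp_path)
        intra = enumerate_pairs("intra", top, coords, BOX)
        assert intra.n_pairs == 2
        inter = enumerate_pairs("inter", top, coords, BOX, cutoff=10.0)
        assert inter.n_pairs == 4
        all_pairs = {tuple(sorted(p)) for p in np.vstack([intra.pairs, inter.pairs])}
        assert len(all_pairs) == 6

    def test_zero_cutoff_no_inter_pairs(self, tmp_path):
        top, coords = self._two_water_topology(tmp_path)
        inter = enumerate_pairs("inter", top, coords, BOX, cutoff=1e-9)
        assert inter.n_pairs == 0

    def test_pept_h_pairs(self, tmp_path):
        from conftest import make_pdb, pdb_atom

        lines = [pdb_atom(1, "CA", "GLY", 1, 12, 10, 10, "C"),
                 pdb_atom(2, "H1", "GLY", 1, 13, 10, 10, "H"),
                 pdb_atom(3, "H2", "GLY", 1, 11, 11, 10, "H")]
        s = 4
        for nm, el, xyz in zip(["O", "H1", "H2"], ["O", "H", "H"], water_at([10, 10, 10])):
            lines.append(pdb_atom(s, nm, "HOH", 2, *xyz, el)); s += 1
        top = read_structure(make_pdb("\n".join(lines), tmp_path, "pep.pdb"))
        coords = np.vstack([[[12, 10, 10], [13, 10, 10], [11, 11, 10]], water_at([10, 10, 10])])
        ph = enumerate_pairs("pept_H", top, coords, BOX, cutoff=10.0)
        assert ph.n_pairs == 4  # 2 water H × 2 peptide H

    def test_cutoff_beyond_half_box_rejected(self, tmp_path):
        top, coords = self._two_water_topology(tmp_path)
        with pytest.raises(ValueError, match="half the smallest box edge"):
            enumerate_pairs("inter", top, coords, BOX, cutoff=25.0)

    def test_missing_cutoff_rejected(self, tmp_path):
        top, coords = self._two_water_topology(tmp_path)
        with pytest.raises(ValueError, match="cutoff"):
            enumerate_pairs("inter", top, coords, BOX)

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SpinPairSet(kind="inter", pairs=np.array([[1, 2], [2, 1]]))
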