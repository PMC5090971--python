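"""Void detection: occupancy gridding, periodic flood fill vs a
brute-force oracle, per-void statistics, and permeant adjacency."""

import numpy as np
import pytest

from fracperm.synth import AtomicConfiguration, packing_with_cavity
from fracperm.voids import (OccupancyGrid, empty_fraction_profile,
                            flood_fill_voids, mark_occupancy,
                            permeant_adjacent_void, void_statistics)


def _grid_from_bool(occ, spacing=0.5):
    occ = np.asarray(occ, bool)
    sp = np.full(3, spacing)
    return OccupancyGrid(occ, sp, sp * np.array(occ.shape))


def brute_force_components(empty):
    """Reference flood fill: BFS over 26-neighbourhoods with wrapping."""
    shape = empty.shape
    labels = np.zeros(shape, int)
    nxt = 0
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    for start in zip(*np.nonzero(empty & (labels == 0))):
        if labels[start]:
            continue
        nxt += 1
        stack = [start]
        labels[start] = nxt
        while stack:
            a, b, c = stack.pop()
            for di, dj, dk in offsets:
                p = ((a + di) % shape[0], (b + dj) % shape[1],
                     (c + dk) % shape[2])
                if empty[p] and not labels[p]:
                    labels[p] = nxt
                    stack.append(p)
    return labels, nxt


class TestOccupancy:
    def test_empty_cell_all_empty(self):
        cfg = AtomicConfiguration(np.empty((0, 3)), [], {"X": 1.0},
                                  (10, 10, 10))
        g = mark_occupancy(cfg)
        assert not g.occupied.any()

    def test_single_sphere_volume(self):
        """Occupied volume ≈ (4/3)π(2+1.5)³ = 179.6 Å³ at 0.5 Å voxels."""
        cfg = AtomicConfiguration([[15.0, 15.0, 15.0]], ["X"], {"X": 2.0},
                                  (30, 30, 30))
        g = mark_occupancy(cfg, probe_radius=1.5, spacing=0.5)
        vol = g.occupied.sum() * g.voxel_volume
        R = 3.5
        shell = 4 * np.pi * R ** 2 * 0.5  # one voxel-shell tolerance
        assert abs(vol - 4 / 3 * np.pi * R ** 3) < shell

    def test_periodic_translation_invariance(self):
        """An atom shifted across the cell face by a voxel multiple marks
        the same number of voxels."""
        base = AtomicConfiguration([[15.0, 15.0, 15.0]], ["X"], {"X": 2.0},
                                   (30, 30, 30))
        shifted = AtomicConfiguration([[-0.5, 15.0, 15.0]], ["X"],
                                      {"X": 2.0}, (30, 30, 30))
        n1 = mark_occupancy(base).occupied.sum()
        n2 = mark_occupancy(shifted).occupied.sum()
        assert n1 == n2

    def test_hydrogens_skipped_by_default(self):
        cfg = AtomicConfiguration([[5.0, 5.0, 5.0]], ["H"], {"H": 1.0},
                                  (10, 10, 10))
        assert not mark_occupancy(cfg).occupied.any()
        assert mark_occupancy(cfg, include_hydrogens=True).occupied.any()

    def test_unknown_type_errors(self):
        cfg = AtomicConfiguration([[5.0, 5.0, 5.0]], ["Q"], {"X": 1.0},
                                  (10, 10, 10))
        with pytest.raises(KeyError):
            mark_occupancy(cfg)


class TestFloodFill:
    def test_fully_empty_grid_single_void(self):
        lab = flood_fill_voids(_grid_from_bool(np.zeros((8, 8, 8))))
        assert lab.n_voids == 1
        assert lab.stats[0]["voxels"] == 512

    def test_two_separated_cavities(self):
        occ = np.ones((20, 20, 20), bool)
        occ[2:5, 2:5, 2:5] = False
        occ[10:14, 10:14, 10:14] = False
        lab = flood_fill_voids(_grid_from_bool(occ))
        assert lab.n_voids == 2
        assert sorted(s["voxels"] for s in lab.stats) == [27, 64]

    def test_cavity_wrapping_periodic_face_is_one_void(self):
        occ = np.ones((20, 20, 20), bool)
        occ[0:2, 5, 5] = False
        occ[18:20, 5, 5] = False
        assert flood_fill_voids(_grid_from_bool(occ)).n_voids == 1

    def test_agrees_with_brute_force_on_random_grids(self):
        """Exact match of component count and sizes on 25 random ≤20³
        periodic grids."""
        rng = np.random.default_rng(42)
        for trial in range(25):
            shape = tuple(rng.integers(4, 21, 3))
            occ = rng.uniform(size=shape) < rng.uniform(0.3, 0.8)
            lab = flood_fill_voids(_grid_from_bool(occ))
            ref_labels, ref_n = brute_force_components(~occ)
            assert lab.n_voids == ref_n
            sizes = sorted(s["voxels"] for s in lab.stats)
            ref_sizes = sorted(np.bincount(ref_labels.ravel())[1:].tolist())
            assert sizes == ref_sizes
            # identical partitions: same label map up to renaming
            if ref_n:
                pairs = set(zip(lab.labels.ravel(), ref_labels.ravel()))
                assert len(pairs) == ref_n + (1 if (occ).any() else 0)

    def test_total_empty_volume_partitioned(self):
        rng = np.random.default_rng(1)
        occ = rng.uniform(size=(15, 15, 15)) < 0.6
        grid = _grid_from_bool(occ)
        lab = flood_fill_voids(grid)
        total = sum(s["volume"] for s in lab.stats)
        assert total == pytest.approx((~occ).sum() * grid.voxel_volume)

    def test_deterministic_label_order(self):
        occ = np.ones((10, 10, 10), bool)
        occ[1:3, 1:3, 1:3] = False      # 8 voxels
        occ[6:9, 6:9, 6:9] = False      # 27 voxels
        lab = flood_fill_voids(_grid_from_bool(occ))
        assert [s["voxels"] for s in lab.stats] == [27, 8]


class TestVoidStatistics:
    def test_single_voxel_sigma_z_zero(self):
        occ = np.ones((10, 10, 10), bool)
        occ[4, 4, 4] = False
        lab = flood_fill_voids(_grid_from_bool(occ))
        assert lab.stats[0]["sigma_z"] == 0.0

    def test_slab_sigma_z_closed_form(self):
        """10-voxel slab along z at 0.5 Å: population std of the centre
        set {0.25, 0.75, ..., 4.75} ≈ 1.44 Å."""
        occ = np.ones((20, 20, 20), bool)
        occ[:, :, 0:10] = False
        lab = flood_fill_voids(_grid_from_bool(occ))
        expect = np.std((np.arange(10) + 0.5) * 0.5)
        assert lab.stats[0]["sigma_z"] == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(1.44, abs=0.01)

    def test_wrapped_void_same_sigma_as_translate(self):
        occ1 = np.ones((20, 20, 20), bool)
        occ1[5, 5, 4:12] = False  # contiguous slab
        occ2 = np.ones((20, 20, 20), bool)
        occ2[5, 5, 16:20] = False  # same slab wrapped across z face
        occ2[5, 5, 0:4] = False
        s1 = flood_fill_voids(_grid_from_bool(occ1)).stats[0]["sigma_z"]
        s2 = flood_fill_voids(_grid_from_bool(occ2)).stats[0]["sigma_z"]
        assert s1 == pytest.approx(s2, rel=1e-12)


class TestEmptyFraction:
    def test_all_empty(self):
        prof = empty_fraction_profile(
            flood_fill_voids(_grid_from_bool(np.zeros((8, 8, 8)))))
        np.testing.assert_allclose(prof.values, 1.0)

    def test_planted_cavity_peaks_at_cavity_z(self):
        conf = packing_with_cavity(cell=(30, 30, 30), n_atoms=1000,
                                   radius=1.2, cavity_center=(15, 15, 10),
                                   cavity_radius=3.0, seed=5)
        lab = flood_fill_voids(mark_occupancy(conf))
        prof = empty_fraction_profile(lab, z_bin_width=1.0)
        assert abs(prof.z[np.argmax(prof.values)] - 10.0) <= 1.0


class TestPermeantAdjacency:
    @pytest.fixture(scope="class")
    @staticmethod
    def packed_with_permeant():
        conf = packing_with_cavity(cell=(30, 30, 30), n_atoms=1000,
                                   radius=1.2, cavity_center=(15, 15, 15),
                                   cavity_radius=3.0, seed=2)
        coords = np.vstack([conf.coords, [15.0, 15.0, 10.5]])
        types = conf.types + ["P"]
        radii = dict(conf.radii, P=1.0)
        return AtomicConfiguration(coords, types, radii, conf.cell)

    def test_adjacent_cavity_volume_recovered(self, packed_with_permeant):
        """A permeant beside a planted ~113 Å³ cavity reports it (within
        the documented grid/probe tolerance)."""
        v = permeant_adjacent_void(packed_with_permeant,
                                   [packed_with_permeant.n_atoms - 1])
        assert v == pytest.approx(4 / 3 * np.pi * 27, rel=0.4)

    def test_fully_packed_surroundings_report_zero(self):
        conf = packing_with_cavity(cell=(20, 20, 20), n_atoms=300,
                                   radius=1.2, seed=6)
        # permeant at an arbitrary position; dense background packing has
        # no void within reach of the probe-inflated permeant
        coords = np.vstack([conf.coords, [10.0, 10.0, 10.0]])
        cfg = AtomicConfiguration(coords, conf.types + ["P"],
                                  dict(conf.radii, P=0.2), conf.cell)
        v = permeant_adjacent_void(cfg, [cfg.n_atoms - 1])
        assert v < 30.0

    def test_empty_selection_rejected(self, packed_with_permeant):
        with pytest.raises(ValueError):
            permeant_adjacent_void(packed_with_permeant, [])


class TestTranslationInvariance:
    def test_volumes_stable_under_rigid_shift(self):
        conf = packing_with_cavity(cell=(24, 24, 24), n_atoms=500,
                                   radius=1.2, cavity_center=(12, 12, 12),
                                   cavity_radius=2.5, seed=8)
        lab1 = flood_fill_voids(mark_occupancy(conf))
        shifted = AtomicConfiguration(conf.coords + 3.0, conf.types,
                                      conf.radii, conf.cell)
        lab2 = flood_fill_voids(mark_occupancy(shifted))
        v1 = max(s["volume"] for s in lab1.stats)
        v2 = max(s["volume"] for s in lab2.stats)
        R = (3 * v1 / (4 * np.pi)) ** (1 / 3)
        shell = 4 * np.pi * R ** 2 * 0.5
        assert abs(v1 - v2) < shell
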