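"""Segmentation, solidity, gating, intensities, and generic image operators."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from polcond.lattice import LatticeState, Species
from polcond.morphology import (
    ClusterRecord,
    GateSpec,
    compute_solidity,
    correlate_rc_morphology,
    distance_enrichment,
    gate_clusters,
    gates_from_population,
    gaussian_background_subtract,
    make_fixture_image,
    otsu_threshold,
    phase_concentrations,
    quantify_clusters,
    robust_background_threshold,
    segment_clusters,
)
from polcond.render import SyntheticImage


def raster_with(blocks, shape=(32, 32), value=1.0):
    r = np.zeros(shape)
    for (y0, y1, x0, x1) in blocks:
        r[y0:y1, x0:x1] = value
    return r


class TestSegmentClusters:
    def test_uniform_below_threshold(self):
        assert segment_clusters(np.full((20, 20), 0.2)) == []

    def test_single_block(self):
        r = raster_with([(5, 8, 5, 9)])     # 3x4 block
        masks = segment_clusters(r, min_size=10)
        assert len(masks) == 1
        assert masks[0].sum() == 12

    def test_diagonal_merge_depends_on_connectivity(self):
        r = raster_with([(2, 6, 2, 6), (6, 10, 6, 10)])  # touch at a corner
        assert len(segment_clusters(r, connectivity=8)) == 1
        assert len(segment_clusters(r, connectivity=4)) == 2

    def test_min_size_exclusion(self):
        r = raster_with([(2, 5, 2, 5), (20, 22, 20, 22)])  # areas 9 and 4
        assert segment_clusters(r, min_size=10) == []
        assert len(segment_clusters(r, min_size=4)) == 2

    def test_partition_property(self):
        r = raster_with([(2, 8, 2, 8), (15, 25, 15, 25), (28, 30, 28, 30)])
        masks = segment_clusters(r, min_size=10)
        total_super = int((r >= 0.35).sum())
        assert sum(int(m.sum()) for m in masks) == total_super - 4
        stacked = np.sum(masks, axis=0)
        assert stacked.max() <= 1    # masks are disjoint

    def test_nonfinite_rejected(self):
        r = np.zeros((5, 5))
        r[2, 2] = np.nan
        with pytest.raises(ValueError):
            segment_clusters(r)


class TestSolidity:
    def test_filled_rectangle(self):
        pixels = [(y, x) for y in range(3) for x in range(5)]
        assert compute_solidity(np.array(pixels)) == pytest.approx(1.0)

    def test_l_shape(self):
        pixels = [(0, 0), (1, 0), (2, 0), (2, 1), (2, 2)]
        assert compute_solidity(np.array(pixels)) == pytest.approx(5 / 6)

    def test_ring(self):
        pixels = [(y, x) for y in range(3) for x in range(3)
                  if not (y == 1 and x == 1)]
        assert compute_solidity(np.array(pixels)) == pytest.approx(8 / 9)

    def test_degenerate_line(self):
        assert compute_solidity(np.array([(0, i) for i in range(6)])) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_solidity(np.empty((0, 2)))

    def test_boolean_mask_input(self):
        mask = np.zeros((6, 6), bool)
        mask[1:4, 1:5] = True
        assert compute_solidity(mask) == pytest.approx(1.0)

    def test_scale_consistency(self):
        # L with 6-px arms; pixel replication must barely change solidity
        pixels = np.array([(i, 0) for i in range(6)]
                          + [(5, j) for j in range(1, 6)])
        doubled = []
        for y, x in pixels:
            for dy in (0, 1):
                for dx in (0, 1):
                    doubled.append((2 * y + dy, 2 * x + dx))
        s1 = compute_solidity(pixels)
        s2 = compute_solidity(np.array(doubled))
        assert abs(s1 - s2) < 0.05


class TestQuantifyAndGate:
    def make_image(self, ser5p, ser2p=None):
        ser2p = np.full_like(ser5p, 0.1) if ser2p is None else ser2p
        return SyntheticImage(ser5p=ser5p, ser2p=ser2p, rc=np.zeros_like(ser5p))

    def test_single_cluster_normalizes_to_one(self):
        r = raster_with([(5, 10, 5, 10)], value=0.7)
        img = self.make_image(r)
        recs = quantify_clusters(img, None, segment_clusters(r))
        assert len(recs) == 1
        assert recs[0].norm_ser5p == pytest.approx(1.0)

    def test_hand_computed_means(self):
        ser5p = raster_with([(2, 6, 2, 6)], value=0.5) \
            + raster_with([(20, 24, 20, 26)], value=0.9)
        ser2p = np.full_like(ser5p, 0.25)
        img = self.make_image(ser5p, ser2p)
        recs = quantify_clusters(img, None, segment_clusters(ser5p),
                                 normalize=False)
        by_area = sorted(recs, key=lambda r: r.area)
        assert by_area[0].mean_ser5p == pytest.approx(0.5)
        assert by_area[1].mean_ser5p == pytest.approx(0.9)
        assert all(r.mean_ser2p == pytest.approx(0.25) for r in recs)

    def test_rc_overlap_counted_from_state(self):
        state = LatticeState(32, 32)
        r = raster_with([(5, 10, 5, 10)])
        for (y, x) in [(6, 6), (6, 7), (7, 6), (20, 20)]:
            state.grid[y, x] = Species.RC   # 3 inside the block, 1 outside
        img = self.make_image(r)
        recs = quantify_clusters(img, state, segment_clusters(r))
        assert recs[0].rc_overlap == 3

    def test_zero_median_rejected(self):
        r = raster_with([(5, 10, 5, 10)], value=0.7)
        img = self.make_image(r, ser2p=np.zeros_like(r))
        with pytest.raises(ValueError):
            quantify_clusters(img, None, segment_clusters(r), normalize=True)

    @pytest.mark.parametrize("area,solidity,expected", [
        (20, 0.95, "i"),
        (120, 0.9, "ii"),
        (120, 0.4, "iii"),
        (120, 0.7, "ungated"),
        (49, 0.5, "i"),
    ])
    def test_default_gates(self, area, solidity, expected):
        rec = ClusterRecord(0, np.zeros((1, 2)), area, solidity, (0, 0))
        assert gate_clusters([rec])[0].gate == expected

    def test_overlapping_gates_rejected(self):
        rec = ClusterRecord(0, np.zeros((1, 2)), 120, 0.9, (0, 0))
        bad = GateSpec(size_cut=50, solid_hi=0.5, solid_lo=0.95)
        with pytest.raises(ValueError):
            gate_clusters([rec], bad)

    def test_population_gates_isolate_extremes(self):
        recs = [ClusterRecord(i, np.zeros((1, 2)), 100, s, (0, 0))
                for i, s in enumerate(np.linspace(0.5, 1.0, 21))]
        gates = gates_from_population(recs)
        assert gates.solid_lo == pytest.approx(0.625)
        assert gates.solid_hi == pytest.approx(0.875)
        labels = [r.gate for r in gate_clusters(recs, gates)]
        assert labels.count("ii") == 6 and labels.count("iii") == 5


class TestCorrelations:
    def make_records(self, rc, area, sol):
        return [ClusterRecord(i, np.zeros((1, 2)), a, s, (0, 0), rc_overlap=r)
                for i, (r, a, s) in enumerate(zip(rc, area, sol))]

    def test_exact_linear(self):
        rc = np.arange(10)
        recs = self.make_records(rc, 60 + 3 * rc, 0.5 + 0.04 * rc)
        out = correlate_rc_morphology(recs)
        assert out["rho_rc_area"] == pytest.approx(1.0)
        assert out["rho_rc_solidity_large"] == pytest.approx(1.0)

    def test_exact_antilinear(self):
        rc = np.arange(10)
        recs = self.make_records(rc, 160 - 3 * rc, 0.9 - 0.03 * rc)
        out = correlate_rc_morphology(recs)
        assert out["rho_rc_area"] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self, rng):
        n = 10_000
        recs = self.make_records(rng.integers(0, 9, n),
                                 rng.integers(51, 200, n),
                                 rng.uniform(0.3, 1.0, n))
        out = correlate_rc_morphology(recs)
        assert abs(out["rho_rc_area"]) < 0.05
        assert abs(out["rho_rc_solidity_large"]) < 0.05

    def test_zero_variance_rejected(self):
        recs = self.make_records([2] * 5, [60, 70, 80, 90, 100],
                                 [0.5, 0.6, 0.7, 0.8, 0.9])
        with pytest.raises(ValueError):
            correlate_rc_morphology(recs)


class TestPhaseConcentrations:
    def test_block_coincident_with_mask(self):
        state = LatticeState(20, 20)
        mask = np.zeros((20, 20), bool)
        mask[5:9, 5:9] = True
        for y in range(5, 9):
            for x in range(5, 9):
                state.add_particle(y, x)
        dilute, dense = phase_concentrations(state, [mask])
        assert dense == pytest.approx(1.0)
        assert dilute == 0.0

    def test_uniform_gas_no_mask(self, rng):
        state = LatticeState(50, 50)
        sites = rng.choice(2500, size=250, replace=False)
        for s in sites:
            state.add_particle(s // 50, s % 50)
        dilute, dense = phase_concentrations(state, [])
        assert dilute == pytest.approx(0.1, abs=1e-12)
        assert np.isnan(dense)


class TestImageOperators:
    def test_otsu_between_modes(self):
        r = np.concatenate([np.full(300, 0.1), np.full(200, 0.9)])
        t = otsu_threshold(r.reshape(20, 25))
        assert 0.1 < t < 0.9

    def test_otsu_equals_brute_force(self, rng):
        r = np.concatenate([rng.normal(1, 0.3, 800), rng.normal(5, 0.5, 600)])
        t = otsu_threshold(r)
        # independent oracle: maximize inter-class variance over bin cuts;
        # the returned threshold must achieve the maximum (cuts inside an
        # empty-histogram gap between modes tie exactly)
        counts, edges = np.histogram(r, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        total = counts.sum()

        def interclass_variance(k):
            w0, w1 = counts[:k].sum(), counts[k:].sum()
            if w0 == 0 or w1 == 0:
                return -1.0
            m0 = (counts[:k] * centers[:k]).sum() / w0
            m1 = (counts[k:] * centers[k:]).sum() / w1
            return w0 / total * w1 / total * (m0 - m1) ** 2

        best = max(interclass_variance(k) for k in range(1, 256))
        k_t = int(np.searchsorted(centers, t, side="right"))
        assert interclass_variance(k_t) == pytest.approx(best, rel=1e-9)

    def test_otsu_symmetric_under_weight_swap(self, rng):
        a = np.concatenate([rng.normal(1, 0.2, 900), rng.normal(4, 0.2, 300)])
        b = np.concatenate([rng.normal(1, 0.2, 300), rng.normal(4, 0.2, 900)])
        ta, tb = otsu_threshold(a), otsu_threshold(b)
        assert 1 < ta < 4 and 1 < tb < 4

    def test_otsu_constant_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((10, 10), 3.0))

    def test_robust_background_constant(self):
        r = np.full((20, 20), 7.0)
        mask = np.ones_like(r, bool)
        assert robust_background_threshold(r, mask, 2.0) == pytest.approx(7.0)

    def test_robust_background_zero_std_is_trimmed_mean(self, rng):
        r = rng.normal(10, 2, (50, 50))
        mask = np.ones_like(r, bool)
        t0 = robust_background_threshold(r, mask, 0.0)
        trimmed = stats.trimboth(np.sort(r.ravel()), 0.05)
        assert t0 == pytest.approx(trimmed.mean())

    def test_robust_background_normal(self, rng):
        r = rng.normal(10, 2, (100, 100))
        mask = np.ones_like(r, bool)
        t = robust_background_threshold(r, mask, 0.5)
        trimmed = stats.trimboth(np.sort(r.ravel()), 0.05)
        assert t == pytest.approx(trimmed.mean() + 0.5 * trimmed.std(ddof=1))

    def test_robust_background_small_mask_rejected(self, rng):
        r = rng.normal(size=(5, 5))
        mask = np.zeros((5, 5), bool)
        mask[0, :3] = True
        with pytest.raises(ValueError):
            robust_background_threshold(r, mask, 1.0)

    def test_background_subtract_constant_is_zero(self):
        assert np.allclose(
            gaussian_background_subtract(np.full((20, 20), 3.3), 2.0), 0.0)

    def test_background_subtract_retains_peak(self):
        r = np.full((41, 41), 1.0)
        r[20, 20] = 50.0
        out = gaussian_background_subtract(r, 2.0)
        assert out[20, 20] > 40
        assert out[5, 5] == pytest.approx(0.0, abs=1e-6)
        assert np.all(out >= 0)


class TestDistanceEnrichment:
    def disk_mask(self, shape, center, radius):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2

    def test_boundary_targets_all_in_zero_bin(self):
        ref = self.disk_mask((40, 40), (20, 20), 8)
        boundary = ref & ~ndimage.binary_erosion(ref)
        nucleus = np.ones((40, 40), bool)
        prof = distance_enrichment(boundary, [ref], nucleus,
                                   np.array([0, 1, 3, 6, 10]))
        assert prof[0] > 0
        assert np.nansum(prof[1:] * (prof[1:] > 0)) == 0

    def test_uniform_targets_flat_profile(self, rng):
        ref = self.disk_mask((60, 60), (30, 30), 6)
        nucleus = np.ones((60, 60), bool)
        target = rng.random((60, 60)) < 0.5
        prof = distance_enrichment(target, [ref], nucleus,
                                   np.array([0, 3, 6, 9, 15, 25]))
        valid = prof[np.isfinite(prof)]
        assert np.all(np.abs(valid - 1.0) < 0.25)

    def test_ring_at_fixed_distance_peaks(self):
        ref = self.disk_mask((60, 60), (30, 30), 5)
        ring = self.disk_mask((60, 60), (30, 30), 11) \
            & ~self.disk_mask((60, 60), (30, 30), 9)
        nucleus = np.ones((60, 60), bool)
        edges = np.array([0, 2, 4, 7, 12, 20])
        prof = distance_enrichment(ring, [ref], nucleus, edges)
        # ring sits ~5-6 px from the disk surface -> bin (4, 7]
        assert np.nanargmax(prof) == 2

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            distance_enrichment(np.ones((5, 5), bool), [],
                                np.ones((5, 5), bool), np.array([0, 1]))


class TestFixtureImages:
    def test_disk_recovery(self):
        raster, truth = make_fixture_image(
            [{"kind": "disk", "center": (32, 32), "radius": 8}])
        masks = segment_clusters(raster, threshold=0.5)
        assert len(masks) == 1
        assert masks[0].sum() == truth.area.iloc[0]

    def test_noiseless_exact_area(self):
        raster, truth = make_fixture_image(
            [{"kind": "rect", "center": (20, 20), "half": (3, 5)}])
        assert truth.area.iloc[0] == 7 * 11
        assert int((raster > 0).sum()) == 7 * 11

    def test_crescent_low_solidity(self):
        raster, _ = make_fixture_image(
            [{"kind": "crescent", "center": (32, 32), "radius": 10}])
        masks = segment_clusters(raster, threshold=0.5)
        assert len(masks) == 1
        assert compute_solidity(masks[0]) < 0.8

    def test_overlap_flagged(self):
        _, truth = make_fixture_image(
            [{"kind": "disk", "center": (20, 20), "radius": 6},
             {"kind": "disk", "center": (24, 24), "radius": 6}])
        assert truth.overlaps_any.all()
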