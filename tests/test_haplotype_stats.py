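import math

import numpy as np
import pytest

from conftest import (
    ehh_curve_oracle,
    ehh_oracle,
    ihh_oracle,
    make_hapset,
    xpehh_raw_oracle,
)
from sweepscan.haplotype_stats import (
    STATUS_OK,
    STATUS_TRUNCATED,
    EhhCurve,
    SnpScore,
    ehh_decay,
    ihh,
    ihs_scan,
    window_mean_scores,
    xpehh_scan,
)
from sweepscan.synthetic_data import make_fixture
from sweepscan.windows import WindowGrid, assign_snps, build_window_grid


class TestEhhDecay:
    def test_identical_carriers_full_ehh(self):
        haps = np.zeros((4, 4), dtype=np.int8)
        haps[:, 0] = 1  # all carriers, identical downstream
        h = make_hapset(haps)
        curve = ehh_decay(h, 0, 1, "right", cutoff=0.0)
        np.testing.assert_allclose(curve.ehh, [1.0, 1.0, 1.0, 1.0])

    def test_three_one_split_gives_half(self):
        fx = make_fixture("ehh_toy")
        h = fx["haplotypes"]
        curve = ehh_decay(h, fx["core"], fx["allele"], "right", cutoff=0.0)
        np.testing.assert_allclose(curve.ehh, fx["expected_ehh"])

    def test_matches_pairwise_oracle_random(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(2, 7)) * 2
            m = int(rng.integers(5, 31))
            haps = rng.integers(0, 2, size=(n, m)).astype(np.int8)
            core = int(rng.integers(m))
            h = make_hapset(haps)
            for allele in (0, 1):
                carriers = np.flatnonzero(haps[:, core] == allele)
                if len(carriers) < 2:
                    continue
                for direction, step in (("left", -1), ("right", 1)):
                    curve = ehh_decay(h, core, allele, direction, cutoff=0.05)
                    cm = h.positions.astype(float) * 1e-6
                    d, e, hit_end = ehh_curve_oracle(haps[carriers], core, step,
                                                     cm, 0.05)
                    np.testing.assert_array_equal(curve.ehh, e)
                    np.testing.assert_allclose(curve.dist, d)
                    assert curve.hit_end == hit_end

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(5)
        haps = rng.integers(0, 2, size=(12, 40)).astype(np.int8)
        h = make_hapset(haps)
        core = 20
        for allele in (0, 1):
            curve = ehh_decay(h, core, allele, "right", cutoff=0.0)
            assert np.all(np.diff(curve.ehh) <= 1e-12)

    def test_single_carrier_rejected(self):
        haps = np.zeros((4, 3), dtype=np.int8)
        haps[0, 1] = 1
        h = make_hapset(haps)
        with pytest.raises(ValueError, match="fewer than 2"):
            ehh_decay(h, 1, 1, "right")

    def test_missing_data_rejected(self):
        haps = np.zeros((4, 3), dtype=np.int8)
        haps[:2, 0] = 1
        missing = np.zeros((2, 3), dtype=bool)
        missing[0, 2] = True
        h = make_hapset(haps, missing=missing)
        with pytest.raises(ValueError, match="missing"):
            ehh_decay(h, 0, 1, "right")


class TestIhh:
    def _curve(self, dist, ehh, hit_end=False, direction="right"):
        return EhhCurve(core=0, allele="1", direction=direction,
                        dist=np.array(dist), ehh=np.array(ehh), hit_end=hit_end)

    def test_hand_trapezoid(self):
        # 0.1*(1+0.5)/2 + 0.1*(0.5+0.04)/2 = 0.102 ; other side contributes 0
        left = self._curve([0.0], [1.0], direction="left")
        right = self._curve([0.0, 0.1, 0.2], [1.0, 0.5, 0.04])
        value, truncated = ihh(left, right, cutoff=0.05)
        assert value == pytest.approx(0.102)
        assert not truncated

    def test_hand_trapezoid_plateau(self):
        # 0.3*1 + 0.1*(1+0.01)/2 = 0.3505
        left = self._curve([0.0], [1.0], direction="left")
        right = self._curve([0.0, 0.3, 0.4], [1.0, 1.0, 0.01])
        value, truncated = ihh(left, right, cutoff=0.05)
        assert value == pytest.approx(0.3505)

    def test_chromosome_end_flags_truncated(self):
        left = self._curve([0.0], [1.0], direction="left", hit_end=True)
        right = self._curve([0.0, 0.1], [1.0, 0.02])
        _, truncated = ihh(left, right, cutoff=0.05)
        assert truncated

    def test_matches_oracle_random(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            haps = rng.integers(0, 2, size=(10, 30)).astype(np.int8)
            h = make_hapset(haps)
            core = 15
            carriers = np.flatnonzero(haps[:, core] == 1)
            if len(carriers) < 2:
                continue
            cl = ehh_decay(h, core, 1, "left", cutoff=0.05)
            cr = ehh_decay(h, core, 1, "right", cutoff=0.05)
            value, truncated = ihh(cl, cr, cutoff=0.05)
            cm = h.positions.astype(float) * 1e-6
            exp_value, exp_trunc = ihh_oracle(haps[carriers], core, cm, 0.05)
            assert value == pytest.approx(exp_value)
            assert truncated == exp_trunc


def _symmetric_class_hapset():
    """Core SNP whose ancestral and derived carrier sets have identical
    haplotype structure; flanks decay EHH to 0 within two markers."""
    m, core = 9, 4
    pattern = {
        core - 1: [0, 0, 1, 1], core - 2: [0, 1, 0, 1],
        core + 1: [0, 0, 1, 1], core + 2: [0, 1, 0, 1],
    }
    haps = np.zeros((8, m), dtype=np.int8)
    haps[4:, core] = 1  # derived class = rows 4..7
    for j, pat in pattern.items():
        haps[:4, j] = pat
        haps[4:, j] = pat
    return make_hapset(haps)


class TestIhsScan:
    def test_identical_class_structure_gives_zero(self):
        h = _symmetric_class_hapset()
        scores = ihs_scan(h, h.sample_ids, maf_min=0.05)
        core_score = [s for s in scores if s.index == 4][0]
        assert core_score.raw == pytest.approx(0.0)

    def test_long_shared_derived_haplotype_negative(self):
        # 20 haplotypes; derived carriers identical over a long stretch,
        # ancestral carriers maximally diverse -> iHH_D > iHH_A -> raw < 0
        rng = np.random.default_rng(42)
        n, m, core = 20, 41, 20
        haps = rng.integers(0, 2, size=(n, m)).astype(np.int8)
        haps[:, core] = 0
        # derived carriers share an identical stretch of +/- 8 markers around
        # the core but diverge beyond it, so EHH still decays (not truncated)
        haps[:8, core - 8:core + 9] = 0
        haps[:8, core] = 1
        h = make_hapset(haps)
        scores = ihs_scan(h, h.sample_ids, maf_min=0.05, cutoff=0.05)
        core_score = [s for s in scores if s.index == core][0]
        assert core_score.status == STATUS_OK
        assert core_score.raw < 0
        # verify against the brute-force oracle
        cm = h.positions.astype(float) * 1e-6
        anc = np.flatnonzero(haps[:, core] == 0)
        der = np.flatnonzero(haps[:, core] == 1)
        ihh_a, _ = ihh_oracle(haps[anc], core, cm, 0.05)
        ihh_d, _ = ihh_oracle(haps[der], core, cm, 0.05)
        assert core_score.raw == pytest.approx(math.log(ihh_a / ihh_d))

    def test_bins_standardized_mean0_sd1(self):
        rng = np.random.default_rng(1)
        haps = rng.integers(0, 2, size=(40, 300)).astype(np.int8)
        h = make_hapset(haps, positions=np.arange(1, 301) * 37)
        scores = ihs_scan(h, h.sample_ids, maf_min=0.05, n_bins=10)
        by_bin = {}
        for s in scores:
            if s.status == STATUS_OK:
                by_bin.setdefault(min(int(s.freq * 10), 9), []).append(s.z)
        assert by_bin, "expected at least one populated bin"
        for zs in by_bin.values():
            zs = np.array(zs)
            assert abs(zs.mean()) < 1e-9
            assert abs(zs.std(ddof=0) - 1) < 1e-9

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(14)
        haps = rng.integers(0, 2, size=(20, 60)).astype(np.int8)
        h = make_hapset(haps)
        perm = rng.permutation(h.n_samples)
        h2 = h.subset_samples([h.sample_ids[i] for i in perm])
        s1 = ihs_scan(h, h.sample_ids)
        s2 = ihs_scan(h2, h2.sample_ids)
        for a, b in zip(s1, s2):
            assert a.status == b.status
            if a.status == STATUS_OK:
                assert a.raw == pytest.approx(b.raw)

    def test_truncated_core_skipped(self):
        # carriers identical everywhere -> EHH never decays -> truncated
        haps = np.zeros((8, 5), dtype=np.int8)
        haps[:4, 2] = 1
        h = make_hapset(haps)
        scores = ihs_scan(h, h.sample_ids)
        core_score = [s for s in scores if s.index == 2][0]
        assert core_score.status == STATUS_TRUNCATED


class TestXpehhScan:
    def test_identical_populations_zero(self):
        rng = np.random.default_rng(3)
        haps = rng.integers(0, 2, size=(12, 50)).astype(np.int8)
        hA = make_hapset(haps)
        hB = make_hapset(haps.copy())
        scores = xpehh_scan(hA, hB)
        ok = [s for s in scores if s.status == STATUS_OK]
        assert ok
        for s in ok:
            assert s.raw == pytest.approx(0.0)

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(6)
        hA = make_hapset(rng.integers(0, 2, size=(10, 60)).astype(np.int8))
        hB = make_hapset(rng.integers(0, 2, size=(14, 60)).astype(np.int8))
        ab = xpehh_scan(hA, hB)
        ba = xpehh_scan(hB, hA)
        for x, y in zip(ab, ba):
            assert x.status == y.status
            if x.status == STATUS_OK:
                assert x.raw == -y.raw  # exact ln-ratio antisymmetry

    def test_repeated_haplotype_population_positive_and_matches_oracle(self):
        rng = np.random.default_rng(9)
        m = 41
        one_hap = rng.integers(0, 2, size=m).astype(np.int8)
        hapsA = np.tile(one_hap, (10, 1))               # A: one repeated haplotype
        hapsB = rng.integers(0, 2, size=(10, m)).astype(np.int8)  # B: diverse
        hA = make_hapset(hapsA)
        hB = make_hapset(hapsB)
        # population A never decays below the cutoff, so cores are truncated;
        # keep them (the documented flag) to exercise the fixture
        scores = xpehh_scan(hA, hB, cutoff=0.05, keep_truncated=True)
        cm = hA.positions.astype(float) * 1e-6
        interior = [s for s in scores if s.status == STATUS_OK
                    and 5 <= s.index <= m - 6]
        assert interior
        for s in interior:
            assert s.raw > 0
            expected = xpehh_raw_oracle(hapsA, hapsB, s.index, cm, 0.05,
                                        keep_truncated=True)
            assert s.raw == pytest.approx(expected)

    def test_mismatched_grids_rejected(self):
        hA = make_hapset(np.zeros((4, 3), dtype=np.int8), positions=[1, 2, 3])
        hB = make_hapset(np.zeros((4, 3), dtype=np.int8), positions=[1, 2, 4])
        with pytest.raises(ValueError, match="identical variant grid"):
            xpehh_scan(hA, hB)


class TestWindowMeanScores:
    def _grid(self, min_snps=1):
        grid = build_window_grid(300, 100, 100, min_snps=min_snps)
        h = make_hapset(np.zeros((2, 6), dtype=np.int8),
                        positions=[10, 50, 110, 150, 210, 250])
        return assign_snps(grid, h)

    def _score(self, index, position, z):
        return SnpScore(index=index, position=position, freq=0.5, raw=z, z=z,
                        status=STATUS_OK)

    def test_abs_mode(self):
        grid = self._grid()
        scores = [self._score(0, 10, -2.0), self._score(1, 50, 2.0)]
        track = window_mean_scores(scores, grid, mode="abs")
        assert track.values[0] == pytest.approx(2.0)

    def test_signed_mode(self):
        grid = self._grid()
        scores = [self._score(0, 10, -2.0), self._score(1, 50, 2.0)]
        track = window_mean_scores(scores, grid, mode="signed")
        assert track.values[0] == pytest.approx(0.0)

    def test_three_window_hand_averages(self):
        grid = self._grid()
        zs = [1.0, 3.0, -1.0, 2.0, 0.5, -0.5]
        positions = [10, 50, 110, 150, 210, 250]
        scores = [self._score(i, p, z) for i, (p, z) in enumerate(zip(positions, zs))]
        track = window_mean_scores(scores, grid, mode="abs")
        np.testing.assert_allclose(track.values, [2.0, 1.5, 0.5])
        track_s = window_mean_scores(scores, grid, mode="signed")
        np.testing.assert_allclose(track_s.values, [2.0, 0.5, 0.0])

    def test_min_snps_enforced(self):
        grid = self._grid(min_snps=2)
        scores = [self._score(0, 10, 1.0)]  # only one ok SNP in window 0
        track = window_mean_scores(scores, grid)
        assert np.isnan(track.values[0])
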