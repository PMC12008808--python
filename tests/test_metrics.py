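"""Dichromatin metrics: classification, spacing, patch counts, occupancy."""

import numpy as np
import pytest

from dichrom import metrics as M
from dichrom import simulate as sim
from dichrom.model import DichromError, GenomicInterval
from tests.conftest import make_fiber


class TestClassifyFeatures:
    def test_strict_cutoffs(self):
        f = make_fiber(nucleosomes=[(0, 147), (200, 411)],
                       msps=[(500, 650), (700, 851)])
        s = M.classify_features(f)
        assert s.pct_dinucleosome == pytest.approx(50.0)  # 211 > 210, 147 not
        assert s.pct_large_msp == pytest.approx(50.0)     # 151 > 150, 150 not

    def test_exact_cutoff_is_not_dinucleosomal(self):
        f = make_fiber(nucleosomes=[(0, 210)])
        assert M.classify_features(f).pct_dinucleosome == 0.0

    def test_zero_denominator_is_nan(self):
        s = M.classify_features(make_fiber())
        assert np.isnan(s.pct_dinucleosome) and np.isnan(s.pct_large_msp)

    def test_matches_filter_oracle(self, rng):
        for _ in range(20):
            cuts = int(rng.integers(150, 260)), int(rng.integers(100, 200))
            n = int(rng.integers(1, 12))
            pos = 0
            nucs = []
            for _ in range(n):
                ln = int(rng.integers(50, 400))
                nucs.append((pos, pos + ln))
                pos += ln + 10
            f = make_fiber(end=pos + 10, nucleosomes=nucs)
            s = M.classify_features(f, dinuc_cutoff=cuts[0], msp_cutoff=cuts[1])
            want = 100.0 * sum(1 for a, b in nucs if b - a > cuts[0]) / n
            assert s.pct_dinucleosome == pytest.approx(want)

    def test_threshold_monotone(self):
        f = make_fiber(nucleosomes=[(0, 180), (200, 420), (500, 790)])
        pcts = [M.classify_features(f, dinuc_cutoff=c).pct_dinucleosome
                for c in (150, 210, 250, 300)]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))


class TestRegionalSummaries:
    def test_majority_overlap_assignment(self):
        r1 = GenomicInterval("chr1", 0, 700, "core")
        r2 = GenomicInterval("chr1", 700, 1400, "flank")
        f = make_fiber(start=0, end=1000)       # 70/30 split
        t = M.regional_summaries([f], [r1, r2])
        assert t.loc[0, "region"] == "core"

    def test_unassigned_when_no_majority(self):
        r1 = GenomicInterval("chr1", 5000, 6000, "far")
        f = make_fiber(start=0, end=1000)
        t = M.regional_summaries([f], [r1])
        assert t.loc[0, "region"] == "unassigned"

    def test_core_exceeds_flank_dinucleosome_fraction(self):
        cfg = sim.FixtureConfig.cdr_calling(
            seed=30, n_monomers=600, n_fibers=60, flank_length=40_000,
            cdr_offset=0, cdr_length=600 * 170, fiber_length=8_000,
            fiber_region=None,
        )
        b = sim.make_reference(cfg)
        fibers, _ = sim.simulate_fibers(cfg, b)
        regions = [
            GenomicInterval(cfg.chrom, b.array.start, b.array.end, "core"),
            GenomicInterval(cfg.chrom, 0, b.array.start, "flank_l"),
            GenomicInterval(cfg.chrom, b.array.end, len(b.seq), "flank_r"),
        ]
        t = M.regional_summaries(fibers, regions)
        core = t[t.region == "core"]["pct_dinucleosome"].dropna().mean()
        flank = t[t.region.str.startswith("flank")]["pct_dinucleosome"].dropna().mean()
        assert core > flank
        assert flank == 0.0  # no di-nucleosomes planted outside the core


class TestPatchSpacing:
    def test_observed_start_to_start(self):
        f = make_fiber(end=5000, msps=[(100, 300), (400, 650), (1000, 1200)])
        r = M.patch_spacing([f], GenomicInterval("chr1", 0, 5000))
        assert r.observed.tolist() == [300, 600]

    def test_expected_formula_arithmetic(self):
        # ten 10 kb traversals of a 10 kb core with 2 contained patches each
        region = GenomicInterval("chr1", 0, 10_000)
        fibers = [
            make_fiber(fiber_id=f"f{i}", end=10_000,
                       msps=[(1000, 1200), (5000, 5200)])
            for i in range(10)
        ]
        r = M.patch_spacing(fibers, region)
        assert r.sequenced_bases == 100_000
        assert r.n_msps_contained == 20
        assert r.expected == pytest.approx(5000.0)

    def test_expected_identity_on_random_inputs(self, rng):
        region = GenomicInterval("chr1", 200, 4200)
        fibers = []
        for i in range(30):
            start = int(rng.integers(0, 800))
            msps = []
            p = start + int(rng.integers(0, 300))
            while p + 260 < start + 3000:
                msps.append((p, p + 151 + int(rng.integers(0, 100))))
                p = msps[-1][1] + int(rng.integers(20, 600))
            fibers.append(make_fiber(fiber_id=f"f{i}", start=start,
                                     end=start + 3000, msps=msps))
        r = M.patch_spacing(fibers, region)
        if r.n_msps_contained:
            assert r.expected == pytest.approx(
                r.sequenced_bases / r.n_msps_contained)

    def test_no_contained_patches_flags_expected(self):
        f = make_fiber(end=1000)
        r = M.patch_spacing([f], GenomicInterval("chr1", 0, 1000))
        assert np.isnan(r.expected)

    def test_clustered_cores_shorten_observed_spacing(self):
        # directional: Gamma-mixed placement pulls the median observed gap
        # below the density-based expectation; Poisson does not
        med_ratio = {}
        for factor in (1.0, 4.0):
            cfg = sim.FixtureConfig.spacing(factor, seed=42, n_fibers=80)
            b = sim.make_reference(cfg)
            fibers, _ = sim.simulate_fibers(cfg, b)
            r = M.patch_spacing(fibers, b.cdr)
            med_ratio[factor] = np.median(r.observed) / r.expected
        assert med_ratio[4.0] < med_ratio[1.0]
        assert med_ratio[4.0] < 0.8


class TestPatchCount:
    def test_arithmetic(self):
        region = GenomicInterval("chr1", 0, 10_000)
        fibers = [
            make_fiber(fiber_id=f"f{i}", end=10_000,
                       msps=[(1000, 1200), (5000, 5200)])
            for i in range(10)
        ]
        assert M.estimate_patch_count(fibers, region) == pytest.approx(2.0)

    def test_duplication_invariance(self):
        region = GenomicInterval("chr1", 0, 10_000)
        fibers = [make_fiber(fiber_id="a", end=10_000, msps=[(100, 300)])]
        one = M.estimate_patch_count(fibers, region)
        two = M.estimate_patch_count(fibers + [fibers[0].copy()], region)
        assert one == pytest.approx(two)

    def test_zero_sequenced_raises(self):
        with pytest.raises(DichromError):
            M.estimate_patch_count([], GenomicInterval("chr1", 0, 100))

    def test_recovers_planted_rate(self):
        cfg = sim.FixtureConfig.core(
            seed=19, n_fibers=300, msp_rate_core=0.05, msp_cluster_factor=1.0,
            p_occupy_given_mcpg={0: 0, 1: 0, 2: 0},
        )
        b = sim.make_reference(cfg)
        fibers, _ = sim.simulate_fibers(cfg, b)
        est = M.estimate_patch_count(fibers, b.cdr)
        want = cfg.msp_rate_core * len(b.cdr) / 1000.0
        # 3 SE of the per-fiber contained-count mean, scaled to the region
        counts = [sum(1 for m in f.msps if len(m) > 150 and
                      b.cdr.contains(m)) for f in fibers]
        scale = len(b.cdr) / np.mean([f.interval.overlap(b.cdr) for f in fibers])
        se = np.std(counts, ddof=1) / np.sqrt(len(counts)) * scale
        assert abs(est - want) < 3 * se


class TestIntervalSpanFraction:
    TARGET = GenomicInterval("chr1", 400, 520)

    def test_direct_fraction(self):
        fibers = [
            make_fiber(fiber_id=f"f{i}", end=1000, nucleosomes=[(390, 530)])
            for i in range(9)
        ] + [make_fiber(fiber_id="f9", end=1000)]
        assert M.interval_span_fraction(fibers, self.TARGET) == pytest.approx(0.9)

    def test_partial_footprint_below_threshold_not_counted(self):
        # footprint covering 89% of the 120 bp target
        f = make_fiber(end=1000, nucleosomes=[(400, 507)])
        assert M.interval_span_fraction([f], self.TARGET) == 0.0
        f2 = make_fiber(end=1000, nucleosomes=[(400, 508)])  # exactly 90%
        assert M.interval_span_fraction([f2], self.TARGET) == 1.0

    def test_no_spanning_fibers_is_nan(self):
        f = make_fiber(start=0, end=450)
        assert np.isnan(M.interval_span_fraction([f], self.TARGET))

    def test_permutation_invariance_and_planted_occupancy(self, rng):
        p = 0.7
        fibers = []
        for i in range(400):
            nucs = [(380, 540)] if rng.random() < p else []
            fibers.append(make_fiber(fiber_id=f"f{i}", end=1000,
                                     nucleosomes=nucs))
        frac = M.interval_span_fraction(fibers, self.TARGET)
        perm = list(fibers)
        rng.shuffle(perm)
        assert M.interval_span_fraction(perm, self.TARGET) == frac
        se = np.sqrt(p * (1 - p) / len(fibers))
        assert abs(frac - p) < 3 * se


class TestFootprintSizes:
    def test_median_and_tally(self):
        f = make_fiber(end=1000, nucleosomes=[(0, 100), (200, 300), (400, 600)])
        counts, edges, q = M.footprint_size_distribution([f])
        assert q["median"] == 100
        assert q["n"] == 3
        # histogram equals a brute-force tally
        lengths = [100, 100, 200]
        want, _ = np.histogram(lengths, bins=edges)
        np.testing.assert_array_equal(counts, want)

    def test_empty_region(self):
        f = make_fiber(end=1000, nucleosomes=[(0, 100)])
        counts, _, q = M.footprint_size_distribution(
            [f], GenomicInterval("chr2", 0, 10))
        assert counts.sum() == 0 and q["n"] == 0
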