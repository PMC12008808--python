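"""CENP-B box scanning, profiles, footprint scores, edge positioning."""

import re

import numpy as np
import pytest

from dichrom import cenpb as cb
from dichrom import simulate as sim
from dichrom.model import DichromError, GenomicInterval
from tests.conftest import make_fiber

BOX = "ATTCGAAAAATACGGGT"  # one consensus instance with exactly 2 CpGs


def _regex_oracle(seq):
    """Independent regex scan of both strands with coordinate mapping and
    the exactly-2-CG filter applied on the reference 17-mer."""
    pat = re.compile("(?=([ACGT]TTCG[ACGT]{4}A[ACGT]{2}CGGG[ACGT]))")
    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    hits = set()
    for m in pat.finditer(seq):
        hits.add((m.start(), "+"))
    for m in pat.finditer(rc):
        hits.add((len(seq) - m.start() - 17, "-"))
    out = set()
    for s, strand in hits:
        mer = seq[s: s + 17]
        if sum(1 for j in range(16) if mer[j: j + 2] == "CG") == 2:
            out.add((s, strand))
    return out


class TestScan:
    def test_planted_forward_site(self):
        seq = "A" * 100 + BOX + "A" * 100
        sites = cb.scan_cenpb_boxes(seq, chrom="c")
        assert len(sites) == 1
        s = sites[0]
        assert (s.interval.start, s.interval.end, s.strand) == (100, 117, "+")
        assert s.center == 108
        assert len(s.cpg_positions) == 2

    def test_reverse_complement_is_mirrored(self):
        seq = "A" * 100 + BOX + "A" * 100
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        sites = cb.scan_cenpb_boxes(rc, chrom="c")
        assert len(sites) == 1
        s = sites[0]
        assert (s.interval.start, s.interval.end, s.strand) == (100, 117, "-")
        assert s.center == 117 - 1 - 8

    def test_poly_a_has_no_sites(self):
        assert cb.scan_cenpb_boxes("A" * 500, chrom="c") == []

    def test_cpg_count_filter(self):
        # third CG introduced in an N slot -> filtered out
        box3 = "CGTCGAAAAATACGGGT"
        assert _regex_oracle("A" * 50 + box3 + "A" * 50) == set()
        assert cb.scan_cenpb_boxes("A" * 50 + box3 + "A" * 50, chrom="c") == []

    def test_matches_regex_oracle_on_random_sequences(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(200):
            seq = "".join(bases[rng.integers(0, 4, size=10_000)])
            # spike in a couple of boxes on both strands
            rcbox = BOX.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            seq = seq[:1000] + BOX + seq[1017:5000] + rcbox + seq[5017:]
            got = {
                (s.interval.start, s.strand)
                for s in cb.scan_cenpb_boxes(seq, chrom="c")
            }
            assert got == _regex_oracle(seq)

    def test_non_iupac_motif_rejected(self):
        from dichrom.model import ConfigError

        with pytest.raises(ConfigError):
            cb.scan_cenpb_boxes("ACGT" * 100, chrom="c", motif="NTTZG")


def _site(start=100, strand="+"):
    seq = "A" * start + BOX + "A" * 200
    return cb.scan_cenpb_boxes(seq, chrom="chr1")[0]


class TestObserve:
    def test_mcpg_states(self):
        s = _site()
        p1, p2 = s.cpg_positions
        f2 = make_fiber(fiber_id="a", end=400, cpg={p1: True, p2: True})
        f1 = make_fiber(fiber_id="b", end=400, cpg={p1: True, p2: False})
        fm = make_fiber(fiber_id="c", end=400, cpg={p1: True})
        obs = cb.observe_boxes([f2, f1, fm], [s])
        states = {o.fiber_id: o.mcpg_state for o in obs}
        assert states == {"a": 2, "b": 1, "c": None}
        strata = cb.stratify(obs)
        assert len(strata[2]) == 1 and len(strata[1]) == 1 and len(strata[0]) == 0

    def test_non_spanning_fibers_skipped(self):
        s = _site()
        f = make_fiber(end=s.center + 10)
        assert cb.observe_boxes([f], [s]) == []

    def test_window_matches_lookup_oracle(self, rng):
        s = _site()
        pos = np.sort(rng.choice(300, size=40, replace=False))
        f = make_fiber(end=400, m6a=pos.tolist())
        (o,) = cb.observe_boxes([f], [s])
        for off in range(-50, 51):
            assert o.m6a_window[off + 50] == int(s.center + off in set(pos))

    def test_minus_strand_window_flipped(self):
        seq = "A" * 100 + BOX + "A" * 100
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        s = cb.scan_cenpb_boxes(rc, chrom="chr1")[0]
        f = make_fiber(end=217, m6a=[s.center + 7])
        (o,) = cb.observe_boxes([f], [s])
        # +7 on the reference is -7 in motif orientation
        assert o.m6a_window[50 - 7] == 1 and o.m6a_window.sum() == 1


class TestProfileAndScore:
    def test_constant_profiles_survive_smoothing(self):
        obs0 = [cb.BoxFiberObservation(0, "f", 0, np.zeros(101, dtype=np.uint8))]
        obs1 = [cb.BoxFiberObservation(0, "f", 0, np.ones(101, dtype=np.uint8))]
        assert cb.aggregate_profile(obs0).tolist() == [0.0] * 101
        np.testing.assert_allclose(cb.aggregate_profile(obs1), 1.0)

    def test_rolling_mean_matches_bruteforce(self, rng):
        mat = (rng.random((13, 101)) < 0.3).astype(np.uint8)
        obs = [cb.BoxFiberObservation(0, f"f{i}", 0, row)
               for i, row in enumerate(mat)]
        got = cb.aggregate_profile(obs)
        raw = mat.mean(axis=0)
        for i in range(101):
            lo, hi = max(0, i - 5), min(101, i + 5)
            assert got[i] == pytest.approx(raw[lo:hi].mean())

    def test_score_arithmetic(self):
        prof = np.zeros(101)
        prof[cb.FLANK_OFFSETS + 50] = 0.4
        prof[cb.CORE_OFFSETS + 50] = 0.1
        assert cb.footprint_score(prof) == pytest.approx(0.4 / 0.101, rel=1e-6)

    def test_flat_profile_scores_one(self):
        prof = np.full(101, 0.35)
        assert cb.footprint_score(prof) == pytest.approx(1.0, abs=0.01)

    def test_zero_core_is_finite(self):
        prof = np.zeros(101)
        prof[cb.FLANK_OFFSETS + 50] = 0.4
        assert cb.footprint_score(prof) == pytest.approx(0.4 / 1e-3)

    def test_short_profile_raises(self):
        with pytest.raises(DichromError):
            cb.footprint_score(np.zeros(50))


class TestScoreDistribution:
    def _obs(self, rng, n=60):
        return [
            cb.BoxFiberObservation(
                0, f"f{i}", 0, (rng.random(101) < 0.3).astype(np.uint8))
            for i in range(n)
        ]

    def test_full_fraction_is_degenerate(self, rng):
        obs = self._obs(rng)
        fs = cb.score_distribution(obs, subsample_fraction=1.0,
                                   n_subsamples=20, seed=5)
        assert np.allclose(fs.distribution, fs.score)

    def test_seed_reproducibility(self, rng):
        obs = self._obs(rng)
        a = cb.score_distribution(obs, n_subsamples=50, seed=42)
        b = cb.score_distribution(obs, n_subsamples=50, seed=42)
        np.testing.assert_array_equal(a.distribution, b.distribution)

    def test_small_stratum_raises(self, rng):
        with pytest.raises(DichromError, match="too small"):
            cb.score_distribution(self._obs(rng, n=10), seed=1)

    def test_occupancy_discrimination_on_synthetic_boxes(self):
        cfg = sim.FixtureConfig.cenpb_strata(seed=77)
        b = sim.make_reference(cfg)
        fibers, _ = sim.simulate_fibers(cfg, b)
        sites = cb.scan_cenpb_boxes(
            b.seq, [a.interval for a in b.annotations], chrom=cfg.chrom)
        strata = cb.stratify(cb.observe_boxes(fibers, sites))
        med = {
            s: np.median(cb.score_distribution(g, seed=1).distribution)
            for s, g in strata.items()
        }
        assert med[0] > med[1] > med[2]


class TestEdgePositioning:
    def test_single_downstream_nucleosome(self):
        s = _site()
        c = s.center
        p1, p2 = s.cpg_positions
        f = make_fiber(end=c + 600, nucleosomes=[(c + 10, c + 157)],
                       cpg={p1: False, p2: False})
        out = cb.nucleosome_edge_positioning([f], [s], halfwidth=108)
        down = out[0]["downstream"]
        assert down[10 + 108] == 100.0
        assert out[0]["upstream"].sum() == 0.0

    def test_mirror_symmetric_input(self):
        s = _site(start=300)
        c = s.center
        p1, p2 = s.cpg_positions
        f = make_fiber(
            end=800,
            nucleosomes=[(c - 157, c - 10), (c + 10, c + 157)],
            cpg={p1: True, p2: True},
        )
        out = cb.nucleosome_edge_positioning([f], [s], halfwidth=200)
        up, down = out[2]["upstream"], out[2]["downstream"]
        np.testing.assert_array_equal(up, down[::-1])
        assert up[-10 + 200] == 100.0 and down[10 + 200] == 100.0

    def test_planted_flanking_offsets_recovered(self):
        # occupied boxes clear +/- (30 + linker) and keep the 60 bp core
        # footprint; adjacent planted nucleosomes produce histogram modes
        # at the planted offsets
        s = _site(start=400)
        c = s.center
        p1, p2 = s.cpg_positions
        fibers = [
            make_fiber(
                fiber_id=f"f{i}", end=1000,
                nucleosomes=[(c - 202, c - 55), (c - 30, c + 30),
                             (c + 55, c + 202)],
                cpg={p1: False, p2: False},
            )
            for i in range(20)
        ]
        out = cb.nucleosome_edge_positioning(fibers, [s], halfwidth=300)
        up, down = out[0]["upstream"], out[0]["downstream"]
        assert np.argmax(up) - 300 == -55
        assert np.argmax(down) - 300 == 55
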