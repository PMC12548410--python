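"""PWM scanning, set enrichment and the strict presence filter."""

from math import comb

import numpy as np
import pytest
from scipy import stats

from ervfootprint import motif_enrichment as me
from ervfootprint import synthetic_data as sd
from ervfootprint.types import CpGIslandRecord
from tests.conftest import consensus_motif, make_seq, random_seq


class TestScanMotif:
    def test_single_consensus_hit(self):
        m = consensus_motif("GATTACAG")
        seq = make_seq("A" * 40 + "GATTACAG" + "T" * 40)
        hits = me.scan_motif(seq, m)
        plus = [h for h in hits if h.strand == "+"]
        assert [(h.start, h.strand) for h in plus] == [(40, "+")]

    def test_no_hits_in_hostile_sequence(self):
        m = consensus_motif("GCGCGCGC")
        assert me.scan_motif(make_seq("A" * 200), m) == []

    def test_strand_symmetry_under_reverse_complement(self, rng):
        m = consensus_motif("GATTACAG")
        s = random_seq(rng, 300) + "GATTACAG" + random_seq(rng, 300)
        seq = make_seq(s)
        seq_rc = make_seq(me.reverse_complement(s), id="rc")
        fwd = {(h.start, h.strand) for h in me.scan_motif(seq, m)}
        flipped = {
            (seq.length - h.start - m.width, {"+": "-", "-": "+"}[h.strand])
            for h in me.scan_motif(seq_rc, m)
        }
        assert fwd == flipped

    def test_hit_count_non_increasing_with_stricter_quantile(self, rng):
        m = consensus_motif("GATTAC", weight=0.7)
        seq = make_seq(random_seq(rng, 3_000))
        counts = [
            len(me.scan_motif(seq, m, threshold_quantile=q))
            for q in (1e-2, 1e-3, 1e-4, 1e-5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_motif_wider_than_sequence_warns_empty(self, caplog):
        m = consensus_motif("GATTACAG")
        with caplog.at_level("WARNING"):
            assert me.scan_motif(make_seq("ACGT"), m) == []
        assert "wider" in caplog.text

    def test_threshold_quantile_is_honoured_by_dp_distribution(self):
        """Fraction of random windows above threshold <= quantile (DP is exact)."""
        m = consensus_motif("GATTAC", weight=0.6)
        thr = me.score_threshold(m, threshold_quantile=1e-2)
        rng = np.random.default_rng(0)
        lo = me._log_odds_matrix(m)
        draws = rng.integers(0, 4, size=(40_000, m.width))
        scores = lo[np.arange(m.width)[None, :], draws].sum(axis=1) / me._SCALE
        frac = float(np.mean(scores >= thr))
        assert frac <= 1.5e-2  # sampling slack above the exact 1e-2 bound
        # and the next-laxer threshold admits more
        assert thr > me.score_threshold(m, threshold_quantile=5e-2)


class TestSeaEnrich:
    def test_perfect_separation_p(self, rng):
        m = consensus_motif("GATTACAGATTACA")
        primary = [
            make_seq(random_seq(rng, 200) + m.consensus + random_seq(rng, 200),
                     id=f"p{i}")
            for i in range(8)
        ]
        control = [make_seq("AT" * 210, id=f"c{i}") for i in range(8)]
        (res,) = me.sea_enrich(primary, control, [m])
        assert res.n_primary_with_hit == 8 and res.n_control_with_hit == 0
        assert res.p_value == pytest.approx(1 / comb(16, 8), rel=1e-9)
        assert res.passes_bespoke_filter

    def test_identical_presence_no_signal(self, rng):
        m = consensus_motif("GATTACAG")
        seqs = [
            make_seq(random_seq(rng, 100) + m.consensus + random_seq(rng, 100),
                     id=f"s{i}")
            for i in range(10)
        ]
        (res,) = me.sea_enrich(seqs[:5], seqs[5:], [m])
        assert res.p_value >= 0.5

    def test_evalue_is_bonferroni(self, rng):
        m = consensus_motif("GATTACAG")
        primary = [make_seq(m.consensus + "A" * 50, id=f"p{i}") for i in range(4)]
        control = [make_seq("T" * 58, id=f"c{i}") for i in range(4)]
        (res,) = me.sea_enrich(primary, control, [m], n_motifs_tested=10)
        assert res.e_value == pytest.approx(res.p_value * 10)

    def test_fisher_matches_enumeration_small_sets(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n1, n0 = int(rng.integers(2, 31)), int(rng.integers(2, 31))
            k1, k0 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n0 + 1))
            _, p = stats.fisher_exact([[k1, n1 - k1], [k0, n0 - k0]],
                                      alternative="greater")
            K = k1 + k0
            expected = sum(
                comb(n1, k) * comb(n0, K - k)
                for k in range(k1, min(n1, K) + 1)
                if 0 <= K - k <= n0
            ) / comb(n1 + n0, K)
            assert p == pytest.approx(expected, rel=1e-9)


class TestBespokeFilter:
    def build(self, k1, n1, k0, n0, e):
        return me.EnrichmentResult(
            motif_name="m", n_primary_with_hit=k1, n_primary=n1,
            n_control_with_hit=k0, n_control=n0,
            p_value=e / 10, e_value=e, passes_bespoke_filter=False,
        )

    @pytest.mark.parametrize(
        "k1,k0,e,expected",
        [
            (8, 1, 0.01, True),    # all primary, one control allowed
            (7, 0, 0.01, True),    # all-but-one primary, zero control
            (8, 2, 0.001, False),  # two controls break the rule despite tiny E
            (7, 1, 0.001, False),  # all-but-one primary tolerates no control
            (6, 0, 0.001, False),  # two primary misses fail both clauses
            (8, 0, 0.2, False),    # E-value cutoff still applies
        ],
    )
    def test_truth_table(self, k1, k0, e, expected):
        assert me.bespoke_filter(self.build(k1, 8, k0, 8, e)) is expected


class TestCgiOverlapFilter:
    ISLAND = CpGIslandRecord("s", 0, 200, mean_gc=60.0, mean_oe=0.8)

    def hit(self, start, mark):
        return me.MotifHit("s", mark or "m", start, "+", 10.0)

    def test_restricted_hit_inside_island_kept(self):
        hits = [me.MotifHit("s", "mk", 50, "+", 9.0)]
        kept = me.cgi_overlap_filter(
            hits, [self.ISLAND], marks={"H3K4me3"},
            motif_widths={"mk": 10}, motif_marks={"mk": "H3K4me3"},
        )
        assert kept == hits

    def test_restricted_hit_outside_island_dropped(self):
        hits = [me.MotifHit("s", "mk", 500, "+", 9.0)]
        kept = me.cgi_overlap_filter(
            hits, [self.ISLAND], marks={"H3K4me3"},
            motif_widths={"mk": 10}, motif_marks={"mk": "H3K4me3"},
        )
        assert kept == []

    def test_unrestricted_mark_passes_through(self):
        hits = [me.MotifHit("s", "mk", 500, "+", 9.0)]
        kept = me.cgi_overlap_filter(
            hits, [self.ISLAND], marks={"H3K4me3", "H3K27ac", "H3K27me3"},
            motif_widths={"mk": 10}, motif_marks={"mk": "H3K9me3"},
        )
        assert kept == hits


class TestImplantationEndToEnd:
    def test_implanted_motif_passes_filter_decoy_does_not(self):
        """Over 20 seeded trials: implanted motif flagged, absent decoy never."""
        motif = consensus_motif("GATTACAGATTACAGT", name="real")
        decoy = consensus_motif("CCTTGGAACCTTGGAA", name="decoy")
        for trial in range(20):
            rng = np.random.default_rng(100 + trial)
            primary = [make_seq(random_seq(rng, 400), id=f"p{i}") for i in range(8)]
            control = [make_seq(random_seq(rng, 400), id=f"c{i}") for i in range(8)]
            primary, _ = sd.implant_motifs(primary, motif, seed=trial)
            results = {
                r.motif_name: r
                for r in me.sea_enrich(primary, control, [motif, decoy])
            }
            assert results["real"].passes_bespoke_filter
            assert not results["decoy"].passes_bespoke_filter
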