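"""The CpG-decay simulator: calibration, mechanism conservation, recovery."""

import numpy as np
import pytest

from ervfootprint import kmer_stats as ks
from ervfootprint import synthetic_data as sd


class TestMarkovGenerator:
    def test_calibration_at_target_one(self):
        cfg = sd.SimulationConfig(length=10_000, target_cpg_oe=1.0, seed=3)
        seq = sd.gen_markov_sequence(cfg)
        assert 0.95 <= ks.d_ratio(seq, "CG").d_ratio <= 1.05

    def test_calibration_at_target_half(self):
        cfg = sd.SimulationConfig(length=10_000, target_cpg_oe=0.5, seed=3)
        seq = sd.gen_markov_sequence(cfg)
        assert 0.45 <= ks.d_ratio(seq, "CG").d_ratio <= 0.55

    def test_same_seed_same_sequence(self):
        cfg = sd.SimulationConfig(length=2_000, seed=5)
        assert sd.gen_markov_sequence(cfg).residues == sd.gen_markov_sequence(cfg).residues

    def test_different_lineages_differ(self):
        cfg = sd.SimulationConfig(length=2_000, seed=5)
        assert (sd.gen_markov_sequence(cfg, lineage=0).residues
                != sd.gen_markov_sequence(cfg, lineage=1).residues)

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError):
            sd._calibrate_cg_transition(20.0)


class TestAssignMethylation:
    def seq(self, length=60_000, seed=2):
        return sd.gen_markov_sequence(sd.SimulationConfig(length=length, seed=seed))

    def test_probability_one_methylates_all(self):
        s = self.seq(2_000)
        probs = {c: 1.0 for c in ("CGA", "CGC", "CGG", "CGT")}
        _, states = sd.assign_methylation(s, probs, seed=1, default_prob=1.0)
        assert states.all()

    def test_probability_zero_methylates_none(self):
        s = self.seq(2_000)
        probs = {c: 0.0 for c in ("CGA", "CGC", "CGG", "CGT")}
        _, states = sd.assign_methylation(s, probs, seed=1, default_prob=0.0)
        assert not states.any()

    def test_context_fractions_near_targets(self):
        s = self.seq()
        probs = {"CGC": 0.9, "CGA": 0.1, "CGG": 0.5, "CGT": 0.5}
        positions, states = sd.assign_methylation(s, probs, seed=9)
        r = s.residues
        for ctx, target in (("CGC", 0.9), ("CGA", 0.1)):
            mask = np.array([r[i : i + 3] == ctx for i in positions])
            assert mask.sum() >= 500
            assert abs(states[mask].mean() - target) < 0.05

    def test_no_cpg_rejected(self):
        from ervfootprint.types import NucleotideSequence

        with pytest.raises(ValueError):
            sd.assign_methylation(NucleotideSequence(id="x", residues="ATAT"), seed=0)


class TestEvolveDeamination:
    def lineage(self, rate, generations, length=30_000, seed=6, meth_prob=1.0):
        cfg = sd.SimulationConfig(length=length, seed=seed)
        s = sd.gen_markov_sequence(cfg)
        probs = {c: meth_prob for c in ("CGA", "CGC", "CGG", "CGT")}
        positions, states = sd.assign_methylation(
            s, probs, seed=seed, default_prob=meth_prob
        )
        return sd.evolve_deamination(s, positions, states, rate, generations, seed=seed)

    def test_rate_zero_is_identity(self):
        rec = self.lineage(0.0, 10, length=2_000)
        assert rec.descendant.residues == rec.ancestor.residues

    def test_rate_one_destroys_all_methylated_cpgs(self):
        rec = self.lineage(1.0, 1, length=2_000)
        d = rec.descendant.residues
        assert all(d[i : i + 2] != "CG" for i in rec.cpg_positions)

    def test_survival_matches_closed_form(self):
        """Survival per methylated CpG after 10 generations at rate 0.1: 0.9^10."""
        rec = self.lineage(0.1, 10)
        assert rec.methylated.sum() >= 1_000
        survived = rec.surviving_methylated.sum() / rec.methylated.sum()
        assert abs(survived - 0.9**10) < 0.05

    def test_conservation_of_events(self):
        rec = self.lineage(0.2, 5, length=10_000, meth_prob=0.7)
        anc, desc = rec.ancestor.residues, rec.descendant.residues
        diffs = [i for i in range(len(anc)) if anc[i] != desc[i]]
        meth_sites = set()
        for j, i in enumerate(rec.cpg_positions):
            if rec.methylated[j]:
                meth_sites.update((int(i), int(i) + 1))
        # changes only at initially methylated CpG positions
        assert set(diffs) <= meth_sites
        lost = int(rec.methylated.sum() - rec.surviving_methylated.sum())
        assert rec.n_cg_to_tg + rec.n_cg_to_ca == lost == len(diffs)


class TestEmitReport:
    def seq_and_probs(self, p, length=6_000, seed=8):
        s = sd.gen_markov_sequence(sd.SimulationConfig(length=length, seed=seed))
        probs = {}
        for i in range(length - 2):
            if s.residues[i : i + 2] == "CG":
                probs[(i, "+")] = p
                probs[(i + 1, "-")] = p
        return s, probs

    def test_probability_one_fully_methylated(self):
        s, probs = self.seq_and_probs(1.0, length=1_000)
        recs = sd.emit_cytosine_report(s, probs, coverage=10, seed=1)
        assert all(r.count_unmethylated == 0 for r in recs)

    def test_probability_zero_unmethylated(self):
        s, probs = self.seq_and_probs(0.0, length=1_000)
        recs = sd.emit_cytosine_report(s, probs, coverage=10, seed=1)
        assert all(r.count_methylated == 0 for r in recs)

    def test_both_strands_emitted_with_correct_contexts(self):
        s, probs = self.seq_and_probs(0.5, length=1_000)
        recs = sd.emit_cytosine_report(s, probs, coverage=10, seed=1)
        strands = {r.strand for r in recs}
        assert strands == {"+", "-"}
        assert all(r.trinucleotide[0] == "C" for r in recs)
        assert all(r.context_class == "CpG" for r in recs)

    def test_nonpositive_coverage_rejected(self):
        s, probs = self.seq_and_probs(0.5, length=1_000)
        with pytest.raises(ValueError):
            sd.emit_cytosine_report(s, probs, coverage=0, seed=1)


class TestImplantMotifs:
    def test_fixed_seed_reproducible(self, rng):
        from tests.conftest import consensus_motif, make_seq, random_seq

        seqs = [make_seq(random_seq(rng, 300), id=f"s{i}") for i in range(4)]
        m = consensus_motif("GATTACAG")
        _, pos1 = sd.implant_motifs(seqs, m, seed=11)
        _, pos2 = sd.implant_motifs(seqs, m, seed=11)
        assert pos1 == pos2

    def test_consensus_present_at_recorded_positions(self, rng):
        from tests.conftest import consensus_motif, make_seq, random_seq

        seqs = [make_seq(random_seq(rng, 300), id=f"s{i}") for i in range(4)]
        m = consensus_motif("GATTACAG")
        out, positions = sd.implant_motifs(seqs, m, seed=1)
        for s, p in zip(out, positions):
            assert s.residues[p : p + m.width] == m.consensus

    def test_width_exceeding_length_rejected(self):
        from tests.conftest import consensus_motif, make_seq

        with pytest.raises(ValueError):
            sd.implant_motifs([make_seq("ACGT")], consensus_motif("GATTACAG"), seed=0)

    def test_in_cgi_requires_island(self):
        from tests.conftest import consensus_motif, make_seq

        with pytest.raises(ValueError, match="island"):
            sd.implant_motifs(
                [make_seq("AT" * 200)], consensus_motif("GATTACAG"), where="in-CGI",
                seed=0,
            )


class TestEndToEndRecovery:
    def test_deamination_signature_recovered(self):
        """CpG D-ratio anticorrelates with mean(TpG, CpA) across 20 lineages."""
        from ervfootprint import comparative_stats as cs

        cfg = sd.SimulationConfig(seed=7)
        lineages = sd.simulate_lineages(cfg)
        table = ks.d_ratio_table([l.descendant for l in lineages], ["CG", "TG", "CA"])
        res = cs.deamination_correlation(table)
        assert res.r < -0.5
        assert res.p_value < 0.01

    def test_context_preference_footprint(self):
        """Dominant CGC methylation -> largest D-ratio drop at CGC, TGC/CAC rise."""
        cfg = sd.SimulationConfig(
            length=20_000, seed=13,
            context_meth_prob={"CGC": 0.95, "CGA": 0.3, "CGG": 0.3, "CGT": 0.3},
            default_meth_prob=0.3,
            deamination_rate=0.05, generations=30, n_lineages=6,
        )
        drops = {c: [] for c in ("CGA", "CGC", "CGG", "CGT")}
        tgc_diffs, cac_diffs = [], []
        for k in range(cfg.n_lineages):
            s = sd.gen_markov_sequence(cfg, lineage=k)
            positions, states = sd.assign_methylation(
                s, cfg.context_meth_prob, seed=cfg.seed + k,
                default_prob=cfg.default_meth_prob,
            )
            rec = sd.evolve_deamination(
                s, positions, states, cfg.deamination_rate, cfg.generations,
                seed=cfg.seed + k,
            )
            anc = ks.full_spectrum(rec.ancestor)
            desc = ks.full_spectrum(rec.descendant)
            for c in drops:
                drops[c].append(
                    ks.d_ratio(rec.ancestor, c, spectrum=anc).d_ratio
                    - ks.d_ratio(rec.descendant, c, spectrum=desc).d_ratio
                )
            tgc_diffs.append(
                ks.d_ratio(rec.descendant, "TGC", spectrum=desc).d_ratio
                - ks.d_ratio(rec.ancestor, "TGC", spectrum=anc).d_ratio
            )
            cac_diffs.append(
                ks.d_ratio(rec.descendant, "CAC", spectrum=desc).d_ratio
                - ks.d_ratio(rec.ancestor, "CAC", spectrum=anc).d_ratio
            )
        medians = {c: float(np.median(v)) for c, v in drops.items()}
        assert all(medians["CGC"] > medians[c] for c in ("CGA", "CGG", "CGT"))
        assert np.median(tgc_diffs) > 0 and np.median(cac_diffs) > 0
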