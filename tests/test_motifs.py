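"""PWM scanning, peak-to-gene assignment, hypergeometric enrichment and
motif-based regulon pruning."""

import math

import numpy as np
import pandas as pd
import pytest

import hepatoregulon as hr
from hepatoregulon.datatypes import MotifPWM, PeakSet, reverse_complement
from hepatoregulon.motifs import (
    assign_peaks_to_genes,
    compute_motif_support,
    motif_enrichment,
    prune_regulons,
    scan_sequence,
)


def make_peakset(entries, width):
    """entries: list of (chrom, start, stage, seq)."""
    rows = [{"chrom": c, "start": s, "end": s + width, "stage": st} for c, s, st, _ in entries]
    seqs = {f"{c}:{s}-{s + width}": seq for c, s, _, seq in entries}
    return PeakSet(intervals=pd.DataFrame(rows), sequences=seqs, width=width)


class TestScan:
    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = MotifPWM("U", np.full((3, 4), 0.25), pseudocount=0.0)
        hits = scan_sequence(pwm, "ACGTACGT", score_threshold=-1e-9)
        assert hits and all(score == pytest.approx(0.0) for _, _, score in hits)

    def test_single_position_log_odds_hand_value(self):
        pwm = MotifPWM("A1", np.array([[0.8, 0.1, 0.05, 0.05]]), pseudocount=0.0)
        ((off, strand, score),) = [h for h in scan_sequence(pwm, "A", score_threshold=1.0) if h[1] == "+"]
        assert (off, strand) == (0, "+")
        assert score == pytest.approx(math.log2(3.2), abs=1e-12)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=80))
        mat = rng.dirichlet(np.ones(4), size=6)
        pwm = MotifPWM("S", mat, pseudocount=0.0)
        fwd = sorted(s for _, _, s in scan_sequence(pwm, seq, score_threshold=-1e9))
        rev = sorted(s for _, _, s in scan_sequence(pwm, reverse_complement(seq), score_threshold=-1e9))
        assert fwd == pytest.approx(rev)

    def test_scanner_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for trial in range(5):
            length = int(rng.integers(50, 1000))
            seq = "".join(rng.choice(list("ACGT"), size=length))
            mat = rng.dirichlet(np.ones(4) * 2, size=int(rng.integers(4, 10)))
            pwm = MotifPWM("B", mat, pseudocount=1e-3)
            got = {(o, s): sc for o, s, sc in scan_sequence(pwm, seq, score_threshold=-1e9)}
            lo = {b: np.log2(pwm.matrix[:, i] / 0.25) for i, b in enumerate("ACGT")}
            L = len(pwm)
            for off in range(length - L + 1):
                win = seq[off : off + L]
                exp_fwd = sum(lo[b][p] for p, b in enumerate(win))
                exp_rev = sum(lo[b][p] for p, b in enumerate(reverse_complement(win)))
                assert got[(off, "+")] == pytest.approx(exp_fwd, abs=1e-9)
                assert got[(off, "-")] == pytest.approx(exp_rev, abs=1e-9)

    def test_short_sequence_and_n_windows(self):
        pwm = MotifPWM("N", np.full((4, 4), 0.25), pseudocount=0.0)
        assert scan_sequence(pwm, "ACG", score_threshold=-1) == []
        hits = scan_sequence(pwm, "ACNGT", score_threshold=-1)
        assert hits == []  # every 4-mer window contains the N


class TestAssignment:
    tss = pd.DataFrame({"chrom": ["chr1", "chr1"], "tss": [10_000, 40_000]}, index=["geneA", "geneB"])

    def test_midpoint_at_tss_assigned(self):
        peaks = make_peakset([("chr1", 9_750, "S", "A" * 500)], 500)
        assert assign_peaks_to_genes(peaks, self.tss) == {"chr1:9750-10250": "geneA"}

    def test_equidistant_tie_goes_to_lexicographically_smaller_gene(self):
        peaks = make_peakset([("chr1", 24_750, "S", "A" * 500)], 500)  # midpoint 25 000
        assert assign_peaks_to_genes(peaks, self.tss, max_distance=20_000) == {"chr1:24750-25250": "geneA"}

    def test_distance_boundary_inclusive_then_unassigned(self):
        at_limit = make_peakset([("chr1", 19_750, "S", "A" * 500)], 500)  # midpoint 20 000
        assert assign_peaks_to_genes(at_limit, self.tss, max_distance=10_000) != {}
        beyond = make_peakset([("chr1", 19_751, "S", "A" * 500)], 500)  # midpoint 20 001
        assert assign_peaks_to_genes(beyond, self.tss, max_distance=10_000) == {}


class TestEnrichment:
    def test_foreground_equal_universe_gives_one(self):
        u = {f"p{i}" for i in range(10)}
        assert motif_enrichment({"p0", "p1"}, u, u) == pytest.approx(1.0)

    def test_exact_combinatorial_instance(self):
        universe = {f"p{i}" for i in range(20)}
        hits = {f"p{i}" for i in range(5)}
        foreground = {"p0", "p1", "p2", "p3", "p10"}  # 4 of 5 carry hits
        assert motif_enrichment(hits, foreground, universe) == pytest.approx(76 / 15504, abs=1e-15)

    def test_no_hits_anywhere_gives_one(self):
        u = {f"p{i}" for i in range(8)}
        assert motif_enrichment(set(), {"p0", "p1"}, u) == pytest.approx(1.0)

    def test_monotone_in_foreground_hit_count(self):
        universe = {f"p{i}" for i in range(30)}
        hits = {f"p{i}" for i in range(10)}
        prev = 1.1
        for k in range(6):
            fg = {f"p{i}" for i in range(k)} | {f"p{i}" for i in range(10, 16 - k)}
            p = motif_enrichment(hits, fg, universe)
            assert 0 <= p <= 1
            assert p <= prev + 1e-12
            prev = p

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            motif_enrichment(set(), set(), set())
        with pytest.raises(ValueError, match="subset"):
            motif_enrichment(set(), {"x"}, {"y"})


class TestPruning:
    def test_tf_without_hits_is_dropped(self):
        # peak assigned to the target but carrying no motif instance
        pwm = MotifPWM("TFX", np.array([[0.97, 0.01, 0.01, 0.01]] * 6), pseudocount=0.0)
        peaks = make_peakset([("chr1", 9_750, "S", "C" * 500)], 500)
        tss = pd.DataFrame({"chrom": ["chr1"], "tss": [10_000]}, index=["t1"])
        cand = hr.Regulon(tf="TFX", link_scores={"t1": 0.9})
        support = compute_motif_support([cand], {"TFX": pwm}, peaks, tss)
        assert prune_regulons([cand], support, enrichment_alpha=1.0, min_size=1) == []

    def test_zero_noise_pruning_recovers_planted_regulons_exactly(self, zero_noise_dataset):
        ds = zero_noise_dataset
        cands = hr.infer_candidate_regulons(ds.expression, set(ds.motifs), corr_threshold=0.3, min_size=5)
        support = compute_motif_support(cands, ds.motifs, ds.peaks, ds.tss_table)
        pruned = {r.tf: r.targets for r in prune_regulons(cands, support, 0.05, 5)}
        planted = {
            tf: tg
            for tf, tg in ds.truth.regulons.items()
            if ds.truth.activity_profile.loc[tf].nunique() > 1  # constant TFs have no co-expression signal
        }
        assert pruned == planted

    def test_vacuous_gate_reduces_to_presence_rule(self):
        # two targets, only one of whose peaks carries the motif
        pwm = MotifPWM("TFY", np.array([[0.97, 0.01, 0.01, 0.01]] * 6), pseudocount=0.0)
        entries = [
            ("chr1", 9_750, "S", "C" * 200 + "A" * 6 + "C" * 294),
            ("chr1", 39_750, "S", "C" * 500),
        ]
        peaks = make_peakset(entries, 500)
        tss = pd.DataFrame({"chrom": ["chr1", "chr1"], "tss": [10_000, 40_000]}, index=["t1", "t2"])
        cand = hr.Regulon(tf="TFY", link_scores={"t1": 0.9, "t2": 0.8})
        support = compute_motif_support([cand], {"TFY": pwm}, peaks, tss, max_distance=np.inf)
        (reg,) = prune_regulons([cand], support, enrichment_alpha=1.0, min_size=1)
        assert reg.targets == {"t1"}

    def test_pruned_sets_are_subsets_of_candidates(self, default_dataset):
        ds = default_dataset
        cands = hr.infer_candidate_regulons(ds.expression, set(ds.motifs), 0.3, 5)
        support = compute_motif_support(cands, ds.motifs, ds.peaks, ds.tss_table)
        pruned = prune_regulons(cands, support, 0.05, 5)
        assert len(pruned) <= len(cands)
        by_tf = {c.tf: c.targets for c in cands}
        for reg in pruned:
            assert reg.targets <= by_tf[reg.tf]
            assert reg.targets <= support.supported_targets[reg.tf]
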