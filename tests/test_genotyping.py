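"""Clone alignment, outcome classification, and frequency aggregation."""

import numpy as np
import pytest

from bequant import (
    CloneCall,
    SimConfig,
    align_clone,
    classify_clone,
    classify_clones,
    embryo_outcome,
    gen_site,
    sim_embryo_clones,
    site_frequencies,
)
from conftest import CBE_SPACER, make_amplicon, mutate


def gotoh_score(a, b, match=2, mismatch=-3, gap_open=-8, gap_extend=-1):
    """Independent affine-gap global alignment score (plain DP)."""
    inf = float("-inf")
    n, m = len(a), len(b)
    M = [[inf] * (m + 1) for _ in range(n + 1)]
    X = [[inf] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[inf] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


class TestAlignClone:
    def test_identical_sequences_gapless(self, cbe_site):
        aln = align_clone(cbe_site.amplicon_ref, cbe_site.amplicon_ref)
        assert aln.ref_aln == aln.query_aln == cbe_site.amplicon_ref

    def test_single_substitution_one_mismatch_column(self, cbe_site):
        ref = cbe_site.amplicon_ref
        idx = cbe_site.plus_index(5)
        clone = mutate(ref, idx, "T")
        aln = align_clone(clone, ref)
        assert "-" not in aln.ref_aln and "-" not in aln.query_aln
        mismatches = [i for i, (r, q) in enumerate(zip(aln.ref_aln, aln.query_aln)) if r != q]
        assert mismatches == [idx]

    def test_deletion_left_normalized_in_repeat(self):
        # deleting TTT from the TTTT run: the canonical gap sits leftmost
        ref = "AAGTTTTCAAGGC"
        clone = "AAGTCAAGGC"
        aln = align_clone(clone, ref)
        assert aln.ref_aln == ref
        assert aln.query_aln == "AAG---TCAAGGC"

    @pytest.mark.parametrize(
        "ref, clone",
        [
            ("AAGTTTTCAAGGC", "AAGTCAAGGC"),        # 3-bp deletion
            ("ACGTACGTACGT", "ACGTACGT"),            # 4-bp deletion in repeat
            ("ACGGATTACAGGAT", "ACGGATTTTACAGGAT"),  # 2-bp insertion
            ("ACGTGGCATTTACA", "ACTTGGCATTAACA"),    # substitutions only
        ],
    )
    def test_score_matches_independent_dp(self, ref, clone):
        aln = align_clone(clone, ref)
        assert aln.score == gotoh_score(ref, clone)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_clone("", "ACGT")
        with pytest.raises(ValueError):
            align_clone("ACXT", "ACGT")


class TestClassifyClone:
    def call(self, clone, site, editor, **kw):
        return classify_clone(align_clone(clone, site.amplicon_ref), site, editor, **kw)

    def test_intended_double_conversion(self, cbe_site, be3):
        clone = cbe_site.amplicon_ref
        for p in (5, 6):
            clone = mutate(clone, cbe_site.plus_index(p), "T")
        call = self.call(clone, cbe_site, be3)
        assert call.category == "intended"
        assert call.intended_positions == (5, 6)
        assert call.per_position_base[5] == "T" and call.per_position_base[6] == "T"

    def test_unintended_conversion(self, cbe_site, be3):
        clone = mutate(cbe_site.amplicon_ref, cbe_site.plus_index(5), "A")
        call = self.call(clone, cbe_site, be3)
        assert call.category == "unintended"
        assert call.unintended_positions == (5,)

    def test_wild_type(self, cbe_site, be3):
        call = self.call(cbe_site.amplicon_ref, cbe_site, be3)
        assert call.category == "WT"
        assert not call.has_indel

    def test_mixed(self, cbe_site, be3):
        clone = mutate(cbe_site.amplicon_ref, cbe_site.plus_index(5), "T")
        clone = mutate(clone, cbe_site.plus_index(8), "C")
        call = self.call(clone, cbe_site, be3)
        assert call.category == "mixed"

    def test_indel_precedence_and_masked_positions(self, cbe_site, be3):
        # 2-bp deletion spanning window positions 5-6, plus an intended edit
        ref = cbe_site.amplicon_ref
        lo = cbe_site.plus_index(5)
        clone = ref[:lo] + ref[lo + 2:]
        call = self.call(clone, cbe_site, be3)
        assert call.category == "indel"
        assert call.has_indel

    def test_background_mismatch_tolerance(self, cbe_site, be3):
        clone = cbe_site.amplicon_ref
        for i in range(3):  # 3 errors in the left flank, far from the spacer
            clone = mutate(clone, 2 + 3 * i, "A" if clone[2 + 3 * i] != "A" else "G")
        call = self.call(clone, cbe_site, be3)
        assert call.informative and call.category == "WT"
        assert call.background_mismatches == 3
        strict = self.call(clone, cbe_site, be3, max_background_mismatches=2)
        assert not strict.informative

    def test_truncated_clone_uninformative(self, cbe_site, be3):
        flank_only = cbe_site.amplicon_ref[:cbe_site.spacer_start - 6]
        call = self.call(flank_only, cbe_site, be3)
        assert not call.informative
        assert call.category == "uninformative"

    def test_minus_strand_reports_protospacer_coordinates(self, be3):
        from bequant import locate_protospacer, revcomp

        amplicon = revcomp(make_amplicon(CBE_SPACER))
        site = locate_protospacer(amplicon, CBE_SPACER, be3)
        # a C->T conversion at protospacer position 6 is G->A on the plus strand
        clone = mutate(amplicon, site.plus_index(6), "A")
        call = self.call(clone, site, be3)
        assert call.category == "intended"
        assert call.intended_positions == (6,)


class TestSiteFrequencies:
    def _intended_call(self, cid, positions=(5, 6)):
        bases = {p: CBE_SPACER[p - 1] for p in range(1, 21)}
        for p in positions:
            bases[p] = "T"
        return CloneCall(cid, bases, False, "intended", True, tuple(positions))

    def _wt_call(self, cid):
        bases = {p: CBE_SPACER[p - 1] for p in range(1, 21)}
        return CloneCall(cid, bases, False, "WT", True)

    def test_unanimous_frequency(self):
        f = site_frequencies([self._intended_call(f"c{i}") for i in range(8)])
        assert f.intended[5] == 1.0 and f.intended[6] == 1.0
        assert f.n_clones == 8

    def test_half_frequency(self):
        calls = [self._intended_call(f"i{k}") for k in range(4)]
        calls += [self._wt_call(f"w{k}") for k in range(4)]
        f = site_frequencies(calls)
        assert f.intended[5] == 0.5
        assert f.indel_frequency == 0.0

    def test_gapped_position_denominator(self):
        calls = [self._intended_call(f"i{k}") for k in range(3)]
        gap = {p: CBE_SPACER[p - 1] for p in range(1, 21)}
        gap[5] = "-"
        calls.append(CloneCall("del", gap, True, "indel", True))
        f = site_frequencies(calls)
        assert f.n_informative[5] == 3
        assert f.intended[5] == 1.0
        assert f.indel_frequency == 0.25  # indel clone still in the indel denominator

    def test_no_informative_clone_errors(self):
        bad = CloneCall("x", {}, False, "uninformative", False)
        with pytest.raises(ValueError):
            site_frequencies([bad])

    def test_order_invariance(self):
        calls = [self._intended_call("a"), self._wt_call("b"), self._intended_call("c")]
        f1 = site_frequencies(calls)
        f2 = site_frequencies(calls[::-1])
        assert f1.intended == f2.intended
        assert f1.indel_frequency == f2.indel_frequency


class TestEmbryoOutcome:
    def test_all_wt(self, cbe_site, be3):
        calls = classify_clones(
            [(f"c{i}", cbe_site.amplicon_ref) for i in range(4)], cbe_site, be3
        )
        out = embryo_outcome("E1", {"S": calls}, {"S": (cbe_site, be3)})
        flags = out.flags["S"]
        assert not flags.edited and not flags.mosaic and not flags.fully_converted

    def test_fully_converted_implies_edited(self, cbe_site, be3):
        clone = cbe_site.amplicon_ref
        for p in (5, 6):
            clone = mutate(clone, cbe_site.plus_index(p), "T")
        calls = classify_clones([(f"c{i}", clone) for i in range(4)], cbe_site, be3)
        flags = embryo_outcome("E1", {"S": calls}, {"S": (cbe_site, be3)}).flags["S"]
        assert flags.fully_converted and flags.edited and not flags.mosaic

    def test_mosaic_mixture(self, cbe_site, be3):
        edited = mutate(cbe_site.amplicon_ref, cbe_site.plus_index(5), "T")
        seqs = [("e1", edited), ("e2", edited), ("e3", edited),
                ("w1", cbe_site.amplicon_ref), ("w2", cbe_site.amplicon_ref)]
        calls = classify_clones(seqs, cbe_site, be3)
        flags = embryo_outcome("E1", {"S": calls}, {"S": (cbe_site, be3)}).flags["S"]
        assert flags.edited and flags.mosaic and not flags.fully_converted
        assert embryo_outcome("E1", {"S": calls}).freqs["S"].intended[5] == 0.6


class TestSyntheticRecovery:
    def test_partition_into_categories(self):
        cfg = SimConfig(seed=7, clones_per_embryo=60, allele_pool="per-clone",
                        unintended_rate=0.2, indel_rate=0.15)
        amp, site = gen_site(cfg, "BE3")
        from bequant import build_editor_spec
        be3 = build_editor_spec("BE3")
        clones, _ = sim_embryo_clones(site, be3, cfg)
        calls = classify_clones(clones, site, be3)
        informative = [c for c in calls if c.informative]
        by_cat = {cat: sum(c.category == cat for c in informative)
                  for cat in ("WT", "intended", "unintended", "mixed", "indel")}
        assert sum(by_cat.values()) == len(informative)

    def test_mask_recovery_exact_on_clean_clones(self, be3):
        """Per-position edit masks are recovered exactly on >=1000 clones."""
        cfg = SimConfig(seed=11, clones_per_embryo=1000, allele_pool="per-clone",
                        intended_rate=0.5, bystander_rate=0.3,
                        unintended_rate=0.25, indel_rate=0.0, seq_error_rate=0.0)
        amp, site = gen_site(cfg, be3)
        clones, truth = sim_embryo_clones(site, be3, cfg)
        calls = classify_clones(clones, site, be3)
        assert len(calls) == 1000
        for call, row in zip(calls, truth.itertuples()):
            assert call.informative
            expected_intended = tuple(
                int(p) for p in row.intended_positions.split(",") if p
            )
            expected_unintended = tuple(
                int(x.split(":")[0]) for x in row.unintended_positions.split(",") if x
            )
            assert call.intended_positions == expected_intended
            assert call.unintended_positions == expected_unintended
            assert not call.has_indel
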