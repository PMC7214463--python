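"""Trio de novo filtering cascade: hard filters, density, Mendelian, pileup."""

import numpy as np
import pysam
import pytest

from bequant import (
    SampleCall,
    SimConfig,
    TrioVariantRecord,
    density_filter,
    hard_filter,
    possible_denovo,
    read_pileup_tsv,
    read_trio_vcf,
    refine_denovo,
    run_denovo_pipeline,
    sim_trio,
    spectrum_from_calls,
    write_pileup_tsv,
    write_trio_vcf,
)

CLEAN_INFO = {"QD": 20.0, "FS": 1.0, "MQ": 60.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0}


def record(chrom="chr1", pos=1000, ref="A", alt="G", qual=500.0,
           annotations=None, mother=(0, 0), father=(0, 0), fetus=(0, 1),
           gq=(99, 99, 99)):
    samples = {
        "mother": SampleCall(gt=mother, gq=gq[0], dp=40, ad=(40, 0)),
        "father": SampleCall(gt=father, gq=gq[1], dp=40, ad=(40, 0)),
        "fetus": SampleCall(gt=fetus, gq=gq[2], dp=40, ad=(20, 20)),
    }
    return TrioVariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual,
        annotations=dict(CLEAN_INFO if annotations is None else annotations),
        samples=samples,
    )


CLEAN_PILEUP = {"mother": (40, 0), "father": (40, 0), "fetus": (22, 18)}


class TestHardFilter:
    def test_qual_boundary_snv(self):
        assert not hard_filter(record(qual=99.0)).passed
        assert hard_filter(record(qual=100.0)).passed

    def test_qd_boundary_is_strict(self):
        annotations = dict(CLEAN_INFO, QD=2.0)
        assert hard_filter(record(annotations=annotations)).passed
        annotations["QD"] = 1.99
        assert not hard_filter(record(annotations=annotations)).passed

    def test_fs_threshold_differs_by_class(self):
        annotations = dict(CLEAN_INFO, FS=150.0)
        assert not hard_filter(record(annotations=annotations)).passed  # SNV: FS > 60
        indel = record(ref="AT", alt="A", annotations=annotations)
        assert hard_filter(indel).passed  # indel: FS > 200
        annotations["FS"] = 250.0
        assert not hard_filter(record(ref="AT", alt="A", annotations=annotations)).passed

    def test_indel_ignores_mq_clauses(self):
        annotations = dict(CLEAN_INFO, MQ=10.0, MQRankSum=-20.0)
        assert hard_filter(record(ref="AT", alt="A", annotations=annotations)).passed
        assert not hard_filter(record(annotations=annotations)).passed

    def test_missing_annotation_does_not_fail(self):
        result = hard_filter(record(annotations={"QD": 20.0}))
        assert result.passed
        assert set(result.missing) == {"FS", "MQ", "MQRankSum", "ReadPosRankSum"}

    def test_ranksum_thresholds(self):
        assert not hard_filter(record(annotations=dict(CLEAN_INFO, MQRankSum=-13.0))).passed
        assert not hard_filter(record(annotations=dict(CLEAN_INFO, ReadPosRankSum=-9.0))).passed


class TestDensityFilter:
    def test_five_in_window_all_removed(self):
        records = [record(pos=p) for p in (100, 110, 120, 130, 140)]
        assert density_filter(records) == []

    def test_four_in_window_retained(self):
        records = [record(pos=p) for p in (100, 110, 120, 130)]
        assert density_filter(records) == records

    def test_window_span_is_inclusive_100_bases(self):
        # positions 100..199 span exactly 100 bases -> counted together
        inside = [record(pos=p) for p in (100, 120, 140, 160, 199)]
        assert density_filter(inside) == []
        outside = [record(pos=p) for p in (100, 120, 140, 160, 200)]
        assert len(density_filter(outside)) == 5

    def test_chromosomes_independent(self):
        records = [record(chrom="chr1", pos=p) for p in (100, 110, 120)]
        records += [record(chrom="chr2", pos=p) for p in (105, 115)]
        assert density_filter(records) == records

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            density_filter([record(pos=200), record(pos=100)])

    def test_matches_bruteforce_oracle_and_idempotent(self):
        rng = np.random.default_rng(3)
        positions = sorted(int(p) for p in rng.integers(1, 3000, size=200))
        positions = list(dict.fromkeys(positions))
        records = [record(pos=p) for p in positions]
        retained = density_filter(records)

        def brute(pos_list):
            removed = set()
            for w in range(min(pos_list), max(pos_list) + 1):
                inside = [p for p in pos_list if w <= p <= w + 99]
                if len(inside) >= 5:
                    removed.update(inside)
            return [p for p in pos_list if p not in removed]

        assert [r.pos for r in retained] == brute(positions)
        assert density_filter(retained) == retained


class TestPossibleDenovo:
    def test_canonical_denovo(self):
        assert possible_denovo(record()).passed

    def test_inherited_allele(self):
        assert not possible_denovo(record(father=(0, 1))).passed

    def test_gq_boundary(self):
        assert not possible_denovo(record(gq=(29, 99, 99))).passed
        assert possible_denovo(record(gq=(30, 30, 30))).passed

    def test_missing_genotype(self):
        result = possible_denovo(record(mother=(None, None)))
        assert not result.passed
        assert "missing-genotype:mother" in result.reasons

    def test_reverse_denovo_hom_alt_parents(self):
        # parents 1/1, fetus 0/1: the reference allele is the novel one
        assert possible_denovo(record(mother=(1, 1), father=(1, 1), fetus=(0, 1))).passed


class TestRefineDenovo:
    def test_clean_candidate_passes(self):
        # fetus 15 alt / 35 total -> balance 0.4286
        pileup = {"mother": (40, 0), "father": (40, 0), "fetus": (20, 15)}
        assert refine_denovo(record(), pileup).passed

    def test_depth_boundary(self):
        pileup = {"mother": (19, 0), "father": (40, 0), "fetus": (20, 15)}
        result = refine_denovo(record(), pileup)
        assert not result.passed and "DP<20:mother" in result.reasons
        pileup["mother"] = (20, 0)
        assert refine_denovo(record(), pileup).passed

    def test_single_parental_alt_read_fails(self):
        pileup = {"mother": (40, 0), "father": (39, 1), "fetus": (20, 15)}
        result = refine_denovo(record(), pileup)
        assert not result.passed and "parent-alt-reads:father" in result.reasons

    def test_hom_alt_parents_zero_ref_reads(self):
        rec = record(mother=(1, 1), father=(1, 1), fetus=(0, 1))
        pileup = {"mother": (0, 40), "father": (1, 39), "fetus": (20, 20)}
        assert not refine_denovo(rec, pileup).passed
        pileup["father"] = (0, 40)
        assert refine_denovo(rec, pileup).passed

    def test_allele_balance_bounds_inclusive(self):
        for fetus, ok in [((70, 30), True), ((30, 70), True),
                          ((71, 29), False), ((29, 71), False)]:
            pileup = {"mother": (40, 0), "father": (40, 0), "fetus": fetus}
            assert refine_denovo(record(), pileup).passed is ok

    def test_missing_pileup(self):
        result = refine_denovo(record(), {"mother": (40, 0), "father": (40, 0)})
        assert not result.passed and result.reasons == ("no-coverage:fetus",)


class TestPipeline:
    def test_empty_input(self):
        result = run_denovo_pipeline([], {})
        assert result.calls == []
        assert all(v == 0 for v in result.stage_counts.values())

    def test_density_applied_after_hard_filters(self):
        # 5 clustered candidates, one of which fails the hard filter: the
        # remaining 4 no longer form a dense cluster and survive
        records = [
            record(pos=100 + 10 * i, qual=(50.0 if i == 0 else 500.0))
            for i in range(5)
        ]
        pileups = {("chr1", r.pos): dict(CLEAN_PILEUP) for r in records}
        result = run_denovo_pipeline(records, pileups)
        assert result.stage_counts["hard_filter"] == 4
        assert result.stage_counts["density_filter"] == 4
        assert len(result.calls) == 4

    def test_true_denovo_inside_cluster_removed(self):
        records = [record(pos=100 + 10 * i) for i in range(5)]
        pileups = {("chr1", r.pos): dict(CLEAN_PILEUP) for r in records}
        result = run_denovo_pipeline(records, pileups)
        assert result.calls == []
        assert result.stage_counts["density_filter"] == 0

    def test_stage_monotonicity_and_trails(self):
        sim = sim_trio(SimConfig(seed=9, n_variants=300, n_true_denovo=8))
        result = run_denovo_pipeline(sim.records, sim.pileups)
        counts = list(result.stage_counts.values())
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        for call in result.calls:
            assert call.passed_stages == (
                "chromosomes", "hard_filter", "density_filter",
                "possible_denovo", "refine",
            )

    def test_chromosome_allow_list(self):
        records = [record(chrom="chrX", pos=100), record(chrom="chr1", pos=200)]
        pileups = {(r.chrom, r.pos): dict(CLEAN_PILEUP) for r in records}
        result = run_denovo_pipeline(
            sorted(records, key=lambda r: r.chrom),
            pileups, allowed_chroms={"chr1"},
        )
        assert [c.record.chrom for c in result.calls] == ["chr1"]

    def test_substitution_tallies_sum_to_snv_count(self):
        sim = sim_trio(SimConfig(seed=4, n_variants=400, n_true_denovo=12))
        result = run_denovo_pipeline(sim.records, sim.pileups)
        spectrum = spectrum_from_calls(result.calls)
        n_snv = sum(c.var_class == "SNV" for c in result.calls)
        assert spectrum.total == n_snv


class TestVcfRoundTrip:
    def test_file_round_trip_matches_in_memory(self, tmp_path):
        sim = sim_trio(SimConfig(seed=2, n_variants=300, n_true_denovo=10))
        vcf = tmp_path / "trio.vcf"
        tsv = tmp_path / "pileup.tsv"
        write_trio_vcf(sim, str(vcf))
        write_pileup_tsv(sim, str(tsv))
        records = read_trio_vcf(
            str(vcf), {"mother": "mother", "father": "father", "fetus": "fetus"}
        )
        pileups = read_pileup_tsv(str(tsv))
        from_file = run_denovo_pipeline(records, pileups)
        in_memory = run_denovo_pipeline(sim.records, sim.pileups)
        assert [
            (c.record.chrom, c.record.pos, c.record.ref, c.record.alt)
            for c in from_file.calls
        ] == [
            (c.record.chrom, c.record.pos, c.record.ref, c.record.alt)
            for c in in_memory.calls
        ]

    def test_multiallelic_split(self, tmp_path):
        header = pysam.VariantHeader()
        header.contigs.add("chr1", length=1_000_000)
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("GQ", 1, "Integer", "Genotype quality")
        for name in ("mom", "dad", "kid"):
            header.add_sample(name)
        path = tmp_path / "multi.vcf"
        with pysam.VariantFile(str(path), "w", header=header) as out:
            rec = out.new_record(contig="chr1", start=99, alleles=("A", "G", "T"), qual=500)
            for name, gt in (("mom", (0, 0)), ("dad", (0, 1)), ("kid", (0, 2))):
                rec.samples[name]["GT"] = gt
                rec.samples[name]["GQ"] = 99
            out.write(rec)
        records = read_trio_vcf(
            str(path), {"mother": "mom", "father": "dad", "fetus": "kid"}
        )
        assert [(r.ref, r.alt) for r in records] == [("A", "G"), ("A", "T")]
        # the A>T split is a candidate de novo; A>G is inherited from father
        assert not possible_denovo(records[0]).passed
        assert possible_denovo(records[1]).passed
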