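"""Trio whole-genome de novo variant refinement.

Implements the filtering cascade from joint-genotyped trio variant
records (mother, father, fetus) to a final set of de novo SNV/indel
calls:

1. hard filters on site annotations, class-specific —
   SNVs:   QD < 2.0 | FS > 60.0 | MQ < 40 | MQRankSum < -12.5 |
           ReadPosRankSum < -8.0 | QUAL < 100;
   indels: QD < 2.0 | FS > 200 | ReadPosRankSum < -20 | QUAL < 100;
   a missing annotation never fails its clause on its own (counted);
2. variant-density filter — any site with >= 5 variants inside a 100-bp
   window is removed (mapping-artifact regions);
3. Mendelian de novo candidacy — the fetus carries an allele found in
   neither parental genotype and all three genotype qualities are >= 30;
4. pileup-based refinement — raw read depth >= 20 in all three samples,
   zero reads supporting the disallowed allele in either parent, and
   fetal allele balance within [0.3, 0.7] (inclusive).

The cascade consumes variant records (e.g. from a joint-genotyped VCF);
it does not call variants from reads. Only autosomes are expected; a
chromosome allow-list can enforce this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd
import pysam

ROLES = ("mother", "father", "fetus")

SNV_HARD_FILTERS = {
    "QD": ("<", 2.0),
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
    "QUAL": ("<", 100.0),
}

INDEL_HARD_FILTERS = {
    "QD": ("<", 2.0),
    "FS": (">", 200.0),
    "ReadPosRankSum": ("<", -20.0),
    "QUAL": ("<", 100.0),
}


@dataclass(frozen=True)
class SampleCall:
    gt: tuple[int | None, ...]
    gq: int | None = None
    dp: int | None = None
    ad: tuple[int, ...] | None = None


@dataclass(frozen=True)
class TrioVariantRecord:
    """One bi-allelic variant with trio genotypes and site annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None
    annotations: dict[str, float]
    samples: dict[str, SampleCall]  # keyed by role: mother/father/fetus
    filter_state: frozenset[str] = frozenset()

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def var_class(self) -> str:
        return "SNV" if self.is_snv else "indel"

    @property
    def substitution(self) -> str | None:
        """Reference-strand substitution class, e.g. ``"C>T"`` (SNVs only)."""
        return f"{self.ref}>{self.alt}" if self.is_snv else None


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reasons: tuple[str, ...] = ()
    missing: tuple[str, ...] = ()


@dataclass(frozen=True)
class DenovoCall:
    record: TrioVariantRecord
    var_class: str
    substitution: str | None
    passed_stages: tuple[str, ...]


def read_trio_vcf(path: str, pedigree: dict[str, str]) -> list[TrioVariantRecord]:
    """Read a joint-genotyped trio VCF into bi-allelic records.

    ``pedigree`` maps roles (mother/father/fetus) to VCF sample names.
    Multi-allelic records are split per alternate allele; in a split
    record the focal alternate is allele 1 and any other alternate is
    represented by the sentinel allele index 2, so Mendelian logic still
    sees those alleles as present (and distinct from the focal one).
    """
    missing = set(pedigree) ^ set(ROLES)
    if missing:
        raise ValueError(f"pedigree must map exactly {ROLES}, mismatch: {sorted(missing)}")
    records: list[TrioVariantRecord] = []
    with pysam.VariantFile(path) as vcf:
        sample_names = list(vcf.header.samples)
        for role, name in pedigree.items():
            if name not in sample_names:
                raise ValueError(f"sample {name!r} ({role}) not in VCF: {sample_names}")
        for rec in vcf:
            alts = rec.alts or ()
            for k, alt in enumerate(alts, start=1):
                annotations: dict[str, float] = {}
                info_keys = set(rec.info.keys())
                for key in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
                    if key in info_keys and rec.info[key] is not None:
                        annotations[key] = float(rec.info[key])
                samples: dict[str, SampleCall] = {}
                for role, name in pedigree.items():
                    s = rec.samples[name]
                    gt = tuple(
                        (None if a is None else (0 if a == 0 else (1 if a == k else 2)))
                        for a in (s.get("GT") or (None, None))
                    )
                    ad = s.get("AD")
                    ad_pair = None
                    if ad is not None and len(ad) > k and ad[0] is not None:
                        ad_pair = (int(ad[0]), int(ad[k]) if ad[k] is not None else 0)
                    samples[role] = SampleCall(
                        gt=gt,
                        gq=None if s.get("GQ") is None else int(s.get("GQ")),
                        dp=None if s.get("DP") is None else int(s.get("DP")),
                        ad=ad_pair,
                    )
                records.append(
                    TrioVariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        qual=None if rec.qual is None else float(rec.qual),
                        annotations=annotations,
                        samples=samples,
                    )
                )
    return records


def hard_filter(record: TrioVariantRecord) -> FilterResult:
    """Class-specific annotation thresholds; strict inequalities.

    A record fails iff any clause is true for its class; clauses with a
    missing annotation are skipped and reported in ``missing``.
    """
    thresholds = SNV_HARD_FILTERS if record.is_snv else INDEL_HARD_FILTERS
    reasons: list[str] = []
    missing: list[str] = []
    for key, (op, cut) in thresholds.items():
        value = record.qual if key == "QUAL" else record.annotations.get(key)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            missing.append(key)
            continue
        if (op == "<" and value < cut) or (op == ">" and value > cut):
            reasons.append(f"{key}{op}{cut}")
    return FilterResult(passed=not reasons, reasons=tuple(reasons), missing=tuple(missing))


def density_filter(
    records: list[TrioVariantRecord], window: int = 100, max_per_window: int = 4
) -> list[TrioVariantRecord]:
    """Drop variants in high-density clusters (>=5 in any 100-bp window).

    A variant is removed iff some window of ``window`` consecutive bases on
    its chromosome contains it together with at least ``max_per_window``
    others. Input must be sorted by (chrom, pos); the operation is
    idempotent.
    """
    keys = [(r.chrom, r.pos) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, pos)")
    removed = [False] * len(records)
    start = 0
    for end in range(len(records) + 1):
        if end == len(records) or (end > start and records[end].chrom != records[start].chrom):
            _mark_dense(records, start, end, window, max_per_window, removed)
            start = end
    return [r for r, gone in zip(records, removed) if not gone]


def _mark_dense(records, lo, hi, window, max_per_window, removed):
    positions = [r.pos for r in records[lo:hi]]
    j = 0
    for i in range(len(positions)):
        while positions[i] - positions[j] > window - 1:
            j += 1
        if i - j + 1 >= max_per_window + 1:
            for k in range(j, i + 1):
                removed[lo + k] = True


def possible_denovo(record: TrioVariantRecord, min_gq: int = 30) -> FilterResult:
    """Mendelian-violation candidacy with a genotype-quality gate.

    True iff the fetus carries at least one allele absent from both
    parental genotypes and every sample has GQ >= ``min_gq``.
    """
    reasons: list[str] = []
    calls = {role: record.samples.get(role) for role in ROLES}
    for role, call in calls.items():
        if call is None or any(a is None for a in call.gt):
            return FilterResult(False, (f"missing-genotype:{role}",))
    parent_alleles = set(calls["mother"].gt) | set(calls["father"].gt)
    # only the ref or the focal alt can make this record de novo; a novel
    # "other alternate" (sentinel 2 from multi-allelic splitting) belongs
    # to its own split record
    novel = [a for a in calls["fetus"].gt if a not in parent_alleles and a in (0, 1)]
    if not novel:
        reasons.append("allele-inherited")
    for role, call in calls.items():
        if call.gq is None or call.gq < min_gq:
            reasons.append(f"GQ<{min_gq}:{role}")
    return FilterResult(passed=not reasons, reasons=tuple(reasons))


def refine_denovo(
    candidate: TrioVariantRecord,
    pileup: dict[str, tuple[int, int]],
    min_dp: int = 20,
    ab_range: tuple[float, float] = (0.3, 0.7),
) -> FilterResult:
    """Pileup-based final filter on a de novo candidate.

    ``pileup`` maps each role to raw (ref_reads, alt_reads); this raw
    depth, not FORMAT/DP, governs the depth rule. Homozygous-ref parents
    must show zero alternate reads (homozygous-alt parents zero reference
    reads), and the fetal allele balance alt/(ref+alt) must lie within
    ``ab_range`` inclusive.
    """
    reasons: list[str] = []
    for role in ROLES:
        if role not in pileup:
            return FilterResult(False, (f"no-coverage:{role}",))
    for role in ROLES:
        ref_n, alt_n = pileup[role]
        if ref_n + alt_n < min_dp:
            reasons.append(f"DP<{min_dp}:{role}")
    mother = candidate.samples["mother"].gt
    father = candidate.samples["father"].gt
    if set(mother) == {0} and set(father) == {0}:
        for role in ("mother", "father"):
            if pileup[role][1] > 0:
                reasons.append(f"parent-alt-reads:{role}")
    elif set(mother) == {1} and set(father) == {1}:
        for role in ("mother", "father"):
            if pileup[role][0] > 0:
                reasons.append(f"parent-ref-reads:{role}")
    ref_n, alt_n = pileup["fetus"]
    if ref_n + alt_n == 0:
        reasons.append("no-coverage:fetus")
    else:
        ab = alt_n / (ref_n + alt_n)
        if not (ab_range[0] <= ab <= ab_range[1]):
            reasons.append(f"allele-balance:{ab:.3f}")
    return FilterResult(passed=not reasons, reasons=tuple(reasons))


@dataclass(frozen=True)
class PipelineResult:
    calls: list[DenovoCall]
    stage_counts: dict[str, int]

    def stage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"stage": k, "n_retained": v} for k, v in self.stage_counts.items()]
        )


STAGES = ("input", "chromosomes", "hard_filter", "density_filter", "possible_denovo", "refine")


def run_denovo_pipeline(
    records: list[TrioVariantRecord],
    pileups: dict[tuple[str, int], dict[str, tuple[int, int]]],
    allowed_chroms: set[str] | None = None,
    min_gq: int = 30,
    min_dp: int = 20,
    ab_range: tuple[float, float] = (0.3, 0.7),
    density_window: int = 100,
    density_max: int = 4,
) -> PipelineResult:
    """Run the full cascade in stage order and keep per-stage counts.

    ``pileups`` is keyed by (chrom, pos) -> role -> (ref_reads, alt_reads).
    """
    counts = {"input": len(records)}
    stage: list[tuple[TrioVariantRecord, list[str]]]
    if allowed_chroms is not None:
        stage = [(r, ["chromosomes"]) for r in records if r.chrom in allowed_chroms]
    else:
        stage = [(r, ["chromosomes"]) for r in records]
    counts["chromosomes"] = len(stage)

    stage = [(r, t + ["hard_filter"]) for r, t in stage if hard_filter(r).passed]
    counts["hard_filter"] = len(stage)

    retained = density_filter([r for r, _ in stage], density_window, density_max)
    retained_keys = {(r.chrom, r.pos, r.ref, r.alt) for r in retained}
    stage = [
        (r, t + ["density_filter"])
        for r, t in stage
        if (r.chrom, r.pos, r.ref, r.alt) in retained_keys
    ]
    counts["density_filter"] = len(stage)

    stage = [
        (r, t + ["possible_denovo"])
        for r, t in stage
        if possible_denovo(r, min_gq=min_gq).passed
    ]
    counts["possible_denovo"] = len(stage)

    calls: list[DenovoCall] = []
    for r, trail in stage:
        site_pileup = pileups.get((r.chrom, r.pos))
        if site_pileup is None:
            continue
        if refine_denovo(r, site_pileup, min_dp=min_dp, ab_range=ab_range).passed:
            calls.append(
                DenovoCall(
                    record=r,
                    var_class=r.var_class,
                    substitution=r.substitution,
                    passed_stages=tuple(trail + ["refine"]),
                )
            )
    counts["refine"] = len(calls)
    return PipelineResult(calls=calls, stage_counts=counts)


def read_pileup_tsv(path: str) -> dict[tuple[str, int], dict[str, tuple[int, int]]]:
    """Read per-site read counts (chrom, pos, sample, ref_count, alt_count)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    pileups: dict[tuple[str, int], dict[str, tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        pileups.setdefault((row.chrom, int(row.pos)), {})[row.sample] = (
            int(row.ref_count),
            int(row.alt_count),
        )
    return pileups


def calls_to_frame(calls: list[DenovoCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.record.chrom,
                "pos": c.record.pos,
                "ref": c.record.ref,
                "alt": c.record.alt,
                "class": c.var_class,
                "substitution": c.substitution or "",
                "stages": ">".join(c.passed_stages),
            }
            for c in calls
        ]
    )


def write_denovo_vcf(calls: list[DenovoCall], path: str, contigs: dict[str, int]) -> None:
    """Write final de novo calls as a minimal sites-plus-genotypes VCF."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for role in ROLES:
        header.add_sample(role)
    with pysam.VariantFile(path, "w", header=header) as out:
        for c in calls:
            r = c.record
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt), qual=r.qual
            )
            for role in ROLES:
                rec.samples[role]["GT"] = tuple(
                    a if a is not None else None for a in r.samples[role].gt
                )
            out.write(rec)
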