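"""Experiment-level summaries and single-blastomere multiplex statistics.

Aggregates per-embryo outcomes into the summary-table shape used for
multiplex zygote-injection experiments (n analyzed / edited / indel /
intended-conversion / 100%-conversion, with single/double/triple tiers),
and per-blastomere genotypes into multiplex-efficiency rate tables.

Percentage conventions (reverse-engineered from the printed summary
tables and asserted in tests): edited% is over embryos analyzed; indel%
and intended% over edited embryos; tier% over edited embryos; the
"100% tier-k" percentage is over the tier-k embryos themselves (single-
site experiments: 100% over the intended-conversion count). Percentages
are rounded to one decimal, half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .genotyping import CloneCall, EmbryoOutcome


def pct(count: int, denom: int) -> float:
    """Percentage rounded to one decimal, half away from zero (19.4, 94.9...)."""
    if denom == 0:
        return 0.0
    value = Decimal(count) * 100 / Decimal(denom)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MultiplexRecord:
    """Tier classification of one embryo across the experiment's sites."""

    embryo_id: str
    edited: bool
    tier: int       # sites with >=1 intended conversion
    full_tier: int  # sites fully converted (some editable position at 100%)


def classify_embryo_multiplex(outcome: EmbryoOutcome) -> MultiplexRecord:
    """Count the sites with intended conversions and with 100% conversion.

    Embryos edited only by indels or unintended conversions still count as
    edited but sit at tier 0.
    """
    flags = outcome.flags.values()
    return MultiplexRecord(
        embryo_id=outcome.embryo_id,
        edited=any(f.edited for f in flags),
        tier=sum(f.has_intended for f in flags),
        full_tier=sum(f.fully_converted for f in flags),
    )


@dataclass(frozen=True)
class ExperimentSummary:
    n_analyzed: int
    n_edited: int
    n_indel: int
    n_intended: int
    n_full: int
    tiers: dict[int, int]
    full_tiers: dict[int, int]

    @property
    def edited_pct(self) -> float:
        return pct(self.n_edited, self.n_analyzed)

    @property
    def indel_pct(self) -> float:
        return pct(self.n_indel, self.n_edited)

    @property
    def intended_pct(self) -> float:
        return pct(self.n_intended, self.n_edited)

    @property
    def full_pct(self) -> float:
        """100%-conversion embryos over intended-conversion embryos."""
        return pct(self.n_full, self.n_intended)

    def tier_pct(self, k: int) -> float:
        return pct(self.tiers.get(k, 0), self.n_edited)

    def full_tier_pct(self, k: int) -> float:
        """Embryos of tier k whose k edited sites are all at 100%."""
        return pct(self.full_tiers.get(k, 0), self.tiers.get(k, 0))

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "analyzed": self.n_analyzed,
            "edited": self.n_edited,
            "edited_pct": self.edited_pct,
            "indel": self.n_indel,
            "indel_pct": self.indel_pct,
            "intended": self.n_intended,
            "intended_pct": self.intended_pct,
            "full_conversion": self.n_full,
            "full_conversion_pct": self.full_pct,
        }
        for k in sorted(self.tiers):
            rows[f"tier{k}"] = self.tiers[k]
            rows[f"tier{k}_pct"] = self.tier_pct(k)
            rows[f"tier{k}_full"] = self.full_tiers.get(k, 0)
            rows[f"tier{k}_full_pct"] = self.full_tier_pct(k)
        return pd.DataFrame([rows])


def summarize_experiment(outcomes: list[EmbryoOutcome]) -> ExperimentSummary:
    """Summary-table counts and percentages for one injection experiment."""
    if not outcomes:
        raise ValueError("at least one embryo outcome required")
    records = [classify_embryo_multiplex(o) for o in outcomes]
    n_edited = sum(r.edited for r in records)
    tiers: dict[int, int] = {}
    full_tiers: dict[int, int] = {}
    for r in records:
        if r.tier >= 1:
            tiers[r.tier] = tiers.get(r.tier, 0) + 1
            if r.full_tier >= r.tier:
                full_tiers[r.tier] = full_tiers.get(r.tier, 0) + 1
    n_indel = sum(
        any(f.has_indel for f in o.flags.values()) and r.edited
        for o, r in zip(outcomes, records)
    )
    n_intended = sum(r.tier >= 1 for r in records)
    n_full = sum(r.full_tier >= 1 for r in records)
    return ExperimentSummary(
        n_analyzed=len(outcomes),
        n_edited=n_edited,
        n_indel=n_indel,
        n_intended=n_intended,
        n_full=n_full,
        tiers=tiers,
        full_tiers=full_tiers,
    )


SITE_CALLS = ("hom_edited", "het_edited", "WT", "indel", "unintended", "uninformative")


@dataclass(frozen=True)
class BlastomereGenotype:
    embryo_id: str
    blastomere_id: str
    site_calls: dict[str, str]  # site -> one of SITE_CALLS

    @property
    def multiplex_tier(self) -> int:
        return sum(c in ("hom_edited", "het_edited") for c in self.site_calls.values())

    def edited_at(self, sites) -> bool:
        return all(
            self.site_calls.get(s) in ("hom_edited", "het_edited") for s in sites
        )


def call_blastomere_genotype(
    embryo_id: str,
    blastomere_id: str,
    calls_by_site: dict[str, list[CloneCall]],
    min_clones: int = 3,
) -> BlastomereGenotype:
    """Genotype one blastomere per site from its clone calls.

    Zygosity comes from clone counts, not read depth: homozygous-edited
    means every informative clone carries the intended conversion,
    heterozygous means intended and WT alleles are both observed. Sites
    with fewer than ``min_clones`` informative clones are uninformative.
    Within a blastomere, indel clones dominate, then unintended/mixed,
    then the intended/WT zygosity calls.
    """
    site_calls: dict[str, str] = {}
    for name, calls in calls_by_site.items():
        informative = [c for c in calls if c.informative]
        if len(informative) < min_clones:
            site_calls[name] = "uninformative"
            continue
        if any(c.category == "indel" for c in informative):
            site_calls[name] = "indel"
        elif any(c.category in ("unintended", "mixed") for c in informative):
            site_calls[name] = "unintended"
        elif all(c.category == "intended" for c in informative):
            site_calls[name] = "hom_edited"
        elif any(c.category == "intended" for c in informative):
            site_calls[name] = "het_edited"
        else:
            site_calls[name] = "WT"
    return BlastomereGenotype(
        embryo_id=embryo_id, blastomere_id=blastomere_id, site_calls=site_calls
    )


@dataclass(frozen=True)
class BlastomereRates:
    """Overall pie-chart fractions and per-embryo bar-graph counts."""

    counts: dict[str, int]
    total: int
    per_embryo: pd.DataFrame

    def pct_of(self, category: str) -> float:
        return pct(self.counts.get(category, 0), self.total)

    @property
    def fractions(self) -> dict[str, float]:
        return {k: v / self.total for k, v in self.counts.items()}


def _category(g: BlastomereGenotype, design: list[str]) -> str:
    tier = sum(g.site_calls.get(s) in ("hom_edited", "het_edited") for s in design)
    if tier >= 2:
        return f"edited_{tier}_sites"
    if tier == 1:
        edited_site = next(
            s for s in design if g.site_calls.get(s) in ("hom_edited", "het_edited")
        )
        return f"single_{edited_site}"
    calls = [g.site_calls.get(s, "uninformative") for s in design]
    if "indel" in calls:
        return "indel"
    if "unintended" in calls:
        return "unintended"
    if all(c == "uninformative" for c in calls):
        return "uninformative"
    return "WT"


def aggregate_blastomeres(
    genotypes: list[BlastomereGenotype], design: list[str]
) -> BlastomereRates:
    """Exclusive-category blastomere counts over an experiment design.

    Category precedence mirrors the exclusive colour codes of the
    genotyping figures: multiplex-edited > single-site-edited > indel >
    unintended > WT.
    """
    if not genotypes:
        raise ValueError("at least one blastomere genotype required")
    counts: dict[str, int] = {}
    rows = []
    for g in genotypes:
        cat = _category(g, design)
        counts[cat] = counts.get(cat, 0) + 1
        rows.append(
            {"embryo_id": g.embryo_id, "blastomere_id": g.blastomere_id, "category": cat}
        )
    per_embryo = (
        pd.DataFrame(rows)
        .groupby(["embryo_id", "category"])
        .size()
        .rename("n")
        .reset_index()
    )
    return BlastomereRates(counts=counts, total=len(genotypes), per_embryo=per_embryo)


def multiplex_rate(
    genotypes: list[BlastomereGenotype], sites: list[str]
) -> tuple[int, int, float]:
    """(count, total, %) of blastomeres edited at every site in ``sites``.

    This is the quoted single-cell efficiency: e.g. double-editing counts
    blastomeres hom- or het-edited at both sites of a two-site design.
    """
    count = sum(g.edited_at(sites) for g in genotypes)
    return count, len(genotypes), pct(count, len(genotypes))
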