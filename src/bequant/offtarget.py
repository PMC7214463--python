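"""Guide-dependent off-target enumeration and deaminase-excess spectra.

``scan_offtargets`` enumerates every genomic position, on both strands,
where the PAM pattern is satisfied and the protospacer differs from the
spacer by at most ``max_mismatch`` substitutions (no bulges).
``overlap_variants_sites`` intersects de novo variants with candidate
sites. The spectrum operations estimate guide-independent deaminase
activity as the observed-minus-expected excess of C>T / G>A de novo
counts, with expectations drawn from a reference SNP substitution-class
frequency table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .denovo import DenovoCall
from .editors import IUPAC, revcomp

#: all 12 reference-strand substitution classes; C>T and G>A are tracked
#: separately (complementary readouts of cytosine deamination).
SUBSTITUTION_CLASSES = tuple(
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
)

#: pyrimidine-centred collapse (6 classes), for comparison only.
COLLAPSE_6 = {
    "C>T": "C>T", "G>A": "C>T",
    "C>A": "C>A", "G>T": "C>A",
    "C>G": "C>G", "G>C": "C>G",
    "T>A": "T>A", "A>T": "T>A",
    "T>C": "T>C", "A>G": "T>C",
    "T>G": "T>G", "A>C": "T>G",
}


@dataclass(frozen=True)
class OfftargetSite:
    """A spacer+PAM match; coordinates 0-based half-open on the plus strand."""

    chrom: str
    start: int
    end: int
    strand: str
    n_mismatches: int
    matched_sequence: str  # protospacer-strand sequence (spacer-equivalent)

    def to_bed_fields(self) -> tuple:
        return (
            self.chrom,
            self.start,
            self.end,
            f"mm{self.n_mismatches}",
            self.n_mismatches,
            self.strand,
        )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype="S1")


def _scan_strand(seq: str, spacer: str, pam: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(start, n_mismatches) of hits on the given (already oriented) sequence."""
    L, P = len(spacer), len(pam)
    n = len(seq)
    if n < L + P:
        return []
    arr = _encode(seq)
    m = n - L - P + 1
    mm = np.zeros(m, dtype=np.int16)
    sp = _encode(spacer)
    for k in range(L):
        mm += arr[k:k + m] != sp[k]
    pam_ok = np.ones(m, dtype=bool)
    for k, code in enumerate(pam):
        allowed = np.frombuffer(IUPAC[code].encode(), dtype="S1")
        pam_ok &= np.isin(arr[L + k:L + k + m], allowed)
    hits = np.nonzero((mm <= max_mismatch) & pam_ok)[0]
    return [(int(i), int(mm[i])) for i in hits]


def scan_offtargets(
    genome: dict[str, str],
    spacer: str,
    pam: str,
    max_mismatch: int,
) -> list[OfftargetSite]:
    """Exhaustive mismatch+PAM search over both strands of a genome.

    ``genome`` maps chromosome name to sequence. Mismatches are counted
    over the spacer only; the PAM must match its degenerate pattern
    exactly. Output is deterministic, sorted by (chrom, start, strand).
    """
    spacer = spacer.upper()
    if set(spacer) - set("ACGT"):
        raise ValueError("spacer must be plain ACGT")
    if max_mismatch > len(spacer):
        raise ValueError("max_mismatch exceeds spacer length")
    span = len(spacer) + len(pam)
    sites: list[OfftargetSite] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for start, n_mm in _scan_strand(seq, spacer, pam, max_mismatch):
            sites.append(
                OfftargetSite(
                    chrom=chrom,
                    start=start,
                    end=start + span,
                    strand="+",
                    n_mismatches=n_mm,
                    matched_sequence=seq[start:start + len(spacer)],
                )
            )
        rc = revcomp(seq)
        n = len(seq)
        for rc_start, n_mm in _scan_strand(rc, spacer, pam, max_mismatch):
            start = n - rc_start - span
            sites.append(
                OfftargetSite(
                    chrom=chrom,
                    start=start,
                    end=start + span,
                    strand="-",
                    n_mismatches=n_mm,
                    matched_sequence=rc[rc_start:rc_start + len(spacer)],
                )
            )
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def write_sites_bed(sites: list[OfftargetSite], path: str) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write("\t".join(str(x) for x in s.to_bed_fields()) + "\n")


def read_sites_bed(path: str) -> list[OfftargetSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, _name, score, strand = line.rstrip("\n").split("\t")[:6]
            sites.append(
                OfftargetSite(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    n_mismatches=int(score),
                    matched_sequence="",
                )
            )
    return sites


def overlap_variants_sites(
    denovo: list[DenovoCall],
    sites: list[OfftargetSite],
    slop: int = 0,
) -> list[tuple[DenovoCall, OfftargetSite]]:
    """Interval intersection of de novo variants with candidate sites.

    Each variant occupies the 0-based span of its reference allele; site
    spans are padded by ``slop`` on each side. Raises if the two inputs
    use completely disjoint chromosome name sets (likely a naming-scheme
    mismatch, e.g. ``chr1`` vs ``1``).
    """
    if denovo and sites:
        var_chroms = {c.record.chrom for c in denovo}
        site_chroms = {s.chrom for s in sites}
        if not var_chroms & site_chroms:
            raise ValueError(
                "no shared chromosome names between variants "
                f"{sorted(var_chroms)} and sites {sorted(site_chroms)}"
            )
    trees: dict[str, IntervalTree] = {}
    for idx, s in enumerate(sites):
        start = max(0, s.start - slop)
        trees.setdefault(s.chrom, IntervalTree()).addi(start, s.end + slop, idx)
    pairs: list[tuple[DenovoCall, OfftargetSite]] = []
    for call in denovo:
        tree = trees.get(call.record.chrom)
        if tree is None:
            continue
        v_start = call.record.pos - 1
        v_end = v_start + len(call.record.ref)
        hits = sorted(tree.overlap(v_start, v_end), key=lambda iv: iv.data)
        pairs.extend((call, sites[iv.data]) for iv in hits)
    return pairs


@dataclass(frozen=True)
class SubstitutionSpectrum:
    """Counts or fractions keyed by reference-strand substitution class."""

    values: dict[str, float]
    kind: str  # "counts" or "fractions"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "fractions"):
            raise ValueError("kind must be 'counts' or 'fractions'")
        if any(v < 0 for v in self.values.values()):
            raise ValueError("spectrum values must be non-negative")

    @property
    def total(self) -> float:
        return sum(self.values.values())

    def fractions(self) -> "SubstitutionSpectrum":
        if self.kind == "fractions":
            return self
        total = self.total
        if total == 0:
            raise ValueError("cannot normalise an empty spectrum")
        return SubstitutionSpectrum(
            {k: v / total for k, v in self.values.items()}, "fractions"
        )

    def collapse6(self) -> "SubstitutionSpectrum":
        out: dict[str, float] = {}
        for k, v in self.values.items():
            out[COLLAPSE_6[k]] = out.get(COLLAPSE_6[k], 0.0) + v
        return SubstitutionSpectrum(out, self.kind)


def spectrum_from_calls(calls: list[DenovoCall]) -> SubstitutionSpectrum:
    """Observed substitution-class counts over final de novo SNVs."""
    values = {k: 0.0 for k in SUBSTITUTION_CLASSES}
    for c in calls:
        if c.substitution is not None:
            values[c.substitution] = values.get(c.substitution, 0.0) + 1
    return SubstitutionSpectrum(values, "counts")


def read_spectrum_tsv(path: str, kind: str) -> SubstitutionSpectrum:
    """Two-column TSV (class, value) -> spectrum."""
    df = pd.read_csv(path, sep="\t", header=None, names=["class", "value"], comment="#")
    return SubstitutionSpectrum(
        dict(zip(df["class"], df["value"].astype(float))), kind
    )


def expected_spectrum(
    total_denovo: int, reference_fractions: SubstitutionSpectrum
) -> SubstitutionSpectrum:
    """Expected class counts: total de novo SNVs times the reference fraction.

    The reference fractions (e.g. from a species SNP catalogue) must be
    normalised to 1.
    """
    if reference_fractions.kind != "fractions":
        raise ValueError("reference spectrum must hold fractions")
    if abs(reference_fractions.total - 1.0) > 1e-9:
        raise ValueError(
            f"fractions must sum to 1 (got {reference_fractions.total})"
        )
    return SubstitutionSpectrum(
        {k: total_denovo * f for k, f in reference_fractions.values.items()}, "counts"
    )


def excess_substitutions(
    observed: SubstitutionSpectrum, expected: SubstitutionSpectrum
) -> tuple[dict[str, float], float]:
    """Per-class observed-minus-expected counts, plus the deaminase excess.

    The second return value sums the cytosine-deamination-relevant classes
    (C>T plus G>A); negative per-class values are kept as-is.
    """
    if set(observed.values) != set(expected.values):
        raise ValueError(
            "class key mismatch: "
            f"{sorted(set(observed.values) ^ set(expected.values))}"
        )
    excess = {k: observed.values[k] - expected.values[k] for k in observed.values}
    deaminase = excess.get("C>T", 0.0) + excess.get("G>A", 0.0)
    return excess, deaminase
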