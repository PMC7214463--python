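"""Clone alignment and per-clone editing-outcome classification.

Each sequenced clone (a Sanger-sequenced plasmid from a cloned PCR
amplicon) is globally aligned to the reference amplicon, the bases at the
protospacer positions are read off, and the clone is classified as
WT / intended / unintended / mixed / indel:

* intended — at least one substrate->product conversion (C->T for a CBE,
  A->G for an ABE, bystanders included) and no other substitution in the
  spacer;
* unintended — at least one non-product substitution and no intended one;
* mixed — both kinds present;
* indel — any insertion or deletion overlapping the spacer (+/- a margin);
  takes precedence over the substitution categories.

Per-position conversion frequencies use position-specific denominators
(clones with an ungapped base at that position); the indel frequency uses
all informative clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .editors import EditorSpec, TargetSite, revcomp

_VALID = set("ACGTN")

CATEGORIES = ("WT", "intended", "unintended", "mixed", "indel")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -8
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class CloneAlignment:
    """A gapped global alignment of (reference, clone)."""

    ref_aln: str
    query_aln: str
    score: float


def _left_normalize(a: str, b: str) -> tuple[str, str]:
    """Shift score-neutral gap runs to their leftmost position.

    A gap run in one string may slide left by one column whenever the
    flanking bases of the other string are equal, leaving the score
    unchanged; iterating to a fixpoint gives a canonical placement.
    """
    xs, ys = list(a), list(b)
    changed = True
    while changed:
        changed = False
        for x, y in ((xs, ys), (ys, xs)):
            i = 0
            n = len(x)
            while i < n:
                if y[i] == "-":
                    j = i
                    while j < n and y[j] == "-":
                        j += 1
                    while (
                        i > 0
                        and y[i - 1] != "-"
                        and x[i - 1] != "-"
                        and x[i - 1] == x[j - 1]
                    ):
                        y[i - 1], y[j - 1] = y[j - 1], y[i - 1]
                        i -= 1
                        j -= 1
                        changed = True
                    i = j
                else:
                    i += 1
    return "".join(xs), "".join(ys)


def align_clone(clone_seq: str, amplicon_ref: str) -> CloneAlignment:
    """Global alignment of a clone against the reference amplicon.

    Scoring: match +2, mismatch -3, gap open -8, gap extend -1; gap runs
    are left-normalized so indel coordinates are deterministic.
    """
    clone_seq = clone_seq.upper()
    amplicon_ref = amplicon_ref.upper()
    if not clone_seq or not amplicon_ref:
        raise ValueError("empty sequence")
    for name, seq in (("clone", clone_seq), ("amplicon", amplicon_ref)):
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"{name} contains non-ACGTN characters: {sorted(bad)}")
    aln = _ALIGNER.align(amplicon_ref, clone_seq)[0]
    ref_aln, query_aln = _left_normalize(aln[0], aln[1])
    return CloneAlignment(ref_aln=ref_aln, query_aln=query_aln, score=aln.score)


@dataclass(frozen=True)
class CloneCall:
    """Classification of one clone at one target site."""

    clone_id: str
    per_position_base: dict[int, str]  # protospacer position -> base or '-'
    has_indel: bool
    category: str
    informative: bool
    intended_positions: tuple[int, ...] = ()
    unintended_positions: tuple[int, ...] = ()
    background_mismatches: int = 0

    def allele_string(self) -> str:
        positions = sorted(self.per_position_base)
        s = "".join(self.per_position_base[p] for p in positions)
        return s + ("|indel" if self.has_indel else "")


def classify_clone(
    alignment: CloneAlignment,
    site: TargetSite,
    editor: EditorSpec,
    clone_id: str = "clone",
    max_background_mismatches: int = 5,
    indel_margin: int = 5,
) -> CloneCall:
    """Read protospacer bases off the alignment and categorise the clone.

    Substitutions outside the spacer (+/- ``indel_margin``) never change
    the category but are counted as background mismatches; clones
    exceeding ``max_background_mismatches`` of them, or not covering any
    spacer position, are marked uninformative (WGA/PCR clones carry
    occasional random errors).

    Minus-strand sites are read back onto the protospacer strand so that
    conversions always report as C->T / A->G regardless of the amplicon
    orientation.
    """
    ref_aln, query_aln = alignment.ref_aln, alignment.query_aln

    # leading/trailing query gaps are truncation, not indels
    lead = 0
    while lead < len(query_aln) and query_aln[lead] == "-":
        lead += 1
    trail = len(query_aln)
    while trail > lead and query_aln[trail - 1] == "-":
        trail -= 1

    # map 0-based reference index -> (column, query char); detect insertions
    ref_index_col: dict[int, int] = {}
    insertion_after_ref: set[int] = set()  # insertion between ref index r-1 and r
    r = 0
    for col, (rc, qc) in enumerate(zip(ref_aln, query_aln)):
        if rc == "-":
            if lead <= col < trail:
                insertion_after_ref.add(r)
        else:
            ref_index_col[r] = col
            r += 1

    span_start = site.spacer_start
    span_end = site.spacer_start + site.spacer_len
    ext_start = max(0, span_start - indel_margin)
    ext_end = min(len(site.amplicon_ref), span_end + indel_margin)

    has_indel = any(ext_start < r <= ext_end for r in insertion_after_ref)
    if not has_indel:
        for ri in range(ext_start, ext_end):
            col = ref_index_col.get(ri)
            if col is not None and lead <= col < trail and query_aln[col] == "-":
                has_indel = True
                break

    per_position: dict[int, str] = {}
    for p in range(1, site.spacer_len + 1):
        ri = site.plus_index(p)
        col = ref_index_col.get(ri)
        if col is None or not (lead <= col < trail):
            per_position[p] = "-"
            continue
        obs = query_aln[col]
        if obs in "ACGT" and site.strand == "-":
            obs = revcomp(obs)
        per_position[p] = obs if obs in "ACGT" else "-"

    informative_positions = [p for p, b in per_position.items() if b in "ACGT"]
    background = 0
    for ri, col in ref_index_col.items():
        if ext_start <= ri < ext_end:
            continue
        if lead <= col < trail:
            qc = query_aln[col]
            if qc in "ACGT" and qc != ref_aln[col]:
                background += 1

    informative = bool(informative_positions) and background <= max_background_mismatches
    if not informative:
        return CloneCall(
            clone_id=clone_id,
            per_position_base=per_position,
            has_indel=has_indel,
            category="uninformative",
            informative=False,
            background_mismatches=background,
        )

    substrate = {p: base for p, base, _ in site.substrate_positions}
    intended: list[int] = []
    unintended: list[int] = []
    for p in informative_positions:
        ref_base = site.spacer[p - 1]
        obs = per_position[p]
        if obs == ref_base:
            continue
        if p in substrate and obs == editor.product:
            intended.append(p)
        else:
            unintended.append(p)

    if has_indel:
        category = "indel"
    elif intended and unintended:
        category = "mixed"
    elif unintended:
        category = "unintended"
    elif intended:
        category = "intended"
    else:
        category = "WT"

    return CloneCall(
        clone_id=clone_id,
        per_position_base=per_position,
        has_indel=has_indel,
        category=category,
        informative=True,
        intended_positions=tuple(sorted(intended)),
        unintended_positions=tuple(sorted(unintended)),
        background_mismatches=background,
    )


def classify_clones(
    clone_seqs: list[tuple[str, str]],
    site: TargetSite,
    editor: EditorSpec,
    max_background_mismatches: int = 5,
    indel_margin: int = 5,
) -> list[CloneCall]:
    """Align and classify ``(clone_id, sequence)`` pairs against one site.

    Identical sequences are aligned once and the call reused, which makes
    large simulated clone sets cheap.
    """
    cache: dict[str, CloneCall] = {}
    calls = []
    for clone_id, seq in clone_seqs:
        seq = seq.upper()
        cached = cache.get(seq)
        if cached is None:
            aln = align_clone(seq, site.amplicon_ref)
            cached = classify_clone(
                aln, site, editor,
                clone_id=clone_id,
                max_background_mismatches=max_background_mismatches,
                indel_margin=indel_margin,
            )
            cache[seq] = cached
        calls.append(
            CloneCall(
                clone_id=clone_id,
                per_position_base=cached.per_position_base,
                has_indel=cached.has_indel,
                category=cached.category,
                informative=cached.informative,
                intended_positions=cached.intended_positions,
                unintended_positions=cached.unintended_positions,
                background_mismatches=cached.background_mismatches,
            )
        )
    return calls


@dataclass(frozen=True)
class SiteFrequencies:
    """Per-position conversion frequencies for one site in one embryo.

    Frequencies are conversion-positive clones over informative clones at
    that position; ``None`` marks positions with no informative clone
    (undefined, never reported as 0).
    """

    intended: dict[int, float | None]
    unintended: dict[int, float | None]
    indel_frequency: float
    n_clones: int
    n_informative: dict[int, int]
    editable_positions: tuple[int, ...] = ()


def site_frequencies(
    calls: list[CloneCall],
    site: TargetSite | None = None,
    editor: EditorSpec | None = None,
) -> SiteFrequencies:
    """Aggregate clone calls into per-position frequencies.

    Uninformative clones are excluded everywhere; indel clones count in the
    indel denominator but contribute per-position data only where ungapped.
    """
    informative = [c for c in calls if c.informative]
    if not informative:
        raise ValueError("no informative clones")
    positions: set[int] = set()
    for c in informative:
        positions.update(c.per_position_base)
    intended: dict[int, float | None] = {}
    unintended: dict[int, float | None] = {}
    n_informative: dict[int, int] = {}
    for p in sorted(positions):
        covered = [c for c in informative if c.per_position_base.get(p, "-") in "ACGT"]
        n_informative[p] = len(covered)
        if not covered:
            intended[p] = None
            unintended[p] = None
            continue
        intended[p] = sum(p in c.intended_positions for c in covered) / len(covered)
        unintended[p] = sum(p in c.unintended_positions for c in covered) / len(covered)
    editable: tuple[int, ...] = ()
    if site is not None and editor is not None:
        editable = tuple(p for p, _, in_w in site.substrate_positions if in_w)
    return SiteFrequencies(
        intended=intended,
        unintended=unintended,
        indel_frequency=sum(c.has_indel for c in informative) / len(informative),
        n_clones=len(informative),
        n_informative=n_informative,
        editable_positions=editable,
    )


@dataclass(frozen=True)
class SiteFlags:
    """Per-site qualitative flags for one embryo."""

    edited: bool
    has_intended: bool
    fully_converted: bool
    mosaic: bool
    has_indel: bool
    has_unintended: bool


@dataclass(frozen=True)
class EmbryoOutcome:
    embryo_id: str
    freqs: dict[str, SiteFrequencies]
    flags: dict[str, SiteFlags]


def embryo_outcome(
    embryo_id: str,
    calls_by_site: dict[str, list[CloneCall]],
    sites: dict[str, tuple[TargetSite, EditorSpec]] | None = None,
) -> EmbryoOutcome:
    """Summarise one embryo across its assayed sites.

    ``fully_converted`` requires an in-window editable position with
    intended frequency 1.0 (when site/editor context is supplied;
    otherwise any position qualifies); ``mosaic`` means >=2 distinct
    allele strings among informative clones.
    """
    if not calls_by_site:
        raise ValueError("at least one site required")
    freqs: dict[str, SiteFrequencies] = {}
    flags: dict[str, SiteFlags] = {}
    for name, calls in calls_by_site.items():
        site_editor = sites.get(name) if sites else None
        f = site_frequencies(calls, *(site_editor or (None, None)))
        informative = [c for c in calls if c.informative]
        edited = any(c.category != "WT" for c in informative)
        has_intended = any(c.intended_positions for c in informative)
        check_positions = f.editable_positions or tuple(f.intended)
        fully = any(
            f.intended.get(p) == 1.0 and f.n_informative.get(p, 0) > 0
            for p in check_positions
        )
        mosaic = len({c.allele_string() for c in informative}) >= 2
        freqs[name] = f
        flags[name] = SiteFlags(
            edited=edited,
            has_intended=has_intended,
            fully_converted=fully,
            mosaic=mosaic,
            has_indel=any(c.has_indel for c in informative),
            has_unintended=any(c.unintended_positions for c in informative),
        )
    return EmbryoOutcome(embryo_id=embryo_id, freqs=freqs, flags=flags)
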