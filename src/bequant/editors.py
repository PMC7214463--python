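"""Base editors, target sites, and the protospacer coordinate system.

All conversion accounting in this package is done in protospacer
coordinates: 1-based positions along the spacer, position 1 being the
5'-most (PAM-distal) base, the PAM lying immediately 3' of position
``spacer_len``. A cytosine base editor (CBE) converts C->T and an adenine
base editor (ABE) converts A->G within an editor-specific activity window
of protospacer positions; substrate bases outside the window (bystanders)
are still tracked, flagged out-of-window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterator

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement; degenerate IUPAC codes are complemented too."""
    return seq.translate(_COMP)[::-1]


def iupac_match(base: str, code: str) -> bool:
    return base in IUPAC.get(code, "")


def pam_matches(seq: str, pattern: str) -> bool:
    """True if ``seq`` satisfies the degenerate PAM ``pattern`` base by base."""
    if len(seq) != len(pattern):
        return False
    return all(iupac_match(b, c) for b, c in zip(seq, pattern))


class UnknownEditorError(KeyError):
    """Requested editor name is not in the registry."""


class ProtospacerNotFoundError(ValueError):
    """Spacer + PAM not found on either strand of the amplicon."""


class AmbiguousProtospacerError(ValueError):
    """Spacer + PAM matches the amplicon at more than one location."""

    def __init__(self, matches: list[tuple[int, str]]):
        self.matches = matches
        coords = ", ".join(f"{start}({strand})" for start, strand in matches)
        super().__init__(f"protospacer matches at multiple coordinates: {coords}")


@dataclass(frozen=True)
class EditorSpec:
    """A base editor's chemistry and targeting rules.

    Parameters
    ----------
    name : str
        Short identifier, e.g. ``"BE3"``.
    conversion : tuple of str
        ``(substrate, product)`` on the protospacer strand, either
        ``("C", "T")`` or ``("A", "G")``.
    window : tuple of int
        Closed 1-based interval of protospacer positions in which the
        deaminase is active ("core" window).
    pam : str
        Degenerate IUPAC pattern required immediately 3' of the spacer.
    spacer_len : int
        Spacer length in nucleotides.
    """

    name: str
    conversion: tuple[str, str]
    window: tuple[int, int]
    pam: str
    spacer_len: int = 20

    def __post_init__(self) -> None:
        if tuple(self.conversion) not in {("C", "T"), ("A", "G")}:
            raise ValueError(f"conversion must be C->T or A->G, got {self.conversion}")
        lo, hi = self.window
        if not (1 <= lo <= hi <= self.spacer_len):
            raise ValueError(f"window {self.window} outside [1, {self.spacer_len}]")
        if not self.pam or any(c not in IUPAC for c in self.pam):
            raise ValueError(f"PAM {self.pam!r} must be a non-empty IUPAC pattern")

    @property
    def substrate(self) -> str:
        return self.conversion[0]

    @property
    def product(self) -> str:
        return self.conversion[1]

    def in_window(self, position: int) -> bool:
        return self.window[0] <= position <= self.window[1]


#: Editors used in the embryo experiments. SpCas9 scaffolds carry an NGG PAM;
#: the SaCas9-KKH scaffold recognises NNNRRT with a 21-nt spacer.
EDITOR_REGISTRY = MappingProxyType({
    "BE3": EditorSpec("BE3", ("C", "T"), (4, 8), "NGG", 20),
    "BE4-Gam": EditorSpec("BE4-Gam", ("C", "T"), (4, 8), "NGG", 20),
    "SaKKH-BE3": EditorSpec("SaKKH-BE3", ("C", "T"), (3, 12), "NNNRRT", 21),
    "ABE7.10": EditorSpec("ABE7.10", ("A", "G"), (4, 7), "NGG", 20),
})


def build_editor_spec(name: str) -> EditorSpec:
    """Look up a registered editor by name.

    Raises
    ------
    UnknownEditorError
        If ``name`` is not registered. User-defined editors are constructed
        directly via :class:`EditorSpec`.
    """
    try:
        return EDITOR_REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(EDITOR_REGISTRY))
        raise UnknownEditorError(f"unknown editor {name!r}; registered: {known}") from None


@dataclass(frozen=True)
class TargetSite:
    """One amplicon/genomic target of a guide.

    ``spacer_start`` is the 0-based offset of the protospacer span on the
    *plus* strand of the amplicon (half-open span ``[spacer_start,
    spacer_start + spacer_len)``); for ``strand == "-"`` the protospacer
    reads 3'->5' along the plus strand and the PAM lies immediately 5' of
    the span in plus-strand coordinates.

    ``substrate_positions`` lists every substrate base in the spacer as
    ``(protospacer_position, base, in_window)`` so that out-of-window
    (bystander) edits remain trackable.
    """

    locus: str
    amplicon_ref: str
    spacer: str
    spacer_start: int
    strand: str
    pam_seq: str
    substrate_positions: tuple[tuple[int, str, bool], ...]
    intended_edit: str | None = None

    @property
    def spacer_len(self) -> int:
        return len(self.spacer)

    def plus_index(self, position: int) -> int:
        """Map a 1-based protospacer position to a 0-based plus-strand index."""
        if not 1 <= position <= self.spacer_len:
            raise ValueError(f"protospacer position {position} outside spacer")
        if self.strand == "+":
            return self.spacer_start + position - 1
        return self.spacer_start + self.spacer_len - position


def _scan_one_strand(amplicon: str, spacer: str, pam: str) -> Iterator[int]:
    span = len(spacer) + len(pam)
    for i in range(len(amplicon) - span + 1):
        if amplicon[i:i + len(spacer)] == spacer and pam_matches(
            amplicon[i + len(spacer):i + span], pam
        ):
            yield i


def locate_protospacer(
    amplicon: str,
    spacer: str,
    editor: EditorSpec,
    locus: str = "site",
    intended_edit: str | None = None,
) -> TargetSite:
    """Find the unique protospacer+PAM match of ``spacer`` in ``amplicon``.

    Both strands are searched; exactly one match must exist.

    Raises
    ------
    ProtospacerNotFoundError, AmbiguousProtospacerError
    """
    amplicon = amplicon.upper()
    spacer = spacer.upper()
    if len(spacer) != editor.spacer_len:
        raise ValueError(
            f"spacer length {len(spacer)} != editor spacer_len {editor.spacer_len}"
        )
    if len(amplicon) < editor.spacer_len + len(editor.pam):
        raise ValueError("amplicon shorter than spacer + PAM")

    matches: list[tuple[int, str]] = []  # (plus-strand protospacer start, strand)
    for i in _scan_one_strand(amplicon, spacer, editor.pam):
        matches.append((i, "+"))
    rc = revcomp(amplicon)
    for i in _scan_one_strand(rc, spacer, editor.pam):
        # rc span [i, i+L+P) maps to plus span [n-i-L-P, n-i); protospacer
        # occupies the last L bases of that span on the plus strand.
        matches.append((len(amplicon) - i - editor.spacer_len, "-"))

    if not matches:
        raise ProtospacerNotFoundError(
            f"spacer not found with PAM {editor.pam} in amplicon ({locus})"
        )
    if len(matches) > 1:
        raise AmbiguousProtospacerError(matches)

    start, strand = matches[0]
    if strand == "+":
        pam_seq = amplicon[start + editor.spacer_len:start + editor.spacer_len + len(editor.pam)]
    else:
        pam_seq = revcomp(amplicon[start - len(editor.pam):start])
    substrate = tuple(
        (p, spacer[p - 1], editor.in_window(p))
        for p in range(1, editor.spacer_len + 1)
        if spacer[p - 1] == editor.substrate
    )
    return TargetSite(
        locus=locus,
        amplicon_ref=amplicon,
        spacer=spacer,
        spacer_start=start,
        strand=strand,
        pam_seq=pam_seq,
        substrate_positions=substrate,
        intended_edit=intended_edit,
    )


def editable_positions(site: TargetSite, editor: EditorSpec) -> list[tuple[int, str]]:
    """Substrate bases inside the editor's activity window, ascending.

    These are the positions written C4..C8 / A4..A7 etc.; bases outside the
    window are excluded here but remain in ``site.substrate_positions``.
    """
    return [
        (p, base)
        for p, base, in_window in site.substrate_positions
        if in_window and base == editor.substrate
    ]
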