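import pytest

from bequant import build_editor_spec, locate_protospacer

LEFT_FLANK = "ATTACGAATTTAGCATTGAACTTGGCA"
RIGHT_FLANK = "TTAACGGTATTCGATCCATAATGGTCA"

# C at protospacer positions 5 and 6 only; BE3 window 4-8
CBE_SPACER = "GATTCCGTAAGGTAAGATGA"
# A at protospacer positions 5 and 7; ABE window 4-7
ABE_SPACER = "GTTGACATGGCTTGGTCGTG"


def make_amplicon(spacer: str, pam: str = "AGG") -> str:
    return LEFT_FLANK + spacer + pam + RIGHT_FLANK


def mutate(seq: str, index: int, base: str) -> str:
    return seq[:index] + base + seq[index + 1:]


@pytest.fixture(scope="session")
def be3():
    return build_editor_spec("BE3")


@pytest.fixture(scope="session")
def abe():
    return build_editor_spec("ABE7.10")


@pytest.fixture(scope="session")
def cbe_site(be3):
    amplicon = make_amplicon(CBE_SPACER)
    return locate_protospacer(amplicon, CBE_SPACER, be3, locus="FAH-like")


@pytest.fixture(scope="session")
def abe_site(abe):
    amplicon = make_amplicon(ABE_SPACER)
    return locate_protospacer(amplicon, ABE_SPACER, abe, locus="APP-like")
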