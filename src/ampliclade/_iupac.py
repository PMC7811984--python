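"""IUPAC nucleotide ambiguity codes: base sets, complements, minimal covering codes."""

from __future__ import annotations

# code -> set of concrete bases it stands for
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# base set -> minimal code covering exactly that set
SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

IUPAC_CODES = frozenset(IUPAC_SETS)
CONCRETE = ("A", "C", "G", "T")

# precomputed pairwise compatibility: codes whose base sets intersect
MATCH: frozenset[tuple[str, str]] = frozenset(
    (a, b) for a in IUPAC_SETS for b in IUPAC_SETS if IUPAC_SETS[a] & IUPAC_SETS[b]
)


def code_size(code: str) -> int:
    """Number of concrete bases a single IUPAC code represents."""
    try:
        return len(IUPAC_SETS[code])
    except KeyError:
        raise KeyError(f"not an IUPAC nucleotide code: {code!r}") from None


def minimal_code(bases: frozenset[str] | set[str]) -> str:
    """The single IUPAC code covering exactly the given set of concrete bases."""
    return SET_TO_CODE[frozenset(bases)]
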