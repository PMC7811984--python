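"""Degenerate IUPAC primers: degeneracy, expansion, consensus design.

Degeneracy of a primer is the product over positions of the number of
concrete bases each IUPAC code represents; a primer set's degeneracy is the
product of its forward and reverse primers'. ``consensus_primer`` derives
the minimal covering code per column of an alignment window, which
guarantees a 0-mismatch match to every reference in the clade.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from Bio.Seq import Seq

from ._iupac import IUPAC_CODES, IUPAC_SETS, code_size, minimal_code
from .conservation import Msa, ConservationProfile, top_windows
from .errors import AlphabetError, PrimerDesignError
from .seqio import NucRecord

Orientation = Literal["forward", "reverse"]

MIN_PRIMER_LEN = 10
# candidate enumeration default length range, matching the published sets (20-29 nt)
DEFAULT_LENGTH_RANGE = (20, 29)


def _validate_iupac(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - IUPAC_CODES
    if bad:
        raise AlphabetError(f"not IUPAC nucleotide code(s): {sorted(bad)!r}")
    return seq


@dataclass(frozen=True)
class DegeneratePrimer:
    name: str
    seq: str
    orientation: Orientation = "forward"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _validate_iupac(self.seq))
        if len(self.seq) < MIN_PRIMER_LEN:
            raise PrimerDesignError(
                f"primer {self.name!r} is {len(self.seq)} nt; minimum is {MIN_PRIMER_LEN}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerSet:
    name: str
    fw: DegeneratePrimer
    rv: DegeneratePrimer
    target_clade: str
    expected_size: int

    def __post_init__(self) -> None:
        if self.expected_size <= len(self.fw) + len(self.rv):
            raise PrimerDesignError(
                f"set {self.name!r}: expected amplicon size {self.expected_size} "
                f"does not exceed the combined primer length"
            )


def degeneracy(p: DegeneratePrimer | str) -> int:
    """Number of concrete oligonucleotides the degenerate sequence represents."""
    seq = p.seq if isinstance(p, DegeneratePrimer) else _validate_iupac(p)
    d = 1
    for c in seq:
        d *= code_size(c)
    return d


def set_degeneracy(ps: PrimerSet) -> int:
    return degeneracy(ps.fw) * degeneracy(ps.rv)


def expand(p: DegeneratePrimer | str, cap: int = 4096) -> list[str]:
    """All concrete expansions, lexicographic; refuses above ``cap``."""
    seq = p.seq if isinstance(p, DegeneratePrimer) else _validate_iupac(p)
    d = degeneracy(seq)
    if d > cap:
        raise PrimerDesignError(f"degeneracy {d} exceeds expansion cap {cap}")
    per_pos = [sorted(IUPAC_SETS[c]) for c in seq]
    return ["".join(t) for t in itertools.product(*per_pos)]


def reverse_complement(p: DegeneratePrimer) -> DegeneratePrimer:
    """IUPAC-aware reverse complement; an involution that preserves degeneracy."""
    rc = str(Seq(p.seq).reverse_complement())
    flipped: Orientation = "reverse" if p.orientation == "forward" else "forward"
    return DegeneratePrimer(p.name, rc, flipped)


def gc_fraction(seq: str) -> float:
    """GC content of a degenerate sequence: S counts 1, W counts 0, any other
    code counts by the G/C share of its base set."""
    total = 0.0
    for c in _validate_iupac(seq):
        bases = IUPAC_SETS[c]
        total += len(bases & {"G", "C"}) / len(bases)
    return total / len(seq)


def consensus_primer(
    msa_slice: Msa,
    max_degeneracy: int,
    name: str = "candidate",
    orientation: Orientation = "forward",
    gc_range: tuple[float, float] | None = None,
) -> DegeneratePrimer:
    """Minimal-covering-code consensus over an alignment window.

    Every observed base at a column is covered by the reported code, so the
    primer matches every row of the window with zero mismatches. Columns
    containing gaps refuse outright; if total degeneracy exceeds
    ``max_degeneracy`` the refusal names the ambiguous columns. ``gc_range``
    optionally rejects candidates outside a GC-content band.
    """
    codes: list[str] = []
    gap_cols = [i for i in range(msa_slice.ncol) if "-" in msa_slice.column(i)]
    if gap_cols:
        raise PrimerDesignError(f"gap character in window column(s) {gap_cols}")
    for i in range(msa_slice.ncol):
        observed: set[str] = set()
        for c in msa_slice.column(i):
            observed |= IUPAC_SETS[c]
        codes.append(minimal_code(observed))
    d = 1
    for c in codes:
        d *= code_size(c)
    if d > max_degeneracy:
        offending = [i for i, c in enumerate(codes) if code_size(c) > 1]
        raise PrimerDesignError(
            f"consensus degeneracy {d} exceeds cap {max_degeneracy}; "
            f"ambiguous column(s) {offending}"
        )
    seq = "".join(codes)
    if gc_range is not None:
        gc = gc_fraction(seq)
        if not gc_range[0] <= gc <= gc_range[1]:
            raise PrimerDesignError(f"GC fraction {gc:.2f} outside {gc_range}")
    return DegeneratePrimer(name, seq, orientation)


def enumerate_candidates(
    msa: Msa,
    profile: ConservationProfile,
    k: int = 10,
    min_separation: int = 50,
    length: int = 20,
    max_degeneracy: int = 64,
    gc_range: tuple[float, float] | None = None,
) -> list[tuple[int, DegeneratePrimer]]:
    """Candidate primers from the top-k conserved windows of a profile.

    Windows whose consensus refuses (gaps, degeneracy, GC band) are skipped.
    Returns (window start, primer) pairs in ranking order. This automates
    candidate-site selection; final primer choice remains the designer's.
    """
    if profile.window != length:
        raise ValueError("profile window and requested primer length differ")
    out: list[tuple[int, DegeneratePrimer]] = []
    for start, _score in top_windows(profile, k, min_separation):
        try:
            p = consensus_primer(
                msa.slice(start, start + length),
                max_degeneracy,
                name=f"cand_{start}",
                gc_range=gc_range,
            )
        except PrimerDesignError:
            continue
        out.append((start, p))
    return out


# The six published primer sets targeting the Firmicutes CODH-ECH (CODHech)
# gene subclades E4a, F4a, F4c1 and F4c2.
CODHECH_PRIMER_TABLE: tuple[tuple[str, str, str, str, int], ...] = (
    ("E4a_p1", "E4a", "CCCAGAGCTTGAAGCTTTAGCC", "CTACTAGCGCCGCTATACCAC", 500),
    ("F4a_p1", "F4a", "GTGGTRGGCATCTGCTGYAC", "GCGKRAYCTTGACGTTRTTGCA", 490),
    ("F4a_p2", "F4a", "TGGATTACCAGTGCATCATGCC", "CRAACCCGTGGCGCATGAGC", 473),
    ("F4c1_p1", "F4c1", "GTCGTATYGATCCWTTTGGCAATGG", "KTATAATCRGCMAGTGCTCCCTTTA", 502),
    ("F4c1_p2", "F4c1", "GGSGTGCTGAAGGAAGATGC", "RATTGCCTCRGCACTGAAMC", 501),
    ("F4c2_p1", "F4c2", "GATGCWCAYACCATTGTGGC", "GATAATTCGGTWGACAAATACATTCCGGT", 478),
)


def codhech_primer_sets() -> list[PrimerSet]:
    """The six published CODHech-targeted primer sets."""
    return [
        PrimerSet(
            name,
            DegeneratePrimer(f"{name}_fw", fw, "forward"),
            DegeneratePrimer(f"{name}_rv", rv, "reverse"),
            clade,
            size,
        )
        for name, clade, fw, rv, size in CODHECH_PRIMER_TABLE
    ]


def read_primer_table(path) -> list[PrimerSet]:
    """Read `name  clade  fw_seq  rv_seq  expected_size` (tab-separated, header optional)."""
    sets: list[PrimerSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lower().startswith("name\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise PrimerDesignError(
                    f"line {lineno}: expected 5 tab-separated primer-table fields"
                )
            name, clade, fw, rv, size = fields[:5]
            sets.append(
                PrimerSet(
                    name,
                    DegeneratePrimer(f"{name}_fw", fw, "forward"),
                    DegeneratePrimer(f"{name}_rv", rv, "reverse"),
                    clade,
                    int(size),
                )
            )
    return sets


def write_primer_table(path, sets: Sequence[PrimerSet]) -> None:
    with open(path, "w") as fh:
        fh.write("name\tclade\tfw_seq\trv_seq\texpected_size\n")
        for ps in sets:
            fh.write(
                f"{ps.name}\t{ps.target_clade}\t{ps.fw.seq}\t{ps.rv.seq}\t{ps.expected_size}\n"
            )
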