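"""Sequence and taxonomy I/O.

FASTA (nucleotide or protein), FASTQ (Phred+33 only) and the tab-separated
taxonomy table ``id<TAB>genus<TAB>species[<TAB>strain]``. Parsers validate
alphabets and report format errors with line numbers. All coordinates in
this package are 0-based half-open; strands are '+'/'-'.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from ._iupac import IUPAC_CODES
from .errors import AlphabetError, FormatError

NUC_ALPHABET = frozenset(IUPAC_CODES) | {"-"}
# the 20 amino acids plus X/B/Z/U ambiguity and * stop
PROT_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU*-")


@dataclass(frozen=True)
class NucRecord:
    """A named sequence; despite the name it also carries protein records
    (the ``alphabet`` argument of :func:`read_fasta` decides validation)."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class QualRead:
    id: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq):
            raise FormatError(
                f"read {self.id!r}: {len(self.quals)} quality values for "
                f"{len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)


class TaxonEntry(NamedTuple):
    genus: str
    species: str
    strain: str | None = None


@dataclass
class TaxonomyTable:
    """Map sequence id -> (genus, species[, strain])."""

    entries: dict[str, TaxonEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.entries

    def __getitem__(self, seq_id: str) -> TaxonEntry:
        return self.entries[seq_id]

    def species(self, seq_id: str) -> str:
        e = self.entries[seq_id]
        return f"{e.genus} {e.species}"


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _fold_nuc(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _check_alphabet(seq: str, alphabet: frozenset[str], ident: str, lineno: int) -> None:
    bad = set(seq) - alphabet
    if bad:
        raise AlphabetError(
            f"line {lineno}: record {ident!r} contains illegal character(s) "
            f"{sorted(bad)!r}"
        )


def read_fasta(path, alphabet: str = "nucleotide") -> list[NucRecord]:
    """Read a FASTA file into records, wrap-agnostic, sequences upper-cased.

    ``alphabet`` is ``"nucleotide"`` (IUPAC codes, U folded to T) or
    ``"protein"``. Duplicate ids, empty sequences and illegal characters
    raise :class:`FormatError`/:class:`AlphabetError` naming the line.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = NUC_ALPHABET if alphabet == "nucleotide" else PROT_ALPHABET

    records: list[NucRecord] = []
    seen: set[str] = set()
    ident = None
    desc = ""
    chunks: list[str] = []
    start_line = 0

    def flush(lineno: int) -> None:
        nonlocal ident, chunks
        if ident is None:
            return
        seq = "".join(chunks)
        if alphabet == "nucleotide":
            seq = _fold_nuc(seq)
        else:
            seq = seq.upper()
        if not seq:
            raise FormatError(f"line {start_line}: record {ident!r} has an empty sequence")
        _check_alphabet(seq, allowed, ident, start_line)
        records.append(NucRecord(ident, seq, desc))
        ident, chunks = None, []

    with _open_text(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                parts = header.split(None, 1)
                ident = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                start_line = lineno
                if ident in seen:
                    raise FormatError(f"line {lineno}: duplicate record id {ident!r}")
                seen.add(ident)
            else:
                if ident is None:
                    raise FormatError(f"line {lineno}: sequence data before any header")
                chunks.append(line.strip())
        flush(lineno + 1)
    return records


def write_fasta(path, records: Iterable[NucRecord], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path) -> list[QualRead]:
    """Read Phred+33 FASTQ. Truncated records and seq/qual length mismatches
    raise :class:`FormatError`; quality characters below '!' are rejected
    (Phred+64 files trip this on purpose rather than decoding silently)."""
    reads: list[QualRead] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(f"line {len(lines)}: truncated FASTQ record")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise FormatError(f"line {lineno}: expected '@' header")
        if not plus.startswith("+"):
            raise FormatError(f"line {lineno + 2}: expected '+' separator")
        ident = head[1:].split()[0] if head[1:].strip() else ""
        if not ident:
            raise FormatError(f"line {lineno}: empty read id")
        if ident in seen:
            raise FormatError(f"line {lineno}: duplicate read id {ident!r}")
        seen.add(ident)
        seq = _fold_nuc(seq)
        _check_alphabet(seq, NUC_ALPHABET, ident, lineno + 1)
        if len(seq) != len(qual):
            raise FormatError(
                f"line {lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        quals = tuple(ord(c) - 33 for c in qual)
        if any(q < 0 for q in quals):
            raise FormatError(f"line {lineno + 3}: quality character below '!' (not Phred+33)")
        reads.append(QualRead(ident, seq, quals))
    return reads


def write_fastq(path, reads: Iterable[QualRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def read_taxonomy(path) -> TaxonomyTable:
    """Read the taxonomy TSV (header ``id  genus  species  [strain]``)."""
    table = TaxonomyTable()
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = [c.strip().lower() for c in header]
        for required in ("id", "genus", "species"):
            if required not in cols:
                raise FormatError(f"line 1: missing required column {required!r}")
        idx = {c: cols.index(c) for c in cols}
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: expected at least 3 tab-separated fields")
            ident = fields[idx["id"]].strip()
            genus = fields[idx["genus"]].strip()
            species = fields[idx["species"]].strip()
            strain = None
            if "strain" in idx and len(fields) > idx["strain"]:
                strain = fields[idx["strain"]].strip() or None
            if ident in table:
                raise FormatError(f"line {lineno}: duplicate id {ident!r}")
            if not species:
                raise FormatError(f"line {lineno}: empty species for id {ident!r}")
            table.entries[ident] = TaxonEntry(genus, species, strain)
    return table


def write_taxonomy(path, table: TaxonomyTable) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgenus\tspecies\tstrain\n")
        for ident, e in table.entries.items():
            fh.write(f"{ident}\t{e.genus}\t{e.species}\t{e.strain or ''}\n")
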