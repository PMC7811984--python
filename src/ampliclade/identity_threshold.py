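"""Species-level identity cutoff from labeled pairwise gene identities.

Pairwise identities come from true global (end-gap penalized) Needleman-
Wunsch alignment with affine gaps under the EDNAFULL nucleotide matrix,
with identity computed over the full alignment length including gap
columns. Labeled intra-/inter-species pairs are then swept over a cutoff
grid (80-100%, 0.1 steps); at each cutoff pairs at or above it are called
"same species" and the F-measure (harmonic mean of precision and recall)
scores the call. The optimum is reported as the full plateau of cutoffs
attaining the maximum F, since ties across a contiguous range are the rule
rather than the exception.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AmplicladeError
from .insilico_pcr import amplify, best_hit
from .primers import PrimerSet
from .seqio import NucRecord, TaxonomyTable


@dataclass(frozen=True)
class AlignParams:
    """EMBOSS-needle-style affine gap penalties over EDNAFULL.

    A gap of length L costs ``gap_open + L * gap_extend``; end gaps are
    penalized, making the alignment truly global.
    """

    gap_open: float = 10.0
    gap_extend: float = 0.5
    matrix: str = "NUC.4.4"  # EDNAFULL

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # first gap position costs open+extend, later ones extend each
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_alignment(
    a: NucRecord | str, b: NucRecord | str, params: AlignParams = AlignParams()
) -> tuple[float, float]:
    """(score, identity%) of the optimal global alignment.

    Identity is 100 * identical columns / alignment length (gap columns
    included), rounded to 0.1 — the convention needleall reports.
    """
    seq_a = a.seq if isinstance(a, NucRecord) else a
    seq_b = b.seq if isinstance(b, NucRecord) else b
    if not seq_a or not seq_b:
        raise AmplicladeError("cannot align an empty sequence")
    # co-optimal alignments may differ in identity; canonicalize the argument
    # order so the reported identity is symmetric
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    aligner = _make_aligner(params)
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    identity = round(100.0 * counts.identities / length, 1)
    return float(aln.score), identity


def global_identity(
    a: NucRecord | str, b: NucRecord | str, params: AlignParams = AlignParams()
) -> float:
    return global_alignment(a, b, params)[1]


@dataclass(frozen=True)
class IdentityRecord:
    id_a: str
    id_b: str
    identity: float  # percent, [0, 100]
    same_species: bool

    def __post_init__(self) -> None:
        if self.id_a >= self.id_b:
            raise ValueError("records are canonically ordered with id_a < id_b")


def pairwise_records(
    refs: Sequence[NucRecord],
    taxonomy: TaxonomyTable,
    params: AlignParams = AlignParams(),
) -> list[IdentityRecord]:
    """All C(n,2) labeled identities, canonically ordered by id pair."""
    for ref in refs:
        if ref.id not in taxonomy:
            raise AmplicladeError(f"reference {ref.id!r} missing from the taxonomy table")
    ordered = sorted(refs, key=lambda r: r.id)
    records = []
    for ra, rb in combinations(ordered, 2):
        ident = global_identity(ra, rb, params)
        same = taxonomy.species(ra.id) == taxonomy.species(rb.id)
        records.append(IdentityRecord(ra.id, rb.id, ident, same))
    return records


def confusion_at_cutoff(
    records: Sequence[IdentityRecord], cutoff: float
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) calling pairs with identity >= cutoff same-species."""
    if not 0 <= cutoff <= 100:
        raise ValueError("cutoff must be in [0, 100]")
    tp = sum(1 for r in records if r.same_species and r.identity >= cutoff)
    fp = sum(1 for r in records if not r.same_species and r.identity >= cutoff)
    tn = sum(1 for r in records if not r.same_species and r.identity < cutoff)
    fn = sum(1 for r in records if r.same_species and r.identity < cutoff)
    return tp, fp, tn, fn


@dataclass(frozen=True)
class ThresholdCurve:
    cutoffs: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f_measure: np.ndarray
    argmax_interval: tuple[float, float]

    @property
    def max_f(self) -> float:
        return float(self.f_measure.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "TP": self.tp,
                "FP": self.fp,
                "TN": self.tn,
                "FN": self.fn,
                "precision": self.precision,
                "recall": self.recall,
                "f_measure": self.f_measure,
            }
        )


def optimize_threshold(
    records: Sequence[IdentityRecord],
    grid: tuple[float, float, float] = (80.0, 100.0, 0.1),
) -> ThresholdCurve:
    """Sweep the cutoff grid and locate the F-measure plateau.

    F is defined 0 where precision + recall is 0. The argmax interval is
    the contiguous run of cutoffs attaining the maximum F that contains its
    first attainment.
    """
    intra = sum(r.same_species for r in records)
    inter = len(records) - intra
    if intra == 0:
        raise AmplicladeError("no intra-species pairs: recall is undefined at every cutoff")
    lo, hi, step = grid
    # integer-tenths grid avoids float drift in cutoff values
    n_steps = int(round((hi - lo) / step))
    cutoffs = np.round(lo + step * np.arange(n_steps + 1), 10)

    ident = np.array([r.identity for r in records])
    same = np.array([r.same_species for r in records])
    ge = ident[None, :] >= cutoffs[:, None]  # cutoffs x records
    tp = (ge & same[None, :]).sum(axis=1)
    fp = (ge & ~same[None, :]).sum(axis=1)
    fn = intra - tp
    tn = inter - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        recall = tp / intra
        denom = precision + recall
        f = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)

    max_f = f.max()
    attain = f >= max_f - 1e-12
    first = int(np.argmax(attain))
    last = first
    while last + 1 < len(cutoffs) and attain[last + 1]:
        last += 1
    interval = (float(cutoffs[first]), float(cutoffs[last]))
    return ThresholdCurve(cutoffs, tp, fp, tn, fn, precision, recall, f, interval)


def trim_to_region(
    refs: Sequence[NucRecord],
    ps: PrimerSet,
    tol: float = 0.10,
    size_range: tuple[int, int] = (50, 5000),
) -> list[NucRecord]:
    """Replace each reference by its amplicon interior for the primer set.

    The interior excludes the primer-binding tracts themselves. References
    the set does not amplify are dropped with a warning; if none amplify an
    error is raised.
    """
    trimmed: list[NucRecord] = []
    for ref in refs:
        hit = best_hit(amplify(ps, ref, tol, size_range))
        if hit is None:
            warnings.warn(f"{ref.id!r} not amplified by set {ps.name!r}; dropped", stacklevel=2)
            continue
        interior = hit.product_seq[len(ps.fw) : hit.product_len - len(ps.rv)]
        trimmed.append(NucRecord(ref.id, interior, ref.description))
    if not trimmed:
        raise AmplicladeError(f"no reference was amplified by set {ps.name!r}")
    return trimmed


def write_records(path, records: Sequence[IdentityRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tidentity\tsame_species\n")
        for r in records:
            fh.write(f"{r.id_a}\t{r.id_b}\t{r.identity:.1f}\t{str(r.same_species).lower()}\n")
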