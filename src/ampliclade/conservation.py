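"""Sliding-window conservation over a nucleotide multiple sequence alignment.

The score of a column is the ratio of the dominant concrete base (A/C/G/T)
to all counted rows; a window score is the mean over its columns with a
20-base default window, which is how conserved candidate primer regions are
located in an alignment of a target gene clade. Ambiguity codes form their
own symbol class and are never dominant; gap handling is a policy switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .seqio import NucRecord
from .errors import AmplicladeError

GapPolicy = Literal["count", "ignore"]
_BASES = "ACGT"


@dataclass(frozen=True)
class Msa:
    """An aligned set of nucleotide records (gap character '-')."""

    records: tuple[NucRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AmplicladeError("an alignment needs at least 2 rows")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise AmplicladeError(f"rows have unequal aligned lengths: {sorted(lengths)}")

    @property
    def ncol(self) -> int:
        return len(self.records[0].seq)

    @property
    def nrow(self) -> int:
        return len(self.records)

    def column(self, i: int) -> str:
        return "".join(r.seq[i] for r in self.records)

    def slice(self, start: int, end: int) -> "Msa":
        return Msa(tuple(NucRecord(r.id, r.seq[start:end], r.description) for r in self.records))

    @classmethod
    def from_records(cls, records: Iterable[NucRecord]) -> "Msa":
        return cls(tuple(records))


@dataclass(frozen=True)
class ConservationProfile:
    window: int
    scores: np.ndarray          # per window start, ncol - window + 1 values
    column_scores: np.ndarray   # per column


def _column_matrix(msa: Msa) -> np.ndarray:
    """Rows x columns array of single characters."""
    return np.array([list(r.seq) for r in msa.records])


def _column_scores(msa: Msa, gap_policy: GapPolicy) -> np.ndarray:
    if gap_policy not in ("count", "ignore"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    mat = _column_matrix(msa)
    counts = np.stack([(mat == b).sum(axis=0) for b in _BASES])  # 4 x ncol
    dominant = counts.max(axis=0).astype(float)
    if gap_policy == "count":
        denom = np.full(msa.ncol, msa.nrow, dtype=float)
    else:
        denom = (mat != "-").sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, dominant / np.maximum(denom, 1), 0.0)
    return scores


def column_conservation(msa: Msa, column: int, gap_policy: GapPolicy = "count") -> float:
    """Dominant-base ratio of one alignment column.

    With ``gap_policy="count"`` gaps stay in the denominator (a gappy column
    scores low); with ``"ignore"`` they are dropped from it. Gaps and
    ambiguity codes are never the dominant base. An all-gap column under
    ``"ignore"`` scores 0.
    """
    if not 0 <= column < msa.ncol:
        raise IndexError(f"column {column} out of range [0, {msa.ncol})")
    return float(_column_scores(msa, gap_policy)[column])


def conservation_profile(
    msa: Msa, window: int = 20, gap_policy: GapPolicy = "count"
) -> ConservationProfile:
    """Per-window mean dominant-base ratio; ``scores[i]`` covers columns
    ``[i, i + window)``."""
    if window < 1 or window > msa.ncol:
        raise ValueError(f"window {window} outside [1, {msa.ncol}]")
    col = _column_scores(msa, gap_policy)
    kernel = np.ones(window) / window
    scores = np.convolve(col, kernel, mode="valid")
    return ConservationProfile(window=window, scores=scores, column_scores=col)


def top_windows(
    profile: ConservationProfile, k: int, min_separation: int
) -> list[tuple[int, float]]:
    """The k highest-scoring window starts, greedily spaced at least
    ``min_separation`` apart; ties break toward the smaller start."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(range(len(profile.scores)), key=lambda i: (-profile.scores[i], i))
    chosen: list[tuple[int, float]] = []
    for i in order:
        if len(chosen) == k:
            break
        if all(abs(i - start) >= min_separation for start, _ in chosen):
            chosen.append((i, float(profile.scores[i])))
    return chosen


def write_profile(path, profile: ConservationProfile) -> None:
    with open(path, "w") as fh:
        fh.write("start\tscore\n")
        for i, s in enumerate(profile.scores):
            fh.write(f"{i}\t{s:.6f}\n")


def plot_profile(path, profile: ConservationProfile) -> None:
    """Optional visual artifact: window-score trace along the alignment."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(np.arange(len(profile.scores)), profile.scores, lw=0.8)
    ax.set_xlabel("alignment position (window start)")
    ax.set_ylabel(f"mean dominant-base ratio ({profile.window}-nt window)")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
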