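"""Mock-community evaluation: expected composition from qPCR copy numbers
versus observed target-OTU relative abundances."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import AmplicladeError


@dataclass(frozen=True)
class Composition:
    """Relative abundances summing to 1."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        if self.fractions:
            if any(v < 0 for v in self.fractions.values()):
                raise AmplicladeError("negative relative abundance")
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise AmplicladeError(f"fractions sum to {total}, not 1")

    def __getitem__(self, label: str) -> float:
        return self.fractions.get(label, 0.0)

    def labels(self) -> set[str]:
        return set(self.fractions)


def composition_from_copies(copies: Mapping[str, float]) -> Composition:
    """Normalize per-label copy numbers (e.g. qPCR copies per microliter)."""
    if not copies:
        raise AmplicladeError("empty copy-number table")
    if any(v <= 0 for v in copies.values()):
        raise AmplicladeError("copy numbers must be positive")
    total = float(sum(copies.values()))
    return Composition({k: v / total for k, v in copies.items()})


def composition_from_counts(counts: Mapping[str, int]) -> Composition:
    """Normalize observed read counts (zero-count labels are dropped)."""
    positive = {k: v for k, v in counts.items() if v > 0}
    return composition_from_copies(positive)


@dataclass(frozen=True)
class ComparisonReport:
    deltas: dict[str, float]   # expected - observed, signed
    l1: float
    bray_curtis: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": list(self.deltas), "delta": list(self.deltas.values())}
        )


def compare_compositions(expected: Composition, observed: Composition) -> ComparisonReport:
    """Per-label signed deltas, L1 distance and Bray-Curtis dissimilarity
    (L1/2 for normalized compositions); labels absent on one side count 0."""
    labels = sorted(expected.labels() | observed.labels())
    if not labels:
        raise AmplicladeError("both compositions are empty")
    deltas = {lab: expected[lab] - observed[lab] for lab in labels}
    l1 = sum(abs(d) for d in deltas.values())
    return ComparisonReport(deltas, l1, l1 / 2.0)


def read_copies_table(path) -> dict[str, float]:
    """Read `label<TAB>copies` (header optional)."""
    copies: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.lower().startswith("label\t"):
                continue
            label, value = line.split("\t")[:2]
            copies[label] = float(value)
    return copies


def write_comparison(path, report: ComparisonReport) -> None:
    with open(path, "w") as fh:
        fh.write("label\tdelta\n")
        for lab, d in report.deltas.items():
            fh.write(f"{lab}\t{d:+.4f}\n")
        fh.write(f"# L1={report.l1:.4f}\tBray-Curtis={report.bray_curtis:.4f}\n")
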