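"""In-silico PCR with degenerate primers under a fractional mismatch budget.

Primer/template matching is ungapped; a primer position matches a template
position when the concrete base sets of the two IUPAC codes intersect. The
mismatch budget is floor(max_mismatch_frac * primer_length), so the default
10% tolerance gives 2 mismatches for the 20-29-nt published primers. Both
strands are scanned and all products inside the size window are reported,
including nested ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from ._iupac import IUPAC_SETS, MATCH
from .primers import DegeneratePrimer, PrimerSet
from .seqio import NucRecord


@dataclass(frozen=True)
class BindingSite:
    """An ungapped primer placement; start/end are 0-based half-open on the
    + strand. Strand '+' means the primer's sequence is read on the plus
    strand, '-' that it is read on the reverse complement."""

    template_id: str
    strand: str
    start: int
    end: int
    mismatches: int
    primer_name: str


@dataclass(frozen=True)
class AmpliconHit:
    template_id: str
    fw_site: BindingSite
    rv_site: BindingSite
    product_seq: str
    product_len: int

    @property
    def total_mismatches(self) -> int:
        return self.fw_site.mismatches + self.rv_site.mismatches


def base_matches(primer_code: str, template_code: str) -> bool:
    """True iff the base sets of the two IUPAC codes intersect."""
    if primer_code not in IUPAC_SETS:
        raise KeyError(f"illegal IUPAC code {primer_code!r}")
    if template_code not in IUPAC_SETS:
        raise KeyError(f"illegal IUPAC code {template_code!r}")
    return (primer_code, template_code) in MATCH


def _scan(primer_seq: str, template_seq: str, budget: int) -> list[tuple[int, int]]:
    """(start, mismatches) of every ungapped placement within the budget."""
    plen = len(primer_seq)
    hits: list[tuple[int, int]] = []
    for start in range(len(template_seq) - plen + 1):
        mm = 0
        for i in range(plen):
            if (primer_seq[i], template_seq[start + i]) not in MATCH:
                mm += 1
                if mm > budget:
                    break
        else:
            hits.append((start, mm))
    return hits


def match_sites(
    p: DegeneratePrimer,
    template: NucRecord,
    max_mismatch_frac: float = 0.10,
) -> list[BindingSite]:
    """All binding sites of a primer on both strands of a template."""
    seq = template.seq
    if len(seq) <= len(p):
        return []
    n_frac = seq.count("N") / len(seq)
    if n_frac > 0.05:
        warnings.warn(
            f"template {template.id!r} is {n_frac:.0%} N; degenerate matching "
            "against N is promiscuous",
            stacklevel=2,
        )
    budget = int(max_mismatch_frac * len(p))
    sites = [
        BindingSite(template.id, "+", s, s + len(p), mm, p.name)
        for s, mm in _scan(p.seq, seq, budget)
    ]
    rc = str(Seq(p.seq).reverse_complement())
    sites += [
        BindingSite(template.id, "-", s, s + len(p), mm, p.name)
        for s, mm in _scan(rc, seq, budget)
    ]
    sites.sort(key=lambda b: (b.start, b.strand))
    return sites


def amplify(
    ps: PrimerSet,
    template: NucRecord,
    max_mismatch_frac: float = 0.10,
    size_range: tuple[int, int] = (50, 5000),
) -> list[AmpliconHit]:
    """Every product the set would amplify from the template.

    A product needs the forward primer's sequence on one strand and the
    reverse primer's on the other, facing each other; the product is
    reported 5'->3' from the forward primer. Nested products are all kept.
    """
    fw_sites = match_sites(ps.fw, template, max_mismatch_frac)
    rv_sites = match_sites(ps.rv, template, max_mismatch_frac)
    lo, hi = size_range
    hits: list[AmpliconHit] = []
    # forward primer on +, reverse primer on - (product read on the + strand)
    for f in (s for s in fw_sites if s.strand == "+"):
        for r in (s for s in rv_sites if s.strand == "-"):
            if r.start >= f.end and lo <= r.end - f.start <= hi:
                seq = template.seq[f.start : r.end]
                hits.append(AmpliconHit(template.id, f, r, seq, len(seq)))
    # forward primer on -, reverse primer on + (product read on the - strand)
    for f in (s for s in fw_sites if s.strand == "-"):
        for r in (s for s in rv_sites if s.strand == "+"):
            if f.start >= r.end and lo <= f.end - r.start <= hi:
                seq = str(Seq(template.seq[r.start : f.end]).reverse_complement())
                hits.append(AmpliconHit(template.id, f, r, seq, len(seq)))
    hits.sort(key=lambda h: (h.total_mismatches, h.product_len, h.fw_site.start))
    return hits


def best_hit(hits: Sequence[AmpliconHit]) -> AmpliconHit | None:
    """Fewest total mismatches, ties to the shorter then leftmost product."""
    return hits[0] if hits else None


def coverage_matrix(
    primer_sets: Sequence[PrimerSet],
    refs: Sequence[NucRecord],
    tol: float = 0.10,
    size_range: tuple[int, int] = (50, 5000),
) -> pd.DataFrame:
    """Amplification of every reference by every set: one row per
    (primer_set, template) with amplified flag and the best product's
    length and total mismatches (NA when not amplified)."""
    if not primer_sets or not refs:
        raise ValueError("primer_sets and refs must be non-empty")
    rows = []
    for ps in primer_sets:
        for ref in refs:
            hit = best_hit(amplify(ps, ref, tol, size_range))
            rows.append(
                {
                    "primer_set": ps.name,
                    "template": ref.id,
                    "amplified": hit is not None,
                    "product_len": hit.product_len if hit else pd.NA,
                    "total_mismatches": hit.total_mismatches if hit else pd.NA,
                }
            )
    return pd.DataFrame(rows)


def write_hits(path, hits_by_set: dict[str, dict[str, list[AmpliconHit]]]) -> None:
    """Tab-separated hit table keyed primer_set -> template -> hits."""
    with open(path, "w") as fh:
        fh.write(
            "primer_set\ttemplate\tstrand\tfw_start\trv_end\tfw_mm\trv_mm\tlen\n"
        )
        for set_name, per_template in hits_by_set.items():
            for template, hits in per_template.items():
                for h in hits:
                    fh.write(
                        f"{set_name}\t{template}\t{h.fw_site.strand}\t"
                        f"{h.fw_site.start}\t{h.rv_site.end}\t"
                        f"{h.fw_site.mismatches}\t{h.rv_site.mismatches}\t"
                        f"{h.product_len}\n"
                    )
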