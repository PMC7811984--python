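"""Synthetic gene families and amplicon read sets with planted truth.

``simulate_gene_family`` emulates a clade-structured functional gene family:
each genus (clade) descends from a stop-codon-free ancestral gene carrying
concrete primer-binding tracts for its clade's primer sets; species and
strain variants accumulate substitutions at disjoint positions, calibrated
so that realized inter-species identities fall in the planted inter range
and intra-species identities in the (strictly higher) intra range. Primer
tracts are conserved except in designated "edge" taxa, which receive
exactly floor(0.1 * primer length) planted site mismatches — at the budget
of the default 10% in-silico PCR tolerance. Inter-species substitutions are
down-weighted inside the amplicon interior (``region_conservation``),
reflecting that primer target regions sit in the conserved parts of a gene.

``simulate_reads`` draws reads multinomially from template amplicon regions
with i.i.d. substitution errors and single-crossover chimeras, emitting a
per-read truth table. Everything is deterministic under the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._iupac import IUPAC_SETS
from .errors import AmplicladeError
from .primers import PrimerSet, codhech_primer_sets, expand
from .seqio import NucRecord, QualRead, TaxonomyTable, TaxonEntry, write_fasta, write_taxonomy

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_NONSTOP_CODONS = [
    a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class FamilySpec:
    n_genera: int = 4
    species_per_genus: int = 3
    strains_per_species: int = 2
    gene_len: int = 1200
    inter_species_identity: tuple[float, float] = (0.85, 0.93)
    intra_species_identity: tuple[float, float] = (0.98, 1.00)
    primer_sets: tuple[PrimerSet, ...] | None = None  # None -> the published six
    region_conservation: float = 0.4  # inter-species mutation weight inside amplicons
    n_edge_per_genus: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intra_species_identity[0] <= self.inter_species_identity[1]:
            raise AmplicladeError(
                "intra-species identity range must lie strictly above the inter range"
            )
        if self.gene_len % 3:
            object.__setattr__(self, "gene_len", self.gene_len + 3 - self.gene_len % 3)

    @property
    def planted_boundary(self) -> float:
        """Midpoint of the planted identity gap, in percent."""
        return 100.0 * (self.intra_species_identity[0] + self.inter_species_identity[1]) / 2


@dataclass
class GeneFamily:
    spec: FamilySpec
    refs: list[NucRecord]
    proteins: list[NucRecord]
    taxonomy: TaxonomyTable
    # primer set name -> ref id -> (aa_start, aa_end) target region on that protein
    regions: dict[str, dict[str, tuple[int, int]]]
    # ref id -> primer set name -> (fw_start, rv_end) on the gene
    sites: dict[str, dict[str, tuple[int, int]]]
    edge_ids: frozenset[str]
    clade_of: dict[str, str]

    def refs_in_clade(self, clade: str) -> list[NucRecord]:
        return [r for r in self.refs if self.clade_of[r.id] == clade]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "refs.fasta", self.refs)
        write_fasta(outdir / "proteins.faa", self.proteins)
        write_taxonomy(outdir / "taxonomy.tsv", self.taxonomy)
        with open(outdir / "regions.tsv", "w") as fh:
            fh.write("primer_set\tref_protein_id\tstart\tend\n")
            for set_name, per_ref in self.regions.items():
                for ref_id, (s, e) in per_ref.items():
                    fh.write(f"{set_name}\t{ref_id}\t{s}\t{e}\n")
        with open(outdir / "truth_sites.tsv", "w") as fh:
            fh.write("ref_id\tprimer_set\tfw_start\trv_end\tedge\n")
            for ref_id, per_set in self.sites.items():
                for set_name, (s, e) in per_set.items():
                    fh.write(
                        f"{ref_id}\t{set_name}\t{s}\t{e}\t"
                        f"{str(ref_id in self.edge_ids).lower()}\n"
                    )


def _repair_stops(gene: list[str], protected: set[int]) -> None:
    """Rewrite frame-0 stop codons at unprotected positions (in place)."""
    for c in range(len(gene) // 3):
        codon = "".join(gene[3 * c : 3 * c + 3])
        if codon not in _STOPS:
            continue
        for off in range(3):
            pos = 3 * c + off
            if pos in protected:
                continue
            fixed = False
            for b in "CAGT":
                if b == gene[pos]:
                    continue
                trial = codon[:off] + b + codon[off + 1 :]
                if trial not in _STOPS:
                    gene[pos] = b
                    fixed = True
                    break
            if fixed:
                break
        else:
            raise AmplicladeError("stop codon fully inside a protected tract")


def _mutate(gene: list[str], pos: int, rng, forbidden: frozenset[str] = frozenset()) -> None:
    """Substitute gene[pos] with a different base that creates no frame-0
    stop codon and is outside ``forbidden``."""
    c = pos // 3
    codon = "".join(gene[3 * c : 3 * c + 3])
    off = pos % 3
    choices = [
        b
        for b in _BASES
        if b != gene[pos]
        and b not in forbidden
        and (codon[:off] + b + codon[off + 1 :]) not in _STOPS
    ]
    if not choices:
        raise AmplicladeError(f"no admissible substitution at position {pos}")
    gene[pos] = choices[int(rng.integers(len(choices)))]


def _genus_layout(sets: Sequence[PrimerSet], gene_len: int, rng) -> list[tuple[PrimerSet, int]]:
    """Offsets for each set's amplicon on the genus ancestor, spaced apart."""
    margin = 60
    offsets = []
    cursor = margin
    for ps in sets:
        offsets.append((ps, cursor))
        cursor += ps.expected_size + margin
    if cursor > gene_len:
        raise AmplicladeError(
            f"gene_len {gene_len} too short for amplicons totalling {cursor} nt"
        )
    return offsets


def _build_ancestor(
    sets_at: list[tuple[PrimerSet, int]], gene_len: int, rng
) -> tuple[list[str], set[int], dict[str, tuple[int, int]], set[int]]:
    """Ancestral gene with embedded primer tracts; returns (gene, tract
    positions, site coordinates per set, amplicon-interior positions)."""
    for shift in range(0, 9, 1):
        n_codons = gene_len // 3
        idx = rng.integers(len(_NONSTOP_CODONS), size=n_codons)
        gene = list("".join(_NONSTOP_CODONS[i] for i in idx))
        tract: set[int] = set()
        interior: set[int] = set()
        sites: dict[str, tuple[int, int]] = {}
        ok = True
        for ps, base_off in sets_at:
            off = base_off + shift
            rv_tract_start = off + ps.expected_size - len(ps.rv)
            if rv_tract_start + len(ps.rv) > gene_len:
                ok = False
                break
            fw_choices = _admissible_expansions(ps.fw.seq, off, rc=False)
            rv_choices = _admissible_expansions(ps.rv.seq, rv_tract_start, rc=True)
            if not fw_choices or not rv_choices:
                ok = False
                break
            fw_concrete = fw_choices[int(rng.integers(len(fw_choices)))]
            rv_concrete = rv_choices[int(rng.integers(len(rv_choices)))]
            gene[off : off + len(ps.fw)] = list(fw_concrete)
            gene[rv_tract_start : rv_tract_start + len(ps.rv)] = list(rv_concrete)
            tract |= set(range(off, off + len(ps.fw)))
            tract |= set(range(rv_tract_start, rv_tract_start + len(ps.rv)))
            interior |= set(range(off + len(ps.fw), rv_tract_start))
            sites[ps.name] = (off, off + ps.expected_size)
        if not ok:
            continue
        try:
            _repair_stops(gene, tract)
        except AmplicladeError:
            continue  # a stop sits fully inside a tract at this frame; shift
        return gene, tract, sites, interior
    raise AmplicladeError("could not embed primer tracts without frame-0 stop codons")


def _admissible_expansions(iupac_seq: str, start: int, rc: bool) -> list[str]:
    """Concrete tract sequences (reverse-complemented for a reverse primer)
    that place no stop codon fully in frame 0 at the given gene offset."""
    out = []
    for variant in expand(iupac_seq, cap=4096):
        tract = str(Seq(variant).reverse_complement()) if rc else variant
        if any(
            tract[k : k + 3] in _STOPS and (start + k) % 3 == 0
            for k in range(len(tract) - 2)
        ):
            continue
        out.append(tract)
    return out


def _draw_positions(pool: list[int], weights: np.ndarray, k: int, rng) -> list[int]:
    if k > len(pool):
        raise AmplicladeError("identity ranges infeasible: mutation pool exhausted")
    if k == 0:
        return []
    p = weights / weights.sum()
    chosen = rng.choice(len(pool), size=k, replace=False, p=p)
    return [pool[i] for i in chosen]


def simulate_gene_family(spec: FamilySpec) -> GeneFamily:
    """Generate the reference family, taxonomy, proteins, target regions and
    planted-site truth. Byte-identical outputs for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    primer_sets = list(spec.primer_sets) if spec.primer_sets else codhech_primer_sets()
    clades: list[str] = []
    for ps in primer_sets:
        if ps.target_clade not in clades:
            clades.append(ps.target_clade)

    L = spec.gene_len
    intra_lo = spec.intra_species_identity[0]
    inter_lo, inter_hi = spec.inter_species_identity
    m_max = int(L * (1 - intra_lo) / 2)
    d_min = math.ceil(L * (1 - inter_hi) / 2)
    d_max = int(L * (1 - inter_lo) / 2) - m_max
    if d_min > d_max:
        raise AmplicladeError(
            f"identity ranges infeasible at gene_len {L}: species divergence "
            f"bounds [{d_min}, {d_max}] are empty"
        )

    refs: list[NucRecord] = []
    proteins: list[NucRecord] = []
    taxonomy = TaxonomyTable()
    regions: dict[str, dict[str, tuple[int, int]]] = {ps.name: {} for ps in primer_sets}
    sites: dict[str, dict[str, tuple[int, int]]] = {}
    edge_ids: set[str] = set()
    clade_of: dict[str, str] = {}

    for g in range(spec.n_genera):
        clade = clades[g % len(clades)]
        genus_sets = [ps for ps in primer_sets if ps.target_clade == clade]
        layout = _genus_layout(genus_sets, L, rng)
        ancestor, tract, genus_sites, interior = _build_ancestor(layout, L, rng)

        pool = [i for i in range(L) if i not in tract]
        weights = np.array(
            [spec.region_conservation if i in interior else 1.0 for i in pool]
        )
        available = list(range(len(pool)))  # indices into pool, shared budget

        def draw_disjoint(k: int) -> list[int]:
            if k > len(available):
                raise AmplicladeError("identity ranges infeasible: mutation pool exhausted")
            w = weights[available]
            picked = rng.choice(len(available), size=k, replace=False, p=w / w.sum()) if k else []
            picked = sorted(picked, reverse=True)
            out = []
            for i in picked:
                out.append(pool[available[i]])
                del available[i]
            return out

        genus_name = f"G{g + 1}{clade}"
        for s in range(spec.species_per_genus):
            d_s = int(rng.integers(d_min, d_max + 1))
            sp_positions = draw_disjoint(d_s)
            sp_gene = list(ancestor)
            for pos in sp_positions:
                _mutate(sp_gene, pos, rng)
            species_name = f"species{g + 1}_{s + 1}"
            for t in range(spec.strains_per_species):
                m_t = int(rng.integers(0, m_max + 1))
                # strain positions uniform over the remaining pool
                if m_t > len(available):
                    raise AmplicladeError("identity ranges infeasible: mutation pool exhausted")
                idxs = sorted(rng.choice(len(available), size=m_t, replace=False), reverse=True)
                st_gene = list(sp_gene)
                for i in idxs:
                    _mutate(st_gene, pool[available[i]], rng)
                    del available[i]
                ref_id = f"{clade}_g{g + 1}s{s + 1}t{t + 1}"
                is_edge = (
                    spec.n_edge_per_genus > 0
                    and s >= spec.species_per_genus - 1
                    and t >= spec.strains_per_species - spec.n_edge_per_genus
                )
                if is_edge:
                    _plant_edge_mismatches(st_gene, genus_sets, genus_sites, rng)
                    edge_ids.add(ref_id)
                seq = "".join(st_gene)
                refs.append(NucRecord(ref_id, seq, f"clade={clade}"))
                proteins.append(
                    NucRecord(ref_id, str(Seq(seq).translate()), f"clade={clade}")
                )
                taxonomy.entries[ref_id] = TaxonEntry(genus_name, species_name, f"st{t + 1}")
                sites[ref_id] = dict(genus_sites)
                clade_of[ref_id] = clade
                for ps in genus_sets:
                    fw_start, rv_end = genus_sites[ps.name]
                    regions[ps.name][ref_id] = (fw_start // 3, math.ceil(rv_end / 3))

    return GeneFamily(
        spec, refs, proteins, taxonomy, regions, sites, frozenset(edge_ids), clade_of
    )


def _plant_edge_mismatches(
    gene: list[str],
    genus_sets: Sequence[PrimerSet],
    genus_sites: dict[str, tuple[int, int]],
    rng,
) -> None:
    """Give each primer tract exactly floor(0.1 * primer length) mismatches
    against the degenerate primer — at the default tolerance budget."""
    for ps in genus_sets:
        fw_start, rv_end = genus_sites[ps.name]
        for primer, start in (
            (ps.fw.seq, fw_start),
            (str(Seq(ps.rv.seq).reverse_complement()), rv_end - len(ps.rv)),
        ):
            n_mm = int(0.1 * len(primer))
            positions = list(rng.permutation(len(primer)))
            planted = 0
            for off in positions:
                if planted == n_mm:
                    break
                allowed = IUPAC_SETS[primer[off]]
                forbidden = frozenset(allowed)
                try:
                    _mutate(gene, start + off, rng, forbidden)
                except AmplicladeError:
                    continue  # no stop-free mismatching base here; next position
                planted += 1
            if planted < n_mm:
                raise AmplicladeError(
                    f"could not plant {n_mm} edge mismatches in a {ps.name} tract"
                )


@dataclass(frozen=True)
class ReadSimSpec:
    """Amplicon read simulation over template region sequences."""

    templates: tuple[NucRecord, ...]
    abundances: tuple[float, ...]
    n_reads: int
    per_base_error: float = 0.0
    chimera_rate: float = 0.0
    seed: int = 0
    q_correct: int = 35
    q_error: int = 15

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise AmplicladeError("n_reads must be >= 1")
        if not 0 <= self.per_base_error < 1 or not 0 <= self.chimera_rate < 1:
            raise AmplicladeError("rates must be in [0, 1)")
        if len(self.templates) != len(self.abundances) or any(
            a <= 0 for a in self.abundances
        ):
            raise AmplicladeError("abundances must be positive, one per template")


def simulate_reads(spec: ReadSimSpec) -> tuple[list[QualRead], pd.DataFrame]:
    """Multinomial template draws with i.i.d. substitution errors and
    single-crossover chimeras; errors carry quality ``q_error``, correct
    bases ``q_correct``. Returns (reads, truth table) with one truth row per
    read: origin template (or left+right parents for chimeras) and the
    planted error count."""
    rng = np.random.default_rng(spec.seed)
    probs = np.array(spec.abundances, dtype=float)
    probs /= probs.sum()
    reads: list[QualRead] = []
    truth_rows = []
    for i in range(spec.n_reads):
        is_chimera = rng.random() < spec.chimera_rate
        if is_chimera:
            a, b = rng.choice(len(spec.templates), size=2, replace=False, p=probs)
            left, right = spec.templates[a].seq, spec.templates[b].seq
            cut = int(rng.integers(1, min(len(left), len(right))))
            seq = left[:cut] + right[cut:]
            origin = f"{spec.templates[a].id}+{spec.templates[b].id}"
        else:
            t = int(rng.choice(len(spec.templates), p=probs))
            seq = spec.templates[t].seq
            origin = spec.templates[t].id
        bases = list(seq)
        err_mask = rng.random(len(bases)) < spec.per_base_error
        n_err = 0
        for pos in np.flatnonzero(err_mask):
            alternatives = [b for b in _BASES if b != bases[pos]]
            bases[pos] = alternatives[int(rng.integers(3))]
            n_err += 1
        quals = tuple(
            spec.q_error if err_mask[j] else spec.q_correct for j in range(len(bases))
        )
        read_id = f"read{i + 1}"
        reads.append(QualRead(read_id, "".join(bases), quals))
        truth_rows.append(
            {"read_id": read_id, "origin": origin, "chimera": is_chimera, "errors": n_err}
        )
    return reads, pd.DataFrame(truth_rows)


def amplicon_regions(
    family: GeneFamily, ps: PrimerSet, ref_ids: Sequence[str] | None = None
) -> list[NucRecord]:
    """Planted amplicon interiors (primer tracts excluded) for the given
    references — the regions merged reads cover after primer trimming."""
    out = []
    for ref in family.refs:
        if ref_ids is not None and ref.id not in ref_ids:
            continue
        if ps.name not in family.sites.get(ref.id, {}):
            continue
        fw_start, rv_end = family.sites[ref.id][ps.name]
        interior = ref.seq[fw_start + len(ps.fw) : rv_end - len(ps.rv)]
        out.append(NucRecord(ref.id, interior))
    return out
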