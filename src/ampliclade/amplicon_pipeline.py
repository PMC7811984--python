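"""Merged amplicon reads -> denoised, chimera-free, target-gene OTUs.

Stages mirror a UNOISE3-style workflow: quality control of merged reads,
full-length dereplication, greedy abundance-ordered denoising with the
beta(d) = 1/2^(alpha*d + 1) skew rule and an identity floor, de novo
single-crossover chimera removal under an abundance-skew test, translated
search of OTUs against reference proteins with a bit-score and target-region
filter, species assignment by nucleotide identity against region-trimmed
references, and finally mapping of all quality-controlled reads back onto
the retained OTUs at the clustering identity to obtain quantitative OTU
abundances (the standard read-mapping step of UNOISE pipelines).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .errors import AmplicladeError
from .identity_threshold import AlignParams, global_identity, trim_to_region
from .primers import PrimerSet
from .seqio import NucRecord, QualRead, TaxonomyTable


@dataclass(frozen=True)
class PipelineParams:
    """Pipeline settings; the defaults are the published workflow's."""

    min_len: int = 200          # nt, minimum merged-read length
    max_ns: int = 0             # ambiguous bases allowed per read
    min_q: int = 20             # minimum per-base Phred quality
    minsize: int = 8            # minimum unique abundance to found an OTU
    unoise_alpha: float = 2.0   # skew-curve steepness
    neighborhood_id: float = 0.979  # identity floor for joining a centroid
    abskew: float = 16.0        # parent/candidate abundance ratio for chimeras
    bit_min: float = 80.0       # translated-search bit-score floor
    species_cutoff: float = 94.5    # percent identity for species assignment
    otu_cluster_id: float = 0.979   # identity for read->OTU mapping


@dataclass(frozen=True)
class UniqueSeq:
    seq: str
    abundance: int
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.abundance != len(self.members) or self.abundance < 1:
            raise AmplicladeError("unique abundance must equal its member count (>= 1)")


@dataclass
class Otu:
    otu_id: str
    rep_seq: str
    abundance: int                       # accumulated at denoising
    founding_abundance: int              # the founding unique's own abundance
    mapped_abundance: int = 0            # reads mapped back at otu_cluster_id
    is_target: bool = False
    best_ref: tuple[str, float] | None = None   # (ref id, identity %)
    species_call: str = "unclassified"


def qc_merged_reads(reads: Sequence[QualRead], params: PipelineParams = PipelineParams()) -> list[QualRead]:
    """Keep reads of at least ``min_len`` nt with no more than ``max_ns``
    ambiguous bases and every base quality >= ``min_q``."""
    kept = []
    for r in reads:
        if len(r) < params.min_len:
            continue
        if r.seq.count("N") > params.max_ns:
            continue
        if any(q < params.min_q for q in r.quals):
            continue
        kept.append(r)
    return kept


def dereplicate(reads: Sequence[QualRead | NucRecord]) -> list[UniqueSeq]:
    """Exact full-length dereplication, sorted by abundance descending with
    lexicographic sequence tie-break; deterministic under input shuffles."""
    groups: dict[str, list[str]] = {}
    for r in reads:
        groups.setdefault(r.seq, []).append(r.id)
    uniques = [
        UniqueSeq(seq, len(ids), tuple(sorted(ids))) for seq, ids in groups.items()
    ]
    uniques.sort(key=lambda u: (-u.abundance, u.seq))
    return uniques


def _edlib_dist(a: str, b: str) -> tuple[int, int]:
    """(edit distance, alignment length) of a global alignment."""
    res = edlib.align(a, b, task="path")
    aln_len = sum(int(n) for n, _ in _cigar_ops(res["cigar"]))
    return res["editDistance"], aln_len


def _cigar_ops(cigar: str):
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield num, c
            num = ""


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical columns in a global edit-distance alignment."""
    d, aln_len = _edlib_dist(a, b)
    return 1.0 - d / aln_len


def beta(d: int, alpha: float = 2.0) -> float:
    """Maximum abundance skew at which a unique ``d`` differences from a
    centroid is treated as an error variant of it: 1 / 2^(alpha*d + 1)."""
    return 1.0 / 2 ** (alpha * d + 1)


@dataclass
class DenoiseStats:
    assigned_reads: int = 0
    discarded_reads: int = 0
    discarded_uniques: int = 0


def unoise_denoise(
    uniques: Sequence[UniqueSeq], params: PipelineParams = PipelineParams()
) -> tuple[list[Otu], DenoiseStats]:
    """Greedy abundance-ordered centroid clustering.

    A unique joins the first centroid (in founding order) within the
    identity floor whose skew test abundance(u)/founding_abundance(c) <=
    beta(d) passes, where d is the edit distance to the centroid (indels
    count 1 each); otherwise it founds a centroid iff abundance >= minsize,
    else its reads are discarded. Centroid output abundance accumulates its
    members' reads.
    """
    otus: list[Otu] = []
    stats = DenoiseStats()
    for u in uniques:
        joined = False
        for c in otus:
            d, aln_len = _edlib_dist(u.seq, c.rep_seq)
            if d == 0:
                continue  # cannot happen for distinct uniques
            if 1.0 - d / aln_len < params.neighborhood_id:
                continue
            if u.abundance / c.founding_abundance <= beta(d, params.unoise_alpha):
                c.abundance += u.abundance
                stats.assigned_reads += u.abundance
                joined = True
                break
        if joined:
            continue
        if u.abundance >= params.minsize:
            otus.append(
                Otu(
                    otu_id=f"centroid_{len(otus) + 1}",
                    rep_seq=u.seq,
                    abundance=u.abundance,
                    founding_abundance=u.abundance,
                )
            )
            stats.assigned_reads += u.abundance
        else:
            stats.discarded_reads += u.abundance
            stats.discarded_uniques += 1
    otus.sort(key=lambda o: (-o.abundance, o.rep_seq))
    return otus, stats


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def _is_perfect_chimera(cand: str, left: str, right: str) -> bool:
    """True iff some crossover splits cand into a prefix identical to the
    start of ``left`` and a suffix identical to the end of ``right``."""
    if cand == left or cand == right:
        return False
    p, s = _lcp(cand, left), _lcs(cand, right)
    # need a crossover i with 1 <= i <= len-1, i <= p and len-i <= s;
    # the smallest admissible i is max(1, len-s)
    return max(1, len(cand) - s) <= min(p, len(cand) - 1)


def remove_chimeras(
    otus: Sequence[Otu], abskew: float = 16.0
) -> tuple[list[Otu], list[Otu]]:
    """De novo single-crossover chimera removal.

    Walking OTUs in decreasing abundance, a candidate is removed iff two
    already-retained parents, each at least ``abskew`` times as abundant,
    explain it as a perfect two-parent splice. Returns (retained, removed).
    """
    ordered = sorted(otus, key=lambda o: (-o.abundance, o.rep_seq))
    retained: list[Otu] = []
    removed: list[Otu] = []
    for cand in ordered:
        parents = [p for p in retained if p.abundance >= abskew * cand.abundance]
        chimeric = any(
            _is_perfect_chimera(cand.rep_seq, a.rep_seq, b.rep_seq)
            for a in parents
            for b in parents
            if a is not b
        )
        (removed if chimeric else retained).append(cand)
    return retained, removed


# gapped Karlin-Altschul constants for BLOSUM62 with gap open 11 / extend 1
_KA_LAMBDA = 0.267
_KA_K = 0.041


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12.0  # gap of length L costs 11 + L
    aligner.extend_gap_score = -1.0
    return aligner


def bit_score(raw_score: float) -> float:
    """Normalized bit score of a gapped local-alignment raw score."""
    return (_KA_LAMBDA * raw_score - math.log(_KA_K)) / math.log(2)


def six_frame_translations(seq: str) -> list[str]:
    frames = []
    rc = str(Seq(seq).reverse_complement())
    for s in (seq, rc):
        for off in range(3):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            if sub:
                frames.append(str(Seq(sub).translate()))
    return frames


def best_protein_hit(
    otu_seq: str, ref_proteins: Sequence[NucRecord]
) -> tuple[float, str, tuple[int, int]] | None:
    """Best gapped local alignment of any reading frame against the
    reference proteins: (bit score, ref id, ref aa interval)."""
    aligner = _protein_aligner()
    best: tuple[float, str, tuple[int, int]] | None = None
    for frame in six_frame_translations(otu_seq):
        if not frame:
            continue
        for ref in ref_proteins:
            try:
                aln = aligner.align(ref.seq, frame)[0]
            except (IndexError, OverflowError):
                continue
            bits = bit_score(aln.score)
            if best is None or bits > best[0]:
                blocks = aln.aligned[0]
                interval = (int(blocks[0][0]), int(blocks[-1][1]))
                best = (bits, ref.id, interval)
    return best


def annotate_targets(
    otus: Sequence[Otu],
    ref_proteins: Sequence[NucRecord],
    region: dict[str, tuple[int, int]],
    bit_min: float = 80.0,
) -> list[Otu]:
    """Set ``is_target`` on every OTU: best translated hit must reach the
    bit-score floor and fall within the primer set's target region on the
    reference protein (region given per reference id, aa coordinates)."""
    if not ref_proteins:
        raise AmplicladeError("reference protein set is empty")
    out = []
    for o in otus:
        hit = best_protein_hit(o.rep_seq, ref_proteins)
        is_target = False
        if hit is not None:
            bits, ref_id, (h_start, h_end) = hit
            if bits >= bit_min and ref_id in region:
                r_start, r_end = region[ref_id]
                is_target = r_start <= h_start and h_end <= r_end
        o.is_target = is_target
        out.append(o)
    return out


def filter_target_otus(
    otus: Sequence[Otu],
    ref_proteins: Sequence[NucRecord],
    region: dict[str, tuple[int, int]],
    bit_min: float = 80.0,
) -> list[Otu]:
    """The OTUs passing the translated-search target filter."""
    return [o for o in annotate_targets(otus, ref_proteins, region, bit_min) if o.is_target]


def assign_species(
    otu: Otu,
    refs: Sequence[NucRecord],
    taxonomy: TaxonomyTable,
    species_cutoff: float = 94.5,
    params: AlignParams = AlignParams(),
) -> Otu:
    """Closest-reference species call over the amplified region.

    ``refs`` should already be trimmed to the amplicon interior. The call is
    the best reference's species iff identity >= cutoff (inclusive), else
    "novel"."""
    if not otu.is_target:
        raise AmplicladeError("species assignment applies to target OTUs only")
    best_id, best_ident = None, -1.0
    for ref in refs:
        ident = global_identity(otu.rep_seq, ref.seq, params)
        if ident > best_ident:
            best_id, best_ident = ref.id, ident
    otu.best_ref = (best_id, best_ident)
    if best_ident >= species_cutoff:
        otu.species_call = taxonomy.species(best_id)
    else:
        otu.species_call = "novel"
    return otu


def map_reads_to_otus(
    uniques: Sequence[UniqueSeq], otus: Sequence[Otu], id_floor: float = 0.979
) -> int:
    """Map dereplicated reads onto OTU representatives (best identity,
    at least ``id_floor``); sets ``mapped_abundance``. Returns the number of
    reads mapped."""
    for o in otus:
        o.mapped_abundance = 0
    total = 0
    for u in uniques:
        best_otu, best_ident = None, -1.0
        for o in otus:
            if u.seq == o.rep_seq:
                best_otu, best_ident = o, 1.0
                break
            ident = sequence_identity(u.seq, o.rep_seq)
            if ident > best_ident:
                best_otu, best_ident = o, ident
        if best_otu is not None and best_ident >= id_floor:
            best_otu.mapped_abundance += u.abundance
            total += u.abundance
    return total


@dataclass
class PipelineResult:
    otus: list[Otu]
    report: dict[str, int]
    denoise_stats: DenoiseStats
    removed_chimeras: list[Otu] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        total = sum(o.mapped_abundance for o in self.otus) or 1
        rows = []
        for o in self.otus:
            rows.append(
                {
                    "otu_id": o.otu_id,
                    "abundance": o.mapped_abundance,
                    "rel_abundance": o.mapped_abundance / total,
                    "is_target": o.is_target,
                    "best_ref": o.best_ref[0] if o.best_ref else "",
                    "identity": o.best_ref[1] if o.best_ref else float("nan"),
                    "species_call": o.species_call,
                }
            )
        return pd.DataFrame(rows)


def run_pipeline(
    reads: Sequence[QualRead],
    primer_set: PrimerSet,
    refs: Sequence[NucRecord],
    ref_proteins: Sequence[NucRecord],
    taxonomy: TaxonomyTable,
    region: dict[str, tuple[int, int]],
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    """Compose QC, dereplication, denoising, chimera removal, target
    filtering, species assignment and read mapping; OTU ids are
    ``<primerset>_<rank>`` by descending mapped abundance."""
    qc = qc_merged_reads(reads, params)
    uniques = dereplicate(qc)
    otus, stats = unoise_denoise(uniques, params)
    retained, removed = remove_chimeras(otus, params.abskew)
    retained = annotate_targets(retained, ref_proteins, region, params.bit_min)

    mapped = map_reads_to_otus(uniques, retained, params.otu_cluster_id)
    retained.sort(key=lambda o: (-o.mapped_abundance, o.rep_seq))
    for rank, o in enumerate(retained, 1):
        o.otu_id = f"{primer_set.name}_{rank}"

    target_otus = [o for o in retained if o.is_target]
    if target_otus:
        trimmed_refs = trim_to_region(refs, primer_set)
        for o in target_otus:
            assign_species(o, trimmed_refs, taxonomy, params.species_cutoff)

    report = {
        "total_reads": len(reads),
        "qc_reads": len(qc),
        "unique_sequences": len(uniques),
        "denoised_chimera_free_reads": mapped,
        "otus": len(retained),
        "target_otus": len(target_otus),
        "target_reads": sum(o.mapped_abundance for o in target_otus),
    }
    return PipelineResult(retained, report, stats, removed)


def write_otu_table(path, result: PipelineResult) -> None:
    result.table().to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_otu_fasta(path, result: PipelineResult) -> None:
    from .seqio import write_fasta

    write_fasta(
        path,
        [NucRecord(o.otu_id, o.rep_seq, f"size={o.mapped_abundance}") for o in result.otus],
    )
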