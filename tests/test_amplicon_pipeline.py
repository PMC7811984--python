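import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from ampliclade.amplicon_pipeline import (
    Otu,
    PipelineParams,
    UniqueSeq,
    _protein_aligner,
    annotate_targets,
    assign_species,
    beta,
    best_protein_hit,
    bit_score,
    dereplicate,
    filter_target_otus,
    map_reads_to_otus,
    qc_merged_reads,
    remove_chimeras,
    run_pipeline,
    sequence_identity,
    six_frame_translations,
    unoise_denoise,
)
from ampliclade.seqio import NucRecord, QualRead
from ampliclade.synth_fixtures import ReadSimSpec, amplicon_regions, simulate_reads


def _read(seq, ident="r", q=35):
    return QualRead(ident, seq, (q,) * len(seq))


def _rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestQc:
    def test_short_read_removed(self):
        rng = random.Random(1)
        assert qc_merged_reads([_read(_rand_seq(rng, 199))]) == []

    def test_read_with_n_removed(self):
        rng = random.Random(2)
        seq = _rand_seq(rng, 249) + "N"
        assert qc_merged_reads([_read(seq)]) == []

    def test_low_quality_base_removed(self):
        rng = random.Random(3)
        seq = _rand_seq(rng, 250)
        quals = (35,) * 249 + (19,)
        assert qc_merged_reads([QualRead("r", seq, quals)]) == []

    def test_clean_read_kept(self):
        rng = random.Random(4)
        read = QualRead("r", _rand_seq(rng, 250), (20,) * 250)
        assert qc_merged_reads([read]) == [read]


class TestDereplicate:
    def test_grouping_and_order(self):
        rng = random.Random(5)
        a, b = sorted([_rand_seq(rng, 30), _rand_seq(rng, 30)])
        reads = [_read(a, "r1"), _read(b, "r2"), _read(a, "r3"), _read(a, "r4")]
        uniques = dereplicate(reads)
        assert [(u.seq, u.abundance) for u in uniques] == [(a, 3), (b, 1)]
        assert uniques[0].members == ("r1", "r3", "r4")

    def test_abundance_conservation_and_shuffle_determinism(self):
        rng = random.Random(6)
        pool = [_rand_seq(rng, 25) for _ in range(8)]
        reads = [_read(rng.choice(pool), f"r{i}") for i in range(200)]
        uniques = dereplicate(reads)
        assert sum(u.abundance for u in uniques) == 200
        for _ in range(3):
            rng.shuffle(reads)
            assert dereplicate(reads) == uniques


class TestDenoise:
    def test_beta_matches_hand_table(self):
        # 1 / 2^(2d + 1) for alpha = 2
        expected = {1: 1 / 8, 2: 1 / 32, 3: 1 / 128, 4: 1 / 512, 5: 1 / 2048}
        for d, value in expected.items():
            assert beta(d, 2.0) == pytest.approx(value)

    def test_error_free_templates_give_one_otu_each(self):
        rng = random.Random(7)
        t1, t2 = _rand_seq(rng, 300), _rand_seq(rng, 300)
        uniques = dereplicate(
            [_read(t1, f"a{i}") for i in range(100)] + [_read(t2, f"b{i}") for i in range(50)]
        )
        otus, stats = unoise_denoise(uniques)
        assert sorted(o.abundance for o in otus) == [50, 100]
        assert stats.discarded_reads == 0

    def test_one_mismatch_variant_merges_under_skew(self):
        rng = random.Random(8)
        t = _rand_seq(rng, 100)
        variant = ("C" if t[0] != "C" else "G") + t[1:]
        uniques = [
            UniqueSeq(t, 100, tuple(f"a{i}" for i in range(100))),
            UniqueSeq(variant, 2, ("b0", "b1")),
        ]
        otus, stats = unoise_denoise(uniques)
        # 2/100 <= beta(1) = 1/8, identity 0.99 >= 0.979 -> merged
        assert len(otus) == 1 and otus[0].abundance == 102
        assert stats.assigned_reads == 102

    def test_abundant_variant_stays_separate(self):
        rng = random.Random(9)
        t = _rand_seq(rng, 100)
        variant = ("C" if t[0] != "C" else "G") + t[1:]
        uniques = [
            UniqueSeq(t, 100, tuple(f"a{i}" for i in range(100))),
            UniqueSeq(variant, 40, tuple(f"b{i}" for i in range(40))),
        ]
        otus, _ = unoise_denoise(uniques)
        # 40/100 > beta(1): a genuine co-occurring variant founds its own OTU
        assert len(otus) == 2

    def test_small_unique_without_centroid_discarded(self):
        rng = random.Random(10)
        uniques = [UniqueSeq(_rand_seq(rng, 100), 7, tuple(f"x{i}" for i in range(7)))]
        otus, stats = unoise_denoise(uniques)
        assert otus == [] and stats.discarded_reads == 7 and stats.discarded_uniques == 1

    def test_read_count_conservation(self):
        rng = random.Random(11)
        template = _rand_seq(rng, 150)
        reads = []
        for i in range(300):
            seq = list(template)
            for pos in rng.sample(range(150), rng.choice([0, 0, 0, 1, 2])):
                seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            reads.append(_read("".join(seq), f"r{i}"))
        uniques = dereplicate(reads)
        otus, stats = unoise_denoise(uniques)
        assert stats.assigned_reads + stats.discarded_reads == 300
        assert sum(o.abundance for o in otus) == stats.assigned_reads


def _otu(seq, ab, ident="o"):
    return Otu(ident, seq, ab, founding_abundance=ab)


class TestChimeraRemoval:
    def setup_method(self):
        rng = random.Random(12)
        self.a = _rand_seq(rng, 120)
        b = list(self.a)
        for pos in rng.sample(range(120), 20):
            b[pos] = rng.choice([x for x in "ACGT" if x != b[pos]])
        self.b = "".join(b)
        self.chimera = self.a[:60] + self.b[60:]
        assert self.chimera not in (self.a, self.b)

    def test_perfect_chimera_removed_at_high_skew(self):
        otus = [_otu(self.a, 2000, "A"), _otu(self.b, 2000, "B"), _otu(self.chimera, 100, "C")]
        retained, removed = remove_chimeras(otus, abskew=16)
        assert [o.otu_id for o in removed] == ["C"]
        assert {o.otu_id for o in retained} == {"A", "B"}

    def test_insufficient_skew_retains_candidate(self):
        otus = [_otu(self.a, 800, "A"), _otu(self.b, 800, "B"), _otu(self.chimera, 100, "C")]
        retained, removed = remove_chimeras(otus, abskew=16)
        assert removed == [] and len(retained) == 3

    def test_non_recombinant_low_abundance_retained(self):
        rng = random.Random(13)
        other = _rand_seq(rng, 120)
        otus = [_otu(self.a, 2000, "A"), _otu(self.b, 2000, "B"), _otu(other, 50, "D")]
        retained, removed = remove_chimeras(otus, abskew=16)
        assert removed == []

    def test_candidate_contained_in_one_parent_not_chimeric(self):
        # identical to a parent's prefix+suffix trivially; must not be flagged
        shorter = self.a[:119]
        otus = [_otu(self.a, 2000, "A"), _otu(self.b, 2000, "B"), _otu(shorter, 40, "S")]
        retained, removed = remove_chimeras(otus, abskew=16)
        assert removed == []


def smith_waterman_score(a, b, gap_open=11.0, gap_extend=1.0):
    """Independent local affine DP; gap of length L costs open + L*ext."""
    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), -1e9)
    Y = np.full((n + 1, m + 1), -1e9)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]))
            X[i, j] = max(M[i - 1, j] - gap_open - gap_extend, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open - gap_extend, Y[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return best


class TestTargetFilter:
    def test_local_aligner_matches_independent_dp(self):
        rng = random.Random(14)
        aligner = _protein_aligner()
        for _ in range(15):
            a = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(5, 18)))
            b = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(5, 18)))
            expected = smith_waterman_score(a, b)
            got = aligner.align(a, b).score if expected > 0 else 0.0
            assert got == pytest.approx(expected)

    def test_six_frame_translation_covers_both_strands(self):
        frames = six_frame_translations("ATGGCCATTGTAATG")
        assert len(frames) == 6
        assert "MAIV" in frames[0]

    def test_exact_in_frame_fragment_kept(self, single_clade_family):
        family, ps = single_clade_family
        interior = amplicon_regions(family, ps)[0]
        otu = _otu(interior.seq, 100)
        kept = filter_target_otus([otu], family.proteins, family.regions[ps.name])
        assert kept == [otu] and otu.is_target

    def test_random_sequence_scores_below_bit_floor(self, single_clade_family):
        family, ps = single_clade_family
        rng = random.Random(15)
        otu = _otu(_rand_seq(rng, 450), 100)
        hit = best_protein_hit(otu.rep_seq, family.proteins)
        assert hit is not None and hit[0] < 80.0
        assert filter_target_otus([otu], family.proteins, family.regions[ps.name]) == []

    def test_fragment_outside_region_discarded(self, single_clade_family):
        family, ps = single_clade_family
        ref = family.refs[0]
        _, rv_end = family.sites[ref.id][ps.name]
        tail = ref.seq[rv_end + 30 :]
        otu = _otu(tail, 100)
        hit = best_protein_hit(otu.rep_seq, family.proteins)
        assert hit is not None and hit[0] >= 80.0  # genuine gene fragment
        assert filter_target_otus([otu], family.proteins, family.regions[ps.name]) == []

    def test_filter_is_idempotent(self, single_clade_family):
        family, ps = single_clade_family
        otus = [_otu(t.seq, 50, t.id) for t in amplicon_regions(family, ps)[:2]]
        kept = filter_target_otus(otus, family.proteins, family.regions[ps.name])
        again = filter_target_otus(kept, family.proteins, family.regions[ps.name])
        assert again == kept


class TestAssignSpecies:
    def _refs_and_tax(self):
        from ampliclade.seqio import TaxonEntry, TaxonomyTable

        rng = random.Random(16)
        ref = NucRecord("ref1", _rand_seq(rng, 200))
        tax = TaxonomyTable()
        tax.entries["ref1"] = TaxonEntry("Carboxydothermus", "hydrogenoformans")
        return ref, tax

    def _mutated(self, seq, k, rng):
        out = list(seq)
        for pos in rng.sample(range(len(seq)), k):
            out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
        return "".join(out)

    def test_identical_fragment_full_identity(self):
        ref, tax = self._refs_and_tax()
        otu = _otu(ref.seq, 10)
        otu.is_target = True
        assign_species(otu, [ref], tax)
        assert otu.best_ref == ("ref1", 100.0)
        assert otu.species_call == "Carboxydothermus hydrogenoformans"

    def test_cutoff_is_inclusive(self):
        ref, tax = self._refs_and_tax()
        rng = random.Random(17)
        # 11 substitutions over 200 nt: identity exactly 94.5%
        otu = _otu(self._mutated(ref.seq, 11, rng), 10)
        otu.is_target = True
        assign_species(otu, [ref], tax)
        assert otu.best_ref[1] == pytest.approx(94.5)
        assert otu.species_call == "Carboxydothermus hydrogenoformans"

    def test_below_cutoff_is_novel(self):
        ref, tax = self._refs_and_tax()
        rng = random.Random(18)
        # 12 substitutions: identity 94.0% < 94.5
        otu = _otu(self._mutated(ref.seq, 12, rng), 10)
        otu.is_target = True
        assign_species(otu, [ref], tax)
        assert otu.best_ref[1] < 94.5
        assert otu.species_call == "novel"


class TestRunPipeline:
    def test_zero_error_reads_recover_template_set(self, single_clade_family):
        family, ps = single_clade_family
        templates = amplicon_regions(family, ps, ref_ids=[r.id for r in family.refs[:3]])
        reads, _ = simulate_reads(
            ReadSimSpec(tuple(templates), (100, 50, 25), n_reads=600, seed=19)
        )
        result = run_pipeline(
            reads, ps, family.refs, family.proteins, family.taxonomy,
            family.regions[ps.name],
        )
        assert {o.rep_seq for o in result.otus} == {t.seq for t in templates}
        assert all(o.is_target for o in result.otus)
        assert all(o.best_ref[1] == 100.0 for o in result.otus)
        # mapping assigns every read to an identical representative
        assert result.report["denoised_chimera_free_reads"] == 600
        r = result.report
        assert r["total_reads"] >= r["qc_reads"] >= r["denoised_chimera_free_reads"]
        assert [o.otu_id for o in result.otus] == [f"{ps.name}_{k}" for k in (1, 2, 3)]

    def test_stage_counts_internally_consistent(self, single_clade_family):
        family, ps = single_clade_family
        templates = amplicon_regions(family, ps, ref_ids=[family.refs[0].id])
        reads, _ = simulate_reads(
            ReadSimSpec(tuple(templates), (1,), n_reads=400, per_base_error=0.01,
                        chimera_rate=0.0, seed=20)
        )
        params = PipelineParams(min_q=15)
        result = run_pipeline(
            reads, ps, family.refs, family.proteins, family.taxonomy,
            family.regions[ps.name], params,
        )
        stats = result.denoise_stats
        assert stats.assigned_reads + stats.discarded_reads == result.report["qc_reads"]
        assert result.report["denoised_chimera_free_reads"] <= result.report["qc_reads"]
        assert result.report["target_otus"] == len([o for o in result.otus if o.is_target])

    def test_identity_helper_symmetry(self):
        rng = random.Random(21)
        a, b = _rand_seq(rng, 80), _rand_seq(rng, 78)
        assert sequence_identity(a, b) == pytest.approx(sequence_identity(b, a))
        assert sequence_identity(a, a) == 1.0


def test_bit_score_conversion_known_point():
    # bits = (lambda * S - ln K) / ln 2 with lambda = 0.267, K = 0.041
    assert bit_score(0.0) == pytest.approx(-np.log(0.041) / np.log(2), abs=1e-9)
    assert bit_score(300.0) == pytest.approx((0.267 * 300 + 3.19418) / 0.693147, abs=0.01)


def test_map_reads_respects_identity_floor():
    rng = random.Random(22)
    t = _rand_seq(rng, 200)
    far = _rand_seq(rng, 200)
    otu = _otu(t, 10, "keep")
    uniques = [
        UniqueSeq(t, 5, tuple(f"a{i}" for i in range(5))),
        UniqueSeq(far, 3, tuple(f"b{i}" for i in range(3))),
    ]
    mapped = map_reads_to_otus(uniques, [otu], id_floor=0.979)
    assert mapped == 5 and otu.mapped_abundance == 5
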