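"""Local alignment, e-values, KO rule, and respiratory profiling."""

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from sagkit.community import mutate_peptide, random_peptide
from sagkit.constants import AMINO_ACIDS
from sagkit.energy import (apply_ko_rule, detect_o2red, etc_profile, evalue,
                           genome_energy_profile, reference_o2red_db,
                           smith_waterman)
from _oracles import local_align_paths, local_align_score

_B62 = substitution_matrices.load("BLOSUM62")
_SUB = {a: {b: float(_B62[a][b]) for b in AMINO_ACIDS} for a in AMINO_ACIDS}


def _biopython_local(q, s, gap_open=11, gap_ext=1):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _B62
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_ext
    return aligner.score(q, s)


class TestSmithWaterman:
    def test_identity_scores_sum_of_diagonal(self):
        score, aln_len = smith_waterman("ACDE", "ACDE")
        assert score == 4 + 9 + 6 + 5
        assert aln_len == 4

    def test_symmetry(self, rng):
        for _ in range(10):
            q = random_peptide(int(rng.integers(5, 30)), rng)
            s = random_peptide(int(rng.integers(5, 30)), rng)
            assert smith_waterman(q, s)[0] == smith_waterman(s, q)[0]

    def test_empty_inputs(self):
        assert smith_waterman("", "ACDE") == (0.0, 0)
        assert smith_waterman("ACDE", "") == (0.0, 0)

    def test_nonnegative_and_equals_global_on_identity(self, rng):
        for _ in range(10):
            p = random_peptide(int(rng.integers(4, 20)), rng)
            score, aln_len = smith_waterman(p, p)
            assert score == sum(_SUB[a][a] for a in p)
            assert aln_len == len(p)

    def test_matches_substring_enumeration_oracle(self, rng):
        for _ in range(25):
            q = random_peptide(int(rng.integers(3, 9)), rng)
            s = random_peptide(int(rng.integers(3, 9)), rng)
            score, _ = smith_waterman(q, s)
            assert score == local_align_score(q, s, _SUB, 11.0, 1.0)

    def test_matches_exhaustive_path_dfs_with_length(self, rng):
        for _ in range(12):
            q = random_peptide(int(rng.integers(2, 6)), rng)
            s = random_peptide(int(rng.integers(2, 6)), rng)
            score, aln_len = smith_waterman(q, s)
            oscore, olen = local_align_paths(q, s, _SUB, 11.0, 1.0)
            assert score == oscore
            assert aln_len == olen

    def test_matches_biopython_on_longer_pairs(self, rng):
        for _ in range(20):
            root = random_peptide(int(rng.integers(30, 80)), rng)
            q = mutate_peptide(root, 0.2, rng)
            assert smith_waterman(q, root)[0] == _biopython_local(q, root)

    def test_gap_validation(self):
        with pytest.raises(ValueError):
            smith_waterman("ACD", "ACD", gap_open=0)


class TestEvalue:
    def test_linear_in_database_length(self):
        assert evalue(50, 100, 2000) == pytest.approx(2 * evalue(50, 100, 1000))

    def test_monotone_decreasing_in_score(self):
        assert evalue(110, 100, 1000) < evalue(100, 100, 1000)

    def test_closed_form_ratio(self):
        r = evalue(100, 50, 1000) / evalue(110, 50, 1000)
        assert r == pytest.approx(np.exp(0.267 * 10))

    def test_validation(self):
        with pytest.raises(ValueError):
            evalue(10, 0, 100)


class TestDetectO2red:
    def test_verbatim_reference_is_hit(self):
        ref = reference_o2red_db()[0]
        hits, tree = detect_o2red({"p1": ref.sequence})
        assert len(hits) == 1
        assert hits[0].family == ref.family
        assert hits[0].evalue <= 1e-10
        assert "p1" in tree  # 560 aa > 400

    def test_diverged_homolog_detected_with_family(self, rng):
        refs = reference_o2red_db()
        bd = next(r for r in refs if r.family == "bd")
        query = "M" + mutate_peptide(bd.sequence[1:], 0.10, rng)
        hits, _ = detect_o2red({"q": query})
        assert len(hits) == 1
        assert hits[0].family == "bd" and hits[0].affinity == "high"

    def test_random_decoys_never_hit(self, rng):
        decoys = {f"d{i}": random_peptide(300, rng) for i in range(100)}
        hits, _ = detect_o2red(decoys)
        assert len(hits) / 100 < 0.01

    def test_short_hit_excluded_from_tree_subset(self, rng):
        ref = reference_o2red_db()[0]
        frag = ref.sequence[:380]
        hits, tree = detect_o2red({"frag": frag})
        assert len(hits) == 1
        assert tree == []

    def test_empty_refdb_rejected(self):
        with pytest.raises(ValueError):
            detect_o2red({"p": "MKL"}, refdb=[])


class TestKoRule:
    @pytest.mark.parametrize("score,thr,accepted", [
        (50.0, 100.0, True),     # boundary: >= 50% of threshold
        (49.99, 100.0, False),
        (200.0, 100.0, True),
    ])
    def test_boundary(self, score, thr, accepted):
        rows = [dict(protein_id="p", ko_id="K00330", ko_score=score,
                     ko_threshold=thr)]
        (hit,) = apply_ko_rule(rows)
        assert hit.accepted is accepted

    def test_scale_invariance(self, rng):
        rows = [dict(protein_id=f"p{i}", ko_id="K00330",
                     ko_score=float(rng.uniform(1, 200)),
                     ko_threshold=float(rng.uniform(50, 300)))
                for i in range(50)]
        base = [h.accepted for h in apply_ko_rule(rows)]
        scaled_rows = [dict(r, ko_score=r["ko_score"] * 7.5,
                            ko_threshold=r["ko_threshold"] * 7.5)
                       for r in rows]
        assert [h.accepted for h in apply_ko_rule(scaled_rows)] == base

    def test_missing_threshold_warns(self):
        with pytest.warns(UserWarning):
            out = apply_ko_rule([dict(protein_id="p", ko_id="K00330",
                                      ko_score=10.0, ko_threshold=None)])
        assert out == []


class TestEtcProfile:
    def test_single_complex_not_complete(self):
        rows = [dict(protein_id="p1", ko_id="K02274", ko_score=100.0,
                     ko_threshold=100.0)]
        hits = apply_ko_rule(rows)
        ep = etc_profile(hits, [], protein_count=100, ec1_count=5)
        assert ep.complexes_present == {"IV"}
        assert ep.complete_etc is False
        assert ep.ec1_fraction == pytest.approx(5.0)

    def test_zero_proteins_rejected(self):
        with pytest.raises(ValueError):
            etc_profile([], [], protein_count=0, ec1_count=0)

    def test_cohort_contract_on_full_genomes(self, genome_pool):
        """Candidate-phyla genomes have no complete ETC; standard do."""
        for g in genome_pool:
            ep = genome_energy_profile(g.annotations, None,
                                       genome_id=g.profile.taxon_id)
            if g.profile.style in ("patesci_like", "dpann_like"):
                assert not ep.complete_etc
                assert ep.complex_counts == dict.fromkeys("I II III IV".split(), 0)
            elif g.profile.style == "standard":
                assert ep.complete_etc

    def test_ec1_fraction_group_gap(self, rng):
        """EC1 rates 0.01 vs 0.05 separate cohorts by rank-sum test."""
        from sagkit.community import make_taxon_profile, synthesize_genome
        from sagkit.ordination import ranksum_test

        lo, hi = [], []
        for i in range(12):
            pa = make_taxon_profile("Patescibacteria", "patesci_like", 900 + i)
            st = make_taxon_profile("Other-Bacteria", "standard", 950 + i)
            ga = synthesize_genome(pa, i)
            gs = synthesize_genome(st, i)
            lo.append(genome_energy_profile(ga.annotations, None).ec1_fraction)
            hi.append(genome_energy_profile(gs.annotations, None).ec1_fraction)
        r = ranksum_test(lo, hi)
        assert r.p_value < 0.01
        assert np.mean(lo) < np.mean(hi)
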