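import math
import random

import numpy as np
import pytest

from smilesalign import fixtures as fx
from smilesalign.molecule_io import compute_blueprint
from smilesalign.scoring import (
    N_BINS,
    PairedScoringSet,
    ScoringMatrix,
    bin_index,
    build_all_vs_all,
    build_charge_pool,
    build_paired,
    build_scoring_matrix,
    pairwise_abs_differences,
    score_lookup,
)

from .oracles import survival_raw_scores


class TestChargePool:
    def test_pool_size_is_sum_of_blueprint_sizes(self):
        bps = [compute_blueprint("CCO"), compute_blueprint("OC(=O)C")]
        pool = build_charge_pool(bps)
        assert len(pool.charges) == len(bps[0]) + len(bps[1])

    def test_methane_corpus_partitions_to_carbon_only(self):
        pool = build_charge_pool([compute_blueprint("C")])
        assert set(pool.per_element) == {"C"} and len(pool.per_element["C"]) == 1

    def test_per_element_partition_identity(self, combined_blueprints):
        pool = build_charge_pool(combined_blueprints)
        assert sum(len(v) for v in pool.per_element.values()) == len(pool.charges)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_charge_pool([])


class TestPairwiseDifferences:
    def test_single_list_enumerates_unordered_pairs(self):
        diffs = pairwise_abs_differences([0.0, 0.1, 0.3])
        assert sorted(np.round(diffs, 10)) == [0.1, 0.2, 0.3]

    def test_single_value_gives_empty_multiset(self):
        assert pairwise_abs_differences([0.5]).size == 0

    def test_cross_mode_full_product(self):
        diffs = pairwise_abs_differences([0.0], [0.2, 0.5])
        assert sorted(diffs) == [0.2, 0.5]
        assert pairwise_abs_differences([0.0, 1.0], [0.5, 0.5]).size == 4


class TestBuildScoringMatrix:
    def test_toy_survival_scores_by_hand(self):
        m = build_scoring_matrix([0.1, 0.2, 0.3])
        assert m.raw_scores[0] == 0.0
        assert m.raw_scores[1] == 0.0  # all three diffs >= 0.1
        assert m.raw_scores[2] == pytest.approx(math.log2(2 / 3))
        assert m.raw_scores[3] == pytest.approx(math.log2(1 / 3))

    def test_toy_normalization_about_mean_bin(self):
        # mean = 0.2 -> bin 2 anchors at zero
        m = build_scoring_matrix([0.1, 0.2, 0.3])
        assert m.scores[2] == 0.0
        assert m.scores[0] == pytest.approx(-math.log2(2 / 3))
        assert m.scores[3] == pytest.approx(math.log2(1 / 3) - math.log2(2 / 3))

    def test_raw_scores_match_brute_force_recount(self):
        rng = random.Random(11)
        for _ in range(25):
            diffs = [rng.uniform(0, 3.5) for _ in range(rng.randint(1, 10))]
            m = build_scoring_matrix(diffs)
            expected = survival_raw_scores(diffs)
            # clamp: recount treats >=3 tails via the last bin's edge
            assert np.allclose(m.raw_scores, expected)

    def test_raw_scores_monotone_nonincreasing(self):
        rng = random.Random(5)
        for _ in range(20):
            diffs = [rng.uniform(0, 3) for _ in range(rng.randint(2, 50))]
            m = build_scoring_matrix(diffs)
            assert np.all(np.diff(m.raw_scores) <= 1e-12)

    def test_empty_tail_floor_uses_pseudocount(self):
        m = build_scoring_matrix([0.05] * 8)
        assert m.raw_scores[0] == 0.0
        assert np.allclose(m.raw_scores[1:], math.log2(1 / 8))

    def test_empty_diffs_rejected(self):
        with pytest.raises(ValueError):
            build_scoring_matrix([])

    def test_normalization_contract_on_random_corpora(self):
        rng = random.Random(123)
        for _ in range(50):
            diffs = [abs(rng.gauss(0, 0.6)) for _ in range(rng.randint(3, 200))]
            m = build_scoring_matrix(diffs)
            mu_bin = bin_index(m.mean_diff)
            assert m.scores[mu_bin] == 0.0
            assert np.all(m.scores[:mu_bin] >= -1e-12)
            assert np.all(m.scores[mu_bin + 1 :] <= 1e-12)
            assert m.floor == m.scores.min()


class TestAllVsAll:
    def test_identical_atoms_floor_everything_above_bin_zero(self):
        bps = [compute_blueprint("C") for _ in range(3)]
        m = build_all_vs_all(bps)
        assert m.scores[0] == 0.0  # mean diff 0 -> bin 0 anchors at 0
        n = m.n_observations
        assert np.allclose(m.raw_scores[1:], math.log2(1 / n))

    def test_matches_direct_construction(self, combined_blueprints):
        pool = build_charge_pool(combined_blueprints)
        direct = build_scoring_matrix(pairwise_abs_differences(pool.charges))
        built = build_all_vs_all(combined_blueprints)
        assert np.allclose(built.scores, direct.scores)
        assert built.n_observations == direct.n_observations

    def test_monotone_on_random_corpus(self):
        smis = fx.random_smiles(seed=42, n=120, max_heavy_atoms=7)
        bps = [compute_blueprint(s) for s in smis]
        m = build_all_vs_all(bps)
        assert np.all(np.diff(m.raw_scores) <= 1e-12)
        m.validate()


class TestPaired:
    def test_carbon_only_corpus_has_cc_matrix_and_fallback(self):
        bps = [compute_blueprint(s) for s in ("CC", "CCC", "CCCC")]
        pset = build_paired(bps, min_pair_observations=1)
        assert set(pset.matrices) == {("C", "C")}
        assert pset.matrix_for("C", "O") is pset.fallback

    def test_cc_matrix_equals_manual_pool(self):
        bps = [compute_blueprint("CCC")]
        pset = build_paired(bps, min_pair_observations=1)
        carbons = bps[0].charges
        manual = build_scoring_matrix(pairwise_abs_differences(carbons))
        assert np.allclose(pset.matrix_for("C", "C").scores, manual.scores)

    def test_all_stored_matrices_satisfy_invariants(self, paired_set):
        for m in paired_set.matrices.values():
            m.validate()
        paired_set.fallback.validate()

    def test_rare_pairs_resolve_to_fallback(self, paired_set):
        assert paired_set.matrix_for("S", "P") is paired_set.fallback

    def test_intra_molecule_pooling_differs_from_cross(self, combined_blueprints):
        cross = build_paired(combined_blueprints, min_pair_observations=10)
        intra = build_paired(
            combined_blueprints, min_pair_observations=10, intra_molecule_only=True
        )
        cc_cross = cross.matrix_for("C", "C")
        cc_intra = intra.matrix_for("C", "C")
        assert cc_intra.n_observations < cc_cross.n_observations


class TestScoreLookup:
    def test_equal_charges_hit_bin_zero(self, all_matrix):
        assert score_lookup(all_matrix, "C", 0.3, "C", 0.3) == all_matrix.scores[0]
        assert all_matrix.scores[0] == all_matrix.scores.max()

    def test_huge_difference_clamps_to_last_bin(self, all_matrix):
        assert score_lookup(all_matrix, "C", 5.0, "O", 0.0) == all_matrix.scores[N_BINS - 1]

    def test_bin_arithmetic(self):
        m = build_scoring_matrix([0.1, 0.2, 0.3])
        assert score_lookup(m, "C", 0.1, "O", -0.25) == m.scores[3]

    def test_symmetry_randomized(self, paired_set, all_matrix):
        rng = random.Random(3)
        elems = ["C", "O", "N", "S", "P"]
        for _ in range(200):
            ea, eb = rng.choice(elems), rng.choice(elems)
            qa, qb = rng.uniform(-1, 1), rng.uniform(-1, 1)
            for scorer in (paired_set, all_matrix):
                assert score_lookup(scorer, ea, qa, eb, qb) == score_lookup(
                    scorer, eb, qb, ea, qa
                )


class TestSerialization:
    def test_matrix_roundtrip(self, all_matrix, tmp_path):
        all_matrix.save(tmp_path / "m")
        loaded = ScoringMatrix.load(tmp_path / "m")
        assert np.allclose(loaded.scores, all_matrix.scores)
        assert loaded.mean_diff == pytest.approx(all_matrix.mean_diff)
        assert loaded.n_observations == all_matrix.n_observations
        assert loaded.metadata.get("mode") == "all_vs_all"

    def test_paired_set_roundtrip(self, paired_set, tmp_path):
        paired_set.save(tmp_path / "pairs")
        loaded = PairedScoringSet.load(tmp_path / "pairs")
        assert set(loaded.matrices) == set(paired_set.matrices)
        for key, m in loaded.matrices.items():
            assert np.allclose(m.scores, paired_set.matrices[key].scores)
        assert loaded.min_pair_observations == paired_set.min_pair_observations
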