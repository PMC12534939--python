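import random
import string

import numpy as np
import pytest

from smilesalign import fixtures as fx
from smilesalign.alignment import GapPenalties, align_blueprints
from smilesalign.molecule_io import compute_blueprint
from smilesalign.validation import (
    SWEEP_RANGE,
    TruthEntry,
    TruthSet,
    best_parameters,
    exact_similarity,
    levenshtein_similarity,
    parameter_sweep,
    sweep_to_frame,
    tanimoto_coefficient,
    truth_from_mcs,
)

from .oracles import levenshtein_dp


class TestLevenshteinSimilarity:
    def test_identical_strings(self):
        assert levenshtein_similarity("OCOCC", "OCOCC") == 1.0

    def test_kitten_sitting(self):
        assert levenshtein_similarity("kitten", "sitting") == pytest.approx(1 - 3 / 7)

    def test_against_empty(self):
        assert levenshtein_similarity("OCC", "") == 0.0
        assert levenshtein_similarity("", "") == 1.0

    def test_matches_reference_dp_on_random_strings(self):
        rng = random.Random(77)
        for _ in range(100):
            s1 = "".join(rng.choices("CONS-", k=rng.randint(0, 12)))
            s2 = "".join(rng.choices("CONS-", k=rng.randint(0, 12)))
            if not s1 and not s2:
                continue
            expected = 1 - levenshtein_dp(s1, s2) / max(len(s1), len(s2))
            got = levenshtein_similarity(s1, s2)
            assert got == pytest.approx(expected)
            assert got == pytest.approx(levenshtein_similarity(s2, s1))
            assert 0.0 <= got <= 1.0
            assert (got == 1.0) == (s1 == s2)


class TestLevenshteinProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    token_strings = st.text(alphabet="CONSP-", max_size=15)

    @settings(derandomize=True, max_examples=150)
    @given(token_strings, token_strings)
    def test_bounds_symmetry_and_identity(self, s1, s2):
        v = levenshtein_similarity(s1, s2)
        assert 0.0 <= v <= 1.0
        assert v == levenshtein_similarity(s2, s1)
        assert (v == 1.0) == (s1 == s2)
        assert v == pytest.approx(
            1 - levenshtein_dp(s1, s2) / max(len(s1), len(s2), 1)
            if (s1 or s2) else 1.0
        )


class TestExactSimilarity:
    def test_identical(self):
        assert exact_similarity("OC-O", "OC-O") == 1.0

    def test_positionwise_count(self):
        assert exact_similarity("AB-", "A-B") == pytest.approx(1 / 3)

    def test_disjoint_alphabets(self):
        assert exact_similarity("CCC", "OOO") == 0.0

    def test_unequal_lengths_padded_with_gap(self):
        # "OC" pads to "OC--" against "OCCO": two matches over width 4
        assert exact_similarity("OC", "OCCO") == pytest.approx(0.5)

    def test_equality_iff_identical(self):
        assert exact_similarity("OCC", "OCO") < 1.0


class TestTanimoto:
    def test_self_similarity_is_one_for_fixtures(self):
        for _, smi in fx.builtin_corpus("krebs").molecules:
            assert tanimoto_coefficient(smi, smi) == 1.0

    def test_benzene_toluene_strictly_between_zero_and_one(self):
        v = tanimoto_coefficient("c1ccccc1", "Cc1ccccc1")
        assert 0.0 < v < 1.0
        assert v == pytest.approx(tanimoto_coefficient("Cc1ccccc1", "c1ccccc1"))

    def test_parse_error_propagates(self):
        from smilesalign.molecule_io import SmilesParseError

        with pytest.raises(SmilesParseError):
            tanimoto_coefficient("notasmiles((", "C")


def _self_truth(pairs, scorer, penalties=GapPenalties(0, 0)):
    """Truth set equal to the aligner's own output at the given penalties."""
    entries = []
    for (ia, sa), (ib, sb) in pairs:
        res = align_blueprints(
            compute_blueprint(sa, molecule_id=ia),
            compute_blueprint(sb, molecule_id=ib),
            scorer,
            penalties,
        )
        ga, gb = res.gapped_token_strings
        entries.append(TruthEntry(ia, ib, ga, gb))
    return TruthSet("self", entries)


def _corpus_pairs(name, limit=None):
    mols = fx.builtin_corpus(name).molecules
    pairs = [
        (mols[i], mols[j]) for i in range(len(mols)) for j in range(i + 1, len(mols))
    ]
    return pairs[:limit] if limit else pairs


class TestParameterSweep:
    def test_grid_has_exactly_121_cells_in_fixed_order(self, all_matrix):
        pairs = _corpus_pairs("krebs", limit=3)
        truth = _self_truth(pairs, all_matrix)
        cells = parameter_sweep(pairs, truth, all_matrix)
        assert len(cells) == 121
        assert [(c.g_open, c.g_extend) for c in cells] == [
            (go, ge) for go in SWEEP_RANGE for ge in SWEEP_RANGE
        ]

    def test_self_truth_cell_scores_perfectly(self, all_matrix):
        pairs = _corpus_pairs("krebs", limit=4)
        truth = _self_truth(pairs, all_matrix, GapPenalties(0, 0))
        cells = parameter_sweep(pairs, truth, all_matrix)
        cell = next(c for c in cells if (c.g_open, c.g_extend) == (0, 0))
        assert cell.mean_levenshtein_similarity == pytest.approx(1.0)
        assert cell.mean_exact_similarity == pytest.approx(1.0)
        assert cell.difference == pytest.approx(0.0)

    def test_missing_truth_entry_names_the_pair(self, all_matrix):
        pairs = _corpus_pairs("krebs", limit=2)
        truth = _self_truth(pairs[:1], all_matrix)
        with pytest.raises(KeyError, match="oxaloacetate"):
            parameter_sweep(pairs, truth, all_matrix)

    def test_sweep_is_deterministic(self, all_matrix):
        pairs = _corpus_pairs("krebs", limit=2)
        truth = _self_truth(pairs, all_matrix)
        df1 = sweep_to_frame(parameter_sweep(pairs, truth, all_matrix))
        df2 = sweep_to_frame(parameter_sweep(pairs, truth, all_matrix))
        assert df1.to_csv(index=False) == df2.to_csv(index=False)

    def test_cell_metrics_recomputable_from_emitted_alignments(self, all_matrix):
        from smilesalign.validation import levenshtein_similarity as lsim

        pairs = _corpus_pairs("krebs", limit=3)
        truth = fx.builtin_truth("krebs")
        cells = parameter_sweep(pairs, truth, all_matrix, grid=[0])
        # independent recomputation of the single cell
        lev = []
        for (ia, sa), (ib, sb) in pairs:
            res = align_blueprints(
                compute_blueprint(sa, molecule_id=ia),
                compute_blueprint(sb, molecule_id=ib),
                all_matrix,
                GapPenalties(0, 0),
            )
            pa, pb = res.gapped_token_strings
            ta, tb = truth.lookup(ia, ib)
            lev.append(0.5 * (lsim(pa, ta) + lsim(pb, tb)))
        assert cells[0].mean_levenshtein_similarity == pytest.approx(np.mean(lev))


class TestBestParameters:
    def _cell(self, go, ge, lev, exact):
        from smilesalign.validation import SweepCell

        return SweepCell(go, ge, lev, exact)

    def test_single_cell(self):
        assert best_parameters([self._cell(2, 3, 0.5, 0.4)]) == (2, 3)

    def test_strictly_dominant_cell_wins(self):
        cells = [self._cell(0, 0, 0.9, 0.8), self._cell(1, 1, 0.5, 0.5)]
        assert best_parameters(cells) == (0, 0)

    def test_tie_broken_by_smaller_difference_then_lexicographic(self):
        cells = [
            self._cell(1, 0, 0.9, 0.5),
            self._cell(0, 1, 0.9, 0.8),
            self._cell(2, 2, 0.9, 0.8),
        ]
        assert best_parameters(cells) == (0, 1)


class TestTruthSets:
    def test_bundled_truth_sets_cover_all_pairs(self):
        for name, n_mols in (("krebs", 7), ("glycolysis", 10)):
            truth = fx.builtin_truth(name)
            assert len(truth.entries) == n_mols * (n_mols - 1) // 2
            for e in truth.entries:
                assert len(e.gapped_a) == len(e.gapped_b)

    def test_truth_gapped_strings_strip_to_token_strings(self):
        truth = fx.builtin_truth("krebs")
        corpus = dict(fx.builtin_corpus("krebs").molecules)
        for e in truth.entries:
            bp = compute_blueprint(corpus[e.id_a])
            assert e.gapped_a.replace("-", "") == bp.token_string

    def test_tsv_roundtrip(self, tmp_path):
        truth = fx.builtin_truth("krebs")
        truth.to_tsv(tmp_path / "t.tsv", header_comment="roundtrip")
        loaded = TruthSet.from_tsv(tmp_path / "t.tsv")
        assert loaded.entries == truth.entries

    def test_lookup_is_order_aware(self):
        truth = fx.builtin_truth("krebs")
        a, b = truth.entries[0].id_a, truth.entries[0].id_b
        ga, gb = truth.lookup(a, b)
        gb2, ga2 = truth.lookup(b, a)
        assert (ga, gb) == (ga2, gb2)

    def test_mcs_reconstruction_matches_bundled_file(self):
        corpus = fx.builtin_corpus("krebs").molecules[:3]
        rebuilt = truth_from_mcs(corpus, name="krebs")
        bundled = fx.builtin_truth("krebs")
        for e in rebuilt.entries:
            assert bundled.lookup(e.id_a, e.id_b) == (e.gapped_a, e.gapped_b)
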