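"""Engine correctness: full DP, thresholded variants, pruning register."""

import math

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gedmatch.engines import (
    ENGINES,
    OVER_K,
    PruningRegister,
    compute_skip_stats,
    decide_match,
    full_distance_diagonal,
    full_distance_vertical,
    kmismatch_cellwise,
    kmismatch_diagonal_skip,
    run_engine,
)
from gedmatch.synthetic import oracle_distance

from conftest import ALL_METRICS, SOUND_METRICS, model_for, random_pairs

K_ENGINES = ("cellwise", "diag-skip", "diag-skip2")


class TestFullDistance:
    @pytest.mark.parametrize(
        "X,Y,expected",
        [
            ("ccatese", "catch", 4),  # worked example: bottom-right cell is 4
            ("bat", "bad", 1),
            ("", "abc", 3),
            ("abc", "", 3),
            ("", "", 0),
            ("ab", "ba", 2),
            ("kitten", "sitting", 3),
        ],
    )
    def test_unit_distances(self, unit_model, X, Y, expected):
        assert full_distance_vertical(X, Y, unit_model).distance == expected
        assert full_distance_diagonal(X, Y, unit_model).distance == expected

    @pytest.mark.parametrize("metric", ALL_METRICS)
    def test_identical_strings_have_zero_distance(self, metric):
        model = model_for(metric, "catch")
        assert full_distance_vertical("catch", "catch", model).distance == 0

    @pytest.mark.parametrize("metric", ALL_METRICS)
    def test_diagonal_matches_vertical_cell_for_cell(self, metric):
        for X, Y in random_pairs(seed=7, n=250, max_len=12):
            model = model_for(metric, Y)
            vertical = full_distance_vertical(X, Y, model)
            diagonal = full_distance_diagonal(X, Y, model)
            np.testing.assert_allclose(diagonal.values, vertical.values, atol=1e-9)

    def test_boundaries_are_cumulative_indels(self, unit_model):
        matrix = full_distance_vertical("abc", "de", unit_model)
        assert list(matrix.values[:, 0]) == [0, 1, 2, 3]
        assert list(matrix.values[0, :]) == [0, 1, 2]

    def test_unit_distance_agrees_with_edlib(self, unit_model):
        """Independent cross-check against an external Levenshtein engine."""
        for X, Y in random_pairs(seed=13, n=300, max_len=12, min_len=1):
            expected = edlib.align(X, Y)["editDistance"]
            assert full_distance_vertical(X, Y, unit_model).distance == expected

    def test_matrix_dump_marks_skipped_cells(self, unit_model):
        result = kmismatch_diagonal_skip(
            "ccatese", "catch", 2, unit_model, keep_matrix=True, early_stop=False
        )
        dump = result.matrix.to_tsv()
        assert "INF" in dump and dump.startswith("\t-\tc\ta\tt\tc\th")


class TestCellwise:
    def test_worked_example_rejected_at_k2(self, unit_model):
        result = kmismatch_cellwise("ccatese", "catch", 2, unit_model)
        assert not result.matched

    def test_close_pair_matches(self, unit_model):
        result = kmismatch_cellwise("bat", "bad", 1, unit_model)
        assert result.matched and result.distance == 1

    @pytest.mark.parametrize("metric", ALL_METRICS)
    def test_decision_equals_thresholded_full_dp_any_metric(self, metric):
        """Eq-style per-operator checks never change the decision, any metric."""
        rng = np.random.default_rng(23)
        for X, Y in random_pairs(seed=29, n=400, max_len=10):
            model = model_for(metric, Y)
            k = float(rng.uniform(0, 8))
            full = full_distance_vertical(X, Y, model).distance
            result = kmismatch_cellwise(X, Y, k, model)
            assert result.matched == (full <= k)
            if result.matched:
                assert result.distance == pytest.approx(full)

    def test_negative_k_rejected(self, unit_model):
        for engine in K_ENGINES:
            with pytest.raises(ValueError):
                run_engine("a", "b", -1, unit_model, engine=engine)


class TestDiagonalSkip:
    def test_register_prunes_first_column_on_worked_example(self, unit_model):
        """At k=2 the 'c' column's bit gets set and the pair is rejected."""
        result = kmismatch_diagonal_skip("ccatese", "catch", 2, unit_model)
        assert result.register[1]
        assert not result.matched
        assert result.stats.skipped_cells > 0

    def test_identity_match_at_k_zero(self, unit_model):
        result = kmismatch_diagonal_skip("catch", "catch", 0, unit_model)
        assert result.matched and result.distance == 0
        assert result.stats.skipped_cells > 0  # off-diagonal cells pruned

    @pytest.mark.parametrize("variant", ["I", "II"])
    @pytest.mark.parametrize("metric", SOUND_METRICS)
    def test_pruning_soundness(self, metric, variant):
        """Every skipped or sentinel cell truly exceeds k (sub <= indel metrics)."""
        rng = np.random.default_rng(31)
        for X, Y in random_pairs(seed=37, n=300, max_len=10):
            model = model_for(metric, Y)
            k = float(rng.uniform(0, 6))
            full = full_distance_vertical(X, Y, model).values
            result = kmismatch_diagonal_skip(
                X, Y, k, model, variant=variant, keep_matrix=True, early_stop=False
            )
            skipped = np.isinf(result.matrix.values)
            assert (full[skipped] > k).all()
            assert result.register.is_monotone_prefix

    @pytest.mark.parametrize("variant", ["I", "II"])
    @pytest.mark.parametrize("metric", SOUND_METRICS)
    def test_decision_equivalence(self, metric, variant):
        rng = np.random.default_rng(41)
        for X, Y in random_pairs(seed=43, n=300, max_len=10):
            model = model_for(metric, Y)
            k = float(rng.uniform(0, 6))
            full = full_distance_vertical(X, Y, model).distance
            result = kmismatch_diagonal_skip(X, Y, k, model, variant=variant)
            assert result.matched == (full <= k)

    @pytest.mark.parametrize("metric", ALL_METRICS)
    def test_pruning_is_one_sided_for_every_metric(self, metric):
        """Register engines never report a false match and never underestimate.

        For metrics whose substitution costs can exceed the indel cost the
        register may over-prune (a missed match is possible), but a reported
        match is always a true match and matched distances are exact.
        """
        rng = np.random.default_rng(47)
        for X, Y in random_pairs(seed=53, n=300, max_len=10):
            model = model_for(metric, Y)
            k = float(rng.uniform(0, 8))
            true = full_distance_vertical(X, Y, model).distance
            for variant in ("I", "II"):
                result = kmismatch_diagonal_skip(X, Y, k, model, variant=variant)
                assert result.distance >= true - 1e-9
                if result.matched:
                    assert true <= k
                    assert result.distance == pytest.approx(true)

    def test_thresholded_cells_are_exact(self, unit_model):
        """Any computed cell value <= k equals the full-DP value."""
        rng = np.random.default_rng(59)
        for X, Y in random_pairs(seed=61, n=200, max_len=10):
            k = float(rng.integers(0, 6))
            full = full_distance_vertical(X, Y, unit_model).values
            result = kmismatch_diagonal_skip(
                X, Y, k, unit_model, keep_matrix=True, early_stop=False
            )
            values = result.matrix.values
            within = np.isfinite(values) & (values <= k)
            np.testing.assert_allclose(values[within], full[within], atol=1e-9)

    def test_hand_derived_skip_counts_on_divergent_pair(self, unit_model):
        """k=0 on fully divergent strings: only the top row frontier is computed.

        Hand derivation for 'aaaaaa' vs 'bbbbbb': traversal t computes the
        single cell (1, t-1), sets that column's bit, and every later cell
        breaks -- 6 computed cells, 30 skipped, 5 register-dropped insertions.
        """
        result = kmismatch_diagonal_skip(
            "aaaaaa", "bbbbbb", 0, unit_model, keep_matrix=True, early_stop=False
        )
        stats = result.stats
        assert stats.computed_cells == 6
        assert stats.skipped_cells == 30
        assert stats.skipped_insertion_ops == 5
        assert stats.combined_skip_ratio == pytest.approx(95 / 108)

    def test_early_termination_matches_full_run_decision(self, unit_model):
        for X, Y in random_pairs(seed=67, n=200, max_len=10):
            for k in (0, 1, 2):
                eager = kmismatch_diagonal_skip(X, Y, k, unit_model, early_stop=True)
                lazy = kmismatch_diagonal_skip(X, Y, k, unit_model, early_stop=False)
                assert eager.matched == lazy.matched

    def test_register_rejects_prefix_violation(self):
        register = PruningRegister(4)
        with pytest.raises(ValueError):
            register.set(2)  # bit 1 not yet set
        register.set(1)
        register.set(2)
        assert register.is_monotone_prefix

    def test_invalid_variant_rejected(self, unit_model):
        with pytest.raises(ValueError):
            kmismatch_diagonal_skip("a", "b", 1, unit_model, variant="III")


class TestDecideMatchAndStats:
    def test_decide_match_examples(self, unit_model):
        assert decide_match(4.0, 2) is False
        assert decide_match(0.0, 0) is True
        assert decide_match(OVER_K, 1e9) is False
        matrix = full_distance_vertical("ccatese", "catch", unit_model)
        assert decide_match(matrix, 2) is False
        assert decide_match(matrix, 4) is True

    def test_no_pruning_means_zero_ratio(self, unit_model):
        result = kmismatch_diagonal_skip("catch", "catch", 100, unit_model)
        assert compute_skip_stats(result).combined_skip_ratio == 0.0

    def test_empty_problem_has_zero_ratio(self, unit_model):
        result = kmismatch_diagonal_skip("", "", 1, unit_model)
        assert compute_skip_stats(result).combined_skip_ratio == 0.0
        assert result.matched

    @pytest.mark.parametrize("engine", K_ENGINES)
    def test_cell_accounting_sums_to_interior(self, unit_model, engine):
        rng = np.random.default_rng(71)
        for X, Y in random_pairs(seed=73, n=100, max_len=10):
            k = float(rng.integers(0, 5))
            stats = run_engine(X, Y, k, unit_model, engine=engine).stats
            assert stats.computed_cells + stats.skipped_cells == len(X) * len(Y)
            assert 0.0 <= stats.combined_skip_ratio <= 1.0

    def test_ratio_nonincreasing_in_k_on_fixed_pairs(self, unit_model):
        pairs = random_pairs(seed=79, n=150, max_len=12, min_len=4)
        ratios = []
        for k in range(1, 9):
            runs = [kmismatch_diagonal_skip(X, Y, k, unit_model) for X, Y in pairs]
            ratios.append(sum(r.stats.combined_skip_ratio for r in runs) / len(runs))
        assert all(a >= b for a, b in zip(ratios, ratios[1:]))


class TestMetricAxioms:
    def test_unit_metric_axioms_on_random_triples(self, unit_model):
        """Symmetry, triangle inequality, identity of indiscernibles."""
        triples = list(
            zip(
                random_pairs(seed=83, n=300, max_len=8),
                (p[0] for p in random_pairs(seed=89, n=300, max_len=8)),
            )
        )
        for (X, Y), Z in triples:
            dxy = full_distance_vertical(X, Y, unit_model).distance
            assert dxy == full_distance_vertical(Y, X, unit_model).distance
            dxz = full_distance_vertical(X, Z, unit_model).distance
            dyz = full_distance_vertical(Y, Z, unit_model).distance
            assert dxz <= dxy + dyz + 1e-9
            assert (dxy == 0) == (X == Y)

    def test_levenshtein_bounds(self, unit_model):
        for X, Y in random_pairs(seed=97, n=300, max_len=12):
            d = full_distance_vertical(X, Y, unit_model).distance
            assert max(0, abs(len(X) - len(Y))) <= d <= max(len(X), len(Y), 0)
        assert full_distance_vertical("hello", "", unit_model).distance == 5


class TestDispatch:
    def test_unknown_engine_lists_valid_names(self, unit_model):
        with pytest.raises(ValueError, match="vertical"):
            run_engine("a", "b", 1, unit_model, engine="banded")

    @pytest.mark.parametrize("engine", ENGINES)
    def test_all_engines_accept_empty_strings(self, unit_model, engine):
        assert run_engine("", "", 0, unit_model, engine=engine).matched
        result = run_engine("", "abc", 2, unit_model, engine=engine)
        assert not result.matched
        assert run_engine("", "abc", 3, unit_model, engine=engine).matched


@settings(deadline=None, derandomize=True, max_examples=300)
@given(
    X=st.text(alphabet="abc", max_size=8),
    Y=st.text(alphabet="abc", max_size=8),
    k=st.integers(min_value=0, max_value=6),
)
def test_every_engine_agrees_with_the_recursive_oracle(X, Y, k):
    """Decision of every engine equals thresholding the independent oracle."""
    from gedmatch.cost_models import unit_cost_model

    model = unit_cost_model()
    truth = oracle_distance(X, Y, model)
    for engine in ENGINES:
        result = run_engine(X, Y, float(k), model, engine=engine)
        assert result.matched == (truth <= k)
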