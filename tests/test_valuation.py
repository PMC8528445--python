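"""Shapley valuation: exact enumeration, MC sampling, LR importance."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression

from fedequity import (
    CoalitionGame,
    GeneratorSpec,
    TooManyPlayersError,
    coalition_utility,
    exact_shapley,
    generate_institutions,
    lr_feature_importance,
    make_accuracy_game,
    mc_shapley,
)

from conftest import make_dataset


def permutation_oracle(players, values):
    """Average marginal over all n! orderings — the defining formula."""
    n = len(players)
    phi = {p: 0.0 for p in players}
    for order in itertools.permutations(players):
        coalition = frozenset()
        for p in order:
            phi[p] += values[coalition | {p}] - values[coalition]
            coalition = coalition | {p}
    return {p: v / math.factorial(n) for p, v in phi.items()}


def table_game(players, values):
    return CoalitionGame(players=tuple(players), utility=lambda s: values[frozenset(s)])


def random_game(rng, n):
    players = tuple(f"p{i}" for i in range(n))
    values = {}
    for r in range(n + 1):
        for combo in itertools.combinations(players, r):
            values[frozenset(combo)] = float(rng.random())
    values[frozenset()] = 0.0
    return players, values


class TestExactShapley:
    def test_two_player_hand_enumeration(self):
        values = {
            frozenset(): 0.0,
            frozenset({"p1"}): 0.6,
            frozenset({"p2"}): 0.7,
            frozenset({"p1", "p2"}): 0.9,
        }
        result = exact_shapley(table_game(["p1", "p2"], values))
        assert result.phi["p1"] == pytest.approx(0.4)
        assert result.phi["p2"] == pytest.approx(0.5)

    def test_dummy_player_gets_zero(self):
        base = {
            frozenset(): 0.0,
            frozenset({"a"}): 0.5,
            frozenset({"b"}): 0.3,
            frozenset({"a", "b"}): 0.8,
        }
        values = dict(base)
        for s, v in base.items():
            values[s | {"d"}] = v
        result = exact_shapley(table_game(["a", "b", "d"], values))
        assert result.phi["d"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_players_get_equal_values(self):
        values = {
            frozenset(): 0.0,
            frozenset({"a"}): 0.4,
            frozenset({"b"}): 0.4,
            frozenset({"a", "b"}): 0.9,
        }
        result = exact_shapley(table_game(["a", "b"], values))
        assert result.phi["a"] == pytest.approx(result.phi["b"])

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_matches_permutation_oracle_on_random_games(self, n):
        rng = np.random.default_rng(n)
        players, values = random_game(rng, n)
        result = exact_shapley(table_game(players, values))
        oracle = permutation_oracle(players, values)
        for p in players:
            assert result.phi[p] == pytest.approx(oracle[p], abs=1e-12)

    def test_efficiency_to_machine_precision(self):
        rng = np.random.default_rng(9)
        players, values = random_game(rng, 4)
        result = exact_shapley(table_game(players, values))
        grand = values[frozenset(players)]
        assert sum(result.phi.values()) == pytest.approx(grand, abs=1e-12)

    def test_additivity_of_two_games(self):
        rng = np.random.default_rng(11)
        players, v1 = random_game(rng, 3)
        _, v2 = random_game(rng, 3)
        v_sum = {s: v1[s] + v2[s] for s in v1}
        r1 = exact_shapley(table_game(players, v1))
        r2 = exact_shapley(table_game(players, v2))
        rs = exact_shapley(table_game(players, v_sum))
        for p in players:
            assert rs.phi[p] == pytest.approx(r1.phi[p] + r2.phi[p], abs=1e-12)

    def test_refuses_more_than_twelve_players(self):
        players = tuple(f"p{i}" for i in range(13))
        game = CoalitionGame(players=players, utility=lambda s: len(s))
        with pytest.raises(TooManyPlayersError):
            exact_shapley(game)

    def test_evaluation_count_is_two_to_the_n(self):
        rng = np.random.default_rng(3)
        players, values = random_game(rng, 4)
        game = table_game(players, values)
        exact_shapley(game)
        assert game.n_evaluations == 2**4


class TestMCShapley:
    def _fixed_game(self):
        rng = np.random.default_rng(21)
        return random_game(rng, 3)

    def test_same_seed_is_bitwise_identical(self):
        players, values = self._fixed_game()
        r1 = mc_shapley(table_game(players, values), 100, seed=5)
        r2 = mc_shapley(table_game(players, values), 100, seed=5)
        assert r1.phi == r2.phi
        assert r1.std_err == r2.std_err

    def test_telescoping_efficiency_is_exact(self):
        players, values = self._fixed_game()
        result = mc_shapley(table_game(players, values), 17, seed=2)
        grand = values[frozenset(players)] - values[frozenset()]
        assert sum(result.phi.values()) == pytest.approx(grand, abs=1e-12)

    def test_estimate_within_three_standard_errors_of_exact(self):
        players, values = self._fixed_game()
        exact = exact_shapley(table_game(players, values))
        mc = mc_shapley(table_game(players, values), 500, seed=7)
        for p in players:
            margin = max(3 * mc.std_err[p], 1e-9)
            assert abs(mc.phi[p] - exact.phi[p]) <= margin

    def test_error_shrinks_with_more_permutations(self):
        players, values = self._fixed_game()
        exact = exact_shapley(table_game(players, values))

        def mae(n_perm):
            mc = mc_shapley(table_game(players, values), n_perm, seed=13)
            return np.mean([abs(mc.phi[p] - exact.phi[p]) for p in players])

        assert mae(10000) < mae(100)


@pytest.fixture(scope="module")
def institutions():
    spec = GeneratorSpec(
        n_institutions=3,
        records_per_institution=(120, 120, 120),
        n_features=5,
        effect_size=3.0,
        seed=42,
    )
    datasets, _ = generate_institutions(spec)
    return datasets


@pytest.fixture(scope="module")
def heldout():
    spec = GeneratorSpec(
        n_institutions=1,
        records_per_institution=(200,),
        n_features=5,
        effect_size=3.0,
        seed=43,
    )
    datasets, _ = generate_institutions(spec)
    ds = datasets[0]
    ds.institution_id = "heldout"
    ds.record_ids = [f"h-{i}" for i in range(ds.n_records)]
    return ds


class TestCoalitionUtility:
    def test_empty_coalition_scores_majority_class(self, heldout):
        acc = coalition_utility([], heldout)
        majority = np.bincount(np.asarray(heldout.labels)).argmax()
        assert acc == pytest.approx(np.mean(np.asarray(heldout.labels) == majority))

    def test_full_coalition_nearly_separates_strong_signal(self, institutions, heldout):
        assert coalition_utility(institutions, heldout) >= 0.95

    def test_duplicate_institution_leaves_utility_unchanged(self, institutions, heldout):
        base = coalition_utility(institutions, heldout)
        doubled = coalition_utility(list(institutions) + [institutions[0]], heldout)
        assert doubled == pytest.approx(base)

    def test_single_class_pool_falls_back_to_majority(self, heldout):
        ds = make_dataset("solo", [[0.1, 0.2, 0.3, 0.4, 0.5]] * 4,
                          schema=heldout.schema,
                          labels=np.ones(4, dtype=int))
        acc = coalition_utility([ds], heldout)
        assert acc == pytest.approx(np.mean(np.asarray(heldout.labels) == 1))

    def test_dice_pipeline_needs_no_utility_evaluations(self, institutions, heldout):
        from fedequity import institution_similarity_scores

        game = make_accuracy_game(institutions, heldout)
        institution_similarity_scores(institutions)
        assert game.n_evaluations == 0  # similarity scoring touched no utility
        exact_shapley(game)
        assert game.n_evaluations == 2 ** len(institutions)


class TestLRImportance:
    def test_dominant_coefficient_ranks_first(self):
        rng = np.random.default_rng(3)
        n = 2000
        X = rng.standard_normal((n, 4))
        logits = 10.0 * X[:, 2] + 1.0 * X[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        model = LogisticRegression(max_iter=1000).fit(X, y)
        ranked = lr_feature_importance(model, ["a", "b", "c", "d"])
        assert ranked[0][0] == "c"

    def test_zero_coefficients_keep_input_order(self):
        model = LogisticRegression()
        model.coef_ = np.zeros((1, 3))
        model.intercept_ = np.zeros(1)
        ranked = lr_feature_importance(model, ["x", "y", "z"])
        assert [f for f, _ in ranked] == ["x", "y", "z"]
        assert all(v == 0.0 for _, v in ranked)

    def test_permuting_features_permutes_output_consistently(self):
        model = LogisticRegression()
        model.coef_ = np.array([[0.5, 2.0, 1.0]])
        model.intercept_ = np.zeros(1)
        ranked = lr_feature_importance(model, ["a", "b", "c"])
        permuted = LogisticRegression()
        permuted.coef_ = np.array([[2.0, 1.0, 0.5]])
        permuted.intercept_ = np.zeros(1)
        ranked_p = lr_feature_importance(permuted, ["b", "c", "a"])
        assert ranked == ranked_p

    def test_unfitted_model_rejected(self):
        from fedequity import ValidationError

        with pytest.raises(ValidationError):
            lr_feature_importance(LogisticRegression(), ["a"])
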