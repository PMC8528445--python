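"""Shapley-value data valuation over institutions.

The comparator to the cheap Dice-based contribution scores: treat the
institutions as players in a cooperative game whose utility v(S) is the
held-out accuracy of a logistic-regression model trained on the pooled
data of coalition S, and allocate credit by the Shapley value

    phi_i = sum_{S not containing i} |S|! (n-|S|-1)! / n! * [v(S u {i}) - v(S)].

Exact enumeration costs 2^n utility evaluations and is limited here to
n <= 12 players; the Monte-Carlo permutation estimator averages each
player's marginal contribution over uniformly sampled join orders and
satisfies efficiency (sum phi = v(all) - v(empty)) exactly, because each
permutation's marginals telescope. The game counts its utility
evaluations so the cost asymmetry against the Dice pipeline (which
needs none) is measurable in counts rather than wall-clock seconds.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, FrozenSet, Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .data_model import InstitutionDataset, ValidationError

logger = logging.getLogger(__name__)

MAX_EXACT_PLAYERS = 12


class TooManyPlayersError(ValueError):
    """Exact enumeration refused; use mc_shapley instead."""


@dataclass
class CoalitionGame:
    """Utility function over institution subsets, with memoisation.

    ``n_evaluations`` counts distinct utility evaluations (cache
    misses), the currency of the Shapley cost argument.
    """

    players: tuple[str, ...]
    utility: Callable[[FrozenSet[str]], float]
    cache: dict[FrozenSet[str], float] = field(default_factory=dict)
    n_evaluations: int = 0

    def __post_init__(self):
        self.players = tuple(self.players)
        if len(self.players) != len(set(self.players)):
            raise ValidationError("player ids must be unique")

    def value(self, subset: Sequence[str] | FrozenSet[str]) -> float:
        key = frozenset(subset)
        if not key <= set(self.players):
            raise ValidationError(f"unknown players in coalition: {key}")
        if key not in self.cache:
            self.cache[key] = float(self.utility(key))
            self.n_evaluations += 1
        return self.cache[key]


@dataclass(frozen=True)
class ShapleyResult:
    """Per-player values phi, with standard errors for MC estimates."""

    phi: dict[str, float]
    std_err: dict[str, float]
    n_permutations: int
    seed: int | None
    method: str
    n_evaluations: int

    def to_dict(self) -> dict:
        return {
            "phi": dict(self.phi),
            "std_err": dict(self.std_err),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "method": self.method,
            "n_evaluations": self.n_evaluations,
        }


# ---------------------------------------------------------------------------
# Model-performance utility
# ---------------------------------------------------------------------------

# Fixed settings keep the utility a pure function of the data:
# standardized features, L2 penalty (sklearn default), deterministic
# lbfgs solver with a fixed iteration cap.
_LR_SETTINGS = dict(C=1.0, solver="lbfgs", max_iter=1000)


def _pool_coalition(subset: Sequence[InstitutionDataset]):
    """Pooled (X, y) over a coalition, deduplicated by record identity."""
    seen: set[str] = set()
    xs, ys = [], []
    for ds in subset:
        if ds.labels is None:
            raise ValidationError(
                f"institution {ds.institution_id!r} has no labels"
            )
        mat = ds.numeric_matrix()
        for i, rid in enumerate(ds.effective_record_ids()):
            if rid in seen:
                continue
            seen.add(rid)
            xs.append(mat[i])
            ys.append(int(ds.labels[i]))
    if not xs:
        return np.empty((0, 0)), np.empty((0,), dtype=int)
    return np.asarray(xs), np.asarray(ys, dtype=int)


def coalition_utility(
    subset: Sequence[InstitutionDataset],
    heldout: InstitutionDataset,
    settings: Mapping | None = None,
) -> float:
    """Held-out accuracy of a logistic model trained on a coalition.

    The empty coalition — and any single-class training pool — falls
    back to the majority-class predictor (class priors taken from the
    held-out labels for the empty coalition, from the training pool
    otherwise), so every marginal contribution is well defined.
    """
    if heldout.labels is None:
        raise ValidationError("held-out dataset must carry labels")
    X_test = heldout.numeric_matrix()
    y_test = np.asarray(heldout.labels, dtype=int)
    if y_test.size == 0:
        raise ValidationError("held-out dataset is empty")

    X, y = _pool_coalition(subset)
    if X.size == 0:
        majority = np.bincount(y_test).argmax()
        return float(np.mean(y_test == majority))
    if len(np.unique(y)) < 2:
        logger.warning("single-class training pool; majority-class fallback")
        majority = np.bincount(y).argmax()
        return float(np.mean(y_test == majority))

    params = dict(_LR_SETTINGS)
    if settings:
        params.update(settings)
    model = make_pipeline(StandardScaler(), LogisticRegression(**params))
    model.fit(X, y)
    return float(model.score(X_test, y_test))


def make_accuracy_game(
    institutions: Sequence[InstitutionDataset],
    heldout: InstitutionDataset,
    settings: Mapping | None = None,
) -> CoalitionGame:
    """Coalition game with held-out accuracy utility over institutions."""
    by_id = {d.institution_id: d for d in institutions}

    def u(subset: FrozenSet[str]) -> float:
        return coalition_utility(
            [by_id[i] for i in sorted(subset)], heldout, settings
        )

    return CoalitionGame(players=tuple(by_id), utility=u)


# ---------------------------------------------------------------------------
# Shapley estimators
# ---------------------------------------------------------------------------


def exact_shapley(game: CoalitionGame) -> ShapleyResult:
    """Closed-form Shapley values by subset enumeration (2^n utilities)."""
    players = game.players
    n = len(players)
    if n > MAX_EXACT_PLAYERS:
        raise TooManyPlayersError(
            f"{n} players would need 2^{n} utility evaluations; "
            "use mc_shapley for sampled estimates"
        )
    fact = [math.factorial(k) for k in range(n + 1)]
    phi = {p: 0.0 for p in players}
    for p in players:
        others = [q for q in players if q != p]
        for r in range(n):
            weight = fact[r] * fact[n - r - 1] / fact[n]
            for combo in itertools.combinations(others, r):
                s = frozenset(combo)
                phi[p] += weight * (game.value(s | {p}) - game.value(s))
    return ShapleyResult(
        phi=phi,
        std_err={p: 0.0 for p in players},
        n_permutations=0,
        seed=None,
        method="exact",
        n_evaluations=game.n_evaluations,
    )


def mc_shapley(
    game: CoalitionGame, n_permutations: int, seed: int
) -> ShapleyResult:
    """Monte-Carlo permutation-sampling Shapley estimate.

    Each sampled join order contributes one marginal per player; the
    marginals along a permutation telescope to v(all) - v(empty), so the
    estimates sum to that difference exactly regardless of sample size.
    Standard errors come from the across-permutation variance.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    players = list(game.players)
    marginals = {p: np.empty(n_permutations) for p in players}
    for t in range(n_permutations):
        order = [players[i] for i in rng.permutation(len(players))]
        prev = game.value(frozenset())
        coalition: set[str] = set()
        for p in order:
            coalition.add(p)
            cur = game.value(frozenset(coalition))
            marginals[p][t] = cur - prev
            prev = cur
    phi = {p: float(m.mean()) for p, m in marginals.items()}
    std_err = {
        p: float(m.std(ddof=1) / math.sqrt(n_permutations))
        if n_permutations > 1
        else float("nan")
        for p, m in marginals.items()
    }
    return ShapleyResult(
        phi=phi,
        std_err=std_err,
        n_permutations=n_permutations,
        seed=seed,
        method="mc",
        n_evaluations=game.n_evaluations,
    )


# ---------------------------------------------------------------------------
# Logistic-regression feature importance
# ---------------------------------------------------------------------------


def lr_feature_importance(
    model, feature_names: Sequence[str]
) -> list[tuple[str, float]]:
    """Rank features by |coefficient| of a fitted standardized logistic model.

    Accepts a fitted LogisticRegression or a pipeline ending in one.
    Descending by importance; ties broken by input feature order.
    """
    lr = model
    if hasattr(model, "named_steps"):
        lr = model.steps[-1][1]
    if not hasattr(lr, "coef_"):
        raise ValidationError("model is not fitted")
    coefs = np.abs(np.ravel(lr.coef_))
    if len(coefs) != len(feature_names):
        raise ValidationError("feature_names length must match coefficients")
    order = sorted(range(len(coefs)), key=lambda j: (-coefs[j], j))
    return [(feature_names[j], float(coefs[j])) for j in order]
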