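# Methods

## Scope and model

`fedequity` scores the contribution of each institution in a horizontal
federated-learning (FL) collaboration — same feature space, different
records — from five agreed components: completeness, heterogeneity,
quantity, conformance, and provenance. Two normalized share equations
carry the arithmetic: a model-contribution share `M_i / Σ M_j` over
levels `M_i ∈ [0,1]`, and a data-contribution share `D_i / N` over
record counts. A Shapley-value baseline over a coalition game of
institutions, and a minimal FedAvg simulator, provide the expensive
comparator the cheap scores are meant to approximate in spirit.

`D_i` deserves a note: the component level is nominally defined on
[0,1], but the worked 227-of-569 example divides a record *count* by
`N`. The package exposes both readings — `data_contribution_share`
takes counts, while the composite report treats the resulting fraction
as the "quantity" component level.

## Dice heterogeneity

The Sørensen–Dice coefficient is defined on (multi)sets, but the
motivating use case has 30 continuous features. The package therefore
reduces each dataset to a multiset of tokens: `(feature, bin)` for
continuous/binary features, with per-feature bin edges at the pooled
data's `k/n_bins` quantiles (default `n_bins = 10`), and
`(feature, category)` for categoricals. Quantile binning is
distribution-free, deterministic, and makes every non-missing cell
contribute exactly one token; missing cells contribute none. Values
outside the fitted edges clamp to the boundary bins. Duplicate
quantiles collapse, so a constant feature yields a single degenerate
bin. The multiset form `2 Σ min / (|A|+|B|)` rather than the set form
is used because institutions differ in size and record counts should
matter.

Two reference modes give one score per institution:

* `pooled` (default): each institution's bag against the union of all
  bags, itself included. Because the institution's token counts are
  always dominated by the pool's, this mode reduces algebraically to
  the bag-size share `2 t_i / (t_i + T)` — it measures *how much* of
  the pool an institution holds, not how its distribution differs.
* `leave_one_out`: each institution against the union of the others.
  This is the mode that is actually sensitive to distributional
  differences, and the one used wherever heterogeneity sensitivity is
  the point (e.g., the generator's shift-knob property).

The two reported per-institution coefficients of the original worked
example (0.712854305 / 0.728524045) depend on an unrecorded random
split and an unspecified continuous-feature treatment; they are treated
as non-reproducible inputs. The normalization arithmetic downstream of
them is reproduced exactly.

The heterogeneity term enters the composite either as similarity
(default, matching the worked example's proportional-to-similarity
shares) or as dissimilarity `1 − s_i` (rewarding diverse data, which
the framework's motivation favors). Both are exposed because the two
readings genuinely conflict; the default reproduces the published
arithmetic.

## Quality components

No closed formulas exist in the source framework for completeness,
conformance, or provenance; the package picks the simplest monotone,
cell-level definitions:

* completeness = 1 − missing-cell fraction;
* value conformance = in-range fraction of non-missing cells of
  range-constrained features (vacuously 1, with a logged warning, when
  the schema constrains nothing);
* relational conformance = 1 − duplicate record-identity fraction
  (identity = explicit ID column, else institution + row index);
* computational conformance = dtype-parseable fraction of non-missing
  cells;
* provenance = satisfied fraction of a declarative lineage checklist
  (documentation is the stated intent; no automated lineage mining).

The five component weights default to uniform (1/5): the framework
prescribes none and expects them to be fixed contractually, so they are
plain configuration. Shannon entropy (base 2) is provided as a
profiling tool for value distributions but does not enter the default
composite.

## Shapley baseline

Players are institutions; `v(S)` is held-out accuracy of an
L2-regularized logistic regression (standardized features,
deterministic lbfgs, fixed iteration cap, C = 1) trained on coalition
`S`'s pooled records, deduplicated by record identity so contributing
the same records twice earns nothing. `v(∅)` — and any single-class
training pool — falls back to the majority-class predictor so every
marginal is defined. Exact enumeration is limited to 12 players
(2^n trainings); the Monte-Carlo estimator samples join orders
uniformly, which keeps efficiency (`Σφ = v(all) − v(∅)`) exact by
telescoping and yields per-player standard errors from the
across-permutation variance. The coalition game counts distinct
utility evaluations, so the cost argument against Shapley is
reproducible in counts (2^n vs 0 for the Dice pipeline) rather than
hardware-bound seconds. Per-record and per-feature Shapley attribution
are out of scope.

## FedAvg simulator

The FL loop is the minimal hub topology: per round, every institution
runs `local_epochs` of gradient descent on its local mean logistic
loss starting from the global coefficients; the hub averages the local
coefficients with record-count (default) or uniform weights. The
optimizer is deliberately plain full-batch gradient descent (mini-batch
behind `batch_size`), because with one local epoch and record-count
weights a FedAvg round is *algebraically* one centralized full-batch
step on the pooled data — the simulator is pinned to its baseline at
1e−9, not approximately. Features are standardized with pooled
statistics so coefficient magnitudes are comparable and usable as
feature importances. Zero initialization plus seeded mini-batch
shuffling make every run a pure function of (data, config).

## Synthetic data

The generator draws feature `j` of a record with label `y` in
institution `k` from `N(shift_kj + (y − ½)·effect_j, 1)`, with labels
Bernoulli(class balance), so logistic regression is the correctly
specified model and utility/importance tests have known ground truth.
`institution_shift` scales random per-institution mean offsets — the
heterogeneity knob; raising it lowers leave-one-out Dice similarity.
Missing cells and out-of-range violations are injected independently at
their stated rates (violations are written as values above the schema's
allowed range of ±15).

The canonical fixture is a 569-record, 30-feature, two-class table
split 227/342: class balance 212/569 and per-feature effects declining
linearly 1.2 → 0.05 standardized units, chosen once so a standardized
logistic model separates the classes well but not perfectly (held-out
accuracy ≈ 0.97–0.99), comparable in difficulty to the classic
breast-cancer diagnostic benchmark it stands in for. It does not
reproduce that benchmark's values, moments, or the unrecorded split of
the original experiment — passing tests show the pipeline's arithmetic
and invariants, not agreement with any real clinical data. Real data
can be supplied as ordinary institution CSVs plus a schema file;
nothing depends on the bundled generator.

## Numerical and design notes

* Share vectors are normalized exactly (asserted to 1e−9); share
  normalization is scale-invariant.
* Gini uses the discrete mean-absolute-difference formula with no
  small-sample correction: exact, closed form, bounded in [0, (n−1)/n].
* Dice of two empty bags, entropy of an empty distribution, shares of
  an all-zero vector, and completeness of zero records are errors, not
  silently 0.
* Missing tokens in CSVs: empty field, `NA`, `NaN` (case-insensitive).
  Strict reads fail on unparseable numeric cells naming row and column;
  lenient reads keep the raw string so computational conformance can
  count it.
* Problem sizes in the test suite and acceptance script (hundreds of
  records, ≤5 features for valuation, ≤10⁴ MC permutations) were chosen
  as the smallest sizes at which each statistical property is stable;
  every run completes in seconds.

## Known limitations

* Tabular features only; no imaging, text, or FHIR resources.
* Pooled-mode Dice is a size share by construction (above); use
  leave-one-out mode for distributional comparisons.
* No privacy mechanisms (secure aggregation, DP, encryption), no
  monetary payout or blockchain mechanics, no deep models.
* The composite's component weights are policy, not statistics: the
  package computes shares under whatever weights the collaboration
  agrees on and cannot say what the weights should be.
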