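# Methods

## Problem and model

`healthrank` implements an integrated multi-criteria decision-making
(MCDM) pipeline for comparing alternatives — in the shipped analysis,
27 OECD countries — on n conflicting indicators with known
optimization directions. Three stages: objective weighting (CRITIC),
ranking (MAIRCA and MARCOS), and rank-concordance assessment
(Spearman's ρ). The pipeline is a pure function of the decision matrix
and the configuration; no stage draws random numbers.

The underlying assumptions are those of the component methods: the
indicators are continuous, every cell is observed (no imputation —
incomplete alternatives must be dropped upstream), each column has
positive range, and for MARCOS every value in a cost column is
strictly positive (ratio normalization). Violations raise validation
errors rather than being silently repaired; for an analysis pipeline
whose equations divide by column ranges and cell values, failing
loudly is safer than dropping or shifting data behind the user's back.

## Normalization

CRITIC and MAIRCA share direction-aware min-max normalization:
`r = (x − min)/(max − min)` for benefit columns and
`(max − x)/(max − min)` for cost columns, so the best observed value in
every column maps to exactly 1 and the worst to exactly 0. This makes
all downstream quantities invariant to positive rescaling and
translation of any raw column, which the test suite asserts. Flipping a
criterion's direction maps its normalized column to its complement.

Numeric parsing of delimited input strips comma thousands separators
(`10,963.43066` → `10963.43066`); locale decimal commas are *not*
supported. Values are carried at full double precision end to end;
the 9-decimal rounding used in published tables happens only in report
rendering.

## CRITIC

Weights combine contrast intensity (the sample standard deviation of
each normalized column, denominator m − 1) with conflict
(`Σ_k (1 − ρ_jk)` over Pearson correlations of normalized columns):
`C_j = σ_j Σ_k (1 − ρ_jk)`, `w_j = C_j / Σ C_k`. Three choices are
deliberate:

- Correlation is computed on the **direction-adjusted normalized**
  matrix, not the raw columns. This matters: flipping a cost column
  changes the sign of its correlations and hence every `1 − ρ` conflict
  term.
- **Pearson**, not rank, correlation — the product-moment form is the
  method's definition.
- Negative correlations are kept as-is (conflict above 1); the
  absolute-value variant used by some implementations is intentionally
  not offered, to keep one well-defined estimator.

A population-denominator σ (`sd="population"`) exists only for
cross-checking other CRITIC implementations. If all columns are
perfectly correlated the total information content is zero and the
computation raises rather than returning NaN weights.

## MAIRCA

Uniform prior preference `P = 1/m` (non-uniform priors are out of
scope), theoretical matrix `Tp_ij = P w_j`, real matrix
`Tr_ij = Tp_ij r_ij`, score `G_i = Σ_j (Tp_ij − Tr_ij)`, lower better.
Since `Σ w_j = 1`, every score lies in `[0, P]`, and an alternative
holding every column best scores exactly 0.

## MARCOS variants

Two printed forms of MARCOS circulate that are *not* internally
consistent with each other, so the module exposes both and defaults to
the self-consistent one:

- **Cost normalization** (`ideal_referenced`, default):
  `n_ij = x_AI_j / x_ij`, making the ideal row normalize to all ones so
  that `S_AI = Σ w_j = 1` and `K⁺ = S_i/S_AI ∈ (0, 1]` — the ideal is
  the utility ceiling, as the utility-degree definitions require. The
  alternative `anti_ideal_referenced` form (`n_ij = x_AAI_j / x_ij`)
  pins the *anti-ideal* row at 1 instead, which contradicts using
  `S_AI` as the reference in `K⁺`; it is retained behind a flag for
  comparison with sources that print it.
- **Final utility** (`standard_compromise`, default): the MARCOS
  compromise utility function, bounded in (0, 1). The `simple_mean`
  variant `(K⁺ + K⁻)/2` is monotone in `S_i` — so it induces the
  *same ordering* (asserted on random instances) — but exceeds 1 for
  strong alternatives because `K⁻ ≫ 1`.

With the default variants the pipeline reproduces the published OECD
score tables to all nine printed decimals; the tests verify this
against hand-computed ratios and an independent loop oracle.

## Ranks and ties

Competition ("min") ranking: best score → rank 1, exact ties share the
smallest rank and the next rank is skipped. The published tables are
tie-free, so the tie rule never fires there, but it is defined and
tested because downstream concordance arithmetic needs deterministic
ranks for arbitrary data.

## Concordance

Spearman's ρ is computed on the rank vectors the pipeline itself
produces (never re-read from a published table), via the tie-safe
definition (Pearson correlation of average ranks, delegated to scipy).
For tie-free permutations this equals `1 − 6Σd²/(m(m²−1))`; both
identities are asserted against a summation oracle. The stability sets
report alternatives in the top-k (and bottom-k) of *both* rankings;
k defaults to 5, the convention used when highlighting stable top and
bottom groups in the shipped analysis.

## Synthetic data generator

`SyntheticSpec`/`generate` emulate the statistical shape of
cross-country indicator tables: positive continuous columns on
heterogeneous scales (default ranges spread over successive decades,
1–10, 10–100, …), mixed benefit/cost directions, and controllable
inter-criterion correlation. Columns are drawn through a Gaussian
copula: a latent multivariate normal with the target correlation is
mapped through the normal CDF to uniform marginals and rescaled to the
per-criterion ranges. The copula was chosen over a raw multivariate
normal because MARCOS needs bounded, strictly positive marginals while
the correlation structure stays controlled. Seeds are mandatory; there
is no global RNG state.

What the generator does **not** emulate: real indicators' marginal
shapes (spending is heavy-tailed, mortality rates are skewed — the
copula marginals are uniform on their ranges), missingness, or
country-level clustering. Passing property tests on synthetic matrices
therefore demonstrates algorithmic correctness and invariances, not
that any conclusion about real health systems transfers to other years
or indicator sets.

The `plant="dominant"` option overwrites the first row with the best
possible value in every column; by weak dominance that row must rank
first under both methods for any valid weights, giving recovery tests
planted ground truth. `perturb` applies multiplicative uniform noise
`x · (1 + ε)`, `ε ~ U(−δ, +δ)`, clipped to stay positive, for
sensitivity harnesses.

## Problem sizes and tolerances

Oracle-equivalence tests run 10×4 random matrices against naive
loop implementations at 1e−12 (1e−14 for MAIRCA, which is pure
arithmetic on the same normalized matrix); planted-dominance runs 200
seeds at 12×4; the copula correlation check samples m = 5000 at
tolerance ±0.03; weight-normalization sweeps 1000 random 8×3
matrices. The published-table reproductions use 1e−5 (weights, their
printed precision) and 1e−8 (scores printed to 9 decimals). The noise
sensitivity analysis uses 100 seeds per level at δ ∈ {1%, 2%, 5%}.

## Known limitations

- Cross-sectional only: one matrix, one reference period; no panel or
  temporal analysis.
- No missing-data handling by design; upstream exclusion is the
  supported path.
- CRITIC weights are data-driven but not "objective" in any causal
  sense — they reward dispersion and non-redundancy, nothing else.
- MARCOS cost columns must be strictly positive; data containing zeros
  need a pre-shift the package intentionally does not apply for you.
- Mid-table orderings are sensitive to method choice (that is precisely
  what the concordance report quantifies); only the stable top/bottom
  groups should be read as robust findings.
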