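# Methods

This note documents the models, conventions and design choices behind
`qsarwb`, in the spirit of a statistical software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Scope and model

The package builds and audits interpretable linear QSAR models
`pIC50 = b0 + Σ b_j x_j` on descriptor tables, with activities on the molar
log scale (`pIC50 = −log10(IC50/10⁶)`, IC50 in µM). The intended regime is
a few hundred compounds and at most eight descriptors per model, the
conventional ceiling for interpretable MLR QSAR. Nine descriptor sets
crossed with eight SFS configurations plus one GA configuration give the
standard 81-candidate screen.

## Dataset handling

* **Split.** Seeded Fisher–Yates shuffle, then partition with
  `|test| = ceil(n · fraction)`; 184 compounds at fraction 0.2 give 147/37.
  The contract guarantees internal reproducibility for a fixed
  (seed, row order) only — the split is *not* bit-compatible with other
  tools' PRNGs, so matching any external tool's exact membership is out of
  scope.
* **Pretreatment.** Variance filter first (cutoff 1e−4; constant columns
  also break Pearson correlation), then iterative correlation pruning at
  |r| > 0.99: the most correlated pair is resolved by dropping the member
  with the larger mean absolute correlation to all remaining columns, ties
  to the higher column index. This rule is deterministic and idempotent;
  the removal log is attached to the returned table.
* Missing values are an error, never imputed.

## Descriptor conventions

All topological descriptors operate on the hydrogen-depleted graph;
attached-H counts are kept as atom attributes for donor typing. Atomic
weights (mass, polarizability, Bondi vdW radius → sphere volume) ship as an
editable YAML table and are used carbon-scaled, `w̃ = w / w_C`. Specific
choices, all documented as such rather than reverse-engineered from any
commercial engine (numerical identity with proprietary engines is
explicitly a non-goal — published coefficients fitted on proprietary
descriptor values therefore cannot be transplanted onto these values):

* **ATS (Broto–Moreau, "log function")** — `ln(1 + Σ_{d(i,j)=k} w̃_i w̃_j)`.
* **Barysz–Balaban `J_Dz(w)`** — edge length `1/(π_rs · w̃_r · w̃_s)`
  (aromatic order 1.5) accumulated along shortest paths, diagonal
  `1 − 1/w̃_i`, then the Balaban-type sum `m/(μ+1) Σ_edges (VS_i VS_j)^−½`
  over off-diagonal row sums. With all-carbon weights and single bonds this
  reduces exactly to the classic Balaban J, which the tests exploit as an
  oracle.
* **CATS2D** — raw (unscaled) counts of unordered PPP-type pairs at exact
  topological distance 0–9.
* **PPP typing** (fixed rule table): A = N/O with an available lone pair,
  excluding amide and pyrrole-type N, protonatable N (protonated at pH 7.4,
  no lone pair left) and acid-group O already typed negative; D = N/O with
  ≥1 H, except negative-typed atoms (deprotonated form); P = aliphatic
  amine, amidine/guanidine, or explicit cationic N; N = oxygens of
  carboxylic/sulfonic/phosphorus acid groups and tetrazole nitrogens;
  L = carbon or halogen with only C/H/halogen neighbours. Assignment is a
  pure function of the graph (the RDKit mol is rebuilt from the graph when
  needed).
* **Edge spectral moment `SM_k(dm)`** — `ln(1 + trace(B̃^k))` with B̃ the
  edge adjacency matrix augmented on the diagonal by bond dipole moments
  (Debye) from an editable literature lookup keyed by (element pair, bond
  order). The lookup is an acknowledged approximation of any proprietary
  dipole weighting.
* **RDF** — `Σ w̃_i w̃_j exp(−β(R − r_ij)²)` with β = 100 Å⁻² (the common
  RDF-code default; configurable). Needs 3D coordinates (3D SDF); without
  them `RDF140v` is reported as NaN rather than silently zero.

## Feature selection

* **SFS** is greedy forward addition, deterministic for a fixed column
  order; ties break toward the lower column index. Scoring is on the
  training fit (`cv=none`) or the mean over a seeded shuffled 5-fold split.
  Poisson/gamma deviance scorers require positive responses (true for
  pIC50 data in the 4–9 range) and treat non-positive predictions as a
  worst score rather than an exception.
* **GA** evolves subsets of size ≤ 8: random initial population (100),
  elitist survival (top 30 by fitness), refill by one-point crossover
  (p = 1.0) on the sorted index lists with duplicate repair by redrawing,
  and per-gene mutation (p = 0.3) to a random unused descriptor. Fitness is
  the configured scorer on the training data; subset fitness is memoised
  within a run since it is a pure function of the subset. Run r of the
  `n_runs` repeats is seeded `seed + r`. Winners across runs are re-ranked
  by `(Q²_LOO + R²_Pred)/2` when a test table is available — the "average
  of internal and external predictivity" convention — otherwise by Q²_LOO
  alone; the GA signature takes the test table as an optional argument for
  this reason.

## Models

* **MLR** is ordinary least squares (statsmodels) behind a named-coefficient
  facade; rank deficiency raises an error naming the collinear columns.
  Standardized coefficients are `b_j · s_xj / s_y` (sample SDs, ddof 1) and
  drive the relative-significance ranking.
* **PLS** uses scikit-learn's NIPALS per component count; the component
  count is chosen by the leave-one-out Q² increment rule: add a component
  only while `Q²_new ≥ Q²_old · 1.05` (relative form, used when
  `Q²_old > 0`) or `Q²_new ≥ Q²_old + 0.05` otherwise, capped at
  min(5, rank X). The relative reading of "improve by at least 5%" is a
  deliberate choice where the verbal rule is ambiguous; the absolute branch
  prevents the rule from becoming vacuous around zero.
* **Non-linear wrappers** (MLP / random forest / SVR) are exhaustive grid
  searches scored by 5-fold CV R² with `random_state = 42` by default,
  refit on the full training set; they exist for the tuning/reporting
  contract, not as production predictors.

## Validation battery

`Q²_LOO` uses the exact hat-matrix identity `e_(i) = e_i/(1 − h_ii)`; the
test suite checks it against an explicit n-refit loop to 1e−9. External
metrics: `Q²_F1 = 1 − SSE/Σ(y_test − ȳ_train)²`, `Q²_F2` with the test
mean, `Q²_F3` with per-observation training variance, plus RMSEP. Roy's
rm² uses the through-origin regression in both directions; the radicand
`r² − r0²` is clipped at zero when negative (the source recipes are silent
on that case), and the averaged form plus |Δ| is reported, with both raw
directions available. `K_xx` is the Todeschini eigenvalue dispersion index
of the descriptor correlation matrix; `ΔK = K_xy − K_xx` (the QSARINS sign
convention; the opposite order appears in some write-ups). Y-randomization
permutes the response (run i seeded `seed + i`), refits, and reports
`cR_p² = R·√(R² − R̄_r²)`, floored at 0 with a warning when the model does
no better than chance.

## Applicability domain

Leverages use the intercept-augmented training hat matrix; query compounds
are projected without refitting. Thresholds: `h* = 3(p+1)/n`, standardized
residual cutoff ±3 (standardized, not externally studentized, matching
common Williams-plot practice; the residual scale uses n − p − 1 degrees of
freedom). Outlier retention is a user decision — the package flags, it does
not drop.

## Consensus (CM0–CM3)

Qualification and weighting follow declared, configurable conventions: a
model qualifies if its training LOO MAE is within 1.5× the best model's;
CM2 weights ∝ 1/LOO-MAE normalized over qualified models; CM3 picks, per
query compound, the qualified model with the smallest mean |LOO residual|
over the query's 5 nearest training neighbours (Euclidean distance on the
standardized union of the models' descriptors). When nothing qualifies the
combiner falls back to CM0 with a warning.

## Synthetic data

The generator emulates a pretreated descriptor matrix, not chemistry:
standard-Gaussian columns (optionally a block correlated at pairwise ρ via
a shared latent factor), response `y = β0 + Σ β_j x_j + ε` with β0 = 6 and
a default signal `2x₁ − 3x₂`, σ = 0.1, n = 150, p = 22 — activities then
span roughly 4–9 pIC50 units, the dynamic range of a typical µM-to-nM
inhibitor panel. What it does **not** emulate: discrete/count-valued
descriptors, heavy-tailed and block-structured real correlation patterns,
activity cliffs, or assay error heterogeneity. Passing recovery tests
therefore demonstrates correctness of the selection/validation machinery
under a known truth, not expected performance on laboratory data.

Problem sizes in tests and the acceptance script (50 selection seeds, 100
coverage seeds, 1000-run Y-randomization over 20 null seeds, 100×10 LOO
oracle) were chosen as the smallest sizes at which the binomial pass
criteria (≥95%) are meaningful.

## Numerical choices and degenerate inputs

OLS rank checks use `numpy.linalg.matrix_rank` on the intercept-augmented
design; VIF reports +inf (with a warning) for perfect collinearity instead
of raising, since the flag itself is the diagnostic. Leverage computation
inverts the Gram matrix directly (p ≤ 8 in the intended regime). All
stochastic procedures take explicit integer seeds; repeated calls are
bit-reproducible. Degenerate cases raise typed exceptions: empty matrices
after pretreatment, disconnected graphs (fragments listed), zero-variance
responses, constant vectors in correlation-based metrics.

## Known limitations

* Descriptor values follow open conventions; they are internally consistent
  and unit-tested against brute-force oracles, but not numerically
  interchangeable with any proprietary engine's output.
* PPP typing is rule-based and covers the common ionizable/H-bonding
  groups; exotic tautomers or charge states beyond the rule table fall
  through to unlabeled.
* The GA fitness is the configured training-set scorer; no parsimony
  pressure beyond the max-feature cap is applied, so GA winners tend to use
  the full budget of eight descriptors.
* Conformer generation is out of scope; RDF descriptors require supplied
  3D coordinates.
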