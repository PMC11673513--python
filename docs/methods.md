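# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, and the limits of what the synthetic studies can
demonstrate.

## Cohort model and factors

Subjects carry a continuous BMI (kg/m²) and a continuous IPAQ activity
score (MET-min/week). Both are dichotomized at fixed cutoffs — BMI at
25 kg/m² (lean < 25 ≤ overweight/obese) and IPAQ at 3066 MET-min/week
(low ≤ 3066 < high) — and the cross of the two binary factors defines four
interaction cells. The default design is unbalanced: 13 Lean+Low,
7 Lean+High, 20 Obese+Low, 9 Obese+High (49 subjects; 20 lean / 29 obese,
33 low / 16 high). All class labels are derived from the continuous values
at these cutoffs and re-validated on every generated cohort.

## Synthetic data generator

The generator emulates the feature table an alignment tool exports from an
untargeted LC–MS experiment, starting *after* peak alignment; it does not
model spectra, retention times, adducts or chromatographic drift.

* **Abundances** are log-normal: features are organised in blocks of
  `block_size` (default 5) whose latent Gaussians share an equicorrelation
  `block_rho` (default 0.6), scaled by `latent_sigma` (default 0.5, a
  typical log-scale biological CV for plasma metabolites) and
  exponentiated. Log-normality is the standard LC–MS abundance assumption
  and guarantees positivity; per-feature log-means are uniform over
  ln(10⁴)–ln(10⁶), a realistic intensity span.
* **Planted effects** add `effect_size × latent_sigma` on the latent
  scale — i.e. `effect_size` is a Cohen's d against the latent noise — for
  obese subjects (BMI features), high-IPAQ subjects (IPAQ features), or
  subjects of exactly one designated cell (interaction features, default
  Obese+Low, matching the cell where the reference study found most
  interaction contrasts). With `effect_size = 0` nothing is planted and
  all effect labels collapse to `null`. The default planted counts
  (64 BMI, 5 IPAQ, 26 interaction out of 2534 features) mirror the
  reference study's selection sizes; `effect_size = 1.5` is a calibration
  choice, not a measured quantity — real effect magnitudes for this design
  are unknown.
* **Phenotype values** are uniform within their class bounds (lean BMI in
  [18, 25), obese in [25, 40]; low IPAQ in [0, 3066], high in
  (3066, 15000]), which keeps class membership exact by construction; body
  mass is derived as BMI × height² so the defining identity holds to
  machine precision. Sex and age are generated but carry no effect.
* **Pooled-QC replicates** (default 6) have per-feature expectation equal
  to the study mean with multiplicative Gaussian noise of CV
  `qc_cv_pass` = 0.05, except for the `n_fail_rsd` features planted to
  fail the filter, which get CV `qc_cv_fail` = 0.6 (values truncated at
  zero). The QC error structure of real instruments (drift, carryover) is
  not modelled; only the magnitude of technical variation is.
* Everything is drawn from `numpy.random.default_rng` seeded from the
  config, so identical configs give bitwise-identical tables.

Because QC noise is stochastic, the planted pass/fail split is recovered
only approximately by the filter; `make_rsd_fixture` exists for exact
worked examples, constructing three QC replicates (m, m+x, m−x) per
feature whose RSD is exactly x/m, strictly above or below the threshold.

## Preprocessing

Order: half-minimum imputation → QC-RSD filter → sample-median
normalization → cube root → range scaling.

* **RSD** uses the n−1 standard deviation over QC rows divided by their
  mean; a zero QC mean leaves it undefined and the feature is removed.
  The default threshold is 0.30: the reference workflow states the filter
  and the resulting counts but not the cutoff, and 30% is the common
  untargeted-metabolomics QC convention. Retention is RSD ≤ threshold.
* **Median normalization** divides (not subtracts) each study row by its
  median over retained features, the convention of abundance-processing
  platforms; QC and blank rows are dropped here, having served the filter.
* **Cube root** is implemented signed, sign(x)·|x|^(1/3), so it is total;
  raw abundances are non-negative so this only matters defensively.
* **Range scaling** maps each feature to (x − x̄)/(max − min); zero-range
  features become all-zero with a warning rather than erroring, since
  constant features are statistically inert downstream.

Each step preserves sample order; the filter preserves relative feature
order; provenance records every step with its parameters.

## Two-way ANOVA and selection

Each feature is fit with the full two-factor model with interaction on the
processed values. The design being unbalanced, the sums-of-squares type
matters: the default is **sequential (Type I) with BMI entered first**,
matching the default behaviour of the point-and-click platforms this
analysis is usually run on; Type II is available via `ss_type="II"` and
the choice is logged in provenance. The implementation computes the
sequential SS from a QR decomposition of the design matrix, vectorized
over features (and is verified against `statsmodels.anova_lm` in the test
suite); error df = n − 4. If the error variance is exactly zero, effects
with positive SS report p = 0 and the rest p = 1, with a warning.

Selection is **raw p < α** (strict inequality, default α = 0.05) with no
multiplicity correction, because the workflow being reproduced selects on
raw p; Benjamini–Hochberg q-values are emitted alongside for users who
want them. The three significance sets are partitioned by exact set
algebra into the seven disjoint Venn regions.

**Post hoc** contrasts are Fisher's LSD: each cell mean minus the
reference cell mean (default Obese+Low), standardised by the pooled
within-cell mean square of the cell-means model with df = n − (number of
non-empty cells), unadjusted two-sided p. With only two cells present
this reduces exactly to the pooled two-sample t-test. Each contrast has
~5% type-I error under the null; the familywise rate over the three
contrasts is correspondingly higher (~14% measured), as expected for an
unadjusted procedure. Direction arrows ("up"/"down") come from marginal
group means of the *processed* (scaled) data; the reference cell's own
column in the direction table shows the direction opposing the significant
contrasts, a presentation convenience.

Descriptive outputs: within-cell Pearson correlations between continuous
BMI and IPAQ (r, n, two-sided p; undefined below n = 3 or at degenerate
variance), and mean ± SD group summaries with two-group one-way ANOVA p
per phenotype variable.

## Targeted network and eigenvector centrality

Nodes are the selected metabolites plus one target node. Metabolite–
metabolite edges require pairwise Pearson p < α on processed values;
metabolite–target edges require p < α for the correlation with the
subjects' *continuous* BMI — the construction consistent with "directly
linked to the BMI" — computed identically. Signed r is stored; weights
use |r|.

Connection degree is 1 + the minimum endpoint geodesic distance to the
target (breadth-first), so target-incident edges have degree 1 and weight
|r|; weight = |r| · 0.5^(degree−1). The halving continues geometrically
past degree 5. An alternative reading of the weighting — dividing |r| by
the path length — is inconsistent with the enumerated factors 0.5, 0.25,
0.125, 0.0625, which halve; the enumerated values are taken as
authoritative. Edges in components not containing the target get weight 0
and their nodes score 0.

Centrality is the dominant eigenvector of the weighted adjacency of the
target's component: power iteration from the uniform positive vector,
L2-normalized, stopping when successive iterates differ by < 1e-10 in
max-norm. The iteration cap is 10 000: convergence slows as the two
leading eigenvalues approach, and the cap is cheap at these graph sizes.
If iteration still fails (bipartite-like spectra, where the leading
eigenvalues coincide in magnitude), it restarts once on A + 0.1·max(w)·I,
a diagonal shift that separates the magnitudes without changing any
eigenvector. λ is the Rayleigh quotient; the residual ‖Ax − λx‖ is below
1e-8 at convergence and the scores match a dense symmetric
eigendecomposition to 1e-8 (tested on 100 random graphs). Ranking sorts
metabolites (target excluded) by score descending, ties broken by node id.

## Pipeline, determinism, problem sizes

`run_all` chains the stages and produces a pure-JSON report (counts, Venn
regions, subgroup correlations, group summaries, top-k ranking,
provenance) that is byte-identical across runs with the same config and
seed. Every analysis constant — cutoffs 25 and 3066, α = 0.05, RSD 0.30,
k = 25 — is a named default, never inlined.

Simulation-based tests run at reduced table sizes (a few hundred features)
and 20–50 seeds, chosen so that Monte-Carlo bands (binomial 3σ, KS at 1%)
are tight enough to detect real miscalibration while the whole suite stays
interactive; the statistical conclusions are size-independent because the
per-feature tests are exact under normality.

## Limitations

* Passing tests on synthetic log-normal data demonstrates correctness of
  the statistics, not robustness to real-data pathologies (heavy drift,
  missingness mechanisms, batch effects), none of which are modelled.
* The ANOVA assumes normal errors; after cube-root transformation the
  simulated log-normal noise is near-normal, but real features can be
  worse-behaved.
* No covariate adjustment (age, sex) or repeated-measures structure; the
  reproduced workflow fits none.
* The network stage does not do community detection, alternative
  centralities, or graph layout; exports are GraphML and flat CSV.
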