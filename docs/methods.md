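# Methods

## Model

Item responses are treated as continuous scores and summarized by their
Pearson correlation matrix *S* (Spearman and two-step polychoric
correlations are available as options; polychoric estimates the latent
correlation of an ordinal pair by maximum likelihood over a bivariate
normal with thresholds fixed from the margins).  The network is the
Gaussian graphical model selected by the EBIC graphical lasso:

- solver: block coordinate descent on the working covariance *W*, penalty
  λ on off-diagonal precision entries only (the diagonal of the fitted
  covariance equals the sample diagonal);
- path: 100 log-spaced penalties from λ_max = max|s_ij| (i ≠ j) down to
  λ_max/100; warm starts along the path;
- selection: minimum EBIC with γ = 0.5, the standard choice for symptom
  networks; the edge count *E* in the EBIC is the number of nonzero
  upper-triangle entries of the selected precision matrix itself;
- edges: partial correlations w_ij = −θ_ij/√(θ_ii θ_jj), zero diagonal.

Convergence is declared when the largest change in any entry of *W*
during a sweep falls below 1e−4 (at most 10,000 sweeps; non-convergence
raises with the penalty and dimension in the message).  Coefficients
below 1e−10 in magnitude are treated as exact zeros so the selected
support is genuinely sparse rather than littered with floating-point
dust.  The solver is verified in the test suite against an independent
implementation (scikit-learn's graphical lasso, run to tight tolerance)
and against the Karush–Kuhn–Tucker optimality conditions, which are
solver-independent.

## Centrality and screening

Strength is the sum of absolute incident edge weights; bridge strength
restricts the sum to edges crossing the a-priori scale communities
(depression / anxiety / sleep disturbance — instrument membership, not
data-driven clusters).  Both are z-standardized across all nodes pooled
(not within community; the pooling convention is a documented choice
since either is defensible).  A node is a screened **bridge symptom**
when its z bridge strength is ≥ 1.  Predictability is the in-sample R² of
an ordinary least-squares regression of each item on all the others;
collinear predictor sets are tolerated through the minimum-norm solution
because R² remains well defined even when individual coefficients are
not.

## Bootstrap stability

- **Edge accuracy**: B nonparametric row-resamples (default B = 1000),
  full re-estimation per resample including EBIC re-selection, percentile
  (α/2, 1−α/2) intervals per edge.  A resample that leaves an item
  constant is redrawn up to 10 times, then dropped with a warning and
  counted in the report.
- **Difference tests**: a pair of edges (or node strengths) differs when
  the 95% bootstrap CI of their difference excludes zero; no multiplicity
  adjustment is applied, matching standard practice for this procedure.
- **Case dropping**: for each drop proportion q in 0.05…0.75 (step 0.05),
  B subsamples of size round((1−q)·n) without replacement; the Pearson
  correlation between subsampled and original strength vectors is
  recorded (q = 0 is the identity subsample and records exactly 1).
- **CS coefficient**: the largest q such that at *every* q′ ≤ q the
  empirical 5th percentile of the correlations is ≥ 0.70 (a prefix rule,
  so sampling wiggles at intermediate proportions cannot inflate CS);
  0.75 is the grid maximum and therefore the ceiling of reportable CS.

A calibration caveat established by simulation: percentile CIs are
near-nominal (≈ 92–95%) for the *same-n* estimand — the shrunk edge
weight the estimator targets at that sample size — but cover the
unshrunk large-sample edge value only ~65–75% of the time, because lasso
shrinkage biases strong edges downward by an amount comparable to the CI
width at every n.  Bootstrap CIs from this machinery quantify sampling
variability, not regularization bias.

## Network comparison test

Two groups' networks are compared on M = max|w_ij^(1) − w_ij^(2)| (edge
invariance) and S = |GS₁ − GS₂| (global strength, GS = Σ|w_ij| over the
upper triangle).  Group labels are permuted over the pooled rows
(preserving group sizes), both networks re-estimated from scratch —
including EBIC re-selection — for each of n_perm permutations (default
1000), and p = (1 + #{permuted ≥ observed}) / (1 + n_perm), ties counted
as exceedances.  The add-one rule keeps p strictly positive; pooled rows
are put in canonical lexicographic order before permuting so the test is
exactly symmetric in group order.  Covariate adjustment residualizes
every item on the covariate by least squares before estimation, which is
equivalent to partialling the covariate out of the correlation input.
The 30%-subsample sensitivity analysis compares an overlapping subsample
against the full sample, as in the survey workflow it mirrors; the
overlap makes the NCT conservative there, which is documented rather
than corrected.

## Synthetic data generator

A stated latent model: precision Θ with unit diagonal and Θ_ij = −ρ_ij
for each planted partial correlation ρ_ij; latent correlation
Σ = standardize(Θ⁻¹); responses are the latent normals cut at per-item
thresholds (4 categories scored 0–3 for PHQ/GAD items, 5 scored 1–5 for
YSIS items).  Model construction refuses non-positive-definite precision
matrices outright (reporting the smallest eigenvalue) — no silent repair.

The two-group preset emulates a junior/senior school survey:

- within-scale edges GAD1–GAD2 (0.38) > YSIS4–YSIS5 (0.30) > PHQ1–PHQ2
  (0.26) > YSIS3–YSIS4 (0.20) for juniors; 0.38/0.31/0.28/0.22 for
  seniors, whose network therefore carries strictly more total weight;
- bridge edges of 0.12 concentrated on GAD1 (junior) or PHQ2 (senior),
  so each group has one planted bridge symptom;
- first thresholds between 0.39 and 0.50 on the latent scale (lowest
  category holds ~65–69% of the mass; skewness ≈ 1.5–2), ordered so item
  means rank PHQ1 > PHQ2 > GAD1 > GAD2 and YSIS3 > YSIS4 > YSIS5; the
  senior group's thresholds sit 0.35 lower, raising every senior item
  mean.

Edge magnitudes were calibrated once, by simulation, to the fact that
discretizing skewed ordinal margins attenuates Pearson correlations
scale-dependently (4-category skewed items attenuate more than
5-category ones) and that heavier planted graphs flatten the EBIC path
minimum and inflate the false-edge rate of recovery.  With these
constants the estimated networks reproduce the planted ordering
(anxiety pair strongest, GAD1 top strength in the junior group, correct
bridge symptom in both groups) with recovery sensitivity ≈ 1.0 and
false-edge rate ≈ 0.09 at n = 5,000.  Because the senior preset
concentrates its cross-scale edges on PHQ2, PHQ2 (not GAD1) is the senior
group's top-strength node — a known, accepted divergence from the survey
the preset emulates, which reported GAD1 on top in every group.

What the generator does **not** emulate: missing responses, longitudinal
structure, item-response-theory measurement (thresholds are the only
item parameters), differential item functioning, and the survey's exact
marginal frequencies (Table-level moments are approximated, not
reproduced).  A green recovery test therefore establishes that the
pipeline recovers a known sparse copula structure from skewed ordinal
data at realistic sizes — not that it would reproduce any particular
published network.

## Descriptives

Moments use the n−1 SD and moment-based g1 (skewness) and g2 (excess
kurtosis); other conventions (e.g. adjusted Fisher–Pearson) differ by
O(1/n) factors, which matters when comparing printed tables.  The
informativeness screen excludes an item when its SD falls below
mean(SDs) − 2.5·SD(SDs); it is scale-equivariant.  Cronbach's α is
computed per scale from the community map.  Group comparisons use
Welch's unequal-variance t-test, two-sided — the robust default when
group sizes differ.

## Determinism

Every stochastic stage takes a seed; the pipeline derives per-stage
seeds from the single config seed via a seed sequence, so a rerun with
the same config writes a byte-identical `summary.json`.  Degenerate
resamples are the only data-dependent branch, and they are counted in
the outputs.

## Known limitations

- Pearson input on ordinal scores is attenuated; the polychoric option
  recovers latent correlations but is O(p² · categories²) slower and is
  not the default because the emulated workflow treats items as
  continuous.
- EBIC-glasso's false-edge rate grows with the density/weight of the true
  graph (the path minimum flattens); at n = 5,000 on the preset it is
  ≈ 0.09 but roughly doubles for graphs with 0.45-strength hubs.
- The glasso support is not mathematically monotone along the penalty
  path on pathological dense inputs; on questionnaire-like inputs no
  violations were observed.
- The NCT permutes under full exchangeability; covariates other than the
  one adjusted for are not preserved within permuted groups.
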