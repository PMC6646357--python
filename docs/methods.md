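# Methods

This note documents the models, parameter choices and numerical conventions
behind `gbmsubtypes`, and what the synthetic-data tests do and do not show
about real cohorts.

## Prognosis-gene selection

Each gene's expression is Pearson-correlated with overall survival (OS, in
months) separately in two discovery cohorts. All samples with recorded OS
enter the correlation, censored or not — the correlation targets the
observed follow-up time, which is the plain reading of a gene-vs-OS
association; a `use_events_only` switch restricts to observed deaths for
sensitivity analyses. Genes with zero expression variance are excluded.

Concordance is strict: a gene qualifies only if both correlations are
strictly negative (poor direction) or strictly positive (favorable
direction). A correlation of exactly zero in either cohort therefore
disqualifies a gene. The ranking metric is the *sign-preserving magnitude
product* sign(r) · |r_A · r_B| rather than the raw product, because the raw
product of two negative correlations would be positive and erase the
direction the selection must preserve. Ties in the score break by gene
identifier, so reruns are bit-identical. If a direction holds fewer than the
requested k concordant genes the list is truncated with a warning — the
favorable direction in real tumor data is typically the scarcer one, which
is why the default stops at k = 40 per direction.

The packaged signature (`data/pg_signature.gmt`, `data/pg_signature.tsv`)
carries the published 40 poor + 40 favorable genes with both Entrez and
symbol identifiers, in printed order; the order is not asserted to encode
rank. Gene identifiers are opaque case-sensitive strings throughout, and
matching across cohorts is by exact identifier.

## ssGSEA

With the G measured genes of one sample ordered by decreasing expression and
rank values v_j = G − j + 1, the enrichment score of a set S with m measured
members is

    ES = Σ_{i=1..G} [ Σ_{j≤i, g_j∈S} v_j^τ / Σ_{j∈S} v_j^τ
                      − |{j≤i : g_j∉S}| / (G − m) ]

The weighting exponent defaults to τ = 0.25, the convention of the
originally published single-sample variant; it is exposed in
`SsgseaParams`, and the acceptance-level checks avoid depending on the
specific value. Expression ties share the average rank value by default
(`tie_method="average"`); a stable-input-order alternative is available, and
the choice is recorded in the score table's metadata. No ES range
normalization is applied across gene sets: scores are immediately
z-standardized across samples (sample SD, ddof = 1), which absorbs scale.
Standardization is per cohort — each dataset is scored on its own — and the
prognosis score is the standardized favorable score minus the standardized
poor score. Set genes missing from the matrix are dropped with a logged
overlap count; fewer than `min_overlap = 5` measured members, or a set
covering every measured gene (undefined complement), is an error, as is a
cohort with fewer than two samples (nothing to standardize against).

Because the score depends on expression only through within-sample ranks,
any strictly monotone per-sample transform — log, affine, or the platform
map used by the simulator — leaves every ES unchanged. This is the formal
basis for applying one signature across microarray and RNA-seq data.

## Subtype assignment and the cutoff scan

Scores below −1 map to *invasive*, above +1 to *mitotic*, and everything
else — including scores exactly at a cutoff, per the strict inequalities —
to *intermediate*. The sensitivity scan dichotomizes at each grid cutoff c
into {score < c} vs {score ≥ c} (grid −2…2, step 0.1 by default), records
the two-group log-rank p, and flags cutoffs leaving fewer than two samples
or no event on either side as invalid rather than scoring them. A local
minimum is a grid point strictly below its left neighbor and no higher than
its right neighbor, so a flat plateau reports its left edge. The scan
supplies evidence only; it does not auto-select cutoffs, since the published
choice balanced the p-value profile against group-size balance by
inspection.

One caveat the package's own simulations exposed: the *pointwise* log-rank
test is well calibrated (null rejection ≈ 5%, verified at 1000 replicates),
but the *minimum* p across a scan is not — under the null, roughly 40% of
scans contain some cutoff with p < 0.05 because ~17 correlated tests are
inspected. Scan minima should therefore be read as descriptive, not as
significance statements.

## Survival statistics

Kaplan–Meier estimation and the K-sample log-rank test are delegated to
`lifelines`; subjects censored at an event time remain at risk at that time,
and the three-subtype comparison uses the K-sample statistic with K − 1 = 2
degrees of freedom. Univariate Cox regression is implemented directly:
Newton iteration on the partial likelihood with step-halving (likelihood
never decreases), convergence at |Δβ| < 1e−8 within 50 iterations, Breslow
tie handling by default and Efron optionally. The covariate is centered
internally for numerical stability, which leaves β unchanged. Monotone
likelihoods (perfect separation) surface as estimation errors rather than
silent huge estimates. Confidence intervals use the normal approximation
exp(β ± 1.96·se). Tests cross-check the Efron fit against `lifelines` and
against a derivative-free maximizer of an independently coded partial
likelihood; the agreement tolerance (1e−3) reflects lifelines' own stopping
rule, not ours. ANOVA and Tukey's HSD delegate to scipy/statsmodels, with
the all-identical-values degenerate case defined as F = 0, p = 1.

## Differential expression, ORA, kappa clustering, markers

DEGs between invasive and mitotic samples (intermediates excluded) use the
pooled-variance two-sided t-test — Welch optional — with Benjamini–Hochberg
adjustment and a DEG threshold of adjusted p < 0.001. Genes constant in both
groups are skipped with a logged count. Over-representation uses the
two-sided Fisher exact test (sum of conditional table probabilities not
exceeding the observed one) on a 2×2 in-set × in-DEG table over a universe
defaulting to all genes tested for differential expression — the natural
background for expression-based ORA. The heat-map statistic is
−log10(p). Enriched terms cluster by Cohen's kappa on membership indicator
vectors (threshold 0.4), single-linkage connected components with
deterministic ordering; an empty within-universe set has kappa 0 by
convention. Subtype markers are the intersection of the PG lists with the
DEG table, requiring direction consistency (a poor PG must be up in
invasive), ranked by |t| within direction; fold-change-style preferences can
be expressed through the exclusion list that also serves to drop, e.g.,
secreted-protein genes.

## Clinical indices

MRI invasiveness is (T2-FLAIR area − T1-CE area)/T1-CE area, unit-free and
scale invariant; dual-rater area columns are averaged. Negative values
(FLAIR below CE) are returned with a warning, not clamped. The spheroid
invasion index is (area at 72 h − area at 0 h)/area at 0 h. Subtype-vs-binary
feature tables (e.g. MGMT promoter methylation) report the definitional odds
ratio ad/bc, with the Haldane–Anscombe +0.5 correction (flagged) when a cell
is zero, and the same two-sided Fisher exact p used by the ORA module.

## Synthetic cohorts

The generator's defaults describe the desk-scale study the tests run: 500
genes × 200 patients per cohort, 20 poor + 20 favorable planted genes, unit
log-hazard effect, baseline hazard 0.05 events/month (median OS ≈ 14 months,
in the range typical for GBM), 30% censoring, unit log-scale Gaussian
expression noise, per-gene baseline intensities ~ N(7, 1).

A per-patient latent factor u ~ N(0,1) loads +1 on planted poor genes and −1
on planted favorable genes. The latent risk driving survival is *realized*
from the expression matrix — mean z-expression of planted poor genes minus
that of planted favorable genes — so the survival signal is exactly the
quantity a rank-based scorer can recover. Survival times are Weibull with a
log-linear hazard in the latent risk (shape exposed, default 1 =
exponential, the simplest model giving the required monotone score–OS
relation). Censoring is independent exponential with its rate solved
numerically so the expected censored fraction matches `censoring_rate`
(exact at shape 1; approximate otherwise). MGMT methylation is drawn with
base rate 0.45 and log-odds shifted by −log(OR)·z(risk), OR defaulting to 4
to emulate the strong methylation enrichment reported in favorable tumors.
Grade labels shift the latent factor by `grade_effect` per step above
grade 2.

Cohort pairs share gene baselines and planted programs but draw independent
samples and noise; the second cohort passes through the strictly monotone
elementwise map y = x + shift·tanh(x − 7), which preserves all within-sample
and within-gene ranks — emulating a platform change while keeping the
rank-invariance property exactly testable.

What the simulations do *not* emulate: probe-level artifacts, batch effects
beyond the monotone map, real gene–gene covariance, missing values, or
informative censoring. Passing tests therefore demonstrate correctness of
the machinery and the qualitative behavior of the method under its own
assumptions — not the published effect sizes, which derive from external
patient cohorts. Reported problem sizes in the test-suite (e.g. 20-seed
calibration batches, 1000-replicate null calibrations at n = 50–60,
150-gene pipeline smoke runs) were chosen as the smallest sizes at which the
statistical properties under test are stable.

## Known limitations

- Only univariate Cox; no proportional-hazards diagnostics or multivariate
  adjustment.
- ORA ignores gene-set hierarchy (no GO-graph traversal).
- The exact ssGSEA variant used in the original analysis is unspecified
  upstream; τ and tie handling are configuration, and conclusions that
  depend on a specific variant should be checked across settings.
- Probe-to-gene collapsing and normalization are assumed done; inputs are
  gene-level normalized matrices.
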