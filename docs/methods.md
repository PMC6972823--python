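# Methods

This note documents the statistical model behind `fecanet`, the choices
made where the procedure was genuinely open, and what the synthetic-data
experiments do and do not establish.

## Study design and data model

The unit of analysis is a features × samples intensity matrix in arbitrary
units, with two sample types: *study* samples (one per participant ×
drill area; the reference design is 10 participants × 4 cryogenic drill
areas) and *pooled-QC* samples (repeat injections of pooled study
material). Features carry a platform (polar metabolites measured by
GC×GC–MS-type workflows, lipids by LC–MS-type workflows), a compound
class, an annotation level (1 = authentic standard … 4 = unknown) and an
internal-standard flag. Intensities are kept on the raw linear scale in
the data model; every operation that assumes additivity (correlation,
ANOVA, network inference, imputation) log-transforms internally and never
stores transformed values. Missing cells are explicit markers (below-LOD
censoring is the dominant mechanism), written as `NA`.

## Error model of the generator

All variation is multiplicative (log-normal). This is the natural choice
for mass-spectrometric intensities — positive, right-skewed, with
replicate spread proportional to abundance — and it makes the pipeline's
RSD-based QC scale-free. Per feature *f*, participant *i*, area *a*,
sample *j*:

```
log x = mu_f + s_j + b_{f,i} + d_{f,i,a} + eps
```

with `mu_f ~ U(log 1e4, log 1e6)` (base abundance), `s_j ~ N(0, 0.3²)` a
per-sample, per-platform extraction/drift factor shared by all features of
the platform in that injection, `b ~ N(0, σ_P²)` the participant effect,
`d ~ N(0, σ_A²)` the drill-area effect and `eps ~ N(0, σ_T²)` technical
noise. Log-scale SDs derive from the configured CV percentages through
the log-normal identity `CV = sqrt(exp(σ²) − 1)`; defaults
CV_T/CV_A/CV_P = 10/25/60 % reflect a well-behaved platform, visible
specimen heterogeneity, and dominant inter-individual variation.

Design features worth calling out:

* **Pools estimate technical CV by construction.** A pooled injection
  measures the grand mean of all study aliquots' `b + d` plus fresh `s`
  and `eps`, so replicate pool spread contains only technical components.
* **Internal standards** have constant true amount (`b = d = 0`) and half
  the technical log-SD of endogenous features — spiked compounds are
  chosen and dosed for repeatability, and an IS whose own injection noise
  matched the endogenous features would add as much noise to the ratio as
  it removes drift. With this choice, normalized pooled CV lands within
  ~1 percentage point of CV_T (√(1 + ¼) · 10 % ≈ 11.2 %), which the tests
  assert at a ±3-point tolerance.
* **Level-4 unknowns** carry no biological signal and doubled technical
  noise, so the unknowns filter loses no planted truth and the pool-RSD
  gate has a population of genuinely noisy features to remove. Unknowns
  are split across platforms pro rata to the annotated counts (182:116).
* **A planted Gaussian graphical model.** For `network_size` selected
  annotated features the participant-effect vector is multivariate normal
  with covariance `inverse(K)` rescaled so every marginal variance equals
  σ_P², where K is a random sparse precision matrix (off-diagonal support
  at the requested density, weights ±[0.2, 0.5], diagonal = absolute row
  sum + 0.5, hence diagonally dominant and positive definite). The
  network lives on participant-level effects because the inferred network
  describes between-person covariation. An optional hub argument forces
  one node to a given degree for recovery experiments.
* **Censoring**: per platform, all non-IS intensities below the 5 %
  quantile are replaced by missing (positions recorded); internal
  standards are never censored.

The generator is deterministic given its config (one `default_rng` seed,
fixed draw order).

What the generator does **not** emulate: water-content differences
between specimens (a real confounder of fecal concentrations that no
within-sample normalization can remove), injection-order drift, batch
structure beyond one extraction factor per platform, correlated technical
noise, and realistic compound-class abundance differences. Green tests
therefore certify the *statistical machinery* — filters, estimators,
penalty selection — under a clean multiplicative model, not performance
on any particular real dataset.

## Normalization

Each endogenous feature is divided by the same-platform internal standard
maximizing Pearson correlation on log intensities over jointly observed
samples (study + pools pooled for estimation; ≥ 3 complete pairs per
candidate; ties by lexicographic id). Correlation on logs rather than raw
intensities keeps high-abundance samples from dominating; restricting to
the feature's platform reflects that each platform has its own IS set.
The ratio cancels the shared per-injection factor exactly, which is the
entire point: after normalization, pooled RSD estimates technical CV even
in the presence of strong extraction drift.

## QC gate

Order: unknowns → pool-RSD → missingness → imputation (each filter is
idempotent). RSD is computed on the raw linear scale (the analytical
convention for %RSD), with an n−1 standard deviation. The pool-RSD gate
keeps features at exactly 30 % (the exclusion is strictly "greater
than"); features with fewer than two observed pool values cannot be QC'd
and are excluded. The missingness filter removes features missing in
strictly more than 20 % of samples; pools count in the denominator and
participate in imputation, since they are injections of the same matrix
and stabilize neighbor distances.

Imputation is feature-space kNN on logs (k = 10): for a missing value of
feature *f* in sample *s*, candidate neighbors are features observed in
*s* sharing at least one observed sample with *f*; distance is the mean
squared log difference over jointly observed samples scaled by the total
sample count; each of the k nearest neighbors' log values in *s* is
shifted by the mean log offset between *f* and that neighbor over their
common samples, and the shifts are averaged (a duplicate feature thus
imputes exactly its own value). Fewer than k eligible neighbors: use all;
none: fall back to *f*'s observed mean. Imputed intensities are
exponentials of log values, hence strictly positive; observed values are
never modified.

## Variance decomposition and testing

Three RSDs per feature: over pools (technical); the mean of
within-participant RSDs across drill replicates (drill-area) — averaging
within participants first keeps between-person variance out of the
heterogeneity number, which pooling all 40 drills would confound; and
over participant means (participant). All three are invariant to scaling
a feature by a positive constant.

The per-feature test is a one-way ANOVA on log intensities with
participant as the factor (pools excluded — the factor is undefined for
them). The default applies empirical-Bayes moderation: the residual
variances s² (d degrees of freedom each) are modeled as scaled-F around a
common prior (d₀, s₀²) estimated by moment-matching of log variances
(digamma/trigamma inversion, Newton), and the moderated F uses posterior
variance (d₀s₀² + d·s²)/(d₀ + d) with (g−1, d₀ + d) degrees of freedom.
With 4 replicates per participant the raw variance estimates are noisy,
and moderation is the standard remedy; the unmoderated mode is retained
because its null distribution is exact and is what the calibration tests
check (p < 0.05 fraction 0.048 at 2000 null features). When the
moment-matcher returns an infinite prior df (log-variance spread at or
below the theoretical χ² spread), every feature gets the common variance
and the denominator df is effectively infinite (capped at 1e9 for the F
tail). Multiple testing uses Benjamini–Hochberg step-up q-values
(monotone, ≥ p, ≤ 1).

## Network inference

Pipeline: log → participant means (default; an all-study-samples mode
exists because the aggregation level is a genuine modeling choice) →
auto-scale columns (mean 0, sd 1, n−1) → correlation matrix → penalty by
rotation criterion → graphical lasso → partial correlations → edges, hub,
Spearman-to-hub coloring. Node shape encodes platform (lipid circle,
polar rectangle); edge sign is exported as a label, not a color.

**Graphical lasso.** Maximizes `logdet Θ − tr(SΘ) − λ Σ_{i≠j}|θ_ij|`
(diagonal unpenalized, input is a correlation matrix consistent with
prior auto-scaling) by block coordinate descent on the covariance: each
column is an L1 regression solved by coordinate-wise soft-thresholding
with an incrementally maintained gradient. Singular S is ridged by
1e-8·I (λ = 0 on singular S is refused). Convergence: mean absolute
off-diagonal change of the working covariance < tol × mean |off-diagonal
of S|; non-convergence returns the best iterate with a warning and a
flag. Every returned Θ is symmetric positive definite and satisfies the
stationarity conditions |Σ̂ᵢⱼ − Sᵢⱼ| ≤ λ with equality (sign-consistent)
on the support; tests verify this, agreement with scikit-learn's
implementation, and objective equality (≤ 1e-6, typically ~1e-15)
against an independent proximal-gradient maximizer.

**Rotation criterion (RIC).** Each rotation independently permutes the
rows of every column (destroying all cross-feature dependence, preserving
marginals); λ is the mean over 50 rotations of the maximum absolute
off-diagonal correlation — the strongest association pure chance produces
at this sample size. Permutations are seeded per (seed, rotation,
column), so the selection is exactly reproducible. This criterion is
deliberately conservative: it calibrates against the *maximum* spurious
correlation, so with 10 participants it selects λ ≈ 0.95 and returns a
near-empty graph, and even at n = 200 it holds edge precision near 1 at
the cost of recall (measured ≈ 0.4–0.5 against planted support whose
partial correlations are 0.08–0.33). Recovering weak edges would require
a less conservative selector (cross-validation, EBIC, or stability
selection), which is out of scope; consumers should read the returned
network as "edges we are confident in", not "all edges present".
The same conservatism means the maximum-degree hub of a weak planted
graph is usually *not* identified — hub edges are shrunk first because a
high-degree node's diagonal dominance makes its individual partial
correlations the weakest.

**Hub and coloring.** Hub = maximal degree, ties by larger sum of
absolute edge weights, then lexicographic id. All nodes get a Spearman
rank correlation (average ranks on ties) to the hub across individuals;
the hub maps to 1.

## Integration summary

Features are auto-scaled on logs, averaged over each participant's drill
replicates, then over features within each (platform, compound class);
platform summaries are concatenated and each row standardized (mean 0,
sd 1, n−1). Scaling happens before averaging, in that order, so each
feature contributes comparably to its class mean. Rows with zero sd
raise rather than emit NaN. The default scales individual-rows; the
matrix is emitted in tidy long format for heatmap rendering.

## Numerical and bookkeeping choices

* Stage counts track endogenous (non-IS) features, so a default run reads
  2326 detected → 298 annotated → pool-RSD survivors → missingness
  survivors, and RunReport enforces out(k) = in(k+1).
* TSV exchange: UTF-8, Unix newlines, `NA` for missing on write
  (`""`/`NA`/`NaN` accepted on read), intensities serialized by `repr`
  for exact round-trips.
* One config seed fans out to per-stage seeds by fixed offsets
  (simulation +11, rotations +17); reruns are byte-identical except the
  timestamped log.
* Edge threshold 1e-8 on |ρ| separates numerically-zero from
  shrunk-but-nonzero precision entries.
* Experiment sizes used by the test suite and `scripts/acceptance.py`
  were chosen to exercise each property at the smallest informative
  scale: 2000 features for calibration, 40 replicates for FDR, n = 200
  participants for network recovery, 50 small matrices for the glasso
  oracle, and 60 random tables for the imputation oracle.

## Known limitations

* The pool-RSD and CV numbers of any real study also reflect
  chromatographic and annotation artifacts the generator does not model;
  the simulated survival rates (e.g. nearly all annotated features pass
  the 30 % gate at CV_T = 10 %) are best-case.
* The RIC-selected network is conservative by design (see above); at the
  reference design size (10 participants) it typically returns very few
  edges.
* Between-participant CVs of fecal metabolites confound true biological
  variation with water content; nothing in this pipeline can separate
  the two.
* The empirical-Bayes moderation assumes a common residual df across
  features (true for balanced complete designs; the median df is used
  otherwise).
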