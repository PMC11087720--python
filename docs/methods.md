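# Methods

`episig` implements the derivation, validation and comparative analysis of a
blood DNA-methylation *episignature*: a genome-wide pattern of CpG
methylation specific to a genetic disorder, usable as a diagnostic
classifier. The concrete target is a Pitt-Hopkins-syndrome-like setting —
a disorder cohort profiled on an Infinium-EPIC-like array against age- and
sex-matched controls, with a predominantly hypermethylated signature — but
every stage is parameterised and cohort-agnostic.

## The discovery model

**Scales.** Methylation is carried as beta values (methylated fraction,
`[0,1]`). All linear modelling is done on M-values,
`M = log2(b/(1-b))` with `b` clipped to `[0.01, 0.99]`: M is approximately
variance-stabilised where beta is heteroskedastic, and the clipping keeps
the transform total and finite. Effect sizes are always reported as
delta-beta (case mean beta − control mean beta), the interpretable scale.
Classifier features are beta values of the signature probes: bounded
features stabilise the SVM margin (a config flag allows M instead).

**Per-probe statistics.** For each probe, ordinary least squares of M on
`[intercept, group, age, sex]` gives the group coefficient, residual mean
square `s²` and residual df. Residual variances are then moderated
empirically: under the scaled-F model `s² ~ s0² F(df, d0)`, the prior
`(d0, s0²)` is fit by the method of moments on `log s²` (trigamma
inversion by Newton iteration), the posterior variance is
`s~² = (d0·s0² + df·s²)/(d0 + df)`, and the moderated t uses `d0 + df`
degrees of freedom. When the empirical variance of `log s²` does not
exceed its sampling component, `d0` is infinite and every probe is tested
at `s0²`. The implementation is hand-written so the blend and its limits
(`d0=0` → ordinary t, `d0=∞` → common variance) are contractual; a test
cross-checks it against Bioconductor limma's `eBayes` on the same design
(agreement to ~1e-14 on the moderated t). Multiple testing uses
Benjamini-Hochberg step-up (via statsmodels, tested against an exhaustive
step-up oracle).

**Probe selection.** Probes pass if `q ≤ 0.01` and `|Δβ| ≥ 0.05`, are
ranked by `rank_score = |Δβ|·(−log10 p)` (ties broken by probe id), capped
at 500, and greedily de-correlated: a probe whose Pearson correlation with
an already-kept probe exceeds 0.85 is dropped, so one co-methylated block
cannot dominate the signature. The `|Δβ|` floor is deliberately set
*below* the planted effect size of the default simulation (0.10): a floor
equal to the typical true effect would censor roughly half of the true
probes, since the sampling error of `Δβ` at these cohort sizes (~0.008 SD)
is symmetric around the truth. 0.05 is also a common minimum
methylation-difference convention for episignature work. All four
thresholds are exposed in `SelectionParams`.

**Iterative case pruning.** Real disorder cohorts contain cases that do
not carry the episignature (mosaicism, hypomorphic or misclassified
variants, confounding exposures). Per round, the signature is derived on
the current cohort and every case is scored by a classifier trained with
that case held out (leave-one-case-out, so a case cannot vouch for
itself); cases with held-out MVP < 0.25 are removed, up to 3 rounds. A
round flagging more than half the cases — or a cohort on which no probe
set is derivable at all — aborts with an instability error rather than
returning a signature nobody should trust.

**Classifier and MVP score.** A linear-kernel SVM (C=1, balanced class
weights; scikit-learn) is trained on the signature probes. Its signed
decision value `d` is mapped to the MVP score by Platt's sigmoid
`mvp = 1/(1 + exp(A·d + B))`, with `(A, B)` fit by BFGS on 3-fold
cross-validated decision values using Platt's regularised targets
`(N₊+1)/(N₊+2)` and `1/(N₋+2)` — calibration therefore never sees a
decision value from a model trained on the same sample, and remains finite
on separable data. Following the published training design, the 75/25
split applies to the *negative* class only (controls and, when present,
other-disorder samples): all retained cases train, and specificity is
measured on the held-out 25% negatives. Calls use strict cutoffs —
positive above 0.5, negative below 0.25, inconclusive otherwise,
boundaries included in inconclusive.

**Robustness views.** Leave-25%-out cross-validation (default 20 rounds)
holds out a stratified quarter of cases and controls and re-runs the
*entire* derivation — selection included — on the remainder; reusing the
globally selected probes would leak selection information into the
held-out scores. Per-round seeds derive from the master seed by fixed
arithmetic. Hierarchical clustering is Ward linkage on Euclidean
distances with columns pre-sorted lexicographically (deterministic
tie-break); MDS is classical Torgerson scaling (double-centred Gram
matrix, top-2 eigenpairs, eigenvalues at numerical zero truncated, sign
fixed so each dimension's first nonzero loading is positive; metric MDS,
labelled as such).

## The comparative stage

Per cohort, the signature for comparison is the top 500 DMPs at FDR < 0.05
(strict), ranked by p ascending (ties by |Δβ| descending, then probe id);
cohorts with fewer than 500 significant probes contribute all of them.
Overlap entry (y, x) is `100·|S_y ∩ S_x|/|S_y|` — directional and
generally asymmetric. The tree-and-leaf view clusters cohorts
(Ward/Euclidean) on the union probe space, each cohort contributing its
per-probe methylation difference and 0 where a probe is outside its
signature (0 = "no differential methylation" is the natural neutral fill);
leaf size is the signature's probe count and leaf colour its mean
methylation difference.

CpG-island context uses BED-style 0-based half-open island intervals
(probe positions are 1-based and converted before intersection): *island*
on intersection, *shore* within (0, 2000] bp of the nearest island
boundary, *shelf* within (2000, 4000], *open sea* beyond — the shore
definition extended symmetrically to shelves. Gene-region categories
(promoter, promoter+, gene body, intergenic) are carried through from the
annotation, not recomputed from transcription starts. Enrichment of a
signature against background is a per-category 2×2 Fisher exact test with
BH across categories; odds ratios use Haldane's +0.5 correction when a
cell is zero, with raw-infinite and undefined (category absent from
background) outcomes flagged explicitly.

A small reporting utility computes the loss-of-function transcript
fraction of a splice-affecting variant from its mRNA assay percentages:
the mis-spliced-but-detected classes (exon skipping + intron retention)
carry the LoF effect; the four classes must sum to 100 ± 0.5.

## The synthetic cohort generator

The generator defines the study conditions for every test and analysis.

* **Baselines.** Probe mean betas from a three-component mixture: 45%
  low (Beta(2,18), mean ≈ 0.1), 45% high (mirrored), 10% intermediate
  (uniform 0.25-0.75) — the characteristic bimodality of array betas.
* **Planted signature.** Default 200 probes of 20,000, |Δβ| = 0.10, 70%
  hypermethylated, planted only on probes whose baseline leaves room for
  the full shift. The effect size is constant per probe; the scale
  (0.05-0.15 across configs) reflects typical blood episignature effects.
* **Noise.** Per observation, Beta-distributed around the (clipped)
  shifted mean with concentration 100 — bounded, heteroskedastic, with
  per-sample SD ≈ 0.03-0.05 at intermediate means, a realistic array
  noise level.
* **Mosaicism.** A sample with the variant in a fraction `m` of cells
  shifts by `m·Δβ` — the linear bulk-mixture model, the simplest
  defensible dilution. Episignature-negative cases are `m = 0`.
* **Covariates.** Age adds a small M-scale slope (SD 0.01 M-units/year)
  to a random 1% of non-planted probes; a 100-probe "sexlike" block
  separates the sexes by 1 M-unit. This exercises covariate adjustment
  without modelling chromosome X explicitly.
* **Cohort sizes.** 60 cases vs 85 controls by default, ages uniform on
  2-40 years, sexes balanced.
* **Multi-cohort runs** share one probe universe and baseline; cohort
  i > 1 shares exactly `round(f·n_dmps)` planted probes with cohort 1
  (consistent direction), the remainder disjoint across cohorts.

What the generator does *not* emulate: probe-chemistry differences
(type I/II), detection failures and missingness patterns, batch and
position effects, cell-composition heterogeneity beyond the scalar
dilution, CNV dosage, and genomically clustered (regional) signatures —
planted probes are positionally random, so passing tests demonstrate the
statistics and bookkeeping, not robustness to array artefacts that
normalisation pipelines exist to remove.

## Problem sizes and numerical choices

Tests and the acceptance script run the full default conditions
(20,000 × 145) for the headline checks; multi-seed recovery suites use 5
seeds at full size for selection and 10,000-probe cohorts (20 cases, 3
planted negatives) for pruning; cross-validation property checks use a
4,000-probe cohort over all 20 rounds; null-calibration checks use 10
delta-0 cohorts at full probe count. These sizes give stable pass/fail
behaviour at interactive runtimes. Betas are clipped to
`[1e-6, 1 − 1e-6]` after drawing; probe means to `[0.01, 0.99]` before.
Deterministic tie-breaks throughout (probe id in ranking, lexicographic
sample id in clustering); all randomness flows from explicit seeds, and
identical config + seed reproduces byte-identical artifacts.

## Known limitations

* Thresholds (q ≤ 0.01, |Δβ| ≥ 0.05, top 500, corr ≤ 0.85) are
  conventions, not optimised values; real cohorts may need tuning, which
  is why they are config-exposed.
* Greedy nearest-age control matching is deterministic but not optimal
  matching.
* The moderated-t model assumes exchangeable per-probe variances around a
  single scaled-F prior; strong variance strata (e.g. probe-type effects)
  would call for robust or stratified moderation.
* MVP calibration quality depends on the negative class mix; with
  controls only (no other-disorder samples), specificity against
  *related* disorders is untested by construction.
* Probes with any missing value are dropped, not imputed.
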