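# Methods

This note documents the statistical models implemented in `gicoreg`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic cohorts the test suite runs on do and do not emulate.

## Weighted genome instability index (wGII)

A sample's copy-number profile is a set of non-overlapping integer-copy
segments per chromosome (1-based inclusive coordinates). Relative to a
per-sample **baseline copy number** b, the aberrant fraction of chromosome c
is

    a_c = (length of segments on c with CN != b) / (covered length of c)

and the wGII is the unweighted mean of a_c over the chromosome set (default:
autosomes 1–22). Normalizing per chromosome before averaging gives every
chromosome equal weight regardless of its physical size, so instability of
a small chromosome counts as much as instability of chromosome 1.

Design choices where the definition is under-specified in the literature:

* **Baseline.** The baseline is the length-weighted modal integer copy
  number of the profile, ties broken toward the smaller copy number. This is
  robust to focal events and agrees with rounded ploidy for most tumors; a
  user-supplied integer ploidy can override it.
* **Denominator.** The covered segment length, not the nominal chromosome
  size. Segment files rarely tile a chromosome exactly; using covered length
  keeps partial coverage from deflating fractions.
* wGII is invariant to splitting a segment into adjacent sub-segments with
  the same copy number, and equals a per-base-pair tally by construction;
  both are property-tested.

## Survival stratification and the wGII cutoff

High/low-instability groups are defined by dichotomizing wGII at a cutoff
chosen to minimize the p-value of the group indicator in a Cox
proportional-hazards model, scanned over a grid (default step 0.01) from
just above the observed minimum to just below the maximum, keeping only
candidates where both groups hold at least `min_group_fraction` (default
0.1) of the cohort. Ties on the minimal p-value break toward the more
balanced split. The boundary convention is `wgii > cutoff → high`, so a
sample exactly at the cutoff is low.

Minimizing a p-value over a grid is anti-conservative by construction; the
result object therefore always carries the full p-curve, and a cutoff chosen
this way should be validated on an independent cohort before use. The scan's
Cox model is univariate by default; clinical covariates (age, gender, race,
stage, tumor purity) can be added. The pipeline accepts a fixed cutoff in
place of the search — the intended pattern for small cohorts is to select
the cutoff on a large independent cohort (or adopt a published round value
such as 0.3) and apply it fixed, which is how the acceptance script
separates cutoff selection from the co-regulation analysis.

Cox fits use the Efron approximation for tied event times (lifelines
backend). The log-rank test is the standard two-group chi-square with the
hypergeometric variance. The package also implements the partial-likelihood
score test at β = 0 directly; for a binary covariate it equals the log-rank
statistic, which the test suite uses as a cross-check between the two
routes. Kaplan–Meier curves are emitted as step-function tables rather than
plots so they can be asserted against.

## Purity-adjusted moderated differential expression

Tumor purity confounds bulk expression contrasts: a change in tumor-cell
fraction moves every tumor-cell-expressed feature. Per feature (log2 ratio
scale, missing values excluded feature-wise):

* between-groups mode: `value ~ intercept + group + purity`; the group
  coefficient is the log2 fold change;
* tumor-vs-normal mode: `value ~ intercept + purity`, valid because purity
  is 0 for normal tissue, so the purity coefficient carries the
  tumor-associated effect.

Features with fewer than 3 observed samples per design level, or a singular
observed design, are dropped with a logged reason rather than failing the
fit.

Residual variances s_g² (d_g degrees of freedom) are shrunk toward a prior
estimated across features by modelling s² ~ s0²·F(d, d0) and matching the
mean and variance of log s² through digamma/trigamma identities (the
trigamma inverse is solved by Newton iteration). The posterior variance is
the df-weighted blend (d0·s0² + d·s²)/(d0 + d); the moderated t divides the
coefficient by the posterior standard error and is referred to t with
d + d0 df. When the observed log-variances are no more dispersed than
sampling alone explains, d0 = ∞ and all features share s0² (complete
pooling). d0 = 0 reproduces the ordinary per-feature t-test. The
implementation is verified against limma's `lmFit`/`eBayes` in the test
suite. Two-sided p-values throughout; Benjamini–Hochberg step-up q-values.

## PTM residual normalization

Phosphosite (or glycosite) intensity tracks its parent protein's abundance;
to isolate modification-specific regulation, each site's log2 ratios are
regressed on the parent protein's global log2 ratios across samples
(simple linear regression on samples observed in both, minimum 3 pairs) and
the residuals replace the site's values. Samples missing in either matrix
stay missing; sites without a quantified parent protein pass through
unchanged and are flagged. Residuals are exactly orthogonal to the
predictor and invariant to constant shifts of it.

## Metagene scores

For a gene set, each member gene is standardized across samples (mean 0,
sd 1, NaN-aware) and a sample's score is the mean z-score over the genes
present. Used to summarize signature gene sets as single per-sample tracks.

## Two-dimensional kinase–substrate co-regulation

Every relation links a kinase protein (global proteome) to a phosphosite
(site-level phosphoproteome, identifier `PROTEIN_{residue}{position}`).
Features with missing values in 6 or more samples are excluded ("missing in
fewer than 6 samples" retained); the filter applies per feature, not per
pair. For each retained pair, Z = (Zk, Zs) collects the purity-adjusted
moderated t-statistics of the kinase and of the site between the two groups,
computed once per unique feature and shared across pairs. The observed
cloud is modelled as

    f(Z) = p0·f0(Z) + p1·f1(Z),   p0 + p1 = 1,

with f0 the null density of non-co-regulated pairs. The null is simulated
by permuting the group labels (default 200 iterations): one shared
permutation per iteration is applied to both matrices so the
kinase–substrate dependence survives under the null, tumor purity stays
attached to its sample and is never permuted, and the full moderated fit —
including re-estimation of the variance-prior hyperparameters — is rerun per
permutation, exactly as on the observed labelling. A permutation that
happens to reproduce the original labels is kept. All permuted (Zk, Zs) are
pooled into one null sample (subsampled, seeded, to at most 100,000 points
before density fitting; far more than density estimation on the plane
needs).

Densities f and f0 are product-Gaussian kernel density estimates sharing
one kernel: the per-dimension scale is the standard deviation of the pooled
null and the Scott factor n^(−1/6) uses the observed sample size. Two
reasons: (i) the alternative component inflates the observed sample's
spread, so bandwidths computed on the observed sample would oversmooth f
relative to f0 and bias the density ratio; (ii) the variance of the ratio
is dominated by f, the density estimated from the smaller sample. Under a
shared kernel the smoothing bias largely cancels in the ratio.

The null proportion is read at the origin — a pair with no effect in either
coordinate concentrates there:

    p0 = f(0,0) / f0(0,0),   clipped into (0, 1],

and per pair

    fdr(Z) = p0·f0(Z) / f(Z)   (local false discovery rate, clipped to [0,1])
    p1(Z) = 1 − fdr(Z)          (posterior probability of co-regulation).

Computing p1 as the complement of the clipped fdr makes the identity
p1 + fdr = 1 exact; the two printed formulas are algebraically redundant.
A density floor of 1e-12 guards the division. By construction the unclipped
fdr at the origin equals 1. Significant co-regulated pairs require local
fdr < 0.05, |log2 fc| of the kinase > 0.05, and |log2 fc| of the substrate
site > 0.5 (all configurable); outputs include per-kinase substrate counts
for network rendering.

The sampling error of the p0 estimate is governed by the number of
*independent* pair draws: pairs sharing a kinase share Zk, so the
kinase-ensemble width fluctuates with the number of unique kinases and
propagates into f(0,0). At 2,000 fully independent pairs the estimate's
seed-to-seed sd is about 0.035; with 10 substrates per kinase it roughly
doubles. The recovery test therefore uses one substrate per kinase and
compares the median over three replicate cohorts; the end-to-end tests keep
the realistic shared-kinase structure. "FDR < 0.05" is interpreted as the
local fdr above — the only false-discovery quantity the model defines; a
tail-area variant is deliberately not offered.

## Other deterministic scores

* **H-score** (RNA-ISH/IHC): with A..E the percentages of cells in staining
  bins 0–4 (summing to 100), the score is 0·A + 1·B + 2·C + 3·D + 4·E,
  bounded [0, 400].
* **Glycoform classes** from N-glycan composition (HexNAc, Hex, Fuc, NeuAc,
  NeuGc): sialic = NeuAc + NeuGc; fuco-sialylated if Fuc > 0 and
  sialic > 0; else sialylated if sialic > 0; else fucosylated if Fuc > 0;
  else oligomannose if the composition is the bare HexNAc(2)Hex(≥5) core;
  else neutral. The precedence (composite class first) and the oligomannose
  core are the standard N-glycan convention, made explicit and configurable.

## Synthetic cohorts

The generator produces the inputs the pipeline assumes, with known ground
truth, so every stage is testable without external data:

* **Segments.** Each chromosome (default: hg38 autosome lengths) is cut at
  1–19 random breakpoints; whole segments are aberrated greedily in random
  order until the per-sample target aberrant fraction is met, then one
  segment is split so the realized fraction equals the target to base-pair
  rounding — the realized wGII equals the planted one by construction.
  Aberrant copies are baseline ± 1 or 2 (never negative, never the
  baseline). Default baseline ploidy 2; per-sample targets drawn uniformly
  from (0.05, 0.6) so the cohort straddles the 0.3 cutoff.
* **Survival.** Exponential event times; the hazard is multiplied by the
  hazard ratio (default 3) for samples with true wGII above the true cutoff
  (default 0.3). Censoring is independent uniform on (0, c) with c
  calibrated to ~30% censoring under the baseline hazard (median survival
  36 months). Purity is drawn group-shifted toward the top of (0.4, 0.9)
  for high-wGII samples, so purity genuinely confounds expression contrasts
  and the adjustment path is exercised; age, gender, race and stage are
  independent fillers.
* **Omics.** 30 samples by default. The global matrix holds kinase proteins
  (default 100), the substrate parent proteins (null background for the
  PTM normalization), and 200 extra background proteins; the phospho matrix
  holds one row per substrate site (10 per kinase). Noise is Gaussian
  (sd 0.5 log2 units); every feature carries a random purity slope
  (sd 0.3); planting operates at kinase level — a planted kinase (10% of
  kinases by default) gets +1 log2 in the high group on its protein and
  +1.5 on all of its sites — so unplanted pairs are null in both
  coordinates and the planted fraction equals the non-null pair fraction.
  Missingness is 5% completely at random.

What the generator does **not** emulate, hence what passing tests do not
show about real data: missingness in proteomics is intensity-dependent
(MNAR), not MCAR — the missingness filter under test only counts missing
values, so this does not affect its contract; TMT plex/batch structure,
normalization artifacts and ratio compression are absent; effects are
homoscedastic mean shifts, real co-regulation is correlated and
heterogeneous; survival is exponential with proportional hazards by
construction; kinase–substrate relations are a balanced synthetic table,
not the heavy-tailed degree distribution of curated databases.

## Numerical and reproducibility choices

* All randomness flows through `numpy` Generators seeded from a single
  configuration seed; reruns of the pipeline with the same config produce
  byte-identical result files (wall-clock timestamps appear only in the run
  log). Matrix TSVs round-trip bit-exactly (`float_precision="round_trip"`
  on read).
* Degenerate inputs fail loudly with typed errors: empty profiles, missing
  chromosomes, constant covariates, single-group designs, zero-variance Z
  samples, out-of-range p-values.
* The trigamma inverse runs Newton to a relative tolerance of 1e-10 with
  closed-form guards at both asymptotes; identical residual variances take
  the d0 = ∞ branch.
* Problem sizes in the test suite (cohorts of 16–500, 100–2,000 pairs,
  20–200 permutations) are chosen so each test isolates one contract at the
  smallest scale where its signal is unambiguous.

## Known limitations

* p0 is a ratio of kernel density estimates at a single point; at a few
  hundred effective pairs its sampling error is several percentage points,
  and it degrades when alternative effects are weak enough to overlap the
  origin.
* The permutation null inherits a mild contamination when many strong
  effects are present: permuting converts real group shifts into extra
  per-feature variance. Re-estimating the moderation prior per permutation
  (as the observed-data fit does) keeps the net bias of p0 small, but it is
  not exactly zero.
* The cutoff search exposes, but does not correct, its multiplicity.
* `tumor-vs-normal` mode assumes purity 0 for normals and does not model
  tumor-in-normal contamination.
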