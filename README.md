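# gicoreg

Genome-instability scoring and kinase–substrate co-regulation analysis for
proteogenomic tumor cohorts.

Chromosomally unstable tumors behave differently — they are enriched for
worse outcomes and distinct signaling — but calling a tumor "genome
unstable" and then asking *which kinase programs move with instability*
takes several statistical steps that are usually scattered across ad-hoc
scripts. This package implements that chain as a tested, reusable pipeline
for analysts working with bulk copy-number, clinical, proteome and
phosphoproteome data (e.g. TMT ratio matrices):

1. **wGII scoring** — the weighted genome instability index of an absolute
   copy-number segment profile: with baseline copy number b and aberrant
   fraction a_c = (length of segments on chromosome c with CN ≠ b)/(covered
   length of c),

       wGII = mean_c a_c

   so every chromosome contributes equally regardless of size.
2. **Survival stratification** — Cox proportional-hazards and log-rank
   machinery, and a cutoff search that dichotomizes wGII at the value
   minimizing the Cox p-value of the high/low indicator (full p-curve
   reported; the multiplicity of a minimized p-value is documented, not
   hidden).
3. **Purity-adjusted moderated differential expression** — per-feature OLS
   (`value ~ group + purity`, or `value ~ purity` for tumor-vs-normal since
   normals have purity 0) with empirical-Bayes variance shrinkage: the
   moderated t divides each coefficient by the posterior standard error
   from s̃² = (d0·s0² + d·s²)/(d0 + d) and is referred to t with d + d0 df;
   BH q-values.
4. **PTM normalization** — each phosphosite regressed on its parent
   protein's global abundance; residuals are the normalized PTM signal.
5. **Kinase–substrate co-regulation (2D empirical Bayes)** — for each
   relation pair the statistic Z = (Zk, Zs) of kinase protein and substrate
   site; the observed cloud is deconvolved as f(Z) = p0·f0(Z) + p1·f1(Z)
   with f0 estimated from label permutations (default 200), the null
   proportion read at the origin, p0 = f(0,0)/f0(0,0), and per pair the
   local false discovery rate fdr(Z) = p0·f0(Z)/f(Z) with posterior
   p1(Z) = 1 − fdr(Z). Significant pairs require fdr < 0.05 and minimum
   absolute log2 fold changes on both coordinates.

A synthetic-cohort generator with known ground truth (planted wGII, hazard
ratio, co-regulated pairs, purity confounding, missing values) is a
first-class module, so the full chain is testable end-to-end without any
external download. See `docs/methods.md` for models, assumptions and
limitations.

## Worked example

Run the whole pipeline on a simulated cohort (30 samples, hazard ratio 3
across a true wGII cutoff of 0.3, 10% of kinases planted as co-regulated
with effects of +1 log2 on the kinase and +1.5 on its sites):

```sh
gicoreg run --outdir run --seed 1
```

The run directory contains the simulated inputs (`segments.tsv`,
`clinical.tsv`, `global.tsv`, `phospho.tsv`, `ks_table.tsv`, `truth.json`),
per-stage outputs (`wgii.tsv`, `cutoff_pcurve.tsv`, `groups.tsv`,
`diffexpr_*.tsv`, `phospho_normalized.tsv`, `pairs.tsv`,
`significant_pairs.tsv`, `mixture.json`, `edges.tsv`) and a truth-vs-result
summary, `report.json`:

```json
{
  "chosen_cutoff": 0.28,
  "true_cutoff": 0.3,
  "n_high": 17,
  "n_low": 13,
  "wgii_max_abs_error": 1.1102230246251565e-16,
  "n_pairs": 937,
  "p0": 0.9905951336469268,
  "true_null_fraction": 0.9,
  "n_called": 93,
  "sensitivity": 0.9789473684210527,
  "false_call_fraction": 0.0
}
```

Reading this: the realized wGII of the emitted segments matches the planted
values to machine precision; the survival-driven cutoff search lands at
0.28 against a true 0.3 (17 high / 13 low); of 937 analyzable
kinase–substrate pairs the mixture model estimates a 99% null proportion
against a planted 90%, and at the default significance thresholds 93 pairs
are called, recovering 98% of the planted pairs with no false calls.

Each stage is also exposed separately (`gicoreg simulate | wgii | stratify |
diffexpr | ksa2d`, see `--help`), and everything is importable as a
library:

```python
from gicoreg import SegmentProfile, infer_baseline, compute_wgii
result = compute_wgii(profile, baseline=infer_baseline(profile))
```

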