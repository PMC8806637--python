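# irgp-surv

Rank-based **immune-related gene-pair (IRGP)** prognostic signatures for
censored survival data, with a united clinical-stage + gene-score nomogram.

## The problem

Gene-expression prognostic signatures built from absolute expression
levels travel poorly between platforms: RNA-seq FPKM and microarray
intensities live on different scales, and normalisation choices change
the scores. A gene-*pair* signature sidesteps this. For an ordered pair
of genes (a, b), a sample's feature is

```
I(a, b) = 1  if expr(a) > expr(b) in that sample,  else 0
```

a within-sample rank comparison that is invariant to any strictly
increasing transform of that sample's expression values — log
transforms, scaling, quantile normalisation, platform gain and offset
all leave it untouched. This package implements the full workflow around
that primitive for overall-survival (OS) modelling in clear cell renal
cell carcinoma (ccRCC) and similar settings:

1. **Candidate pairs** — keep immune genes with median absolute
   deviation (MAD) > 0.5 across samples, form all gene pairs, drop pairs
   whose majority indicator class covers ≥ 80% of samples, and intersect
   the surviving pairs across platforms.
2. **Signature selection** — univariate Cox screen per pair
   (Wald p < 0.001), then LASSO-penalised Cox regression with the
   penalty chosen by 10-fold cross-validated partial-likelihood
   deviance; pairs with non-zero coefficients form the signature.
3. **Risk score** — `risk = Σ_k I_k · β_k`, dichotomised at each
   cohort's median (ties to low risk).
4. **Evaluation** — Kaplan–Meier curves with the log-rank test,
   IPCW cumulative/dynamic AUC at 1/3/5 years, Harrell's C-index, and
   uni-/multivariable Cox over age, gender, grade, stage and score.
5. **United model** — a two-covariate Cox fit on stage + risk score,
   re-expressed as a nomogram (points mapping, Breslow baseline,
   `S(t|x) = S0(t)^exp(βᵀx)`) with calibration tables.

The published 11-pair ccRCC signature ships as package data
(`load_published_signature()`), and a synthetic-cohort generator
produces two-platform studies with known ground-truth pairs so that
every stage can be tested against a recoverable truth.

## Worked example

```python
import irgp_surv as ig

cfg = ig.SimulationConfig(
    n_samples=(400, 150), n_genes=120, n_immune_genes=80,
    n_true_pairs=5, true_log_hazard_ratios=(0.7,) * 5,
    censoring_rate=0.3, seed=11,
)
manifest = ig.run_pipeline(ig.PipelineConfig(simulation=cfg, out_dir="run"))
print(manifest.counts)
```

prints (abridged):

```
genes_retained_common: 79        # immune genes with MAD > 0.5 on both platforms
pairs_built: 3081                # 79*78/2 ordered pairs
candidate_pairs: 1430            # after prevalence filter + platform intersection
pairs_screened: 8                # univariate Cox p < 0.001 in training (n=273)
signature_size: 8                # non-zero LASSO-Cox coefficients
united_c_index: {training: 0.719, validation1: 0.673, validation2: 0.594}
```

Three of the five planted pairs appear in the selected signature
(`run/signature.tsv`), and `run/evaluation.json` holds the per-cohort
metrics — for this run, training AUC 0.70/0.74/0.80 at 1/3/5 years with
log-rank p = 1.2e-14, validation-1 AUC 0.65/0.67/0.71 — showing honest
shrinkage from training to validation at this modest signal strength.

Scoring new samples with the published signature needs only an
expression table containing the 20 signature genes:

```python
sig = ig.load_published_signature()              # 11 (gene_a, gene_b, β) entries
profile = ig.median_stratify(ig.score_expression(cohort, sig))
```

The same workflow is scriptable from the shell:

```
irgp-surv simulate --out study --seed 11 --samples 400,150
irgp-surv run --out run --seed 11
irgp-surv score --expr expr.tsv --out risk.tsv   # published signature by default
```

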