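# latentsurv

Autoencoder latent-feature survival subtyping for paired RNA/miRNA
expression cohorts.

## The problem

Bulk tumor cohorts such as TCGA lung adenocarcinoma pair RNA-seq and
miRNA-seq expression with overall-survival follow-up. A recurring analysis
pattern integrates the two omics layers, compresses them into a small
latent representation, and asks whether patients fall into prognosis
subtypes — a poor-survival (high-risk) and a good-survival (low-risk)
group — that can then be characterized molecularly and predicted from a
handful of features. `latentsurv` implements that pattern end to end for
analysts who want a tested, reproducible version of the pipeline and a
synthetic cohort generator to validate it against planted ground truth.

## The method

1. **Preprocessing** — features and then samples with more than 20% zeros
   are dropped, every feature is z-scored across patients, and the RNA and
   miRNA matrices are concatenated into one patient × feature matrix.
2. **Autoencoder** — a tanh bottleneck network (default 500–100–500
   hidden nodes) trained with SGD (lr 0.01, decay 1e-6, batch size 1,
   150 epochs, dropout 0.5, L1 1e-3 / L2 1e-4 weight penalties) on the
   mean-squared reconstruction error. The bottleneck activations
   `z = encoder(x)` are the compressed patient representation.
3. **Cox screening** — each latent feature is screened with a univariate
   Cox proportional-hazards model, `h(t|z_j) = h_0(t) exp(β_j z_j)`,
   maximizing the Efron partial likelihood by Newton–Raphson; features
   with score-test (log-rank-type) p < 0.05 are kept. For a binary
   covariate this score test is exactly the two-group log-rank statistic.
4. **Subtyping** — K-means over k = 1..10 scored by the elbow curve,
   Silhouette index and Calinski–Harabasz criterion (Silhouette decides;
   disagreement is flagged); the cluster with worse Kaplan–Meier survival
   at median follow-up is named high-risk.
5. **Classification** — one-way ANOVA F ranks RNAs and miRNAs on a 60%
   training split; an RBF-kernel SVM (and KNN / random-forest /
   logistic-regression comparison grids) is fit on top-m miRNA + top-n RNA
   combinations and evaluated on the held-out 40%.
6. **Characterization** — Welch-t differential expression on log2(x+1),
   preranked GSEA with a gene-set permutation null, hypergeometric
   over-representation, Fisher exact tests on clinical/mutation tables,
   per-chromosome Mann–Whitney copy-number comparison, quartile
   expression-survival screens and Pearson co-expression, all with
   Benjamini–Hochberg adjustment.

A synthetic-cohort generator plants two subtypes with a configurable
hazard ratio (exponential survival, uniform administrative censoring),
subtype-differential features among many nulls, negative miRNA→target
coupling, excess zeros and subtype-conditional binary covariates, so every
stage can be tested against known truth.

## Worked example

`examples/02_subtype_discovery.py` runs the unsupervised half of the
pipeline on a 200-patient synthetic cohort (hazard ratio 3, effect size
1.5) with the scaled-down autoencoder configuration:

```
after preprocessing: 172 patients x 448 features
reconstruction loss: 1.008 -> 0.982 over 2000 epochs
survival-associated latent features (Cox p < 0.05): 2 of 2
chosen cluster number: k = 2 (silhouette -> 2, Calinski-Harabasz -> 10)
adjusted Rand index vs planted subtypes: 1.00
log-rank p between inferred subtypes: 1.8e-11
```

The two bottleneck features both carry survival signal, the cluster-number
indices select k = 2, K-means recovers the planted subtypes exactly
(ARI 1.0), and the inferred subtypes separate survival decisively. The
other example scripts cover simulation, the classifier sweep
(`examples/03`), differential expression + enrichment (`examples/04`) and
the association statistics (`examples/05`).

The full pipeline is one call (or `latentsurv run --config cfg.yaml` from
a shell):

```python
import latentsurv as ls

config = ls.PipelineConfig(cohort=ls.CohortConfig.scaled_down(seed=1),
                           autoencoder=ls.AEConfig.scaled_down(),
                           seed=1, outdir="out")
result = ls.run_pipeline(config)
```

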