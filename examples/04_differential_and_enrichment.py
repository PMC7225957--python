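"""Subtype characterization: differential expression, preranked gene-set
enrichment, and the quartile expression-survival screen.
"""

import latentsurv as ls
from latentsurv.enrich import GeneSetCollection

cohort = ls.simulate_cohort(ls.CohortConfig.scaled_down(seed=1))
labels = cohort.true_labels

# differential expression on the normalized (unstandardized) RNA matrix
de = ls.differential_expression(cohort.rna, labels)
top = ls.top_k(de, 10)
print("top differentially expressed RNAs (Welch t on log2(x+1)):")
print(top[["feature", "log2_fold_change", "p_value", "adjusted_p"]]
      .to_string(index=False))
planted = set(cohort.truth["diff_rna"])
print(f"planted differential features in top 10: "
      f"{sum(f in planted for f in top['feature'])}/10")

# preranked GSEA with one planted signal set and ten null sets
sets = GeneSetCollection(ls.simulate_gene_sets(cohort.truth, n_null_sets=10,
                                               set_size=15, seed=2))
enr = ls.preranked_gsea(de.set_index("feature")["t"], sets,
                        n_perm=500, seed=3)
print("\nenrichment (signal set should lead):")
print(enr.head(3).to_string(index=False))

# quartile survival screen on one planted differential gene
records = ls.records_from_clinical(cohort.clinical)
gene = cohort.truth["diff_rna"][0]
n_hi, n_lo, p = ls.quartile_survival_screen(cohort.rna.values[gene], records)
print(f"\nquartile screen for {gene}: top/bottom {n_hi}/{n_lo} patients, "
      f"log-rank p = {p:.3g}")
# The signal set's permutation p should sit below the null sets'; the
# quartile screen tests whether extreme expression of one gene separates
# survival.
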