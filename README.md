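# gbmsubtypes

Transcriptome-based prognostic subtyping of glioblastoma (GBM), packaged as a
reusable, tested Python pipeline.

Glioblastoma's established expression classes correlate poorly with patient
outcome. An alternative is to build the classification *from* outcome: find
the genes whose expression tracks overall survival (OS) consistently across
independent cohorts, summarize each tumor by how strongly it expresses the
poor-prognosis versus favorable-prognosis program, and cut that score into
clinically distinct groups. `gbmsubtypes` implements this analysis end to
end, together with a synthetic-cohort generator that plants known prognostic
programs so every stage can be validated without any external download.

## Method

1. **Prognosis-gene (PG) selection.** For two discovery cohorts, compute each
   gene's Pearson correlation r(gene, OS). Keep genes whose correlations have
   the same strict sign in both cohorts and rank them by the sign-preserving
   product score sign(r) · |r_A · r_B|. The k most negative genes form the
   *poor* set and the k most positive the *favorable* set (k = 40 each by
   default).
2. **ssGSEA scoring.** Each sample gets a single-sample GSEA enrichment score
   for each PG set — a weighted ECDF-difference sum over the sample's
   expression ranking (weight exponent τ = 0.25). Scores are z-standardized
   across the cohort, and the **prognosis score** is
   `favorable_score − poor_score`. Because ssGSEA sees only within-sample
   ranks, the score is invariant to monotone platform transforms
   (microarray vs RNA-seq).
3. **Subtype assignment.** Prognosis score < −1 → *invasive* (poor
   prognosis), > +1 → *mitotic* (favorable), otherwise *intermediate*.
   A cutoff sensitivity scan (two-group log-rank p across a −2…2 grid)
   supplies the evidence behind those cutoffs.
4. **Annotation.** Kaplan–Meier curves, K-group log-rank tests, univariate
   Cox hazard ratios, score–OS regression and grade-wise ANOVA/Tukey;
   invasive-vs-mitotic differential expression (Student's t, BH-FDR,
   adjusted p < 0.001), Fisher's-exact over-representation analysis,
   Cohen's-kappa term clustering (κ > 0.4), PG ∩ DEG marker genes; MRI
   invasiveness `(FLAIR − CE)/CE`, spheroid invasion `(72h − 0h)/0h`, and
   subtype-vs-MGMT-methylation contingency statistics.

The published 40 + 40-gene signature ships with the package
(`gbmsubtypes.load_published_pg_sets()`), so cohorts can also be scored
directly without re-running selection.

## Worked example

```python
from gbmsubtypes import (SimulationConfig, simulate_cohort_pair, select_pgs,
                         score_cohort, assign_subtypes, km_by_group,
                         logrank_test, cox_univariate)

config = SimulationConfig(seed=7)   # 500 genes, 200 patients/cohort, 20+20 planted
cohort_a, cohort_b, truth = simulate_cohort_pair(config)

selection = select_pgs(cohort_a, cohort_b, k=20)
scores = score_cohort(cohort_a, *selection.gene_sets())
assignment = assign_subtypes(scores)          # cutoffs -1 / +1

groups = assignment["subtype"].astype(str)
curves = km_by_group(cohort_a.os_months, cohort_a.event, groups)
cox = cox_univariate(cohort_a.os_months, cohort_a.event, scores["prognosis_score"])
```

With seed 7 this prints (via the accessors shown in the docstrings):

```
selected 20+20 genes, 40/40 planted
{'intermediate': 75, 'mitotic': 63, 'invasive': 62}
{'invasive': 3.1, 'intermediate': 13.5, 'mitotic': 65.3}   # median OS, months
log-rank p = 8.40e-28
HR per score unit = 0.485 (95% CI 0.427-0.552)
```

Selection recovered all 40 planted genes; the three subtypes separate median
survival in the expected order (mitotic longest, invasive shortest); the
three-group log-rank test is overwhelmingly significant; and a higher
prognosis score is protective (hazard ratio < 1 per score unit).

The same pipeline runs from the shell:

```bash
gbmsubtypes simulate --pair --seed 7 -o sim/
gbmsubtypes select-pgs --cohort-a sim/cohort_a_expression.tsv \
    --clinical-a sim/cohort_a_clinical.tsv \
    --cohort-b sim/cohort_b_expression.tsv \
    --clinical-b sim/cohort_b_clinical.tsv -k 40 -o sel/
gbmsubtypes score --expression sim/cohort_a_expression.tsv \
    --gene-sets sel/pg_sets.gmt -o scores.tsv
gbmsubtypes assign --scores scores.tsv -o subtypes.tsv
gbmsubtypes survival --clinical sim/cohort_a_clinical.tsv \
    --assignment subtypes.tsv -o surv/
```

`gbmsubtypes run --config config.yaml` executes all six stages
(select → score → assign → survival → enrichment → clinical) and writes a
JSON run report; see `gbmsubtypes.PipelineConfig` for the configuration
fields. Expression matrices are read as TSV or GCT 1.2 and gene sets as GMT.

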