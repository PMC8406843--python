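# scfamet

Toolkit for profiling gut-metagenome short-chain-fatty-acid (SCFA) synthesis
function in a two-group (control vs. atrial-fibrillation) cohort design:

- **synthetic cohorts** with planted ground truth (differential KOs, a
  species × enzyme harboring matrix, a known mediation triple) so every stage
  is testable offline,
- **KO catalogs** built from a compound → KO map, intersected with a cohort's
  annotated KOs, with UpSet-style compound-combination counts,
- **abundance normalization** `G_i = (r_i/L_i) / Σ (r_j/L_j)` after a
  minimum-read filter, plus gene → feature aggregation with conserved mass,
- **taxonomic assignment** by significant-hit retention (e-value ≤ 10× the
  best hit) and lowest-common-ancestor placement, with harboring-species
  tables,
- **differential abundance** (two-sided Wilcoxon rank-sum, BH-FDR, log2 fold
  change, enriched/deficient calls),
- the **OR(k) group-enrichment statistic** (odds of a feature's pooled
  abundance versus all other features, control over case) with a
  configurable sign convention,
- **sparse score models** (L1-penalized logistic selection with CV'd penalty,
  min or 1-SE rule), ROC/AUC with DeLong CIs, Nagelkerke R², and
  Harrell-style bootstrap optimism correction; the three published score
  formulae (KO / enzyme / species) ship as packaged JSON,
- **mediation** via standardized path analysis (the single-indicator PLS
  path-model special case) with the exact decomposition identity
  `total = direct + a·b`, VAF, and bootstrap CIs,
- **association stats**: Spearman correlation networks with FDR + |r|
  thresholds, and uni/multivariable logistic regression.

## CLI

All functionality is exposed through the `scfa` command:

```bash
scfa simulate --seed 1 --out cohort/            # synthetic cohort + truth.json
scfa catalog --annotated cohort/ko_matrix.tsv --out catalog_out/
scfa diff --matrix cohort/ko_matrix.tsv --out diff.tsv
scfa orscore --matrix cohort/ko_matrix.tsv --out or.tsv
scfa score fit --matrix cohort/ko_matrix.tsv --out model.json
scfa score roc --matrix cohort/ko_matrix.tsv --model model.json --out roc.json
scfa mediate --table cohort/clinical.tsv --x diversity --m hsCRP \
    --y LA_diameter --boot 500 --out mediation.json
scfa assoc network --table cohort/species_matrix.tsv --out edges.tsv
scfa run --seed 1 --out run_out/                # full 8-stage pipeline
```

`scfa run` writes a `manifest.json` with per-artifact SHA-256 checksums;
re-running with the same config and seed reproduces identical checksums.

## Library example

```python
from scfamet import CohortConfig, generate_cohort, differential_table

cohort = generate_cohort(CohortConfig(n_ctr=50, n_af=50, n_diff=10, seed=1))
table = differential_table(cohort.abundances, alpha=0.05)
print(table[table.direction != "NS"])
```

## Notes

- The OR(k) formula puts the control group in the numerator, so OR > 1 means
  relatively more abundant in controls; published descriptions of this
  statistic disagree on the sign convention, hence
  `--or-convention {formula,af-positive}` (default `formula`, the literal
  reading).
- Abundance matrices are TSV (rows = samples, `group` column + one column per
  feature); models and reports are JSON; everything is plain text.
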