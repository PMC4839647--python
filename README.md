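# stromabalance

Tissue-composition-aware differential analysis for mixed-tissue cohorts.
When bulk cancer samples are compared against normal samples, a systematic
difference in stroma content between the groups confounds the molecular
contrast. This package implements the balancing strategy: sort each group by
its histopathology-determined stroma fraction and build

* a **balanced** dataset (highest-stroma half of the cancer group vs.
  lowest-stroma half of the normal group) that equalizes average stroma and
  isolates the cancer-vs-benign-epithelium contrast,
* an **unbalanced** dataset (the complementary halves) that maximizes the
  stroma difference and isolates the cancer-vs-stroma contrast,
* **unstratified** datasets — seeded random subsets at the balanced size —
  representing a typical confounded design.

On top of the splits it provides per-feature differential testing (pooled or
empirical-Bayes moderated t for genes, variance-pretest t for metabolites,
Benjamini–Hochberg FDR, p-value averaging over unstratified draws), tools to
quantify how the choice of split changes the results (top-N overlap curves
against a resampling baseline, p-value order-of-magnitude shift counts, the
significance-ratio score and its cross-study concordance, pathway reports),
and a synthetic mixed-tissue cohort generator with planted marker classes so
the entire pipeline is testable without any external data.

## Library sketch

```python
from stromabalance import (
    GeneratorParams, generate_cohort, split_balanced_unbalanced,
    average_composition, net_tissue_contrast, differential_genes,
    differential_metabolites, draw_unstratified, average_pvalues,
    shared_fraction_curve, sr_rank,
)

cohort, truth = generate_cohort(GeneratorParams(seed=1))
balanced, unbalanced = split_balanced_unbalanced(cohort.samples)
res_b = differential_genes(balanced, cohort)            # moderated t + BH
res_u = differential_genes(unbalanced, cohort)
curve = shared_fraction_curve(res_b, res_u, [200, 2000])
ranking = sr_rank(res_b, res_u, "balanced_specific")    # split-specific genes
```

Real data enters through `read_composition_table` (CSV/TSV/XLSX with columns
`sample_id, group, pct_cancer, pct_stroma, pct_benign[, gleason]`) and
`read_matrix` (features × samples TSV). Expression matrices should be log2
scale; apply `quantile_normalize` to the full matrix *before* splitting.

## CLI

```sh
stromabalance simulate --outdir sim --seed 1 --n-genes 2000
stromabalance split --composition sim/composition.tsv --out splits.json
de-genes --composition sim/composition.tsv --expression sim/genes.tsv \
         --split balanced --moderation on --out genes_balanced.tsv
de-metabolites --composition sim/composition.tsv --metabolites sim/metabolites.tsv \
               --rule as_published --split complete --out mets.tsv
stromabalance overlap --results-a genes_balanced.tsv --results-b genes_unbalanced.tsv \
                      --ns 200,2000 --out curve.json
```

`--split` is one of `balanced`, `unbalanced`, `complete`, `unstratified`
(the latter averages raw p over `--k` seeded draws of `--n-cancer`/`--n-normal`
samples). Options may also come from a YAML/JSON file via `--config`.

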