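# mpramars

Predict the transcriptional activity of DNA constructs measured by massively
parallel reporter assays (MPRA) or luciferase reporter assays, directly from
their sequence, and read back which transcription-factor binding sites
(TFBSs) drive the prediction.

The package is aimed at regulatory-genomics analysts who have (i) a motif
library (TRANSFAC flat-file or JASPAR PFM), (ii) construct sequences in
FASTA, and (iii) either a per-construct activity table or raw mRNA/DNA
barcode count tables, and who want an interpretable model rather than a
black box.

## Method

1. **Encoding.** Every sequence *j* is encoded as one TFBS enrichment score
   per matrix *i*:

   `enrichment_ij = Σ_k PWM_score(site k of matrix i in sequence j)`

   where windows on both strands are scored with the information-weighted
   matrix similarity score normalised to [0, 1] (consensus = 1), and only
   windows above the per-matrix cutoff are summed. Cutoffs chosen to bound
   the false-negative rate can be supplied or calibrated by Monte Carlo.
   Experimental conditions (cell types, assay types) are appended as binary
   0/1 columns. MPRA activities are `log2(mRNA/DNA)` barcode-count ratios,
   aggregated per construct, with irregular constructs removed by a
   replicate-variability filter.

2. **Clustering with a redundancy-sized regression tree.** A CART-style
   regression tree splits constructs into clusters, with the minimum
   terminal-cluster size set from the data by

   `variation parameter = 2^(−PC1 proportion) · 1e7 / n²`,
   `minbucket = variation parameter · n`,

   where the PC1 proportion is the fraction of variance on the first
   principal component of the enrichment columns (a redundancy measure) and
   *n* is the number of observations. Small or highly redundant libraries
   therefore yield `minbucket ≥ n` — a single cluster, no splitting — while
   large diverse libraries may split. The grown tree is trimmed back by
   cost-complexity pruning under seeded cross-validation.

3. **Per-cluster MARS response functions.** In each terminal cluster a
   multivariate adaptive regression splines model is fit:

   `activity_j = Σ c′·h(e_i′j)·h(e_i″j) + Σ c″·h(e_i‴j) + c`

   with hinge functions `h(x) = max(0, x − c)` or `max(0, c − x)`. The
   forward pass adds the reflected hinge pair that most reduces the residual
   sum of squares; the backward pass deletes terms under generalized
   cross-validation, `GCV = (RSS/n) / (1 − M_eff/n)²`.

Evaluation reports the Pearson correlation between predicted and observed
activities for the closed test (training fit) and the open test (pooled
held-out predictions under 100-fold cross-validation). Interpretation
helpers export the candidate-active-TFBS tree, per-matrix selection
frequencies, condition-specific TFBS sets, and a misfit screen that flags
motifs enriched among the most over-/under-estimated constructs.

## Worked example

The built-in simulator generates a library with the structure the method
assumes: planted motifs, a copy-number-defined pair of clusters with
different hinge response functions, Gaussian noise, and Poisson barcode
counts.

```python
from mpramars import (ScenarioSpec, simulate_dataset, activity_from_counts,
                      filter_irregular, build_design_matrix, fit, evaluate_cv,
                      selected_tfbs_frequencies)

spec = ScenarioSpec(seed=1)                      # 5000 constructs, 12 motifs
ds, counts, _ = simulate_dataset(spec, with_counts=True)
activities, _ = activity_from_counts(counts)     # log2 mRNA/DNA per construct
kept, removed = filter_irregular(activities, sd_quantile=0.95)
dm = build_design_matrix(ds.enrichments, kept)
fitted = fit(dm)
print(fitted.tree.report_text())
result = evaluate_cv(dm, n_folds=100, seed=1)
print(result.pearson_r_closed, result.pearson_r_open)
```

Output:

```
SYN00 < 2 [mean=0.753 n=4750 (100.0%)]
  leaf 0: mean=-1.806 n=2388 (50.3%)
  leaf 1: mean=3.340 n=2362 (49.7%)
0.994 0.994
```

The tree recovers the planted cluster rule (copy number of motif `SYN00`
at threshold 2), the leaf means are the average activities of the two
populations with their sample proportions, and both the closed- and the
open-test correlation are 0.994 — the simulated noise floor. The
selected-TFBS frequencies rank the planted effect motifs (`SYN01`–`SYN04`)
at the top:

```python
selected_tfbs_frequencies(fitted)
# {'SYN01': 12, 'SYN02': 4, 'SYN03': 4, 'SYN04': 5, 'SYN05': 2, ...}
```

The same pipeline is scriptable from the shell: `mpramars simulate`,
`mpramars fit`, `mpramars predict --condition none` (cross-condition
prediction with all condition indicators at zero), `mpramars evaluate
--folds 100`, and `mpramars report`.

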