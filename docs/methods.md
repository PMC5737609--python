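# Methods

This note documents the modelling choices, defaults, and numerical details
of `mpramars`, and what the synthetic benchmarks do and do not demonstrate.

## Sequence encoding

**Similarity score.** Windows are scored with the information-weighted
matrix-similarity score used with TRANSFAC-style profiles:

```
score(w) = (Σ_i I(i)·f(i, w_i) − Min) / (Max − Min)
I(i)     = Σ_b f(i,b) · ln(4 f(i,b))
```

with `Min`/`Max` the sums of the per-position minima/maxima of the
info-weighted frequencies. The consensus window scores exactly 1 and the
anti-consensus exactly 0, which places the per-matrix cutoffs on the
conventional 0–1 profile scale. The score is invariant to rescaling the
information vector by a positive constant. Degenerate matrices whose score
span is zero (e.g. uniform frequencies everywhere) score every window 1.
Ambiguous bases contribute the position's mean frequency, i.e. they neither
reward nor penalise a window.

**Enrichment.** The enrichment score of a sequence for one matrix is the sum
of above-cutoff window scores over both strands. Only above-cutoff windows
are counted — with sub-threshold windows included the score would no longer
track site copy number, which is the interpretation the cutoff exists to
support (a total of 3.9 at cutoff 0.866 is attainable only with exactly
four sites; see `copy_number_range`). Overlapping hits and opposite-strand
hits at the same offset are counted independently. Scanning both strands
makes the enrichment of a sequence equal to that of its reverse complement.

**Cutoffs.** Vendor-distributed minimum-false-negative profiles cannot be
shipped, so cutoffs are accepted from configuration, and
`calibrate_minfn_cutoff` provides a Monte-Carlo substitute: it draws windows
from the matrix's own frequency model (default 10 000 samples) and returns
the `target_fnr` quantile (default 0.05) of their scores, so at least 95 %
of model-generated sites pass. Matrices with a single possible window
return 1 − 1e-9.

**Pseudocounts.** Count matrices are normalised with pseudocount 1.0 by
default, frequency matrices with 0.0; the heuristic for distinguishing the
two (any cell > 1, or row sums far from 1) can be overridden explicitly.

## Activity preprocessing

Per barcode, activity is `log2((mRNA + p)/(DNA + p))` with pseudocount
`p = 1` by default (required to be positive only when zero counts occur).
Aggregation is the median over barcodes within a replicate (robust to
barcode dropout) and the mean over replicates; the replicate SD is kept for
QC. The irregularity filter removes constructs whose replicate SD exceeds
the `sd_quantile` quantile (default 0.95) of all replicate SDs; ties at the
threshold are kept, so a dataset with identical replicates everywhere loses
nothing, and at most `⌈(1 − q)·n⌉` constructs are removed.

## Design matrix and tree sizing

Rows are (construct, condition) pairs. With more than one condition label,
each label becomes a 0/1 column; the label "none" maps to an all-zero row
and is the device for condition-free prediction. The redundancy statistic is
the explained-variance proportion of the first principal component of the
**standardised** enrichment columns (condition columns excluded,
zero-variance columns dropped). Standardisation makes the statistic
invariant to per-column affine rescaling — redundancy is treated as a
correlation notion; the covariance-based alternative would let a single
high-variance matrix dominate. The sizing formulas

```
variation parameter = 2^(−pc1) · 1e7 / n²
minbucket           = variation parameter · n
```

are evaluated exactly as written (the second literally as the product, so
the identity holds bit-exactly), with `n` the number of design-matrix rows
after filtering. Enforcement uses `⌈minbucket⌉`, floored at 10 rows — the
minimum worth handing to a spline fit — which also keeps per-fold refits
legal during cross-validation.

## Regression tree

Splits minimise the within-node sum of squared errors (the ANOVA criterion)
subject to both children holding at least `⌈minbucket⌉` rows. Candidate
thresholds are midpoints of consecutive distinct values; gain ties break
towards the lowest column index, then the lowest threshold; rows equal to
the threshold go right. A split must improve the SSE by at least `cp` times
the root SSE (default `cp = 0.01`). Pruning builds the weakest-link
cost-complexity sequence, evaluates each candidate complexity (geometric
means of consecutive alphas) by seeded k-fold cross-validation (default 10
folds, fold assignment by seeded permutation, trees regrown per fold), and
keeps the subtree with minimum CV error, preferring the smaller tree on
ties. The minimum-CV rule rather than the 1-SE rule was chosen to keep the
selection a pure argmin with no additional tuning constant; the noise
benchmark (pure-noise response pruned to the bare root in ≥ 18/20 seeds)
shows it is conservative enough in practice.

## MARS

Degree is capped at 2 — single hinges and two-hinge products — matching the
response-function form above; the two factors of a product must use
different columns. Knot candidates are the distinct observed values of each
column, subsampled deterministically (even stride) to at most 500 when
there are more. The forward pass adds the reflected hinge pair (evaluated
jointly through its projection on the orthonormalised current basis) with
the largest RSS reduction; numerically dependent halves of a pair are
dropped. It stops at `max_terms = 61` basis functions or when the best
candidate improves R² by less than `rel_tol = 1e-4` — the improvement is
measured against the total sum of squares so the threshold has the same
meaning at every step. Coefficients are refit by least squares with a tiny
ridge (1e-8) for stability. The backward pass works on the Gram matrix,
deletes the term whose removal yields the lowest GCV, and returns the
subset along the deletion path with the global minimum GCV (ties to the
smaller model). The GCV penalty defaults to 3 when interactions are enabled
and 2 otherwise, with `M_eff = n_terms + penalty·(n_terms − 1)/2` counting
the intercept in `n_terms`; inadmissible models (`M_eff ≥ n`) score +∞.

## Pipeline and evaluation

`fit` chains sizing → growth → CV pruning → per-leaf MARS, all deterministic
given the config seed. When `⌈minbucket⌉ ≥ n` the pipeline is a single
cluster with one response function — the intended behaviour for small
libraries. Cross-validation (`evaluate_cv`, default 100 folds) partitions
design rows by a seeded permutation and refits the entire pipeline per fold
(the tree is not reused across folds); the open-test Pearson r is computed
on the pooled held-out predictions rather than averaged per fold, since
with 100 folds the per-fold test sets are too small for stable per-fold
correlations. A grouped-fold option keeping all rows of one construct in
the same fold would be the leakage-safe variant for multi-condition data;
row-level folds are the default.

The misfit screen compares mean enrichments in the 5 % most over- and 5 %
most under-estimated rows against the 10 % best-predicted rows, with a
pseudo-mean `ε = 0.01` (about 1 % of a single weak hit) guarding the ratio;
the two tails are evaluated and reported separately, and fold changes
≥ 2 or ≤ 0.5 are reported. The report is invariant to shifting all
activities by a constant because every stage (tree, least squares) is
shift-equivariant.

## Synthetic data

The generator emulates the structure the method assumes, not any published
dataset. Defaults of the reference scenario: 12 motifs of length 10 with
one dominant base per position (weight 0.9), 5000 constructs of 250 bp,
scan cutoff 0.95 (planted sites are exact consensus, so they score exactly
1.0 and the cutoff is effectively a zero-false-negative profile with a
near-zero background rate — enrichment then equals planted copy number
almost surely). Motif `SYN00` defines two equally likely clusters (0–1
copies vs 3–4 copies, threshold 2); cluster "low" has response
`−2 + 1.0·h(SYN01 − 1.5) − 0.8·h(2.5 − SYN02)` and cluster "high"
`+2 + 1.2·h(SYN03 − 1.5) + 0.3·h(SYN01 − 1.5)·h(SYN04 − 1.5)`; Gaussian
noise has sd 0.3. Sites are planted non-overlapping on random strands with
random gaps; when a draw would overflow the sequence, decoy and then effect
copies are trimmed (cluster copies never are), so packing is always
feasible at the defaults. Counts are Poisson: DNA at depth 500, mRNA at
depth·2^activity, 8 barcodes × 3 replicates; 5 % of constructs get extra
per-replicate activity noise (sd 1.5) to stand in for irregular constructs.
The count model is Poisson rather than negative binomial for simplicity;
overdispersion can be emulated through the irregular-noise knob.

What passing the benchmarks shows: the pipeline recovers cluster structure,
knots, coefficients and held-out correlation when the data-generating
process matches the model class and motifs are cleanly separable. What it
does not show: performance under motif similarity/overlap (real PWM
libraries are highly redundant), soft binding sites far from consensus,
non-hinge response shapes, sequence-position effects, or realistic barcode
overdispersion — on real data the open-test correlations will be
substantially lower than on these simulations.

## Problem sizes used in the checks

The recovery benchmarks run the reference scenario (n = 5000) across seeds
1–5 with full 100-fold cross-validation per seed, and 20-seed replicate
batches for knot recovery (n = 2000) and root-split recovery; the oracle
equivalences run on instances up to n = 200 (splits), 200 bp (scanning) and
10 basis functions (subset search), where exhaustive enumeration is exact.

## Known limitations

- The forward pass is plain (no fast-MARS candidate queues); very large
  knot sets rely on the stride subsampling for tractability.
- No surrogate splits or missing-value handling in the tree; features must
  be complete.
- Linear (unhinged) MARS terms and degree-3 interactions are deliberately
  unsupported.
- The greedy backward pass coincides with exhaustive best-GCV subset search
  on well-separated instances (verified on the oracle benchmarks) but is
  not guaranteed to globally optimise GCV in adversarial cases.
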