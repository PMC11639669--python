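# Methods

## Model and assumptions

A motif binding-determinant model is a PSSM: a 20 × L matrix of per-position
amino-acid preference weights over the canonical alphabet
`ACDEFGHIKLMNPQRSTVWY`. The comparison framework assumes positions are
independent (no inter-position coupling) and motifs are fixed-length
(no variable gaps); both are standard PSSM limitations. All scoring happens
on min-max-normalised matrices so PSSMs from different numeric encodings
(frequencies, log-odds, mutational-effect scores) live in one comparable
space.

### Column scores

- **Importance** is the Gini coefficient of a normalised column, computed
  with the small-sample correction `n/(n−1)` (n = 20). The correction is
  deliberate: under it a one-hot column (a single-residue determinant)
  scores exactly 1, so the IWS of two identical one-hot columns is exactly
  1, the top of its stated range. The population form would cap importance
  at 0.95. Computation uses the sorted-value identity (O(n log n)); the
  test suite pins it to an O(n²) pairwise-difference oracle at 1e−12.
- **Similarity** is Pearson's correlation between two 20-vectors. A column
  with zero variance has undefined correlation; we return 0 by convention.
  Constancy is detected exactly (max == min), not by an epsilon, because the
  convention is about columns that encode no preference at all — and such a
  column has Gini 0, so the IWS is unaffected either way.
- **IWS** = similarity × importance_A × importance_B. The two importance
  terms are multiplied together first; floating-point multiplication is
  commutative, so IWS(a, b) == IWS(b, a) bit-exactly and equal-length
  all-vs-all matrices are exactly symmetric. Negative IWS values are kept;
  the background distribution carries their probability mass.
- **IWD** = (mean absolute difference over the 20 residues) × importance of
  the *query* column only. It is directional by design: it flags
  determinants the query requires that the comparison lacks. Note a literal
  consequence of the formula: for min-max-normalised columns two disjoint
  one-hot columns score 0.1, not the nominal maximum of 1. Larger values
  arise for columns with many high-weight residues in the query and none in
  the comparison. We implement the formula literally and do not rescale;
  the dissimilarity filter threshold (< 1) is interpreted on this scale.

### Significance

The null is randomisation-based: pool every column of the query PSSM set
and every column of the comparison PSSM set, draw `size` pairs uniformly
with replacement (one from each pool, i.i.d. — matching the independence
assumption of the window correction below), score IWS, sort. The empirical
probability of an observed IWS is `(r + 1)/(N + 1)` where `r` counts null
samples ≥ the observation (ties count). The add-one smoothing is the
standard permutation-test correction; it keeps every probability strictly
positive so window products never vanish. Lookup is a binary search on the
sorted sample. One pooled background is built per query-set/comparison-set
pairing and reused across all window comparisons in the run.

Because the pools are finite, the quality of the null depends on the column
set size: with a single short query PSSM the per-column probability floor is
coarse and the attainable significance is limited. Use the largest PSSM sets
available.

A window of n columns multiplies n probabilities; under the null each is
approximately Uniform(0, 1), so the product is corrected by the CDF of a
product of n independent uniforms, `p · Σ_{k<n} (−ln p)^k / k!`. We evaluate
it through the identity with the Poisson CDF / upper regularised incomplete
gamma function, `Q(n, −ln p)` (`scipy.special.gammaincc`), which is stable
for very small p; `n = 1` and `p = 1` are short-circuited so the exact
identities `udf(p, 1) = p` and `udf(1, n) = 1` hold to the bit.

### Alignment

The smaller PSSM slides across the larger one column at a time with full
containment (no overhangs — overhangs would change n per window and break
the correction's comparability). `|ΔL| + 1` windows are scored; the window
with the smallest corrected probability wins, ties going to the leftmost
offset. Bonferroni correction multiplies the best window's probability by
the window count — across windows only, not across comparison PSSMs; the
set-level ranking is reported uncorrected. IWD direction is always
query → comparison, even when the query is the larger matrix. Result lists
are sorted by corrected p, then dissimilarity, then name, so output order is
deterministic.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `background size` | 100 000 | null sample pairs; larger = finer p resolution (floor 1/(N+1)) |
| `seed` | 42 | PRNG seed for background sampling and simulation |
| `p cutoff` | 0.001 | significance flag on the corrected p-value |
| `dissimilarity cutoff` | 1.0 | flag results whose best-window max IWD is below this |
| `normalisation mode` | column | per-column min-max; `matrix` uses global extrema (useful when absolute scale across positions is meaningful) |
| `scoring method` | frequency | PSSM construction from peptides; also `binomial_log`, `psiblast_ic` |
| `pseudocount` | 0 | additive smoothing for frequency PSSMs; raise for small peptide sets |

Two normalisation modes exist because both per-column and whole-matrix
min-max scaling are defensible (per-column equalises position importance
before Gini weighting; whole-matrix preserves relative column magnitudes).
Column mode is the default throughout.

`binomial_log` scores a cell as −log10 of the upper-tail binomial
probability of the observed count under a flat 1/20 background (the
background rate is a parameter). `psiblast_ic` mixes observed frequencies
with BLOSUM62-derived pseudocount frequencies (β = 10, Robinson–Robinson
background) and weights the log-odds by column information content. Both are
the standard published forms; they are provided for cross-encoding
comparisons and are approximations in their finer constants.

## Synthetic data: what it emulates and what it does not

`simulate` builds motif classes as a few fixed (or small allowed-set)
positions among wildcards — the structure of curated motif consensus
patterns — samples peptides position-independently from the class PSSM,
contaminates them with uniform-random peptides at a chosen noise fraction,
and splits peptide sets into halves to create matched PSSM pairs that share
true determinants. Decoy classes draw fixed residues from per-position
pools so classes do not share a determinant at the same position until the
pools are exhausted (> 20 classes per position), at which point overlap is
allowed and logged.

The generator does **not** emulate: physicochemical correlation between
residues (noise is uniform, real phage-display noise is biased), positional
coupling, variable motif length, or the curation biases of real motif
databases. Passing the synthetic benchmarks therefore demonstrates the
pipeline's statistical machinery — calibration, recovery, robustness trends
— not performance on any real curated dataset.

### Benchmark designs and problem sizes

- **Split-half recovery**: 20 classes, length 8, 3 fixed positions, 40
  peptides each split into disjoint halves; frequency PSSMs from the A
  halves queried against the B-half set; pooled background of 100 000
  samples, seed 42. The matched half should rank first for ≥ 90% of classes
  and the ROC AUC of −log10(corrected p) for matched-vs-mismatched pairs
  should be ≥ 0.95. Under these conditions recovery is in fact perfect
  (all ranks 1, AUC 1.0).
- **Noise titration**: queries built from 20 peptides plus uniform noise at
  fractions {0, 0.25, 2.0}, compared against the ideal class PSSMs;
  5 seeds (42–46), background 20 000. Mean AUC must not increase with
  noise. With strength-1 determinants the task saturates (AUC 1.0 at every
  level), so the trend holds with equality — the fixed residues survive
  even 200% noise, consistent with the robustness this design probes.
- **Peptide-count titration**: same design with {2, 5, 80} clean peptides;
  mean AUC must not decrease with more peptides. Also saturated under the
  default conditions.
- **Null calibration**: p-values of fresh column pairs drawn from the same
  pools as a 100 000-sample background are uniform (KS test at α = 0.01,
  10 000 draws), and unrelated random PSSM pairs exceed the 0.001 cutoff in
  ≥ 95 of 100 seeded trials.

These sizes keep the full suite under a minute on one CPU while leaving the
statistical assertions well-powered.

## Numerical choices and degenerate inputs

- Constant columns normalise to all zeros (importance 0, similarity 0 by
  convention, IWD contribution 0): a preference-free position cannot
  contribute signal in either direction.
- `build_background` normalises its inputs itself (normalisation is
  idempotent and is the pipeline's first step); `compare_windows` instead
  raises on unnormalised input so a user cannot silently compare
  incomparable encodings they built by hand.
- Probabilities are clamped into (0, 1] at every stage; corrected p-values
  never reach 0 (smoothing) and never exceed 1 (min with 1 after
  Bonferroni).
- Ties: equal window significance → leftmost offset; equal corrected p
  across comparisons → smaller dissimilarity, then lexicographic name.
- PSSM equality is defined on the weight matrix (exact), not on name or
  flag metadata; TSV files carry no metadata, JSON files carry all of it.
  TSV/JSON writers print full `repr` precision so round trips are
  bit-faithful.

## Known limitations

- Fixed-length, position-independent models only; no gapped motifs (an HMM
  or SCFG territory).
- The empirical null inherits the composition of the input PSSM sets; small
  or unrepresentative sets bias p-values, and cross-dataset comparisons are
  only as calibrated as the pooled columns are representative.
- The IWD scale depends on column shape (see above); thresholds tuned on
  one dataset need not transfer to another.
- `binomial_log` and `psiblast_ic` use standard published constants, not
  dataset-fitted ones.
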