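# Methods

## Problem and model

`sixma` classifies fixed-width DNA windows centered on a candidate adenine
as 6mA-methylated or not. The model is a radial-basis-function SVM over a
fused feature space built from two sequence encodings — nucleotide
positional specificity (NPS) and pseudo dinucleotide composition (PseDNC) —
filtered by ANOVA-F incremental feature selection. The two encodings are
deliberately complementary: NPS captures where particular bases sit relative
to the site (positional one-hot block) and which short words occur anywhere
in the window (k-mer block); PseDNC captures global composition and
sequence-order structure through physicochemical correlation tiers.

## Window extraction

Windows are 41 nt (odd, so the site is exactly central). When a window runs
off the end of its source sequence, the missing flank is filled with the gap
character `N` on whichever side underruns, keeping the site central — both
encoders assume a site-centered frame. Indexing is 0-based internally; the
CLI reports 1-based positions. A non-adenine center is a warning by default
(`center_check="warn"`), so users may scan arbitrary positions; a strict
mode raises instead. Lowercase input is uppercased and `U` is accepted as
`T`.

## NPS encoder

The binary code table is A→(0,0,0,1), T→(0,0,1,0), C→(0,1,0,0),
G→(1,0,0,0), N→(0,0,0,0). This is a nonstandard column order for a one-hot
code, but an RBF kernel is invariant to the permutation, so it is kept as
the method's canonical form. K-mer counting is overlapping — the only
convention that gives usable counts at k = 4 in a 41-nt window — with k-mers
containing `N` skipped and the denominator reduced to the number of N-free
windows (an all-`N` stretch yields a zero block rather than an error). The
k-mer window is the full 41-nt window; the dimension identity
4·41 + 16 + 64 + 256 = 500 confirms the positional block spans all 41
positions. Block order (binary, k=2, k=3, k=4; k-mers lexicographic) is
fixed so that selected feature indices are stable and nameable.

## PseDNC encoder

Parameters:

| parameter | default | meaning |
|---|---|---|
| λ | 6 | number of correlation tiers; output dimension is 16 + λ = 22; must satisfy λ < L − 1 |
| w | 0.1 | weight of the correlation block in the shared normalization; any value in (0, 1] |
| counting | overlapping | dinucleotide frequency mode; a literal non-overlapping mode is available as a flag |
| properties | ΔH, ΔS, ΔG37 | per-dinucleotide stacking enthalpy (kcal/mol), entropy (cal/mol·K) and free energy at 37 °C (kcal/mol) |

The default property values are the unified nearest-neighbor thermodynamic
parameters (SantaLucia, 1998), the standard source for dinucleotide
enthalpy/entropy/free-energy triples in this encoding lineage. Each property
is standardized to mean 0 and population (÷16) standard deviation 1 over the
16 dinucleotides before use; the standardization denominator is the SD of
the property values themselves (the only reading under which the transform
is non-degenerate). Because standardization is affine-invariant, any
linearly rescaled table gives identical encodings — a tested invariant — so
exact units do not matter, and a user table can be dropped in as a TSV
(columns: dinucleotide, then one column per property).

Dinucleotides containing `N` are excluded from both the frequency counts
and the correlation sums, with denominators adjusted to the number of valid
terms; a tier with no valid term is 0. The assembled vector is a probability
simplex (d_u ≥ 0, Σd_u = 1), checked to 1e−9.

The overlapping default and the w = 0.1 default cannot be cross-checked
against any published reference values for this exact predictor; both are
exposed as configuration and flagged here rather than silently fixed.

## Feature selection

Features are ranked by the two-group one-way ANOVA F statistic
(df 1, n − 2), computed via `sklearn.feature_selection.f_classif` and
verified in the tests against a brute-force sums-of-squares transcription
at 1e−10 relative error. Conventions: a constant feature gets F = 0; a
perfect separator (zero within-class variance) is capped at the largest
float64 and therefore ranks first, ties among such features broken by
feature index.

The incremental sweep evaluates nested top-d subsets with a 5-fold
cross-validated SVM at default hyperparameters (folds configurable to 10);
the selected dimension is the smallest d attaining the maximum accuracy
(parsimony tie-break). The `dims` argument restricts which subset sizes are
visited when sweeping all 522 would be wasteful; results record exactly
which dimensions were evaluated.

Two protocols are provided. `"paper"` (default) ranks once on the full
dataset and reports cross-validated accuracy on the same data — the filter
protocol standard in this predictor literature, which is optimistically
biased because the ranking has seen the test folds. `"honest"` re-ranks
within each training fold and is the mode to use when the reported curve
must be an unbiased generalization estimate.

## Classifier and evaluation

The SVM uses an RBF kernel (linear/polynomial/sigmoid are configurable but
not tuned by default). Cost and gamma are chosen by exhaustive grid search
over the standard libsvm-guide lattice (C ∈ 2^−5..2^15, γ ∈ 2^−15..2^3,
steps of 2²) scored by inner stratified CV accuracy; ties break toward the
smallest cost, then the smallest gamma. Features are standardized with
training-fold mean/SD before fitting: the fused space mixes {0,1}
indicators with frequencies of order 1/40, and RBF distances are
scale-sensitive. The scaler is part of the persisted model.

Probabilities come from the SVM library's Platt-style calibration
(implementation-defined); a window is called positive iff its probability
strictly exceeds 0.5, so a tie at exactly 0.5 is a negative call.

Evaluation is stratified n-fold cross-validation (stratification keeps both
classes in every fold so per-fold Sn/Sp are defined), repeated over
independent fold assignments when `repeats > 1`, reporting per-fold and mean
Sn, Sp, ACC, MCC and AUC plus pooled ROC points and confusion counts.
Zero-denominator conventions: an undefined Sn or Sp is reported as 0; an
MCC with a zero factor under the root is 0. AUC is computed by threshold
sweep and equals the Mann–Whitney pair-counting probability (ties ½), an
identity the tests enforce at 1e−10.

All randomness (fold assignment, Platt calibration, the synthetic
generator) is driven by explicit integer seeds; identical seeds reproduce
results bit-for-bit, including saved-then-reloaded models.

## Synthetic benchmark

The generator emulates the structure of the published rice 6mA benchmark:
balanced classes of 41-nt A/C/G/T windows with an adenine at the center.
Positives draw each position uniformly except at the informative positions
(default 17, 18, 19, 23, 24, 25, 1-based — flanking the central adenine at
21), where a designated nucleotide (cycle G, C, T) has probability
0.25 + 0.75·effect_size; effect_size ∈ [0, 1] thus interpolates from
uniform background to deterministic planting. Negatives are uniform
background with the `GAGG` context motif placed so its adenine is the
candidate site, mirroring how the real negatives were drawn from
GAGG-containing coding subsequences. The default effect_size is 0.5, a
mid-strength signal; the acceptance checks use 0.8 (strong signal) for the
recovery criterion and permuted labels for the null criterion.

What passing on this generator shows: the pipeline detects positional
composition bias and motif contrast, ranks the planted indicators highly,
and behaves at chance on label-permuted data. What it does not show:
performance on real genomes — the generator has uniform base composition,
no CD-HIT-style redundancy structure, no sequencing-error label noise, and
its signal is exactly the kind the encoders were built to see. Numbers on
real benchmarks (e.g. the published ~87% accuracy on the rice dataset)
depend on that dataset and on unrecoverable details (original property
table, w, CV partition) and are not asserted anywhere in this package.

## Problem sizes used in checks

The automated checks run the PseDNC oracle over all 4,096 hexamers (λ = 4,
the deepest valid tier at L = 6) plus 100 random 41-mers at λ = 6; the null
behavior over 10 permutation seeds at n = 400 samples; and the signal
recovery on 400 + 400 samples at effect_size 0.8 with the dimension sweep
restricted to d ∈ {1..40, 45, 50, …, 150} and a coarse 5 × 4 (C, γ) grid —
sizes chosen to exercise every stage at meaningful scale while keeping the
full run in tens of seconds.

## Known limitations

- The "paper" selection protocol is optimistically biased by construction;
  use `"honest"` mode for unbiased curves.
- Sweeping all 522 dimensions with default settings fits ~2,600 SVMs; use
  `dims` to thin the sweep on large inputs.
- The PseDNC w and counting-mode defaults are conventions, not validated
  constants (see above).
- Model persistence uses a joblib sidecar for the fitted SVM; the JSON part
  alone is metadata, not the model.
- Genome-scale scanning (coordinates, BED/BAM input, liftover) is out of
  scope; inputs are window FASTA files.
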