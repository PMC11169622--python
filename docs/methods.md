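# Methods

This note documents the models and procedures implemented in `idrbind`,
the defaults and why they were chosen, what the synthetic data does and
does not emulate, and the numerical decisions a maintainer should know
about.

## Task and scope

Given a protein sequence with per-residue disorder annotation and a
per-residue embedding matrix from a protein language model (pLM), the
pipeline predicts for every residue inside an intrinsically disordered
region (IDPR) whether it binds a ligand (any ligand type; the labels are
binary). Everything downstream of the pLM is implemented here; running
ProtT5/ESM-2 themselves is out of scope and enters only through the
pluggable embedder interface. Dataset acquisition from curated disorder
databases is likewise out of scope: the package reads a simple
annotated-FASTA dialect (4 lines per protein: id, sequence, disorder
mask, binding mask) chosen for bit-exact diffability, and a synthetic
generator stands in for real corpora during testing.

## Curation

**Record invariants.** Binding annotations may exist only inside
disordered regions; violations are rejected at read time. Sequences use
the 20 standard letters plus X; the rare codes B, Z, U, O, J are mapped
to X with a warning because neither embedders nor the AAindex table have
entries for them. Proteins longer than 10,000 residues are excluded
(extreme outliers such as titin dominate memory cost and add little
signal).

**Redundancy reduction.** Pairs are aligned with an affine-gap local
(Smith–Waterman) aligner — BLOSUM62, gap open 11, extend 1, so a gap of
length g costs 11 + (g−1) — provided by Biopython's `PairwiseAligner`;
an independent textbook DP implementation serves as the oracle in the
test suite. Percent identity (PIDE) is computed over the alignment
length *including* gap columns (the conservative denominator).
Alignments shorter than 11 columns, or pairs with no positively scoring
local match, are flagged and treated as non-redundant. The homology
threshold is the HSSP twilight-zone curve

    p(L) = 480 · L^(−0.32 · (1 + e^(−L/1000)))   for L ≤ 450,
    p(L) = p(450)                                  beyond,

clamped to [0, 100]; the HSSP-value of a pair is HVAL = PIDE − p(L), and
HVAL ≤ 0 marks a pair non-redundant. At L = 250 the curve evaluates to
20.72%, so 20% identity over 250 aligned residues is the largest integer
identity still accepted — the anchor that pins this parameterization.
One property of the closed form worth knowing: it is not perfectly
monotone near the plateau — it has a shallow minimum at L = 417
(19.5095) and rises by < 0.03 points to 19.5366 at L = 450. The
property tests assert strict decrease only up to the minimum and
non-increase within that tolerance; the formula is used as written.

**Reduction algorithm.** Neither a maximum independent set nor any
canonical order is prescribed for "remove redundant sequences", so the
package uses deterministic greedy hub removal: repeatedly drop the
record with the most redundant partners, breaking ties by retaining the
longer sequence and then by lexicographic id. This is reproducible,
idempotent, and heuristically maximizes the retained count. Cross-set
reduction (`reduce_against`) removes any query redundant to any
reference and never touches the reference set. A `pide` criterion mode
(redundant iff PIDE ≥ cutoff) approximates identity-threshold clustering
without re-implementing word-filter heuristics.

## Features

The model input is the L×m embedding matrix with one binary disorder
column appended as the **last** input dimension (index m). Fixing the
position makes the ablation index of the disorder unit well defined.
Embeddings are used raw (no normalization). Predicted disorder masks are
accepted exactly like curated ones; binarizing a continuous disorder
predictor is the caller's responsibility.

The classical baseline replaces the embedding with the 566 AAindex1
property scales per residue. Missing (`NA`) values are imputed with the
per-index mean over the present letters, and each index is z-scored
across the 20 standard letters so magnitudes are comparable with
embedding activations and the same training code applies; X maps to the
all-zero (mean) vector.

## Model and training

The production model is a single-hidden-layer feed-forward network:
input (m+1) → 612 hidden units with ReLU (dropout optional, default 0)
→ 1 sigmoid output, trained with binary cross-entropy (computed from
logits in log-sum-exp form for stability) and Adam at learning rate
0.01, on residue batches of 512. With the 1025-dimensional ProtT5 input
this network has 628,525 free parameters; descriptions of the published
architecture quote 1.7 M, which is inconsistent with 1025→612→1 — the
architecture is implemented as stated and the discrepancy is recorded,
not resolved. ReLU placement for a single hidden layer is taken as:
ReLU after the hidden layer, sigmoid on the output (required for a
probability under BCE). Weights are initialized uniform with fan-in
scaling; initialization, batch shuffling, dropout and under-sampling all
draw from one seeded generator, making training bit-reproducible.

**Balancing.** Binding residues are a minority (≈ 38% of disordered
residues, far less of all residues). The training residue set keeps
*all* binding residues and under-samples each of the two non-binding
groups — inside and outside IDPRs — down to the binding count (a group
smaller than that is kept whole). Under-sampling happens once per
training run, not per epoch, for reproducibility. Training can
alternatively be restricted to disordered residues only
(`training_subset="disorder_only"`).

**Early stopping.** Validation loss (on the held-out fold, unbalanced)
is monitored each epoch; training stops after 5 consecutive epochs
without improvement or at `max_epochs` (default 200 — a cap, since most
runs stop far earlier), and the weights of the best validation epoch are
restored. Per-epoch train/validation losses are logged to the
checkpoint.

**Cross-validation and cutoffs.** Proteins are split uniformly at
random into 5 folds (sizes differ by ≤ 1), one model per fold. Each
model's decision cutoff is selected on its validation fold's disordered
residues by a grid search over thresholds 0.05, 0.10, …, 0.95
maximizing balanced accuracy, with ties broken toward the lower
threshold (favouring recall); a manual override reproduces externally
chosen cutoffs. A residue is called binding only when score > cutoff —
equality is non-binding. Inference uses either the single final fold
model with its own cutoff (default) or the 5-model ensemble (mean of raw
outputs, mean cutoff); two methods can also be merged by consensus
(element-wise mean score, cutoff re-selected on validation labels).

**CNN variant.** An experimental 1-D convolutional alternative (two
same-padded conv layers, input→128→32 channels, kernel 5, ReLU, per-
residue linear head) trains one protein per gradient step — convolutions
must not cross chain boundaries — and balances classes at the protein
level by over-sampling positive proteins. It exists for architecture
comparison; the FNN is the production model.

All networks and the optimizer are implemented in numpy with gradients
verified against numerical differentiation in the test suite.

## Evaluation

All confusion counts are computed **over disordered residues only**.
Residues outside IDPRs are trivially non-binding in this task, and
including them would reward order/disorder discrimination rather than
binding prediction. The seven measures (precision, recall, negative
precision, negative recall, balanced accuracy, F1, MCC) follow the
standard formulas; any measure with a zero denominator is *undefined*
and reported as NaN, never silently zero-filled.

**Bootstrap.** Disordered residues are pooled across proteins — so a
long protein does not weight the estimate more than a short one per
residue — and 1000 batches of 100 residues are drawn uniformly *with
replacement*. Each metric is computed per batch; undefined batch values
are excluded (with the exclusion count reported). The point estimate is
the mean of the defined batch values; the standard error is taken as
the population standard deviation of those batch values (the spread of
the bootstrap sampling distribution — deliberately not divided by √n),
and the 95% CI is ±1.96·SE. Methods whose CIs do not overlap differ
significantly; otherwise Welch's t-test (via `scipy.stats.ttest_ind`
with unequal variances) on the per-batch values decides.

**Baselines and region statistics.** The random baseline calls each
disordered residue binding independently with probability q = 0.388
(the training-corpus binding frequency); its expected recall is q and
its expected balanced accuracy 1/2, both verified by simulation.
`segment_regions` enumerates maximal runs of predicted binding and
reports mean/median run lengths, a useful check of spatial coherence
(curated binding regions are long: mean ≈ 74, median ≈ 41 residues).

## Synthetic data

The generator emulates the curated corpus statistics: log-normal protein
lengths with median 399; about half the proteins positive; contiguous
disorder regions (positives ≈ 50% disordered, negatives ≈ 30%, so
positive proteins carry more disorder, as in curated data); binding
stretches with log-normal lengths parameterized by mean 74 / median 41,
placed strictly inside disorder regions; and a global binding fraction
among disordered residues steered to 0.38 by proportional allocation of
the binding budget across positive proteins (with a scattered-residue
fallback only when a protein's regions cannot absorb its quota).
Because binding runs are truncated by their host disorder region
(median region length 60), realized run lengths are shorter than the
nominal distribution (median ≈ 27 in a typical corpus) while remaining
long, right-skewed stretches.

Embeddings are class-conditional Gaussians: isotropic noise of standard
deviation σ plus a mean shift of Δ·σ on the first k of m dimensions for
binding residues, optionally AR(1)-smoothed along the chain with
parameter ρ (the smoothing is applied to the noise before the shift, so
the class-conditional means stay exact and the lag-1 autocorrelation
equals ρ). A mean-shift signal was chosen over a learned manifold
because its separability is analytic (Mahalanobis distance √(k·Δ²)),
which lets test thresholds be derived rather than tuned. Sequences are
uniform over the 20 letters and, by default, embeddings do not depend on
residue identity — so a sequence-only baseline such as AAindex *cannot*
succeed on these fixtures, a deliberate negative control
(`identity_linked=True` switches on per-letter mean vectors when a
learnable sequence signal is wanted).

What passing tests therefore show: the pipeline recovers planted
mean-shift signal at the expected strength, is calibrated at chance on
null signal, and is deterministic end to end. What they do not show:
performance on real pLM embedding geometry (anisotropic, sequence-
correlated, non-Gaussian) or real IDPR composition biases; no claim
about real-data accuracy follows from the synthetic results.

## Problem sizes used in tests

The heavier checks use deliberately modest corpora chosen to exercise
the full pipeline: signal-recovery cross-validation runs on 200 proteins
with m = 64, k = 10, Δ ∈ {0, 2} and 64 hidden units; redundancy
post-condition audits use 30-record fixtures; bootstrap calibration uses
10⁵-residue label sets. These sizes give stable pass/fail behaviour at
the stated thresholds on a single CPU.

## Known limitations

* The aligner enumerates one optimal alignment; co-optimal alignments
  can differ in PIDE/length by small amounts, so the reduction is
  deterministic only given Biopython's internal tie-breaking (tests
  compare scores exactly and stats on the returned alignment).
* Greedy hub removal does not guarantee a maximum retained set, only a
  valid one (no violating pair survives).
* The CNN variant is a minimal reference implementation (no striding,
  no pooling, protein-level batching only) and is not tuned.
* `select_cutoff` assumes scores in [0, 1]; grids are fixed-step only.
* The bootstrap draws residues independently, ignoring within-protein
  correlation of predictions; CIs are therefore anti-conservative for
  strongly autocorrelated predictors.
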