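# Methods

## Alignments as images

A simulated sample is a `HaplotypeAlignment`: a binary matrix (rows =
chromosomes, columns = segregating sites, 0 = ancestral, 1 = derived) with
site positions scaled to [0, 1] over a locus of known physical length.
`msio` reads and writes the text dialect of ms-family simulators
(`//` replicate blocks, `segsites:`, `positions:`, 0/1 rows); positions
are printed with six decimals, so round trips are exact on alleles and
accurate to 5×10⁻⁷ on positions. Only biallelic 0/1 data are accepted;
multiallelic codes raise an error rather than being recoded.

`imageprep` turns an alignment into fixed-shape network inputs:

- **Encoding.** Alleles map to one of three pixel pairs: 0/1, 0/255
  (grayscale) or −1/1. All three are symbol bijections; decoding is exact.
- **Similarity sorting.** Chromosomes are reordered by greedy
  nearest-neighbour chaining: seed with input row 0, repeatedly append the
  unplaced row with minimum Hamming distance (L1 for real-valued
  read-fraction matrices) to the last placed row, ties to the lowest
  original index. The rule is deterministic and idempotent, and reduces
  the mean adjacent-row Hamming distance on random matrices. Greedy
  chaining was chosen as the simplest deterministic scheme consistent with
  "sorted by genetic similarity"; an optimal leaf ordering could differ.
  Sorting always precedes transposition, because it is defined on
  chromosomes (rows of the raw matrix). Two-species introgression inputs
  are *not* sorted: chromosomes stay grouped by species.
- **Padding and transposition.** The site dimension is right-padded to a
  fixed width W (the maximum segregating-site count over the data set)
  with the active encoding's ancestral symbol; an alignment wider than W
  is an error. With `transpose=True` the final orientation is sites ×
  chromosomes, so 1D filters slide along sites.
- **Positional features.** Either the raw position vector padded with −1
  to W, or the adjacent-gap vector d (dᵢ = posᵢ₊₁ − posᵢ, length W − 1,
  zero-padded — zero meaning "no gap").
- **Target transforms.** Regression responses are optionally
  natural-logged, then centred (and optionally z-scored) using statistics
  of the *training split only*, so validation/test information never leaks
  into the transform. ρ uses log + centring; demographic parameters use
  log + z-score per parameter.

## Simulated study conditions

All simulation runs through a pluggable engine; the reference engine is
msprime with continuous (infinite-sites) coordinates and a binary mutation
model, so sites are biallelic with known ancestral state. Haploid
chromosomes are sampled from diploid populations (`SampleSet(n, ploidy=1)`
under `ploidy=2`), giving the standard scaling θ = 4Nμ L and ρ = 4Nr L.
Everything is deterministic given a scenario and seed.

- **θ toy task**: constant-size panmictic locus, 40 chromosomes,
  θ ~ U(10, 50); 4,000 training, 500 validation, 1,000 test alignments.
- **Recombination**: 20-kb loci, 50 chromosomes (48 for the tetraploid
  variant), μ = 1.5×10⁻⁸, N uniform on {5, 10, 15, 20, 50}×10³ and r from
  an exponential with mean 10⁻⁷ truncated by rejection to [10⁻⁸, 10⁻⁶]
  (the truncation bounds are stated study conditions; the exponential mean
  is this package's choice, as no rate is printed). This gives ρ/bp in
  [2×10⁻⁴, 2×10⁻¹] and θ ∈ {6, 12, 18, 24, 60}. An interpolation test set
  draws N from the held-out {30, 35, 40, 45}×10³.
- **Autotetraploid reads**: 48 chromosomes are randomly partitioned into
  12 groups of 4; per site and individual the derived-allele dosage x ∈
  {0, ¼, ½, ¾, 1} parameterizes coverage C ~ Poisson(25) (zero draws
  redrawn, avoiding 0/0) and derived reads R ~ Binomial(C, x); the input
  is R/C. Homozygous dosages are exactly 0 or 1. No sequencing error and
  no per-site depth field are simulated.
- **Introgression**: two-species isolation-with-migration model, 20 + 14
  chromosomes, 10-kb windows, with an optional single pulse of gene flow
  (lineage movement backward in time) in one direction. The shipped
  parameter values (N₁ = 10⁵, N₂ = 5×10⁴, ancestral 10⁵, split 5×10⁵
  generations, pulse at 2.5×10⁴ generations moving 25% of lineages,
  μ = 2.5×10⁻⁹, r = 10⁻⁸) are *artifact defaults* sketched on a
  Drosophila-like pair — the original fitted model lives in prior work —
  and are user-replaceable via `IntrogressionModel`. The training split is
  deliberately imbalanced 107,500 : 107,500 : 7,500 (donor direction that
  proved easy is undersampled); validation and test are exactly balanced
  so accuracy estimates are unbiased.
- **Sweeps**: a 3-window region under a stepwise size history (default:
  10,000 → 2,000 at 2,000 generations → 14,000 at 5,000 generations, an
  artifact default sketching a bottlenecked human-like population);
  the focal middle window is cropped out and positions rescaled. The
  selected site (structured-coalescent sweep completing at sampling, s ~
  U(0.03, 0.1); soft sweeps start from a standing frequency U(0.05, 0.2))
  sits at the centre of the middle window for hard/soft, at the centre of
  a random flanking window for the linked classes, and is absent for
  neutral. The sweep machinery requires the selected phase to finish
  inside the most recent constant-size epoch; scenario draws that violate
  this are redrawn, and the lower bound on s keeps such draws rare.
  Replicates with more than 5,000 segregating sites are discarded.
  Training composition is rebalanced to ≈17% hard, 17% soft, 26.5%
  linked-hard, 26.5% linked-soft, 13% neutral; validation/test balanced.
- **Demography**: three-epoch histories (N₀ now, N₁ after T₁, N₂ beyond
  T₂; parameters drawn uniformly, times re-ordered so T₁ < T₂), 50
  chromosomes, region ≈1.5 Mb with r = 10⁻⁸ and mutation rate
  1.2×10⁻⁹ — i.e. 1.2×10⁻⁸ thinned tenfold to keep image widths
  tractable. The default ranges (sizes 10²–10⁵; T₁ up to 2×10⁴, T₂ up to
  4×10⁴ generations) are artifact defaults standing in for unpublished
  supplementary ranges.

Every dataset builder is reproducible from its seed, keeps train/
validation/test replicates disjoint by construction, and balances
validation/test classes exactly for classification tasks.

## Networks and training

`nets` declares architectures as data (`NetworkSpec`) and compiles them
against concrete input shapes. A network has an image branch
(convolutions + pooling), an optional positional branch (dense), and a
head applied to their concatenation. 1D filters have a kernel of k sites,
span all chromosomes (channels), and slide with stride 1; 2D filters are
square. The output of neuron j is f(Σᵢ wᵢⱼ xᵢ + bⱼ) with ReLU hidden
activations throughout. The per-task architectures:

- **Introgression** (input 1,201 × 34): conv 256/128/128 (kernel 2,
  average pooling, 25% dropout), dense 128 + 128 with 50% dropout, 3-unit
  **sigmoid** output trained with categorical cross-entropy exactly as
  published; probabilities are renormalized to sum to one (matching what
  the cross-entropy itself does), which leaves argmax decisions
  unchanged. 19 epochs, Adam, batch 256.
- **ρ, phased** (418 × 50 + positions): conv 1,250/256/256 (kernel 2,
  average pooling, 25% dropout, L2 10⁻⁴), positions → dense 64 (10%
  dropout), merge → dense 256 → linear unit; MSE loss on log-centred ρ,
  16 epochs, batch 32.
- **ρ, autotetraploid** (460 × 12): identical except the first
  convolution shrinks to 256 filters; 9 epochs.
- **Sweeps** (5,000 × 208 + positions): five conv layers of 256 (kernel
  2, average pooling, 20% dropout), positions → dense 64 (10%), merge →
  dense 256 (25% dropout), L2 10⁻⁴, 5-way softmax; 3 epochs, batch 32.
- **Demography** (image + distance vector): four conv layers of 128 (1D
  or 2D per hyperparameter point, same-padding so large kernels survive
  repeated pooling of the narrow chromosome axis), size-2 max pooling,
  distances → dense 32, merge → dense 256 → 5 linear outputs; optional
  25% dropout after each pooling step, the distance layer and the final
  dense layer; RMSE loss on z-scored (optionally logged) parameters; up
  to 10 epochs, batch 200.

Training uses mini-batch Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999 — conventional
defaults, none are published), Glorot-uniform initialization from a
recorded seed, per-epoch train/validation loss logging, and
best-on-validation model selection (the returned parameters are those of
the epoch with minimal validation loss). Dropout is inverted and active
only in training mode; evaluation is deterministic. Average-pooling
windows default to 2 wherever no size is printed. All gradients are
checked against central finite differences in the test suite. A non-finite
training loss aborts with diagnostics.

The hyperparameter grid (`hypersearch`) enumerates the full 160-point
factorial product — convolution dimensionality {1, 2} × kernel {2, 4, 6,
8, 10} × dropout {off, on} × sorting {off, on} × log targets {off, on} ×
encoding {−1/1, 0/255} — trains each point for up to ten epochs with one
seed derived from (master seed, point index), reports the minimum
validation RMSE per point, and summarizes axes with per-level medians and
two-sided Mann-Whitney U tests. For kernel size both a Spearman
correlation (the natural test for an ordered axis) and a smallest-vs-
largest Mann-Whitney comparison are reported, since the published analysis
quotes a U test for what reads as a correlation.

## Evaluation

`evalmetrics` computes pooled RMSE; R² as the coefficient of
determination 1 − SS_res/SS_tot (not squared Pearson — a biased estimator
scores lower even when well correlated); Spearman rank correlation with
average ranks per output dimension; row-normalized confusion matrices
with overall accuracy; exact Clopper–Pearson binomial confidence
intervals (verified to agree with R's `binom.test` to six decimals); and
a lowess-smoothed paired-comparison curve (tricube weights, one
robustness iteration, default span 15%) giving the probability that one
estimator beats another as a function of the true value.

## Profiles, problem sizes, and what desk runs show

Each task ships a `paper` preset carrying the published counts, epochs and
batch sizes, and a `desk` preset that keeps the same scenario
distributions, class compositions, preprocessing and topology but shrinks
simulation counts (θ toy 4,000/500/1,000 — already desk-sized; ρ
2,500/400/600; introgression 1,075/1,075/75 with balanced 150+200 per
class; sweeps 1,500 train with balanced 60/100 per class; demography
1,500/250/300 over narrower ranges and a 300-kb region) and layer widths
(e.g. 64-filter instead of 1,250-filter convolutions), so each task runs
in roughly half a minute to two minutes on one CPU. Two desk-specific
departures: the desk demography preset uses 0/1 pixels because 0/255
inputs converge far more slowly at small sample sizes (consistent with
the observation that encoding preferences can flip with training-set
size), and desk classification runs use smaller batches with more epochs
to reach a comparable number of optimizer updates.

Desk-scale results (seed 1): θ-toy RMSE 5.9 vs 11.5 for the constant-mean
baseline, with final-epoch input-layout ordering transposed+sorted (7.0) ≤
transposed (7.3) ≤ raw (11.2); ρ R² 0.66 (0.63 on interpolated population
sizes; 0.24 for the much harder tetraploid variant at 1,500 training
examples); introgression accuracy 90.5%; sweep accuracy 50.8% vs 20%
chance; demography z-scored RMSE 0.89 vs 1.0 for predicting the mean.
These desk numbers demonstrate learnability and correct wiring, not the
published full-scale accuracies, which require 10⁵–10⁶ simulations and
hours of GPU-friendly compute via the `paper` presets.

The simulated conditions omit several features of real data: no
sequencing error, missing genotypes, mispolarized ancestral states,
multiallelic sites, or variable per-site depth; introgression and sweep
parameter defaults are sketches rather than fitted histories; and a CNN
trained under one parameterization need not transfer to another. Passing
tests therefore certify the machinery and its calibration on the stated
simulation distributions, not performance on empirical genomes.

## Numerical choices

Float32 arithmetic throughout the engine (losses accumulated in float64);
convolution as sliding-window gather + matrix product; position padding
−1, distance padding 0, image padding with the ancestral symbol;
cross-entropy clips probabilities at 10⁻⁷; similarity-sort ties break to
the lowest original row index; uniform time draws for the three-epoch
model are re-ordered (not rejected) to enforce T₁ < T₂; zero-coverage
Poisson draws are redrawn; empty (zero-segsite) replicates are legal
alignments with empty matrices.
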