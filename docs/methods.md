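# Methods

## Window representation

A window is an N × W ternary SNP matrix (rows = haplotypes, columns =
loci; states ancestral `0`, derived `1`, missing `-1`) with
nondecreasing per-locus coordinates — fractional in [0, 1] for
simulator output, 1-based base pairs for VCF input.  It is collapsed to
a 2 × W feature matrix:

- **DAF row** — per locus, derived count over called (non-missing)
  count; a locus with no called alleles is an error.  The row is
  invariant to any permutation of sample rows and to the sample size.
- **Distance row** — `D_i = P_{i+1} − P_i`, with `D_{W−1} = 0`, so a
  window produces identical features wherever it sits on the
  chromosome (translation invariance).  Simulator coordinates are used
  as-is; base-pair coordinates should be divided by a region-span
  `scale` (exposed on `featurize` and stored in checkpoints) so train
  and scan scales match.

Centre windows cut W contiguous columns whose centre is nearest to
`n_snps / 2`, ties resolved to the lower start index:
`start = (n_snps − W + 1) // 2`.  Window indices are 0-based half-open;
base-pair output coordinates are 1-based inclusive (VCF convention).

## Classifier family and architecture search

The 1-D model is `n_layers` × [Conv1d(channels, kernel_width, stride,
"same" padding) → ReLU → MaxPool(width 2, stride 2)] → flatten → one
dense layer → 2 logits (softmax for probabilities).  "Same" padding
makes each conv stage output `ceil(w / stride)` and each pool stage
`floor(w / 2)`; a spec whose width would fall below one SNP is
infeasible and reported as such.  A standalone bookkeeping function
predicts every stage width and is asserted against the built network.

The search space is layers {2,3,4,5} × channels {8,16,32,64,80} ×
kernel {2,3,4} × stride {1,2,3} (180 candidates; 105 feasible at
W = 128).  The grid search trains every candidate once with a shared
seed and data order and ranks by best validation accuracy; ties break
toward fewer parameters, then fewer layers.  The shipped default
(`best_1d_spec()`) is the 3-layer / 80-channel / kernel-2 winner;
its stride is not uniquely determined by the selection procedure's
published summary, so stride 1 is the recorded default and the search
can re-derive the full tuple.  Head design (single dense layer), ReLU
nonlinearity, and the absence of dropout/batch-norm are deliberate
minimal choices; overfitting is handled by best-validation
checkpointing instead.

The 2-D reference classifiers consume the raw N × W allele image
(missing → 0.5) through a conv/pool trunk (default 3 layers, 32
channels, 3×3 kernels) and differ only in position fusion: none;
late (distances through a dense branch, default 32 units, concatenated
before the head); early (distances broadcast across rows as a second
input channel).  All trunk layer shapes are shared except the first
convolution's input-channel count.

Both families run on a small numpy layer engine written for this
package (1-D/2-D convolution, max pooling, dense, ReLU, Adam, softmax
cross-entropy) with explicit backpropagation; gradients are verified
against central finite differences in the test suite, and all
initialization and batching is driven by seeded generators, so training
is bitwise reproducible on a given machine.

## Training protocol

Mini-batches of 8, 100 epochs, Adam at learning rate 0.5e-3 (moment
defaults 0.9/0.999, eps 1e-8), cross-entropy loss.  After each epoch
validation accuracy is measured; the parameter state of the epoch with
the highest validation accuracy (earliest on ties — preferring the
state before the model overfits) becomes the checkpoint, and test
accuracy is computed once, on that checkpoint.  For raw-image models
the sample rows of every training window are re-shuffled each epoch as
augmentation; the 1-D pipeline is row-order invariant by construction
and needs none.  Repeated runs derive seeds as `seed + run_index` and
report mean/min/max with all per-run reports retained.

For the 2-D fusion models the distance vectors are divided by the
training-set mean distance before entering the network: raw fractional
distances in dense simulations are of order 1e-4, numerically invisible
next to 0/1 allele pixels at the modest training budgets used here.

## Simulation scenarios

Six scenarios pair a hard complete sweep (selection coefficient
s = 0.02, beneficial site at the region centre) with a confounding
demography, with a present-day population of N0 = 50 000 diploids;
scenario times are in coalescent units of 4·N0 generations and are
converted to generations for the engine (msprime 1.x):

| id | confounder | parameters |
|----|------------|------------|
| D1 | mild bottleneck | size 0.5·N0 during [0.1, 0.101], sweep fixed 0.016 ago |
| D2 | severe bottleneck | size 0.005·N0 during [0.01, 0.012], sweep 0.016 |
| D3 | recent divergence | two demes joining 0.003 ago, sweep 0.005 |
| D4 | old divergence | join 3 ago, sweep 0.005 |
| D5 | hotspot ×2 | central 5 kb at 2× recombination, θ = ρ = 2000, sweep 0.005 |
| D6 | hotspot ×20 | as D5 with 20× | 

θ/ρ and the region length are not part of the scenario definitions for
D1–D4; the committed configs use θ = ρ = 200 over 100 kb, chosen so
replicates comfortably exceed the 128-SNP window; they are marked as
package defaults in the YAML comments.  Replicates shorter than the
window are resimulated with a fresh derived seed (cap 10).

Sweeps use the engine's structured-coalescent sweep model as a model
sequence [standard coalescent for the time since fixation, sweep phase
from frequency 1 − 1/(2N0) down to 1/(2N0), standard coalescent], i.e.
"sweep start 0.016" is read as the time since fixation of the
beneficial allele.  The engine supports sweeps only in single-deme
models, so the two-deme scenarios are composed: each deme (64 + 64
haplotypes, each deme of size N0) is simulated independently back to
the join time — with the sweep inside the sampled deme when it
completes before the join, as in D4 — the lineages are merged
(`tskit.union`), and the ancestral population is continued, with the
sweep there when it postdates the join (D3).  Hotspots are a three-part
recombination rate map.  Mutations follow the infinite-sites binary
model (continuous coordinates), so every site is biallelic with derived
state 1; non-segregating sites are dropped.

Datasets follow the evaluation protocol: 1700 / 300 / 2000 windows for
train / val / test, each split exactly half neutral and half sweep,
128 haplotypes, 128-SNP centre windows.  Per-replicate seeds derive
deterministically from the dataset seed (split, index), so any single
window is reproducible in isolation.

**What the generator emulates, and what it does not.**  It reproduces
the window-level statistical signatures the classifier learns (verified
by rank tests in the suite): sweeps deplete SNP density near the centre
and push the SFS toward the frequency extremes; the severe bottleneck
suppresses diversity; old divergence inflates intermediate-frequency
variants.  It does not emulate empirical complications — genotyping
error, unpolarized or mispolarized alleles, variable missingness,
background selection, or realistic chromosome-scale rate maps — so
passing tests demonstrate correctness of the method under its model
assumptions, not field performance on real data.

## Binary window format

Little-endian throughout.  24-byte header (magic `SFWB`, version, mode
raw/daf, allele bits, W, N, window count) followed by fixed-size
records: RAW = W float32 inter-SNP distances then W bit-packed allele
columns (sample 0 in the least-significant bit, final partial byte
zero-padded; 2-bit codes 00 ancestral / 01 derived / 10 missing / 11
reserved when missing data are present); DAF = W float32 DAFs then W
float32 distances.  Payloads are `W·(4+⌈N/8⌉)` (raw, 1-bit) and `W·8`
(DAF, independent of N).  The format stores distances, not absolute
positions — reading a RAW file reconstructs positions accumulating from
zero, which is lossless for every downstream feature.  Truncation and
magic/version mismatches fail with byte offsets.

## Scanning

Windows are defined in SNP-index space (default width 128, step 32 —
the step is an exposed choice) so the model always sees fixed-width
inputs and SNP density travels in the distance channel.  With feature
reuse enabled, per-locus DAF and distance values are computed once per
chromosome and sliced per window; the result is bit-identical to the
per-window path.  Reuse inside the convolutions themselves (sharing
computation between overlapping windows) is enabled by the
representation's translation invariance but deliberately not
implemented.

## Desk-scale test design

The full protocol (1700/300/2000 windows × 100 epochs, 10 repeats,
full 180-cell search) runs for hours; the shipped suite uses reduced
budgets chosen to preserve each qualitative effect:

- D1 accuracy: 400/100/200 windows, 20 epochs (reaches ≥ 0.95).
- Scenario hardness: severe bottleneck (D2) and old divergence (D4)
  accuracy materially below D1 under identical budgets.
- Architecture ranking: subsampled grid (layers {2,3} × channels
  {16,80} × kernels {2,3}, stride 1) on 200 old-migration windows,
  3 seeds, 10 epochs: 3-layer/80-channel cells outrank
  2-layer/16-channel cells.
- Fusion ordering: low-intensity hotspot data at 32 haplotypes ×
  32-SNP windows, 400 training windows, 40 epochs, 3 runs per variant.
  At this scale the position-fusing models beat the no-fusion
  baseline; the early-versus-late gap is inside run-to-run noise (see
  limitations).
- Scan localization: a constant-size scenario with θ = ρ = 2000 and a
  recent sweep, where the sweep footprint covers only part of the
  region, so the top-probability window can be required to centre on
  the swept site in most replicates.

## Known limitations

- The numpy engine is single-threaded aside from BLAS; it is meant for
  correctness and desk-scale experiments, not production-scale training.
- Early fusion's advantage over late fusion — clear at full scale —
  does not reliably emerge at the reduced training sizes used in the
  suite: with few hundred windows the extra input channel lets the 2-D
  model memorize windows through their distance fingerprints (row
  shuffling never perturbs that channel), and the late variant's
  bottlenecked side branch is more data-efficient.  The suite therefore
  observes fusion ≥ no-fusion robustly, while early-vs-late ranking at
  desk scale fluctuates around equality.
- Two-deme sweeps assume the sweep completes within the sampled deme
  (D4) or the merged ancestral population (D3); sweeps overlapping the
  join time are not modeled.
- VCF polarization defaults to ALT = derived when no ancestral-allele
  tag is present (logged); mispolarization is not modeled or corrected.
- Hard complete sweeps only; no soft/partial sweep classes, no
  composite-likelihood site-level localization, no summary statistics.
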