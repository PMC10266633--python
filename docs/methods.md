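# Methods

## Observation model and the recalibration problem

A WGBS methylome is a set of per-CpG read counts (Meth_C, Unmeth_C); the
methylation level is m = Meth_C / (Meth_C + Unmeth_C), defined only when the
site has coverage. Symmetric CpG counts on the two strands are combined
(the − strand C at p+1 is added to the + strand C at p), and replicates are
combined by summing counts. At coverage c the observed level has binomial
standard error sqrt(m(1−m)/c); below c ≈ 4 it is close to useless for
downstream work. The recalibration model replaces the observed level at
such sites with a prediction from local sequence and the surrounding
methylation chain, and leaves all other sites untouched.

## Features

Per site, a 5 × 100 × 1 matrix:

* **Sequence rows (1–4).** The window is 101 bp — 50 bp on each side of the
  target C — which yields exactly 100 overlapping dinucleotides at step 1
  (a 100 bp window would yield 99). Each dinucleotide maps to its
  lexicographic index (A < C < G < T, index = 4·first + second) written as a
  big-endian 4-bit column, so AA → [0,0,0,0] and TT → [1,1,1,1]. A
  dinucleotide containing N produces an all-zero column; training sites
  with more than 10 such columns (10 % of the window) are dropped.
  The alternative one-hot scheme encodes the 100 non-center window bases
  with A → [0,0,0,1], C → [0,0,1,0], G → [0,1,0,0], T → [1,0,0,0], keeping
  the same shape; the scheme used at training time is recorded in the
  checkpoint and enforced at prediction time.
* **Chain row (5).** The observed levels of the 50 nearest *covered* CpGs
  strictly upstream and the 50 nearest strictly downstream, in genomic
  order, the target site always excluded (a leakage guard that is asserted
  in the tests). Uncovered CpGs are skipped rather than zero-filled, so the
  chain carries only real observations; where a chromosome edge leaves
  fewer than 50 neighbors, the outer entries are padded with 0.5, the
  maximally uninformative level.

## Network

Input (5, 100, 1) → conv 5×5 (128 filters, valid, stride 1, ReLU) →
max-pool 2 → conv 3×1 (128, ReLU) → max-pool 2 → conv 3×1 (128, ReLU) →
dense 2688 → 1280 (ReLU; a 10 × 1 × 128 representation of the 21 × 1 × 128
map) → dense 1280 → 1 (sigmoid). The first kernel is as tall as the input,
so after one convolution the map is one row high and the remaining
convolutions are one-dimensional. Pooling of size 2 after the first two
convolutions — and none after the third — is the only pooling arrangement
consistent with a 21-long pre-dense map; the first dense layer is realized
on the flattened map, which matches the 2688 → 1280 sizes literally. The
sigmoid output keeps predictions in [0, 1] and is differentiable at the
bounds, which a linear-plus-clipping head is not.

The network is implemented directly in numpy: convolutions are im2col
matrix products, gradients are hand-derived, and the optimizer is Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Weights use Glorot-uniform initialization
from a seeded generator and are stored in float32, which roughly halves
training time at no measurable cost in recalibration error; a float64 mode
exists and is used by the numerical gradient check in the tests. Everything
downstream of one integer seed — weight init, the validation split, batch
order — is deterministic, so identical runs produce byte-identical outputs.

## Training

* Targets: observed levels of sites whose coverage lies in [median, Q3] of
  the covered-site coverage distribution (nearest-rank percentiles,
  inclusive at both ends), sampled uniformly without replacement.
* Loss MSE; metric MAE; both recorded per epoch for the training and
  validation splits (default validation fraction 0.1, random split from the
  training seed) and exportable as a TSV and a plot.
* Learning rate 1e-3 with a linear warmup over the first 50 batches.
  The warmup is load-bearing: Adam's earliest updates move every parameter
  by a full learning-rate step (the second-moment estimate equals the
  squared first moment at t = 1), and with ~3.5 M parameters that first
  coherent step can throw the sigmoid output into saturation where MSE
  gradients vanish and training never recovers.
* Early stopping on validation MAE with patience 5 (defaults: max 50
  epochs, batch 128); the weights of the best validation epoch are kept.
  This replaces manual inspection of the loss curves with the standard
  automated equivalent.

## Downsampling and site selection

Sequencing at a fraction f of the original depth is emulated by binomial
thinning: retained methylated reads ~ Binomial(Meth_C, f) and likewise for
unmethylated reads, independently per site — the per-site equivalent of
retaining each aligned read independently with probability f. Read-pairing
effects are not modeled. Thinning composes as expected
(f₁ then f₂ ≈ f₁·f₂), never increases a count, and keeps counts integral.

"Low coverage" is coverage ≤ 3 (configurable), including zero-coverage
sites, which can be recovered from the genome's CpG inventory when a
reference is supplied.

## Evaluation

MAE = Σ|mᵢ − mᵢ′|/N and Pearson r with sample (n−1) standard deviations; a
constant vector makes r undefined and the pair is excluded with a logged
note. The headline comparison scores, per chromosome and pooled, both the
raw shallow levels and the recalibrated levels against a reference at
*eligible* sites: coverage ≤ 3 in the shallow data, coverage > 10 in the
deep/original data, at least one read in the shallow data (so the raw level
exists), and a defined reference level. Requiring ≥ 1 shallow read keeps
the raw and recalibrated errors on exactly the same site set. The reference
can be a simulator ground truth or a deep methylome's observed levels. The
depth-monotonicity check (raw error grows as the retained fraction falls)
drops the ≤ 3 filter — at 90 % retention of 50× data essentially no site is
that shallow — and evaluates all covered, well-referenced sites.

The feature-set comparison trains chain-only (sequence rows zeroed),
chain+one-hot and chain+2-mer networks on one split and scores them with
the untrained neighbor-average baseline on a disjoint test split drawn from
the same coverage band.

## Synthetic data

The generator produces the statistical structure the method exploits, with
every knob in `SimulationConfig`:

* genome: i.i.d. bases at background C+G 0.40 with non-overlapping islands
  (default one 1 kb island per 20 kb) at C+G 0.70 — island CpG density is
  then ~3× background;
* methylation: a two-state (M/U) Markov chain along consecutive CpGs with
  switch probability 0.02 per step (lag-1 level autocorrelation well above
  0.3), levels Beta(20, 2) in M and Beta(2, 20) in U (bimodal marginal,
  little mass near 0.5), and island CpGs forced to U with probability 0.9 —
  this is what makes sequence predictive;
* reads: coverage ~ Poisson(mean depth, default 50) and methylated count
  ~ Binomial(coverage, true level). The written CpG report splits each
  site's counts binomially between the two strands so strand merging is
  exercised on read-back.

What the simulator does not emulate: bisulfite conversion failure, mapping
bias, SNPs under CpGs, fragment-level (paired-read) correlation in
coverage, chromosome-scale domain structure, and real human sequence
composition. Passing tests therefore demonstrate that the implementation
recovers signal of the kind the method assumes — spatial correlation plus
sequence dependence — not that it attains any particular accuracy on real
ENCODE-scale methylomes.

## Problem sizes

The end-to-end experiments run on a 500 kb genome (~22,000 CpGs) at 50×,
downsampled to 20 % (~10× effective), training on 5,000 median–Q3 sites for
up to 15 epochs — small enough to run on a laptop CPU in a couple of
minutes while leaving ~200 eligible low-coverage sites for evaluation. On
that configuration the recalibrated MAE is about 0.08 against a raw 0.12
and a neighbor-average 0.25. Unit tests use an 8-filter variant of the
architecture; all shape-critical checks use the full 128-filter default.

## Known limitations

* Chain features are built from covered neighbors only; in extremely sparse
  data (mean depth ≪ 1) the chain degenerates toward the 0.5 pad and
  predictions fall back on sequence alone.
* Training targets are observed levels of moderately covered sites and thus
  carry binomial noise; the network fits the conditional mean, which is the
  intended behavior but caps the achievable MAE at the noise floor.
* The per-site binomial thinning equivalence to read-level downsampling is
  exact only for single-end, duplicate-free data.
* Checkpoints store raw weights; there is no architecture migration between
  package versions.
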