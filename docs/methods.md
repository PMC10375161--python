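# Methods

## The generation problem

Paired multiomics protocols (10x Multiome, SHARE-seq, SNARE-seq, CITE-seq)
measure two molecular layers in the same cells. `scmog` fits a
cross-modality map on such paired data and then applies it to cells measured
in only one layer, producing a hypothetical paired profile. The three maps —
expression → accessibility, accessibility → expression, expression → surface
protein — are trained separately, each as an encoder/decoder pair through a
16-dimensional per-cell latent code.

The central statistical assumptions are:

* a low-dimensional latent cell state is sufficient to predict each
  modality's systematic signal (16 dimensions by construction);
* scRNA-seq counts are negative-binomially distributed around a cell- and
  gene-specific mean, so generated expression is parameterised as (μ, θ) and
  scored by the NB likelihood;
* scATAC-seq is effectively binary per (cell, peak) and extremely
  0/1-imbalanced (a few percent accessible), so generation is a per-peak
  Bernoulli probability trained with focal loss rather than plain
  cross-entropy;
* CLR-transformed ADT counts are approximately Gaussian, so protein is
  generated on the CLR scale under squared error.

## Architectures

All networks are plain fully connected stacks, leaky-ReLU (negative slope
0.01) between layers, no batch normalisation and no dropout — their absence
makes every forward pass batch-independent and per-cell deterministic, which
the tests rely on. Widths:

| network | widths | output |
| --- | --- | --- |
| RNA encoder | genes, 256, 64, 16 | linear latent |
| ATAC encoder | peaks, 512, 64, 16 | linear latent |
| ATAC decoder | 16, 64, 512, peaks | sigmoid probability |
| RNA decoder | 16, 64, 256 → two heads 256→genes | μ = exp, θ = softplus |
| protein decoder | 16, 64, proteins | identity (CLR scale) |
| RNA/ATAC critic | features, 1024, 256, 64, 16, 1 | linear score |
| protein critic | proteins, 256, 64, 1 | linear score |

Initialisation is Xavier-uniform per layer with zero biases, except the ATAC
decoder's final bias, set to −2: a fresh decoder then predicts
σ(−2) ≈ 0.119 per peak, close to the sparse regime, which speeds up
convergence on imbalanced data. The NB dispersion is a full decoder head —
per gene *and* per cell — not a global per-gene parameter.

Numerical guards on the NB heads: the mean's log-argument is clipped to
[−30, ln 10⁶] (so μ ≤ 10⁶) and θ gets a 10⁻⁴ floor added to the softplus;
probabilities are clamped to [10⁻⁷, 1−10⁻⁷] before any logarithm.

The networks run on `scmog.nn`, a compact numpy feed-forward core (dense
layers, reverse-mode gradients, RMSProp and Adam) written for exactly these
architectures; float64 throughout.

## Losses

With p_t = p if y = 1 else 1 − p:

* binary cross-entropy: CE = −log p_t (mean over matrix elements);
* focal loss: FL = −α_t (1 − p_t)^γ log p_t, α_t = α for class 1 and 1 − α
  for class 0; defaults α = 0.93, γ = 2. With γ = 0 and weighting disabled
  (α_t ≡ 1) this is exactly CE, which the tests assert to machine precision.
* NB negative log-likelihood with stability constant ε (default 10⁻⁸):

  −θ[log(θ+ε) − log(θ+μ)] − x[log(μ+ε) − log(θ+μ)]
  − log Γ(x+θ) + log Γ(x+1) + log Γ(θ+ε)

  At ε = 0 this equals −log NB(x; μ, θ) exactly; the test suite verifies
  this against an independently written log-pmf and checks that the implied
  pmf sums to ≥ 0.999 over x ≤ 500. Real-valued x ≥ 0 is accepted (the
  factorial generalises through Γ), so size-normalised counts can serve as
  targets.
* Wasserstein critic objective: critic loss E[s_fake] − E[s_real],
  generator loss −E[s_fake]; the critic's unbounded score with weight
  clipping stands in for the optimal-transport formulation, per the standard
  WGAN construction.
* protein: mean squared error on the CLR scale.

All reconstruction losses reduce by the mean over matrix elements (the
source text does not state a reduction; the mean keeps loss magnitudes
comparable across feature dimensions).

## Preprocessing conventions

* Filter boundaries follow strict inequalities — "fewer than 200 genes",
  "more than 10% of cells" — so equality is always kept. A detected gene is
  a strictly positive count.
* RNA order: cell filter → sex-chromosome drop (genes on chrX/chrY;
  unannotated genes kept) → size normalisation to the median per-cell
  total → log1p → per-gene z-score. Standardisation uses the population std
  (ddof = 0, the common single-cell toolchain convention); zero-variance
  genes get std := 1 (their values become 0) instead of being dropped, so
  dimensionality is stable between fitting and inference. The fitted
  mean/std are stored in the model and replayed on new data.
* ATAC: prevalence filter (≥ 5 cells, ≤ 10% of cells) then binarisation
  (count > 0). Binarised peaks are also the encoder input.
* ADT: CLR with pseudocount 1 by default — ADT counts contain zeros and the
  geometric mean would otherwise vanish; each CLR row sums to 0 within
  10⁻⁹.
* Split: Leiden clustering of the processed RNA (neighbours graph on up to
  50 principal components, resolution 1.0, seeded). The largest cluster is
  the test set, the second largest validation, the rest train — fixed this
  way so runs are comparable. Fewer than 3 clusters triggers a random
  70/15/15 fallback with a warning (or an error if the fallback is
  disabled).

## Training procedure

Pre-training (phase 1): RMSProp on both critic and generator, 5 critic steps
(each followed by clipping every critic weight to ±0.01) per generator step,
10 epochs by default. The learning rate default is 2 × 10⁻³. The
conventional WGAN recipe value (5 × 10⁻⁵) is tuned for runs of 10⁵ or more
iterations; at this package's scale a pre-training phase is a few dozen
generator steps, where 5 × 10⁻⁵ moves parameters by ~10⁻² of a weight's
typical magnitude and the phase does nothing. 2 × 10⁻³ was chosen so the
phase demonstrably performs its function — the mean generated peak
probability moves from the 0.119 initialisation to near the data's true
base rate within the default 10 epochs (a property the test suite asserts)
— and is configurable like every other pre-training parameter. After phase
1 the critic is discarded.

Training (phase 2): Adam, learning rate 0.01, batch size 256, shuffled
batches per epoch (last partial batch kept), validation loss evaluated each
epoch. Early stopping: no relative improvement of at least 10⁻⁴ for 10
consecutive epochs ends training, and the best-validation checkpoint is
restored. Validation and test cells never contribute to a gradient step; a
test corrupts held-out targets with NaN and verifies training is bit-for-bit
unchanged. Any non-finite loss aborts with the epoch/batch in the message.
No gradient clipping and no learning-rate schedule are used.

Everything is driven by `numpy.random.default_rng` seeds carried in the
configs; a fixed seed makes simulation, preprocessing, splitting, training
and generation bit-reproducible (single-threaded).

## Generation and QC

Feature alignment at inference matches columns by feature id: features the
model knows but the input lacks are zero-filled, unknown input features are
dropped, and generation refuses to run when fewer than 50% of the model's
features are present. Outputs per direction: peak probabilities (binarised
at ≥ 0.1 — the boundary is inclusive by convention, fixed here since the
threshold's boundary semantics are otherwise unspecified), the NB mean μ as
the expression estimate (log1p and NB-sampling variants available), CLR
protein abundances. Generated-ATAC QC removes peaks present in < 10 cells
first, then cells with < 200 accessible peaks (the documented order; an
alternative order would change the counts, which is why the report records
both).

## Evaluation

AUROC (rank-based, midrank ties — computed with scikit-learn and verified in
tests against a brute-force pairwise-comparison oracle) for generated peaks
against the binarised measurement; Pearson correlation between
ln(1 + generated) and ln(1 + measured) for expression (natural log,
pseudocount 1 — fixed here); plain Pearson on the CLR scale for protein.
Headline numbers flatten the whole cells × features matrix; per-cell
distributions are reported separately because a global and a per-cell
average answer different questions, and both are labelled in reports.

## The simulator

`simulate_paired` draws a shared latent state per cell (one Gaussian
centroid per cell type, unit-variance noise, 16 dimensions, 4 types by
default) and maps it to all modalities:

* RNA: softplus link of latent × loadings, normalised per cell and scaled
  by a log-normal(0, 0.3) library-size factor times a base depth of 2,000;
  counts drawn NB with dispersion θ = 2 (gamma–Poisson).
* ATAC: Bernoulli through a sigmoid of latent × loadings plus per-peak
  offsets, with a global offset calibrated by root finding so the mean
  accessibility matches the target base rate (3% by default) — the extreme
  0/1 imbalance the focal loss exists for. Peak dimensionality (1,000)
  exceeds gene dimensionality (300).
* ADT: exponentiated linear readout of the latent with Gaussian noise
  (σ = 0.25), floored to integer counts; 8 proteins by default (17 when
  mimicking a CITE-seq panel).

Only a fraction of genes/peaks (0.3) load on the latent; setting that
fraction to 0 gives a negative control with no cell-type signal in any
modality. The default shape (2,000 × 300 × 1,000) is large enough for the
networks to learn from and small enough for minutes-scale CPU training.

What the simulator does *not* emulate: genomic coordinate structure and
peak–gene linkage by proximity, TF-motif structure, batch effects, doublets,
ambient contamination, and realistic numbers of features (a real experiment
has ~30k genes and ~100k peaks). Passing tests therefore demonstrate that
the machinery recovers a shared latent signal under the assumed noise
models at reduced scale — not that it matches any particular real-data
benchmark.

## The synthetic benchmark and its split

The held-out evaluation in `scripts/acceptance.py` and the acceptance test
uses a random 70/15/15 cell split. With only 4 discrete simulated
populations, the Leiden cluster-holdout split makes the test set an entire
population absent from training; on that task the achievable ceiling is low
regardless of the model (on the default data: correlating the *true*
simulated means with the measurements gives 0.73, heavily regularised ridge
regression reaches 0.60, and the translator saturates near 0.47 for
expression while peak AUROC stays above 0.80). Real paired datasets contain
dozens of subpopulations, so their held-out clusters remain surrounded by
related training cells — a regime the random held-out-cell split
approximates better at this scale. Both splits are first-class in the
package; the acceptance script reports the cluster-holdout numbers alongside
the primary ones so the gap is visible rather than hidden.

Problem sizes used by the test suite: unit tests run on 400-cell micro
simulations; the end-to-end study uses the simulator defaults (2,000 cells);
the pre-training ablation uses 800 cells × 150 genes × 400 peaks over seeds
{1, 2, 3} with 10 pre-training epochs, 12 training epochs and patience 5,
comparing mean best validation loss with and without the warm start.

## Known limitations

* The Wasserstein phase uses plain weight clipping (no gradient penalty),
  faithful to the original recipe but known to limit critic capacity.
* μ is returned as the expression estimate; sampling NB counts is available
  but the default output is a conditional mean, smoother than real data.
* The per-gene-per-cell dispersion head can absorb residual structure;
  with little training data this biases the model toward gene-mean
  solutions before cell-specific signal is learned.
* No batch correction, doublet handling or peak calling — inputs are
  assumed QC'd count matrices in Cell Ranger conventions, and peak ids are
  kept as `chr:start-end` strings without coordinate lift-over.
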