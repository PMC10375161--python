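# scmog

Cross-modality generation for paired single-cell multiomics: given cells
measured in one omics layer, generate the profile another layer would have
shown for the same cells. Three directions are supported:

* **rna2atac** — scATAC-seq peak profiles from scRNA-seq expression,
* **atac2rna** — scRNA-seq expression from scATAC-seq peaks,
* **rna2adt** — surface-protein (CITE-seq ADT) abundances from scRNA-seq.

It is aimed at analysts who have single-omics data (or unpaired multiomics)
and want a hypothetical paired view — e.g. peak profiles for an
scRNA-seq-only experiment — after fitting on a paired multiome, SHARE-seq,
SNARE-seq or CITE-seq dataset.

## Model

Each direction is an encoder/decoder pair over a shared 16-dimensional
per-cell latent code z:

```
RNA  encoder   x ∈ R^genes  → 256 → 64 → z ∈ R^16
ATAC encoder   x ∈ {0,1}^peaks → 512 → 64 → z
ATAC decoder   z → 64 → 512 → σ(·) ∈ (0,1)^peaks      (peak probabilities)
RNA  decoder   z → 64 → 256 → (μ, θ) via exp / softplus (NB mean, dispersion)
ADT  decoder   z → 64 → identity ∈ R^proteins          (CLR scale)
```

Hidden layers use leaky-ReLU; weights are Xavier-uniform; the ATAC decoder's
final bias starts at −2 so a fresh model already predicts the sparse regime
(σ(−2) ≈ 0.12 accessible).

Training has two phases. First an **adversarial warm start**: the generated
target profiles are played against the measured ones through a Wasserstein
critic (scores s, critic loss E[s_fake] − E[s_real], RMSProp with weight
clipping, several critic steps per generator step), which pulls the
generator's output distribution toward the measured one before any
reconstruction objective is seen; the critic is then discarded. Second,
**reconstruction training** with Adam (batch 256, lr 0.01) under the loss
matched to the target modality, early-stopped on validation loss:

* peaks (binary, heavily 0/1-imbalanced): focal loss
  FL(p_t) = −α_t (1 − p_t)^γ log p_t with α = 0.93, γ = 2;
* counts (overdispersed): negative-binomial negative log-likelihood in
  (μ, θ);
* protein (CLR-transformed, z_i = ln t_i − mean ln t): mean squared error.

Preprocessing follows the standard single-cell recipe: RNA cells filtered to
200–7000 detected genes (2500 for mouse), sex-chromosome genes dropped,
counts size-normalized to the median per-cell total, log1p, per-gene
z-scoring; ATAC peaks filtered to ≥5 cells and ≤10% of cells, then
binarized; ADT counts CLR-transformed per cell. The train/validation/test
split holds out whole Leiden clusters (largest → test, second → validation)
so test metrics reflect generalisation rather than neighbour lookup.

Generated peaks are binarized at probability ≥ 0.1 and quality-controlled
(peaks in <10 cells removed, then cells with <200 accessible peaks).
Benchmarks use AUROC for generated peaks and Pearson correlation of
log-scaled expression for generated RNA.

## Worked example

```python
import numpy as np

from scmog import (
    SyntheticSpec, simulate_paired,
    size_normalize, log_and_standardize, binarize_atac,
    TrainConfig, benchmark_report,
)
from scmog.networks import new_translator
from scmog.preprocessing import random_split
from scmog.training import fit_translator
from scmog.generation import generate, binarize_predictions, qc_generated_atac

# 1. paired scRNA-seq / scATAC-seq counts (here: simulated; readers for
#    10x MTX triplets and HDF5 are in scmog.io)
spec = SyntheticSpec(n_cells=1000, n_genes=200, n_peaks=500, seed=0)
paired, adt, truth = simulate_paired(spec)

# 2. modality-specific preprocessing and a train/validation/test split
rna = log_and_standardize(size_normalize(paired.primary))
atac = binarize_atac(paired.secondary)
split = random_split(spec.n_cells, seed=0)

# 3. two-phase training: adversarial warm start, then focal-loss training
model = new_translator("rna2atac", rna.feature_ids, atac.feature_ids, seed=0)
cfg = TrainConfig(seed=0)
cfg.train.max_epochs = 40
model, history = fit_translator(model, rna.values, atac.values, split, cfg)
print(f"best validation focal loss {history.best_val_loss():.5f} "
      f"at epoch {history.best_epoch}")

# 4. generate peak probabilities for held-out cells and score them
report = benchmark_report(model, rna, atac, split, partition="test")
print(f"held-out AUROC = {report.value:.3f} over {report.n_cells} cells "
      f"x {report.n_features} peaks")

# 5. binarize at the 0.1 threshold and QC the generated profiles
calls = binarize_predictions(generate(model, rna), threshold=0.1)
qc, qc_report = qc_generated_atac(calls, min_cells_per_peak=10,
                                  min_peaks_per_cell=10)
print(f"generated peak matrix after QC: {qc.values.shape[0]} cells x "
      f"{qc.values.shape[1]} peaks (removed {qc_report.removed})")
```

prints

```
best validation focal loss 0.00575 at epoch 20
held-out AUROC = 0.968 over 150 cells x 500 peaks
generated peak matrix after QC: 1000 cells x 283 peaks (removed {'peaks_below_min_cells': 217, 'cells_below_min_peaks': 0})
```

The AUROC is the probability that a randomly chosen truly-accessible
(cell, peak) entry receives a higher predicted probability than a randomly
chosen inaccessible one, over held-out cells the optimiser never saw. The
QC step removes generated peaks too rare to be trustworthy and cells left
with too few peaks (here none, at a cell threshold scaled to the 500-peak
toy panel).

The same workflow is available from the shell:

```sh
scmog --seed 0 simulate --n-cells 1000 --out data/
scmog --seed 0 split --rna data/rna --method leiden --out split.json
scmog --seed 0 train --source data/rna --target data/atac \
      --direction rna2atac --split split.json --out model.npz
scmog generate --model model.npz --input data/rna --out generated/
scmog evaluate --model model.npz --source data/rna --target data/atac \
      --split split.json --out report.json
```

Every subcommand writes a manifest (parameters + SHA-256 of inputs) next to
its output.

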