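import warnings

import numpy as np
import pytest

from scmog.preprocessing import (
    binarize_atac,
    clr_transform,
    log_and_standardize,
    random_split,
    size_normalize,
)
from scmog.synthetic import SyntheticSpec, make_fixture_suite, simulate_paired

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def fixtures():
    return make_fixture_suite()


@pytest.fixture(scope="session")
def tiny_paired():
    """A small simulated paired dataset shared by training-adjacent tests."""
    spec = SyntheticSpec(n_cells=400, n_genes=80, n_peaks=160, n_proteins=6, seed=11)
    paired, adt, truth = simulate_paired(spec)
    return spec, paired, adt, truth


@pytest.fixture(scope="session")
def tiny_processed(tiny_paired):
    spec, paired, adt, _ = tiny_paired
    rna_proc = log_and_standardize(size_normalize(paired.primary))
    rna_target = size_normalize(paired.primary)
    atac_bin = binarize_atac(paired.secondary)
    adt_clr = clr_transform(adt)
    split = random_split(spec.n_cells, seed=11)
    return {
        "rna_proc": rna_proc,
        "rna_target": rna_target,
        "atac_bin": atac_bin,
        "adt_clr": adt_clr,
        "split": split,
    }


@pytest.fixture(scope="session")
def tiny_trained_rna2atac(tiny_processed):
    """A briefly trained rna2atac translator for generation/evaluation tests."""
    from scmog.networks import new_translator
    from scmog.training import TrainConfig, fit_translator

    d = tiny_processed
    cfg = TrainConfig(seed=5)
    cfg.pretrain.epochs = 3
    cfg.train.max_epochs = 15
    cfg.train.early_stop_patience = 5
    model = new_translator(
        "rna2atac", d["rna_proc"].feature_ids, d["atac_bin"].feature_ids, seed=5
    )
    model, history = fit_translator(
        model, d["rna_proc"].values, d["atac_bin"].values, d["split"], cfg
    )
    return model, history


@pytest.fixture(scope="session")
def tiny_trained_atac2rna(tiny_processed):
    from scmog.networks import new_translator
    from scmog.training import TrainConfig, fit_translator

    d = tiny_processed
    cfg = TrainConfig(seed=6)
    cfg.pretrain.epochs = 3
    cfg.train.max_epochs = 15
    cfg.train.early_stop_patience = 5
    model = new_translator(
        "atac2rna", d["atac_bin"].feature_ids, d["rna_proc"].feature_ids, seed=6
    )
    model, history = fit_translator(
        model, d["atac_bin"].values, d["rna_target"].values, d["split"], cfg
    )
    return model, history
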