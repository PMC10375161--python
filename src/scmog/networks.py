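"""Encoder, decoder and critic architectures for the three modalities.

Every translator couples a modality-specific encoder to a 16-dimensional
per-cell latent code and a decoder for the target modality:

* RNA encoder      [n_genes, 256, 64, 16]
* ATAC encoder     [n_peaks, 512, 64, 16]
* ATAC decoder     [16, 64, 512, n_peaks], sigmoid output (peak probability),
  final-layer bias initialised to -2 so a fresh decoder already predicts the
  sparse regime (sigmoid(-2) ~ 0.12 accessible)
* RNA decoder      trunk [16, 64, 256] with two parallel heads 256 -> n_genes:
  mean = exp(linear), dispersion = softplus(linear) — the parameters of a
  per-gene, per-cell negative binomial
* protein decoder  [16, 64, n_proteins], identity output (CLR scale)
* critics          [n_features, 1024, 256, 64, 16, 1] (RNA/ATAC) and
  [n_proteins, 256, 64, 1] (protein), linear unbounded score

Hidden layers use leaky-ReLU; weights are Xavier-uniform; hidden biases are
zero.  Architectures are declared as :class:`NetworkSpec` values and realised
by :func:`build_network`.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from scmog import nn

LATENT_DIM = 16

#: exp-head clamp: mean capped at 1e6, softplus floor keeps dispersion > 0
MU_LOG_MAX = float(np.log(1e6))
MU_LOG_MIN = -30.0
THETA_EPS = 1e-4

DIRECTIONS = ("rna2atac", "atac2rna", "rna2adt")


@dataclass
class NetworkSpec:
    """Declarative description of one feed-forward network.

    ``layer_widths`` includes input and output widths.  For the ``nb_params``
    head the final width is realised as two parallel linear layers (mean and
    dispersion) from the last trunk width.
    """

    name: str
    layer_widths: list[int]
    output_head: str  # sigmoid | nb_params | identity | latent
    negative_slope: float = 0.01
    init: dict = field(default_factory=lambda: {"weights": "xavier_uniform", "final_bias": 0.0})

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.layer_widths):
            raise ValueError("layer widths must be positive")
        if self.output_head not in ("sigmoid", "nb_params", "identity", "latent"):
            raise ValueError(f"unknown output head {self.output_head!r}")
        if self.output_head == "latent" and self.layer_widths[-1] != LATENT_DIM:
            raise ValueError(f"encoder latent width must be {LATENT_DIM}")

    def n_parameters(self) -> int:
        widths = self.layer_widths
        n = sum((widths[i] + 1) * widths[i + 1] for i in range(len(widths) - 2))
        if self.output_head == "nb_params":
            n += 2 * (widths[-2] + 1) * widths[-1]
        else:
            n += (widths[-2] + 1) * widths[-1]
        return n


def make_rna_encoder(n_genes: int) -> NetworkSpec:
    return NetworkSpec("rna_encoder", [n_genes, 256, 64, LATENT_DIM], "latent")


def make_atac_encoder(n_peaks: int) -> NetworkSpec:
    return NetworkSpec("atac_encoder", [n_peaks, 512, 64, LATENT_DIM], "latent")


def make_atac_decoder(n_peaks: int) -> NetworkSpec:
    return NetworkSpec(
        "atac_decoder",
        [LATENT_DIM, 64, 512, n_peaks],
        "sigmoid",
        init={"weights": "xavier_uniform", "final_bias": -2.0},
    )


def make_rna_decoder(n_genes: int) -> NetworkSpec:
    return NetworkSpec("rna_decoder", [LATENT_DIM, 64, 256, n_genes], "nb_params")


def make_discriminator(n_features: int) -> NetworkSpec:
    return NetworkSpec(
        "discriminator", [n_features, 1024, 256, 64, LATENT_DIM, 1], "identity"
    )


def make_protein_decoder(n_proteins: int = 17) -> NetworkSpec:
    return NetworkSpec("protein_decoder", [LATENT_DIM, 64, n_proteins], "identity")


def make_protein_discriminator(n_proteins: int = 17) -> NetworkSpec:
    return NetworkSpec("protein_discriminator", [n_proteins, 256, 64, 1], "identity")


# ---------------------------------------------------------------------------
# realisation


class FeedForward:
    """A realised NetworkSpec with single output (sigmoid/identity/latent)."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        widths = spec.layer_widths
        layers: list = []
        for i in range(len(widths) - 1):
            layers.append(nn.Linear(widths[i], widths[i + 1]))
            last = i == len(widths) - 2
            if not last:
                layers.append(nn.LeakyReLU(spec.negative_slope))
            elif spec.output_head == "sigmoid":
                layers.append(nn.Sigmoid())
        self.net = nn.Sequential(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(np.asarray(x, dtype=float))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.net.backward(g)

    def parameters(self):
        return self.net.parameters()


class NBDecoder:
    """Trunk plus parallel exp-mean / softplus-dispersion heads.

    Outputs are clamped to a numerically safe range: the mean's log is
    clipped to [-30, log(1e6)] and a floor of 1e-4 is added to the
    dispersion, keeping both strictly positive.
    """

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        widths = spec.layer_widths
        layers: list = []
        for i in range(len(widths) - 2):
            layers.append(nn.Linear(widths[i], widths[i + 1]))
            layers.append(nn.LeakyReLU(spec.negative_slope))
        self.trunk = nn.Sequential(layers)
        self.mean_head = nn.Linear(widths[-2], widths[-1])
        self.disp_head = nn.Linear(widths[-2], widths[-1])
        self._zm: np.ndarray | None = None
        self._zt: np.ndarray | None = None
        self._mu: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = self.trunk.forward(np.asarray(x, dtype=float))
        self._zm = self.mean_head.forward(h)
        self._zt = self.disp_head.forward(h)
        self._mu = np.exp(np.clip(self._zm, MU_LOG_MIN, MU_LOG_MAX))
        theta = nn.softplus(self._zt) + THETA_EPS
        return self._mu, theta

    def backward(self, g_mu: np.ndarray, g_theta: np.ndarray) -> np.ndarray:
        in_range = (self._zm > MU_LOG_MIN) & (self._zm < MU_LOG_MAX)
        g_zm = g_mu * self._mu * in_range
        g_zt = g_theta / (1.0 + np.exp(-self._zt))  # d softplus = sigmoid
        g_h = self.mean_head.backward(g_zm) + self.disp_head.backward(g_zt)
        return self.trunk.backward(g_h)

    def parameters(self):
        return (
            self.trunk.parameters()
            + self.mean_head.parameters()
            + self.disp_head.parameters()
        )


def build_network(spec: NetworkSpec, rng: np.random.Generator | None = None):
    """Realise a NetworkSpec; parameters are zero unless ``rng`` is given,
    in which case :func:`initialize` is applied."""
    net = NBDecoder(spec) if spec.output_head == "nb_params" else FeedForward(spec)
    if rng is not None:
        initialize(net, rng)
    return net


def initialize(net, rng: np.random.Generator) -> None:
    """Xavier-uniform weights, zero biases; the spec's ``final_bias`` override
    (-2 for the ATAC decoder's last layer) is applied afterwards."""
    if isinstance(net, NBDecoder):
        linears = net.trunk.linears() + [net.mean_head, net.disp_head]
    else:
        linears = net.net.linears()
    for lin in linears:
        lin.init_xavier(rng)
    final_bias = net.spec.init.get("final_bias", 0.0)
    if final_bias and not isinstance(net, NBDecoder):
        net.net.linears()[-1].b[:] = final_bias


# ---------------------------------------------------------------------------
# translator model


@dataclass
class TranslatorModel:
    """A fitted encoder/decoder pair for one generation direction."""

    direction: str  # rna2atac | atac2rna | rna2adt
    encoder_spec: NetworkSpec
    decoder_spec: NetworkSpec
    encoder: object
    decoder: object
    source_features: list[str]
    target_features: list[str]
    preprocessing: dict = field(default_factory=dict)
    history: object | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.encoder_spec.layer_widths[0] != len(self.source_features):
            raise ValueError("encoder input width != number of source features")
        if self.decoder_spec.layer_widths[-1] != len(self.target_features):
            raise ValueError("decoder output width != number of target features")

    def forward(self, x: np.ndarray):
        return self.decoder.forward(self.encoder.forward(x))


def new_translator(
    direction: str,
    source_features: list[str],
    target_features: list[str],
    seed: int = 0,
    preprocessing: dict | None = None,
) -> TranslatorModel:
    """Build and initialise a fresh translator for one direction."""
    n_src, n_tgt = len(source_features), len(target_features)
    if direction == "rna2atac":
        enc, dec = make_rna_encoder(n_src), make_atac_decoder(n_tgt)
    elif direction == "atac2rna":
        enc, dec = make_atac_encoder(n_src), make_rna_decoder(n_tgt)
    elif direction == "rna2adt":
        enc, dec = make_rna_encoder(n_src), make_protein_decoder(n_tgt)
    else:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    rng = np.random.default_rng(seed)
    return TranslatorModel(
        direction=direction,
        encoder_spec=enc,
        decoder_spec=dec,
        encoder=build_network(enc, rng),
        decoder=build_network(dec, rng),
        source_features=list(source_features),
        target_features=list(target_features),
        preprocessing=preprocessing or {},
    )


def make_critic(direction: str, n_target_features: int, seed: int = 0):
    """The Wasserstein critic matched to a direction's target modality."""
    if direction == "rna2adt":
        spec = make_protein_discriminator(n_target_features)
    else:
        spec = make_discriminator(n_target_features)
    return build_network(spec, np.random.default_rng(seed))


def encode(model: TranslatorModel, x: np.ndarray) -> np.ndarray:
    """Map a processed source batch to 16-dimensional latent codes."""
    z = model.encoder.forward(np.asarray(x, dtype=float))
    return z


def decode(model: TranslatorModel, z: np.ndarray):
    """Map latent codes to the target modality's output (probabilities,
    (mean, dispersion), or CLR-scale abundances)."""
    return model.decoder.forward(np.asarray(z, dtype=float))


# ---------------------------------------------------------------------------
# serialisation


def _spec_to_dict(spec: NetworkSpec) -> dict:
    return asdict(spec)


def save_model(model: TranslatorModel, path: str | Path) -> None:
    """Single-file checkpoint: specs + feature lists + preprocessing stats as
    JSON, parameter tensors as npz arrays."""
    meta = {
        "direction": model.direction,
        "encoder_spec": _spec_to_dict(model.encoder_spec),
        "decoder_spec": _spec_to_dict(model.decoder_spec),
        "source_features": model.source_features,
        "target_features": model.target_features,
        "preprocessing": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in model.preprocessing.items()
        },
    }
    arrays = {
        f"enc_{i}": p for i, p in enumerate(nn.get_state(model.encoder))
    }
    arrays.update({f"dec_{i}": p for i, p in enumerate(nn.get_state(model.decoder))})
    with open(path, "wb") as fh:
        np.savez(fh, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> TranslatorModel:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta"]).decode())
        enc_state = [archive[f"enc_{i}"] for i in range(len([k for k in archive.files if k.startswith("enc_")]))]
        dec_state = [archive[f"dec_{i}"] for i in range(len([k for k in archive.files if k.startswith("dec_")]))]
    enc_spec = NetworkSpec(**meta["encoder_spec"])
    dec_spec = NetworkSpec(**meta["decoder_spec"])
    encoder = build_network(enc_spec)
    decoder = build_network(dec_spec)
    nn.set_state(encoder, enc_state)
    nn.set_state(decoder, dec_state)
    preproc = {
        k: (np.asarray(v) if isinstance(v, list) and v and isinstance(v[0], (int, float)) else v)
        for k, v in meta["preprocessing"].items()
    }
    return TranslatorModel(
        direction=meta["direction"],
        encoder_spec=enc_spec,
        decoder_spec=dec_spec,
        encoder=encoder,
        decoder=decoder,
        source_features=meta["source_features"],
        target_features=meta["target_features"],
        preprocessing=preproc,
    )
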