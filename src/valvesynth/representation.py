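"""Convolutional autoencoders for leaflet images (2D) and root volumes (3D).

Both autoencoders share one parameterized architecture.  The encoder stacks
``conv_layers`` blocks of [3(x3) convolution with ``filters`` channels,
ReLU, 2x(2x) average pooling], flattens, applies one fully connected ReLU
layer with as many units as the last pooling output, and projects linearly
onto a ``latent_dim``-dimensional bottleneck.  The decoder mirrors this:
one dense ReLU layer back to the last pooling size, a reshape, and per
level nearest-neighbour 2x upsampling followed by a convolution (ReLU
inside, linear at the output resolution).  Training minimizes the pixelwise
MSE with Adam; decoded images are clipped to [0, 1] only when reported.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .preprocess import LEAFLET_SHAPE, VOLUME_SHAPE

#: Hyperparameters found optimal for both autoencoders: three convolutional
#: blocks with 16 filters and a 20-dimensional latent space.
OPTIMAL_LEAFLET_SPEC: "AutoencoderSpec"
OPTIMAL_US_SPEC: "AutoencoderSpec"


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture hyperparameters of one autoencoder."""

    dims: str  # "2d" or "3d"
    conv_layers: int
    filters: int
    latent_dim: int
    input_shape: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.dims not in ("2d", "3d"):
            raise ValueError("dims must be '2d' or '3d'")
        if not self.input_shape:
            object.__setattr__(self, "input_shape",
                               LEAFLET_SHAPE if self.dims == "2d" else VOLUME_SHAPE)
        if self.conv_layers < 1:
            raise ValueError("conv_layers must be >= 1")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        div = 2 ** self.conv_layers
        if any(s % div for s in self.input_shape):
            raise ValueError(
                f"input extents {self.input_shape} must be divisible by 2^conv_layers={div}")

    @property
    def ndim(self) -> int:
        return 2 if self.dims == "2d" else 3

    @property
    def pooled_shape(self) -> tuple[int, ...]:
        div = 2 ** self.conv_layers
        return tuple(s // div for s in self.input_shape)

    @property
    def dense_units(self) -> int:
        """Units of the fully connected layer = outputs of the last pooling."""
        return int(np.prod(self.pooled_shape)) * self.filters


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol: Adam on MSE, batch 32, 100 epochs by default."""

    optimizer: str = "adam"
    loss: str = "mse"
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.optimizer != "adam" or self.loss != "mse":
            raise ValueError("only adam/mse training is implemented")


OPTIMAL_LEAFLET_SPEC = AutoencoderSpec("2d", conv_layers=3, filters=16, latent_dim=20)
OPTIMAL_US_SPEC = AutoencoderSpec("3d", conv_layers=3, filters=16, latent_dim=20)


@dataclass
class LatentCode:
    """A point in one of the learned latent spaces."""

    values: np.ndarray
    source: str = "leaflet"  # "leaflet" or "ultrasound"
    valve_id: str | None = None
    leaflet_type: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent values must be finite")
        if self.source not in ("leaflet", "ultrasound"):
            raise ValueError("source must be 'leaflet' or 'ultrasound'")

    def __len__(self) -> int:
        return len(self.values)


class Autoencoder:
    """Encoder/decoder pair built from one :class:`AutoencoderSpec`."""

    def __init__(self, spec: AutoencoderSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        nd = spec.ndim
        enc: list[nn.Layer] = []
        c_in = 1
        for _ in range(spec.conv_layers):
            enc.append(nn.Conv(nd, c_in, spec.filters, rng))
            enc.append(nn.AvgPool(nd))
            c_in = spec.filters
        enc.append(nn.Flatten())
        enc.append(nn.Dense(spec.dense_units, spec.dense_units, rng))
        enc.append(nn.Dense(spec.dense_units, spec.latent_dim, rng, activation="linear"))
        dec: list[nn.Layer] = [
            nn.Dense(spec.latent_dim, spec.dense_units, rng),
            nn.Reshape(spec.pooled_shape + (spec.filters,)),
        ]
        for level in range(spec.conv_layers):
            last = level == spec.conv_layers - 1
            dec.append(nn.Upsample(nd))
            dec.append(nn.Conv(nd, spec.filters, 1 if last else spec.filters, rng,
                               activation="linear" if last else "relu"))
        self._n_enc = len(enc)
        self.net = nn.Sequential(enc + dec)
        self.history: list[float] = []
        self.trained = False

    # -- helpers ---------------------------------------------------------
    def _with_channel(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float32)
        expected = self.spec.input_shape
        if batch.shape == expected:
            batch = batch[None]
        if batch.shape[1:] != expected:
            raise ValueError(f"expected samples of shape {expected}, got {batch.shape[1:]}")
        return batch[..., None]

    @property
    def encoder_layers(self) -> list[nn.Layer]:
        return self.net.layers[:self._n_enc]

    @property
    def decoder_layers(self) -> list[nn.Layer]:
        return self.net.layers[self._n_enc:]

    # -- public API ------------------------------------------------------
    def encode(self, batch: np.ndarray, chunk: int = 8) -> np.ndarray:
        """Encode samples to latent vectors; returns ``(n, latent_dim)``."""
        x = self._with_channel(batch)
        outs = []
        for start in range(0, len(x), chunk):
            h = x[start:start + chunk]
            for layer in self.encoder_layers:
                h = layer.forward(h)
            outs.append(h)
        return np.concatenate(outs, axis=0)

    def decode(self, codes: np.ndarray, clip: bool = True, chunk: int = 8) -> np.ndarray:
        """Decode latent vectors to images/volumes of the input shape."""
        codes = np.atleast_2d(np.asarray(codes, dtype=np.float32))
        if codes.shape[1] != self.spec.latent_dim:
            raise ValueError(
                f"expected codes of length {self.spec.latent_dim}, got {codes.shape[1]}")
        outs = []
        for start in range(0, len(codes), chunk):
            h = codes[start:start + chunk]
            for layer in self.decoder_layers:
                h = layer.forward(h)
            outs.append(h[..., 0])
        out = np.concatenate(outs, axis=0)
        return np.clip(out, 0.0, 1.0) if clip else out

    def reconstruct(self, batch: np.ndarray, clip: bool = True) -> np.ndarray:
        return self.decode(self.encode(batch), clip=clip)


def build_autoencoder(spec: AutoencoderSpec, seed: int = 0) -> Autoencoder:
    """Instantiate an untrained autoencoder for the given architecture."""
    return Autoencoder(spec, seed=seed)


def train_autoencoder(model: Autoencoder, images: np.ndarray,
                      config: TrainConfig | None = None,
                      chunk: int | None = None) -> list[float]:
    """Train in place on a stack of images/volumes; returns per-epoch loss."""
    config = config or TrainConfig()
    x = model._with_channel(images)
    if len(x) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    history = nn.train(model.net, x, x, epochs=config.epochs,
                       batch_size=config.batch_size, rng=rng,
                       lr=config.learning_rate,
                       chunk=chunk if chunk is not None else (2 if model.spec.ndim == 3 else 64))
    model.history.extend(history)
    model.trained = True
    return history


def median_latent(codes: list[LatentCode] | np.ndarray) -> np.ndarray:
    """Per-dimension median of a nonempty, homogeneous set of latent codes.

    For an even count the standard convention (mean of the two middle
    values per dimension) applies.
    """
    if isinstance(codes, np.ndarray):
        mat = np.atleast_2d(codes)
    else:
        if len(codes) == 0:
            raise ValueError("median of an empty code list is undefined")
        sources = {c.source for c in codes}
        if len(sources) > 1:
            raise ValueError(f"mixed latent sources {sources}")
        mat = np.stack([c.values for c in codes])
    if mat.size == 0:
        raise ValueError("median of an empty code list is undefined")
    return np.median(mat, axis=0)


DEFAULT_OFFSETS = (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5)


def explore_latent(model: Autoencoder, base: np.ndarray,
                   offsets: tuple[float, ...] = DEFAULT_OFFSETS,
                   dims: list[int] | None = None) -> np.ndarray:
    """Decode perturbations of a base code: one image per (dimension, offset).

    Returns an array of shape ``(len(dims), len(offsets), *input_shape)``;
    the zero offset is not part of the default grid.
    """
    base = np.asarray(base, dtype=np.float64).reshape(-1)
    if len(base) != model.spec.latent_dim:
        raise ValueError("base code length must equal the latent dimension")
    if dims is None:
        dims = list(range(model.spec.latent_dim))
    codes = []
    for d in dims:
        for o in offsets:
            c = base.copy()
            c[d] += o
            codes.append(c)
    decoded = model.decode(np.stack(codes))
    return decoded.reshape((len(dims), len(offsets)) + model.spec.input_shape)


def save_autoencoder(model: Autoencoder, path: str | Path) -> None:
    """Persist weights (.npz) plus a JSON sidecar with spec and seed."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), **model.net.state_dict())
    sidecar = {"spec": asdict(model.spec), "seed": model.seed,
               "trained": model.trained, "history": model.history}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_autoencoder(path: str | Path) -> Autoencoder:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec_d = dict(sidecar["spec"])
    spec_d["input_shape"] = tuple(spec_d["input_shape"])
    model = Autoencoder(AutoencoderSpec(**spec_d), seed=sidecar["seed"])
    with np.load(path.with_suffix(".npz")) as data:
        model.net.load_state_dict(dict(data))
    model.trained = sidecar["trained"]
    model.history = list(sidecar["history"])
    return model
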