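"""The two synthesis paths from a root volume to leaflet shape images.

*Shape estimation* regresses the leaflet latent code directly from the
volume with a VGG-style 3D CNN; *domain mapping* first encodes the volume
with the ultrasound autoencoder and then maps between the two latent
spaces with a random forest or an MLP.  In both paths three independent
predictors are trained, one per leaflet type (rc, lc, nc), sharing the
architecture but not the weights, and the predicted code is decoded with
the leaflet autoencoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor

from . import nn
from .preprocess import LEAFLET_TYPES, VOLUME_SHAPE, LeafletImage, RootVolume
from .representation import Autoencoder, TrainConfig

#: Optimal regression-CNN hyperparameters: four blocks of three
#: convolutions with 16 filters, one dense layer of 100 units.
OPTIMAL_REGRESSOR_SPEC: "RegressorSpec"
#: Optimal mapper hyperparameters: 200 trees (RF); 4x100 hidden units (MLP).
OPTIMAL_RF_SPEC: "MapperSpec"
OPTIMAL_MLP_SPEC: "MapperSpec"


@dataclass(frozen=True)
class RegressorSpec:
    """VGG-like 3D CNN: blocks of convolutions, pooling, dense head."""

    blocks: int
    convs_per_block: int
    filters: int
    dense_layers: int
    dense_units: int
    output_dim: int
    input_shape: tuple[int, int, int] = VOLUME_SHAPE

    def __post_init__(self) -> None:
        if min(self.blocks, self.convs_per_block, self.filters,
               self.dense_layers, self.dense_units, self.output_dim) < 1:
            raise ValueError("all regressor hyperparameters must be >= 1")
        div = 2 ** self.blocks
        if any(s % div for s in self.input_shape):
            raise ValueError(
                f"input extents {self.input_shape} must be divisible by 2^blocks={div}")

    @property
    def pooled_shape(self) -> tuple[int, ...]:
        div = 2 ** self.blocks
        return tuple(s // div for s in self.input_shape)


OPTIMAL_REGRESSOR_SPEC = RegressorSpec(blocks=4, convs_per_block=3, filters=16,
                                       dense_layers=1, dense_units=100, output_dim=20)


@dataclass(frozen=True)
class MapperSpec:
    """Latent-to-latent regressor: random forest or MLP."""

    method: str  # "rf" or "mlp"
    trees: int = 200
    hidden_layers: int = 4
    hidden_units: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("rf", "mlp"):
            raise ValueError("method must be 'rf' or 'mlp'")
        if self.method == "rf" and self.trees < 1:
            raise ValueError("rf needs trees >= 1")
        if self.method == "mlp" and (self.hidden_layers < 1 or self.hidden_units < 1):
            raise ValueError("mlp needs hidden_layers >= 1 and hidden_units >= 1")


OPTIMAL_RF_SPEC = MapperSpec("rf", trees=200)
OPTIMAL_MLP_SPEC = MapperSpec("mlp", hidden_layers=4, hidden_units=100)


def build_regression_cnn(spec: RegressorSpec, seed: int = 0) -> nn.Sequential:
    """Build the 3D regression CNN for 32x128x128 volume input.

    Each block: ``convs_per_block`` 3x3x3 convolutions (``filters``
    channels, ReLU) then 2x2x2 average pooling; head: ``dense_layers``
    ReLU layers of ``dense_units`` and a linear output of ``output_dim``.
    """
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_in = 1
    for _ in range(spec.blocks):
        for _ in range(spec.convs_per_block):
            layers.append(nn.Conv(3, c_in, spec.filters, rng))
            c_in = spec.filters
        layers.append(nn.AvgPool(3))
    layers.append(nn.Flatten())
    units_in = int(np.prod(spec.pooled_shape)) * spec.filters
    for _ in range(spec.dense_layers):
        layers.append(nn.Dense(units_in, spec.dense_units, rng))
        units_in = spec.dense_units
    layers.append(nn.Dense(units_in, spec.output_dim, rng, activation="linear"))
    return nn.Sequential(layers)


def _volume_batch(volumes) -> np.ndarray:
    arrs = [v.voxels if isinstance(v, RootVolume) else np.asarray(v, dtype=np.float32)
            for v in volumes]
    return np.stack(arrs)[..., None].astype(np.float32)


def fit_domain_mapper(spec: MapperSpec, z_us: np.ndarray, z_lf: np.ndarray,
                      standardize: bool = False):
    """Fit one latent-to-latent mapper on paired code matrices.

    Latent inputs are used unscaled by default (the bottlenecks are linear
    and unnormalized); ``standardize`` toggles z-scoring of the inputs.
    RF: ``trees`` estimators, unlimited depth, all features.  MLP: ReLU
    hidden layers, linear output, Adam, max 2000 iterations, tol 1e-6.
    """
    z_us = np.atleast_2d(np.asarray(z_us, dtype=np.float64))
    z_lf = np.atleast_2d(np.asarray(z_lf, dtype=np.float64))
    if len(z_us) != len(z_lf):
        raise ValueError(f"paired code lists differ in length: {len(z_us)} vs {len(z_lf)}")
    if spec.method == "rf":
        model = RandomForestRegressor(n_estimators=spec.trees, random_state=spec.seed)
    else:
        model = MLPRegressor(hidden_layer_sizes=(spec.hidden_units,) * spec.hidden_layers,
                             activation="relu", solver="adam", max_iter=2000,
                             tol=1e-6, random_state=spec.seed)
    mean = z_us.mean(axis=0) if standardize else np.zeros(z_us.shape[1])
    scale = np.where(z_us.std(axis=0) > 0, z_us.std(axis=0), 1.0) if standardize \
        else np.ones(z_us.shape[1])
    model.fit((z_us - mean) / scale, z_lf)
    return _Mapper(model=model, spec=spec, in_dim=z_us.shape[1],
                   out_dim=z_lf.shape[1], mean=mean, scale=scale)


@dataclass
class _Mapper:
    model: object
    spec: MapperSpec
    in_dim: int
    out_dim: int
    mean: np.ndarray
    scale: np.ndarray

    def predict(self, z_us: np.ndarray) -> np.ndarray:
        z_us = np.atleast_2d(np.asarray(z_us, dtype=np.float64))
        if z_us.shape[1] != self.in_dim:
            raise ValueError(f"expected codes of length {self.in_dim}, got {z_us.shape[1]}")
        out = self.model.predict((z_us - self.mean) / self.scale)
        return np.atleast_2d(out)


def map_latent(mapper: _Mapper, z_us: np.ndarray) -> np.ndarray:
    """Map ultrasound latent code(s) into the leaflet latent space."""
    return mapper.predict(z_us)


@dataclass
class SynthesisPipeline:
    """A fully specified volume-to-leaflets synthesis path.

    ``method`` is one of shape_estimation / domain_rf / domain_mlp;
    ``predictors`` maps each leaflet type to its trained per-type model
    (a CNN for shape estimation, a latent mapper otherwise).
    """

    method: str
    leaflet_ae: Autoencoder
    us_ae: Autoencoder | None = None
    predictors: dict = field(default_factory=dict)
    regressor_spec: RegressorSpec | None = None

    def __post_init__(self) -> None:
        if self.method not in ("shape_estimation", "domain_rf", "domain_mlp"):
            raise ValueError(f"unknown method {self.method!r}")

    def _check_trained(self) -> None:
        if not self.leaflet_ae.trained:
            raise RuntimeError("leaflet autoencoder is untrained")
        missing = [lt for lt in LEAFLET_TYPES if lt not in self.predictors]
        if missing:
            raise RuntimeError(f"missing trained predictor(s) for {missing}")
        if self.method.startswith("domain"):
            if self.us_ae is None or not self.us_ae.trained:
                raise RuntimeError("ultrasound autoencoder is untrained")


def train_shape_estimator(leaflet_ae: Autoencoder, spec: RegressorSpec,
                          volumes, leaflets_by_type: dict[str, np.ndarray],
                          config: TrainConfig | None = None,
                          types: tuple[str, ...] = LEAFLET_TYPES) -> SynthesisPipeline:
    """Train the three per-type regression CNNs against encoded leaflet targets.

    ``volumes`` and each entry of ``leaflets_by_type`` must be aligned by
    valve.  Targets are the latent codes of the ground-truth leaflets under
    the (already trained) leaflet autoencoder.
    """
    if not leaflet_ae.trained:
        raise RuntimeError("train the leaflet autoencoder first")
    config = config or TrainConfig()
    missing = [lt for lt in types if lt not in leaflets_by_type]
    if missing:
        raise ValueError(f"missing training leaflets for type(s) {missing}")
    x = _volume_batch(volumes)
    pipeline = SynthesisPipeline(method="shape_estimation", leaflet_ae=leaflet_ae,
                                 regressor_spec=spec)
    for i, lt in enumerate(types):
        targets = leaflet_ae.encode(np.asarray(leaflets_by_type[lt])).astype(np.float32)
        if len(targets) != len(x):
            raise ValueError(f"{lt}: {len(targets)} leaflets vs {len(x)} volumes")
        cnn = build_regression_cnn(spec, seed=config.seed * 31 + i)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 100 + i]))
        nn.train(cnn, x, targets, epochs=config.epochs, batch_size=config.batch_size,
                 rng=rng, lr=config.learning_rate, chunk=2)
        pipeline.predictors[lt] = cnn
    return pipeline


def train_domain_pipeline(leaflet_ae: Autoencoder, us_ae: Autoencoder,
                          mapper_spec: MapperSpec, volumes,
                          leaflets_by_type: dict[str, np.ndarray],
                          standardize: bool = False,
                          types: tuple[str, ...] = LEAFLET_TYPES) -> SynthesisPipeline:
    """Fit one latent mapper per leaflet type on encoded training pairs."""
    if not leaflet_ae.trained or not us_ae.trained:
        raise RuntimeError("train both autoencoders first")
    z_us = us_ae.encode(_volume_batch(volumes)[..., 0])
    pipeline = SynthesisPipeline(method=f"domain_{mapper_spec.method}",
                                 leaflet_ae=leaflet_ae, us_ae=us_ae)
    for i, lt in enumerate(types):
        z_lf = leaflet_ae.encode(np.asarray(leaflets_by_type[lt]))
        spec = MapperSpec(mapper_spec.method, trees=mapper_spec.trees,
                          hidden_layers=mapper_spec.hidden_layers,
                          hidden_units=mapper_spec.hidden_units,
                          seed=mapper_spec.seed * 31 + i)
        pipeline.predictors[lt] = fit_domain_mapper(spec, z_us, z_lf,
                                                    standardize=standardize)
    return pipeline


def predict_codes(pipeline: SynthesisPipeline, volumes) -> dict[str, np.ndarray]:
    """Predicted leaflet latent codes per type for a batch of volumes."""
    pipeline._check_trained()
    x = _volume_batch(volumes)
    out = {}
    if pipeline.method == "shape_estimation":
        for lt, cnn in pipeline.predictors.items():
            preds = [cnn.forward(x[i:i + 2]) for i in range(0, len(x), 2)]
            out[lt] = np.concatenate(preds, axis=0)
    else:
        z_us = pipeline.us_ae.encode(x[..., 0])
        for lt, mapper in pipeline.predictors.items():
            out[lt] = mapper.predict(z_us)
    return out


def synthesize(pipeline: SynthesisPipeline, volume: RootVolume) -> dict[str, LeafletImage]:
    """End-to-end synthesis: one volume in, three leaflet images out."""
    codes = predict_codes(pipeline, [volume])
    images = {}
    for lt in LEAFLET_TYPES:
        decoded = pipeline.leaflet_ae.decode(codes[lt])[0]
        images[lt] = LeafletImage(decoded.astype(np.float32), leaflet_type=lt,
                                  valve_id=volume.valve_id)
    return images
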