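"""Experimental harness: Monte-Carlo crossvalidation, hyperparameter grid
search, the five-method performance analysis, and distribution summaries.

Splits are drawn at the level of the valve, so a valve's volume and its
three leaflets always travel together; the auxiliary leaflet set (extra
leaflet images without volumes) joins autoencoder training folds only and
never any test set or predictor training.  Folds are independent random
80/20 draws rather than a partition.  Aggregates weight every predicted
leaflet equally ("sample-equal"); per-fold means are also exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as vmetrics
from .features import shape_features
from .prediction import (MapperSpec, OPTIMAL_MLP_SPEC, OPTIMAL_REGRESSOR_SPEC,
                         OPTIMAL_RF_SPEC, RegressorSpec, SynthesisPipeline,
                         build_regression_cnn, predict_codes,
                         train_domain_pipeline, train_shape_estimator)
from .preprocess import LEAFLET_TYPES, LeafletImage
from .representation import (Autoencoder, AutoencoderSpec, OPTIMAL_LEAFLET_SPEC,
                             OPTIMAL_US_SPEC, TrainConfig, build_autoencoder,
                             median_latent, train_autoencoder)
from .synthetic import ValveRecord

ALL_METHODS = ("reconstruction", "mean_baseline", "shape_estimation",
               "domain_rf", "domain_mlp")


@dataclass(frozen=True)
class SplitPlan:
    """Monte-Carlo crossvalidation plan over valve identifiers."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    fraction_train: float
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def monte_carlo_split(ids: list[str], n_folds: int = 10,
                      fraction_train: float = 0.8, seed: int = 0) -> SplitPlan:
    """Independent random train/test splits by valve, deterministic in seed.

    The per-fold test size is round-half-up of ``(1 - fraction_train) * n``;
    identical test sets across folds may occur by chance (folds are draws,
    not a partition).
    """
    ids = list(ids)
    n = len(ids)
    if n < 5:
        raise ValueError(f"need at least 5 ids to split, got {n}")
    if not 0 < fraction_train < 1:
        raise ValueError("fraction_train must lie in (0, 1)")
    test_size = int(np.floor((1.0 - fraction_train) * n + 0.5))
    test_size = min(max(test_size, 1), n - 1)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x59117]))
    folds = []
    for _ in range(n_folds):
        perm = rng.permutation(n)
        test = tuple(ids[i] for i in sorted(perm[:test_size]))
        train = tuple(ids[i] for i in sorted(perm[test_size:]))
        folds.append((train, test))
    return SplitPlan(folds=tuple(folds), fraction_train=fraction_train, seed=seed)


@dataclass
class GridResult:
    """Grid-search outcome: per-combination fold scores and the argmin."""

    table: pd.DataFrame  # columns: spec, mean, sd, n_params
    best: object

    def __post_init__(self) -> None:
        if len(self.table) == 0:
            raise ValueError("empty grid")


def _select_best(rows: list[dict]) -> object:
    """Minimal mean score; ties broken toward the smaller model."""
    frame = pd.DataFrame(rows)
    order = frame.sort_values(["mean", "n_params"], kind="stable")
    return order.iloc[0]["spec"]


@dataclass(frozen=True)
class ExperimentConfig:
    """All specs and training protocols of one evaluation run."""

    leaflet_spec: AutoencoderSpec = OPTIMAL_LEAFLET_SPEC
    us_spec: AutoencoderSpec = OPTIMAL_US_SPEC
    regressor_spec: RegressorSpec = OPTIMAL_REGRESSOR_SPEC
    rf_spec: MapperSpec = OPTIMAL_RF_SPEC
    mlp_spec: MapperSpec = OPTIMAL_MLP_SPEC
    leaflet_train: TrainConfig = TrainConfig()
    us_train: TrainConfig = TrainConfig()
    cnn_train: TrainConfig = TrainConfig()
    segmentation_threshold: float = 0.45


def _leaflet_stack(records: list[ValveRecord], ids, types=LEAFLET_TYPES) -> np.ndarray:
    by_id = {r.valve_id: r for r in records}
    return np.stack([by_id[i].leaflets[lt].pixels for i in ids for lt in types])


def _per_type(records: list[ValveRecord], ids) -> dict[str, np.ndarray]:
    by_id = {r.valve_id: r for r in records}
    return {lt: np.stack([by_id[i].leaflets[lt].pixels for i in ids])
            for lt in LEAFLET_TYPES}


def _volumes(records: list[ValveRecord], ids) -> np.ndarray:
    by_id = {r.valve_id: r for r in records}
    return np.stack([by_id[i].volume.voxels for i in ids])


def grid_search_autoencoder(grid: list[AutoencoderSpec], images: np.ndarray,
                            n_folds: int = 10, seed: int = 0,
                            config: TrainConfig | None = None,
                            aux_images: np.ndarray | None = None) -> GridResult:
    """Mean +- sd held-out reconstruction RMSE per architecture.

    ``aux_images`` (leaflets without volumes) are appended to every fold's
    training data and never scored.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    for spec in grid:
        AutoencoderSpec(spec.dims, spec.conv_layers, spec.filters,
                        spec.latent_dim, spec.input_shape)  # validate early
    config = config or TrainConfig()
    ids = [str(i) for i in range(len(images))]
    plan = monte_carlo_split(ids, n_folds=n_folds, seed=seed)
    rows = []
    for spec in grid:
        scores = []
        for f, (train_ids, test_ids) in enumerate(plan.folds):
            tr = images[[int(i) for i in train_ids]]
            if aux_images is not None and len(aux_images):
                tr = np.concatenate([tr, aux_images])
            te = images[[int(i) for i in test_ids]]
            model = build_autoencoder(spec, seed=seed + f)
            train_autoencoder(model, tr, replace(config, seed=config.seed + f))
            scores.append(vmetrics.rmse(model.reconstruct(te), te))
        model_size = build_autoencoder(spec, seed=0).net
        rows.append({"spec": spec, "mean": float(np.mean(scores)),
                     "sd": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
                     "n_params": model_size.n_params})
    return GridResult(table=pd.DataFrame(rows), best=_select_best(rows))


def grid_search_predictor(grid: list, dataset: list[ValveRecord],
                          config: ExperimentConfig | None = None,
                          n_folds: int = 10, seed: int = 0,
                          aux_images: np.ndarray | None = None) -> GridResult:
    """Latent-space RMSE per predictor architecture (CNN or mapper specs).

    Per fold the autoencoders are retrained with the fixed (optimal) specs,
    then every grid entry is fitted on the training codes and scored by the
    RMSE between predicted and true leaflet codes of the test valves.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    config = config or ExperimentConfig()
    is_cnn = isinstance(grid[0], RegressorSpec)
    for spec in grid:
        if isinstance(spec, RegressorSpec) and spec.output_dim != config.leaflet_spec.latent_dim:
            raise ValueError(
                f"predictor output dim {spec.output_dim} != leaflet latent dim "
                f"{config.leaflet_spec.latent_dim}")
    ids = [r.valve_id for r in dataset]
    plan = monte_carlo_split(ids, n_folds=n_folds, seed=seed)
    fold_ctx = []
    for f, (train_ids, test_ids) in enumerate(plan.folds):
        lf_ae = build_autoencoder(config.leaflet_spec, seed=seed + f)
        tr_leaflets = _leaflet_stack(dataset, train_ids)
        if aux_images is not None and len(aux_images):
            tr_leaflets = np.concatenate([tr_leaflets, aux_images])
        train_autoencoder(lf_ae, tr_leaflets,
                          replace(config.leaflet_train, seed=config.leaflet_train.seed + f))
        ctx = {"lf_ae": lf_ae, "train_ids": train_ids, "test_ids": test_ids, "fold": f}
        if not is_cnn:
            us_ae = build_autoencoder(config.us_spec, seed=seed + f)
            train_autoencoder(us_ae, _volumes(dataset, train_ids),
                              replace(config.us_train, seed=config.us_train.seed + f))
            ctx["us_ae"] = us_ae
        fold_ctx.append(ctx)
    rows = []
    for spec in grid:
        scores = []
        for ctx in fold_ctx:
            lf_ae = ctx["lf_ae"]
            tr_types = _per_type(dataset, ctx["train_ids"])
            te_types = _per_type(dataset, ctx["test_ids"])
            tr_vols = _volumes(dataset, ctx["train_ids"])
            te_vols = _volumes(dataset, ctx["test_ids"])
            if is_cnn:
                pipe = train_shape_estimator(
                    lf_ae, spec, tr_vols, tr_types,
                    replace(config.cnn_train, seed=config.cnn_train.seed + ctx["fold"]))
            else:
                pipe = train_domain_pipeline(lf_ae, ctx["us_ae"], spec, tr_vols, tr_types)
            pred = predict_codes(pipe, te_vols)
            errs = [vmetrics.rmse(pred[lt], lf_ae.encode(te_types[lt]))
                    for lt in LEAFLET_TYPES]
            scores.append(float(np.mean(errs)))
        if is_cnn:
            n_params = build_regression_cnn(spec, seed=0).n_params
        else:
            n_params = (spec.trees if spec.method == "rf"
                        else spec.hidden_layers * spec.hidden_units)
        rows.append({"spec": spec, "mean": float(np.mean(scores)),
                     "sd": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
                     "n_params": n_params})
    return GridResult(table=pd.DataFrame(rows), best=_select_best(rows))


@dataclass
class EvalReport:
    """Per-(fold, method, leaflet, valve) metric rows plus aggregations."""

    frame: pd.DataFrame
    #: optional predicted images keyed (method, valve_id, leaflet_type)
    predictions: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        """Mean +- sd per method over all folds and leaflet types."""
        cols = ["rmse", "jaccard", "hausdorff_px", "ascd_px"]
        g = self.frame.groupby("method")[cols]
        agg = g.agg(["mean", "std"])
        agg["n_failures"] = self.frame.groupby("method")["failure"].sum()
        return agg

    def per_type(self, metric: str = "ascd_px") -> pd.DataFrame:
        return (self.frame.groupby(["method", "leaflet_type"])[metric]
                .agg(["mean", "std"]).reset_index())

    def fold_means(self, method: str, metric: str = "ascd_px") -> pd.Series:
        sub = self.frame[self.frame["method"] == method]
        return sub.groupby("fold")[metric].mean()


def _evaluate_predictions(rows: list, fold: int, method: str, ids, per_type_pred,
                          truth: dict[str, np.ndarray], t: float) -> None:
    for lt in LEAFLET_TYPES:
        for i, vid in enumerate(ids):
            rep = vmetrics.compare_leaflets(per_type_pred[lt][i], truth[lt][i], t=t)
            rows.append({"fold": fold, "method": method, "leaflet_type": lt,
                         "valve_id": vid, "rmse": rep.rmse, "jaccard": rep.jaccard,
                         "hausdorff_px": rep.hausdorff_px, "ascd_px": rep.ascd_px,
                         "hausdorff_mm": rep.hausdorff_mm, "ascd_mm": rep.ascd_mm,
                         "failure": rep.failure})


def run_performance_analysis(dataset: list[ValveRecord],
                             methods: tuple[str, ...] = ALL_METHODS,
                             n_folds: int = 10, seed: int = 0,
                             config: ExperimentConfig | None = None,
                             aux_images: np.ndarray | None = None,
                             keep_predictions: bool = False) -> EvalReport:
    """Train and score the requested synthesis methods fold by fold.

    Per fold: the leaflet autoencoder is trained on the training leaflets
    (plus the auxiliary set), the method-specific predictors on the training
    valves only; test leaflets are synthesized, segmented at the configured
    threshold, and scored with RMSE, Jaccard, Hausdorff and ASCD against
    ground truth.  ``reconstruction`` propagates the ground-truth leaflet
    through the autoencoder; ``mean_baseline`` decodes the per-type median
    of the training codes for every test valve.
    """
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown method(s) {sorted(unknown)}")
    config = config or ExperimentConfig()
    ids = [r.valve_id for r in dataset]
    plan = monte_carlo_split(ids, n_folds=n_folds, seed=seed)
    t = config.segmentation_threshold
    rows: list[dict] = []
    predictions: dict = {}
    for f, (train_ids, test_ids) in enumerate(plan.folds):
        lf_ae = build_autoencoder(config.leaflet_spec, seed=seed + f)
        tr_leaflets = _leaflet_stack(dataset, train_ids)
        if aux_images is not None and len(aux_images):
            tr_leaflets = np.concatenate([tr_leaflets, aux_images])
        train_autoencoder(lf_ae, tr_leaflets,
                          replace(config.leaflet_train, seed=config.leaflet_train.seed + f))
        tr_types = _per_type(dataset, train_ids)
        te_types = _per_type(dataset, test_ids)
        tr_vols = _volumes(dataset, train_ids)
        te_vols = _volumes(dataset, test_ids)

        us_ae = None
        if any(m.startswith("domain") for m in methods):
            us_ae = build_autoencoder(config.us_spec, seed=seed + f)
            train_autoencoder(us_ae, tr_vols,
                              replace(config.us_train, seed=config.us_train.seed + f))

        for method in methods:
            if method == "reconstruction":
                pred = {lt: lf_ae.reconstruct(te_types[lt]) for lt in LEAFLET_TYPES}
            elif method == "mean_baseline":
                pred = {}
                for lt in LEAFLET_TYPES:
                    med = median_latent(lf_ae.encode(tr_types[lt]))
                    pred[lt] = np.repeat(lf_ae.decode(med[None])[0][None],
                                         len(test_ids), axis=0)
            elif method == "shape_estimation":
                pipe = train_shape_estimator(
                    lf_ae, config.regressor_spec, tr_vols, tr_types,
                    replace(config.cnn_train, seed=config.cnn_train.seed + f))
                codes = predict_codes(pipe, te_vols)
                pred = {lt: lf_ae.decode(codes[lt]) for lt in LEAFLET_TYPES}
            else:  # domain_rf / domain_mlp
                spec = config.rf_spec if method == "domain_rf" else config.mlp_spec
                pipe = train_domain_pipeline(lf_ae, us_ae, spec, tr_vols, tr_types)
                codes = predict_codes(pipe, te_vols)
                pred = {lt: lf_ae.decode(codes[lt]) for lt in LEAFLET_TYPES}
            _evaluate_predictions(rows, f, method, test_ids, pred, te_types, t)
            if keep_predictions:
                for lt in LEAFLET_TYPES:
                    for i, vid in enumerate(test_ids):
                        predictions[(method, vid, lt)] = pred[lt][i]
    return EvalReport(frame=pd.DataFrame(rows), predictions=predictions)


def distribution_summary(features: pd.DataFrame,
                         group_cols: tuple[str, ...] = ("leaflet_type", "source")
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shape-feature distribution and predicted-vs-true correlations.

    ``features`` needs columns leaflet_type, source ("true"/method name),
    valve_id, and the feature columns length/width/area.  Returns the
    per-group five-number+variance summary and a per-(method, feature)
    Pearson correlation table against the "true" rows (matched by valve and
    leaflet type).  Correlations are unit-invariant.
    """
    feat_cols = [c for c in ("length", "width", "area") if c in features.columns]
    if not feat_cols:
        raise ValueError("no feature columns (length/width/area) present")
    summary = (features.groupby(list(group_cols))[feat_cols]
               .agg(["median", lambda s: s.quantile(0.25), lambda s: s.quantile(0.75),
                     "min", "max", "var"]))
    summary.columns = [f"{feat}_{name}" for feat, name in
                       zip([c for c, _ in summary.columns],
                           ["median", "q1", "q3", "min", "max", "var"] * len(feat_cols))]
    truth = features[features["source"] == "true"]
    corr_rows = []
    for src, sub in features.groupby("source"):
        if src == "true":
            continue
        merged = sub.merge(truth, on=["valve_id", "leaflet_type"], suffixes=("", "_true"))
        for c in feat_cols:
            if merged[c].std() == 0 or merged[f"{c}_true"].std() == 0:
                r = float("nan")
            else:
                r = float(np.corrcoef(merged[c], merged[f"{c}_true"])[0, 1])
            corr_rows.append({"source": src, "feature": c, "pearson_r": r,
                              "n": len(merged)})
    return summary, pd.DataFrame(corr_rows)


def feature_frame(images_by_source: dict[str, dict[tuple[str, str], LeafletImage | np.ndarray]],
                  t: float = 0.45) -> pd.DataFrame:
    """Measure length/width/area for {source: {(valve_id, type): image}} nests."""
    rows = []
    for source, entries in images_by_source.items():
        for (vid, lt), img in entries.items():
            sf = shape_features(img, t=t)
            rows.append({"source": source, "valve_id": vid, "leaflet_type": lt,
                         "length": sf.length_px, "width": sf.width_px,
                         "area": sf.area_px})
    return pd.DataFrame(rows)


def tsne_embed(codes: np.ndarray, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """2D t-SNE embedding of latent codes (plot/inspection only)."""
    from sklearn.manifold import TSNE

    codes = np.atleast_2d(np.asarray(codes, dtype=np.float64))
    n = len(codes)
    if n < 5:
        raise ValueError(f"need at least 5 codes for an embedding, got {n}")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    if perplexity >= n:
        raise ValueError("perplexity must be smaller than the number of codes")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(codes)
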