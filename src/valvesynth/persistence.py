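"""Saving and loading trained synthesis pipelines.

A pipeline directory holds the autoencoder checkpoints, one file per
per-type predictor (``.npz`` weights for regression CNNs, joblib for the
sklearn mappers) and a ``pipeline.json`` manifest with the method, the
specs and the seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import joblib
import numpy as np

from .prediction import RegressorSpec, SynthesisPipeline, build_regression_cnn
from .preprocess import LEAFLET_TYPES
from .representation import load_autoencoder, save_autoencoder


def save_pipeline(pipeline: SynthesisPipeline, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"method": pipeline.method, "predictors": {}}
    save_autoencoder(pipeline.leaflet_ae, out / "leaflet_ae")
    if pipeline.us_ae is not None:
        save_autoencoder(pipeline.us_ae, out / "us_ae")
        manifest["has_us_ae"] = True
    for lt, predictor in pipeline.predictors.items():
        if pipeline.method == "shape_estimation":
            np.savez_compressed(out / f"predictor_{lt}.npz", **predictor.state_dict())
            manifest["predictors"][lt] = {"kind": "cnn",
                                          "spec": asdict(pipeline.regressor_spec)}
        else:
            joblib.dump(predictor, out / f"predictor_{lt}.joblib")
            manifest["predictors"][lt] = {"kind": "mapper",
                                          "spec": asdict(predictor.spec)}
    (out / "pipeline.json").write_text(json.dumps(manifest, indent=2))


def load_pipeline(in_dir: str | Path) -> SynthesisPipeline:
    src = Path(in_dir)
    manifest = json.loads((src / "pipeline.json").read_text())
    leaflet_ae = load_autoencoder(src / "leaflet_ae")
    us_ae = load_autoencoder(src / "us_ae") if manifest.get("has_us_ae") else None
    pipeline = SynthesisPipeline(method=manifest["method"], leaflet_ae=leaflet_ae,
                                 us_ae=us_ae)
    for lt in LEAFLET_TYPES:
        meta = manifest["predictors"][lt]
        if meta["kind"] == "cnn":
            spec_d = meta["spec"]
            spec_d["input_shape"] = tuple(spec_d["input_shape"])
            pipeline.regressor_spec = RegressorSpec(**spec_d)
            cnn = build_regression_cnn(pipeline.regressor_spec)
            with np.load(src / f"predictor_{lt}.npz") as data:
                cnn.load_state_dict(dict(data))
            pipeline.predictors[lt] = cnn
        else:
            pipeline.predictors[lt] = joblib.load(src / f"predictor_{lt}.joblib")
    return pipeline
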