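"""Readers and writers for the formats the pipeline touches.

Leaflet images travel as 8/16-bit grayscale PNG or TIFF, root volumes as
NIfTI (.nii/.nii.gz) or multi-page TIFF, latent codes as HDF5 (default) or
CSV, dataset manifests and metric tables as CSV, and run configuration as
YAML or JSON.  All readers rescale integer intensities into [0, 1] and all
writer/reader pairs round-trip losslessly at the container's precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import (LEAFLET_RESOLUTION_MM, LEAFLET_TYPES, VOLUME_SHAPE,
                         VOLUME_SPACING_MM, LeafletImage, RootVolume)
from .representation import LatentCode


@dataclass
class DatasetManifest:
    """Index of a paired dataset: per valve one volume and three leaflets."""

    records: list[dict]
    root: Path | None = None

    def __post_init__(self) -> None:
        ids = [r["valve_id"] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("valve_ids must be unique")
        for r in self.records:
            missing = [lt for lt in LEAFLET_TYPES if not r.get(lt)]
            if missing and not r.get("allow_missing", False):
                raise ValueError(f"valve {r['valve_id']} lacks leaflet(s) {missing}")

    @property
    def valve_ids(self) -> list[str]:
        return [r["valve_id"] for r in self.records]

    @property
    def n_leaflet_images(self) -> int:
        return sum(1 for r in self.records for lt in LEAFLET_TYPES if r.get(lt))


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    frame = pd.read_csv(path, dtype=str).fillna("")
    records = frame.to_dict("records")
    return DatasetManifest(records=records, root=path.parent)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    pd.DataFrame(manifest.records, columns=["valve_id", "volume", *LEAFLET_TYPES]) \
        .to_csv(path, index=False)


def read_leaflet_image(path: str | Path, resolution: float = LEAFLET_RESOLUTION_MM,
                       leaflet_type: str | None = None,
                       valve_id: str | None = None) -> LeafletImage:
    """Read a grayscale PNG/TIFF leaflet image, rescaled to [0, 1].

    RGB input is rejected: raw photographs go through
    ``preprocess.preprocess_leaflet`` first.
    """
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        raise ValueError(
            f"{path} is not grayscale; raw RGB photographs must be run through "
            "preprocess_leaflet first")
    if arr.dtype == np.uint8:
        pixels = arr.astype(np.float32) / 255.0
    elif arr.dtype == np.uint16:
        pixels = arr.astype(np.float32) / 65535.0
    else:
        pixels = np.clip(arr.astype(np.float32), 0.0, 1.0)
    return LeafletImage(pixels, leaflet_type=leaflet_type, valve_id=valve_id,
                        resolution=resolution)


def write_leaflet_image(image: LeafletImage, path: str | Path) -> None:
    """Write as 8-bit grayscale PNG/TIFF (values quantized to 1/255)."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.round(image.pixels * 255.0).astype(np.uint8))


def read_volume(path: str | Path, valve_id: str | None = None) -> RootVolume:
    """Read a 32x128x128 (slice, row, col) volume from NIfTI or TIFF stack."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        arr = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        spacing = tuple(float(z) for z in zooms)
    elif name.endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path)
        spacing = VOLUME_SPACING_MM
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    if arr.ndim != 3:
        raise ValueError(
            f"volume must be 3D with (slice, row, col) = {VOLUME_SHAPE}, got ndim={arr.ndim}")
    if arr.shape != VOLUME_SHAPE:
        raise ValueError(
            f"volume shape {arr.shape} does not match the (slice, row, col) "
            f"convention {VOLUME_SHAPE}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float32) / float(np.iinfo(arr.dtype).max)
    return RootVolume(arr.astype(np.float32), spacing=spacing, valve_id=valve_id)


def write_volume(volume: RootVolume, path: str | Path) -> None:
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), path)
    elif name.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, volume.voxels.astype(np.float32))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def save_latents(codes: list[LatentCode], path: str | Path) -> None:
    """Persist latent codes as an HDF5 (.h5) or CSV table.

    Columns: valve_id, leaflet_type, source, then one column per dimension.
    HDF5 round-trips exactly; CSV at full printed precision.
    """
    path = Path(path)
    lengths = {len(c) for c in codes}
    if len(lengths) > 1:
        raise ValueError(f"latent codes have mixed lengths {sorted(lengths)}")
    dim = lengths.pop() if lengths else 0
    ids = [c.valve_id or "" for c in codes]
    types = [c.leaflet_type or "" for c in codes]
    sources = [c.source for c in codes]
    mat = (np.stack([c.values for c in codes]) if codes
           else np.empty((0, dim)))
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=mat)
            str_dt = h5py.string_dtype()
            f.create_dataset("valve_id", data=ids, dtype=str_dt)
            f.create_dataset("leaflet_type", data=types, dtype=str_dt)
            f.create_dataset("source", data=sources, dtype=str_dt)
    elif path.suffix == ".csv":
        frame = pd.DataFrame(mat, columns=[f"z{i}" for i in range(mat.shape[1])])
        frame.insert(0, "source", sources)
        frame.insert(0, "leaflet_type", types)
        frame.insert(0, "valve_id", ids)
        frame.to_csv(path, index=False)  # default repr round-trips float64
    else:
        raise ValueError(f"unsupported latent format: {path.suffix}")


def load_latents(path: str | Path) -> list[LatentCode]:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            mat = f["values"][...]
            ids = [s.decode() for s in f["valve_id"][...]]
            types = [s.decode() for s in f["leaflet_type"][...]]
            sources = [s.decode() for s in f["source"][...]]
    else:
        frame = pd.read_csv(path, dtype={"valve_id": str, "leaflet_type": str,
                                         "source": str},
                            float_precision="round_trip").fillna("")
        zcols = [c for c in frame.columns if c.startswith("z")]
        mat = frame[zcols].to_numpy(dtype=np.float64)
        ids, types, sources = frame["valve_id"], frame["leaflet_type"], frame["source"]
    return [LatentCode(values=row, source=src or "leaflet",
                       valve_id=vid or None, leaflet_type=lt or None)
            for row, vid, lt, src in zip(mat, ids, types, sources)]


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dict, for run logging."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_dataset(manifest: DatasetManifest):
    """Materialize the records of an on-disk dataset into memory."""
    from .synthetic import ValveRecord

    root = manifest.root or Path(".")
    records = []
    for row in manifest.records:
        vol = read_volume(root / row["volume"], valve_id=row["valve_id"])
        leaflets = {lt: read_leaflet_image(root / row[lt], leaflet_type=lt,
                                           valve_id=row["valve_id"])
                    for lt in LEAFLET_TYPES if row.get(lt)}
        records.append(ValveRecord(valve_id=row["valve_id"], volume=vol,
                                   leaflets=leaflets))
    return records
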