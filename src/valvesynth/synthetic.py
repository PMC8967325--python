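"""Synthetic paired valve data with known ground truth.

Every record couples a root-like 3D volume (bright, speckled annular wall
around a dark lumen, zero outside the imaging field) with three planar
leaflet shape images (rc, lc, nc) whose geometric parameters derive from
the root parameters through a configurable noisy linear map.  The data is
emitted in the exact geometry the preprocessing pipeline produces
(128x64 leaflet images, 32x128x128 volumes, intensities in [0, 1],
volume gray values thresholded at 80/255), so every downstream stage can
be trained and validated with no external downloads and with recoverable
ground-truth parameters.

Rendering is a pure function of the parameters and seeds; the benchmark
generator is deterministic given (n_valves, coupling_strength, seed).

Simplifications relative to real data are deliberate and documented: the
speckle is additive Gaussian rather than Rayleigh, the leaflet family is a
two-parameter belly/edge model rather than a biological shape space, and
the coupling between root and leaflet geometry is linear by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import (LEAFLET_RESOLUTION_MM, LEAFLET_SHAPE, LEAFLET_TYPES,
                         VOLUME_GRAY_THRESHOLD, VOLUME_SHAPE, VOLUME_SPACING_MM,
                         LeafletImage, RootVolume, scale_to_unit, threshold_volume)


@dataclass(frozen=True)
class LeafletParams:
    """Geometric parameters of one rendered leaflet.

    ``width``/``height`` are in mm (height runs along the commissure axis,
    i.e. the image rows), ``belly_curvature`` in [0, 1] morphs the free
    boundary from straight tip-to-apex segments (0) to a half-ellipse (1),
    and ``asymmetry`` in [-0.3, 0.3] skews the apex toward one commissure.
    """

    width: float
    height: float
    belly_curvature: float
    asymmetry: float = 0.0
    leaflet_type: str = "rc"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if not 0 <= self.belly_curvature <= 1:
            raise ValueError("belly_curvature must lie in [0, 1]")
        if not -0.3 <= self.asymmetry <= 0.3:
            raise ValueError("asymmetry must lie in [-0.3, 0.3]")
        if self.leaflet_type not in LEAFLET_TYPES:
            raise ValueError(f"leaflet_type must be one of {LEAFLET_TYPES}")
        res = LEAFLET_RESOLUTION_MM
        if self.height > (LEAFLET_SHAPE[0] - 4) * res or self.width > (LEAFLET_SHAPE[1] - 4) * res:
            raise ValueError("leaflet does not fit the 128x64 frame with a 2-pixel margin")


@dataclass(frozen=True)
class RootParams:
    """Geometric/appearance parameters of one rendered root volume."""

    annulus_radius: float  # mm
    wall_thickness: float = 2.2  # mm
    root_height: float = 23.0  # mm
    speckle_sigma: float = 0.05  # intensity units
    tilt: float = 0.0  # degrees

    def __post_init__(self) -> None:
        if self.annulus_radius <= 0 or self.root_height <= 0:
            raise ValueError("annulus_radius and root_height must be positive")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be nonnegative")


#: Per-leaflet-type intercepts: the non-coronary leaflet is slightly smaller
#: and less variable, mimicking the qualitative spread of real valves.
_TYPE_OFFSETS = {"rc": (0.4, 1.2), "lc": (0.0, 0.6), "nc": (-0.6, -0.8)}


@dataclass(frozen=True)
class CouplingModel:
    """Noisy linear map from (annulus_radius, root_height) to leaflet geometry.

    width  = cw . (radius, height) + bw + type_offset_w + N(0, noise_sd_w)
    height = ch . (radius, height) + bh + type_offset_h + N(0, noise_sd_h)

    ``strength`` scales how tightly leaflet geometry follows the root:
    "strong" keeps the noise at about a third of the signal spread
    (R^2 around 0.9), "weak" triples it, and "none" ignores the root
    parameters entirely (leaflets drawn from the marginal distribution).
    """

    coef_width: tuple[float, float] = (0.9, 0.12)
    intercept_width: float = 0.1
    coef_height: tuple[float, float] = (1.6, 0.45)
    intercept_height: float = 1.0
    noise_sd_width: float = 0.35
    noise_sd_height: float = 0.7
    strength: str = "strong"

    def __post_init__(self) -> None:
        if self.strength not in ("strong", "weak", "none"):
            raise ValueError("strength must be 'strong', 'weak' or 'none'")
        if self.noise_sd_width < 0 or self.noise_sd_height < 0:
            raise ValueError("noise standard deviations must be nonnegative")

    def _noise_scale(self) -> float:
        return {"strong": 1.0, "weak": 3.0, "none": 0.0}[self.strength]

    def leaflet_params(self, root: RootParams, leaflet_type: str,
                       rng: np.random.Generator) -> LeafletParams:
        """Draw one leaflet's parameters given the root geometry."""
        ow, oh = _TYPE_OFFSETS[leaflet_type]
        if self.strength == "none":
            # marginal distribution, independent of this valve's root
            radius = float(np.clip(rng.normal(11.5, 1.2), 9.0, 14.0))
            height = float(np.clip(rng.normal(23.0, 2.5), 18.0, 28.0))
        else:
            radius, height = root.annulus_radius, root.root_height
        ns = self._noise_scale() if self.strength != "none" else 1.0
        w = (self.coef_width[0] * radius + self.coef_width[1] * height
             + self.intercept_width + ow + rng.normal(0.0, self.noise_sd_width * ns))
        h = (self.coef_height[0] * radius + self.coef_height[1] * height
             + self.intercept_height + oh + rng.normal(0.0, self.noise_sd_height * ns))
        # upper clips keep the centered shape inside the frame with margin
        w = float(np.clip(w, 8.0, 17.0))
        h = float(np.clip(h, 18.0, 40.0))
        belly = float(np.clip(0.30 + 0.018 * height + rng.normal(0.0, 0.05), 0.25, 0.95))
        asym = float(np.clip(rng.normal(0.0, 0.08), -0.25, 0.25))
        return LeafletParams(width=w, height=h, belly_curvature=belly,
                             asymmetry=asym, leaflet_type=leaflet_type)


@dataclass
class ValveRecord:
    """One synthetic valve: a volume, three leaflets, and their parameters."""

    valve_id: str
    volume: RootVolume
    leaflets: dict[str, LeafletImage]
    root_params: RootParams | None = None
    leaflet_params: dict[str, LeafletParams] = field(default_factory=dict)


def _belly_profile(u: np.ndarray, belly: float, asym: float) -> np.ndarray:
    """Chord fraction of the belly boundary at commissure-axis position u.

    u runs in [-1, 1] between the two commissure tips; the apex sits at
    u = asym.  belly interpolates between a triangular and an elliptic arc.
    """
    upper = np.clip((u - asym) / (1.0 - asym), 0.0, 1.0)
    lower = np.clip((asym - u) / (1.0 + asym), 0.0, 1.0)
    v = np.where(u >= asym, upper, lower)
    tri = 1.0 - v
    ell = np.sqrt(np.clip(1.0 - v * v, 0.0, None))
    return (1.0 - belly) * tri + belly * ell


def _shift_zero_fill(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Integer translation with zero fill; raises if foreground is lost."""
    fg = float(img.sum())
    out = np.zeros_like(img)
    rows, cols = img.shape
    rs, re = max(0, dr), min(rows, rows + dr)
    cs, ce = max(0, dc), min(cols, cols + dc)
    if rs < re and cs < ce:
        out[rs:re, cs:ce] = img[rs - dr:re - dr, cs - dc:ce - dc]
    if fg > 0 and abs(out.sum() - fg) > 1e-6 * fg:
        raise ValueError("leaflet does not fit the frame after centering")
    return out


def render_leaflet(params: LeafletParams, supersample: int = 4) -> LeafletImage:
    """Rasterize a leaflet: straight vertical commissure edge, curved belly.

    The region lies between a straight edge (the commissure-to-commissure
    line, along image rows) and the belly boundary at horizontal chord
    ``width * profile(u)``.  Interior intensities are smooth in (0.6, 1.0],
    the background is exactly 0; edge pixels are area-averaged over a
    ``supersample``-times finer grid.  The rendered shape is centered on its
    center of mass (whole-pixel translation).
    """
    res = LEAFLET_RESOLUTION_MM
    rows, cols = LEAFLET_SHAPE
    s = supersample
    # supersampled pixel centers in mm, origin at the image center
    rr = (np.arange(rows * s) + 0.5) / s - rows / 2.0
    cc = (np.arange(cols * s) + 0.5) / s - cols / 2.0
    r_mm = rr[:, None] * res
    c_mm = cc[None, :] * res

    h, w = params.height, params.width
    u = 2.0 * r_mm / h  # commissure-axis coordinate in [-1, 1] inside the shape
    chord = w * _belly_profile(u, params.belly_curvature, params.asymmetry)
    # straight edge placed so the shape straddles the image center
    edge = -w / 2.0
    inside = (np.abs(u) <= 1.0) & (c_mm >= edge) & (c_mm <= edge + chord)
    if not inside.any():
        raise ValueError("degenerate leaflet: rendered region is empty")
    # smooth interior shading, strictly above the 0.6 floor
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(chord > 0, (c_mm - edge) / np.where(chord > 0, chord, 1.0), 0.0)
    shade = 0.65 + 0.3 * np.sqrt(np.clip(1.0 - u * u, 0.0, None)) * (
        4.0 * np.clip(frac, 0.0, 1.0) * (1.0 - np.clip(frac, 0.0, 1.0)))
    hi = np.where(inside, shade, 0.0)
    img = hi.reshape(rows, s, cols, s).mean(axis=(1, 3))

    # whole-pixel center-of-mass centering (zero fill, never wraps)
    total = img.sum()
    com_r = float((img.sum(axis=1) * np.arange(rows)).sum() / total)
    com_c = float((img.sum(axis=0) * np.arange(cols)).sum() / total)
    img = _shift_zero_fill(img, int(round((rows - 1) / 2.0 - com_r)),
                           int(round((cols - 1) / 2.0 - com_c)))
    return LeafletImage(np.clip(img, 0.0, 1.0).astype(np.float32),
                        leaflet_type=params.leaflet_type)


def render_root_volume(params: RootParams, noise_seed: int = 0,
                       valve_id: str | None = None) -> RootVolume:
    """Rasterize a root-like volume: bright annular wall, speckle, thresholding.

    Per slice z the wall is a Gaussian-profile ring whose radius grows with
    depth at a rate set by ``root_height`` (taller roots flare more slowly)
    and whose center drifts with ``tilt``.  Additive clipped Gaussian
    speckle is applied inside the circular imaging field, then gray values
    run through the same threshold-at-80 and divide-by-255 steps as real
    volumes.
    """
    nz, nr, nc = VOLUME_SHAPE
    sz, sr, sc = VOLUME_SPACING_MM
    rng = np.random.default_rng(noise_seed)
    rows = (np.arange(nr) - (nr - 1) / 2.0) * sr
    cols = (np.arange(nc) - (nc - 1) / 2.0) * sc
    field_radius = 0.46 * min(nr * sr, nc * sc)
    cone = (rows[:, None] ** 2 + cols[None, :] ** 2) <= field_radius ** 2
    sigma_w = params.wall_thickness / 2.355  # FWHM -> Gaussian sigma, in mm
    vol = np.zeros(VOLUME_SHAPE, dtype=np.float64)
    tilt_slope = np.tan(np.radians(params.tilt))
    for z in range(nz):
        depth = z * sz
        radius = params.annulus_radius * (1.0 + 0.5 * depth / params.root_height)
        cr = depth * tilt_slope
        d = np.sqrt((rows[:, None] - cr) ** 2 + cols[None, :] ** 2)
        ring = 0.85 * np.exp(-0.5 * ((d - radius) / sigma_w) ** 2)
        if params.speckle_sigma > 0:
            ring = ring + rng.normal(0.0, params.speckle_sigma, size=ring.shape)
        vol[z] = np.clip(np.where(cone, ring, 0.0), 0.0, 1.0)
    gray = np.round(vol * 255.0)
    gray = threshold_volume(gray, t=VOLUME_GRAY_THRESHOLD)
    return RootVolume(scale_to_unit(gray), valve_id=valve_id)


@dataclass(frozen=True)
class RootPrior:
    """Sampling distribution of the root parameters (means, sds, clip ranges)."""

    radius_mean: float = 11.5
    radius_sd: float = 1.2
    radius_range: tuple[float, float] = (9.0, 14.0)
    height_mean: float = 23.0
    height_sd: float = 2.5
    height_range: tuple[float, float] = (18.0, 28.0)
    wall_mean: float = 2.2
    wall_sd: float = 0.25
    speckle_sigma: float = 0.05
    tilt_sd: float = 2.0

    def sample(self, rng: np.random.Generator) -> RootParams:
        return RootParams(
            annulus_radius=float(np.clip(rng.normal(self.radius_mean, self.radius_sd),
                                         *self.radius_range)),
            wall_thickness=float(np.clip(rng.normal(self.wall_mean, self.wall_sd), 1.2, 3.5)),
            root_height=float(np.clip(rng.normal(self.height_mean, self.height_sd),
                                      *self.height_range)),
            speckle_sigma=self.speckle_sigma,
            tilt=float(np.clip(rng.normal(0.0, self.tilt_sd), -6.0, 6.0)),
        )


def sample_valve(valve_id: str, seed: int, coupling: CouplingModel | None = None,
                 prior: RootPrior | None = None, max_retries: int = 10) -> ValveRecord:
    """Draw one valve: root parameters, coupled leaflet parameters, rendering."""
    coupling = coupling or CouplingModel()
    prior = prior or RootPrior()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA07]))
    for _ in range(max_retries):
        try:
            root = prior.sample(rng)
            leaflet_params = {lt: coupling.leaflet_params(root, lt, rng)
                              for lt in LEAFLET_TYPES}
            break
        except ValueError:
            continue
    else:
        raise ValueError(f"could not sample fitting parameters for valve {valve_id}")
    volume = render_root_volume(root, noise_seed=seed, valve_id=valve_id)
    leaflets = {}
    for lt in LEAFLET_TYPES:
        img = render_leaflet(leaflet_params[lt])
        leaflets[lt] = replace_ids(img, lt, valve_id)
    return ValveRecord(valve_id=valve_id, volume=volume, leaflets=leaflets,
                       root_params=root, leaflet_params=leaflet_params)


def replace_ids(img: LeafletImage, leaflet_type: str, valve_id: str) -> LeafletImage:
    return LeafletImage(img.pixels, leaflet_type=leaflet_type, valve_id=valve_id,
                        resolution=img.resolution)


def sample_dataset(n_valves: int, coupling_strength: str = "strong",
                   seed: int = 0, prior: RootPrior | None = None) -> list[ValveRecord]:
    """In-memory benchmark dataset: n_valves paired records, deterministic in
    (n_valves, coupling_strength, seed)."""
    if n_valves < 1:
        raise ValueError("n_valves must be >= 1")
    coupling = CouplingModel(strength=coupling_strength)
    child_seeds = np.random.SeedSequence([seed, 0xDA7A]).generate_state(n_valves)
    return [sample_valve(f"valve{i:03d}", int(s % (2 ** 31)), coupling, prior)
            for i, s in enumerate(child_seeds)]


def truth_table(records: list[ValveRecord]) -> pd.DataFrame:
    """Ground-truth parameter table: one root row + three leaflet rows per valve."""
    rows = []
    for rec in records:
        rp = rec.root_params
        rows.append({"valve_id": rec.valve_id, "kind": "root",
                     "leaflet_type": "", "annulus_radius": rp.annulus_radius,
                     "wall_thickness": rp.wall_thickness, "root_height": rp.root_height,
                     "speckle_sigma": rp.speckle_sigma, "tilt": rp.tilt})
        for lt, lp in rec.leaflet_params.items():
            rows.append({"valve_id": rec.valve_id, "kind": "leaflet",
                         "leaflet_type": lt, "width": lp.width, "height": lp.height,
                         "belly_curvature": lp.belly_curvature, "asymmetry": lp.asymmetry})
    return pd.DataFrame(rows)


def generate_benchmark(out_dir: str | Path, n_valves: int,
                       coupling_strength: str = "strong", seed: int = 0,
                       raw_mode: bool = False) -> "pd.DataFrame":
    """Write a complete on-disk dataset and return its manifest frame.

    Emits per valve one volume (.nii.gz) and three leaflet PNGs, plus
    ``manifest.csv`` (valve_id, volume, rc, lc, nc) and ``truth.csv``.
    ``raw_mode`` additionally perturbs each leaflet into an un-centered,
    rotated RGB photo (``raw_*.png``) to exercise the preprocessing stage.
    """
    from . import io as vio

    if n_valves < 10:
        raise ValueError("a benchmark needs at least 10 valves")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = sample_dataset(n_valves, coupling_strength, seed)
    manifest_rows = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBE9C]))
    for rec in records:
        vol_path = out / f"{rec.valve_id}_volume.nii.gz"
        vio.write_volume(rec.volume, vol_path)
        row = {"valve_id": rec.valve_id, "volume": vol_path.name}
        for lt, img in rec.leaflets.items():
            img_path = out / f"{rec.valve_id}_{lt}.png"
            vio.write_leaflet_image(img, img_path)
            row[lt] = img_path.name
            if raw_mode:
                _write_raw_photo(img, out / f"raw_{rec.valve_id}_{lt}.png", rng)
        manifest_rows.append(row)
    manifest = pd.DataFrame(manifest_rows, columns=["valve_id", "volume", *LEAFLET_TYPES])
    manifest.to_csv(out / "manifest.csv", index=False)
    truth_table(records).to_csv(out / "truth.csv", index=False)
    return manifest


def _write_raw_photo(img: LeafletImage, path: Path, rng: np.random.Generator) -> None:
    """Invert the preprocessing: offset, rotate and re-embed as an RGB photo."""
    from scipy import ndimage as ndi
    import imageio.v3 as iio

    angle = float(rng.uniform(-25, 25))
    rotated = ndi.rotate(img.pixels, angle, reshape=True, order=1, mode="constant")
    canvas = np.zeros((220, 160), dtype=np.float64)
    r0 = int(rng.integers(0, 220 - rotated.shape[0]))
    c0 = int(rng.integers(0, 160 - rotated.shape[1]))
    canvas[r0:r0 + rotated.shape[0], c0:c0 + rotated.shape[1]] = rotated
    inverted = np.clip(canvas, 0, 1) * 255.0
    photo = 255.0 - inverted  # bright plate, dark leaflet
    rgb = np.repeat(photo[..., None], 3, axis=2).astype(np.uint8)
    iio.imwrite(path, rgb)
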