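"""Synthetic paired bright-field / fluorescence microscopy frames.

Generates the kind of imagery a post-enrichment blood sample produces under a
20x bright-field scope: round, defocused-looking cells (dark rim, brighter
interior) of ~11.5 um mean diameter on a noisy mid-gray background with edge
vignetting, occasional touching pairs, small bright debris specks, and rare
very-bright outlier cells that defeat naive global thresholding.  Each frame
comes with a perfectly registered two-channel fluorescence frame (green =
WBC marker, red = CTC marker) and full ground truth, so segmentation, label
transfer and classification are all testable without real data.

Both classes share the same mean diameter; CTCs draw from a wider size
distribution and are rendered with a thicker/darker rim, brighter interior
and stronger interior texture — size alone does not separate the classes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .errors import FormatError, ParameterError, PlacementError

WBC = "WBC"
CTC = "CTC"
UNLABELED = "UNLABELED"

#: filenames used by write_pair / read_pair
_FILES = {
    "bright": "bright.png",
    "fluor_green": "fluor_green.png",
    "fluor_red": "fluor_red.png",
    "cells": "cells.csv",
    "manifest": "manifest.json",
}


@dataclass
class ClassAppearance:
    """Rendering profile for one cell class (intensity deltas vs. background)."""

    rim_depth_mean: float
    rim_depth_sd: float
    rim_width_px: float
    interior_gain_mean: float
    interior_gain_sd: float
    halo_amp: float
    texture_amp: float


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic scene; defaults define the study conditions."""

    shape: tuple[int, int] = (480, 640)
    pixel_scale_um: float = 0.46

    # size distributions (um); means shared, CTC spread wider
    wbc_diameter_mean_um: float = 11.5
    wbc_diameter_sd_um: float = 0.8
    ctc_diameter_mean_um: float = 11.5
    ctc_diameter_sd_um: float = 1.8
    truncate_sigma: float = 3.0

    # placement
    min_spacing_px: float = 26.0
    border_margin_px: float = 24.0
    touching_fraction: float = 0.10
    max_place_tries: int = 5000

    # scene
    background_level: float = 128.0
    noise_sd: float = 3.0
    vignette_strength: float = 0.12
    cloud_amp: float = 3.0
    cloud_sigma_px: float = 60.0
    n_debris: int = 12
    debris_amp: float = 70.0
    debris_sigma_px: float = 1.2

    # outlier-brightness cells (break naive global Otsu)
    very_bright_fraction: float = 0.05
    very_bright_level: float = 250.0

    # class appearance
    wbc_appearance: ClassAppearance = field(
        default_factory=lambda: ClassAppearance(
            rim_depth_mean=40.0, rim_depth_sd=4.0, rim_width_px=2.0,
            interior_gain_mean=8.0, interior_gain_sd=2.0,
            halo_amp=5.0, texture_amp=2.0))
    ctc_appearance: ClassAppearance = field(
        default_factory=lambda: ClassAppearance(
            rim_depth_mean=60.0, rim_depth_sd=5.0, rim_width_px=3.0,
            interior_gain_mean=26.0, interior_gain_sd=3.0,
            halo_amp=10.0, texture_amp=9.0))

    # fluorescence channels
    fluor_background: float = 10.0
    fluor_noise_sd: float = 2.0
    fluor_amp: float = 170.0


@dataclass
class SyntheticCell:
    """Ground-truth record for one rendered cell."""

    class_label: str                 # WBC or CTC
    center_rc: tuple[float, float]   # 0-based (row, col)
    diameter_um: float
    diameter_px: float
    intensity_profile: dict
    is_very_bright: bool = False

    def to_record(self) -> dict:
        d = dataclasses.asdict(self)
        d["center_rc"] = list(self.center_rc)
        return d

    @classmethod
    def from_record(cls, rec: dict) -> "SyntheticCell":
        rec = dict(rec)
        rec["center_rc"] = tuple(rec["center_rc"])
        return cls(**rec)


@dataclass
class FieldImagePair:
    """One bright-field frame plus its registered fluorescence channels."""

    bright: np.ndarray
    fluor_green: np.ndarray
    fluor_red: np.ndarray
    cells: list[SyntheticCell] = field(default_factory=list)
    pixel_scale_um: float = 0.46
    seed: int = 0
    frame_id: str = "frame0"

    def __post_init__(self) -> None:
        if not (self.bright.shape == self.fluor_green.shape == self.fluor_red.shape):
            raise FormatError(
                f"channel shape mismatch: bright {self.bright.shape}, "
                f"fluor_green {self.fluor_green.shape}, fluor_red {self.fluor_red.shape}")


def _truncnorm(mean: float, sd: float, nsig: float, n: int,
               rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    return stats.truncnorm.rvs(-nsig, nsig, loc=mean, scale=sd, size=n,
                               random_state=rng)


def sample_population(n_wbc: int, n_ctc: int,
                      params: GeneratorConfig | None = None,
                      seed: int = 0) -> list[SyntheticCell]:
    """Draw a cell population (classes, sizes, positions, appearance).

    WBC diameters come from a narrow truncated normal, CTC diameters from a
    wider one with the same mean.  Cells are placed by rejection sampling at
    ``min_spacing_px``; a configured fraction is deliberately placed touching
    a neighbor, and a configured fraction is flagged very-bright.
    Deterministic for a fixed seed.
    """
    if n_wbc < 0 or n_ctc < 0:
        raise ParameterError("cell counts must be non-negative")
    params = params or GeneratorConfig()
    rng = np.random.default_rng(seed)
    nrows, ncols = params.shape

    labels = [WBC] * n_wbc + [CTC] * n_ctc
    d_um = np.concatenate([
        _truncnorm(params.wbc_diameter_mean_um, params.wbc_diameter_sd_um,
                   params.truncate_sigma, n_wbc, rng),
        _truncnorm(params.ctc_diameter_mean_um, params.ctc_diameter_sd_um,
                   params.truncate_sigma, n_ctc, rng),
    ])

    margin = params.border_margin_px
    if labels and (nrows <= 2 * margin or ncols <= 2 * margin):
        raise PlacementError(
            f"frame {params.shape} too small for border margin {margin} px")

    centers: list[tuple[float, float]] = []
    cells: list[SyntheticCell] = []
    for i, lab in enumerate(labels):
        d_px = d_um[i] / params.pixel_scale_um
        touching = bool(centers) and rng.random() < params.touching_fraction
        placed = False
        for _ in range(params.max_place_tries):
            if touching:
                j = int(rng.integers(len(centers)))
                ang = rng.uniform(0, 2 * np.pi)
                dist = 0.95 * 0.5 * (d_px + cells[j].diameter_px)
                r = centers[j][0] + dist * np.sin(ang)
                c = centers[j][1] + dist * np.cos(ang)
                if not (margin <= r < nrows - margin and margin <= c < ncols - margin):
                    continue
                ok = all(np.hypot(r - cr, c - cc) >= 0.8 * dist
                         for k, (cr, cc) in enumerate(centers) if k != j)
            else:
                r = rng.uniform(margin, nrows - margin)
                c = rng.uniform(margin, ncols - margin)
                ok = all(np.hypot(r - cr, c - cc) >= params.min_spacing_px
                         for cr, cc in centers)
            if ok:
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {i + 1}/{len(labels)} after "
                f"{params.max_place_tries} tries (frame {params.shape}, "
                f"min spacing {params.min_spacing_px} px, margin {margin} px)")
        centers.append((r, c))

        app = params.ctc_appearance if lab == CTC else params.wbc_appearance
        very_bright = bool(rng.random() < params.very_bright_fraction)
        profile = {
            "rim_depth": float(rng.normal(app.rim_depth_mean, app.rim_depth_sd)),
            "rim_width_px": float(app.rim_width_px),
            "interior_gain": float(rng.normal(app.interior_gain_mean,
                                              app.interior_gain_sd)),
            "halo_amp": float(app.halo_amp),
            "texture_amp": float(app.texture_amp),
            "texture_seed": int(rng.integers(2 ** 31 - 1)),
        }
        cells.append(SyntheticCell(
            class_label=lab, center_rc=(float(r), float(c)),
            diameter_um=float(d_um[i]), diameter_px=float(d_px),
            intensity_profile=profile, is_very_bright=very_bright))
    return cells


def _render_cell(delta: np.ndarray, cell: SyntheticCell,
                 cfg: GeneratorConfig) -> None:
    """Add one cell's radial intensity profile into the delta image in place."""
    nrows, ncols = delta.shape
    prof = cell.intensity_profile
    R = cell.diameter_px / 2.0
    w = prof["rim_width_px"]
    halo_w = 2.0
    ext = int(np.ceil(R + halo_w + 2))
    r0c, c0c = cell.center_rc
    r0 = max(int(np.floor(r0c)) - ext, 0)
    r1 = min(int(np.ceil(r0c)) + ext + 1, nrows)
    c0 = max(int(np.floor(c0c)) - ext, 0)
    c1 = min(int(np.ceil(c0c)) + ext + 1, ncols)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    rad = np.hypot(rr - r0c, cc - c0c)

    interior_gain = (cfg.very_bright_level - cfg.background_level
                     if cell.is_very_bright else prof["interior_gain"])
    patch = np.zeros_like(rad)
    inner = rad < R - w
    rim = (rad >= R - w) & (rad <= R)
    halo = (rad > R) & (rad <= R + halo_w)
    patch[inner] = interior_gain
    t = (rad[rim] - (R - w)) / max(w, 1e-9)
    patch[rim] = interior_gain * (1 - t) - prof["rim_depth"] * np.sin(np.pi * t)
    patch[halo] = prof["halo_amp"] * (1 - (rad[halo] - R) / halo_w)

    if prof["texture_amp"] > 0 and not cell.is_very_bright:
        trng = np.random.default_rng(prof["texture_seed"])
        tex = ndi.gaussian_filter(trng.standard_normal(rad.shape), 1.5)
        sd = tex.std()
        if sd > 0:
            patch[inner] += prof["texture_amp"] * tex[inner] / sd
    delta[r0:r1, c0:c1] += patch


def render_pair(cells: list[SyntheticCell],
                params: GeneratorConfig | None = None,
                seed: int = 0, frame_id: str = "frame0") -> FieldImagePair:
    """Render a population into a bright-field + fluorescence image pair.

    Bright field: mid-gray background x radial vignette x low-frequency
    "cloud" field, Gaussian pixel noise, per-cell dark-rim/bright-interior
    profile (very-bright cells near saturation) and small bright debris
    specks.  Fluorescence: Gaussian blobs at cell centers, routed to the
    channel of the cell's class only.  Deterministic for a fixed seed.
    """
    params = params or GeneratorConfig()
    rng = np.random.default_rng(seed)
    nrows, ncols = params.shape

    rr, cc = np.mgrid[0:nrows, 0:ncols].astype(float)
    d2 = ((rr - nrows / 2) / (nrows / 2)) ** 2 + ((cc - ncols / 2) / (ncols / 2)) ** 2
    vignette = 1.0 - params.vignette_strength * d2 / 2.0
    cloud = ndi.gaussian_filter(rng.standard_normal((nrows, ncols)),
                                params.cloud_sigma_px)
    if cloud.std() > 0:
        cloud = cloud / cloud.std() * params.cloud_amp
    bright = params.background_level * vignette + cloud
    bright += rng.normal(0.0, params.noise_sd, size=(nrows, ncols))

    delta = np.zeros((nrows, ncols))
    for cell in cells:
        r, c = cell.center_rc
        if not (0 <= r < nrows and 0 <= c < ncols):
            raise ParameterError(f"cell center {cell.center_rc} outside frame")
        _render_cell(delta, cell, params)
    bright += delta

    for _ in range(params.n_debris):
        r = rng.uniform(0, nrows)
        c = rng.uniform(0, ncols)
        ext = int(np.ceil(3 * params.debris_sigma_px))
        rs = slice(max(int(r) - ext, 0), min(int(r) + ext + 1, nrows))
        cs = slice(max(int(c) - ext, 0), min(int(c) + ext + 1, ncols))
        grr, gcc = np.mgrid[rs, cs]
        bright[rs, cs] += params.debris_amp * np.exp(
            -((grr - r) ** 2 + (gcc - c) ** 2) / (2 * params.debris_sigma_px ** 2))

    def fluor_channel(cls: str) -> np.ndarray:
        ch = params.fluor_background + rng.normal(
            0.0, params.fluor_noise_sd, size=(nrows, ncols))
        for cell in cells:
            if cell.class_label != cls:
                continue
            r0c, c0c = cell.center_rc
            sig = cell.diameter_px / 4.0
            ext = int(np.ceil(3 * sig)) + 1
            rs = slice(max(int(r0c) - ext, 0), min(int(r0c) + ext + 1, nrows))
            cs = slice(max(int(c0c) - ext, 0), min(int(c0c) + ext + 1, ncols))
            grr, gcc = np.mgrid[rs, cs]
            ch[rs, cs] += params.fluor_amp * np.exp(
                -((grr - r0c) ** 2 + (gcc - c0c) ** 2) / (2 * sig ** 2))
        return np.clip(ch, 0, 255).astype(np.uint8)

    # channel order fixed (green then red) so noise draws are reproducible
    green = fluor_channel(WBC)
    red = fluor_channel(CTC)
    return FieldImagePair(
        bright=np.clip(bright, 0, 255).astype(np.uint8),
        fluor_green=green, fluor_red=red, cells=list(cells),
        pixel_scale_um=params.pixel_scale_um, seed=seed, frame_id=frame_id)


def generate_pair(n_wbc: int, n_ctc: int,
                  params: GeneratorConfig | None = None,
                  seed: int = 0, frame_id: str = "frame0") -> FieldImagePair:
    """Convenience: sample a population and render it with the same seed."""
    cells = sample_population(n_wbc, n_ctc, params, seed)
    return render_pair(cells, params, seed=seed, frame_id=frame_id)


def write_pair(pair: FieldImagePair, out_dir: str | Path) -> Path:
    """Write a pair as PNG channels + ground-truth CSV + JSON manifest.

    Returns the manifest path.  ``read_pair(write_pair(p).parent)`` restores
    images bit-exactly and cell records field-exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / _FILES["bright"], pair.bright)
    iio.imwrite(out / _FILES["fluor_green"], pair.fluor_green)
    iio.imwrite(out / _FILES["fluor_red"], pair.fluor_red)

    rows = [{"class": c.class_label, "row": c.center_rc[0], "col": c.center_rc[1],
             "diameter_um": c.diameter_um} for c in pair.cells]
    pd.DataFrame(rows, columns=["class", "row", "col", "diameter_um"]).to_csv(
        out / _FILES["cells"], index=False)

    manifest = {
        "frame_id": pair.frame_id,
        "pixel_scale_um": pair.pixel_scale_um,
        "seed": pair.seed,
        "shape": list(pair.bright.shape),
        "files": {k: _FILES[k] for k in ("bright", "fluor_green", "fluor_red", "cells")},
        "cells": [c.to_record() for c in pair.cells],
    }
    mpath = out / _FILES["manifest"]
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_pair(in_dir: str | Path) -> FieldImagePair:
    """Read a pair written by :func:`write_pair`."""
    d = Path(in_dir)
    mpath = d / _FILES["manifest"]
    if not mpath.exists():
        raise FileNotFoundError(f"missing manifest file: {mpath}")
    manifest = json.loads(mpath.read_text())
    channels = {}
    for key in ("bright", "fluor_green", "fluor_red"):
        p = d / manifest["files"][key]
        if not p.exists():
            raise FileNotFoundError(f"missing {key} image file: {p}")
        channels[key] = np.asarray(iio.imread(p))
    cells = [SyntheticCell.from_record(r) for r in manifest["cells"]]
    return FieldImagePair(
        bright=channels["bright"], fluor_green=channels["fluor_green"],
        fluor_red=channels["fluor_red"], cells=cells,
        pixel_scale_um=manifest["pixel_scale_um"], seed=manifest["seed"],
        frame_id=manifest["frame_id"])
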