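"""Single-cell crop dataset construction.

Turns a segmented frame into labeled, normalized, augmented 30x30 crops:

* ``crop_cells`` cuts a fixed-size patch at each region centroid and records
  the source coordinates (needed later to map predictions back to the frame).
* ``transfer_labels`` reads the class off the registered fluorescence
  channels (green = WBC marker, red = CTC marker) by local SNR.
* ``quality_filter`` is an automated surrogate for manual single-cell
  curation: area/shape/border/overlap rules with a per-rejection reason.
* ``normalize_crop`` removes the local background tilt (least-squares plane
  fit on the crop's border ring) and standardizes to mean 0 / sd 1 — cells
  near the well edge sit on a dim, cloudy background that would otherwise
  dominate the classifier input.
* ``augment`` expands each class to a target count with random rotation,
  shear and reflections, tracking every synthetic crop's origin so the
  cross-validation harness can enforce leakage-free splits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import AffineTransform, warp

from .errors import ClassCoverageError, DegeneratePatchError, FormatError
from .segment import CellRegion
from .synthgen import CTC, UNLABELED, WBC

CROP_SIDE = 30


@dataclass
class CellCrop:
    """One single-cell patch plus provenance.

    ``origin_id`` equals ``crop_id`` for unaugmented crops and points to the
    source crop for augmented copies; fold assignment always happens at the
    origin level.
    """

    pixels: np.ndarray
    crop_id: str
    source_frame: str
    centroid_rc: tuple[float, float]
    label: str = UNLABELED
    origin_id: str = ""
    transform_desc: str = "identity"

    def __post_init__(self) -> None:
        if not self.origin_id:
            self.origin_id = self.crop_id


@dataclass
class QualityRules:
    """Automated single-cell curation thresholds."""

    min_area_px: int = 120
    max_area_px: int = 2000
    min_solidity: float = 0.85
    max_eccentricity: float = 0.8
    border_margin_px: int = 16
    max_overlap: float = 0.3


@dataclass
class AugmentSpec:
    """Geometric augmentation policy (rotation, shear, reflections)."""

    target_per_class: int = 1000
    rotation_range_deg: float = 180.0
    shear_range: float = 0.2
    allow_hflip: bool = True
    allow_vflip: bool = True
    seed: int = 0


def crop_cells(bright: np.ndarray, regions: list[CellRegion],
               side: int = CROP_SIDE, frame_id: str = "frame0") -> list[CellCrop]:
    """Cut a side x side patch centered at each region's rounded centroid.

    Patches that fall partially outside the frame are padded by edge
    replication; the exact (float) centroid is recorded on the crop.
    """
    nrows, ncols = bright.shape
    half = side // 2
    crops = []
    img = np.asarray(bright, dtype=float)
    for reg in regions:
        rc = int(round(reg.centroid_rc[0]))
        cc = int(round(reg.centroid_rc[1]))
        r0, c0 = rc - half, cc - half
        r1, c1 = r0 + side, c0 + side
        pr0, pc0 = max(-r0, 0), max(-c0, 0)
        pr1, pc1 = max(r1 - nrows, 0), max(c1 - ncols, 0)
        patch = img[max(r0, 0):min(r1, nrows), max(c0, 0):min(c1, ncols)]
        if pr0 or pc0 or pr1 or pc1:
            patch = np.pad(patch, ((pr0, pr1), (pc0, pc1)), mode="edge")
        crops.append(CellCrop(
            pixels=patch, crop_id=f"{frame_id}:{reg.region_id}",
            source_frame=frame_id, centroid_rc=reg.centroid_rc))
    return crops


def _robust_sigma(channel: np.ndarray) -> float:
    med = np.median(channel)
    return 1.4826 * np.median(np.abs(channel - med)) + 1e-9


def transfer_labels(crops: list[CellCrop], fluor_green: np.ndarray,
                    fluor_red: np.ndarray, min_snr: float = 3.0,
                    frame_shape: tuple[int, int] | None = None) -> list[CellCrop]:
    """Label each crop from the fluorescence channels by local SNR.

    For each crop the mean signal in a disk (radius side/4) around the
    centroid, minus the channel's frame median, is divided by the channel's
    robust noise.  Green wins -> WBC, red wins -> CTC, neither reaches
    ``min_snr`` (or an exact tie) -> UNLABELED.
    """
    green = np.asarray(fluor_green, dtype=float)
    red = np.asarray(fluor_red, dtype=float)
    if green.shape != red.shape:
        raise FormatError(
            f"fluorescence shape mismatch: green {green.shape} vs red {red.shape}")
    if frame_shape is not None and tuple(frame_shape) != green.shape:
        raise FormatError(
            f"fluorescence shape {green.shape} does not match frame {frame_shape}")
    nrows, ncols = green.shape
    bg_g, bg_r = np.median(green), np.median(red)
    sd_g, sd_r = _robust_sigma(green), _robust_sigma(red)

    out = []
    for crop in crops:
        radius = crop.pixels.shape[0] / 4.0
        r0c, c0c = crop.centroid_rc
        r0 = max(int(np.floor(r0c - radius)), 0)
        r1 = min(int(np.ceil(r0c + radius)) + 1, nrows)
        c0 = max(int(np.floor(c0c - radius)), 0)
        c1 = min(int(np.ceil(c0c + radius)) + 1, ncols)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        in_disk = (rr - r0c) ** 2 + (cc - c0c) ** 2 <= radius ** 2
        if not in_disk.any():
            out.append(replace(crop, label=UNLABELED))
            continue
        snr_g = (green[r0:r1, c0:c1][in_disk].mean() - bg_g) / sd_g
        snr_r = (red[r0:r1, c0:c1][in_disk].mean() - bg_r) / sd_r
        if snr_g >= min_snr and snr_g > snr_r:
            label = WBC
        elif snr_r >= min_snr and snr_r > snr_g:
            label = CTC
        else:
            label = UNLABELED
        out.append(replace(crop, label=label))
    return out


def _bbox_overlap_frac(a: tuple[int, int, int, int],
                       b: tuple[int, int, int, int]) -> float:
    """Intersection area of two half-open bboxes over the area of the first."""
    r0 = max(a[0], b[0]); c0 = max(a[1], b[1])
    r1 = min(a[2], b[2]); c1 = min(a[3], b[3])
    inter = max(r1 - r0, 0) * max(c1 - c0, 0)
    area = (a[2] - a[0]) * (a[3] - a[1])
    return inter / area if area else 0.0


def quality_filter(crops: list[CellCrop], regions: list[CellRegion],
                   rules: QualityRules | None = None,
                   frame_shape: tuple[int, int] | None = None):
    """Keep crops whose region looks like a clean, isolated single cell.

    Rules are checked in order area, solidity, eccentricity, border,
    overlap; a rejection records the first rule that failed.  Returns
    ``(kept_crops, [(crop, reason), ...])``.
    """
    rules = rules or QualityRules()
    if len(crops) != len(regions):
        raise FormatError("crops and regions must align 1:1")
    kept, rejected = [], []
    for i, (crop, reg) in enumerate(zip(crops, regions)):
        reason = None
        if not rules.min_area_px <= reg.area_px <= rules.max_area_px:
            reason = "area"
        elif reg.solidity < rules.min_solidity:
            reason = "solidity"
        elif reg.eccentricity > rules.max_eccentricity:
            reason = "eccentricity"
        else:
            if frame_shape is not None:
                r, c = reg.centroid_rc
                m = rules.border_margin_px
                if not (m <= r < frame_shape[0] - m and m <= c < frame_shape[1] - m):
                    reason = "border"
            if reason is None:
                for j, other in enumerate(regions):
                    if j != i and _bbox_overlap_frac(reg.bbox, other.bbox) > rules.max_overlap:
                        reason = "overlap"
                        break
        if reason is None:
            kept.append(crop)
        else:
            rejected.append((crop, reason))
    return kept, rejected


def fit_background_plane(patch: np.ndarray, ring_width: int = 3):
    """Least-squares plane a*r + b*c + d fitted to the patch's border ring.

    Returns ``(plane_image, (a, b, d))``.
    """
    patch = np.asarray(patch, dtype=float)
    rr, cc = np.mgrid[0:patch.shape[0], 0:patch.shape[1]].astype(float)
    ring = np.zeros(patch.shape, dtype=bool)
    ring[:ring_width, :] = ring[-ring_width:, :] = True
    ring[:, :ring_width] = ring[:, -ring_width:] = True
    A = np.column_stack([rr[ring], cc[ring], np.ones(ring.sum())])
    coef, *_ = np.linalg.lstsq(A, patch[ring], rcond=None)
    plane = coef[0] * rr + coef[1] * cc + coef[2]
    return plane, tuple(coef)


def normalize_crop(crop: CellCrop) -> CellCrop:
    """Background-tilt removal + standardization of one crop.

    Subtracts the border-ring plane fit, then scales to mean 0 / sd 1.
    Exactly idempotent after the first application.  A patch with no
    residual variance (constant, or a pure intensity ramp) carries no cell
    signal and raises :class:`DegeneratePatchError`.
    """
    plane, _ = fit_background_plane(crop.pixels)
    resid = np.asarray(crop.pixels, dtype=float) - plane
    sd = resid.std()
    if sd < 1e-9:
        raise DegeneratePatchError(
            f"crop {crop.crop_id}: no variance after background removal")
    return replace(crop, pixels=(resid - resid.mean()) / sd)


def _random_affine(rng: np.random.Generator, spec: AugmentSpec, side: int):
    """Sample one augmentation transform; returns (warp_map or None, desc)."""
    rot = rng.uniform(-spec.rotation_range_deg, spec.rotation_range_deg) \
        if spec.rotation_range_deg else 0.0
    shear = rng.uniform(-spec.shear_range, spec.shear_range) \
        if spec.shear_range else 0.0
    hflip = spec.allow_hflip and bool(rng.integers(2))
    vflip = spec.allow_vflip and bool(rng.integers(2))
    desc = f"rot={rot:.2f};shear={shear:.3f};hflip={hflip};vflip={vflip}"
    if rot == 0.0 and shear == 0.0 and not hflip and not vflip:
        return None, "identity"
    center = (side - 1) / 2.0
    t_center = AffineTransform(translation=(-center, -center))
    flip = AffineTransform(scale=(-1 if hflip else 1, -1 if vflip else 1))
    tf = (t_center
          + AffineTransform(rotation=np.deg2rad(rot), shear=shear)
          + flip
          + AffineTransform(translation=(center, center)))
    return tf, desc


def augment(crops: list[CellCrop], spec: AugmentSpec | None = None) -> list[CellCrop]:
    """Expand labeled crops to ``target_per_class`` per class.

    Originals are emitted first; the remainder are synthesized by sampling a
    source crop uniformly with replacement and applying a seeded random
    rotation/shear/flip (bilinear interpolation, edge padding).  Every
    output's ``origin_id`` resolves to a source crop.  Deterministic for a
    fixed seed.
    """
    spec = spec or AugmentSpec()
    rng = np.random.default_rng(spec.seed)
    by_class = {WBC: [], CTC: []}
    for c in crops:
        if c.label not in by_class:
            raise ClassCoverageError(
                f"augment requires labeled crops; got label {c.label!r} "
                f"on {c.crop_id}")
        by_class[c.label].append(c)
    for cls, members in by_class.items():
        if not members:
            raise ClassCoverageError(f"no source crops for class {cls}")

    out: list[CellCrop] = []
    for cls in (WBC, CTC):          # fixed class order for determinism
        sources = by_class[cls]
        out.extend(sources[:spec.target_per_class])
        n_synth = max(spec.target_per_class - len(sources), 0)
        for k in range(1, n_synth + 1):
            src = sources[int(rng.integers(len(sources)))]
            tf, desc = _random_affine(rng, spec, src.pixels.shape[0])
            if tf is None:
                pixels = src.pixels.copy()
            else:
                pixels = warp(src.pixels, tf.inverse, order=1, mode="edge",
                              preserve_range=True)
            out.append(replace(
                src, pixels=pixels, crop_id=f"{src.crop_id}#aug{cls}{k}",
                origin_id=src.origin_id, transform_desc=desc))
    return out
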