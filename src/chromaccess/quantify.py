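"""Nuclear segmentation and per-object fluorescence quantification.

Implements the measurement side of the assay: mask nuclei in a 16-bit well
image, then report for every object the four readouts used throughout —

* ``size_um``   — longest linear dimension (maximum pairwise pixel-center
  distance, i.e. max Feret diameter over pixel centers) in microns;
* ``area_um2``  — pixel count times the calibrated per-pixel area;
* ``mean``      — background-subtracted intensity averaged over the object;
* ``integral``  — background-subtracted intensity summed over the object.

Objects shorter than 15 μm (debris) or longer than 40 μm (clusters) are
removed by the size gate; touching nuclei are deliberately not split, since
the resulting oversized object falls out of the gate anyway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects

__all__ = [
    "Calibration",
    "CALIBRATIONS",
    "SegmentationParams",
    "SizeGate",
    "SegmentationWarning",
    "segment_nuclei",
    "measure_objects",
    "apply_size_gate",
    "quantify_plate",
]


class SegmentationWarning(UserWarning):
    """Raised (as a warning) for degenerate images, e.g. fully saturated."""


@dataclass(frozen=True)
class Calibration:
    """Objective calibration: micron length and area of one camera pixel."""

    objective: str
    pixel_length_um: float
    pixel_area_um2: float

    def __post_init__(self):
        if self.pixel_length_um <= 0 or self.pixel_area_um2 <= 0:
            raise ValueError("calibration constants must be positive")


#: 4x constants are the instrument-reported values; pixel area is an
#: independent constant, not pixel_length_um squared.  The 10x entry is
#: derived from the 4x pixel pitch.
CALIBRATIONS = {
    "4x": Calibration("4x", pixel_length_um=1.28, pixel_area_um2=1.64825),
    "10x": Calibration("10x", pixel_length_um=0.512, pixel_area_um2=0.262144),
}


@dataclass
class SegmentationParams:
    smoothing_scale: float = 1.0  # Gaussian sigma in pixels; 0 disables
    threshold_method: str = "otsu"  # {"otsu", "fixed"}
    fixed_threshold: float | None = None
    fill_holes: bool = True
    min_object_px: int = 10

    def validate(self) -> None:
        if self.min_object_px < 1:
            raise ValueError("min_object_px must be >= 1")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required for threshold_method='fixed'")
        if self.smoothing_scale < 0:
            raise ValueError("smoothing_scale must be >= 0")


@dataclass
class SizeGate:
    """Inclusive size window in microns; outside lies debris or clusters."""

    min_um: float = 15.0
    max_um: float = 40.0

    def __post_init__(self):
        if not self.min_um < self.max_um:
            raise ValueError("SizeGate requires min_um < max_um")


def segment_nuclei(
    image: np.ndarray,
    sp: SegmentationParams | None = None,
    detector_max: float = 65535.0,
) -> np.ndarray:
    """Label nuclei in a single-channel image; background is label 0.

    Gaussian smoothing, global threshold (Otsu by default), optional hole
    filling, speckle removal and 8-connected component labelling.  Touching
    objects are not split.  A constant image yields no labels; a fully
    saturated image yields a :class:`SegmentationWarning`.
    """
    sp = sp or SegmentationParams()
    sp.validate()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be single-channel (2-D)")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    if np.all(img >= detector_max):
        warnings.warn("image is fully saturated", SegmentationWarning)

    if img.max() == img.min():
        return np.zeros(img.shape, dtype=np.int32)

    sm = gaussian(img, sigma=sp.smoothing_scale, preserve_range=True) if sp.smoothing_scale > 0 else img
    if sp.threshold_method == "otsu":
        thr = threshold_otsu(sm)
    else:
        thr = sp.fixed_threshold
    mask = sm > thr
    if sp.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    try:  # skimage >= 0.26 renamed the size cutoff (and made it inclusive)
        mask = remove_small_objects(mask, max_size=sp.min_object_px - 1)
    except TypeError:
        mask = remove_small_objects(mask, min_size=sp.min_object_px)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    if mask.all():
        warnings.warn("threshold left no background pixels", SegmentationWarning)
    return cc_label(mask, connectivity=2).astype(np.int32)


def _max_feret_px(coords: np.ndarray) -> float:
    """Maximum pairwise distance between pixel centers of one object."""
    if len(coords) == 1:
        return 0.0
    pts = coords.astype(float)
    if len(pts) > 50:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear objects have no 2-D hull
            pass
    return float(pdist(pts).max())


def measure_objects(
    labels: np.ndarray,
    image: np.ndarray,
    edu_image: np.ndarray | None = None,
    cal: Calibration = CALIBRATIONS["4x"],
    background: float | None = None,
    subtract_background: bool = True,
    detector_max: float = 65535.0,
) -> pd.DataFrame:
    """Per-object records for every labelled nucleus.

    ``background`` defaults to the median intensity outside the mask and is
    subtracted from every pixel before computing mean and integral (set
    ``subtract_background=False`` for instrument-style raw readouts).  The
    returned integral is exactly ``mean * pixel_count`` and ``area_um2``
    exactly ``pixel_count * cal.pixel_area_um2``.  Objects containing any
    saturated pixel are flagged, not dropped.
    """
    labels = np.asarray(labels)
    img = np.asarray(image, dtype=float)
    if labels.shape != img.shape:
        raise ValueError("labels and image shapes differ")
    if edu_image is not None and np.asarray(edu_image).shape != img.shape:
        raise ValueError("edu_image shape differs from image")

    ids = np.unique(labels)
    ids = ids[ids > 0]
    records = []
    if len(ids) == 0:
        return pd.DataFrame(
            columns=[
                "object_id", "pixel_count", "size_um", "area_um2", "mean",
                "integral", "centroid_row", "centroid_col", "saturated", "edu_mean",
            ]
        )

    if background is None:
        outside = img[labels == 0]
        background = float(np.median(outside)) if outside.size else 0.0
    if not subtract_background:
        background = 0.0

    edu = np.asarray(edu_image, dtype=float) if edu_image is not None else None
    if edu is not None:
        out = edu[labels == 0]
        edu_bg = float(np.median(out)) if (out.size and subtract_background) else 0.0

    flat = labels.ravel()
    nmax = int(labels.max())
    counts = np.bincount(flat, minlength=nmax + 1)
    sums = np.bincount(flat, weights=img.ravel(), minlength=nmax + 1)
    rsum = np.bincount(flat, weights=np.repeat(np.arange(img.shape[0]), img.shape[1]).astype(float), minlength=nmax + 1)
    csum = np.bincount(flat, weights=np.tile(np.arange(img.shape[1]), img.shape[0]).astype(float), minlength=nmax + 1)
    if edu is not None:
        esums = np.bincount(flat, weights=edu.ravel(), minlength=nmax + 1)
    sat = np.bincount(flat, weights=(img >= detector_max).ravel().astype(float), minlength=nmax + 1)

    slices = ndimage.find_objects(labels)
    for lab in ids:
        cnt = int(counts[lab])
        integral = float(sums[lab] - background * cnt)
        mean = integral / cnt
        sl = slices[lab - 1]
        sub = labels[sl] == lab
        coords = np.argwhere(sub)
        feret = _max_feret_px(coords)
        records.append(
            dict(
                object_id=int(lab),
                pixel_count=cnt,
                # single-pixel objects are one pixel "long" by convention
                size_um=max(feret, 1.0) * cal.pixel_length_um,
                area_um2=cnt * cal.pixel_area_um2,
                mean=mean,
                integral=mean * cnt,
                centroid_row=float(rsum[lab] / cnt),
                centroid_col=float(csum[lab] / cnt),
                saturated=bool(sat[lab] > 0),
                edu_mean=(float(esums[lab] / cnt - edu_bg) if edu is not None else np.nan),
            )
        )
    return pd.DataFrame(records)


def apply_size_gate(records: pd.DataFrame, gate: SizeGate | None = None) -> pd.DataFrame:
    """Keep records with min_um <= size_um <= max_um (inclusive, idempotent)."""
    gate = gate or SizeGate()
    if len(records) == 0:
        return records.copy()
    keep = (records["size_um"] >= gate.min_um) & (records["size_um"] <= gate.max_um)
    return records.loc[keep].copy()


def _image_path(images_dir: Path, row: pd.Series, channel: str) -> Path:
    plate = row.get("plate", "plate1")
    return images_dir / f"{plate}_{row['well']}_{channel}.tif"


def quantify_plate(
    layout: pd.DataFrame | str | Path,
    images_dir: str | Path,
    sp: SegmentationParams | None = None,
    cal: Calibration = CALIBRATIONS["4x"],
    gate: SizeGate | None = None,
    dna_channel: str = "dna",
    edu_channel: str = "edu",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify every well of a plate and pool objects across wells.

    Returns ``(objects, well_summary)``.  ``objects`` is the pooled, size-gated
    object table with well and condition labels retained; ``well_summary`` has
    one row per layout row with the in-gate object count, well-average mean and
    integral and a status (``ok``, ``empty_after_gate`` or ``missing_image``).
    A missing image is recorded as an error entry and the remaining wells are
    still processed.
    """
    if not isinstance(layout, pd.DataFrame):
        layout = pd.read_csv(layout)
    images_dir = Path(images_dir)
    sp = sp or SegmentationParams()
    gate = gate or SizeGate()

    obj_frames, summaries = [], []
    for _, row in layout.iterrows():
        path = _image_path(images_dir, row, dna_channel)
        summary = dict(
            well=row["well"],
            condition=row["condition"],
            n_objects=0,
            well_mean=np.nan,
            well_integral=np.nan,
            status="ok",
        )
        if not path.exists():
            summary["status"] = f"missing_image:{path.name}"
            summaries.append(summary)
            continue
        img = tifffile.imread(path)
        edu_img = None
        if edu_channel and "channels" in row.index and edu_channel in str(row["channels"]).split(";"):
            epath = _image_path(images_dir, row, edu_channel)
            if epath.exists():
                edu_img = tifffile.imread(epath)
            else:
                summary["status"] = f"missing_image:{epath.name}"
        labels = segment_nuclei(img, sp)
        recs = measure_objects(labels, img, edu_image=edu_img, cal=cal)
        recs = apply_size_gate(recs, gate)
        summary["n_objects"] = int(len(recs))
        if len(recs):
            summary["well_mean"] = float(recs["mean"].mean())
            summary["well_integral"] = float(recs["integral"].mean())
            recs = recs.copy()
            recs.insert(0, "well", row["well"])
            recs.insert(1, "condition", row["condition"])
            obj_frames.append(recs)
        elif summary["status"] == "ok":
            summary["status"] = "empty_after_gate"
        summaries.append(summary)

    objects = (
        pd.concat(obj_frames, ignore_index=True)
        if obj_frames
        else pd.DataFrame(columns=["well", "condition", "object_id", "size_um", "area_um2", "mean", "integral", "pixel_count", "edu_mean"])
    )
    return objects, pd.DataFrame(summaries)
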