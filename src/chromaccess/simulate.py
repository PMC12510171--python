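"""Synthetic imaging-cytometry data with known ground truth.

This module generates populations of fixed, DNA-dye-stained nuclei and renders
them into widefield-like 16-bit well images, so that every downstream stage of
the assay (segmentation, per-object quantification, debris gating, DNA-content
peak detection, group statistics) can be exercised against an exact answer.

The signal model is deliberately simple.  A cell in phase G1, S or G2/M carries
a relative DNA content (1, uniform on (1, 2), or 2, times the G1 ploidy), and an
"accessible fraction" — the share of its genome that is nucleosome-free and
therefore available to an intercalating or minor-groove-binding dye.  The total
dye signal collected from the whole nuclear volume is

    total = brightness * dna_content * accessible_fraction * response(dose)

where ``response`` is the dye's dose-response curve (linear-to-saturation for a
propidium-iodide-like dye, bell-shaped for a SYBR-Green-like dye).  Nuclear
area scales as ``dna_content ** area_content_coupling``; with the default
coupling of 1 the per-pixel mean intensity (total / area) is independent of
cell-cycle phase, which is the property that makes the mean the preferred
accessibility readout while the integral tracks DNA content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "PHASES",
    "PopulationParams",
    "CellGroundTruth",
    "DyeModel",
    "RenderParams",
    "sample_population",
    "dye_response",
    "cell_signal",
    "population_signals",
    "simulate_integrals",
    "render_well",
    "generate_plate",
]

PHASES = ("G1", "S", "G2M")

#: Phase multipliers of DNA content relative to the G1 ploidy.
_PHASE_DNA = {"G1": 1.0, "G2M": 2.0}


@dataclass
class PopulationParams:
    """Ground-truth description of one simulated cell population (condition).

    Defaults emulate an asynchronously cycling, near-diploid fibrosarcoma-like
    (HT1080-like) culture in basal conditions: roughly 70% of cells in G1,
    20% in S and 10% in G2/M.
    """

    n_cells: int = 1000
    phase_fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    g1_dna_content: float = 1.0
    accessible_fraction: float = 0.30
    accessible_cv: float = 0.05
    g1_mean_area_px: float = 260.0
    area_cv: float = 0.05
    area_content_coupling: float = 1.0
    aspect_ratio_range: tuple[float, float] = (1.0, 1.25)
    edu_label_s_phase: bool = False
    cytoplasm_signal: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        f = np.asarray(self.phase_fractions, dtype=float)
        if f.shape != (3,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(
                "phase_fractions must be three non-negative numbers summing to 1"
            )
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0.0 < self.accessible_fraction <= 1.0):
            raise ValueError("accessible_fraction must lie in (0, 1]")
        if self.accessible_cv < 0 or self.area_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")
        if self.g1_mean_area_px <= 0 or self.g1_dna_content <= 0:
            raise ValueError("g1_mean_area_px and g1_dna_content must be positive")
        lo, hi = self.aspect_ratio_range
        if not (1.0 <= lo <= hi):
            raise ValueError("aspect_ratio_range must satisfy 1 <= lo <= hi")


@dataclass
class CellGroundTruth:
    """One simulated cell: the exact quantities the assay tries to recover."""

    cell_id: int
    phase: str
    dna_content: float
    accessible_fraction: float
    axes: tuple[float, float]  # ellipse semi-axes (row, col) in pixels
    edu_positive: bool = False
    cytoplasm_signal: float = 0.0
    center_xy: tuple[float, float] | None = None  # (row, col); set at placement

    @property
    def area_px(self) -> float:
        """Analytic nuclear area in pixels (pi * a * b)."""
        return math.pi * self.axes[0] * self.axes[1]


@dataclass
class DyeModel:
    """Dose-response and brightness model of a DNA-binding fluorescent dye.

    ``response_shape='linear'`` emulates intercalators like propidium iodide
    whose signal rises with dose up to a reference dose ``d_ref`` and then
    saturates; ``'bell'`` emulates SYBR-Green-like self-quenching, with the
    maximum at ``d_opt``.  ``brightness`` converts accessible DNA (relative
    units) into fluorescence counts; ``detector_max`` is the 16-bit camera
    ceiling applied at render time.  ``rnase_applied=False`` leaves a
    removable cytoplasmic double-stranded-RNA signal around each nucleus.
    """

    name: str = "PI-like"
    response_shape: str = "linear"  # {"linear", "bell"}
    staining_dose: float = 1.0
    d_ref: float = 1.0
    d_opt: float = 50.0
    brightness: float = 2.0e6
    detector_max: float = 65535.0
    rnase_applied: bool = True

    def validate(self) -> None:
        if self.response_shape not in ("linear", "bell"):
            raise ValueError("response_shape must be 'linear' or 'bell'")
        if self.staining_dose < 0:
            raise ValueError("staining_dose must be >= 0")
        if self.d_ref <= 0 or self.d_opt <= 0:
            raise ValueError("d_ref and d_opt must be positive")
        if self.brightness < 0 or self.detector_max <= 0:
            raise ValueError("brightness must be >= 0 and detector_max > 0")


@dataclass
class RenderParams:
    """Acquisition emulation: frame size, background, noise and placement."""

    image_shape: tuple[int, int] = (384, 384)
    background_level: float = 200.0
    noise_model: str = "none"  # {"none", "gaussian", "poisson_gaussian"}
    noise_sigma: float = 10.0
    photon_gain: float = 2.0  # counts per photon for poisson_gaussian
    min_center_separation: float = 0.0
    allow_overlap: bool = False
    cytoplasm_scale: float = 1.6  # halo semi-axes relative to the nucleus
    seed: int = 0

    def validate(self) -> None:
        if self.noise_model not in ("none", "gaussian", "poisson_gaussian"):
            raise ValueError("unknown noise_model")
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise ValueError("image_shape must be a 2-tuple of at least 8 px")


def sample_population(params: PopulationParams) -> list[CellGroundTruth]:
    """Draw ``params.n_cells`` ground-truth cells, reproducibly from the seed.

    Phases are i.i.d. from ``phase_fractions``; S-phase DNA content is uniform
    on (1, 2); per-cell accessible fractions are normal around the condition
    value with CV ``accessible_cv`` (clipped to (0, 1]); nuclear area scales as
    ``dna_content ** area_content_coupling`` with lognormal-free multiplicative
    jitter of CV ``area_cv``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    if n == 0:
        return []

    phases = rng.choice(PHASES, size=n, p=np.asarray(params.phase_fractions))
    rel = np.ones(n)
    rel[phases == "G2M"] = 2.0
    s_mask = phases == "S"
    rel[s_mask] = rng.uniform(1.0, 2.0, size=int(s_mask.sum()))
    dna = params.g1_dna_content * rel

    af = params.accessible_fraction * (
        1.0 + params.accessible_cv * rng.standard_normal(n)
    )
    af = np.clip(af, 1e-6, 1.0)

    # area tracks absolute DNA content, so ploidy changes move area and
    # integral together while leaving the per-pixel mean untouched
    area = (
        params.g1_mean_area_px
        * dna**params.area_content_coupling
        * (1.0 + params.area_cv * rng.standard_normal(n)).clip(0.2)
    )
    ar = rng.uniform(*params.aspect_ratio_range, size=n)
    semi_minor = np.sqrt(area / (math.pi * ar))
    semi_major = ar * semi_minor

    cyto = (
        params.cytoplasm_signal * rng.uniform(0.7, 1.3, size=n)
        if params.cytoplasm_signal > 0
        else np.zeros(n)
    )

    cells = []
    for i in range(n):
        cells.append(
            CellGroundTruth(
                cell_id=i,
                phase=str(phases[i]),
                dna_content=float(dna[i]),
                accessible_fraction=float(af[i]),
                axes=(float(semi_major[i]), float(semi_minor[i])),
                edu_positive=bool(params.edu_label_s_phase and phases[i] == "S"),
                cytoplasm_signal=float(cyto[i]),
            )
        )
    return cells


def dye_response(dose: float, dye: DyeModel) -> float:
    """Unit dose-response of a dye in [0, 1]; 0 at dose 0.

    linear: ``min(dose / d_ref, 1)``; bell: ``(dose/d_opt) * exp(1 - dose/d_opt)``.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    dye.validate()
    if dye.response_shape == "linear":
        return min(dose / dye.d_ref, 1.0)
    x = dose / dye.d_opt
    return x * math.exp(1.0 - x)


def cell_signal(cell: CellGroundTruth, dye: DyeModel) -> tuple[float, float]:
    """Analytic (per_pixel_mean, total) nuclear fluorescence of one cell.

    ``total = brightness * dna_content * accessible_fraction * response(dose)``
    and ``per_pixel_mean = total / area_px``.  Values are unclipped here; the
    detector ceiling applies per pixel at render time.
    """
    resp = dye_response(dye.staining_dose, dye)
    total = dye.brightness * cell.dna_content * cell.accessible_fraction * resp
    return total / cell.area_px, total


def population_signals(cells: Sequence[CellGroundTruth], dye: DyeModel) -> pd.DataFrame:
    """Vectorised per-cell analytic signals as a tidy table."""
    rows = []
    for c in cells:
        ppm, total = cell_signal(c, dye)
        rows.append(
            dict(
                cell_id=c.cell_id,
                phase=c.phase,
                dna_content=c.dna_content,
                accessible_fraction=c.accessible_fraction,
                area_px=c.area_px,
                mean=ppm,
                integral=total,
                edu_positive=c.edu_positive,
            )
        )
    return pd.DataFrame(rows)


def simulate_integrals(
    params: PopulationParams,
    g1_location: float = 100.0,
    cv: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-cell integral fluorescence values at a chosen G1 histogram location.

    Draws a population from ``params`` and maps DNA content directly to the
    integral scale: G1 cells land around ``g1_location``, G2/M around twice it,
    S-phase uniformly in between, each with multiplicative normal noise of the
    given CV.  This is the measurement-free path used to study the DNA-content
    histogram in isolation from rendering and segmentation.

    Returns a DataFrame with columns ``phase`` and ``integral``.
    """
    p = params if seed is None else replace(params, seed=seed)
    cells = sample_population(p)
    rng = np.random.default_rng((p.seed + 0x9E3779B9) % (2**31))
    rel = np.array([c.dna_content / p.g1_dna_content for c in cells])
    noise = 1.0 + cv * rng.standard_normal(len(cells))
    return pd.DataFrame(
        {
            "phase": [c.phase for c in cells],
            "integral": g1_location * rel * noise,
        }
    )


def _place_cells(
    cells: list[CellGroundTruth], rp: RenderParams, rng: np.random.Generator
) -> None:
    """Assign non-overlapping centers on a jittered grid (deterministic).

    Grid pitch is chosen so that after jitter the pairwise center distance
    still exceeds both the largest nucleus diameter (plus clearance) and
    ``rp.min_center_separation``; this guarantees the separation precondition
    without rejection sampling.
    """
    todo = [c for c in cells if c.center_xy is None]
    if not todo:
        for c in cells:
            _check_in_frame(c, rp)
        return
    h, w = rp.image_shape
    a_max = max(c.axes[0] for c in todo)
    required = max(2.0 * a_max + 3.0, rp.min_center_separation)
    if rp.allow_overlap:
        required = max(rp.min_center_separation, 1.0)
    pitch = required * 1.25
    jitter = (pitch - required) / 2.0
    margin = a_max * (rp.cytoplasm_scale if _any_cyto(todo) else 1.0) + jitter + 2.0
    nr = int((h - 2 * margin) // pitch) + 1
    nc = int((w - 2 * margin) // pitch) + 1
    if nr < 1 or nc < 1 or nr * nc < len(todo):
        raise ValueError(
            f"cannot place {len(todo)} nuclei in a {h}x{w} frame without overlap; "
            "increase image_shape or reduce n_cells"
        )
    sites = [(margin + i * pitch, margin + j * pitch) for i in range(nr) for j in range(nc)]
    idx = rng.permutation(len(sites))[: len(todo)]
    for c, k in zip(todo, idx):
        r0, c0 = sites[k]
        c.center_xy = (
            float(r0 + rng.uniform(-jitter, jitter)),
            float(c0 + rng.uniform(-jitter, jitter)),
        )
    for c in cells:
        _check_in_frame(c, rp)


def _any_cyto(cells: Sequence[CellGroundTruth]) -> bool:
    return any(c.cytoplasm_signal > 0 for c in cells)


def _check_in_frame(cell: CellGroundTruth, rp: RenderParams) -> None:
    h, w = rp.image_shape
    r, c = cell.center_xy
    a = cell.axes[0]
    if not (a <= r <= h - 1 - a and a <= c <= w - 1 - a):
        raise ValueError(f"cell {cell.cell_id} does not fit inside the frame")


def render_well(
    cells: list[CellGroundTruth],
    dye: DyeModel,
    rp: RenderParams,
    edu_signal: float = 3000.0,
    edu_bleed: float = 30.0,
    render_edu: bool = False,
):
    """Render one well as a 16-bit image plus exact ground truth.

    Returns ``(image, labels, truth)`` — or ``(image, edu_image, labels,
    truth)`` when ``render_edu`` — where ``labels`` assigns ``cell_id + 1`` to
    every true nuclear pixel and ``truth`` is an ObjectRecord-compatible table
    whose ``total`` column is the analytic per-pixel mean times the realised
    pixel count (what a perfect background-subtracted measurement would sum).

    Nuclei are filled, axis-aligned ellipses at their analytic per-pixel mean
    over a flat background.  When the dye was applied without RNase, each cell
    contributes a dimmer cytoplasmic halo outside its nucleus.  Pixel values
    are quantised to integers and clipped to ``dye.detector_max``.
    """
    dye.validate()
    rp.validate()
    rng = np.random.default_rng(rp.seed)
    h, w = rp.image_shape
    img = np.full((h, w), float(rp.background_level))
    labels = np.zeros((h, w), dtype=np.int32)
    edu_img = np.full((h, w), float(rp.background_level)) if render_edu else None

    _place_cells(cells, rp, rng)

    # cytoplasmic halos first so nuclear pixels are overwritten, not summed
    if not dye.rnase_applied:
        for cell in cells:
            if cell.cytoplasm_signal <= 0:
                continue
            rr, cc = draw_ellipse(
                cell.center_xy[0],
                cell.center_xy[1],
                cell.axes[0] * rp.cytoplasm_scale,
                cell.axes[1] * rp.cytoplasm_scale,
                shape=(h, w),
            )
            img[rr, cc] += cell.cytoplasm_signal

    rows = []
    for cell in cells:
        ppm, _ = cell_signal(cell, dye)
        rr, cc = draw_ellipse(
            cell.center_xy[0], cell.center_xy[1], cell.axes[0], cell.axes[1], shape=(h, w)
        )
        img[rr, cc] = rp.background_level + ppm
        labels[rr, cc] = cell.cell_id + 1
        if render_edu:
            edu_img[rr, cc] = rp.background_level + (
                edu_signal if cell.edu_positive else edu_bleed
            )
        n_px = len(rr)
        rows.append(
            dict(
                cell_id=cell.cell_id,
                phase=cell.phase,
                dna_content=cell.dna_content,
                accessible_fraction=cell.accessible_fraction,
                center_row=cell.center_xy[0],
                center_col=cell.center_xy[1],
                pixel_count=n_px,
                per_pixel_mean=min(ppm, dye.detector_max - rp.background_level),
                total=min(ppm, dye.detector_max - rp.background_level) * n_px,
                edu_positive=cell.edu_positive,
            )
        )

    def _finish(a: np.ndarray) -> np.ndarray:
        if rp.noise_model == "gaussian":
            a = a + rng.normal(0.0, rp.noise_sigma, size=a.shape)
        elif rp.noise_model == "poisson_gaussian":
            a = rng.poisson(np.clip(a, 0, None) / rp.photon_gain) * rp.photon_gain
            a = a + rng.normal(0.0, rp.noise_sigma, size=a.shape)
        return np.clip(np.rint(a), 0, dye.detector_max).astype(np.uint16)

    truth = pd.DataFrame(rows)
    if render_edu:
        return _finish(img), _finish(edu_img), labels, truth
    return _finish(img), labels, truth


@dataclass
class ConditionSpec:
    """One experimental condition on a simulated plate."""

    name: str
    population: PopulationParams
    dye: DyeModel = field(default_factory=DyeModel)
    n_wells: int = 4  # replicate wells per condition
    edu_channel: bool = False


def _well_names(n: int) -> list[str]:
    return [f"{chr(ord('A') + i // 12)}{i % 12 + 1:02d}" for i in range(n)]


def generate_plate(
    conditions: Sequence[ConditionSpec],
    rp: RenderParams,
    out_dir: str | Path,
    plate: str = "plate1",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a multiwell plate and write its images plus tables to disk.

    Writes one 16-bit grayscale TIFF per well per channel
    (``<plate>_<well>_<channel>.tif``), a ground-truth table
    (``<plate>_truth.csv``) and a layout table (``<plate>_layout.csv``) with
    columns well, condition, replicate, channels.  Per-well randomness comes
    from independent substreams spawned from the one plate seed, so the whole
    plate is reproducible from ``seed`` alone.

    Returns ``(layout, truth)`` as DataFrames.
    """
    names = [c.name for c in conditions]
    if len(set(names)) != len(names):
        raise ValueError("duplicate condition names in plate design")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_wells_total = sum(c.n_wells for c in conditions)
    wells = _well_names(n_wells_total)
    if len(set(wells)) != len(wells):
        raise ValueError("duplicate well IDs in plate design")

    ss = np.random.SeedSequence(seed)
    sub = ss.spawn(n_wells_total)

    layout_rows, truth_frames = [], []
    wi = 0
    for cond in conditions:
        for rep in range(cond.n_wells):
            well = wells[wi]
            well_seed = int(sub[wi].generate_state(1)[0] % (2**31))
            wi += 1
            pop = replace(cond.population, seed=well_seed)
            cells = sample_population(pop)
            wrp = replace(rp, seed=well_seed + 1)
            if cond.edu_channel:
                img, edu_img, labels, truth = render_well(
                    cells, cond.dye, wrp, render_edu=True
                )
                tifffile.imwrite(out_dir / f"{plate}_{well}_edu.tif", edu_img)
                channels = "dna;edu"
            else:
                img, labels, truth = render_well(cells, cond.dye, wrp)
                channels = "dna"
            tifffile.imwrite(out_dir / f"{plate}_{well}_dna.tif", img)
            truth.insert(0, "well", well)
            truth.insert(1, "condition", cond.name)
            truth_frames.append(truth)
            layout_rows.append(
                dict(
                    plate=plate,
                    well=well,
                    condition=cond.name,
                    replicate=rep + 1,
                    channels=channels,
                )
            )

    layout = pd.DataFrame(layout_rows)
    truth_all = pd.concat(truth_frames, ignore_index=True)
    layout.to_csv(out_dir / f"{plate}_layout.csv", index=False)
    truth_all.to_csv(out_dir / f"{plate}_truth.csv", index=False)
    return layout, truth_all
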