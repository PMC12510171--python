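# Methods

## The assay and its model

Some DNA-binding fluorescent small molecules — intercalators such as
propidium iodide (PI) and SYBR Green, and minor-groove binders such as DAPI
and Hoechst — bind nucleosome-free DNA more readily than DNA wrapped around
histone cores. When cells are fixed (so that the ligand itself can no longer
evict histones) and imaged with a low-magnification widefield objective whose
depth of focus exceeds the nuclear thickness, the fluorescence collected from
a nucleus approximates the total amount of dye bound in its whole volume and
is therefore a single-cell proxy for global chromatin accessibility.

`chromaccess` models one nucleus as

    total  = brightness · dna_content · accessible_fraction · response(dose)
    mean   = total / nuclear_area

with `dna_content` the relative genome size (1 in G1, 2 in G2/M, uniform on
(1, 2) in S — no S-phase dwell model is assumed), `accessible_fraction` the
nucleosome-free share of the genome (the quantity experiments perturb), and
`response(dose)` the dye's dose-response: `min(dose/d_ref, 1)` for a
PI-like dye, `(d/d_opt)·exp(1 − d/d_opt)` for a bell-shaped SYBR-Green-like
dye (only the bell *shape* is empirically motivated; this parameterisation
is this package's definition, normalised to its maximum at `d_opt`).

Nuclear area scales as `dna_content ** area_content_coupling` with default
coupling 1. This single choice produces the assay's central contrast: the
per-object **integral** is proportional to DNA content and is bimodal over
the cell cycle, while the per-pixel **mean** cancels the DNA-content factor
and is cycle-invariant, which is why the mean is the preferred accessibility
readout and the integral is the cell-cycle readout. The coupling exponent is
configurable to probe deviations from this idealisation.

## Synthetic data: what it emulates and what it does not

`sample_population` draws phases i.i.d. from the phase mixture (default
0.70/0.20/0.10 G1/S/G2M, an asynchronous near-diploid fibrosarcoma-like
culture in basal conditions), per-cell accessible fractions around the
condition value with CV `accessible_cv`, and ellipse geometry from the area
model with CV `area_cv` and mild aspect-ratio variation (1.0–1.25).

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `phase_fractions` | 0.70/0.20/0.10 | basal G1 occupancy of cycling near-diploid lines |
| `accessible_fraction` | 0.30 | basal condition; perturbations are multipliers of it |
| `accessible_cv` | 0.05 | within-phase spread consistent with the sharp G1/G2 modes of measured integral histograms |
| `g1_mean_area_px` | 260 px | a ~23 μm G1 nucleus at the 4× pixel pitch of 1.28 μm, comfortably inside the 15–40 μm object gate |
| `brightness` | 2·10⁶ | per-pixel means of a few thousand counts — mid-range for a 16-bit camera |
| `background_level` | 200 | typical camera offset scale |
| noise | Gaussian σ = 10 (or Poisson–Gaussian) | shot/read noise small relative to signal, as in the assay's exposure regime |

Rendering places non-rotated, non-overlapping filled ellipses on a jittered
grid (grid pitch guarantees the separation precondition deterministically),
adds an optional cytoplasmic halo when the dye is applied without RNase A
(emulating removable double-stranded-RNA staining), quantises to integers
and clips at the detector ceiling (65535). The ground-truth table reports,
per cell, the analytic per-pixel mean times the realised pixel count — the
value a perfect background-subtracted measurement over the true mask would
return (exact up to ±0.5/pixel quantisation).

Not emulated: optics (PSF, z-structure, vignetting), focus errors, nucleus
rotation or overlap (the assay removes clusters by size gating rather than
splitting them), fixation chemistry, drug pharmacokinetics, or spatial
heterogeneity of chromatin within a nucleus. Passing tests therefore show
that the measurement and analysis chain is correct under the stated signal
model, not that the model captures all features of real plates — in
particular, real within-phase variability has staining and illumination
components this generator folds into a single CV.

## Quantification

Masking: Gaussian smoothing (σ = 1 px), Otsu global threshold, hole filling,
removal of objects under 10 px, 8-connected labelling; touching nuclei are
deliberately not split. The instrument's own masking algorithm is
proprietary; this is the simplest chain that recovers exactly the generated
object count on separated nuclei. A constant image yields no objects; a
fully saturated image raises a warning; objects containing any saturated
pixel are flagged (`saturated`), not dropped — automatic quantitation of an
easily overexposed dye deserves a visible flag rather than silent censoring.

Per object: `pixel_count`; `mean` and `integral` of background-subtracted
intensity (background defaults to the median outside the mask; adding a
constant to the image and to the stated background leaves every record
unchanged); `area_um2 = pixel_count × 1.64825` (the 4× per-pixel area, an
instrument constant independent of the 1.28 μm pixel length); `size_um` =
maximum pairwise pixel-center distance (max Feret diameter, convex-hull
accelerated) × 1.28, with single-pixel objects counted as one pixel long.
The identities `integral = mean × pixel_count` and
`integral/area_um2 = mean/1.64825` hold to floating precision on every
record. The 10× calibration (0.512 μm, 0.262144 μm²) is derived from the 4×
pixel pitch, not instrument-reported. The size gate keeps
15 μm ≤ size ≤ 40 μm inclusive (the instrument's rule excludes strictly
below/above, so boundary values are kept).

## Cell-cycle analysis

`find_g1_g2_peaks` estimates a Gaussian-KDE density of the per-object
integrals on a 512-point grid (bandwidth: 0.9·min(SD, IQR/1.34)·n^(−1/5),
fixed override available for reproducibility), extracts local maxima with
prominences, and returns the pair whose position ratio lies in [1.7, 2.3]
(a window around the DNA-doubling ratio 2) with the greatest combined
prominence; G1 is the smaller position. Peak positions are refined by
3-point parabolic interpolation and are equivariant under positive rescaling
of the input. No admissible pair → `unimodal` (most prominent peak reported
as G1); fewer than 50 values → `ambiguous`. This pair-search definition is
this package's own; only the G1/G2 bimodality it detects is empirical. Full
cell-cycle deconvolution (Dean–Jett–Fox-style mixture fitting) is out of
scope. Peaks are located on condition-pooled objects by default (per-well
optional).

Phase windows are ±12% around each peak (a CV-5% G1 mode is ~98.4% captured;
Φ(2.4) − Φ(−2.4) = 0.9836), non-overlapping by construction for a ratio-2
pair. `g1_fraction` counts the G1 window plus the sub-G1 tail. EdU
positivity is called by an exact 1-D Otsu split of log EdU means — exact
(sorted-sample, no histogram binning) so that a detector-gain change, which
shifts every log value equally, cannot alter the classification; if the two
classes separate by less than 1 natural-log unit the channel is treated as
unimodal and a configured fixed threshold (or all-negative) is used.

A selection effect worth knowing about: gating EdU comparisons on the
*measured* integral window slightly depresses the accessible fraction of
admitted early-S cells (they pass the G1 window only when below-average
accessibility offsets their above-G1 DNA content), producing a ~2% downward
shift of the EdU-positive mean that a rank test will detect at very large n
even though matched true DNA content shows an exact null. At per-well object
counts the shift is far below detection; it is a property of integral-window
matching itself, not of the implementation.

## Statistics

Pooled per-object values are compared with Kruskal–Wallis (tie-corrected,
scipy) plus Dunn's post hoc z tests implemented here —
`z = (R̄ᵢ − R̄ⱼ)/√((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ))`, two-sided
normal p — with Holm step-down adjustment (statsmodels) over the reported
family: each-vs-control by default, all-pairs optional. Per-well quantities
(object counts, well averages) are compared with one-way ANOVA plus Tukey
HSD (statsmodels). All-identical inputs yield defined degenerate results
(H = 0, p = 1; flagged ANOVA) instead of errors. Fold changes divide each
well's average by the mean of the reference wells' averages and summarise
conditions by mean ± sample SD across replicate wells. Violin summaries
report quartiles by linear interpolation between order statistics
(`numpy.quantile` default). P-values are reported to 3 decimals with "ns"
above 0.05; raw values are kept in machine output. Well nesting is not
modelled (no mixed effects).

## Problem sizes and numerical choices

Tests and the acceptance script use n = 8,000–20,000 cells for
histogram-level properties (the regime where peak positions are stable to
≪1%), 40–60 rendered nuclei per 384×384 well (fill factor ~10%, matching
sparse plating), and 4 replicate wells per condition. KDE grid resolution
(512 points over the data range) bounds peak-position quantisation at well
under 0.5% before parabolic refinement. Degenerate inputs — empty
populations, blank images, constant values, single-well groups — all have
defined, tested behaviour rather than exceptions where a result is
representable.
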