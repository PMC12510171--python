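# chromaccess

Imaging-cytometry quantification of **global chromatin accessibility** from
DNA-dye-stained nuclei.

Fluorescent DNA ligands — intercalators (propidium iodide, SYBR Green) and
minor-groove binders (DAPI, Hoechst) — bind nucleosome-free DNA better than
nucleosomal DNA, so the fluorescence of a fixed, stained nucleus imaged with
a low-magnification widefield objective (whose focal depth spans the whole
nucleus) reports the amount of accessible DNA in that cell. This package is
for cell biologists running such plate-based assays: it turns well images
into per-nucleus measurements and group comparisons, and it ships a
ground-truth simulator so the whole chain is testable without any microscope.

The signal model at the core: for a nucleus with relative DNA content *c*
(1 in G1, 2 in G2/M), accessible chromatin fraction *a*, and dye dose-response
*r(d)* (linear-to-saturation for PI-like dyes, bell-shaped
*(d/d_opt)·e^{1−d/d_opt}* for SYBR-Green-like dyes),

    integral I = B · c · a · r(d),        mean M = I / area,   area ∝ c

so the **integral** tracks DNA content (bimodal G1/G2 histogram; the
positions of the two peaks and their ratio ≈ 2 are found by KDE peak
detection), while the per-pixel **mean** cancels DNA content and reads out
accessibility *a* independently of cell-cycle phase. Objects are calibrated
(4×: 1.28 μm/pixel, 1.64825 μm²/pixel), size-gated to 15–40 μm to remove
debris and clusters, and compared across conditions with Kruskal–Wallis +
Dunn + Holm (pooled per-object values) and ANOVA + Tukey (per-well counts).

## Worked example

Simulate a two-condition plate (basal accessible fraction 0.30 vs an opened
0.45, four replicate wells of 60 nuclei each), then run the full pipeline:

```python
import chromaccess as ca
from chromaccess.simulate import ConditionSpec
from chromaccess.pipeline import PipelineConfig, run_pipeline

conds = [
    ConditionSpec("control", ca.PopulationParams(n_cells=60, accessible_fraction=0.30), n_wells=4),
    ConditionSpec("treated", ca.PopulationParams(n_cells=60, accessible_fraction=0.45), n_wells=4),
]
ca.generate_plate(conds, ca.RenderParams(noise_model="gaussian"), "demo", seed=1)
rep = run_pipeline(PipelineConfig(images_dir="demo", layout="demo/plate1_layout.csv",
                                  output_dir="demo/results", reference_condition="control"))
print(rep.peaks)
```

This prints (numbers from an actual run with seed 1):

```
peaks: control g1_x=600805.0  g2_x=1184785.3  ratio=2.0  quality=ok
       treated g1_x=902934.9  g2_x=1768697.9  ratio=2.0  quality=ok
```

Both conditions show the G2/M peak at twice the G1 peak (DNA doubling), and
the treated G1 peak sits at 902935/600805 = 1.50× the control one — the
simulated 0.45/0.30 accessibility ratio, recovered at equal ploidy. The
written tables agree: the median per-object mean is 2313 (control) vs 3457
(treated), the per-well fold change is 1.502 ± 0.014 across replicates, and
the pooled Kruskal–Wallis comparison gives H = 359.3 with Holm-adjusted
Dunn p reported as 0.000, while ANOVA on per-well object counts (60
everywhere) is "ns" — the effect is in accessibility, not cell number.

The same run from a shell:

```sh
chromaccess simulate --out-dir demo --seed 1
chromaccess run-all --config demo/config.yaml
chromaccess compare demo/results/objects.csv
```

Other entry points: `segment_nuclei` / `measure_objects` / `apply_size_gate`
for your own TIFFs (plus a layout CSV with well, condition, replicate,
channels), `find_g1_g2_peaks` / `gate_phases` / `gate_edu` for cell-cycle
work, and `kruskal_dunn_holm` / `anova_tukey` / `fold_change_per_well` /
`distribution_summary` for statistics. See `docs/methods.md` for the model,
parameter defaults and numerical conventions.

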