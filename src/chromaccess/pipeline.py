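"""End-to-end plate analysis: quantify -> gate -> peaks -> statistics.

A single config (YAML file or :class:`PipelineConfig`) drives the whole run;
the effective config is embedded in the report for provenance, and a fixed
config plus fixed inputs reproduces byte-identical output tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cellcycle import PeakParams, PhaseWindows, find_g1_g2_peaks, gate_edu, gate_phases
from .groupstats import anova_tukey, fold_change_per_well, kruskal_dunn_holm
from .quantify import CALIBRATIONS, SegmentationParams, SizeGate, quantify_plate

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    images_dir: str = "."
    layout: str = "plate1_layout.csv"
    output_dir: str = "results"
    calibration: str = "4x"
    dna_channel: str = "dna"
    edu_channel: str | None = None  # set to e.g. "edu" to enable EdU analysis
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    size_gate: SizeGate = field(default_factory=SizeGate)
    peaks: PeakParams = field(default_factory=PeakParams)
    windows: PhaseWindows = field(default_factory=PhaseWindows)
    reference_condition: str | None = None  # default: first condition in layout
    dunn_mode: str = "control"  # {"control", "all"}
    peaks_per_well: bool = False  # default: pool objects per condition
    edu_fallback_threshold: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("segmentation", "size_gate", "peaks", "windows"):
            if key in raw:
                sub = getattr(cfg, key)
                for k, v in (raw.pop(key) or {}).items():
                    if not hasattr(sub, k):
                        raise ValueError(f"unknown {key} option '{k}'")
                    setattr(sub, k, v)
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config option '{k}'")
            setattr(cfg, k, v)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunReport:
    status: dict
    well_counts: dict
    peaks: dict
    config: dict
    version: str
    output_files: list[str]


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return a list of violations; an empty list means the config is usable."""
    issues: list[str] = []
    if cfg.calibration not in CALIBRATIONS:
        issues.append(f"calibration: unknown objective '{cfg.calibration}'")
    if not (cfg.size_gate.min_um < cfg.size_gate.max_um):
        issues.append("SizeGate: min_um must be < max_um")
    try:
        cfg.segmentation.validate()
    except ValueError as e:
        issues.append(f"segmentation: {e}")
    try:
        cfg.peaks.validate()
    except ValueError as e:
        issues.append(f"peaks: {e}")
    if not (0 < cfg.windows.half_width < 0.5):
        issues.append("windows: half_width must be in (0, 0.5)")
    if cfg.dunn_mode not in ("control", "all"):
        issues.append("dunn_mode must be 'control' or 'all'")
    if not isinstance(cfg.seed, int):
        issues.append("seed must be an integer")

    layout_path = Path(cfg.layout)
    if not layout_path.exists():
        issues.append(f"layout file not found: {cfg.layout}")
        return issues
    layout = pd.read_csv(layout_path)
    missing_cols = {"well", "condition"} - set(layout.columns)
    if missing_cols:
        issues.append(f"layout missing columns: {sorted(missing_cols)}")
        return issues
    if layout["well"].duplicated().any():
        dups = layout.loc[layout["well"].duplicated(), "well"].tolist()
        issues.append(f"duplicate well IDs in layout: {dups}")
    images_dir = Path(cfg.images_dir)
    for _, row in layout.iterrows():
        plate = row.get("plate", "plate1")
        f = images_dir / f"{plate}_{row['well']}_{cfg.dna_channel}.tif"
        if not f.exists():
            issues.append(f"well {row['well']}: missing image {f.name}")
        if cfg.edu_channel:
            channels = str(row.get("channels", cfg.dna_channel)).split(";")
            if cfg.edu_channel not in channels:
                issues.append(
                    f"well {row['well']}: EdU analysis requested but channel "
                    f"'{cfg.edu_channel}' not listed for this well"
                )
    return issues


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Run quantification, gating, peak detection and statistics; write outputs.

    Writes ``objects.csv`` (size-gated, phase- and EdU-annotated), per-well
    ``well_summary.csv``, ``peaks.json``, ``fold_change.csv``,
    ``stats_pairwise.csv`` and ``report.json`` under ``cfg.output_dir``.
    Wells whose images are missing are reported with an error status and do
    not stop the remaining wells.
    """
    issues = validate_config(cfg)
    if issues:
        raise ValueError("invalid pipeline config:\n- " + "\n- ".join(issues))

    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = pd.read_csv(cfg.layout)

    objects, well_summary = quantify_plate(
        layout,
        cfg.images_dir,
        sp=cfg.segmentation,
        cal=CALIBRATIONS[cfg.calibration],
        gate=cfg.size_gate,
        dna_channel=cfg.dna_channel,
        edu_channel=cfg.edu_channel or "",
    )

    conditions = list(layout["condition"].drop_duplicates())
    reference = cfg.reference_condition or conditions[0]

    # G1/G2 peaks on the integral distribution, pooled per condition
    peaks_out: dict[str, dict] = {}
    annotated = []
    group_key = "well" if cfg.peaks_per_well else "condition"
    for key, sub in objects.groupby(group_key, sort=False):
        try:
            pk = find_g1_g2_peaks(sub["integral"], cfg.peaks)
            peaks_out[str(key)] = dict(
                g1_x=pk.g1_x, g2_x=pk.g2_x, ratio=pk.ratio, quality=pk.quality
            )
            annotated.append(gate_phases(sub, pk, cfg.windows))
        except ValueError as e:
            peaks_out[str(key)] = dict(error=str(e))
            sub = sub.copy()
            sub["phase_gate"] = "other"
            annotated.append(sub)
    objects = (
        pd.concat(annotated, ignore_index=True) if annotated else objects
    )

    if cfg.edu_channel and len(objects):
        pos, thr = gate_edu(
            objects["edu_mean"], fallback_threshold=cfg.edu_fallback_threshold
        )
        objects["edu_positive"] = pos
        peaks_out["_edu_threshold"] = dict(threshold=thr)

    # statistics: KW/Dunn/Holm on pooled per-object means, ANOVA/Tukey on
    # per-well counts, per-well fold change of well-average mean
    stats_rows = []
    mean_groups = {
        c: objects.loc[objects["condition"] == c, "mean"].to_numpy()
        for c in conditions
        if (objects["condition"] == c).any()
    }
    if len(mean_groups) >= 2:
        kw = kruskal_dunn_holm(mean_groups, control=reference, mode=cfg.dunn_mode)
        tab = kw.formatted()
        tab.insert(0, "test", kw.test)
        tab.insert(1, "global_statistic", kw.statistic)
        tab.insert(2, "global_p", kw.pvalue)
        stats_rows.append(tab)

    count_groups = {
        c: well_summary.loc[well_summary["condition"] == c, "n_objects"].to_numpy()
        for c in conditions
    }
    if all(v.size >= 2 for v in count_groups.values()) and len(count_groups) >= 2:
        an = anova_tukey(count_groups)
        tab = an.formatted()
        tab.insert(0, "test", an.test)
        tab.insert(1, "global_statistic", an.statistic)
        tab.insert(2, "global_p", an.pvalue)
        stats_rows.append(tab)

    stats_table = (
        pd.concat(stats_rows, ignore_index=True) if stats_rows else pd.DataFrame()
    )
    fc_well, fc_cond = fold_change_per_well(well_summary, reference)

    files = []
    for name, df in [
        ("objects.csv", objects),
        ("well_summary.csv", well_summary),
        ("fold_change.csv", fc_cond),
        ("fold_change_per_well.csv", fc_well),
        ("stats_pairwise.csv", stats_table),
    ]:
        df.to_csv(out_dir / name, index=False)
        files.append(str(out_dir / name))

    report = RunReport(
        status={
            str(r["well"]): str(r["status"]) for _, r in well_summary.iterrows()
        },
        well_counts={
            str(r["well"]): int(r["n_objects"]) for _, r in well_summary.iterrows()
        },
        peaks=peaks_out,
        config=cfg.to_dict(),
        version=__version__,
        output_files=files,
    )
    with open(out_dir / "peaks.json", "w") as fh:
        json.dump(peaks_out, fh, indent=2)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(asdict(report), fh, indent=2)
    files += [str(out_dir / "peaks.json"), str(out_dir / "report.json")]
    return report
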