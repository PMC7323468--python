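"""End-to-end orchestration: phantom → maps → ROI table → tracts → statistics.

This module is the library behind the command-line interface and the
reproducibility script: it runs the full per-subject analysis (Dixon
decomposition, tensor fit, ROI aggregation, tractography) and the group
statistics, and writes the standard-format outputs (NIfTI maps, TrackVis
tracts, CSV tables, a text summary).
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import dixon, phantom, roi, tract
from .dti import DiffusionTensorModel
from .grids import DwiSeries, ImageVolume
from .stats import MuscleLevelANOVA

log = logging.getLogger("lumbarqmri")

__all__ = ["RunConfig", "SubjectResult", "analyze_subject", "run", "load_run_config"]

MODES = ("simulate", "analyze", "full")


@dataclass
class RunConfig:
    mode: str = "full"
    output_dir: str = "lumbarqmri_out"
    seed: int = 0
    n_subjects: int = 10
    between_subject_cv: float = 0.10
    snr: float | None = 40.0
    volume_scale: float = 1.0
    alpha: float = 0.05
    log_level: str = "INFO"
    write_maps: bool = True
    track_streamlines: bool = True
    max_seeds: int | None = 400
    tract: tract.TractographyConfig = field(default_factory=tract.TractographyConfig)
    anova_metrics: tuple[str, ...] = ("volume_ml", "fat_fraction", "fa", "md")

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.max_seeds is not None:
            self.tract = dataclasses.replace(self.tract, max_seeds=self.max_seeds)

    def phantom_config(self) -> phantom.PhantomConfig:
        return phantom.default_config(
            n_subjects=self.n_subjects,
            between_subject_cv=self.between_subject_cv,
            snr=self.snr,
            seed=self.seed,
            volume_scale=self.volume_scale,
        )

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["tract"] = dataclasses.asdict(self.tract)
        return yaml.safe_dump(d, sort_keys=False)


def load_run_config(path: str | None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus explicit overrides
    (flags override config-file values; None overrides are ignored)."""
    data: dict = {}
    if path:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    tr = data.pop("tract", {})
    data.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(**{k: v for k, v in data.items() if k != "tract"})
    if tr:
        cfg.tract = dataclasses.replace(cfg.tract, **tr)
        if cfg.max_seeds is not None and "max_seeds" not in tr:
            cfg.tract = dataclasses.replace(cfg.tract, max_seeds=cfg.max_seeds)
    return cfg


@dataclass
class SubjectResult:
    subject: int
    records: pd.DataFrame
    fat_water: dixon.FatWaterMaps
    diffusion_maps: object
    tracts: dict
    fraction_above_045: float
    labeled_voxels_dixon: int


def analyze_subject(
    ds: phantom.PhantomDataset,
    tract_config: tract.TractographyConfig | None = None,
    fit_diffusion: bool = True,
    track_streamlines: bool = True,
) -> SubjectResult:
    """Run the measurement pipeline on one subject's dataset."""
    fw = None
    if ds.in_phase is not None:
        fw = dixon.decompose(ds.in_phase, ds.out_of_phase)

    dmaps = None
    tracts: dict = {}
    if fit_diffusion and ds.dwi is not None:
        labels_dwi = roi.resample_mask(ds.label_volume, ds.dwi.grid)
        fit = DiffusionTensorModel(ds.dwi, mask=labels_dwi).fit()
        dmaps = fit.maps
        if track_streamlines:
            cfg = tract_config or tract.TractographyConfig()
            for muscle, lab in roi.LABELS.items():
                sset = tract.track(
                    fit.field,
                    labels_dwi.data == lab,
                    cfg,
                    seed=ds.subject,
                )
                tracts[muscle] = sset

    records = roi.aggregate(
        ds.subject,
        ds.label_volume,
        ds.level_boundaries,
        fat_fraction=fw.fat_fraction if fw else None,
        fat_flagged=fw.flagged if fw else None,
        diffusion_maps=dmaps,
    )
    frac = float("nan")
    n_labeled = 0
    if fw is not None:
        labels_dixon = roi.resample_mask(ds.label_volume, fw.fat_fraction)
        frac = dixon.fraction_above(fw.fat_fraction, labels_dixon, 0.45)
        n_labeled = int((labels_dixon.data > 0).sum())
    return SubjectResult(
        subject=ds.subject,
        records=records,
        fat_water=fw,
        diffusion_maps=dmaps,
        tracts=tracts,
        fraction_above_045=frac,
        labeled_voxels_dixon=n_labeled,
    )


def _write_maps(outdir: str, sid: str, result: SubjectResult):
    os.makedirs(outdir, exist_ok=True)
    if result.fat_water is not None:
        result.fat_water.fat_fraction.save(os.path.join(outdir, f"{sid}_ff.nii.gz"))
    if result.diffusion_maps is not None:
        for name, vol in result.diffusion_maps.as_dict().items():
            vol.save(os.path.join(outdir, f"{sid}_{name}.nii.gz"))


def _summarize(table: pd.DataFrame, anovas: dict, fraction_above: float) -> str:
    lines = ["lumbarqmri run summary", "=" * 40, ""]
    means = table.groupby("muscle")[["volume_ml", "fat_fraction"]].mean()
    for muscle in roi.MUSCLES:
        lines.append(
            f"{muscle}: mean volume {means.loc[muscle, 'volume_ml']:.1f} mL, "
            f"mean fat fraction {means.loc[muscle, 'fat_fraction']:.3f}"
        )
    pooled = table.groupby("level")["fat_fraction"].mean()
    lines.append(
        "pooled fat fraction by level: "
        + ", ".join(f"{lv} {pooled[lv]:.3f}" for lv in roi.LEVELS)
    )
    lines.append(f"fraction of muscle voxels with fat fraction > 0.45: {fraction_above:.3f}")
    lines.append("")
    for metric, res in anovas.items():
        lines.append(res.summary())
        lines.append("")
    return "\n".join(lines)


def run(config: RunConfig) -> dict:
    """Execute a configured run; returns paths and in-memory results."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "run_config.yaml"), "w") as fh:
        fh.write(config.to_yaml())

    pcfg = config.phantom_config()
    outputs: dict = {"output_dir": out}

    if config.mode == "simulate":
        log.info("simulating %d subjects", pcfg.n_subjects)
        pdir = os.path.join(out, "phantom")
        for ds in phantom.generate_dataset(pcfg):
            phantom.write_dataset(ds, pdir)
            log.info("wrote subject %d", ds.subject)
        outputs["phantom_dir"] = pdir
        return outputs

    if config.mode == "analyze":
        pdir = os.path.join(out, "phantom")
        if not os.path.isdir(pdir):
            raise FileNotFoundError(
                f"analyze mode expects simulated data under {pdir} (run simulate first)"
            )
        datasets = phantom.iter_subjects(pdir)
    else:
        datasets = phantom.generate_dataset(pcfg)

    frames = []
    frac_num = 0.0
    frac_den = 0
    for ds in datasets:
        log.info("stage: analyze subject %d", ds.subject)
        res = analyze_subject(
            ds, config.tract, track_streamlines=config.track_streamlines
        )
        frames.append(res.records)
        frac_num += res.fraction_above_045 * res.labeled_voxels_dixon
        frac_den += res.labeled_voxels_dixon
        sid = f"sub-{ds.subject:02d}"
        if config.write_maps:
            _write_maps(os.path.join(out, "maps"), sid, res)
        for muscle, sset in res.tracts.items():
            if len(sset):
                tdir = os.path.join(out, "tracts")
                os.makedirs(tdir, exist_ok=True)
                tract.write_trk(
                    sset, ds.dwi.grid, os.path.join(tdir, f"{sid}_{muscle}.trk")
                )

    table = roi.build_level_table(frames)
    table_path = os.path.join(out, "level_table.csv")
    table.to_csv(table_path, index=False)
    outputs["level_table"] = table_path

    anovas = {}
    rows = []
    for metric in config.anova_metrics:
        if table[metric].isna().all():
            continue
        try:
            model = MuscleLevelANOVA(table, metric, alpha=config.alpha)
            res = model.fit()
        except Exception as exc:  # zero-variance or unbalanced runs
            log.warning("stage: anova(%s) skipped: %s", metric, exc)
            continue
        anovas[metric] = res
        for _, r in res.effects.iterrows():
            rows.append(dict(metric=metric, kind="omnibus", **r.to_dict()))
        for _, r in res.posthoc.iterrows():
            rows.append(dict(metric=metric, kind="posthoc", **r.to_dict()))
    if rows:
        pd.DataFrame(rows).to_csv(os.path.join(out, "anova.csv"), index=False)
        outputs["anova"] = os.path.join(out, "anova.csv")

    frac = frac_num / frac_den if frac_den else float("nan")
    summary = _summarize(table, anovas, frac)
    with open(os.path.join(out, "summary.txt"), "w") as fh:
        fh.write(summary)
    outputs["summary"] = os.path.join(out, "summary.txt")
    outputs["table"] = table
    outputs["anovas"] = anovas
    outputs["fraction_above_045"] = frac
    return outputs
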