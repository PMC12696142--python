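"""Pipeline driver: simulate -> fit-fwe -> profile -> analyze -> report.

Each stage reads its inputs from, and writes its outputs to, a workspace
directory, so stages are resumable: a stage whose outputs already exist is
reused unless ``force`` is set. A run manifest records the configuration
hash, seeds, checksums and the files each stage produced.
"""
from __future__ import annotations


import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, io as fio
from . import stats as cs
from .fwe import FitConfig, fit_free_water
from .synthetic import CohortConfig, generate_cohort, make_diffusion_scheme
from .tractometry import profile_bundle

__version__ = "0.1.0"
log = logging.getLogger("fwetract")


def _manifest_path(workspace: Path) -> Path:
    return workspace / "run_manifest.json"


def _load_manifest(workspace: Path) -> dict:
    p = _manifest_path(workspace)
    if p.exists():
        return json.loads(p.read_text())
    return {"tool_version": __version__, "stages": {}}


def _save_manifest(workspace: Path, manifest: dict) -> None:
    _manifest_path(workspace).write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))


def _record_stage(workspace: Path, manifest: dict, stage: str,
                  outputs: list[Path], extra: dict | None = None) -> None:
    manifest["stages"][stage] = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {str(p): fio.file_checksum(p) for p in outputs if p.exists()},
        **(extra or {}),
    }
    _save_manifest(workspace, manifest)


def stage_simulate(workspace: str | Path, config: CohortConfig,
                   simulate_signals: bool = False, force: bool = False) -> dict:
    workspace = Path(workspace)
    workspace.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(workspace)
    cohort_dir = workspace / "cohort"
    if (cohort_dir / "manifest.json").exists() and not force:
        log.info("simulate: reusing existing cohort in %s", cohort_dir)
        return json.loads((cohort_dir / "manifest.json").read_text())
    records, cohort_manifest = generate_cohort(
        config, out_dir=cohort_dir, compute_profiles=False,
        simulate_signals=simulate_signals)
    manifest["config_hash"] = fio.config_hash(cohort_manifest["config"])
    manifest["seed"] = config.seed
    _record_stage(workspace, manifest, "simulate",
                  [cohort_dir / "manifest.json"],
                  {"n_subjects": len(records)})
    return cohort_manifest


def stage_fit_fwe(workspace: str | Path, fit_config: FitConfig | None = None,
                  force: bool = False) -> list[Path]:
    """Fit the free-water model for every subject with simulated signals."""
    workspace = Path(workspace)
    manifest = _load_manifest(workspace)
    cohort_manifest = json.loads((workspace / "cohort" / "manifest.json").read_text())
    cfg = cohort_manifest["config"]
    scheme = make_diffusion_scheme(cfg["n_directions"], cfg["b_value"],
                                   cfg["n_b0"], seed=cfg["seed"])
    outputs = []
    for sub in cohort_manifest["subjects"]:
        dwi_path = sub["paths"].get("dwi")
        if dwi_path is None:
            log.info("fit-fwe: %s has no simulated signals; ground-truth maps "
                     "will be used downstream", sub["subject_id"])
            continue
        sub_dir = Path(dwi_path).parent
        out_fwf = sub_dir / "fit_fwf.nii.gz"
        if out_fwf.exists() and not force:
            outputs.append(out_fwf)
            continue
        import nibabel as nib
        dwi = np.asanyarray(nib.load(dwi_path).dataobj).astype(float)
        mask = np.ones(dwi.shape[:3], dtype=bool)
        fit = fit_free_water(dwi, scheme, mask, fit_config)
        affine = nib.load(dwi_path).affine
        from .volumes import MetricVolume
        for name, arr in (("fit_fwf", fit.fwf_map), ("fit_fw_fa", fit.fw_fa_map),
                          ("fit_fw_md", fit.fw_md_map)):
            outputs.append(fio.write_volume(MetricVolume(arr, affine),
                                            sub_dir / f"{name}.nii.gz"))
    _record_stage(workspace, manifest, "fit-fwe", outputs)
    return outputs


def stage_profile(workspace: str | Path, n_nodes: int = 100,
                  use_fitted_maps: bool = False, force: bool = False) -> Path:
    workspace = Path(workspace)
    manifest = _load_manifest(workspace)
    out_path = workspace / "profiles.csv"
    if out_path.exists() and not force:
        log.info("profile: reusing cached %s", out_path)
        return out_path
    cohort_manifest = json.loads((workspace / "cohort" / "manifest.json").read_text())
    frames = []
    metric_names = (("fit_fwf", "fit_fw_fa", "fit_fw_md")
                    if use_fitted_maps else ("fwf", "fw_fa", "fw_md"))
    rename = {"fit_fwf": "fwf", "fit_fw_fa": "fw_fa", "fit_fw_md": "fw_md"}
    for sub in cohort_manifest["subjects"]:
        seg = fio.read_volume(sub["paths"]["segmentation"], kind="label")
        metric_vols = {rename.get(m, m): fio.read_volume(
            str(Path(sub["paths"]["segmentation"]).parent / f"{m}.nii.gz"))
            for m in metric_names}
        profiles = {}
        for key, path in sub["paths"].items():
            if not key.startswith("bundle:"):
                continue
            tract, hemi = key[len("bundle:"):].split("/")
            bundle = fio.read_bundle(path, name=tract, hemisphere=hemi)
            profiles[f"{tract}/{hemi}"] = profile_bundle(
                bundle, metric_vols, seg, n_nodes)
        frames.append(fio.profiles_to_table(profiles, sub["subject_id"]))
    table = pd.concat(frames, ignore_index=True)
    fio.write_profiles(table, out_path)
    _record_stage(workspace, manifest, "profile", [out_path],
                  {"n_nodes": n_nodes, "maps": "fitted" if use_fitted_maps
                   else "ground-truth"})
    return out_path


def stage_analyze(workspace: str | Path, threshold: float = 5.0,
                  sweep: tuple[float, float] | None = None,
                  bins: tuple = cs.DEFAULT_BINS, force: bool = False
                  ) -> dict[str, Path]:
    workspace = Path(workspace)
    manifest = _load_manifest(workspace)
    out_dir = workspace / "analysis"
    out_dir.mkdir(exist_ok=True)
    cohort_manifest = json.loads((workspace / "cohort" / "manifest.json").read_text())
    meta = {s["subject_id"]: s for s in cohort_manifest["subjects"]}
    table = fio.read_profiles(workspace / "profiles.csv")
    per_subject = fio.table_to_profiles(table)
    subjects = [{"subject": sid, "pathology": meta[sid]["pathology"],
                 "tumor_hemisphere": meta[sid]["tumor_hemisphere"],
                 "profiles": profs} for sid, profs in per_subject.items()]

    outputs: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        df = df.assign(threshold_pct=threshold,
                       config_hash=manifest.get("config_hash", ""))
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format=fio.FLOAT_FORMAT)
        outputs[name] = path

    involvement = analysis.cohort_involvement_table(subjects, threshold)
    emit("involvement", involvement)
    emit("involvement_tests", analysis.involvement_group_tests(involvement))
    asymmetry = analysis.cohort_asymmetry_table(subjects, threshold=threshold,
                                                bins=bins)
    emit("asymmetry", asymmetry)
    emit("asymmetry_tests", analysis.asymmetry_group_tests(asymmetry))
    emit("fwf_edema_correlation", analysis.fwf_edema_correlations(subjects))
    if sweep is not None:
        lo, hi = sweep
        thresholds = list(np.arange(lo, hi + 1))
        emit("threshold_sweep",
             analysis.cohort_threshold_sweep(subjects, thresholds))
    _record_stage(workspace, manifest, "analyze", list(outputs.values()),
                  {"threshold": threshold})
    return outputs


def stage_report(workspace: str | Path) -> Path:
    """Static figure: group-mean asymmetry by distance segment per metric."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    workspace = Path(workspace)
    manifest = _load_manifest(workspace)
    asym = pd.read_csv(workspace / "analysis" / "asymmetry.csv")
    binned = asym[asym["level"] == "distance-segment"].dropna(
        subset=["asymmetry_pct"])
    metrics = sorted(binned["metric"].unique())
    segments = list(dict.fromkeys(
        asym[asym["level"] == "distance-segment"]["segment"]))
    fig, axes = plt.subplots(1, len(metrics), figsize=(5 * len(metrics), 4),
                             squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        sub = binned[binned["metric"] == metric]
        groups = sorted(sub["pathology"].unique())
        width = 0.8 / max(len(groups), 1)
        for gi, group in enumerate(groups):
            g = sub[sub["pathology"] == group]
            means = [g[g["segment"] == s]["asymmetry_pct"].mean()
                     for s in segments]
            sems = [g[g["segment"] == s]["asymmetry_pct"].sem()
                    for s in segments]
            x = np.arange(len(segments)) + gi * width
            ax.bar(x, means, width=width, yerr=sems, capsize=2, label=group)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xticks(np.arange(len(segments)) + 0.4)
        ax.set_xticklabels(segments)
        ax.set_xlabel("nodes from tumor margin")
        ax.set_ylabel("asymmetry (%)")
        ax.set_title(metric)
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    out = workspace / "analysis" / "distance_asymmetry.png"
    fig.savefig(out, dpi=120)
    plt.close(fig)
    _record_stage(workspace, manifest, "report", [out])
    return out


def run_pipeline(workspace: str | Path, config: CohortConfig | None = None,
                 stages: tuple[str, ...] = ("simulate", "profile", "analyze",
                                            "report"),
                 threshold: float = 5.0,
                 sweep: tuple[float, float] | None = None,
                 simulate_signals: bool = False,
                 fit_config: FitConfig | None = None,
                 n_nodes: int = 100, force: bool = False) -> dict:
    """Run the requested stages in order; returns the final run manifest."""
    config = config or CohortConfig()
    for stage in stages:
        log.info("stage: %s", stage)
        if stage == "simulate":
            stage_simulate(workspace, config, simulate_signals, force)
        elif stage == "fit-fwe":
            stage_fit_fwe(workspace, fit_config, force)
        elif stage == "profile":
            stage_profile(workspace, n_nodes, force=force)
        elif stage == "analyze":
            stage_analyze(workspace, threshold, sweep, force=force)
        elif stage == "report":
            stage_report(workspace)
        else:
            raise ValueError(f"unknown stage '{stage}'")
    return _load_manifest(Path(workspace))
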