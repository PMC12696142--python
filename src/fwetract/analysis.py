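"""Cohort-level assembly: per-subject summaries stacked into analysis tables
and the group-comparison layer run on top of them.

Test families for the FDR stratification follow the analysis design: one
family per tumor compartment for involvement comparisons and one family per
diffusion metric for asymmetry comparisons. Family labels are explicit
inputs to the correction, never inferred from the data.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats as cs
from .inference import (attach_q_values, group_regression, kruskal_wallis,
                        mann_whitney_pairwise, spearman)
from .tractometry import TractProfile

METRICS = ("fw_fa", "fw_md", "fwf")


def cohort_involvement_table(subjects: list[dict],
                             threshold: float = cs.DEFAULT_THRESHOLD
                             ) -> pd.DataFrame:
    """Involvement summaries per subject x bilateral tract group x compartment.

    ``subjects`` is a list of dicts with keys ``subject``, ``pathology`` and
    ``profiles`` (mapping to TractProfile); SubjectRecord instances work too.
    """
    rows = []
    for sub in _as_dicts(subjects):
        for s in cs.subject_involvement(sub["profiles"], threshold,
                                        sub["subject"]):
            rows.append({"subject": s.subject, "pathology": sub["pathology"],
                         "tract": s.tract, "compartment": s.compartment,
                         "involved": s.involved,
                         "proportion_involved": s.proportion_involved,
                         "threshold": s.threshold})
    return pd.DataFrame(rows)


def cohort_threshold_sweep(subjects: list[dict], thresholds: list[float]
                           ) -> pd.DataFrame:
    frames = [cs.threshold_sweep(sub["profiles"], thresholds, sub["subject"])
              .assign(pathology=sub["pathology"])
              for sub in _as_dicts(subjects)]
    return pd.concat(frames, ignore_index=True)


def cohort_asymmetry_table(subjects: list[dict],
                           metrics: tuple[str, ...] = METRICS,
                           threshold: float = cs.DEFAULT_THRESHOLD,
                           bins: tuple = cs.DEFAULT_BINS) -> pd.DataFrame:
    """Whole-tract and distance-binned asymmetries for every subject."""
    frames = []
    for sub in _as_dicts(subjects):
        df = cs.subject_asymmetry_table(sub["profiles"],
                                        sub["tumor_hemisphere"], metrics,
                                        threshold, bins, sub["subject"])
        frames.append(df.assign(pathology=sub["pathology"]))
    return pd.concat(frames, ignore_index=True)


def fwf_edema_correlations(subjects: list[dict], metric: str = "fwf"
                           ) -> pd.DataFrame:
    """Per-subject Spearman correlation between FWF node values and edema
    involvement fraction, pooled over all nodes of all tracts."""
    rows = []
    for sub in _as_dicts(subjects):
        fwf_vals, edema = [], []
        for prof in sub["profiles"].values():
            fwf_vals.append(prof.metrics[metric])
            edema.append(prof.involvement["edema"])
        rho, p = spearman(np.concatenate(fwf_vals), np.concatenate(edema))
        rows.append({"subject": sub["subject"], "pathology": sub["pathology"],
                     "rho": rho, "p_value": p})
    return pd.DataFrame(rows)


def involvement_group_tests(involvement: pd.DataFrame) -> pd.DataFrame:
    """Across-tract mean proportion involved per subject, compared across
    pathology groups; one FDR family per compartment."""
    per_subject = (involvement.groupby(
        ["subject", "pathology", "compartment"], as_index=False)
        ["proportion_involved"].mean())
    results = []
    for comp, grp in per_subject.groupby("compartment"):
        samples = {p: g["proportion_involved"].to_numpy()
                   for p, g in grp.groupby("pathology")}
        if len(samples) < 2:
            continue
        results.append(kruskal_wallis(samples, family=f"involvement:{comp}"))
        results.extend(mann_whitney_pairwise(samples,
                                             family=f"involvement:{comp}"))
    attach_q_values(results)
    return _results_frame(results)


def asymmetry_group_tests(asymmetry: pd.DataFrame) -> pd.DataFrame:
    """Pairwise group comparisons of subject-level asymmetry, whole-tract and
    per distance segment; one FDR family per diffusion metric."""
    results = []
    keys = []
    for (metric, level, segment), grp in asymmetry.groupby(
            ["metric", "level", "segment"]):
        vals = grp.dropna(subset=["asymmetry_pct"])
        samples = {p: g["asymmetry_pct"].to_numpy()
                   for p, g in vals.groupby("pathology") if len(g) > 0}
        if len(samples) < 2:
            continue
        fam = f"asymmetry:{metric}"
        kw = kruskal_wallis(samples, family=fam)
        pw = mann_whitney_pairwise(samples, family=fam)
        for r in [kw] + pw:
            results.append(r)
            keys.append((metric, level, segment))
    attach_q_values(results)
    frame = _results_frame(results)
    key_frame = pd.DataFrame(keys, columns=["metric", "level", "segment"],
                             index=frame.index)
    return pd.concat([frame, key_frame], axis=1)


def asymmetry_group_regressions(asymmetry: pd.DataFrame) -> list:
    """OLS of subject-level whole-tract asymmetry on pathology dummies
    (glioblastoma reference), no age/sex covariates: asymmetry is a
    within-subject quantity."""
    out = []
    whole = asymmetry[asymmetry["level"] == "whole-tract"]
    for metric, grp in whole.groupby("metric"):
        vals = grp.dropna(subset=["asymmetry_pct"])
        out.append(group_regression(vals["asymmetry_pct"].to_numpy(),
                                    vals["pathology"], family="linear",
                                    outcome_name=f"asymmetry:{metric}"))
    return out


def _as_dicts(subjects) -> list[dict]:
    out = []
    for sub in subjects:
        if isinstance(sub, dict):
            out.append(sub)
        else:  # SubjectRecord-like
            out.append({"subject": sub.subject_id, "pathology": sub.pathology,
                        "tumor_hemisphere": sub.tumor_hemisphere,
                        "profiles": sub.profiles})
    return out


def _results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "test": r.test, "family": r.family, "groups": "|".join(r.groups),
        "statistic": r.statistic, "p_value": r.p_value, "q_value": r.q_value,
        "effect_direction": r.effect_direction, "flag": r.flag,
    } for r in results])
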