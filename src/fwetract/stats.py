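"""Cohort-level summary statistics for tract profiles.

Implements the involvement summaries (subject-level binarization, tract-level
proportions, threshold sensitivity sweep) and the hemispheric asymmetry
analysis: directional percent asymmetry at paired homologous nodes outside
tumor-involved regions, collapsed per tract and per subject, optionally
resolved by along-tract node distance from the tumor margin.

Conventions (strict, as printed in the definitions):
- a node is *involved* when its combined involvement fraction is strictly
  greater than the threshold;
- a node pair is *eligible* for asymmetry when the ipsilateral combined
  fraction is strictly below the threshold;
- a node with fraction exactly at the threshold is therefore neither.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tractometry import TractProfile, classify_involved

DEFAULT_THRESHOLD = 5.0  # percent
DEFAULT_BINS: tuple[tuple[int, float], ...] = (
    (1, 5), (6, 10), (11, 15), (16, 20), (21, np.inf))
COMPARTMENT_KEYS = ("enhancing", "necrotic", "edema", "combined")


def bin_label(lo: int, hi: float) -> str:
    return f"≥{lo}" if np.isinf(hi) else f"{lo}–{hi:.0f}"


@dataclass
class InvolvementSummary:
    subject: str
    tract: str
    compartment: str
    involved: bool
    proportion_involved: float
    threshold: float
    n_nodes: int
    single_hemisphere: bool = False


def bilateral_group(value_left: float | None, value_right: float | None
                    ) -> tuple[float, bool]:
    """Mean of the two hemisphere values; falls back to the available one.

    Returns ``(value, single_hemisphere_flag)``; both missing yields NaN.
    """
    left_ok = value_left is not None and np.isfinite(value_left)
    right_ok = value_right is not None and np.isfinite(value_right)
    if left_ok and right_ok:
        return (value_left + value_right) / 2.0, False
    if left_ok:
        return float(value_left), True
    if right_ok:
        return float(value_right), True
    return float("nan"), True


def subject_involvement(profiles: dict[str, TractProfile],
                        threshold: float = DEFAULT_THRESHOLD,
                        subject: str = "") -> list[InvolvementSummary]:
    """Involvement summaries per bilateral tract group and compartment.

    ``profiles`` maps "{tract}/{hemisphere}" (or any key) to TractProfile;
    homologues are pooled by tract name: with both hemispheres present a
    group has 2 x n_nodes nodes. ``involved`` is True when any pooled node's
    fraction strictly exceeds the threshold; the proportion is the involved
    share of pooled nodes.
    """
    by_tract: dict[str, list[TractProfile]] = {}
    for prof in profiles.values():
        by_tract.setdefault(prof.tract, []).append(prof)

    out = []
    for tract, profs in sorted(by_tract.items()):
        hemis = {p.hemisphere for p in profs}
        single = len(hemis) < 2
        for comp in COMPARTMENT_KEYS:
            fractions = np.concatenate([p.involvement[comp] for p in profs])
            flags = classify_involved(fractions, threshold)
            out.append(InvolvementSummary(
                subject=subject, tract=tract, compartment=comp,
                involved=bool(flags.any()),
                proportion_involved=float(flags.mean()),
                threshold=threshold, n_nodes=len(fractions),
                single_hemisphere=single))
    return out


def threshold_sweep(profiles: dict[str, TractProfile],
                    thresholds: list[float], subject: str = "") -> pd.DataFrame:
    """Involvement summaries recomputed at each threshold, stacked long-format."""
    rows = []
    for thr in thresholds:
        if not 0 <= thr <= 100:
            raise ValueError(f"threshold {thr} outside [0, 100]")
        for s in subject_involvement(profiles, thr, subject):
            rows.append({"subject": s.subject, "tract": s.tract,
                         "compartment": s.compartment, "threshold": thr,
                         "involved": s.involved,
                         "proportion_involved": s.proportion_involved})
    return pd.DataFrame(rows)


def contralateral_mean(profiles: dict[str, TractProfile], tumor_hemisphere: str,
                       metric: str) -> float:
    """Mean metric over all nodes of all contralateral-hemisphere tracts."""
    if tumor_hemisphere not in ("left", "right"):
        raise ValueError("tumor hemisphere must be 'left' or 'right'")
    contra = "right" if tumor_hemisphere == "left" else "left"
    values = [p.metrics[metric] for p in profiles.values() if p.hemisphere == contra]
    if not values:
        return float("nan")
    pooled = np.concatenate(values)
    return float(np.nanmean(pooled)) if np.isfinite(pooled).any() else float("nan")


def node_asymmetry(ipsilateral: float | np.ndarray,
                   contralateral: float | np.ndarray) -> float | np.ndarray:
    """Directional percent asymmetry of a paired node value.

    A = (ipsi - contra) / ((ipsi + contra) / 2) * 100. Positive values mean
    the tumor-side value is higher. Undefined (NaN) when ipsi + contra = 0;
    bounded in [-200, 200] for non-negative inputs.
    """
    ipsi = np.asarray(ipsilateral, dtype=float)
    contra = np.asarray(contralateral, dtype=float)
    denom = (ipsi + contra) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (ipsi - contra) / denom * 100.0, np.nan)
    return float(out) if out.ndim == 0 else out


def eligible_node_pairs(profile_ipsi: TractProfile, profile_contra: TractProfile,
                        metric: str, threshold: float = DEFAULT_THRESHOLD,
                        filter_contralateral: bool = False) -> np.ndarray:
    """0-based node indices usable for asymmetry at this tract.

    Eligible nodes have ipsilateral combined involvement strictly below
    ``threshold`` percent and non-missing paired metric values. With
    ``filter_contralateral`` the contralateral combined fraction is screened
    too (defensive option; contralateral involvement is ~0 for unilateral
    tumors).
    """
    if profile_ipsi.n_nodes != profile_contra.n_nodes:
        raise ValueError("homologous profiles have mismatched n_nodes")
    ok = profile_ipsi.involvement["combined"] < threshold / 100.0
    if filter_contralateral:
        ok &= profile_contra.involvement["combined"] < threshold / 100.0
    ok &= np.isfinite(profile_ipsi.metrics[metric])
    ok &= np.isfinite(profile_contra.metrics[metric])
    return np.nonzero(ok)[0]


def _pair_profiles(profiles: dict[str, TractProfile], tumor_hemisphere: str
                   ) -> list[tuple[TractProfile, TractProfile]]:
    contra_side = "right" if tumor_hemisphere == "left" else "left"
    by_tract: dict[str, dict[str, TractProfile]] = {}
    for p in profiles.values():
        by_tract.setdefault(p.tract, {})[p.hemisphere] = p
    pairs = []
    for tract in sorted(by_tract):
        sides = by_tract[tract]
        if tumor_hemisphere in sides and contra_side in sides:
            pairs.append((sides[tumor_hemisphere], sides[contra_side]))
    return pairs


def whole_tract_asymmetry(profiles: dict[str, TractProfile], tumor_hemisphere: str,
                          metric: str, threshold: float = DEFAULT_THRESHOLD,
                          pooled: bool = False) -> float:
    """Subject-level mean asymmetry for one metric.

    Two-stage by default: node asymmetries averaged within each tract over
    eligible nodes, then the per-tract means averaged (unweighted) across
    tracts. ``pooled=True`` averages all eligible nodes directly, provided
    for comparison only. NaN when no tract has an eligible node.
    """
    per_tract, pool = [], []
    for ipsi, contra in _pair_profiles(profiles, tumor_hemisphere):
        idx = eligible_node_pairs(ipsi, contra, metric, threshold)
        if idx.size == 0:
            continue
        asym = node_asymmetry(ipsi.metrics[metric][idx], contra.metrics[metric][idx])
        asym = asym[np.isfinite(asym)]
        if asym.size == 0:
            continue
        per_tract.append(float(np.mean(asym)))
        pool.extend(asym.tolist())
    if not per_tract:
        return float("nan")
    return float(np.mean(pool)) if pooled else float(np.mean(per_tract))


def node_distance_to_margin(profile_ipsi: TractProfile,
                            threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Shortest along-tract node distance to the nearest involved node.

    Involved nodes (combined fraction strictly > threshold percent) are the
    within-tract tumor margin and get distance 0; every other node's distance
    is the minimum index difference to an involved node. With no involved
    node in the tract all distances are NaN (no margin exists).
    """
    involved = np.nonzero(classify_involved(
        profile_ipsi.involvement["combined"], threshold))[0]
    n = profile_ipsi.n_nodes
    if involved.size == 0:
        return np.full(n, np.nan)
    idx = np.arange(n)
    return np.min(np.abs(idx[:, None] - involved[None, :]), axis=1).astype(float)


def distance_binned_asymmetry(profiles: dict[str, TractProfile],
                              tumor_hemisphere: str, metric: str,
                              threshold: float = DEFAULT_THRESHOLD,
                              bins: tuple[tuple[int, float], ...] = DEFAULT_BINS,
                              ) -> dict[str, float]:
    """Subject-level mean asymmetry per along-tract distance segment.

    Eligible node asymmetries are grouped by the node's distance bin,
    averaged per tract, then across tracts (two-stage, matching the
    whole-tract collapse). Tracts with no involved node have no margin and
    are excluded. Empty segments yield NaN.
    """
    for i, (lo, hi) in enumerate(bins):
        if lo > hi:
            raise ValueError(f"bin ({lo}, {hi}) is empty")
        for lo2, hi2 in bins[i + 1:]:
            if lo <= hi2 and lo2 <= hi:
                raise ValueError("distance bins overlap")

    per_bin_tract: dict[str, list[float]] = {bin_label(lo, hi): [] for lo, hi in bins}
    for ipsi, contra in _pair_profiles(profiles, tumor_hemisphere):
        dist = node_distance_to_margin(ipsi, threshold)
        if not np.isfinite(dist).any():
            continue  # no within-tract margin
        idx = eligible_node_pairs(ipsi, contra, metric, threshold)
        if idx.size == 0:
            continue
        asym = node_asymmetry(ipsi.metrics[metric][idx], contra.metrics[metric][idx])
        for lo, hi in bins:
            sel = (dist[idx] >= lo) & (dist[idx] <= hi) & np.isfinite(asym)
            if sel.any():
                per_bin_tract[bin_label(lo, hi)].append(float(np.mean(asym[sel])))
    return {label: (float(np.mean(v)) if v else float("nan"))
            for label, v in per_bin_tract.items()}


def subject_asymmetry_table(profiles: dict[str, TractProfile],
                            tumor_hemisphere: str,
                            metrics: tuple[str, ...] = ("fw_fa", "fw_md", "fwf"),
                            threshold: float = DEFAULT_THRESHOLD,
                            bins: tuple[tuple[int, float], ...] = DEFAULT_BINS,
                            subject: str = "") -> pd.DataFrame:
    """Long-format whole-tract and distance-binned asymmetries for one subject."""
    rows = []
    for metric in metrics:
        rows.append({"subject": subject, "metric": metric, "level": "whole-tract",
                     "segment": "n/a", "threshold": threshold,
                     "asymmetry_pct": whole_tract_asymmetry(
                         profiles, tumor_hemisphere, metric, threshold)})
        binned = distance_binned_asymmetry(profiles, tumor_hemisphere, metric,
                                           threshold, bins)
        for seg, val in binned.items():
            rows.append({"subject": subject, "metric": metric,
                         "level": "distance-segment", "segment": seg,
                         "threshold": threshold, "asymmetry_pct": val})
    return pd.DataFrame(rows)
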