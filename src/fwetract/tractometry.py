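"""Tract profiling: resample streamlines to equidistant nodes and sample
scalar metrics and tumor-compartment involvement along them.

Each bundle is collapsed to a fixed number of nodes (100 by default) so that
node *k* refers to the same relative anatomical position in every subject and
hemisphere. Metric values are sampled by trilinear interpolation and averaged
over streamlines per node; involvement fractions count the resampled points
whose nearest voxel carries a tumor label.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .volumes import COMPARTMENTS, DEFAULT_LABEL_MAP, LabelVolume, MetricVolume

DEFAULT_N_NODES = 100


@dataclass
class TractBundle:
    """A named streamline bundle in world RAS mm coordinates."""

    name: str
    hemisphere: str  # "left" | "right"
    streamlines: list[np.ndarray]  # each (n_points, 3)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if len(self.streamlines) < 1:
            raise ValueError("bundle must contain at least one streamline")
        cleaned = []
        for sl in self.streamlines:
            arr = np.asarray(sl, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError("each streamline must be an (n>=2, 3) array")
            if not np.all(np.isfinite(arr)):
                raise ValueError("streamline contains non-finite points")
            cleaned.append(arr)
        self.streamlines = cleaned


@dataclass
class TractProfile:
    """Per-node metric values and tumor-involvement fractions for one tract."""

    tract: str
    hemisphere: str
    n_nodes: int = DEFAULT_N_NODES
    metrics: dict[str, np.ndarray] = field(default_factory=dict)
    involvement: dict[str, np.ndarray] = field(default_factory=dict)
    point_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, arr in {**self.metrics, **self.involvement}.items():
            if len(arr) != self.n_nodes:
                raise ValueError(f"profile array '{name}' has length {len(arr)}, "
                                 f"expected {self.n_nodes}")


def resample_streamline(polyline: np.ndarray, n_nodes: int) -> np.ndarray:
    """Resample a polyline to ``n_nodes`` points at equal arc-length spacing.

    The first and last points are preserved exactly.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    pts = np.asarray(polyline, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        raise ValueError("cannot resample a zero-length polyline")
    targets = np.linspace(0.0, total, n_nodes)
    out = np.empty((n_nodes, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, arc, pts[:, d])
    out[0], out[-1] = pts[0], pts[-1]
    return out


def _canonical_start(bundle: TractBundle) -> np.ndarray:
    # Deterministic reference: the first streamline's first endpoint.
    return bundle.streamlines[0][0]


def orient_bundle(bundle: TractBundle, reference_start: np.ndarray | None = None) -> TractBundle:
    """Flip streamlines so all run in a consistent direction.

    Each streamline keeps the endpoint ordering that places its start nearer
    to the canonical start (the first streamline's start by default, or a
    caller-supplied reference, e.g. the mirrored canonical start of the
    contralateral homologue). Idempotent.
    """
    ref = np.asarray(reference_start, dtype=float) if reference_start is not None \
        else _canonical_start(bundle)
    oriented = []
    for sl in bundle.streamlines:
        d_start = np.linalg.norm(sl[0] - ref)
        d_end = np.linalg.norm(sl[-1] - ref)
        oriented.append(sl if d_start <= d_end else sl[::-1].copy())
    return TractBundle(bundle.name, bundle.hemisphere, oriented, bundle.affine)


def _resampled_points(bundle: TractBundle, n_nodes: int) -> np.ndarray:
    """(n_streamlines, n_nodes, 3) array of resampled points."""
    return np.stack([resample_streamline(sl, n_nodes) for sl in bundle.streamlines])


def node_values(bundle: TractBundle, volume: MetricVolume,
                n_nodes: int = DEFAULT_N_NODES) -> np.ndarray:
    """Per-node metric values: trilinear samples averaged over streamlines.

    Points outside the volume are treated as missing and excluded from the
    node mean; a node with no valid points yields NaN.
    """
    pts = _resampled_points(bundle, n_nodes)
    vox = volume.world_to_voxel(pts.reshape(-1, 3))
    inside = np.all((vox >= 0) & (vox <= np.asarray(volume.shape) - 1), axis=1)
    sampled = np.full(len(vox), np.nan)
    if inside.any():
        sampled[inside] = map_coordinates(volume.data.astype(float), vox[inside].T,
                                          order=1, mode="nearest")
    sampled = sampled.reshape(pts.shape[:2])  # (n_streamlines, n_nodes)
    with np.errstate(invalid="ignore"):
        return np.nanmean(sampled, axis=0)


def node_involvement(bundle: TractBundle, segmentation: LabelVolume,
                     n_nodes: int = DEFAULT_N_NODES,
                     label_map: dict[str, int] = DEFAULT_LABEL_MAP,
                     ) -> dict[str, np.ndarray]:
    """Per-node tumor-involvement fraction per compartment plus 'combined'.

    A node's spatial extent is the multiset of resampled streamline points at
    that node index; the fraction is the share of those points whose nearest
    voxel carries the compartment's label (labels are never interpolated).
    Out-of-volume points count toward the denominator as background.
    """
    pts = _resampled_points(bundle, n_nodes)
    n_sl = pts.shape[0]
    vox = segmentation.world_to_voxel(pts.reshape(-1, 3))
    idx = np.rint(vox).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(segmentation.shape)), axis=1)
    labels = np.zeros(len(idx), dtype=int)
    labels[inside] = segmentation.data[tuple(idx[inside].T)]
    labels = labels.reshape(n_sl, n_nodes)

    fractions: dict[str, np.ndarray] = {}
    for comp in COMPARTMENTS:
        fractions[comp] = np.mean(labels == label_map[comp], axis=0)
    tumor_labels = [label_map[c] for c in COMPARTMENTS]
    fractions["combined"] = np.mean(np.isin(labels, tumor_labels), axis=0)
    return fractions


def classify_involved(fraction: float | np.ndarray, threshold: float) -> bool | np.ndarray:
    """True iff the involvement fraction strictly exceeds ``threshold`` percent."""
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must be in [0, 100] percent")
    return np.asarray(fraction) > threshold / 100.0 if np.ndim(fraction) \
        else fraction > threshold / 100.0


def profile_bundle(bundle: TractBundle,
                   metric_volumes: dict[str, MetricVolume],
                   segmentation: LabelVolume | None = None,
                   n_nodes: int = DEFAULT_N_NODES,
                   label_map: dict[str, int] = DEFAULT_LABEL_MAP) -> TractProfile:
    """Build a full TractProfile from a bundle, metric maps and a segmentation."""
    oriented = orient_bundle(bundle)
    metrics = {name: node_values(oriented, vol, n_nodes)
               for name, vol in metric_volumes.items()}
    involvement = (node_involvement(oriented, segmentation, n_nodes, label_map)
                   if segmentation is not None else {})
    counts = np.full(n_nodes, len(oriented.streamlines))
    return TractProfile(bundle.name, bundle.hemisphere, n_nodes,
                        metrics, involvement, counts)
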