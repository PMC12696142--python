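"""Synthetic phantom cohort with the statistical structure the analysis assumes.

Each phantom subject carries:

- a tumor segmentation of nested compartments (necrotic core inside an
  enhancing rim inside edema), concentric ellipsoids by default with
  group-dependent size — glioblastoma largest enhancing/necrotic volumes,
  oligodendroglioma usually non-enhancing;
- schematic bilateral streamline bundles (smooth parasagittal arcs; the
  right homologue is the mirror image of the left through x = 0);
- ground-truth FA / MD / FWF metric fields: white-matter baselines with FWF
  elevated inside tumor compartments and a pathology-specific FA/MD
  asymmetry injected along the ipsilateral tracts that decays exponentially
  with along-tract node distance from the tumor margin
  (FA x (1 + a * exp(-d / tau)), MD with the opposite sign);
- optionally, single-shell diffusion-weighted signals from the bi-tensor
  free-water forward model with Rician noise.

Geometry is schematic, not anatomical: bundle names reuse the ten bilateral
tract groups of the analysis design, but the trajectories are stacked arcs
chosen for separation on the grid, and the brain is the full grid. All
generators are pure functions of (config, seed).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .tractometry import (TractBundle, TractProfile, node_involvement,
                          profile_bundle, resample_streamline)
from .volumes import (DEFAULT_LABEL_MAP, LabelVolume, MetricVolume,
                      default_affine)

PATHOLOGY_GROUPS = ("glioblastoma", "astrocytoma", "oligodendroglioma")

#: the ten bilateral tract groups of the analysis design (schematic geometry)
DEFAULT_TRACTS = ("ATR", "ARC", "pARC", "CGC", "CST",
                  "IFO", "ILF", "SLF", "UNC", "VOF")


@dataclass
class DiffusionScheme:
    """Gradient table: one b-value and one direction per acquired volume."""

    b_values: np.ndarray   # s/mm^2, 0 for non-weighted volumes
    directions: np.ndarray  # (n_volumes, 3) unit vectors; zeros for b = 0

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.shape != (len(self.b_values), 3):
            raise ValueError("directions must be (n_volumes, 3)")
        if not (self.b_values == 0).any():
            raise ValueError("scheme needs at least one b = 0 volume")
        weighted = self.b_values > 0
        norms = np.linalg.norm(self.directions[weighted], axis=1)
        if weighted.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("weighted directions must have unit norm")
        if self._n_distinct_directions() < 6:
            raise ValueError("need at least 6 distinct non-collinear "
                             "weighted directions")

    def _n_distinct_directions(self) -> int:
        dirs = self.directions[self.b_values > 0]
        kept: list[np.ndarray] = []
        for d in dirs:
            if all(abs(abs(d @ k) - 1.0) > 1e-6 for k in kept):
                kept.append(d)
        return len(kept)

    @property
    def n_volumes(self) -> int:
        return len(self.b_values)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z ** 2))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def make_diffusion_scheme(n_directions: int = 55, b_value: float = 2000.0,
                          n_b0: int = 1, seed: int = 0) -> DiffusionScheme:
    """Single-shell scheme with near-uniform directions (spherical Fibonacci
    lattice, rotated by a seeded random rotation)."""
    if n_directions < 6:
        raise ValueError("need at least 6 weighted directions")
    if n_b0 < 1:
        raise ValueError("need at least one b = 0 volume")
    rng = np.random.default_rng(seed)
    dirs = _fibonacci_sphere(n_directions) @ _random_rotation(rng).T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    b_values = np.concatenate([np.zeros(n_b0), np.full(n_directions, b_value)])
    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    return DiffusionScheme(b_values, directions)


@dataclass
class CohortConfig:
    """Parameters of the phantom cohort.

    Sizes, effect signs and the acquisition mirror the study design: three
    pathology groups with glioblastoma > astrocytoma > oligodendroglioma
    enhancing/necrotic volumes, negative peak FA asymmetry for glioblastoma
    and astrocytoma, positive for oligodendroglioma, decaying over ~8 nodes,
    and a 55-direction b = 2000 s/mm^2 shell on a 2 mm grid. Magnitudes are
    free choices at desk scale.
    """

    n_per_group: dict[str, int] = field(default_factory=lambda: {
        "glioblastoma": 14, "astrocytoma": 8, "oligodendroglioma": 8})
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 2.0  # mm
    tracts: tuple[str, ...] = DEFAULT_TRACTS
    n_streamlines: int = 10
    streamline_spread: float = 1.5  # mm
    n_nodes: int = 100
    # tumor geometry: baseline ellipsoid radii (mm) and per-group multipliers
    radius_necrotic: float = 5.0
    radius_enhancing: float = 8.0
    radius_edema: float = 14.0
    group_size_multiplier: dict[str, float] = field(default_factory=lambda: {
        "glioblastoma": 1.2, "astrocytoma": 0.85, "oligodendroglioma": 0.6})
    oligo_enhancement_prob: float = 0.1  # most oligodendrogliomas non-enhancing
    radius_jitter_sd: float = 0.1       # lognormal sd of per-subject size
    irregular: bool = False             # blob-like compartments via smoothed noise
    irregular_weight: float = 0.25
    # injected asymmetry: signed peak fractional FA effect and decay (nodes)
    peak_fa_asymmetry: dict[str, float] = field(default_factory=lambda: {
        "glioblastoma": -0.04, "astrocytoma": -0.02, "oligodendroglioma": 0.05})
    decay_scale_nodes: float = 8.0
    perturbation_radius: float = 4.5  # mm, spatial reach of the tract effect
    # voxel-wise multiplicative noise on the metric maps, emulating the
    # residual measurement noise real fitted maps carry (relative sd)
    metric_noise_sd: float = 0.03
    # tissue baselines
    fa_wm: float = 0.5
    md_wm: float = 0.75e-3   # mm^2/s
    fwf_wm: float = 0.10
    fwf_edema: float = 0.45
    fwf_enhancing: float = 0.25
    fwf_necrotic: float = 0.60
    fa_tumor_core: float = 0.15  # inside enhancing/necrotic
    # acquisition
    n_directions: int = 55
    b_value: float = 2000.0  # s/mm^2
    n_b0: int = 1
    snr: float = 40.0        # b = 0 signal over Rician noise sigma
    # demographics (for the regression layer)
    age_mean: dict[str, float] = field(default_factory=lambda: {
        "glioblastoma": 62.0, "astrocytoma": 46.0, "oligodendroglioma": 44.0})
    age_sd: float = 10.0
    female_prob: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.radius_necrotic <= self.radius_enhancing <= self.radius_edema):
            raise ValueError("tumor radii must nest: necrotic <= enhancing <= edema")
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        if self.decay_scale_nodes <= 0:
            raise ValueError("decay scale must be positive")
        for name, p in (("oligo_enhancement_prob", self.oligo_enhancement_prob),
                        ("female_prob", self.female_prob)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        unknown = set(self.n_per_group) - set(PATHOLOGY_GROUPS)
        if unknown:
            raise ValueError(f"unknown pathology groups: {sorted(unknown)}")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.shape, self.voxel_size)


@dataclass
class SubjectRecord:
    """One phantom subject with all generated artifacts (in memory)."""

    subject_id: str
    pathology: str
    age: float
    sex: str                  # "F" | "M"
    tumor_hemisphere: str     # "left" | "right"
    segmentation: LabelVolume | None = None
    metric_volumes: dict[str, MetricVolume] = field(default_factory=dict)
    bundles: dict[str, TractBundle] = field(default_factory=dict)
    profiles: dict[str, TractProfile] = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pathology not in PATHOLOGY_GROUPS:
            raise ValueError(f"unknown pathology '{self.pathology}'")
        if self.tumor_hemisphere not in ("left", "right"):
            raise ValueError("tumor hemisphere must be unilateral left/right")


class GeometryError(ValueError):
    """Requested geometry does not fit the voxel grid."""


def _group_radii(config: CohortConfig, group: str,
                 rng: np.random.Generator | None = None,
                 ) -> tuple[float, float, float]:
    mult = config.group_size_multiplier[group]
    jitter = 1.0
    enhancing_on = group != "oligodendroglioma"
    if rng is not None:
        jitter = float(np.exp(rng.normal(0.0, config.radius_jitter_sd)))
        if group == "oligodendroglioma":
            enhancing_on = rng.random() < config.oligo_enhancement_prob
    r_ede = config.radius_edema * mult * jitter
    r_enh = config.radius_enhancing * mult * jitter if enhancing_on else 0.0
    r_nec = (config.radius_necrotic * mult * jitter
             if enhancing_on and group != "oligodendroglioma" else 0.0)
    return r_nec, r_enh, r_ede


def generate_tumor_segmentation(config: CohortConfig, hemisphere: str,
                                group: str, center: np.ndarray | None = None,
                                radii: tuple[float, float, float] | None = None,
                                rng: np.random.Generator | None = None,
                                label_map: dict[str, int] = DEFAULT_LABEL_MAP,
                                ) -> LabelVolume:
    """Nested tumor compartments as concentric ellipsoids (or irregular blobs).

    ``radii`` is (necrotic, enhancing, edema) in mm; defaults to the group's
    configured sizes. ``center`` is in world mm and must lie in ``hemisphere``
    (x < 0 is left in RAS).
    """
    affine = config.affine
    if center is None:
        center = np.array([-20.0 if hemisphere == "left" else 20.0, 0.0, 0.0])
    center = np.asarray(center, dtype=float)
    if (hemisphere == "left") != (center[0] < 0):
        raise GeometryError(f"tumor center x={center[0]:.1f} is not in the "
                            f"{hemisphere} hemisphere")
    r_nec, r_enh, r_ede = radii if radii is not None else _group_radii(
        config, group, rng)
    if not r_nec <= r_enh <= r_ede:
        raise GeometryError("tumor radii must nest: necrotic <= enhancing <= edema")

    half_extent = (np.asarray(config.shape) - 1) / 2.0 * config.voxel_size
    if np.any(np.abs(center) + r_ede > half_extent):
        raise GeometryError("tumor extends outside the voxel grid")

    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in config.shape], indexing="ij")
    world = (np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1) @ affine.T)[..., :3]
    dist = np.linalg.norm(world - center, axis=-1)

    if config.irregular:
        noise_rng = rng if rng is not None else np.random.default_rng(0)
        noise = gaussian_filter(noise_rng.standard_normal(config.shape), sigma=3.0)
        noise = noise / max(np.abs(noise).max(), 1e-12)
        dist = dist * (1.0 + config.irregular_weight * noise)

    data = np.zeros(config.shape, dtype=np.int16)
    if r_ede > 0:
        data[dist <= r_ede] = label_map["edema"]
    if r_enh > 0:
        data[dist <= r_enh] = label_map["enhancing"]
    if r_nec > 0:
        data[dist <= r_nec] = label_map["necrotic"]
    return LabelVolume(data, affine)


# --- schematic tract geometry ------------------------------------------------

def _tract_layout(tracts: tuple[str, ...]) -> dict[str, tuple[float, float]]:
    """Deterministic (y_offset, z_offset) in mm per tract, stacked arcs."""
    layout = {}
    for i, name in enumerate(tracts):
        y0 = -15.0 if i % 2 == 0 else 15.0
        z0 = -25.0 + 10.0 * (i // 2)
        layout[name] = (y0, z0)
    return layout


def _core_trajectory(y0: float, z0: float, x0: float = -20.0,
                     length: float = 80.0, arc_height: float = 8.0,
                     n_points: int = 60) -> np.ndarray:
    """Left-hemisphere arc running anterior-posterior at |x| = 20 mm."""
    t = np.linspace(0.0, 1.0, n_points)
    x = np.full_like(t, x0) + 1.5 * np.sin(2 * np.pi * t)
    y = y0 + length * (t - 0.5)
    z = z0 + arc_height * np.sin(np.pi * t)
    return np.column_stack([x, y, z])


def generate_bundle(tract_name: str, hemisphere: str, config: CohortConfig,
                    n_streamlines: int | None = None,
                    spread: float | None = None, seed: int = 0) -> TractBundle:
    """Streamlines jittered around the tract's core arc.

    Streamlines are the core plus a smooth per-streamline offset (constant
    displacement and a low-frequency sinusoidal wobble, both of magnitude
    ``spread``). The right-hemisphere bundle is the exact mirror image of the
    left one through the midsagittal plane, so homologues are point-wise
    mirror-symmetric by construction.
    """
    n_streamlines = config.n_streamlines if n_streamlines is None else n_streamlines
    spread = config.streamline_spread if spread is None else spread
    if n_streamlines < 1:
        raise ValueError("need at least one streamline")
    layout = _tract_layout(config.tracts)
    if tract_name not in layout:
        raise KeyError(f"unknown tract '{tract_name}'; known: {config.tracts}")
    y0, z0 = layout[tract_name]
    core = _core_trajectory(y0, z0)
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, core.shape[0])[:, None]
    streamlines = []
    for s in range(n_streamlines):
        if s == 0 and n_streamlines == 1 and spread == 0:
            streamlines.append(core.copy())
            continue
        offset = rng.normal(0.0, spread, size=(1, 3))
        wobble = (rng.normal(0.0, spread / 2.0, size=(1, 3))
                  * np.sin(2 * np.pi * (t + rng.random())))
        streamlines.append(core + offset + wobble)
    if hemisphere == "right":
        streamlines = [sl * np.array([-1.0, 1.0, 1.0]) for sl in streamlines]
    elif hemisphere != "left":
        raise ValueError("hemisphere must be 'left' or 'right'")
    half_extent = (np.asarray(config.shape) - 1) / 2.0 * config.voxel_size
    for sl in streamlines:
        if np.any(np.abs(sl) > half_extent):
            raise GeometryError(f"bundle '{tract_name}' leaves the grid")
    return TractBundle(tract_name, hemisphere, streamlines, config.affine)


# --- ground-truth metric fields ----------------------------------------------

def compute_node_distance_field(bundles: dict[str, TractBundle],
                                segmentation: LabelVolume,
                                tumor_hemisphere: str, config: CohortConfig,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Voxel fields of along-tract distance-to-margin and tract tangent.

    For every ipsilateral tract core, each of the ``n_nodes`` resampled core
    points gets the along-tract node distance to the nearest tumor-involved
    core node (0 inside the tumor; infinity when the tract misses the tumor).
    Voxels within ``perturbation_radius`` mm of a core point inherit that
    point's distance (nearest point wins); all other voxels are infinity.
    Returns (distance field in node units, (X,Y,Z,3) unit tangent field with
    +z as the off-tract default).
    """
    n = config.n_nodes
    points, dists, tangents = [], [], []
    for bundle in bundles.values():
        if bundle.hemisphere != tumor_hemisphere:
            continue
        core = resample_streamline(bundle.streamlines[0], n)
        frac = node_involvement(
            TractBundle(bundle.name, bundle.hemisphere, [core]),
            segmentation, n)["combined"]
        involved = np.nonzero(frac > 0)[0]
        if involved.size:
            idx = np.arange(n)
            d = np.min(np.abs(idx[:, None] - involved[None, :]), axis=1)
        else:
            d = np.full(n, np.inf)
        tang = np.gradient(core, axis=0)
        tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
        points.append(core)
        dists.append(d.astype(float))
        tangents.append(tang)

    shape = config.shape
    dist_field = np.full(shape, np.inf)
    tangent_field = np.zeros(shape + (3,))
    tangent_field[..., 2] = 1.0
    if not points:
        return dist_field, tangent_field
    points = np.concatenate(points)
    dists = np.concatenate(dists)
    tangents = np.concatenate(tangents)

    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    world = (np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
             @ config.affine.T)[..., :3].reshape(-1, 3)
    tree = cKDTree(points)
    q_dist, q_idx = tree.query(world, distance_upper_bound=config.perturbation_radius)
    hit = np.isfinite(q_dist)
    flat_dist = np.full(world.shape[0], np.inf)
    flat_dist[hit] = dists[q_idx[hit]]
    dist_field = flat_dist.reshape(shape)
    flat_tan = tangent_field.reshape(-1, 3)
    flat_tan[hit] = tangents[q_idx[hit]]
    tangent_field = flat_tan.reshape(shape + (3,))
    return dist_field, tangent_field


def generate_metric_fields(segmentation: LabelVolume, config: CohortConfig,
                           hemisphere: str, group: str,
                           node_distance_field: np.ndarray,
                           label_map: dict[str, int] = DEFAULT_LABEL_MAP,
                           ) -> dict[str, MetricVolume]:
    """Ground-truth FA / MD / FWF fields with the injected asymmetry.

    White-matter baselines everywhere; FWF elevated inside tumor
    compartments; along the ipsilateral tracts FA is multiplied by
    (1 + a * exp(-d / tau)) with a the group's signed peak asymmetry and d
    the along-tract node distance from the tumor margin, MD by the opposite
    factor (1 - a * exp(-d / tau)). The contralateral hemisphere is never
    touched.
    """
    if segmentation.shape != config.shape:
        raise ValueError("segmentation grid does not match config grid")
    shape = config.shape
    fa = np.full(shape, config.fa_wm)
    md = np.full(shape, config.md_wm)
    fwf = np.full(shape, config.fwf_wm)

    fwf[segmentation.compartment_mask("edema", label_map)] = config.fwf_edema
    fwf[segmentation.compartment_mask("enhancing", label_map)] = config.fwf_enhancing
    fwf[segmentation.compartment_mask("necrotic", label_map)] = config.fwf_necrotic
    core = (segmentation.compartment_mask("enhancing", label_map)
            | segmentation.compartment_mask("necrotic", label_map))
    fa[core] = config.fa_tumor_core

    a = config.peak_fa_asymmetry[group]
    d = np.asarray(node_distance_field, dtype=float)
    ii = np.arange(shape[0])
    x_world = config.affine[0, 0] * ii + config.affine[0, 3]
    ipsi = (x_world < 0) if hemisphere == "left" else (x_world > 0)
    with np.errstate(over="ignore"):
        factor = 1.0 + a * np.exp(-d / config.decay_scale_nodes)
    factor = np.where(np.isfinite(d) & ipsi[:, None, None], factor, 1.0)
    fa = fa * factor
    md = md * (2.0 - factor)  # opposite-signed perturbation

    affine = segmentation.affine
    return {"fw_fa": MetricVolume(fa, affine),
            "fw_md": MetricVolume(md, affine),
            "fwf": MetricVolume(fwf, affine)}


# --- forward DWI simulation --------------------------------------------------

def simulate_dwi(fa_field: np.ndarray, md_field: np.ndarray,
                 fwf_field: np.ndarray, principal_direction_field: np.ndarray,
                 scheme: DiffusionScheme, snr: float = 40.0, seed: int = 0,
                 d_iso: float = 3.0e-3, s0: float = 1.0) -> np.ndarray:
    """Bi-tensor forward signals with Rician noise on a voxel grid.

    The tissue tensor in each voxel is axially symmetric, built from
    (FA, MD, principal direction): lambda_1 = MD (1 + 2 alpha),
    lambda_2 = lambda_3 = MD (1 - alpha) with alpha = FA / sqrt(3 - 2 FA^2).
    Noise sigma is the b = 0 signal divided by ``snr``; ``snr=inf`` gives the
    noiseless forward model.
    """
    fa = np.asarray(fa_field, dtype=float)
    md = np.asarray(md_field, dtype=float)
    f = np.asarray(fwf_field, dtype=float)
    e1 = np.asarray(principal_direction_field, dtype=float)
    if np.any(fa < 0) or np.any(fa > 1):
        raise ValueError("FA must lie in [0, 1]")
    if np.any(md < 0):
        raise ValueError("MD must be non-negative")
    if snr <= 0:
        raise ValueError("SNR must be positive")

    alpha = fa / np.sqrt(3.0 - 2.0 * fa ** 2)
    lam_par = md * (1.0 + 2.0 * alpha)
    lam_perp = md * (1.0 - alpha)

    b = np.asarray(scheme.b_values, dtype=float)
    g = np.asarray(scheme.directions, dtype=float)
    # ADC along g: lam_perp + (lam_par - lam_perp) (g . e1)^2
    cos2 = np.einsum("...i,vi->...v", e1, g) ** 2
    adc = lam_perp[..., None] + (lam_par - lam_perp)[..., None] * cos2
    atten = ((1.0 - f[..., None]) * np.exp(-b * adc)
             + f[..., None] * np.exp(-b * d_iso))
    atten[..., b == 0] = 1.0
    signal = s0 * atten

    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        n1 = rng.normal(0.0, sigma, signal.shape)
        n2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)
    return signal


# --- cohort assembly ---------------------------------------------------------

def generate_subject(config: CohortConfig, subject_id: str, group: str,
                     seed_seq: np.random.SeedSequence,
                     compute_profiles: bool = True,
                     simulate_signals: bool = False) -> SubjectRecord:
    """One phantom subject; deterministic given (config, seed sequence)."""
    rng = np.random.default_rng(seed_seq)
    hemisphere = "left" if rng.random() < 0.5 else "right"
    age = float(rng.normal(config.age_mean[group], config.age_sd))
    sex = "F" if rng.random() < config.female_prob else "M"

    bundles: dict[str, TractBundle] = {}
    tract_seeds = {t: int(rng.integers(2 ** 31)) for t in config.tracts}
    for tract in config.tracts:
        for hemi in ("left", "right"):
            bundles[f"{tract}/{hemi}"] = generate_bundle(
                tract, hemi, config, seed=tract_seeds[tract])

    # anchor the tumor on one ipsilateral tract so the margin lies on-tract
    anchor = config.tracts[int(rng.integers(len(config.tracts)))]
    core = resample_streamline(
        bundles[f"{anchor}/{hemisphere}"].streamlines[0], config.n_nodes)
    anchor_node = int(rng.integers(35, 66))
    center = core[anchor_node]
    radii = _group_radii(config, group, rng)
    segmentation = generate_tumor_segmentation(
        config, hemisphere, group, center=center, radii=radii, rng=rng)

    dist_field, tangent_field = compute_node_distance_field(
        bundles, segmentation, hemisphere, config)
    metric_volumes = generate_metric_fields(
        segmentation, config, hemisphere, group, dist_field)
    if config.metric_noise_sd > 0:
        for vol in metric_volumes.values():
            vol.data = vol.data * (1.0 + rng.normal(
                0.0, config.metric_noise_sd, vol.data.shape))

    record = SubjectRecord(
        subject_id=subject_id, pathology=group, age=age, sex=sex,
        tumor_hemisphere=hemisphere, segmentation=segmentation,
        metric_volumes=metric_volumes, bundles=bundles,
        ground_truth={
            "anchor_tract": anchor, "anchor_node": anchor_node,
            "tumor_center": [float(c) for c in center],
            "radii_mm": {"necrotic": radii[0], "enhancing": radii[1],
                         "edema": radii[2]},
            "peak_fa_asymmetry": config.peak_fa_asymmetry[group],
            "decay_scale_nodes": config.decay_scale_nodes,
        })

    if compute_profiles:
        for key, bundle in bundles.items():
            record.profiles[key] = profile_bundle(
                bundle, metric_volumes, segmentation, config.n_nodes)
    if simulate_signals:
        scheme = make_diffusion_scheme(config.n_directions, config.b_value,
                                       config.n_b0, seed=config.seed)
        dwi = simulate_dwi(
            np.clip(metric_volumes["fw_fa"].data, 0.0, 1.0),
            metric_volumes["fw_md"].data, metric_volumes["fwf"].data,
            tangent_field, scheme, snr=config.snr,
            seed=int(np.random.default_rng(seed_seq).integers(2 ** 31)))
        record.ground_truth["dwi_shape"] = list(dwi.shape)
        record.ground_truth["_dwi_array"] = dwi  # kept in memory, not in manifest
    return record


def generate_cohort(config: CohortConfig, out_dir: str | Path | None = None,
                    compute_profiles: bool = True,
                    simulate_signals: bool = False,
                    ) -> tuple[list[SubjectRecord], dict]:
    """Generate the full phantom cohort, optionally writing artifacts to disk.

    Per-subject randomness derives from ``config.seed`` through a spawned
    seed sequence, so the cohort (and its manifest) is reproducible from the
    master seed alone. Returns (records, manifest).
    """
    master = np.random.SeedSequence(config.seed)
    groups = [g for g in PATHOLOGY_GROUPS for _ in range(config.n_per_group.get(g, 0))]
    children = master.spawn(len(groups))
    records, manifest_subjects = [], []
    for i, (group, child) in enumerate(zip(groups, children)):
        subject_id = f"sub-{i:03d}"
        try:
            rec = generate_subject(config, subject_id, group, child,
                                   compute_profiles, simulate_signals)
        except Exception as exc:  # surface failures with subject id
            raise RuntimeError(f"generating {subject_id} failed: {exc}") from exc
        if out_dir is not None:
            from . import io as fio
            rec.paths = fio.write_subject(rec, Path(out_dir) / subject_id,
                                          config)
        records.append(rec)
        gt = {k: v for k, v in rec.ground_truth.items() if k != "_dwi_array"}
        manifest_subjects.append({
            "subject_id": rec.subject_id, "pathology": rec.pathology,
            "age": rec.age, "sex": rec.sex,
            "tumor_hemisphere": rec.tumor_hemisphere,
            "seed_entropy": int(child.entropy) if child.entropy is not None else None,
            "spawn_key": [int(k) for k in child.spawn_key],
            "ground_truth": gt, "paths": rec.paths,
        })
    manifest = {
        "seed": config.seed,
        "n_subjects": len(records),
        "config": _jsonable(asdict(config)),
        "subjects": manifest_subjects,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return records, manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
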