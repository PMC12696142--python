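"""Readers and writers: NIfTI volumes, TRK/TCK streamline bundles, FSL-style
gradient tables, and long-format tract-profile CSV tables.

All geometry is converted to world RAS mm on read, whatever the on-disk
convention. Label volumes are read as integers and never interpolated.
Writers are deterministic given their inputs (stable row ordering, fixed
float formatting).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .tractometry import TractBundle, TractProfile
from .volumes import LabelVolume, MetricVolume, Volume

FLOAT_FORMAT = "%.9g"
PROFILE_COLUMNS = ["subject", "tract", "hemisphere", "node", "metric", "value"]
INVOLVEMENT_PREFIX = "frac_"


class FormatError(ValueError):
    """Unreadable or invalid on-disk data."""


# --- NIfTI volumes -----------------------------------------------------------

def read_volume(path: str | Path, kind: str = "metric") -> Volume:
    """Load a NIfTI volume, reoriented to RAS; ``kind`` is 'metric' or 'label'."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI '{path}': {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)):
        raise FormatError(f"'{path}': missing or non-finite affine")
    if kind == "label":
        if not np.all(data == np.round(data)):
            raise FormatError(f"'{path}': non-integer data read as labels")
        return LabelVolume(np.round(data).astype(np.int16), affine)
    if kind == "metric":
        return MetricVolume(np.asarray(data, dtype=float), affine)
    raise ValueError("kind must be 'metric' or 'label'")


def write_volume(volume: Volume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = volume.data
    if isinstance(volume, LabelVolume):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, volume.affine)
    nib.save(img, str(path))
    return path


# --- streamline bundles ------------------------------------------------------

def read_bundle(path: str | Path, name: str = "", hemisphere: str = "left"
                ) -> TractBundle:
    """Load a TRK or TCK bundle; points come back in world RAS mm."""
    path = Path(path)
    if path.suffix.lower() not in (".trk", ".tck"):
        raise FormatError(f"unsupported streamline format '{path.suffix}'; "
                          "supported: .trk, .tck")
    tractogram = nib.streamlines.load(str(path)).tractogram
    streamlines = [np.asarray(sl, dtype=float) for sl in tractogram.streamlines]
    if not streamlines:
        raise FormatError(f"'{path}' contains no streamlines")
    affine = tractogram.affine_to_rasmm
    return TractBundle(name or path.stem, hemisphere, streamlines,
                       np.asarray(affine) if affine is not None else np.eye(4))


def write_bundle(bundle: TractBundle, path: str | Path,
                 reference_affine: np.ndarray | None = None,
                 reference_shape: tuple[int, int, int] | None = None) -> Path:
    """Write TRK (needs a reference grid in the header) or TCK."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(sl, dtype=np.float32) for sl in bundle.streamlines],
        affine_to_rasmm=np.eye(4))
    if path.suffix.lower() == ".trk":
        affine = (reference_affine if reference_affine is not None
                  else bundle.affine)
        shape = reference_shape or (1, 1, 1)
        header = {
            nib.streamlines.trk.Field.VOXEL_TO_RASMM: np.asarray(affine,
                                                                 dtype=np.float32),
            nib.streamlines.trk.Field.VOXEL_SIZES:
                np.linalg.norm(np.asarray(affine)[:3, :3], axis=0).astype(np.float32),
            nib.streamlines.trk.Field.DIMENSIONS: np.asarray(shape, dtype=np.int16),
        }
        nib.streamlines.save(tractogram, str(path), header=header)
    elif path.suffix.lower() == ".tck":
        nib.streamlines.save(tractogram, str(path))
    else:
        raise FormatError(f"unsupported streamline format '{path.suffix}'; "
                          "supported: .trk, .tck")
    return path


# --- gradient tables ---------------------------------------------------------

def write_gradient_table(scheme, prefix: str | Path) -> tuple[Path, Path]:
    """FSL-style .bval / .bvec (row-major: bvec has 3 rows)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bval = prefix.with_suffix(".bval")
    bvec = prefix.with_suffix(".bvec")
    bval.write_text(" ".join(FLOAT_FORMAT % b for b in scheme.b_values) + "\n")
    rows = [" ".join(FLOAT_FORMAT % v for v in scheme.directions[:, d])
            for d in range(3)]
    bvec.write_text("\n".join(rows) + "\n")
    return bval, bvec


def read_gradient_table(prefix: str | Path):
    from .synthetic import DiffusionScheme
    prefix = Path(prefix)
    b = np.loadtxt(prefix.with_suffix(".bval"), ndmin=1)
    g = np.loadtxt(prefix.with_suffix(".bvec"), ndmin=2).T
    return DiffusionScheme(b, g)


# --- tract-profile tables ----------------------------------------------------

def profiles_to_table(profiles: dict[str, TractProfile], subject: str
                      ) -> pd.DataFrame:
    """Long-format rows; involvement fractions appear as 'frac_<compartment>'."""
    rows = []
    for prof in profiles.values():
        nodes = np.arange(1, prof.n_nodes + 1)  # 1-based node indices
        for metric, values in prof.metrics.items():
            for node, val in zip(nodes, values):
                rows.append((subject, prof.tract, prof.hemisphere, int(node),
                             metric, val))
        for comp, fracs in prof.involvement.items():
            for node, val in zip(nodes, fracs):
                rows.append((subject, prof.tract, prof.hemisphere, int(node),
                             INVOLVEMENT_PREFIX + comp, val))
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    return df.sort_values(PROFILE_COLUMNS[:5], kind="stable",
                          ignore_index=True)


def table_to_profiles(table: pd.DataFrame) -> dict[str, dict[str, TractProfile]]:
    """Rebuild per-subject profile dicts from a validated long table."""
    out: dict[str, dict[str, TractProfile]] = {}
    for (subject, tract, hemi), grp in table.groupby(
            ["subject", "tract", "hemisphere"], sort=True):
        n_nodes = int(grp["node"].max())
        metrics: dict[str, np.ndarray] = {}
        involvement: dict[str, np.ndarray] = {}
        for metric, sub in grp.groupby("metric", sort=True):
            arr = np.full(n_nodes, np.nan)
            arr[sub["node"].to_numpy() - 1] = sub["value"].to_numpy()
            if metric.startswith(INVOLVEMENT_PREFIX):
                involvement[metric[len(INVOLVEMENT_PREFIX):]] = arr
            else:
                metrics[metric] = arr
        out.setdefault(str(subject), {})[f"{tract}/{hemi}"] = TractProfile(
            str(tract), str(hemi), n_nodes, metrics, involvement)
    return out


def validate_profile_table(table: pd.DataFrame, n_nodes: int | None = None
                           ) -> pd.DataFrame:
    missing = [c for c in PROFILE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"profile table missing columns: {missing}")
    nodes = table["node"].to_numpy()
    upper = n_nodes if n_nodes is not None else int(nodes.max())
    bad = np.nonzero((nodes < 1) | (nodes > upper))[0]
    if bad.size:
        raise FormatError(f"node index out of range 1..{upper} at rows "
                          f"{(bad + 2).tolist()[:10]}")
    dup = table.duplicated(subset=PROFILE_COLUMNS[:5])
    if dup.any():
        rows = (np.nonzero(dup.to_numpy())[0] + 2).tolist()[:10]
        raise FormatError(f"duplicate (subject, tract, hemisphere, node, "
                          f"metric) keys at rows {rows}")
    return table


def write_profiles(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    validate_profile_table(table)
    ordered = table.sort_values(PROFILE_COLUMNS[:5], kind="stable")
    ordered.to_csv(path, index=False, float_format=FLOAT_FORMAT, na_rep="")
    return path


def read_profiles(path: str | Path, n_nodes: int | None = None) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_profile_table(table, n_nodes)


# --- per-subject artifact writing -------------------------------------------

def write_subject(record, out_dir: str | Path, config) -> dict[str, str]:
    """Write one phantom subject's volumes, bundles and gradient table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    if record.segmentation is not None:
        paths["segmentation"] = str(write_volume(
            record.segmentation, out / "segmentation.nii.gz"))
    for name, vol in record.metric_volumes.items():
        paths[name] = str(write_volume(vol, out / f"{name}.nii.gz"))
    for key, bundle in record.bundles.items():
        fname = key.replace("/", "_") + ".trk"
        paths[f"bundle:{key}"] = str(write_bundle(
            bundle, out / "bundles" / fname,
            reference_affine=config.affine, reference_shape=config.shape))
    dwi = record.ground_truth.get("_dwi_array")
    if dwi is not None:
        img = nib.Nifti1Image(np.asarray(dwi, dtype=np.float32), config.affine)
        dwi_path = out / "dwi.nii.gz"
        nib.save(img, str(dwi_path))
        paths["dwi"] = str(dwi_path)
        from .synthetic import make_diffusion_scheme
        scheme = make_diffusion_scheme(config.n_directions, config.b_value,
                                       config.n_b0, seed=config.seed)
        bval, bvec = write_gradient_table(scheme, out / "dwi")
        paths["bval"], paths["bvec"] = str(bval), str(bvec)
    return paths


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
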