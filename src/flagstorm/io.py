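"""File formats: localization CSV, ground-truth JSON, configs, TIFF stacks.

The localization CSV schema is the pipeline's lingua franca::

    frame,x_nm,y_nm,z_nm,photons[,sigma_x_nm,sigma_y_nm]

Floats are written with shortest round-trip representation so a write/read
cycle is bit-exact on the numeric fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError
from .synthgen import FlagellumModel, FrameStack, GroundTruth
from .loc3d import AstigCalibration
from .tables import OPTIONAL_COLUMNS, REQUIRED_COLUMNS, LocalizationTable

__all__ = [
    "read_localization_csv",
    "write_localization_csv",
    "write_angular_distribution_csv",
    "write_profile_map_csv",
    "write_acf_csv",
    "write_spectrum_csv",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_model_yaml",
    "read_model_yaml",
    "write_calibration_yaml",
    "read_calibration_yaml",
    "write_frame_stack",
    "read_frame_stack",
]


def write_localization_csv(table: LocalizationTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def read_localization_csv(path: str | Path) -> LocalizationTable:
    """Parse a localization CSV with header and numeric validation.

    Raises :class:`FormatError` naming the missing column, or citing the
    1-based line number of the first non-numeric cell.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path.name}")
    keep = [c for c in df.columns if c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    out = {}
    for col in keep:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based, after header
            raise FormatError(f"non-numeric value in column {col!r} at line {line} of {path.name}")
        if values.isna().any() and col in REQUIRED_COLUMNS:
            line = int(np.nonzero(values.isna().to_numpy())[0][0]) + 2
            raise FormatError(f"empty value in column {col!r} at line {line} of {path.name}")
        # to_numeric's fast parser is not correctly rounded; float() is, so
        # the write/read cycle stays bit-exact
        out[col] = np.array([float(v) if isinstance(v, str) else v for v in df[col]], float)
    frame = out.pop("frame").astype(int)
    n = len(frame)
    result = pd.DataFrame({"frame": frame, **out})
    return LocalizationTable(result if n else result.iloc[0:0], source="file")


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "emitter_xyz": truth.emitter_xyz.tolist(),
        "emitter_stripe_id": truth.emitter_stripe_id.tolist(),
        "emitter_s_nm": truth.emitter_s_nm.tolist(),
        "emitter_theta_rad": truth.emitter_theta_rad.tolist(),
        "gap_intervals": truth.gap_intervals.tolist(),
        "axis_direction": truth.axis_direction.tolist(),
        "annulus_point": truth.annulus_point.tolist(),
        "true_period_nm": truth.true_period_nm,
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        emitter_xyz=np.asarray(d["emitter_xyz"], float).reshape(-1, 3),
        emitter_stripe_id=np.asarray(d["emitter_stripe_id"], int),
        emitter_s_nm=np.asarray(d["emitter_s_nm"], float),
        emitter_theta_rad=np.asarray(d["emitter_theta_rad"], float),
        gap_intervals=np.asarray(d["gap_intervals"], float).reshape(-1, 2),
        axis_direction=np.asarray(d["axis_direction"], float),
        annulus_point=np.asarray(d["annulus_point"], float),
        true_period_nm=float(d["true_period_nm"]),
    )


def write_model_yaml(model: FlagellumModel, path: str | Path) -> None:
    d = dataclasses.asdict(model)
    d["stripe_angles_rad"] = list(d["stripe_angles_rad"])
    d["axis_direction"] = list(d["axis_direction"])
    d["annulus_point"] = list(d["annulus_point"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_model_yaml(path: str | Path) -> FlagellumModel:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("stripe_angles_rad", "axis_direction", "annulus_point"):
        if key in d:
            d[key] = tuple(d[key])
    try:
        return FlagellumModel(**d)
    except TypeError as exc:
        raise FormatError(f"invalid flagellum model config: {exc}") from exc


def write_calibration_yaml(cal: AstigCalibration, path: str | Path) -> None:
    d = dataclasses.asdict(cal)
    d["valid_z_range_nm"] = list(d["valid_z_range_nm"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_calibration_yaml(path: str | Path) -> AstigCalibration:
    d = yaml.safe_load(Path(path).read_text())
    if "valid_z_range_nm" in d:
        d["valid_z_range_nm"] = tuple(d["valid_z_range_nm"])
    try:
        return AstigCalibration(**d)
    except TypeError as exc:
        raise FormatError(f"invalid calibration config: {exc}") from exc


def write_angular_distribution_csv(dist, path: str | Path) -> None:
    """theta_lo_rad, theta_hi_rad, count rows."""
    pd.DataFrame({
        "theta_lo_rad": dist.bin_edges_rad[:-1],
        "theta_hi_rad": dist.bin_edges_rad[1:],
        "count": dist.counts,
    }).to_csv(path, index=False)


def write_profile_map_csv(pmap, path: str | Path) -> None:
    """Count matrix with s-bin rows and theta-bin-edge column headers."""
    cols = [f"theta_{lo:.6f}_{hi:.6f}" for lo, hi in
            zip(pmap.theta_bin_edges_rad[:-1], pmap.theta_bin_edges_rad[1:])]
    df = pd.DataFrame(pmap.counts, columns=cols)
    df.insert(0, "s_lo_nm", pmap.s_bin_edges_nm[:-1])
    df.insert(1, "s_hi_nm", pmap.s_bin_edges_nm[1:])
    df.to_csv(path, index=False)


def write_acf_csv(acf_fn, path: str | Path) -> None:
    pd.DataFrame({"lag_nm": acf_fn.lags_nm, "acf": acf_fn.values}).to_csv(path, index=False)


def write_spectrum_csv(spec, path: str | Path) -> None:
    pd.DataFrame({
        "frequency_per_nm": spec.frequencies_per_nm,
        "power": spec.power,
    }).to_csv(path, index=False)


def write_frame_stack(stack: FrameStack, path: str | Path) -> None:
    """Multi-page grayscale TIFF plus a JSON sidecar with frame origins."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "origins_nm": stack.origins_nm.tolist(),
        "pixel_size_nm": stack.pixel_size_nm,
    }))


def read_frame_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), float)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        origins = np.asarray(meta["origins_nm"], float)
        px = float(meta["pixel_size_nm"])
    else:
        origins = np.zeros((len(frames), 2))
        px = 100.0
    return FrameStack(frames=frames, origins_nm=origins, pixel_size_nm=px)
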