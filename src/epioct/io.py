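"""File round-tripping: 16-bit TIFF B-scans with JSON sidecars, CSV
profiles, traces, surfaces and reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .phantom import BScan, PhantomTruth, ScanGeometry
from .profiling import ThicknessProfile
from .refraction import PhysicalSurface
from .segmentation import BoundaryTrace

__all__ = [
    "write_bscan", "read_bscan",
    "write_profiles", "read_profiles",
    "write_trace_csv", "write_surface_csv",
]


def _tolist(a):
    return np.asarray(a).tolist()


def write_bscan(path: Path, bscan: BScan) -> Path:
    """Write a B-scan as 16-bit grayscale TIFF + JSON metadata sidecar.

    The image is stored depth-down (rows = axial samples); intensities are
    clipped and rounded to uint16.  Ground-truth curves (synthetic scans
    only) go to the sidecar as sampled arrays.
    """
    path = Path(path)
    img = np.clip(np.rint(bscan.intensity), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, img.T)
    meta = {
        "geometry": dataclasses.asdict(bscan.geometry),
        "meridian": bscan.meridian,
        "eye": bscan.eye,
        "test_index": bscan.test_index,
    }
    if bscan.truth is not None:
        t = bscan.truth
        meta["truth"] = {
            "x_mm": _tolist(t.x_mm),
            "front_z_mm": _tolist(t.front_z_mm),
            "back_optical_z_mm": _tolist(t.back_optical_z_mm),
            "path_length_mm": _tolist(t.path_length_mm),
            "thickness_um": _tolist(t.thickness_um),
            "valid": _tolist(t.valid.astype(int)),
            "apex_x_mm": t.apex_x_mm,
            "apex_z_mm": t.apex_z_mm,
            "decenter_mm": t.decenter_mm,
            "tilt_deg": t.tilt_deg,
        }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def read_bscan(path: Path) -> BScan:
    """Read a TIFF + sidecar pair back into a :class:`BScan`.

    Intensities come back as the stored uint16 values (floats); per-A-scan
    truth arrays are restored when present (dense polylines and ray fields
    are not persisted).
    """
    path = Path(path)
    img = tifffile.imread(path).T.astype(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    geometry = ScanGeometry(**meta["geometry"])
    truth = None
    if "truth" in meta:
        tm = meta["truth"]
        n = len(tm["x_mm"])
        truth = PhantomTruth(
            x_mm=np.array(tm["x_mm"]),
            front_z_mm=np.array(tm["front_z_mm"]),
            back_optical_z_mm=np.array(tm["back_optical_z_mm"]),
            path_length_mm=np.array(tm["path_length_mm"]),
            refracted_dir=np.full((n, 2), np.nan),
            surface_normal=np.full((n, 2), np.nan),
            back_point_mm=np.full((n, 2), np.nan),
            thickness_um=np.array(tm["thickness_um"]),
            valid=np.array(tm["valid"], dtype=bool),
            back_surface_mm=np.empty((0, 2)),
            apex_x_mm=tm["apex_x_mm"], apex_z_mm=tm["apex_z_mm"],
            decenter_mm=tm["decenter_mm"], tilt_deg=tm["tilt_deg"],
        )
    return BScan(intensity=img, geometry=geometry, meridian=meta["meridian"],
                 eye=meta["eye"], test_index=meta["test_index"], truth=truth)


def profile_to_frame(profile: ThicknessProfile,
                     subject: Optional[int] = None) -> pd.DataFrame:
    df = pd.DataFrame({
        "position_mm": profile.positions_mm,
        "thickness_um": profile.thickness_um,
        "n": profile.n_samples,
        "missing": profile.missing.astype(int),
        "eye": profile.eye,
        "meridian": profile.meridian,
        "test": profile.test_index,
    })
    if subject is not None:
        df.insert(0, "subject", subject)
    return df


def write_profiles(path: Path, entries: list[tuple[int, ThicknessProfile]]) -> Path:
    """Write a combined long-format profile CSV (one row per grid point)."""
    frames = [profile_to_frame(p, subject=s) for s, p in entries]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_profiles(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)


def frame_to_profile(df: pd.DataFrame) -> ThicknessProfile:
    """Reconstruct one profile from its rows of a combined profile frame."""
    df = df.sort_values("position_mm")
    return ThicknessProfile(
        positions_mm=df["position_mm"].to_numpy(float),
        thickness_um=df["thickness_um"].to_numpy(float),
        n_samples=df["n"].to_numpy(int),
        missing=df["missing"].to_numpy(int).astype(bool),
        eye=str(df["eye"].iloc[0]), meridian=str(df["meridian"].iloc[0]),
        test_index=int(df["test"].iloc[0]))


def write_trace_csv(path: Path, traces: list[BoundaryTrace]) -> Path:
    frames = [pd.DataFrame({"x_mm": t.x_mm, "z_um": t.z_um,
                            "valid": t.valid.astype(int),
                            "interface": t.interface}) for t in traces]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def write_surface_csv(path: Path, surfaces: list[PhysicalSurface]) -> Path:
    frames = [pd.DataFrame({"x_mm": s.x_mm, "z_mm": s.z_mm,
                            "valid": s.valid.astype(int),
                            "surface": s.provenance}) for s in surfaces]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    return Path(path)
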