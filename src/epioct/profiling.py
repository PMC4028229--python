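"""Thickness profiles: perpendicular thickness, apex anchoring, 0.5-mm
binning, left-eye mirroring, and zonal summaries.

The epithelial thickness at a lateral location is the perpendicular
distance from the front surface to the refraction-corrected back surface.
Profiles are averaged into 0.5-mm bins (±0.25 mm boxcar) whose positions
are expressed relative to the corneal apex, span −5…+5 mm on the
horizontal meridian (10-mm zone) and −4.5…+4.5 mm on the vertical (9-mm
zone), and carry an explicit missing-data mask — empty bins are never
imputed.  Zone names follow the clinical convention of zone *diameters*:
central 0–3 mm, paracentral 3–6 mm, peripheral 6–10 mm, i.e. radii
0–1.5 / 1.5–3 / 3–5 mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .refraction import PhysicalSurface

__all__ = [
    "ThicknessProfile",
    "ZonalSummary",
    "ApexResult",
    "standard_grid",
    "find_apex",
    "perpendicular_thickness",
    "bin_profile",
    "mirror_profile",
    "zonal_means",
    "average_profiles",
]

#: zone radii (mm): central, paracentral, peripheral (names are diameters)
ZONE_RADII = {"central": (0.0, 1.5), "paracentral": (1.5, 3.0), "peripheral": (3.0, 5.0)}


def standard_grid(meridian: str) -> np.ndarray:
    """0.5-mm profile grid: ±5.0 mm horizontal, ±4.5 mm vertical."""
    half = 5.0 if meridian == "horizontal" else 4.5
    n = int(round(2 * half / 0.5)) + 1
    return np.linspace(-half, half, n)


@dataclass
class ThicknessProfile:
    """Epithelial thickness (µm) on the 0.5-mm apex-anchored lateral grid."""

    positions_mm: np.ndarray
    thickness_um: np.ndarray
    n_samples: np.ndarray
    missing: np.ndarray
    eye: str = "OD"
    meridian: str = "horizontal"
    test_index: int = 1

    def __post_init__(self) -> None:
        steps = np.diff(self.positions_mm)
        if len(steps) and not np.allclose(steps, 0.5):
            raise ValueError("profile grid step must be exactly 0.5 mm")
        bad = ~self.missing & ~(self.thickness_um > 0)
        if np.any(bad):
            raise ValueError("non-missing thickness must be positive")


@dataclass
class ZonalSummary:
    """Zone means (µm); NaN where a zone has no non-missing grid point."""

    central_um: float
    paracentral_um: float
    peripheral_um: float


@dataclass
class ApexResult:
    x_mm: float
    degenerate: bool = False


def find_apex(front: PhysicalSurface, depth_window_mm: float = 0.15) -> ApexResult:
    """Lateral position of the corneal apex (shallowest front-surface point).

    A quadratic is fitted to the valid front points within
    ``depth_window_mm`` of the minimum depth; the apex is its vertex.  A
    flat (degenerate) surface yields x = 0 with the degenerate flag set.
    """
    x, z = front.masked()
    if len(x) < 3:
        raise ValueError("need >= 3 valid front points")
    zmin = z.min()
    sel = z <= zmin + depth_window_mm
    if sel.sum() < 3:
        sel = np.argsort(z)[:3]
    xs, zs = x[sel], z[sel]
    span = xs.max() - xs.min()
    coef = np.polynomial.polynomial.polyfit(xs, zs, 2)
    curv = coef[2]
    if span <= 0 or curv <= 1e-6 or (zs.max() - zs.min()) < 1e-9:
        return ApexResult(x_mm=0.0, degenerate=True)
    vertex = -coef[1] / (2.0 * curv)
    vertex = float(np.clip(vertex, x.min(), x.max()))
    return ApexResult(x_mm=vertex, degenerate=False)


def perpendicular_thickness(front: PhysicalSurface, back: PhysicalSurface,
                            chunk: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Perpendicular thickness samples (x mm, t µm) at each valid front point.

    t is the minimum Euclidean distance from the front point to the
    piecewise-linear corrected back curve; rigid motions applied to both
    surfaces leave it unchanged.
    """
    bx, bz = back.masked()
    if len(bx) < 2:
        raise ValueError("back surface needs >= 2 valid points")
    fx, fz = front.masked()
    p0 = np.stack([bx[:-1], bz[:-1]], axis=1)
    seg = np.stack([np.diff(bx), np.diff(bz)], axis=1)
    seg_len2 = np.einsum("ij,ij->i", seg, seg)
    seg_len2 = np.where(seg_len2 > 0, seg_len2, 1.0)

    t_um = np.empty(len(fx))
    for start in range(0, len(fx), chunk):
        q = np.stack([fx[start:start + chunk], fz[start:start + chunk]], axis=1)
        w = q[:, None, :] - p0[None, :, :]
        tt = np.clip(np.einsum("qsj,sj->qs", w, seg) / seg_len2[None, :], 0.0, 1.0)
        closest = p0[None, :, :] + tt[:, :, None] * seg[None, :, :]
        d2 = np.sum((q[:, None, :] - closest) ** 2, axis=2)
        t_um[start:start + chunk] = np.sqrt(d2.min(axis=1)) * 1000.0
    return fx.copy(), t_um


def bin_profile(x_mm: np.ndarray, t_um: np.ndarray, *,
                apex_x_mm: float = 0.0,
                grid: Optional[np.ndarray] = None,
                halfwidth_mm: float = 0.25,
                eye: str = "OD", meridian: str = "horizontal",
                test_index: int = 1) -> ThicknessProfile:
    """Average thickness samples into the 0.5-mm grid ('average matrix').

    Each grid value is the mean of samples within ``halfwidth_mm`` of the
    grid point, with lateral positions re-expressed relative to the apex;
    empty bins are flagged missing.
    """
    if grid is None:
        grid = standard_grid(meridian)
    xr = np.asarray(x_mm, dtype=float) - apex_x_mm
    t = np.asarray(t_um, dtype=float)
    keep = np.isfinite(xr) & np.isfinite(t)
    xr, t = xr[keep], t[keep]
    values = np.full(len(grid), np.nan)
    counts = np.zeros(len(grid), dtype=int)
    for k, g in enumerate(grid):
        sel = np.abs(xr - g) <= halfwidth_mm
        counts[k] = int(sel.sum())
        if counts[k]:
            values[k] = t[sel].mean()
    return ThicknessProfile(positions_mm=np.asarray(grid, dtype=float),
                            thickness_um=values, n_samples=counts,
                            missing=counts == 0, eye=eye, meridian=meridian,
                            test_index=test_index)


def mirror_profile(profile: ThicknessProfile,
                   eye: Optional[str] = None) -> ThicknessProfile:
    """Mirror left-eye horizontal profiles onto right-eye orientation.

    OS horizontal profiles get their lateral sign flipped so nasal/temporal
    align with OD; OD and vertical profiles pass through unchanged.
    Applying the operation twice restores the original.
    """
    eye = eye if eye is not None else profile.eye
    if profile.meridian != "horizontal" or eye == "OD":
        return replace(profile)
    return replace(profile,
                   thickness_um=profile.thickness_um[::-1].copy(),
                   n_samples=profile.n_samples[::-1].copy(),
                   missing=profile.missing[::-1].copy())


def zonal_means(profile: ThicknessProfile) -> ZonalSummary:
    """Zone means over non-missing grid points by |x| (radii, half-open
    [lo, hi); the outermost zone includes its upper edge)."""
    r = np.abs(profile.positions_mm)
    t = profile.thickness_um
    ok = ~profile.missing
    out = {}
    for zone, (lo, hi) in ZONE_RADII.items():
        if zone == "peripheral":
            member = ok & (r >= lo) & (r <= hi + 1e-9)
        else:
            member = ok & (r >= lo) & (r < hi)
        out[zone] = float(t[member].mean()) if member.any() else float("nan")
        if not member.any():
            warnings.warn(f"zone {zone!r} entirely missing", stacklevel=2)
    return ZonalSummary(central_um=out["central"],
                        paracentral_um=out["paracentral"],
                        peripheral_um=out["peripheral"])


def average_profiles(profiles: Sequence[ThicknessProfile]) -> ThicknessProfile:
    """Pointwise mean profile; a point is missing only if missing in all."""
    if not profiles:
        raise ValueError("empty profile list")
    grid = profiles[0].positions_mm
    for p in profiles[1:]:
        if not np.allclose(p.positions_mm, grid):
            raise ValueError("profiles must share a common grid")
    stack = np.array([np.where(p.missing, np.nan, p.thickness_um) for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    n = np.sum(~np.isnan(stack), axis=0)
    return ThicknessProfile(positions_mm=grid.copy(), thickness_um=mean,
                            n_samples=n, missing=n == 0,
                            eye=profiles[0].eye, meridian=profiles[0].meridian,
                            test_index=profiles[0].test_index)
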