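"""Snell's-law dewarping of the refraction-distorted back boundary.

OCT records optical path length along the probe beam.  Above the cornea the
beam travels in air, so the front-surface trace is already a physical
surface; below it the beam bends at the air–epithelium interface and the
recorded depth is stretched by the group index n.  The correction places
each back-boundary echo at its physical position: the in-tissue path length
is s = (z_back - z_front)/n and the point lies a distance s from the entry
point along the Snell-refracted ray direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "RefractionParams",
    "PhysicalSurface",
    "estimate_normals",
    "snell_refract",
    "snell_refract_many",
    "dewarp_back_surface",
]


@dataclass(frozen=True)
class RefractionParams:
    n_air: float = 1.0
    n_tissue: float = 1.389  # corneal group index
    normal_fit_halfwidth_mm: float = 0.25
    normal_fit_degree: int = 2

    def __post_init__(self) -> None:
        if self.n_tissue < 1.0:
            raise ValueError("n_tissue must be >= 1")
        if self.normal_fit_halfwidth_mm <= 0:
            raise ValueError("normal_fit_halfwidth_mm must be positive")
        if self.normal_fit_degree < 1:
            raise ValueError("normal_fit_degree must be >= 1")


@dataclass
class PhysicalSurface:
    """Point set (x, z) in physical mm with validity mask."""

    x_mm: np.ndarray
    z_mm: np.ndarray
    provenance: str  # "front" | "back_corrected"
    valid: np.ndarray

    def masked(self) -> tuple[np.ndarray, np.ndarray]:
        return self.x_mm[self.valid], self.z_mm[self.valid]


def estimate_normals(front, params: Optional[RefractionParams] = None) -> tuple[np.ndarray, np.ndarray]:
    """Inward unit surface normals from local polynomial fits of z_f(x).

    At each A-scan a polynomial of ``normal_fit_degree`` is fitted to the
    valid front-trace nodes within ``normal_fit_halfwidth_mm``; the normal
    is perpendicular to the fitted tangent, oriented into the tissue
    (positive z).  Windows shrink one-sidedly at the lateral edges; an
    A-scan whose window holds fewer points than the fit needs is invalid.

    Returns ``(normals (n, 2), valid (n,))``.
    """
    params = params or RefractionParams()
    x = np.asarray(front.x_mm, dtype=float)
    z_mm = np.asarray(front.z_um, dtype=float) / 1000.0
    good = np.asarray(front.valid, dtype=bool)
    n = len(x)
    normals = np.full((n, 2), np.nan)
    valid = np.zeros(n, dtype=bool)
    hw = params.normal_fit_halfwidth_mm
    xg, zg = x[good], z_mm[good]
    if xg.size == 0:
        return normals, valid
    lo = np.searchsorted(xg, x - hw, side="left")
    hi = np.searchsorted(xg, x + hw, side="right")
    for i in range(n):
        if not good[i]:
            continue
        xs, zs = xg[lo[i]:hi[i]], zg[lo[i]:hi[i]]
        deg = min(params.normal_fit_degree, len(xs) - 1)
        if deg < 1:
            continue
        # centre for conditioning
        coef = np.polynomial.polynomial.polyfit(xs - x[i], zs, deg)
        slope = coef[1]
        nv = np.array([-slope, 1.0])
        normals[i] = nv / np.hypot(slope, 1.0)
        valid[i] = True
    return normals, valid


def _check_unit(v: np.ndarray, name: str) -> None:
    norms = np.linalg.norm(v, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError(f"{name} must be unit vectors")


def snell_refract(incident_dir, normal, n1: float, n2: float) -> np.ndarray:
    """Refract a unit direction at an interface with indices n1 -> n2.

    The refracted direction is coplanar with the incident direction and the
    normal and satisfies n1 sin(theta1) = n2 sin(theta2).  Raises on
    non-unit inputs and on total internal reflection.
    """
    d = np.asarray(incident_dir, dtype=float)
    nrm = np.asarray(normal, dtype=float)
    _check_unit(d, "incident_dir")
    _check_unit(nrm, "normal")
    out = snell_refract_many(d[None, :], nrm[None, :], n1, n2)
    return out[0]


def snell_refract_many(dirs: np.ndarray, normals: np.ndarray,
                       n1: float, n2: float) -> np.ndarray:
    """Vectorised Snell refraction; rows of unit directions and normals."""
    d = np.asarray(dirs, dtype=float)
    nrm = np.asarray(normals, dtype=float)
    # orient each normal into the propagation hemisphere
    cos1 = np.sum(d * nrm, axis=1)
    nrm = np.where(cos1[:, None] < 0, -nrm, nrm)
    cos1 = np.abs(cos1)
    mu = n1 / n2
    sin2_sq = mu * mu * (1.0 - cos1 * cos1)
    if np.any(sin2_sq > 1.0 + 1e-12):
        raise ValueError("total internal reflection")
    cos2 = np.sqrt(np.clip(1.0 - sin2_sq, 0.0, 1.0))
    t = mu * d + (cos2 - mu * cos1)[:, None] * nrm
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def dewarp_back_surface(front, back, params: Optional[RefractionParams] = None
                        ) -> tuple[PhysicalSurface, PhysicalSurface]:
    """Correct the back boundary for refraction distortion.

    ``front`` and ``back`` are boundary traces (x in mm, z in optical µm).
    The front surface passes through unchanged (air: optical == physical).
    Each back point moves to entry + s * refracted_direction with
    s = (z_back - z_front) / n_tissue.  Setting n_tissue = 1 makes the
    correction the identity.  Invalid A-scans propagate invalid.
    """
    params = params or RefractionParams()
    x = np.asarray(front.x_mm, dtype=float)
    zf_mm = np.asarray(front.z_um, dtype=float) / 1000.0
    zb_mm = np.asarray(back.z_um, dtype=float) / 1000.0
    normals, n_valid = estimate_normals(front, params)
    joint = (np.asarray(front.valid, dtype=bool)
             & np.asarray(back.valid, dtype=bool) & n_valid)

    incident = np.tile(np.array([0.0, 1.0]), (len(x), 1))
    refr = np.full((len(x), 2), np.nan)
    if joint.any():
        refr[joint] = snell_refract_many(incident[joint], normals[joint],
                                         params.n_air, params.n_tissue)
    s = (zb_mm - zf_mm) / params.n_tissue
    bx = x + s * refr[:, 0]
    bz = zf_mm + s * refr[:, 1]

    front_surface = PhysicalSurface(
        x_mm=x.copy(), z_mm=zf_mm.copy(), provenance="front",
        valid=np.asarray(front.valid, dtype=bool).copy())
    back_surface = PhysicalSurface(
        x_mm=bx, z_mm=bz, provenance="back_corrected", valid=joint)
    return front_surface, back_surface
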