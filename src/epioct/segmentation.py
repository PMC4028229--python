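"""Sub-pixel tracing of the air–epithelium and epithelium–Bowman interfaces.

Boundaries are found as laterally continuous minimum-cost paths through a
ridge-strength map (negative smoothed intensity) by dynamic programming
with a per-step vertical jump limit, which keeps the trace on the surface
through the low-SNR periphery where independent per-A-scan peak picking
breaks down.  Each path node is refined to sub-pixel depth by a parabolic
fit to the log-intensity (exact for a Gaussian ridge).  A-scans whose local
ridge strength falls below an SNR threshold — eyelid-occluded columns, deep
periphery — are flagged invalid rather than guessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d, minimum_filter1d

from .phantom import BScan

__all__ = [
    "SegmentationParams",
    "BoundaryTrace",
    "NoSurfaceFound",
    "preprocess",
    "trace_boundaries",
    "jitter_params",
]

_BIG = 1e9


class NoSurfaceFound(RuntimeError):
    """No boundary path exceeds the ridge-strength threshold anywhere."""


@dataclass(frozen=True)
class SegmentationParams:
    #: axial smoothing sigma in pixels; None -> the axial PSF sigma
    smooth_sigma_px: Optional[float] = None
    #: max per-step vertical move of the DP path, pixels; None -> auto from
    #: the pixel aspect ratio (surface slope < ~1 within the scan)
    jump_limit_px: Optional[int] = None
    min_separation_um: float = 20.0   # optical µm between front and back
    max_separation_um: float = 250.0
    snr_threshold: float = 6.0        # ridge must exceed bg median + k*sigma

    def resolve(self, bscan: BScan) -> tuple[float, int]:
        geo = bscan.geometry
        sigma = self.smooth_sigma_px
        if sigma is None:
            sigma = geo.axial_psf_fwhm_um / (2 * math.sqrt(2 * math.log(2))) \
                / (geo.axial_pitch_mm * 1000.0)
        jump = self.jump_limit_px
        if jump is None:
            # steepest front-surface slope inside the raster is ~1.8 for a
            # 7.8-mm cornea at the 6.7-mm scan edge
            jump = max(2, math.ceil(2.0 * geo.lateral_pitch_mm / geo.axial_pitch_mm))
        return float(sigma), int(jump)


@dataclass
class BoundaryTrace:
    """Per-A-scan sub-pixel axial position of one interface (optical µm)."""

    x_mm: np.ndarray
    z_um: np.ndarray
    valid: np.ndarray
    interface: str  # "front" | "back"


def preprocess(bscan: BScan, sigma_px: Optional[float] = None) -> np.ndarray:
    """Axial Gaussian smoothing + per-A-scan peak normalisation."""
    img = bscan.intensity
    if img.size == 0:
        raise ValueError("empty image")
    sigma, _ = SegmentationParams(smooth_sigma_px=sigma_px).resolve(bscan)
    sm = gaussian_filter1d(img, sigma=sigma, axis=1, mode="nearest")
    peak = sm.max(axis=1, keepdims=True)
    peak = np.where(peak > 0, peak, 1.0)
    return sm / peak


def _dp_path(cost: np.ndarray, jump: int) -> np.ndarray:
    """Min-cost laterally continuous path; ties -> smallest axial index."""
    n_cols, n_rows = cost.shape
    acc = np.empty_like(cost)
    acc[0] = cost[0]
    for i in range(1, n_cols):
        acc[i] = cost[i] + minimum_filter1d(acc[i - 1], size=2 * jump + 1,
                                            mode="nearest")
    path = np.empty(n_cols, dtype=int)
    path[-1] = int(np.argmin(acc[-1]))  # argmin returns first (smallest) index
    for i in range(n_cols - 2, -1, -1):
        j = path[i + 1]
        lo, hi = max(0, j - jump), min(n_rows, j + jump + 1)
        path[i] = lo + int(np.argmin(acc[i, lo:hi]))
    return path


def _subpixel(smoothed: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Log-parabolic vertex refinement around each path node (pixels)."""
    n_cols, n_rows = smoothed.shape
    j = np.clip(path, 1, n_rows - 2)
    cols = np.arange(n_cols)
    eps = 1e-12
    ym = np.log(smoothed[cols, j - 1] + eps)
    y0 = np.log(smoothed[cols, j] + eps)
    yp = np.log(smoothed[cols, j + 1] + eps)
    denom = ym - 2 * y0 + yp
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (ym - yp) / denom, 0.0)
    return j + np.clip(delta, -1.0, 1.0)


def _noise_floor(smoothed: np.ndarray, k: float) -> float:
    med = float(np.median(smoothed))
    mad = float(np.median(np.abs(smoothed - med)))
    return med + k * 1.4826 * mad


def trace_boundaries(bscan: BScan, params: Optional[SegmentationParams] = None
                     ) -> tuple[BoundaryTrace, BoundaryTrace]:
    """Trace the front and back interfaces of one B-scan.

    The front path is the global minimum-cost ridge path; the back path is
    found in a band ``[front + min_separation, front + max_separation]``
    (optical µm) below it.  Raises :class:`NoSurfaceFound` when no A-scan's
    ridge exceeds the noise floor.
    """
    params = params or SegmentationParams()
    sigma, jump = params.resolve(bscan)
    geo = bscan.geometry
    pitch_um = geo.axial_pitch_mm * 1000.0

    img = bscan.intensity
    if img.size == 0:
        raise ValueError("empty image")
    sm = gaussian_filter1d(img, sigma=sigma, axis=1, mode="nearest")
    peak = sm.max(axis=1, keepdims=True)
    norm = sm / np.where(peak > 0, peak, 1.0)

    floor = _noise_floor(sm, params.snr_threshold)
    if float(sm.max()) <= floor or float(sm.max()) <= 0:
        raise NoSurfaceFound("no ridge above the noise floor")

    front_idx = _dp_path(-norm, jump)
    cols = np.arange(img.shape[0])
    front_valid = sm[cols, front_idx] > floor
    if not front_valid.any():
        raise NoSurfaceFound("no A-scan ridge exceeds the SNR threshold")

    # back boundary: DP restricted to a band below the front path; the band
    # must clear the smoothed front ridge, so the floor separation grows
    # with the effective ridge width
    sigma_eff_um = math.hypot(bscan.geometry.axial_psf_fwhm_um
                              / (2 * math.sqrt(2 * math.log(2))),
                              sigma * pitch_um)
    min_sep_um = max(params.min_separation_um, 3.0 * sigma_eff_um)
    lo = front_idx + max(1, int(round(min_sep_um / pitch_um)))
    hi = front_idx + int(round(params.max_separation_um / pitch_um))
    rows = np.arange(img.shape[1])[None, :]
    in_band = (rows >= lo[:, None]) & (rows <= hi[:, None])
    back_cost = np.where(in_band, -norm, _BIG)
    back_idx = _dp_path(back_cost, jump)
    back_valid = front_valid & in_band[cols, back_idx] & (sm[cols, back_idx] > floor)

    front_z = _subpixel(sm, front_idx) * pitch_um + 0.5 * pitch_um
    back_z = _subpixel(sm, back_idx) * pitch_um + 0.5 * pitch_um

    x = geo.x_mm
    front = BoundaryTrace(x_mm=x, z_um=front_z, valid=front_valid, interface="front")
    back = BoundaryTrace(x_mm=x, z_um=back_z, valid=back_valid, interface="back")
    return front, back


def jitter_params(params: SegmentationParams, sd: float, seed: int,
                  bscan_for_defaults: Optional[BScan] = None) -> SegmentationParams:
    """Multiplicatively perturb tuning parameters (a second 'observer').

    Smoothing sigma and the SNR threshold are scaled by exp(sd * g) with
    independent standard-normal g; sd = 0 is the identity.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return params
    rng = np.random.default_rng(seed)
    sigma = params.smooth_sigma_px
    if sigma is None and bscan_for_defaults is not None:
        sigma, _ = params.resolve(bscan_for_defaults)
    g = rng.standard_normal(2)
    new_sigma = sigma * math.exp(sd * g[0]) if sigma is not None else None
    return replace(params,
                   smooth_sigma_px=new_sigma,
                   snr_threshold=params.snr_threshold * math.exp(sd * g[1]))
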