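"""Synthetic anterior-segment OCT B-scans of a layered cornea.

The phantom emulates a spectral-domain OCT cross-section (B-scan) of the
corneal epithelium: a spherical anterior surface, a thin epithelial layer
whose thickness grows from the apex toward the limbus (faster inferiorly
than superiorly, nasal/temporal symmetric), and a physically correct
refraction forward model.  Each A-scan is a telecentric vertical ray; the
front-surface echo sits at the surface's depth in air, while the back
(epithelium–Bowman) echo is displaced to the *optical* depth

    z_back = z_front + n * s(x)

where s(x) is the physical path length along the Snell-refracted ray from
the entry point to the true back surface and n is the corneal group
refractive index.  This is the distortion that the refraction module later
removes, so the phantom carries exact ground truth for every quantity the
analysis pipeline estimates.

Axes: lateral x in mm, origin at the scan centre, positive = nasal (OD) or
superior; axial z in mm of optical depth, increasing downward from the
image top.  Intensity arrays are indexed ``[a_scan, axial_sample]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Optional

import numpy as np
import pandas as pd

from .refraction import snell_refract_many

__all__ = [
    "ScanGeometry",
    "CorneaModel",
    "NoiseModel",
    "SessionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "BScan",
    "build_thickness_field",
    "render_bscan",
    "plan_cohort",
    "render_cohort",
    "simulate_cohort",
    "DEFAULT_T0_MEAN_UM",
    "DEFAULT_T0_SD_UM",
]

# Population central thickness (µm): mean and between-subject SD.
DEFAULT_T0_MEAN_UM = 52.0
DEFAULT_T0_SD_UM = 3.2

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class ScanGeometry:
    """Scan raster of the simulated SD-OCT instrument.

    Defaults correspond to an ultra-long-depth anterior-segment system:
    13.465 mm scan width, 7.281 mm axial depth in air, 2048 x 4096 pixels,
    4.6 µm axial point-spread FWHM in air (3.3 µm in tissue).
    """

    lateral_width_mm: float = 13.465
    n_ascans: int = 2048
    axial_depth_air_mm: float = 7.281
    n_samples: int = 4096
    axial_psf_fwhm_um: float = 4.6

    def __post_init__(self) -> None:
        for name in ("lateral_width_mm", "axial_depth_air_mm", "axial_psf_fwhm_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("n_ascans", "n_samples"):
            if int(getattr(self, name)) < 8:
                raise ValueError(f"{name} must be >= 8")

    @property
    def lateral_pitch_mm(self) -> float:
        return self.lateral_width_mm / self.n_ascans

    @property
    def axial_pitch_mm(self) -> float:
        """Axial sample spacing in mm of optical depth (air)."""
        return self.axial_depth_air_mm / self.n_samples

    @property
    def x_mm(self) -> np.ndarray:
        """Lateral A-scan centre positions, origin at the scan centre."""
        i = np.arange(self.n_ascans)
        return (i + 0.5) * self.lateral_pitch_mm - self.lateral_width_mm / 2.0

    @property
    def z_mm(self) -> np.ndarray:
        """Axial sample centre positions (optical depth, air)."""
        return (np.arange(self.n_samples) + 0.5) * self.axial_pitch_mm

    def scaled(self, factor: int) -> "ScanGeometry":
        """Reduced-resolution raster for fast runs.

        Pixel counts are divided by ``factor`` while the physical field of
        view is kept; the rendered PSF is broadened by the same factor so
        the ridge stays resolvable (~1 px sigma) on the coarser grid.
        """
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return replace(
            self,
            n_ascans=self.n_ascans // factor,
            n_samples=self.n_samples // factor,
            axial_psf_fwhm_um=self.axial_psf_fwhm_um * factor,
        )


@dataclass(frozen=True)
class CorneaModel:
    """Parametric cornea: spherical front surface + radial thickness field.

    The epithelial thickness at signed lateral distance ``d`` (mm) from the
    apex is ``T(d, dir) = T0 + c_dir * |d|**p`` µm, with direction chosen by
    the sign of ``d`` and the meridian.  Defaults put the 5-mm thickness at
    63 µm temporally/nasally, 58 µm superiorly, and 72 µm inferiorly, with
    a 52-µm apex.  The back surface is the front surface offset inward by T
    along the local normal, so perpendicular thickness has exact truth.
    """

    anterior_radius_mm: float = 7.8
    apex_offset_mm: tuple[float, float] = (0.0, 0.8)  # (lateral, axial depth)
    central_thickness_um: float = DEFAULT_T0_MEAN_UM
    coeff_temporal: float = (63.0 - 52.0) / 5.0**3
    coeff_nasal: float = (63.0 - 52.0) / 5.0**3
    coeff_superior: float = (58.0 - 52.0) / 5.0**3
    coeff_inferior: float = (72.0 - 52.0) / 5.0**3
    exponent: float = 3.0
    group_index: float = 1.389

    def __post_init__(self) -> None:
        if not self.group_index >= 1.0:
            raise ValueError("group_index must be >= 1")
        if not self.central_thickness_um > 0:
            raise ValueError("central_thickness_um must be positive")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")
        if np.isfinite(self.anterior_radius_mm) and self.anterior_radius_mm <= 0:
            raise ValueError("anterior_radius_mm must be positive (or inf for flat)")
        # thickness must stay positive over the analysed 5-mm half-chord
        for c in (self.coeff_temporal, self.coeff_nasal,
                  self.coeff_superior, self.coeff_inferior):
            t5 = self.central_thickness_um + c * 5.0**self.exponent
            if not (t5 > 0 and np.isfinite(t5)):
                raise ValueError("thickness field not positive/finite over [0, 5] mm")

    def coeffs(self) -> dict[str, float]:
        return {
            "temporal": self.coeff_temporal,
            "nasal": self.coeff_nasal,
            "superior": self.coeff_superior,
            "inferior": self.coeff_inferior,
        }


@dataclass(frozen=True)
class NoiseModel:
    """Speckle-like intensity noise with depth-dependent SNR roll-off.

    Signal amplitudes are attenuated by ``exp(-z / depth_rolloff_mm)``
    (optical depth z), emulating the spectral-domain sensitivity drop that
    degrades boundary detection toward the deeper, peripheral cornea.
    Multiplicative speckle is Gaussian with relative sd ``speckle_factor``;
    the background floor is folded-Gaussian with sd ``background_sd``.
    Intensities are on a 16-bit scale.
    """

    background_sd: float = 600.0
    surface_amplitude: float = 18000.0
    back_amplitude_ratio: float = 0.6
    speckle_factor: float = 0.25
    depth_rolloff_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_sd < 0 or self.surface_amplitude < 0 or self.speckle_factor < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not self.depth_rolloff_mm > 0:
            raise ValueError("depth_rolloff_mm must be positive")

    def silent(self) -> "NoiseModel":
        return replace(self, background_sd=0.0, speckle_factor=0.0)


@dataclass(frozen=True)
class SessionSpec:
    """One acquisition: which meridian, which eye, occlusion and jitter."""

    meridian: str = "horizontal"  # "horizontal" | "vertical"
    eye: str = "OD"  # "OD" | "OS"
    #: superior cut-off (mm, scan coordinates) on the vertical meridian;
    #: A-scans beyond it contain background only (upper eyelid coverage).
    eyelid_occlusion_from_mm: Optional[float] = 4.5
    #: (decentration sd mm, tilt sd degrees) between repeated tests
    retest_jitter: tuple[float, float] = (0.05, 0.3)

    def __post_init__(self) -> None:
        if self.meridian not in ("horizontal", "vertical"):
            raise ValueError(f"unknown meridian {self.meridian!r}")
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"unknown eye {self.eye!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of a synthetic acquisition."""

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    cornea: CorneaModel = field(default_factory=CorneaModel)
    noise: NoiseModel = field(default_factory=NoiseModel)


@dataclass
class PhantomTruth:
    """Ground truth attached to a synthetic B-scan (per A-scan unless noted)."""

    x_mm: np.ndarray
    front_z_mm: np.ndarray          # optical == physical depth of front surface
    back_optical_z_mm: np.ndarray   # rendered back-echo optical depth
    path_length_mm: np.ndarray      # physical in-tissue path s(x) along refracted ray
    refracted_dir: np.ndarray       # (n, 2) unit refracted directions
    surface_normal: np.ndarray      # (n, 2) inward unit normals at entry
    back_point_mm: np.ndarray       # (n, 2) true physical back-surface hit point
    thickness_um: np.ndarray        # material thickness at each entry point
    valid: np.ndarray               # ray hit the back surface & not occluded
    back_surface_mm: np.ndarray     # (m, 2) dense true back-surface polyline
    apex_x_mm: float
    apex_z_mm: float
    decenter_mm: float
    tilt_deg: float


@dataclass
class BScan:
    """One meridian's intensity grid plus acquisition metadata."""

    intensity: np.ndarray  # [n_ascans, n_samples], finite, >= 0
    geometry: ScanGeometry
    meridian: str
    eye: str
    test_index: int = 1
    truth: Optional[PhantomTruth] = None

    def __post_init__(self) -> None:
        expected = (self.geometry.n_ascans, self.geometry.n_samples)
        if self.intensity.shape != expected:
            raise ValueError(f"intensity shape {self.intensity.shape} != {expected}")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensity must be finite and >= 0")


def build_thickness_field(model: CorneaModel) -> Callable[[np.ndarray, str], np.ndarray]:
    """Return ``T(d, meridian)`` in µm for signed lateral distance d (mm).

    Positive d is nasal on the horizontal meridian and superior on the
    vertical one.  ``T(0, .) = T0`` and T is monotone non-decreasing in |d|
    for the (non-negative) default coefficients.
    """
    c = model.coeffs()
    t0, p = model.central_thickness_um, model.exponent

    def thickness(d: np.ndarray, meridian: str) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if meridian == "horizontal":
            c_pos, c_neg = c["nasal"], c["temporal"]
        elif meridian == "vertical":
            c_pos, c_neg = c["superior"], c["inferior"]
        else:
            raise ValueError(f"unknown meridian {meridian!r}")
        coef = np.where(d >= 0, c_pos, c_neg)
        return t0 + coef * np.abs(d) ** p

    return thickness


# ---------------------------------------------------------------------------
# forward rendering


def _front_surface(cornea: CorneaModel, x: np.ndarray, decenter: float):
    """Front-surface depth z_f(x) plus circle centre; handles the flat limit."""
    ox, oz = cornea.apex_offset_mm
    cx = ox + decenter
    R = cornea.anterior_radius_mm
    if not np.isfinite(R):
        z = np.full_like(x, oz, dtype=float)
        inside = np.ones_like(x, dtype=bool)
        return z, inside, (cx, math.inf)
    cz = oz + R
    dx = x - cx
    inside = np.abs(dx) < R * 0.999
    z = np.full_like(x, np.nan, dtype=float)
    z[inside] = cz - np.sqrt(R * R - dx[inside] ** 2)
    return z, inside, (cx, cz)


def _inward_normals(cornea: CorneaModel, pts: np.ndarray, centre) -> np.ndarray:
    cx, cz = centre
    if not np.isfinite(cz):
        n = np.zeros_like(pts)
        n[:, 1] = 1.0
        return n
    v = np.stack([cx - pts[:, 0], cz - pts[:, 1]], axis=1)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _material_lateral(pts: np.ndarray, centre, tilt_deg: float) -> np.ndarray:
    """Signed lateral distance from the (possibly tilted) corneal axis.

    Tilt rotates the material frame about the sphere centre; the geometric
    surface of a sphere is unchanged, only the thickness pattern moves.
    """
    cx, cz = centre
    if not np.isfinite(cz):
        return pts[:, 0] - cx
    th = math.radians(tilt_deg)
    dx = pts[:, 0] - cx
    dz = pts[:, 1] - cz
    return math.cos(th) * dx + math.sin(th) * dz


def _true_back_polyline(spec: PhantomSpec, meridian: str, decenter: float,
                        tilt_deg: float, n_dense: int) -> np.ndarray:
    """Dense (m, 2) polyline of the true physical back surface."""
    geo, cornea = spec.geometry, spec.cornea
    xs = np.linspace(-geo.lateral_width_mm / 2, geo.lateral_width_mm / 2, n_dense)
    zf, inside, centre = _front_surface(cornea, xs, decenter)
    xs, zf = xs[inside], zf[inside]
    front = np.stack([xs, zf], axis=1)
    normals = _inward_normals(cornea, front, centre)
    thickness = build_thickness_field(cornea)
    d = _material_lateral(front, centre, tilt_deg)
    t_mm = thickness(d, meridian) / 1000.0
    return front + t_mm[:, None] * normals


def _intersect_rays_polyline(entry: np.ndarray, dirs: np.ndarray,
                             poly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force ray–polyline intersection for near-vertical rays.

    For each ray (entry point E, unit direction r) find the smallest s > 0
    with E + s r on the polyline.  Rays deviate laterally by only ~T·sinθ
    (micrometres), so the search is restricted to a window of polyline
    vertices around each entry's lateral position.
    """
    n = entry.shape[0]
    px, pz = poly[:, 0], poly[:, 1]
    pitch = np.median(np.diff(px))
    k = max(8, int(math.ceil(0.6 / pitch)))
    centre_idx = np.clip(np.searchsorted(px, entry[:, 0]), k, len(px) - k - 1)
    offs = np.arange(-k, k + 1)
    idx = centre_idx[:, None] + offs[None, :]          # (n, w)
    bx = px[idx] - entry[:, 0:1]
    bz = pz[idx] - entry[:, 1:2]
    # signed side of each vertex w.r.t. the ray
    cross = dirs[:, 0:1] * bz - dirs[:, 1:2] * bx
    sign_change = np.signbit(cross[:, :-1]) != np.signbit(cross[:, 1:])

    s_out = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    rows, cols = np.nonzero(sign_change)
    if rows.size:
        # segment endpoints for every candidate crossing
        a = np.stack([bx[rows, cols], bz[rows, cols]], axis=1)
        b = np.stack([bx[rows, cols + 1], bz[rows, cols + 1]], axis=1)
        seg = b - a
        r = dirs[rows]
        denom = r[:, 0] * seg[:, 1] - r[:, 1] * seg[:, 0]
        ok = np.abs(denom) > 1e-300
        s = np.where(ok, (a[:, 0] * seg[:, 1] - a[:, 1] * seg[:, 0]) / np.where(ok, denom, 1.0), np.nan)
        good = ok & (s > 0)
        # keep smallest positive s per ray
        order = np.lexsort((s, rows))
        rows_o, s_o, good_o = rows[order], s[order], good[order]
        first = np.ones_like(rows_o, dtype=bool)
        first[1:] = rows_o[1:] != rows_o[:-1]
        seen: dict[int, bool] = {}
        for ri, si, gi in zip(rows_o, s_o, good_o):
            if gi and not seen.get(ri, False):
                s_out[ri] = si
                valid[ri] = True
                seen[ri] = True
    return s_out, valid


def render_bscan(spec: PhantomSpec, session: SessionSpec, test_index: int = 1,
                 seed: Optional[int] = None, decenter_mm: float = 0.0,
                 tilt_deg: float = 0.0) -> BScan:
    """Render one synthetic B-scan with ground truth attached.

    The front echo of A-scan i sits at the surface depth z_f(x_i); the back
    echo at z_f + n·s where s is the refracted physical path length found by
    numerical ray–surface intersection.  Echoes are Gaussian ridges of FWHM
    ``axial_psf_fwhm_um`` (front) and n-broadened (back); amplitudes decay
    as exp(-z/rolloff); noise per :class:`NoiseModel`.  A-scans beyond the
    eyelid cut-off (vertical meridian) contain background only.
    """
    geo, cornea, noise = spec.geometry, spec.cornea, spec.noise
    n_idx = cornea.group_index
    x = geo.x_mm
    zf, inside, centre = _front_surface(cornea, x, decenter_mm)

    front_pts = np.stack([x, np.where(inside, zf, 0.0)], axis=1)
    normals = _inward_normals(cornea, front_pts, centre)
    incident = np.tile(np.array([0.0, 1.0]), (len(x), 1))
    refracted = snell_refract_many(incident, normals, 1.0, n_idx)

    poly = _true_back_polyline(spec, session.meridian, decenter_mm, tilt_deg,
                               n_dense=max(4096, 4 * geo.n_ascans))
    s_mm = np.full(len(x), np.nan)
    hit = np.zeros(len(x), dtype=bool)
    if inside.any():
        s_in, hit_in = _intersect_rays_polyline(front_pts[inside], refracted[inside], poly)
        s_mm[inside], hit[inside] = s_in, hit_in

    occluded = np.zeros(len(x), dtype=bool)
    if session.meridian == "vertical" and session.eyelid_occlusion_from_mm is not None:
        occluded = x > session.eyelid_occlusion_from_mm

    valid = inside & hit & ~occluded
    zb = np.where(hit, zf + n_idx * s_mm, np.nan)

    # material thickness truth at each entry point
    thickness = build_thickness_field(cornea)
    d = _material_lateral(front_pts, centre, tilt_deg)
    t_um = thickness(d, session.meridian)
    back_point = front_pts + np.where(hit, s_mm, np.nan)[:, None] * refracted

    # --- image formation -------------------------------------------------
    z = geo.z_mm
    sigma_f = geo.axial_psf_fwhm_um * _FWHM_TO_SIGMA / 1000.0  # mm
    sigma_b = sigma_f * n_idx
    atten_f = np.exp(-np.nan_to_num(zf, nan=np.inf) / noise.depth_rolloff_mm)
    atten_b = np.exp(-np.nan_to_num(zb, nan=np.inf) / noise.depth_rolloff_mm)
    amp_f = noise.surface_amplitude * atten_f
    amp_b = noise.surface_amplitude * noise.back_amplitude_ratio * atten_b
    render_mask = (inside & ~occluded).astype(float)
    zf_c = np.nan_to_num(zf, nan=-10.0)[:, None]
    zb_c = np.nan_to_num(zb, nan=-10.0)[:, None]
    signal = (render_mask * amp_f)[:, None] * np.exp(-0.5 * ((z[None, :] - zf_c) / sigma_f) ** 2)
    signal += (render_mask * np.nan_to_num(amp_b) * hit)[:, None] * np.exp(
        -0.5 * ((z[None, :] - zb_c) / sigma_b) ** 2)

    if noise.speckle_factor > 0 or noise.background_sd > 0:
        rng = np.random.default_rng(noise.seed if seed is None else seed)
        if noise.speckle_factor > 0:
            signal = signal * (1.0 + noise.speckle_factor * rng.standard_normal(signal.shape))
        if noise.background_sd > 0:
            signal = signal + np.abs(rng.normal(0.0, noise.background_sd, signal.shape))
        np.clip(signal, 0.0, None, out=signal)

    ox, oz = cornea.apex_offset_mm
    truth = PhantomTruth(
        x_mm=x, front_z_mm=zf, back_optical_z_mm=zb, path_length_mm=s_mm,
        refracted_dir=refracted, surface_normal=normals, back_point_mm=back_point,
        thickness_um=t_um, valid=valid, back_surface_mm=poly,
        apex_x_mm=ox + decenter_mm, apex_z_mm=oz,
        decenter_mm=decenter_mm, tilt_deg=tilt_deg,
    )
    return BScan(intensity=signal, geometry=geo, meridian=session.meridian,
                 eye=session.eye, test_index=test_index, truth=truth)


# ---------------------------------------------------------------------------
# cohorts


def plan_cohort(n_subjects: int = 21, seed: int = 0,
                t0_mean_um: float = DEFAULT_T0_MEAN_UM,
                t0_sd_um: float = DEFAULT_T0_SD_UM,
                jitter: tuple[float, float] = (0.05, 0.3),
                meridians: tuple[str, ...] = ("horizontal", "vertical"),
                eyes: tuple[str, ...] = ("OD", "OS")) -> pd.DataFrame:
    """Draw a cohort manifest: one row per B-scan to be rendered.

    Each subject's central thickness T0 is drawn from N(t0_mean, t0_sd)
    (both eyes share it); test 2 differs from test 1 by a fresh noise seed
    plus decentration/tilt jitter.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if t0_sd_um < 0 or jitter[0] < 0 or jitter[1] < 0:
        raise ValueError("spread parameters must be >= 0")
    rng = np.random.default_rng(seed)
    t0 = rng.normal(t0_mean_um, t0_sd_um, n_subjects)
    rows = []
    for s in range(n_subjects):
        for eye in eyes:
            for meridian in meridians:
                for test in (1, 2):
                    dec = rng.normal(0.0, jitter[0]) if test == 2 else 0.0
                    tilt = rng.normal(0.0, jitter[1]) if test == 2 else 0.0
                    rows.append({
                        "subject": s + 1, "eye": eye, "meridian": meridian,
                        "test": test, "t0_um": t0[s],
                        "seed": int(rng.integers(0, 2**31 - 1)),
                        "decenter_mm": dec, "tilt_deg": tilt,
                    })
    return pd.DataFrame(rows)


def render_cohort(plan: pd.DataFrame, spec: Optional[PhantomSpec] = None,
                  session_base: Optional[SessionSpec] = None
                  ) -> Iterator[tuple[pd.Series, BScan]]:
    """Render every scan in a cohort manifest, streaming one at a time."""
    spec = spec or PhantomSpec()
    base = session_base or SessionSpec()
    for _, row in plan.iterrows():
        cornea = replace(spec.cornea, central_thickness_um=float(row["t0_um"]))
        sc = replace(spec, cornea=cornea)
        session = replace(base, meridian=row["meridian"], eye=row["eye"])
        bscan = render_bscan(sc, session, test_index=int(row["test"]),
                             seed=int(row["seed"]),
                             decenter_mm=float(row["decenter_mm"]),
                             tilt_deg=float(row["tilt_deg"]))
        yield row, bscan


def simulate_cohort(n_subjects: int = 21, spec: Optional[PhantomSpec] = None,
                    seed: int = 0, **plan_kwargs):
    """Convenience wrapper: (manifest, scan iterator) for a full cohort."""
    plan = plan_cohort(n_subjects=n_subjects, seed=seed, **plan_kwargs)
    return plan, render_cohort(plan, spec)
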