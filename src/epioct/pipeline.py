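"""End-to-end analysis of one B-scan and of whole cohorts.

segmentation -> Snell dewarping -> apex anchoring -> perpendicular
thickness -> 0.5-mm binning -> left-eye mirroring.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .phantom import BScan
from .profiling import (ThicknessProfile, bin_profile, find_apex,
                        mirror_profile, perpendicular_thickness, standard_grid)
from .refraction import RefractionParams, dewarp_back_surface
from .repeatability import RepeatabilityReport, repeatability_report
from .segmentation import SegmentationParams, trace_boundaries

__all__ = ["profile_bscan", "stack_profiles", "repeatability_from_profiles"]


def profile_bscan(bscan: BScan,
                  seg_params: Optional[SegmentationParams] = None,
                  refr_params: Optional[RefractionParams] = None,
                  anchor_apex: bool = True,
                  mirror: bool = True) -> ThicknessProfile:
    """Run the full thickness pipeline on one B-scan.

    ``anchor_apex=False`` anchors the profile at the scan centre instead of
    the detected apex; ``mirror=False`` skips left-eye mirroring.
    """
    front_tr, back_tr = trace_boundaries(bscan, seg_params)
    front, back = dewarp_back_surface(front_tr, back_tr, refr_params)
    apex = find_apex(front) if anchor_apex else None
    apex_x = apex.x_mm if apex is not None else 0.0
    # thickness samples only where the corrected back surface exists
    joint = front.valid & back.valid
    front_j = type(front)(x_mm=front.x_mm, z_mm=front.z_mm,
                          provenance="front", valid=joint)
    x, t = perpendicular_thickness(front_j, back)
    profile = bin_profile(x, t, apex_x_mm=apex_x,
                          grid=standard_grid(bscan.meridian),
                          eye=bscan.eye, meridian=bscan.meridian,
                          test_index=bscan.test_index)
    return mirror_profile(profile) if mirror else profile


def stack_profiles(df: pd.DataFrame, meridian: str,
                   average_eyes: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arrange a combined profile frame into (test1, test2) cohort arrays.

    Profiles of both eyes (already mirrored) are averaged per subject.
    Returns ``(positions, test1, test2)`` with shape (n_subjects, n_grid);
    NaN marks missing.  Raises if any subject lacks one of the two tests.
    """
    sub = df[df["meridian"] == meridian]
    positions = np.sort(sub["position_mm"].unique())
    subjects = np.sort(sub["subject"].unique())
    out = {}
    for test in (1, 2):
        mat = np.full((len(subjects), len(positions)), np.nan)
        for i, s in enumerate(subjects):
            rows = sub[(sub["subject"] == s) & (sub["test"] == test)]
            if rows.empty:
                raise ValueError(f"subject {s}: no {meridian} profile for test {test}")
            if average_eyes:
                piv = rows.pivot_table(index="position_mm", columns="eye",
                                       values="thickness_um", aggfunc="mean")
                vals = piv.mean(axis=1).reindex(positions).to_numpy()
            else:
                vals = (rows.groupby("position_mm")["thickness_um"].mean()
                        .reindex(positions).to_numpy())
            mat[i] = vals
        out[test] = mat
    return positions, out[1], out[2]


def repeatability_from_profiles(df: pd.DataFrame, meridian: str) -> RepeatabilityReport:
    """Test-retest repeatability report for one meridian of a cohort."""
    positions, t1, t2 = stack_profiles(df, meridian)
    return repeatability_report(t1, t2, positions)
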