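"""Test-retest agreement statistics: CoR, CoR%, ICC(2,1), paired t.

The coefficient of repeatability (CoR) is twice the sample standard
deviation of the between-test differences; CoR% normalises it by the mean
of all measurements (both tests pooled).  The intraclass correlation is
the two-way random-effects, absolute-agreement, single-measurement form
ICC(2,1), computed from the two-way ANOVA mean squares — the standard
choice for test-retest designs.  All statistics are evaluated per grid
location across subjects and aggregated over clinical zones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorResult",
    "RepeatabilityReport",
    "cor",
    "icc",
    "paired_t",
    "repeatability_report",
]


@dataclass
class CorResult:
    cor_um: float
    cor_pct: float


@dataclass
class RepeatabilityReport:
    """Per-location and zonal repeatability of a paired cohort."""

    table: pd.DataFrame   # position_mm, n, cor_um, cor_pct, icc, t, p
    zonal: pd.DataFrame   # zone, n_locations, cor_mean/sd, icc_mean/sd, cor_pct_mean


def _as_pairs(m1, m2) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be aligned 1-D arrays")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("paired samples must be finite")
    return a, b


def cor(m1, m2) -> CorResult:
    """Coefficient of repeatability: 2 x sample SD of the differences.

    CoR% = 100 * CoR / mean of all measurements (both tests pooled).
    """
    a, b = _as_pairs(m1, m2)
    if len(a) < 2:
        raise ValueError("need >= 2 pairs")
    c = 2.0 * float(np.std(a - b, ddof=1))
    total_mean = float(np.mean(np.concatenate([a, b])))
    pct = 100.0 * c / total_mean if total_mean != 0 else math.nan
    return CorResult(cor_um=c, cor_pct=pct)


def icc(m1, m2) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    With n subjects and k = 2 tests, from the two-way ANOVA mean squares
    (MSR between subjects, MSC between tests, MSE residual):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Zero total variance leaves the ICC undefined (NaN, with a warning).
    """
    a, b = _as_pairs(m1, m2)
    n = len(a)
    if n < 3:
        raise ValueError("need >= 3 pairs")
    data = np.stack([a, b], axis=1)  # n x k
    k = 2
    grand = data.mean()
    row_mean = data.mean(axis=1)
    col_mean = data.mean(axis=0)
    if np.allclose(data, grand):
        warnings.warn("zero total variance: ICC undefined", stacklevel=2)
        return math.nan
    ss_rows = k * np.sum((row_mean - grand) ** 2)
    ss_cols = n * np.sum((col_mean - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        warnings.warn("degenerate variance decomposition: ICC undefined",
                      stacklevel=2)
        return math.nan
    return float((msr - mse) / denom)


def paired_t(m1, m2) -> tuple[float, float]:
    """Paired t test on the differences; two-tailed p.

    Degenerate cases: zero-variance differences give t = 0, p = 1 when the
    mean difference is zero, and p = 0 (warned) otherwise.
    """
    a, b = _as_pairs(m1, m2)
    n = len(a)
    if n < 2:
        raise ValueError("need >= 2 pairs")
    d = a - b
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0
        warnings.warn("zero-variance nonzero differences: degenerate t",
                      stacklevel=2)
        return math.copysign(math.inf, mean), 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return t, p


def repeatability_report(test1: np.ndarray, test2: np.ndarray,
                         positions_mm: np.ndarray,
                         central_radius_mm: float = 3.0) -> RepeatabilityReport:
    """Per-location and zonal repeatability across a cohort.

    ``test1``/``test2`` are (n_subjects, n_locations) thickness arrays on a
    common grid (NaN = missing; a location's statistics use its complete
    pairs).  Zones: central 6-mm (|x| <= central_radius) and peripheral
    (|x| > central_radius), matching the diameter naming convention.
    """
    t1 = np.asarray(test1, dtype=float)
    t2 = np.asarray(test2, dtype=float)
    pos = np.asarray(positions_mm, dtype=float)
    if t1.shape != t2.shape or t1.ndim != 2 or t1.shape[1] != len(pos):
        raise ValueError("misaligned cohort arrays/grid")
    if t1.shape[0] < 3:
        raise ValueError("need >= 3 subjects")

    rows = []
    for j, x in enumerate(pos):
        ok = np.isfinite(t1[:, j]) & np.isfinite(t2[:, j])
        a, b = t1[ok, j], t2[ok, j]
        row = {"position_mm": x, "n": int(ok.sum()), "cor_um": np.nan,
               "cor_pct": np.nan, "icc": np.nan, "t": np.nan, "p": np.nan}
        if len(a) >= 3:
            c = cor(a, b)
            row["cor_um"], row["cor_pct"] = c.cor_um, c.cor_pct
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row["icc"] = icc(a, b)
                row["t"], row["p"] = paired_t(a, b)
        rows.append(row)
    table = pd.DataFrame(rows)

    zones = {"central_6mm": np.abs(pos) <= central_radius_mm,
             "peripheral": np.abs(pos) > central_radius_mm}
    zrows = []
    for zone, member in zones.items():
        sub = table[member & np.isfinite(table["cor_um"].to_numpy())]
        zrows.append({
            "zone": zone,
            "n_locations": len(sub),
            "cor_mean_um": sub["cor_um"].mean() if len(sub) else np.nan,
            "cor_sd_um": sub["cor_um"].std(ddof=1) if len(sub) > 1 else np.nan,
            "cor_pct_mean": sub["cor_pct"].mean() if len(sub) else np.nan,
            "icc_mean": sub["icc"].mean() if len(sub) else np.nan,
            "icc_sd": sub["icc"].std(ddof=1) if len(sub) > 1 else np.nan,
        })
    return RepeatabilityReport(table=table, zonal=pd.DataFrame(zrows))
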