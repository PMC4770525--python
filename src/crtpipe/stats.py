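"""Validation statistics: inverse-CRT vs temperature correlation with
Fisher-z' confidence intervals, cohort significance counts, and binned
density summaries with best-fit lines.

Skin cooling lengthens the capillary refill time, so the *inverse* refill
time (1/CRT) is correlated against spot temperature to yield a positive r
for a well-behaved sensor.  Pairs use the raw (unfiltered) accepted CRTs and
the spot temperature at the moment of pressure release.  Confidence
intervals on Pearson's r use Fisher's z' transformation:
``z' = atanh(r)`` is approximately normal with standard error
``1/sqrt(n-3)``, and the z-space interval maps back through tanh.
Significance (p < 0.05, two-sided) is operationalised as the 95% CI
excluding zero; no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedCorrelationError

log = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    significant: bool
    degenerate: bool = False          # |r| = 1: z' infinite, CI collapses
    wavelength: int | None = None
    subject: str | None = None

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "n": self.n,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "significant": self.significant,
            "degenerate": self.degenerate,
            "wavelength": self.wavelength,
            "subject": self.subject,
        }


def pearson_fisher(
    x, y, alpha: float = 0.05, wavelength: int | None = None, subject: str | None = None
) -> CorrelationResult:
    """Pearson product-moment r with a Fisher-z' confidence interval.

    Requires n >= 4 finite pairs with nonzero variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise UndefinedCorrelationError(f"need >= 4 pairs for a finite CI, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    r = float(sps.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-15:
        r = math.copysign(1.0, r)
        return CorrelationResult(
            r=r, n=n, ci_low=r, ci_high=r, significant=True, degenerate=True,
            wavelength=wavelength, subject=subject,
        )
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zc = float(sps.norm.ppf(1.0 - alpha / 2.0))
    lo, hi = math.tanh(z - zc * se), math.tanh(z + zc * se)
    return CorrelationResult(
        r=r, n=n, ci_low=lo, ci_high=hi,
        significant=(lo > 0.0) or (hi < 0.0),
        wavelength=wavelength, subject=subject,
    )


def inverse_crt_pairs(refills: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(temperature, 1/CRT) pairs from used refills of one wavelength group.

    Rejected refills are excluded; non-positive CRTs are dropped with a
    logged warning.
    """
    used = refills[refills["status"] == "used"]
    crt = used["crt_s"].to_numpy(float)
    temp = used["spot_temp_c"].to_numpy(float)
    bad = ~(crt > 0)
    if bad.any():
        log.warning("excluding %d refills with non-positive CRT", int(bad.sum()))
    ok = (crt > 0) & np.isfinite(crt) & np.isfinite(temp)
    return temp[ok], 1.0 / crt[ok]


@dataclass
class BinnedDensity:
    """2-D histogram of (CRT, temperature) with an unbinned best-fit line."""

    crt_bin_edges: np.ndarray      # 0.1 s bins, half-open [lo, hi), anchored at 0
    temp_bin_edges: np.ndarray     # 0.25 degC bins, likewise
    counts: np.ndarray             # shape (n_crt_bins, n_temp_bins)
    fit_slope: float               # d(CRT)/d(temperature), s/degC
    fit_intercept: float


#: guard against float division putting an on-edge value in the lower bin
_EDGE_EPS = 1e-9


def _bin_index(values: np.ndarray, width: float) -> np.ndarray:
    return np.floor(values / width + _EDGE_EPS).astype(int)


def _anchored_edges(values: np.ndarray, width: float) -> np.ndarray:
    lo = int(np.min(_bin_index(np.asarray(values), width)))
    hi = int(np.max(_bin_index(np.asarray(values), width))) + 1
    return np.arange(lo, hi + 1) * width


def binned_density(
    refills: pd.DataFrame, crt_bin_s: float = 0.1, temp_bin_c: float = 0.25
) -> BinnedDensity:
    """Bin used refills by (CRT, spot temperature); fit an OLS line through
    the unbinned points.  Bin edges are anchored at zero and half-open
    [low, high), so a point exactly on an edge belongs to the upper cell's
    lower edge."""
    used = refills[refills["status"] == "used"]
    crt = used["crt_s"].to_numpy(float)
    temp = used["spot_temp_c"].to_numpy(float)
    ok = np.isfinite(crt) & np.isfinite(temp)
    crt, temp = crt[ok], temp[ok]
    ce = _anchored_edges(crt, crt_bin_s)
    te = _anchored_edges(temp, temp_bin_c)
    counts = np.zeros((len(ce) - 1, len(te) - 1), dtype=int)
    ci = _bin_index(crt, crt_bin_s) - int(round(ce[0] / crt_bin_s))
    ti = _bin_index(temp, temp_bin_c) - int(round(te[0] / temp_bin_c))
    np.add.at(counts, (ci, ti), 1)
    if len(crt) >= 2 and np.std(temp) > 0:
        fit = sps.linregress(temp, crt)
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        slope, intercept = math.nan, math.nan
    return BinnedDensity(
        crt_bin_edges=ce,
        temp_bin_edges=te,
        counts=counts,
        fit_slope=slope,
        fit_intercept=intercept,
    )


def cohort_significance(results: list[CorrelationResult]) -> dict:
    """Per-wavelength count and percentage of subjects with a significant
    correlation (e.g. 11 of 15 -> 73%)."""
    out: dict = {}
    by_w: dict = {}
    for res in results:
        by_w.setdefault(res.wavelength, []).append(res)
    for w, group in by_w.items():
        k = sum(1 for g in group if g.significant)
        out[w] = {
            "n_subjects": len(group),
            "n_significant": k,
            "pct_significant": 100.0 * k / len(group) if group else math.nan,
        }
    return out


def percent_per_degree(fit_slope: float, crt_baseline_s: float) -> float:
    """Fractional CRT change per degC as a percentage of a baseline CRT.

    A fit slope of -0.14 s/degC against a 2 s baseline is a 7%/degC change.
    """
    if crt_baseline_s <= 0:
        raise ValueError("baseline CRT must be > 0")
    return 100.0 * abs(fit_slope) / crt_baseline_s
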