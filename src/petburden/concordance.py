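"""Reader-agreement analytics: Lin's CCC, Bland-Altman, stratified tables.

Lin's concordance correlation coefficient measures deviation of paired
measurements from the 45° identity line,

    rho_c = 2·s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2),

with second moments computed with the 1/n convention (Lin's original
estimator); |rho_c| <= |Pearson r| always.  The 95% CI uses the Fisher
z-transform with Lin's asymptotic standard error.

Bland-Altman agreement summarizes paired differences by their mean
(bias) and 1.96·SD limits of agreement, with the SD using 1/(n−1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "AgreementResult",
    "ccc",
    "bland_altman",
    "tertile_strata",
    "stratified_ccc",
]


@dataclass
class ConcordanceResult:
    rho_c: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class AgreementResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    outlier_ids: list


def ccc(x, y, ci_level: float = 0.95) -> ConcordanceResult:
    """Lin's concordance correlation coefficient with Fisher-z CI.

    Raises if n < 2 or the statistic is undefined (both series constant,
    where the denominator is zero when their means also coincide).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x.size
    if n < 2:
        raise ValueError("ccc requires n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("ccc requires finite values")
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))  # 1/n moments
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        # both series constant with equal means: agreement undefined, but a
        # pair of identical constant series is perfect agreement by convention
        if np.array_equal(x, y):
            return ConcordanceResult(rho_c=1.0, ci_low=1.0, ci_high=1.0, n=n)
        raise ValueError("ccc undefined: zero variance and equal means in both series")
    rho_c = 2.0 * sxy / denom

    # Fisher-z CI with Lin's asymptotic SE (needs r and n > 2; degenerate
    # when |rho_c| = 1, where the CI collapses to the point).
    ci_low = ci_high = rho_c
    if n > 2 and abs(rho_c) < 1.0 and sx2 > 0 and sy2 > 0:
        r = sxy / np.sqrt(sx2 * sy2)
        if abs(r) > 0:
            u = (mx - my) / (sx2 * sy2) ** 0.25
            r2, rc2 = r ** 2, rho_c ** 2
            var_z = (
                (1 - r2) * rc2 / ((1 - rc2) * r2)
                + 4 * rho_c ** 3 * (1 - rho_c) * u ** 2 / (r * (1 - rc2) ** 2)
                - 2 * rho_c ** 4 * u ** 4 / (r2 * (1 - rc2) ** 2)
            ) / (n - 2)
            if var_z > 0:
                z = np.arctanh(rho_c)
                zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
                half = zcrit * np.sqrt(var_z)
                ci_low = float(np.tanh(z - half))
                ci_high = float(np.tanh(z + half))
    return ConcordanceResult(rho_c=float(rho_c), ci_low=min(ci_low, rho_c),
                             ci_high=max(ci_high, rho_c), n=n)


def bland_altman(x, y, outlier_ids=None) -> AgreementResult:
    """Bland-Altman bias and 1.96·SD limits of agreement for x − y.

    SD of the differences uses the 1/(n−1) convention.  Samples whose
    |difference − bias| exceeds 1.96·SD are flagged as outliers (reported
    by position, or by the labels in ``outlier_ids``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("bland_altman requires two equal-length 1-D series, n >= 2")
    diff = x - y
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    half = 1.96 * sd
    ids = np.arange(x.size) if outlier_ids is None else np.asarray(outlier_ids)
    flagged = ids[np.abs(diff - bias) > half]
    return AgreementResult(bias=bias, sd_diff=sd,
                           loa_low=bias - half, loa_high=bias + half,
                           outlier_ids=list(flagged))


def tertile_strata(values, reference=None) -> tuple[np.ndarray, np.ndarray]:
    """Assign tertile stratum labels using a reference series' quantiles.

    Edges are the 1/3 and 2/3 quantiles (linear interpolation) of
    ``reference`` (defaults to ``values`` itself); bins are half-open
    [low, high) with the last bin closed at the observed maximum.
    Returns ``(labels, edges)`` where labels are 0/1/2 and ``edges`` the
    two interior cut values.  Duplicate edges (heavy ties) collapse the
    affected bins, which is reported by the duplicated edge values;
    stratification of an all-constant series is an error.
    """
    values = np.asarray(values, dtype=float)
    ref = values if reference is None else np.asarray(reference, dtype=float)
    if ref.size < 3:
        raise ValueError("tertile stratification requires n >= 3")
    if np.ptp(ref) == 0:
        raise ValueError("all reference values equal; tertiles undefined")
    edges = np.quantile(ref, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.searchsorted(edges, values, side="right")
    # values exactly at an edge belong to the upper bin ([low, high)), which
    # searchsorted's 'right' already gives; cap at 2 for the closed last bin
    labels = np.minimum(labels, 2)
    return labels.astype(int), edges


def stratified_ccc(x, y, strata) -> pd.DataFrame:
    """Lin's CCC per stratum; per-stratum failures do not abort the rest.

    Returns a table with columns stratum, n, rho_c, ci_low, ci_high,
    error (empty string when the stratum succeeded).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    rows = []
    for s in np.unique(strata):
        sel = strata == s
        row = {"stratum": s, "n": int(sel.sum()), "rho_c": np.nan,
               "ci_low": np.nan, "ci_high": np.nan, "error": ""}
        try:
            res = ccc(x[sel], y[sel])
            row.update(rho_c=res.rho_c, ci_low=res.ci_low, ci_high=res.ci_high)
        except ValueError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
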