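"""Noncompartmental analysis of concentration-time profiles.

Implements the linear-trapezoidal AUC (equal weighting), terminal-slope
estimation by log-linear regression with the number of terminal points chosen
by adjusted R-squared, the usual single-dose metrics (Cmax, Tmax, AUC0-last,
AUC0-inf, apparent clearance Cl/F = dose / AUC0-inf) and geometric summary
statistics.

Conventions (extravascular single dose): the Cmax point is excluded from
terminal-slope candidate subsets, zero concentrations are dropped from the
log regression, the observed (not fitted) last positive concentration is
used for extrapolation, and candidate subsets need at least three points.
When several subset sizes give adjusted R-squared within 1e-4 of the best,
the larger subset wins (stabilizes lambda_z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PKDataset

__all__ = [
    "LambdaZFit",
    "NCAResult",
    "auc_trapezoid",
    "fit_lambda_z",
    "nca_subject",
    "nca_dataset",
    "summarize_geometric",
]

#: adjusted-R2 plateau width within which a larger terminal subset is preferred
_ADJ_R2_TOL = 1e-4


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal elimination fit: lambda_z (1/h) and its regression metadata."""

    lambda_z: float
    adj_r2: float
    n_points: int
    intercept: float
    failed: bool = False

    @property
    def half_life(self) -> float:
        return np.log(2.0) / self.lambda_z if not self.failed else np.nan


@dataclass(frozen=True)
class NCAResult:
    """Single-subject noncompartmental metrics (ug, L, h units)."""

    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float
    cl_f: float
    lambda_z_fit: LambdaZFit

    @property
    def extrapolated_fraction(self) -> float:
        if not np.isfinite(self.auc_inf) or self.auc_inf <= 0:
            return np.nan
        return 1.0 - self.auc_last / self.auc_inf


def auc_trapezoid(times, conc) -> float:
    """AUC from t[0] to t[-1] by the linear trapezoidal rule."""
    t = np.asarray(times, float)
    c = np.asarray(conc, float)
    if t.ndim != 1 or t.shape != c.shape or len(t) < 2:
        raise ValueError("need >= 2 matching (time, concentration) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    return float(np.trapezoid(c, t))


def _adj_r2(t: np.ndarray, logc: np.ndarray) -> tuple[float, float, float]:
    """OLS of log-concentration on time: slope, intercept, adjusted R2."""
    n = len(t)
    slope, intercept = np.polyfit(t, logc, 1)
    resid = logc - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    if ss_tot == 0:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return float(slope), float(intercept), float(adj)


def fit_lambda_z(times, conc) -> LambdaZFit:
    """Terminal slope by adjusted-R2 subset selection.

    Candidate subsets are the last k = 3..K positive-concentration points
    after (and excluding) the Cmax point; the subset maximizing adjusted R2
    is selected, preferring more points on plateaus.  If every candidate
    gives a nonnegative slope the fit fails (flagged; AUC0-inf undefined).
    """
    t = np.asarray(times, float)
    c = np.asarray(conc, float)
    i_max = int(np.argmax(c))  # first occurrence on ties
    post = np.nonzero((np.arange(len(c)) > i_max) & (c > 0))[0]
    if len(post) < 3:
        return LambdaZFit(np.nan, np.nan, 0, np.nan, failed=True)
    tt, lc = t[post], np.log(c[post])
    best: tuple[float, float, float, int] | None = None  # adj, slope, icpt, k
    for k in range(3, len(post) + 1):
        slope, icpt, adj = _adj_r2(tt[-k:], lc[-k:])
        if slope >= 0:
            continue
        if best is None or adj > best[0] + _ADJ_R2_TOL or (
            adj >= best[0] - _ADJ_R2_TOL and k > best[3]
        ):
            best = (adj, slope, icpt, k)
    if best is None:
        return LambdaZFit(np.nan, np.nan, 0, np.nan, failed=True)
    adj, slope, icpt, k = best
    return LambdaZFit(-slope, adj, k, icpt)


def nca_subject(times, conc, dose: float) -> NCAResult:
    """Full single-subject NCA for one dose and one profile.

    AUC0-inf = AUC0-last + Clast/lambda_z with the observed last positive
    concentration; Cl/F = dose / AUC0-inf.  On lambda_z failure AUC0-inf and
    Cl/F are reported missing (NaN).
    """
    t = np.asarray(times, float)
    c = np.asarray(conc, float)
    if dose <= 0:
        raise ValueError("dose must be positive")
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_last = auc_trapezoid(t, c)
    lz = fit_lambda_z(t, c)
    if lz.failed:
        return NCAResult(cmax, tmax, auc_last, np.nan, np.nan, lz)
    pos = np.nonzero(c > 0)[0]
    c_last = float(c[pos[-1]])
    auc_inf = auc_last + c_last / lz.lambda_z
    return NCAResult(cmax, tmax, auc_last, auc_inf, dose / auc_inf, lz)


def nca_dataset(dataset: PKDataset) -> pd.DataFrame:
    """Per-subject NCA table for an analysis-ready dataset."""
    doses = dataset.doses().set_index("ID")["AMT"]
    rows = []
    for sid, sub in dataset.observations().groupby("ID"):
        r = nca_subject(sub["TIME"].to_numpy(), sub["DV"].to_numpy(), doses[sid])
        rows.append(
            {
                "ID": sid,
                "cmax": r.cmax,
                "tmax": r.tmax,
                "auc_last": r.auc_last,
                "auc_inf": r.auc_inf,
                "cl_f": r.cl_f,
                "lambda_z": r.lambda_z_fit.lambda_z,
                "half_life": r.lambda_z_fit.half_life,
                "lambda_z_points": r.lambda_z_fit.n_points,
                "lambda_z_adj_r2": r.lambda_z_fit.adj_r2,
                "lambda_z_failed": r.lambda_z_fit.failed,
            }
        )
    return pd.DataFrame(rows)


def summarize_geometric(values) -> tuple[float, float]:
    """Geometric mean and geometric SD (sample, n-1) of positive values.

    The geometric SD of a singleton is undefined (NaN).
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("no values to summarize")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("geometric summaries require positive finite values")
    logs = np.log(v)
    gm = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if v.size > 1 else np.nan
    return gm, gsd
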