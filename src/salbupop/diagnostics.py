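"""Model-evaluation surfaces: residuals, VPC, information criteria, strata.

Residual conventions
--------------------
IWRES uses the conditional-mode (EBE) prediction and the residual error
model: ``(y - IPRED) / g(IPRED)``.  PWRES and NPDE are simulation based: the
population mean and covariance of each subject's observation vector are
estimated from replicate simulations of the fitted model, the observation
vector is decorrelated by the symmetric inverse square root of that
covariance (symmetric rather than Cholesky so the result does not depend on
the ordering of observations), and NPDE applies the rank transform of the
decorrelated observation among the decorrelated simulations followed by the
normal quantile, with ranks clamped to (1/(2K), 1 - 1/(2K)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import FitArrays, PKDataset
from .nca import summarize_geometric
from .nlme import FitResult, simulate_observations

__all__ = [
    "residual_table",
    "outlier_proportion",
    "vpc",
    "information_criteria",
    "stratified_summary",
    "individual_parameters_frame",
    "DEFAULT_STRATA",
]


def _inv_sqrt(C: np.ndarray, ridge: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Symmetric inverse square root with ridge regularization fallback."""
    w, V = np.linalg.eigh(0.5 * (C + C.T))
    ridged = bool(w.min() <= ridge * max(w.max(), 1.0))
    w = np.maximum(w, ridge * max(w.max(), 1.0))
    return (V / np.sqrt(w)) @ V.T, ridged


def residual_table(
    fit: FitResult, k_sim: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Per-observation residual table (IPRED, PRED, IWRES, PWRES, NPDE)."""
    arrays = fit.arrays
    ipred = fit.ipred()
    g = fit.model.g(ipred)
    sims = simulate_observations(fit.model, arrays, k_sim, seed)
    rows = []
    for i, sid in enumerate(arrays.ids):
        msk = arrays.mask[i]
        y = arrays.y[i][msk]
        S = sims[:, i, :][:, msk]  # (K, m_i)
        mu = S.mean(axis=0)
        C = np.cov(S, rowvar=False)
        C = np.atleast_2d(C)
        Cinv_half, ridged = _inv_sqrt(C)
        d_obs = Cinv_half @ (y - mu)
        d_sim = (S - mu) @ Cinv_half.T
        below = (d_sim < d_obs).sum(axis=0)
        ties = (d_sim == d_obs).sum(axis=0)
        pde = (below + 0.5 * ties) / k_sim
        pde = np.clip(pde, 1.0 / (2 * k_sim), 1.0 - 1.0 / (2 * k_sim))
        npde = stats.norm.ppf(pde)
        iw = (y - ipred[i][msk]) / g[i][msk]
        for j, t in enumerate(arrays.times[i][msk]):
            rows.append(
                {
                    "ID": sid, "TIME": t, "DV": y[j],
                    "IPRED": ipred[i][msk][j], "PRED": mu[j],
                    "IWRES": iw[j], "PWRES": d_obs[j], "NPDE": npde[j],
                    "cov_ridged": ridged,
                }
            )
    return pd.DataFrame(rows)


def outlier_proportion(
    observed, ipred, model, level: float = 0.90
) -> float:
    """Fraction of observations outside the error-model prediction interval.

    The interval is IPRED +/- z * g(IPRED) with z the two-sided normal
    quantile for ``level``.
    """
    y = np.asarray(observed, float)
    f = np.asarray(ipred, float)
    z = stats.norm.ppf(0.5 + level / 2.0)
    g = model.g(f)
    return float(np.mean(np.abs(y - f) > z * g))


@dataclass
class VPCBands:
    """Visual-predictive-check bands: one row per (time bin, percentile)."""

    table: pd.DataFrame
    merged_bins: list[float]

    def outlier_fraction(self) -> float:
        return float(self.table["outside"].mean())


def vpc(
    fit: FitResult,
    k_sim: int = 500,
    seed: int = 0,
    level: float = 0.90,
    percentiles: tuple[float, ...] = (10.0, 50.0, 90.0),
    min_bin: int = 3,
) -> VPCBands:
    """Observed percentiles per nominal-time bin against simulation-derived
    prediction intervals (percentile-of-percentiles construction).

    Bins with fewer than ``min_bin`` observations are merged with the
    previous bin (logged in ``merged_bins``).
    """
    arrays = fit.arrays
    sims = simulate_observations(fit.model, arrays, k_sim, seed)
    t = arrays.times[arrays.mask]
    y = arrays.y[arrays.mask]
    s = sims[:, arrays.mask]  # (K, n_obs)

    nominal = np.unique(t)
    bins: list[list[float]] = []
    merged: list[float] = []
    for tv in nominal:
        count = int((t == tv).sum())
        if bins and count < min_bin:
            bins[-1].append(tv)
            merged.append(float(tv))
        else:
            bins.append([tv])
    lo_q, hi_q = 100 * (0.5 - level / 2), 100 * (0.5 + level / 2)
    rows = []
    for group in bins:
        sel = np.isin(t, group)
        label = float(np.median(group))
        for q in percentiles:
            obs_q = float(np.percentile(y[sel], q))
            rep_q = np.percentile(s[:, sel], q, axis=1)  # (K,)
            lo, med, hi = np.percentile(rep_q, [lo_q, 50.0, hi_q])
            rows.append(
                {
                    "bin_time": label, "n_obs": int(sel.sum()),
                    "percentile": q, "observed": obs_q,
                    "pi_lower": lo, "pi_median": med, "pi_upper": hi,
                    "outside": not (lo <= obs_q <= hi),
                }
            )
    return VPCBands(pd.DataFrame(rows), merged)


def information_criteria(
    minus2ll: float, census: dict, n_subjects: int, n_obs: int
) -> tuple[float, float, float]:
    """AIC, BIC and the corrected BIC.

    AIC  = -2LL + 2p
    BIC  = -2LL + p log(N)          (N subjects)
    BICc = -2LL + p_R log(N) + p_F log(n)   (subject-level parameters
           penalized by subjects, residual-error parameters by observations)
    """
    p_r = census["p_random"]
    p_f = census["p_fixed"]
    p = census.get("p_total", p_r + p_f)
    aic = minus2ll + 2.0 * p
    bic = minus2ll + p * math.log(n_subjects)
    bicc = minus2ll + p_r * math.log(n_subjects) + p_f * math.log(n_obs)
    return aic, bic, bicc


def individual_parameters_frame(fit: FitResult) -> pd.DataFrame:
    """Per-subject individual parameter values at the conditional modes."""
    return pd.DataFrame(
        np.exp(fit.phi_modes), columns=list(fit.param_names),
        index=pd.Index(fit.arrays.ids, name="ID"),
    )


#: default stratifications of the virtual population
DEFAULT_STRATA = {
    "age_group": ("AGE", (("5-22", 5.0, 22.0), ("23-65", 22.0, 65.0))),
    "weight_group": ("WT", (("<=75", 0.0, 75.0), (">75", 75.0, math.inf))),
    "gender": ("SEX", None),
    "race": ("RACE", None),
}


def stratified_summary(
    params: pd.DataFrame,
    cov: pd.DataFrame,
    strata: dict | None = None,
) -> pd.DataFrame:
    """Geometric mean +/- geometric SD of individual parameters per stratum.

    ``params`` holds per-subject parameter values indexed by subject id;
    ``cov`` the covariate table with the same index.  Continuous strata are
    (label, low, high] intervals; categorical strata use the observed levels.
    Empty strata are omitted (flagged); singleton strata report NaN
    geometric SD.
    """
    strata = strata if strata is not None else DEFAULT_STRATA
    cov = cov.loc[params.index]
    rows = []
    for sname, (column, bands) in strata.items():
        if bands is None:
            levels = [(str(lev), cov[column].astype(str) == str(lev))
                      for lev in sorted(cov[column].astype(str).unique())]
        else:
            levels = [
                (label, (cov[column] > lo) & (cov[column] <= hi))
                for label, lo, hi in bands
            ]
        for label, sel in levels:
            n = int(sel.sum())
            if n == 0:
                rows.append(
                    {"stratum_var": sname, "stratum": label, "parameter": None,
                     "n": 0, "geo_mean": np.nan, "geo_sd": np.nan,
                     "flag": "empty"}
                )
                continue
            for p in params.columns:
                gm, gsd = summarize_geometric(params.loc[sel.values, p])
                rows.append(
                    {"stratum_var": sname, "stratum": label, "parameter": p,
                     "n": n, "geo_mean": gm, "geo_sd": gsd,
                     "flag": "singleton" if n == 1 else ""}
                )
    return pd.DataFrame(rows)
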