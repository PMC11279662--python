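"""Data-driven starting values for SAEM.

Starting values come from the dataset itself: apparent clearance from
dose/AUC (parameterization-free under linear kinetics), the two observable
exponential rates from the terminal slope of the median profile and the peak
time, volumes from a coarse grid, and a cheap weighted least-squares
refinement of the median profile.

Flip-flop: after a depot dose the profile identifies the *pair* of rates
{absorption, elimination}, not which is which.  The default policy ``auto``
builds both assignments, refines each against the median profile and keeps
the better one; on a tie (pure bi-exponential data cannot discriminate) the
absorption-limited assignment wins, because absorption from the lung is
typically rate-limiting for inhaled powders.  Policies
``"absorption-limited"`` / ``"elimination-limited"`` force the assignment.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .data import PKDataset
from .nca import nca_dataset
from .nlme import PopModel
from .pkmodel import get_model

__all__ = ["nca_informed_initials"]

_V2_GRID = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0)  # as multiples of V1
_POLICIES = ("auto", "absorption-limited", "elimination-limited")


def nca_informed_initials(
    dataset: PKDataset,
    structural: str = "two_compartment",
    flip_flop: str = "auto",
    omega0: float = 0.2,
    a0: float = 0.1,
    b0: float = 0.2,
    refine: bool = True,
) -> PopModel:
    """Build an initial :class:`PopModel` from NCA summaries of a dataset."""
    if flip_flop not in _POLICIES:
        raise ValueError(f"unknown flip-flop policy {flip_flop!r}")
    table = nca_dataset(dataset)
    ok = table[~table["lambda_z_failed"]]
    if ok.empty:
        raise ValueError("lambda_z failed for every subject; cannot initialize")
    cl0 = float(np.nanmedian(ok["cl_f"]))
    if not np.isfinite(cl0):
        dose = float(dataset.doses()["AMT"].median())
        cl0 = dose / float(np.nanmedian(ok["auc_last"]))
    r_slow, tmax = _median_profile_rates(dataset)
    if not np.isfinite(r_slow):
        r_slow = float(np.nanmedian(ok["lambda_z"]))
        tmax = float(np.nanmedian(ok["tmax"]))
    r_fast = _fast_rate(r_slow, tmax)

    policies = (
        ("absorption-limited", "elimination-limited")
        if flip_flop == "auto"
        else (flip_flop,)
    )
    candidates = []
    for pol in policies:
        ka0, kel0 = (r_slow, r_fast) if pol == "absorption-limited" else (r_fast, r_slow)
        theta = _candidate_theta(dataset, structural, ka0, kel0, cl0)
        sse = _profile_sse(dataset, structural, theta)
        if refine:
            theta, sse = _refine(dataset, structural, theta)
        candidates.append((sse, pol, theta))
    # prefer the better profile fit; near-ties go to absorption-limited
    candidates.sort(key=lambda c: c[0])
    best_sse, best_pol, theta = candidates[0]
    if len(candidates) > 1 and candidates[1][0] <= best_sse * 1.05:
        for sse, pol, th in candidates:
            if pol == "absorption-limited":
                theta = th
                break

    model = get_model(structural)
    omega = {p: omega0 for p in model.param_names}
    if "tlag" in omega:
        omega["tlag"] = 0.1
    corr = {("ka", "q"): 0.0} if "q" in model.param_names else {}
    return PopModel(
        structural=structural, theta=theta, omega=omega, correlations=corr,
        a=a0, b=b0,
    )


def _candidate_theta(
    dataset: PKDataset, structural: str, ka0: float, kel0: float, cl0: float
) -> dict[str, float]:
    model = get_model(structural)
    v1_0 = cl0 / kel0
    q0 = cl0 / 2.0
    theta = {"ka": ka0, "cl": cl0, "v1": v1_0}
    if "q" in model.param_names:
        theta["q"] = q0
        theta["v2"] = _grid_v2(dataset, ka0, cl0, v1_0, q0)
    if "q3" in model.param_names:
        theta["q3"] = q0 / 2.0
        theta["v3"] = v1_0
    if "tlag" in model.param_names:
        theta["tlag"] = 0.01
    return theta


def _fast_rate(r_slow: float, tmax: float) -> float:
    """Companion rate from the peak-time relation
    tmax = ln(r_fast/r_slow)/(r_fast - r_slow)."""
    if not (0 < tmax < 1.0 / r_slow):
        return 5.0 * r_slow

    def f(x):
        return np.log(x / r_slow) - tmax * (x - r_slow)

    hi = r_slow * 1.001
    while f(hi) > 0 and hi < 1e6:
        hi *= 2
    try:
        return float(optimize.brentq(f, r_slow * 1.0005, hi))
    except ValueError:
        return 5.0 * r_slow


def _median_profile_rates(dataset: PKDataset) -> tuple[float, float]:
    """Terminal slope and peak time of the median observed profile.

    Only the decaying portion above 2% of the peak is used, which keeps the
    slope estimate away from the additive-noise floor of late samples.
    """
    med = dataset.observations().groupby("TIME")["DV"].median()
    t = med.index.to_numpy(float)
    c = med.to_numpy(float)
    i_max = int(np.argmax(c))
    tmax = float(t[i_max]) if t[i_max] > 0 else float(t[min(i_max + 1, len(t) - 1)])
    sel = (np.arange(len(c)) > i_max) & (c > 0.02 * c[i_max])
    if sel.sum() < 3:
        return np.nan, tmax
    slope = np.polyfit(t[sel], np.log(c[sel]), 1)[0]
    return (-float(slope), tmax) if slope < 0 else (np.nan, tmax)


def _median_profile(dataset: PKDataset):
    med = dataset.observations().groupby("TIME")["DV"].median()
    t = med.index.to_numpy(float)
    y = med.to_numpy(float)
    dose = float(dataset.doses()["AMT"].median())
    w = 1.0 / (0.05 * max(y.max(), 1e-12) + 0.1 * np.maximum(y, 0.0)) ** 2
    return t, y, w, dose


def _profile_sse(dataset: PKDataset, structural: str, theta: dict) -> float:
    t, y, w, dose = _median_profile(dataset)
    sm = get_model(structural)
    vec = np.array([[theta[p] for p in sm.param_names]])
    pred = sm.predict_subjects(vec, np.array([dose]), t[None, :])[0]
    return float(np.sum(w * (y - pred) ** 2))


def _refine(dataset: PKDataset, structural: str, theta: dict):
    """Weighted least-squares polish of the median profile (log scale)."""
    t, y, w, dose = _median_profile(dataset)
    sm = get_model(structural)
    names = sm.param_names
    x0 = np.log([max(theta[p], 1e-8) for p in names])

    def obj(x):
        vec = np.exp(np.clip(x, -30, 30))[None, :]
        pred = sm.predict_subjects(vec, np.array([dose]), t[None, :])[0]
        val = float(np.sum(w * (y - pred) ** 2))
        return val if np.isfinite(val) else 1e300

    res = optimize.minimize(
        obj, x0, method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-5, "fatol": 1e-10},
    )
    vals = np.exp(res.x)
    return {n: float(v) for n, v in zip(names, vals)}, float(res.fun)


def _grid_v2(dataset: PKDataset, ka, cl, v1, q) -> float:
    """Coarse grid for the peripheral volume against the median profile."""
    t, y, w, dose = _median_profile(dataset)
    sm = get_model("two_compartment")
    best_v2, best_sse = v1 * _V2_GRID[0], np.inf
    for mult in _V2_GRID:
        v2 = v1 * mult
        pred = sm.predict_subjects(
            np.array([[ka, cl, v1, q, v2]]), np.array([dose]), t[None, :]
        )[0]
        sse = float(np.sum(w * (y - pred) ** 2))
        if sse < best_sse:
            best_sse, best_v2 = sse, v2
    return best_v2
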