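"""Nonlinear mixed-effects machinery: hierarchical model, SAEM, conditionals.

Model
-----
Individual log-parameters are Gaussian around covariate-adjusted typical
values::

    phi_i = log theta_typ(c_i) + eta_i,      eta_i ~ N(0, Omega)

so parameters are log-normal across subjects.  Omega is block-structured:
per-parameter variances plus named correlation entries (default: ka-Q).
Observations follow the combined-1 residual model, in which the residual
standard deviation is affine in the prediction::

    y_ij = f(t_ij; exp(phi_i)) + (a + b * f_ij) * eps_ij,  eps ~ N(0, 1)

Estimation is maximum likelihood by stochastic-approximation EM: a
Metropolis-within-Gibbs kernel refreshes the individual parameters, smoothed
sufficient statistics drive closed-form updates of the fixed effects and
Omega, and the residual parameters are updated by a damped inner
optimization.  The marginal likelihood is recovered afterwards by importance
sampling around the empirical Bayes modes, and standard errors by a
linearized (FOCE-style) Fisher information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .covariates import CovariateEffect, log_adjustment
from .data import FitArrays, PKDataset
from .pkmodel import StructuralModel, get_model

__all__ = [
    "PopModel",
    "SaemSettings",
    "FitResult",
    "individual_parameters",
    "fit_saem",
    "conditional_mcmc",
    "conditional_eta_samples",
    "loglik_importance",
    "standard_errors",
    "simulate_observations",
]

_LOG2PI = math.log(2.0 * math.pi)
_OMEGA_FLOOR = 1e-6  # SD floor keeping the conditional distributions proper
#: log-scale SD ceiling; a 7.4-fold interindividual coefficient of variation
#: is beyond anything physiological, and the cap stops runaway diffusion of
#: parameters the data do not constrain
_OMEGA_CEIL = 2.0
_G_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# population model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopModel:
    """Population PK model: typical values, IIV structure, residual error.

    theta        : population typical values per structural parameter
    omega        : log-scale IIV standard deviations (subset of parameters;
                   absent entries mean "no interindividual variability")
    correlations : random-effect correlations for named parameter pairs
    a, b         : additive (ug/L) and proportional residual components
    error_model  : "combined1" (default), "constant" or "proportional"
    effects      : covariate effects on the typical values
    """

    structural: str = "two_compartment"
    theta: Mapping[str, float] = field(default_factory=dict)
    omega: Mapping[str, float] = field(default_factory=dict)
    correlations: Mapping[tuple[str, str], float] = field(default_factory=dict)
    a: float = 0.05
    b: float = 0.10
    error_model: str = "combined1"
    effects: tuple[CovariateEffect, ...] = ()

    def __post_init__(self) -> None:
        model = get_model(self.structural)
        missing = set(model.param_names) - set(self.theta)
        if missing:
            raise ValueError(f"theta missing entries for {sorted(missing)}")
        for p, v in self.theta.items():
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"theta[{p}] must be positive, got {v}")
        for p, w in self.omega.items():
            if p not in model.param_names:
                raise ValueError(f"omega for unknown parameter {p!r}")
            if w < 0:
                raise ValueError(f"omega[{p}] must be >= 0")
        for (p1, p2), r in self.correlations.items():
            if abs(r) >= 1:
                raise ValueError(f"correlation ({p1},{p2}) must be in (-1,1)")
        if self.error_model not in ("combined1", "constant", "proportional"):
            raise ValueError(f"unknown error model {self.error_model!r}")
        if self.a < 0 or self.b < 0:
            raise ValueError("error parameters must be nonnegative")
        if self.effective_a <= 0 and self.effective_b <= 0:
            raise ValueError("residual error cannot be identically zero")
        object.__setattr__(self, "effects", tuple(self.effects))

    # -- residual error -----------------------------------------------------

    @property
    def effective_a(self) -> float:
        return 0.0 if self.error_model == "proportional" else self.a

    @property
    def effective_b(self) -> float:
        return 0.0 if self.error_model == "constant" else self.b

    def g(self, f: np.ndarray) -> np.ndarray:
        """Residual standard deviation at prediction f."""
        return np.maximum(
            self.effective_a + self.effective_b * np.maximum(f, 0.0), _G_FLOOR
        )

    # -- structure ----------------------------------------------------------

    def structural_model(self) -> StructuralModel:
        return get_model(self.structural)

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.structural_model().param_names

    def omega_matrix(self) -> np.ndarray:
        """Full log-scale covariance matrix of the random effects."""
        names = self.param_names
        sd = np.array([self.omega.get(p, 0.0) for p in names])
        om = np.diag(sd**2)
        idx = {p: j for j, p in enumerate(names)}
        for (p1, p2), r in self.correlations.items():
            i, j = idx[p1], idx[p2]
            om[i, j] = om[j, i] = r * sd[i] * sd[j]
        return om

    def corr(self, p1: str, p2: str) -> float:
        return self.correlations.get((p1, p2), self.correlations.get((p2, p1), 0.0))

    # -- typical values ------------------------------------------------------

    def log_typical(self, cov: pd.DataFrame) -> np.ndarray:
        """(n, p) log typical values after covariate adjustment."""
        names = self.param_names
        base = np.log([self.theta[p] for p in names])[None, :]
        adj = log_adjustment(self.effects, cov, names) if len(cov) else 0.0
        return base + adj

    def individual_matrix(self, cov: pd.DataFrame, eta: np.ndarray) -> np.ndarray:
        """(n, p) individual parameter values for given random effects."""
        return np.exp(self.log_typical(cov) + eta)


def individual_parameters(
    popmodel: PopModel, subject: Mapping, eta: Mapping[str, float] | Sequence[float]
) -> dict[str, float]:
    """Individual parameters theta_i = theta_typ(covariates) * exp(eta_i)."""
    names = popmodel.param_names
    if isinstance(eta, Mapping):
        eta_vec = np.array([eta.get(p, 0.0) for p in names])
    else:
        eta_vec = np.asarray(eta, float)
        if eta_vec.shape != (len(names),):
            raise ValueError(f"eta must have {len(names)} entries")
    cov = pd.DataFrame([dict(subject)]) if subject else pd.DataFrame([{}])
    vals = popmodel.individual_matrix(cov, eta_vec[None, :])[0]
    return dict(zip(names, vals))


# ---------------------------------------------------------------------------
# settings / results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaemSettings:
    """SAEM schedule: constant-step exploration then decreasing-step
    smoothing with gamma_k = (k - n_explore)^(-step_power)."""

    n_explore: int = 500
    n_smooth: int = 200
    step_power: float = 0.7
    seed: int = 12345
    anneal: float = 0.95  # max per-iteration shrink factor for variances
    n_is: int = 5000  # importance-sampling draws for the final -2LL
    compute_loglik: bool = True
    compute_se: bool = True

    @property
    def n_iter(self) -> int:
        return self.n_explore + self.n_smooth


@dataclass
class FitResult:
    """SAEM fit: estimates, uncertainties, criteria and per-subject modes."""

    model: PopModel
    arrays: FitArrays
    settings: SaemSettings
    gamma: np.ndarray
    gamma_names: list[str]
    phi_modes: np.ndarray  # (n, p) conditional-mode log parameters (EBE)
    eta_modes: np.ndarray  # (n, p)
    trace: pd.DataFrame
    flags: dict = field(default_factory=dict)
    minus2ll: float = math.nan
    aic: float = math.nan
    bic: float = math.nan
    bicc: float = math.nan
    se_table: pd.DataFrame | None = None
    loglik_by_subject: pd.DataFrame | None = None
    converged: bool = True

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.model.param_names

    @property
    def iiv_names(self) -> tuple[str, ...]:
        return self.param_names

    @property
    def census(self) -> dict:
        """Parameter census for information criteria: subject-level
        (random-effect-bearing) vs observation-level (residual) parameters."""
        p_r = len(self.gamma) + len(self.model.omega) + len(self.model.correlations)
        p_f = {"combined1": 2, "constant": 1, "proportional": 1}[
            self.model.error_model
        ]
        return {"p_random": p_r, "p_fixed": p_f, "p_total": p_r + p_f}

    def ipred(self) -> np.ndarray:
        """(n, m) individual predictions at the conditional modes."""
        sm = self.model.structural_model()
        t = self.arrays.times - self.arrays.dose_time[:, None]
        return sm.predict_subjects(np.exp(self.phi_modes), self.arrays.dose, t)

    def iwres(self, dataset=None) -> np.ndarray:
        """Individual weighted residuals (flattened over real observations)."""
        f = self.ipred()
        g = self.model.g(f)
        res = (self.arrays.y - f) / g
        return res[self.arrays.mask]

    def estimates_frame(self) -> pd.DataFrame:
        rows = [
            {"parameter": p, "estimate": self.model.theta[p], "kind": "fixed"}
            for p in self.param_names
        ]
        rows += [
            {"parameter": f"beta_{e.label}", "estimate": e.beta, "kind": "covariate"}
            for e in self.model.effects
        ]
        rows += [
            {"parameter": f"omega_{p}", "estimate": self.model.omega[p], "kind": "iiv"}
            for p in self.model.omega
        ]
        rows += [
            {
                "parameter": f"corr_{p1}_{p2}",
                "estimate": r,
                "kind": "correlation",
            }
            for (p1, p2), r in self.model.correlations.items()
        ]
        if self.model.error_model != "proportional":
            rows.append({"parameter": "a", "estimate": self.model.a, "kind": "error"})
        if self.model.error_model != "constant":
            rows.append({"parameter": "b", "estimate": self.model.b, "kind": "error"})
        df = pd.DataFrame(rows)
        if self.se_table is not None:
            df = df.merge(
                self.se_table[["parameter", "se", "rse_percent"]],
                on="parameter",
                how="left",
            )
        return df


# ---------------------------------------------------------------------------
# internal sampler / objective
# ---------------------------------------------------------------------------

class _Problem:
    """Precomputed design and likelihood plumbing for one dataset+model."""

    def __init__(self, model: PopModel, arrays: FitArrays):
        self.sm = model.structural_model()
        self.names = list(self.sm.param_names)
        self.p = len(self.names)
        self.arrays = arrays
        self.n = arrays.n_subjects
        self.t_rel = arrays.times - arrays.dose_time[:, None]
        self.effects = list(model.effects)
        self.d = self.p + len(self.effects)
        cov = arrays.covariates.reset_index()
        X = np.zeros((self.n, self.p, self.d))
        for j in range(self.p):
            X[:, j, j] = 1.0
        idx = {p: j for j, p in enumerate(self.names)}
        for k, e in enumerate(self.effects):
            X[:, idx[e.parameter], self.p + k] = e.design_column(cov)
        self.X = X

    def gamma0(self, model: PopModel) -> np.ndarray:
        g = np.log([model.theta[p] for p in self.names])
        return np.concatenate([g, [e.beta for e in self.effects]])

    def gamma_names(self) -> list[str]:
        return [f"log_{p}" for p in self.names] + [
            f"beta_{e.label}" for e in self.effects
        ]

    def mean(self, gamma: np.ndarray) -> np.ndarray:
        return self.X @ gamma

    def predict(self, phi: np.ndarray) -> np.ndarray:
        return self.sm.predict_subjects(
            np.exp(np.clip(phi, -60.0, 60.0)), self.arrays.dose, self.t_rel
        )

    def data_loglik(self, phi: np.ndarray, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject observation log-likelihood and predictions."""
        f = self.predict(phi)
        g = np.maximum(a + b * np.maximum(f, 0.0), _G_FLOOR)
        z = (self.arrays.y - f) / g
        ll_obs = -0.5 * (_LOG2PI + z * z) - np.log(g)
        ll = np.where(self.arrays.mask, ll_obs, 0.0).sum(axis=1)
        return np.where(np.isfinite(ll), ll, -np.inf), f

    def model_from(self, base: PopModel, gamma, omega_mat, a, b) -> PopModel:
        theta = {p: float(np.exp(gamma[j])) for j, p in enumerate(self.names)}
        effects = tuple(
            replace(e, beta=float(gamma[self.p + k]))
            for k, e in enumerate(self.effects)
        )
        sd = np.sqrt(np.diag(omega_mat))
        omega = {p: float(sd[j]) for j, p in enumerate(self.names) if p in base.omega}
        corr = {}
        idx = {p: j for j, p in enumerate(self.names)}
        for (p1, p2) in base.correlations:
            i, j = idx[p1], idx[p2]
            denom = sd[i] * sd[j]
            corr[(p1, p2)] = float(omega_mat[i, j] / denom) if denom > 0 else 0.0
        return replace(
            base, theta=theta, omega=omega, correlations=corr, a=float(a), b=float(b),
            effects=effects,
        )


def _project_omega(
    S: np.ndarray, base: PopModel, names: Sequence[str]
) -> tuple[np.ndarray, dict]:
    """Project an empirical covariance onto the model's IIV structure."""
    p = len(names)
    idx = {nm: j for j, nm in enumerate(names)}
    var = np.diag(S).copy()
    flags = {}
    out = np.zeros((p, p))
    for j, nm in enumerate(names):
        if nm in base.omega:
            v = float(np.clip(var[j], _OMEGA_FLOOR**2, _OMEGA_CEIL**2))
            if var[j] < _OMEGA_FLOOR**2 or var[j] > _OMEGA_CEIL**2:
                flags[f"omega_{nm}_boundary"] = True
            out[j, j] = v
        else:
            out[j, j] = _OMEGA_FLOOR**2  # kept tiny so the kernel stays proper
    for (p1, p2) in base.correlations:
        i, j = idx[p1], idx[p2]
        denom = math.sqrt(out[i, i] * out[j, j])
        rho = float(np.clip(S[i, j] / denom, -0.95, 0.95)) if denom > 0 else 0.0
        out[i, j] = out[j, i] = rho * denom
    return out, flags


def _error_update(
    a: float, b: float, fbar: np.ndarray, r2bar: np.ndarray, mask: np.ndarray,
    error_model: str,
) -> tuple[float, float]:
    """Maximize the smoothed complete-data likelihood in (a, b)."""
    f = np.maximum(fbar[mask], 0.0)
    r2 = np.maximum(r2bar[mask], 0.0)

    free_a = error_model != "proportional"
    free_b = error_model != "constant"

    def unpack(u):
        ua = math.exp(min(u[0], 20.0)) if free_a else 0.0
        ub = math.exp(min(u[-1], 20.0)) if free_b else 0.0
        return ua, ub

    def obj(u):
        ua, ub = unpack(u)
        g = np.maximum(ua + ub * f, _G_FLOOR)
        val = np.sum(np.log(g) + r2 / (2.0 * g * g))
        core = (1.0 / g) - r2 / g**3
        grads = []
        if free_a:
            grads.append(np.sum(core) * ua)
        if free_b:
            grads.append(np.sum(core * f) * ub)
        return val, np.array(grads)

    u0 = []
    if free_a:
        u0.append(math.log(max(a, 1e-6)))
    if free_b:
        u0.append(math.log(max(b, 1e-6)))
    res = optimize.minimize(
        obj, np.array(u0), jac=True, method="L-BFGS-B", options={"maxiter": 60}
    )
    ua, ub = unpack(res.x)
    if not (np.isfinite(ua) and np.isfinite(ub)):
        return a, b
    return float(ua), float(ub)


class _Sampler:
    """Metropolis-within-Gibbs over the individual log-parameters.

    Three kernels per sweep: (1) independent proposal from the prior,
    (2) joint random walk, (3) componentwise random walk; the random-walk
    scales adapt toward fixed target acceptance rates.  All draws come from
    per-subject streams keyed by (seed, subject id), so results do not depend
    on the order of subjects in the file.
    """

    def __init__(self, prob: _Problem, seed: int):
        self.prob = prob
        self.rngs = [
            np.random.default_rng([seed & 0x7FFFFFFF, int(sid) & 0x7FFFFFFF])
            for sid in prob.arrays.ids
        ]
        self.s_joint = 0.4
        self.s_comp = np.full(prob.p, 0.4)

    def _draws(self, shape) -> np.ndarray:
        return np.stack([rng.standard_normal(shape) for rng in self.rngs])

    def _uniforms(self, k: int = 1) -> np.ndarray:
        u = np.stack([rng.random(k) for rng in self.rngs])
        return u[:, 0] if k == 1 else u

    def sweep(
        self, phi, ll, m, L, W, a, b, adapt: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        prob = self.prob
        eta = phi - m

        def lp(e):
            return -0.5 * np.einsum("np,pq,nq->n", e, W, e)

        # kernel 1: independent prior proposal (prior terms cancel)
        z = self._draws(prob.p)
        eta_new = z @ L.T
        ll_new, _ = prob.data_loglik(m + eta_new, a, b)
        acc = np.log(self._uniforms()) < (ll_new - ll)
        eta = np.where(acc[:, None], eta_new, eta)
        ll = np.where(acc, ll_new, ll)

        # kernel 2: joint random walk
        z = self._draws(prob.p)
        eta_new = eta + self.s_joint * (z @ L.T)
        ll_new, _ = prob.data_loglik(m + eta_new, a, b)
        logr = ll_new + lp(eta_new) - ll - lp(eta)
        acc = np.log(self._uniforms()) < logr
        eta = np.where(acc[:, None], eta_new, eta)
        ll = np.where(acc, ll_new, ll)
        if adapt:
            self.s_joint *= math.exp(0.4 * (acc.mean() - 0.3))
            self.s_joint = min(max(self.s_joint, 1e-3), 10.0)

        # kernel 3: componentwise random walk
        sd = np.sqrt(np.diag(L @ L.T))
        z = self._draws(prob.p)
        u = self._uniforms(prob.p)
        for c in range(prob.p):
            eta_new = eta.copy()
            eta_new[:, c] = eta[:, c] + self.s_comp[c] * sd[c] * z[:, c]
            ll_new, _ = prob.data_loglik(m + eta_new, a, b)
            logr = ll_new + lp(eta_new) - ll - lp(eta)
            acc = np.log(u[:, c]) < logr
            eta = np.where(acc[:, None], eta_new, eta)
            ll = np.where(acc, ll_new, ll)
            if adapt:
                self.s_comp[c] *= math.exp(0.4 * (acc.mean() - 0.4))
                self.s_comp[c] = min(max(self.s_comp[c], 1e-3), 10.0)

        return m + eta, ll


def _prepare_cov(omega_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cholesky factor and inverse of a (floored) IIV covariance."""
    om = omega_mat + np.eye(omega_mat.shape[0]) * (_OMEGA_FLOOR**2 * 0.01)
    L = np.linalg.cholesky(om)
    W = np.linalg.inv(om)
    return L, W


# ---------------------------------------------------------------------------
# SAEM
# ---------------------------------------------------------------------------

def fit_saem(
    dataset: PKDataset | FitArrays,
    model: PopModel,
    settings: SaemSettings | None = None,
) -> FitResult:
    """Maximum-likelihood fit of a population model by SAEM.

    Deterministic for a fixed ``settings.seed``.  Raises ``RuntimeError``
    (with the iteration trace attached) if the objective diverges.
    """
    settings = settings or SaemSettings()
    arrays = dataset.to_fit_arrays() if isinstance(dataset, PKDataset) else dataset
    prob = _Problem(model, arrays)

    gamma = prob.gamma0(model)
    omega_mat, _ = _project_omega(model.omega_matrix(), model, prob.names)
    a = model.effective_a if model.effective_a > 0 else 0.0
    b = model.effective_b if model.effective_b > 0 else 0.0
    if model.error_model != "proportional" and a == 0:
        a = 1e-3
    if model.error_model != "constant" and b == 0:
        b = 1e-3

    sampler = _Sampler(prob, settings.seed)
    m = prob.mean(gamma)
    phi = m.copy()
    ll, f = prob.data_loglik(phi, a, b)

    phi_s = phi.copy()
    outer_s = np.einsum("ni,nj->nij", phi, phi)
    f_s = f.copy()
    r2_s = (arrays.y - f) ** 2

    flags: dict = {}
    rows = []
    n_sub = prob.n

    for k in range(1, settings.n_iter + 1):
        explore = k <= settings.n_explore
        gam_k = 1.0 if explore else (k - settings.n_explore) ** (-settings.step_power)

        L, W = _prepare_cov(omega_mat)
        phi, ll = sampler.sweep(phi, ll, m, L, W, a, b)
        f = prob.predict(phi)

        # stochastic-approximation update of sufficient statistics
        phi_s += gam_k * (phi - phi_s)
        outer_s += gam_k * (np.einsum("ni,nj->nij", phi, phi) - outer_s)
        f_s += gam_k * (f - f_s)
        r2_s += gam_k * ((arrays.y - f) ** 2 - r2_s)

        # M-step: GLS for the mean coefficients
        A = np.einsum("npd,pq,nqe->de", prob.X, W, prob.X)
        rhs = np.einsum("npd,pq,nq->d", prob.X, W, phi_s)
        gamma = np.linalg.solve(A, rhs)
        m = prob.mean(gamma)

        S = (
            outer_s
            - np.einsum("ni,nj->nij", m, phi_s)
            - np.einsum("ni,nj->nij", phi_s, m)
            + np.einsum("ni,nj->nij", m, m)
        ).mean(axis=0)
        omega_new, om_flags = _project_omega(S, model, prob.names)
        if explore and settings.anneal < 1.0:
            # annealing: variances may shrink only gradually early on
            d_old, d_new = np.diag(omega_mat), np.diag(omega_new).copy()
            d_capped = np.maximum(d_new, settings.anneal * d_old)
            scale = np.sqrt(d_capped / np.maximum(d_new, 1e-300))
            omega_new = omega_new * np.outer(scale, scale)
        omega_mat = omega_new
        flags.update(om_flags)

        a_new, b_new = _error_update(
            a, b, f_s, r2_s, arrays.mask, model.error_model
        )
        if explore and settings.anneal < 1.0:
            a_new = max(a_new, settings.anneal * a)
            b_new = max(b_new, settings.anneal * b)
        damp = 1.0 if explore else gam_k
        a += damp * (a_new - a)
        b += damp * (b_new - b)

        ll_s, _ = prob.data_loglik(phi_s, a, b)
        obj = float(-2.0 * ll_s.sum())
        obj_s = obj if k == 1 else obj_s + gam_k * (obj - obj_s)
        if not np.isfinite(obj):
            trace = pd.DataFrame(rows)
            err = RuntimeError(f"SAEM diverged at iteration {k}")
            err.trace = trace  # type: ignore[attr-defined]
            raise err
        row = {"iteration": k, "phase": "explore" if explore else "smooth",
               "objective": obj, "objective_smoothed": obj_s, "a": a, "b": b}
        for j, nm in enumerate(prob.names):
            row[nm] = float(np.exp(gamma[j]))
            row[f"omega_{nm}"] = float(math.sqrt(omega_mat[j, j]))
        for kk, e in enumerate(prob.effects):
            row[f"beta_{e.label}"] = float(gamma[prob.p + kk])
        idx = {p: j for j, p in enumerate(prob.names)}
        for (p1, p2) in model.correlations:
            i, j = idx[p1], idx[p2]
            den = math.sqrt(omega_mat[i, i] * omega_mat[j, j])
            row[f"corr_{p1}_{p2}"] = float(omega_mat[i, j] / den) if den else 0.0
        rows.append(row)

    # Degenerate-IIV polish: when every random-effect SD has collapsed, the
    # latent draws are pinned at the population mean and SAEM can no longer
    # move the fixed effects; the model is then plain nonlinear regression
    # and the means are finished off by direct likelihood maximization.
    if np.sqrt(np.diag(omega_mat)).max() < 0.02:
        for _ in range(2):
            def negll(gam):
                ll_g, _ = prob.data_loglik(prob.mean(gam), a, b)
                val = -float(ll_g.sum())
                return val if np.isfinite(val) else 1e300

            res = optimize.minimize(
                negll, gamma, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 8000},
            )
            res2 = optimize.minimize(
                negll, res.x, method="Powell",
                options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 4000},
            )
            gamma = res2.x if res2.fun <= res.fun else res.x
            m = prob.mean(gamma)
            f = prob.predict(m)
            a, b = _error_update(
                a, b, f, (arrays.y - f) ** 2, arrays.mask, model.error_model
            )
        flags["iiv_collapsed"] = True

    fitted = prob.model_from(model, gamma, omega_mat, a, b)
    trace = pd.DataFrame(rows)

    phi_modes, eta_modes = _conditional_modes(fitted, prob, start=phi)
    result = FitResult(
        model=fitted,
        arrays=arrays,
        settings=settings,
        gamma=gamma,
        gamma_names=prob.gamma_names(),
        phi_modes=phi_modes,
        eta_modes=eta_modes,
        trace=trace,
        flags=flags,
    )
    if settings.compute_loglik:
        m2ll, per_subject, ll_flags = loglik_importance(
            result, n_is=settings.n_is, seed=settings.seed + 1
        )
        result.minus2ll = m2ll
        result.loglik_by_subject = per_subject
        result.flags.update(ll_flags)
        from .diagnostics import information_criteria

        census = result.census
        crit = information_criteria(
            m2ll, census, n_sub, int(arrays.mask.sum())
        )
        result.aic, result.bic, result.bicc = crit
    if settings.compute_se:
        try:
            result.se_table = standard_errors(result)
        except np.linalg.LinAlgError:
            result.se_table = None
            result.flags["se_failed"] = True
    return result


def evaluate_model(
    dataset: PKDataset | FitArrays,
    model: PopModel,
    compute_loglik: bool = True,
    n_is: int = 5000,
    seed: int = 0,
) -> FitResult:
    """Evaluate a fixed population model on a dataset without re-estimating.

    Computes conditional modes (EBEs) and, optionally, the marginal -2LL and
    information criteria — the external-validation path: apply an existing
    model to a new dataset and inspect its diagnostics.
    """
    arrays = dataset.to_fit_arrays() if isinstance(dataset, PKDataset) else dataset
    prob = _Problem(model, arrays)
    phi_modes, eta_modes = _conditional_modes(model, prob)
    result = FitResult(
        model=model,
        arrays=arrays,
        settings=SaemSettings(seed=seed, compute_loglik=compute_loglik),
        gamma=prob.gamma0(model),
        gamma_names=prob.gamma_names(),
        phi_modes=phi_modes,
        eta_modes=eta_modes,
        trace=pd.DataFrame(),
    )
    if compute_loglik:
        m2ll, per_subject, ll_flags = loglik_importance(
            result, n_is=n_is, seed=seed + 1
        )
        result.minus2ll = m2ll
        result.loglik_by_subject = per_subject
        result.flags.update(ll_flags)
        from .diagnostics import information_criteria

        result.aic, result.bic, result.bicc = information_criteria(
            m2ll, result.census, prob.n, int(arrays.mask.sum())
        )
    return result


# ---------------------------------------------------------------------------
# conditional distributions
# ---------------------------------------------------------------------------

def _conditional_modes(
    model: PopModel, prob: _Problem, start: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical Bayes modes by numeric optimization per subject."""
    omega_mat, _ = _project_omega(model.omega_matrix(), model, prob.names)
    L, W = _prepare_cov(omega_mat)
    gamma = prob.gamma0(model)
    m = prob.mean(gamma)
    a, b = model.effective_a, model.effective_b
    n, p = prob.n, prob.p
    phi_modes = np.empty((n, p))
    start = m if start is None else start

    sm = prob.sm
    for i in range(n):
        ti = prob.t_rel[i : i + 1]
        yi = prob.arrays.y[i]
        mi = prob.arrays.mask[i]
        dosei = prob.arrays.dose[i : i + 1]

        def neg(eta_i):
            phi_i = m[i] + eta_i
            f = sm.predict_subjects(
                np.exp(np.clip(phi_i[None, :], -60, 60)), dosei, ti
            )[0]
            g = np.maximum(a + b * np.maximum(f, 0.0), _G_FLOOR)
            z = (yi - f) / g
            ll = np.sum((-0.5 * (_LOG2PI + z * z) - np.log(g))[mi])
            lp = -0.5 * eta_i @ W @ eta_i
            val = -(ll + lp)
            return val if np.isfinite(val) else 1e300

        # multi-start: the conditional density can be bimodal (flip-flop),
        # so optimize from both the chain state and the prior mean
        x0 = start[i] - m[i]
        starts = [x0] if np.allclose(x0, 0.0) else [x0, np.zeros_like(x0)]
        best = None
        for s0 in starts:
            res = optimize.minimize(
                neg, s0, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
            )
            res2 = optimize.minimize(neg, res.x, method="Powell",
                                     options={"xtol": 1e-9, "maxiter": 2000})
            cand = res2 if res2.fun < res.fun else res
            if best is None or cand.fun < best.fun:
                best = cand
        phi_modes[i] = m[i] + best.x
    return phi_modes, phi_modes - m


def conditional_mcmc(
    popmodel: PopModel,
    dataset: PKDataset | FitArrays,
    subject_id: int,
    n_samples: int = 200,
    seed: int = 0,
    burn: int = 200,
    thin: int = 5,
) -> dict:
    """Samples from p(eta | y_i, popmodel) for one subject, plus the mode.

    Returns a dict with ``eta_samples`` (n_samples, p), ``eta_mode`` (p,),
    ``phi_mode`` and the parameter names.
    """
    arrays = dataset.to_fit_arrays() if isinstance(dataset, PKDataset) else dataset
    pos = np.nonzero(arrays.ids == subject_id)[0]
    if len(pos) == 0:
        raise ValueError(f"subject {subject_id} not in dataset")
    i = int(pos[0])
    sub = FitArrays(
        ids=arrays.ids[i : i + 1],
        times=arrays.times[i : i + 1],
        y=arrays.y[i : i + 1],
        mask=arrays.mask[i : i + 1],
        dose=arrays.dose[i : i + 1],
        dose_time=arrays.dose_time[i : i + 1],
        covariates=arrays.covariates.iloc[i : i + 1],
    )
    if not sub.mask.any():
        raise ValueError(f"subject {subject_id} has no observations")
    prob = _Problem(popmodel, sub)
    omega_mat, _ = _project_omega(popmodel.omega_matrix(), popmodel, prob.names)
    L, W = _prepare_cov(omega_mat)
    m = prob.mean(prob.gamma0(popmodel))
    a, b = popmodel.effective_a, popmodel.effective_b
    sampler = _Sampler(prob, seed)
    phi = m.copy()
    ll, _ = prob.data_loglik(phi, a, b)
    if not np.isfinite(ll[0]):
        raise RuntimeError(f"non-finite likelihood for subject {subject_id}")
    draws = []
    for k in range(burn + n_samples * thin):
        phi, ll = sampler.sweep(phi, ll, m, L, W, a, b)
        if k >= burn and (k - burn) % thin == 0:
            draws.append(phi[0] - m[0])
    eta_samples = np.array(draws)[:n_samples]
    phi_modes, eta_modes = _conditional_modes(popmodel, prob, start=phi)
    return {
        "eta_samples": eta_samples,
        "eta_mode": eta_modes[0],
        "phi_mode": phi_modes[0],
        "param_names": prob.names,
    }


def conditional_eta_samples(
    fit: FitResult, n_samples: int = 10, burn: int = 100, thin: int = 10,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Conditional-distribution draws for every subject of a fit.

    Returns {parameter: (n_subjects, n_samples)} aligned with the sorted
    subject ids, for covariate screening.
    """
    model = fit.model
    prob = _Problem(model, fit.arrays)
    omega_mat, _ = _project_omega(model.omega_matrix(), model, prob.names)
    L, W = _prepare_cov(omega_mat)
    m = prob.mean(prob.gamma0(model))
    a, b = model.effective_a, model.effective_b
    sampler = _Sampler(prob, fit.settings.seed + 7 if seed is None else seed)
    phi = fit.phi_modes.copy()
    ll, _ = prob.data_loglik(phi, a, b)
    draws = []
    for k in range(burn + n_samples * thin):
        phi, ll = sampler.sweep(phi, ll, m, L, W, a, b)
        if k >= burn and (k - burn) % thin == 0:
            draws.append(phi - m)
    cube = np.stack(draws[:n_samples], axis=2)  # (n, p, L)
    return {p: cube[:, j, :] for j, p in enumerate(prob.names)}


# ---------------------------------------------------------------------------
# marginal likelihood by importance sampling
# ---------------------------------------------------------------------------

def loglik_importance(
    fit: FitResult | None = None,
    dataset: PKDataset | FitArrays | None = None,
    model: PopModel | None = None,
    phi_modes: np.ndarray | None = None,
    n_is: int = 5000,
    seed: int = 0,
    df: float = 5.0,
    ess_threshold: float = 50.0,
) -> tuple[float, pd.DataFrame, dict]:
    """-2 log marginal likelihood by importance sampling.

    The proposal is a multivariate t (df=5) centered at each subject's
    conditional mode with scale from the local curvature.  Parameters with
    IIV variance at the floor are integrated numerically like any other; a
    model with no IIV at all collapses to the closed-form residual
    likelihood.

    Returns ``(minus2ll, per_subject_table, flags)``; subjects whose
    effective sample size falls below ``ess_threshold`` are flagged.
    """
    if fit is not None:
        arrays, model, phi_modes = fit.arrays, fit.model, fit.phi_modes
    else:
        assert dataset is not None and model is not None
        arrays = dataset.to_fit_arrays() if isinstance(dataset, PKDataset) else dataset
    prob = _Problem(model, arrays)
    if phi_modes is None:
        phi_modes, _ = _conditional_modes(model, prob)

    names = prob.names
    m = prob.mean(prob.gamma0(model))
    a, b = model.effective_a, model.effective_b
    omega_full = model.omega_matrix()
    active = np.array([model.omega.get(p, 0.0) > 0 for p in names])
    rows = []
    flags: dict = {}

    if not active.any():
        ll, _ = prob.data_loglik(m, a, b)
        per = pd.DataFrame({"ID": arrays.ids, "loglik": ll, "ess": np.inf})
        return float(-2.0 * ll.sum()), per, flags

    pa = int(active.sum())
    om_act = omega_full[np.ix_(active, active)]
    om_act = om_act + np.eye(pa) * 1e-12
    W_act = np.linalg.inv(om_act)
    _, logdet_om = np.linalg.slogdet(om_act)

    for i in range(prob.n):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, int(arrays.ids[i]) & 0x7FFFFFFF])
        eta_hat = (phi_modes[i] - m[i])[active]
        H = _numeric_hessian(
            lambda e: _subject_neg_logdensity(prob, model, i, m, e, active, W_act),
            eta_hat,
        )
        H = 0.5 * (H + H.T)
        w_eig, V = np.linalg.eigh(H)
        w_eig = np.clip(w_eig, 1e-6, None)
        Sigma = (V / w_eig) @ V.T
        Ls = np.linalg.cholesky(Sigma + np.eye(pa) * 1e-12)

        z = rng.standard_normal((n_is, pa))
        chi = rng.chisquare(df, n_is) / df
        eta = eta_hat[None, :] + (z @ Ls.T) / np.sqrt(chi)[:, None]

        phi = np.repeat(m[i][None, :], n_is, axis=0)
        phi[:, active] = m[i][active][None, :] + eta
        f = prob.sm.predict_subjects(
            np.exp(np.clip(phi, -60, 60)), np.full(n_is, arrays.dose[i]),
            np.repeat(prob.t_rel[i][None, :], n_is, axis=0),
        )
        g = np.maximum(a + b * np.maximum(f, 0.0), _G_FLOOR)
        zres = (arrays.y[i][None, :] - f) / g
        ll_obs = -0.5 * (_LOG2PI + zres**2) - np.log(g)
        ll_data = np.where(arrays.mask[i][None, :], ll_obs, 0.0).sum(axis=1)

        lp = -0.5 * (
            np.einsum("si,ij,sj->s", eta, W_act, eta)
            + logdet_om + pa * _LOG2PI
        )
        delta = eta - eta_hat[None, :]
        sol = np.linalg.solve(Ls, delta.T).T
        quad = np.sum(sol**2, axis=1)
        _, logdet_sig = np.linalg.slogdet(Sigma)
        logq = (
            math.lgamma((df + pa) / 2) - math.lgamma(df / 2)
            - 0.5 * pa * math.log(df * math.pi) - 0.5 * logdet_sig
            - 0.5 * (df + pa) * np.log1p(quad / df)
        )
        logw = ll_data + lp - logq
        logw = np.where(np.isfinite(logw), logw, -np.inf)
        mx = np.max(logw)
        if not np.isfinite(mx):
            rows.append((arrays.ids[i], -np.inf, 0.0))
            flags[f"subject_{arrays.ids[i]}_loglik"] = "non-finite"
            continue
        wnorm = np.exp(logw - mx)
        ll_i = mx + math.log(wnorm.mean())
        ess = wnorm.sum() ** 2 / np.sum(wnorm**2)
        if ess < ess_threshold:
            flags[f"subject_{arrays.ids[i]}_ess"] = float(ess)
        rows.append((arrays.ids[i], ll_i, ess))

    per = pd.DataFrame(rows, columns=["ID", "loglik", "ess"])
    return float(-2.0 * per["loglik"].sum()), per, flags


def _subject_neg_logdensity(prob, model, i, m, eta_act, active, W_act) -> float:
    phi = m[i].copy()
    phi[active] = m[i][active] + eta_act
    f = prob.sm.predict_subjects(
        np.exp(np.clip(phi[None, :], -60, 60)),
        prob.arrays.dose[i : i + 1],
        prob.t_rel[i : i + 1],
    )[0]
    a, b = model.effective_a, model.effective_b
    g = np.maximum(a + b * np.maximum(f, 0.0), _G_FLOOR)
    z = (prob.arrays.y[i] - f) / g
    ll = np.sum((-0.5 * (_LOG2PI + z * z) - np.log(g))[prob.arrays.mask[i]])
    lp = -0.5 * eta_act @ W_act @ eta_act
    val = -(ll + lp)
    return val if np.isfinite(val) else 1e300


def _numeric_hessian(fun, x0: np.ndarray, h: float = 1e-3) -> np.ndarray:
    d = len(x0)
    H = np.empty((d, d))
    f0 = fun(x0)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            if i == j:
                H[i, i] = (fun(x0 + ei) - 2 * f0 + fun(x0 - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    fun(x0 + ei + ej) - fun(x0 + ei - ej)
                    - fun(x0 - ei + ej) + fun(x0 - ei - ej)
                ) / (4 * h**2)
    return H


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------

def standard_errors(
    fit: FitResult, method: str = "linearization"
) -> pd.DataFrame:
    """SE/RSE table from the Fisher information.

    ``linearization`` (default) linearizes the structural model around the
    conditional modes (FOCE-style Gaussian marginal) and differentiates that
    likelihood; ``score`` approximates the information by the empirical
    covariance of per-subject importance-sampled score vectors.  Parameters
    whose information is not invertible are flagged with NaN rather than
    failing the whole table.
    """
    if method not in ("linearization", "score"):
        raise ValueError(f"unknown SE method {method!r}")
    model = fit.model
    prob = _Problem(model, fit.arrays)
    names = prob.names

    # pack estimates on unconstrained scales
    entries: list[tuple[str, float, float]] = []  # (report name, u, natural)
    for j, p in enumerate(names):
        entries.append((p, math.log(model.theta[p]), model.theta[p]))
    for e in model.effects:
        entries.append((f"beta_{e.label}", e.beta, e.beta))
    omega_names = [p for p in names if p in model.omega]
    for p in omega_names:
        w = max(model.omega[p], _OMEGA_FLOOR)
        entries.append((f"omega_{p}", math.log(w), w))
    corr_pairs = list(model.correlations)
    for (p1, p2) in corr_pairs:
        r = float(np.clip(model.correlations[(p1, p2)], -0.999, 0.999))
        entries.append((f"corr_{p1}_{p2}", math.atanh(r), r))
    if model.error_model != "proportional":
        entries.append(("a", math.log(max(model.a, 1e-10)), model.a))
    if model.error_model != "constant":
        entries.append(("b", math.log(max(model.b, 1e-10)), model.b))
    u0 = np.array([u for _, u, _ in entries])
    report = [nm for nm, _, _ in entries]
    natural = np.array([v for _, _, v in entries])

    def unpack(u):
        k = 0
        gamma = np.empty(prob.d)
        for j in range(len(names)):
            gamma[j] = u[k]; k += 1
        for j in range(len(model.effects)):
            gamma[len(names) + j] = u[k]; k += 1
        sd = {p: 0.0 for p in names}
        for p in omega_names:
            sd[p] = math.exp(u[k]); k += 1
        om = np.diag([sd[p] ** 2 for p in names])
        idx = {p: j for j, p in enumerate(names)}
        for (p1, p2) in corr_pairs:
            r = math.tanh(u[k]); k += 1
            i1, i2 = idx[p1], idx[p2]
            om[i1, i2] = om[i2, i1] = r * sd[p1] * sd[p2]
        ea = eb = 0.0
        if model.error_model != "proportional":
            ea = math.exp(u[k]); k += 1
        if model.error_model != "constant":
            eb = math.exp(u[k]); k += 1
        return gamma, om, ea, eb

    if method == "linearization":
        fhat = prob.predict(fit.phi_modes)
        J = _prediction_jacobian(prob, fit.phi_modes)

        def negll(u):
            gamma, om, ea, eb = unpack(u)
            m = prob.mean(gamma)
            total = 0.0
            for i in range(prob.n):
                msk = fit.arrays.mask[i]
                Ji = J[i][msk]
                mu = fhat[i][msk] + Ji @ (m[i] - fit.phi_modes[i])
                g = np.maximum(ea + eb * np.maximum(fhat[i][msk], 0.0), _G_FLOOR)
                V = Ji @ om @ Ji.T + np.diag(g * g)
                r = fit.arrays.y[i][msk] - mu
                sign, logdet = np.linalg.slogdet(V)
                if sign <= 0:
                    return 1e300
                sol = np.linalg.solve(V, r)
                total += 0.5 * (len(r) * _LOG2PI + logdet + r @ sol)
            return total

        H = _numeric_hessian(negll, u0, h=1e-4)
        info = H
    else:  # score
        d = len(u0)
        h = 1e-4
        scores = np.zeros((prob.n, d))
        for j in range(d):
            up = u0.copy(); up[j] += h
            um = u0.copy(); um[j] -= h
            llp = _per_subject_loglik(prob, model, unpack(up), fit.phi_modes, fit.settings.seed + 3)
            llm = _per_subject_loglik(prob, model, unpack(um), fit.phi_modes, fit.settings.seed + 3)
            scores[:, j] = (llp - llm) / (2 * h)
        info = scores.T @ scores

    flags = np.zeros(len(u0), bool)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        flags[:] = True
    var_u = np.diag(cov).copy()
    bad = ~np.isfinite(var_u) | (var_u <= 0)
    flags |= bad
    se_u = np.sqrt(np.where(bad, np.nan, var_u))

    # delta method back to the reporting scale
    se_nat = np.empty_like(se_u)
    k = 0
    for j, p in enumerate(names):
        se_nat[k] = natural[k] * se_u[k]; k += 1
    for e in model.effects:
        se_nat[k] = se_u[k]; k += 1
    for p in omega_names:
        se_nat[k] = natural[k] * se_u[k]; k += 1
    for _ in corr_pairs:
        se_nat[k] = (1 - natural[k] ** 2) * se_u[k]; k += 1
    while k < len(se_u):
        se_nat[k] = natural[k] * se_u[k]; k += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        rse = 100.0 * se_nat / np.abs(natural)
    return pd.DataFrame(
        {
            "parameter": report,
            "estimate": natural,
            "se": se_nat,
            "rse_percent": rse,
            "undefined": flags,
        }
    )


def _prediction_jacobian(prob: _Problem, phi: np.ndarray, h: float = 1e-5):
    """d f / d phi at the conditional modes, by central differences."""
    n, p = phi.shape
    mcount = prob.t_rel.shape[1]
    J = np.zeros((n, mcount, p))
    for j in range(p):
        up = phi.copy(); up[:, j] += h
        dn = phi.copy(); dn[:, j] -= h
        J[:, :, j] = (prob.predict(up) - prob.predict(dn)) / (2 * h)
    return J


def _per_subject_loglik(prob, base_model, packed, phi_modes, seed) -> np.ndarray:
    gamma, om, ea, eb = packed
    model = prob.model_from(base_model, gamma, om, ea, eb)
    _, per, _ = loglik_importance(
        dataset=prob.arrays, model=model, phi_modes=phi_modes,
        n_is=1000, seed=seed,
    )
    return per["loglik"].to_numpy()


# ---------------------------------------------------------------------------
# simulation from a population model (shared by VPC / NPDE / cohort module)
# ---------------------------------------------------------------------------

def simulate_observations(
    model: PopModel,
    arrays: FitArrays,
    n_replicates: int,
    seed: int,
    truncate: bool = True,
) -> np.ndarray:
    """Simulate replicate observation matrices under a population model.

    Returns (n_replicates, n_subjects, n_times); negative draws are truncated
    at zero when ``truncate`` (plasma concentrations are physical).  Each
    (replicate, subject) pair has its own random stream.
    """
    prob = _Problem(model, arrays)
    omega_full = model.omega_matrix()
    # eigen square root: exact-zero variances give exactly zero random effects
    w_eig, V = np.linalg.eigh(omega_full)
    L = V * np.sqrt(np.maximum(w_eig, 0.0))
    m = prob.mean(prob.gamma0(model))
    a, b = model.effective_a, model.effective_b
    out = np.empty((n_replicates, prob.n, prob.t_rel.shape[1]))
    for r in range(n_replicates):
        eta = np.empty((prob.n, prob.p))
        eps = np.empty_like(out[r])
        for i, sid in enumerate(arrays.ids):
            rng = np.random.default_rng(
                [seed & 0x7FFFFFFF, r, int(sid) & 0x7FFFFFFF]
            )
            eta[i] = L @ rng.standard_normal(prob.p)
            eps[i] = rng.standard_normal(out.shape[2])
        f = prob.predict(m + eta)
        # combined-1: residual SD affine in the prediction, single noise term
        y = f + (a + b * np.maximum(f, 0.0)) * eps
        out[r] = np.maximum(y, 0.0) if truncate else y
    return out
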