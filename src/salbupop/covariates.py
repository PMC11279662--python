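"""Covariate effect parameterization, screening and stepwise selection.

Continuous covariates act as power terms on the ratio to a reference value,
``theta * (cov/ref)**beta`` (log-linear); categorical covariates act as
multiplicative shifts ``theta * exp(beta)`` for non-reference levels.  The
reference level always carries beta = 0.

Screening correlates per-subject random-effect samples drawn from the
conditional distribution with each candidate covariate (Pearson test for
continuous, one-way ANOVA for categorical) and orders candidate pairs by
p-value; the forward-backward stepwise loop then adds/removes effects subject
to a p-value threshold and a corrected-BIC improvement check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CovariateEffect",
    "typical_value",
    "log_adjustment",
    "screen",
    "stepwise_select",
    "confirm_tests",
    "SelectionTrace",
]

#: covariate column -> kind; BMI is excluded from the default candidate set
#: because it is a deterministic function of weight and height.
CONTINUOUS_COVARIATES = ("AGE", "HT", "WT")
CATEGORICAL_COVARIATES = ("SEX", "RACE")
CATEGORICAL_REFERENCE = {"SEX": "M", "RACE": "AmericanIndianAlaskanNative"}


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate effect on one structural parameter.

    For ``kind='power'`` the reference is the (positive) continuous reference
    value and ``level`` is unused.  For ``kind='categorical'`` the effect
    applies ``exp(beta)`` to subjects whose covariate equals ``level``;
    ``reference`` names the reference level (which carries beta = 0).
    """

    parameter: str
    covariate: str
    kind: str  # "power" | "categorical"
    beta: float = 0.0
    reference: float | str = 1.0
    level: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("power", "categorical"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == "power" and not (float(self.reference) > 0):
            raise ValueError("continuous reference value must be > 0")
        if self.kind == "categorical" and self.level is None:
            raise ValueError("categorical effect requires a level")

    @property
    def label(self) -> str:
        lev = f"[{self.level}]" if self.level else ""
        return f"{self.covariate}{lev}->{self.parameter}"

    def design_column(self, cov: pd.DataFrame) -> np.ndarray:
        """Per-subject regressor on the log-parameter scale."""
        x = cov[self.covariate]
        if self.kind == "power":
            vals = x.to_numpy(float)
            if np.any(vals <= 0):
                raise ValueError(
                    f"nonpositive values of continuous covariate {self.covariate}"
                )
            return np.log(vals / float(self.reference))
        return (x.astype(str) == str(self.level)).to_numpy(float)


def log_adjustment(
    effects: Sequence[CovariateEffect], cov: pd.DataFrame, param_names: Sequence[str]
) -> np.ndarray:
    """Additive log-scale adjustment matrix (n_subjects, n_params)."""
    out = np.zeros((len(cov), len(param_names)))
    idx = {p: j for j, p in enumerate(param_names)}
    for e in effects:
        if e.parameter not in idx:
            raise ValueError(f"effect on unknown parameter {e.parameter!r}")
        out[:, idx[e.parameter]] += e.beta * e.design_column(cov)
    return out


def typical_value(
    theta_pop: float, effects: Sequence[CovariateEffect], subject: Mapping
) -> float:
    """Covariate-adjusted typical value for one subject."""
    cov = pd.DataFrame([dict(subject)])
    mult = log_adjustment(effects, cov, [effects[0].parameter] if effects else ["_"])
    return float(theta_pop * np.exp(mult[0, 0])) if effects else float(theta_pop)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def _pair_pvalue(samples: np.ndarray, x: pd.Series, kind: str) -> float:
    """Median p over conditional-sample columns for one (eta, covariate) pair."""
    ps = []
    for col in range(samples.shape[1]):
        eta = samples[:, col]
        if kind == "power":
            r = stats.pearsonr(x.to_numpy(float), eta)
            ps.append(r.pvalue)
        else:
            groups = [eta[(x.astype(str) == lev).to_numpy()] for lev in x.unique()]
            groups = [g for g in groups if len(g) >= 2]
            if len(groups) < 2:
                return np.nan
            ps.append(stats.f_oneway(*groups).pvalue)
    return float(np.median(ps))


def screen(
    eta_samples: Mapping[str, np.ndarray],
    cov: pd.DataFrame,
    continuous: Sequence[str] = CONTINUOUS_COVARIATES,
    categorical: Sequence[str] = CATEGORICAL_COVARIATES,
) -> pd.DataFrame:
    """Random effect vs covariate screening table, sorted ascending by p.

    ``eta_samples`` maps parameter name to an (n_subjects, L) array of
    conditional-distribution draws aligned with the rows of ``cov``.
    Constant covariates yield NaN p with an ``excluded`` flag.
    """
    rows = []
    for param, samples in eta_samples.items():
        samples = np.atleast_2d(np.asarray(samples, float))
        if samples.shape[0] != len(cov):
            samples = samples.T
        for name in continuous:
            if name not in cov.columns:
                continue
            const = cov[name].nunique() < 2
            p = np.nan if const else _pair_pvalue(samples, cov[name], "power")
            rows.append((param, name, "pearson", p, const))
        for name in categorical:
            if name not in cov.columns:
                continue
            const = cov[name].nunique() < 2
            p = np.nan if const else _pair_pvalue(samples, cov[name], "categorical")
            rows.append((param, name, "anova", p, const))
    out = pd.DataFrame(rows, columns=["parameter", "covariate", "test", "p", "excluded"])
    return out.sort_values("p", na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# stepwise forward-backward selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionTrace:
    """Ordered log of add/remove attempts during stepwise selection."""

    steps: list[dict] = field(default_factory=list)

    def log(self, **kw) -> None:
        self.steps.append(kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def __len__(self) -> int:
        return len(self.steps)


def _candidate_effect(
    parameter: str, covariate: str, cov: pd.DataFrame
) -> list[CovariateEffect]:
    """Materialize candidate effect(s) for a (parameter, covariate) pair."""
    if covariate in CONTINUOUS_COVARIATES:
        ref = float(np.median(cov[covariate].to_numpy(float)))
        return [CovariateEffect(parameter, covariate, "power", 0.0, ref)]
    ref = CATEGORICAL_REFERENCE.get(covariate, str(cov[covariate].iloc[0]))
    levels = sorted(set(cov[covariate].astype(str)) - {ref})
    return [
        CovariateEffect(parameter, covariate, "categorical", 0.0, ref, level=lev)
        for lev in levels
    ]


def stepwise_select(
    dataset,
    base_model,
    candidates: Sequence[tuple[str, str]],
    alpha_add: float = 0.05,
    alpha_remove: float = 0.05,
    settings=None,
    n_screen_samples: int = 10,
    max_cycles: int = 6,
):
    """Forward-backward covariate selection on a fitted base model.

    ``candidates`` are (parameter, covariate-column) pairs.  Forward steps add
    the smallest-p screened candidate whose refit strictly lowers BICc;
    backward steps drop the retained effect with the largest Wald p above
    ``alpha_remove``.  Iterates to a fixed point (bounded by ``max_cycles``).

    Returns ``(final_fit, trace)``.
    """
    from . import nlme  # deferred: nlme imports this module for effect types

    if settings is None:
        settings = nlme.SaemSettings()
    cov = dataset.covariates()
    trace = SelectionTrace()

    current_model = base_model
    fit = nlme.fit_saem(dataset, current_model, settings)
    if not candidates:
        return fit, trace

    tried_add: set[tuple[str, str]] = set()
    for _cycle in range(max_cycles):
        changed = False
        # ---- forward ----
        while True:
            eta = nlme.conditional_eta_samples(fit, n_samples=n_screen_samples)
            included = {(e.parameter, e.covariate) for e in fit.model.effects}
            table = screen(eta, cov)
            table = table[~table["excluded"]]
            open_pairs = [
                (r.parameter, r.covariate, r.p)
                for r in table.itertuples()
                if (r.parameter, r.covariate) in set(candidates)
                and (r.parameter, r.covariate) not in included
                and (r.parameter, r.covariate) not in tried_add
                and r.p < alpha_add
            ]
            if not open_pairs:
                break
            param, covname, p = open_pairs[0]
            tried_add.add((param, covname))
            new_effects = list(fit.model.effects) + _candidate_effect(param, covname, cov)
            cand_model = replace(fit.model, effects=new_effects)
            cand_fit = nlme.fit_saem(dataset, cand_model, settings)
            accept = cand_fit.bicc < fit.bicc
            trace.log(
                action="add", parameter=param, covariate=covname, p=p,
                bicc_before=fit.bicc, bicc_after=cand_fit.bicc, accepted=accept,
            )
            if accept:
                fit = cand_fit
                changed = True
        # ---- backward ----
        tried_remove: set[str] = set()
        while fit.model.effects:
            wald = confirm_tests(fit, dataset)["wald"]
            removable = wald[
                (wald["p"] > alpha_remove) & ~wald["effect"].isin(tried_remove)
            ].sort_values("p", ascending=False)
            if removable.empty:
                break
            label = removable.iloc[0]["effect"]
            tried_remove.add(label)
            kept = [e for e in fit.model.effects if e.label != label]
            cand_model = replace(fit.model, effects=kept)
            cand_fit = nlme.fit_saem(dataset, cand_model, settings)
            trace.log(
                action="remove", effect=label, p=float(removable.iloc[0]["p"]),
                bicc_before=fit.bicc, bicc_after=cand_fit.bicc, accepted=True,
            )
            fit = cand_fit
            changed = True
        if not changed:
            break
    return fit, trace


# ---------------------------------------------------------------------------
# confirmatory tests
# ---------------------------------------------------------------------------

def confirm_tests(fit, dataset) -> dict[str, pd.DataFrame]:
    """Wald tests on covariate coefficients, Shapiro-Wilk normality of the
    random effects, and a signed-rank symmetry test of the residuals.

    Wald p = 2*Phi(-|beta/SE|); effects whose SE is unavailable are flagged
    and skipped.
    """
    wald_rows = []
    se_map = {}
    if fit.se_table is not None:
        se_map = {
            r.parameter: r.se for r in fit.se_table.itertuples() if np.isfinite(r.se)
        }
    for e in fit.model.effects:
        key = f"beta_{e.label}"
        se = se_map.get(key, np.nan)
        if np.isfinite(se) and se > 0:
            z = e.beta / se
            p = 2.0 * stats.norm.sf(abs(z))
            wald_rows.append((e.label, e.beta, se, z, p, False))
        else:
            wald_rows.append((e.label, e.beta, np.nan, np.nan, np.nan, True))
    wald = pd.DataFrame(
        wald_rows, columns=["effect", "beta", "se", "z", "p", "se_missing"]
    )

    sw_rows = []
    for j, name in enumerate(fit.iiv_names):
        eta = fit.eta_modes[:, j]
        if len(eta) >= 3 and np.ptp(eta) > 0:
            w, p = stats.shapiro(eta)
        else:
            w, p = np.nan, np.nan
        sw_rows.append((name, w, p))
    shapiro = pd.DataFrame(sw_rows, columns=["parameter", "W", "p"])

    res = fit.iwres(dataset)
    res = res[np.isfinite(res)]
    if len(res) >= 10 and np.any(res != 0):
        try:
            stat, p = stats.wilcoxon(res)
        except ValueError:
            stat, p = np.nan, np.nan
    else:
        stat, p = np.nan, np.nan
    symmetry = pd.DataFrame({"statistic": [stat], "p": [p]})

    return {"wald": wald, "shapiro": shapiro, "symmetry": symmetry}
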