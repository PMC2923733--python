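"""Statistical inference layer.

Implements the model-comparison machinery (BIC, log-Bayes factors), the
condition-prediction regression used to rank response measures, the paired
CS main-effect test, and trial-by-trial Rescorla-Wagner learning fits.

The BIC follows the per-sample convention BIC = log(sigma_e^2) +
(k/n) log(n), so that for two fits with equal k and n the log-Bayes
factor reduces to the log ratio of error variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize

from .design import COND_CS_MINUS, COND_CS_PLUS_NOUS, COND_CS_PLUS_US
from .model_core import ParameterError, ValidationError

__all__ = [
    "bic",
    "log_bayes_factor",
    "evidence_ratio",
    "MeasureTable",
    "ModelComparison",
    "condition_prediction_glm",
    "cs_main_effect",
    "CsEffect",
    "rw_update",
    "rw_trace",
    "LearningTrace",
    "fit_rw",
    "RWFit",
    "ph_update",
    "compare_measures",
]

CONDITIONS = (COND_CS_MINUS, COND_CS_PLUS_NOUS, COND_CS_PLUS_US)


# ---------------------------------------------------------------------------
# evidence


def bic(sigma_e2: float, k: int, n: int) -> float:
    """Per-sample Bayesian information criterion: log(s2) + (k/n) log(n)."""
    if sigma_e2 <= 0:
        raise ParameterError(f"error variance must be positive, got {sigma_e2}")
    if n <= 0:
        raise ParameterError(f"n must be positive, got {n}")
    if k < 0:
        raise ParameterError(f"k must be non-negative, got {k}")
    return float(np.log(sigma_e2) + (k / n) * np.log(n))


def log_bayes_factor(fit1, fit2) -> float:
    """BIC difference of two fits; lower BIC (model 2) wins positive sign.

    With equal k and n this reduces to log(sigma1^2) - log(sigma2^2).
    ``fit1``/``fit2`` need attributes sigma_e2, k, n (e.g. GLMFit).
    """
    return bic(fit1.sigma_e2, fit1.k, fit1.n) - bic(fit2.sigma_e2, fit2.k, fit2.n)


def evidence_ratio(log_bf: float) -> float:
    """Evidence ratio implied by a log-Bayes factor: exp(log BF)."""
    return float(np.exp(log_bf))


# ---------------------------------------------------------------------------
# measure table and condition prediction


@dataclass
class MeasureTable:
    """Long-format trial estimates: one row per (subject, trial, method)."""

    frame: pd.DataFrame  # columns: subject, trial, condition, method, estimate

    REQUIRED = ("subject", "trial", "condition", "method", "estimate")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise ValidationError(f"measure table missing columns: {sorted(missing)}")
        bad = set(self.frame["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition labels: {sorted(bad)}")
        dup = self.frame.duplicated(subset=["subject", "trial", "method"])
        if dup.any():
            raise ValidationError("duplicate (subject, trial, method) rows")

    def methods(self) -> list[str]:
        return sorted(self.frame["method"].unique())

    def for_method(self, method: str) -> pd.DataFrame:
        sub = self.frame[self.frame["method"] == method]
        if sub.empty:
            raise ValidationError(f"no rows for method {method!r}")
        return sub


def condition_prediction_glm(measures: MeasureTable, method: str):
    """Regress the CS+/CS- contrast on a response measure plus subject terms.

    Predicted variable: +1 for non-reinforced CS+ trials, -1 for CS-
    trials; reinforced CS+ trials are excluded.  Predictors: the method's
    trial estimates and one indicator column per subject (absorbing
    subject mean differences).  Returns a GLMFit-compatible object whose
    sigma_e2/k/n feed the BIC.
    """
    from .benchmarks import GLMFit

    sub = measures.for_method(method)
    sub = sub[sub["condition"].isin([COND_CS_MINUS, COND_CS_PLUS_NOUS])]
    subjects = sorted(sub["subject"].unique())
    if len(subjects) < 2:
        raise ValidationError("need at least 2 subjects for the prediction GLM")
    for s in subjects:
        conds = set(sub.loc[sub["subject"] == s, "condition"])
        if len(conds) < 2:
            raise ValidationError(f"subject {s!r} has trials in only one condition")
    y = np.where(sub["condition"] == COND_CS_PLUS_NOUS, 1.0, -1.0)
    est = sub["estimate"].to_numpy(dtype=float)
    subj_cols = np.column_stack([
        (sub["subject"] == s).to_numpy(dtype=float) for s in subjects
    ])
    X = np.column_stack([est, subj_cols])
    betas, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ betas
    sse = float(np.sum((y - fitted) ** 2))
    n = len(y)
    return GLMFit(betas=betas, sigma_e2=sse / n, k=X.shape[1], n=n, fitted=fitted)


@dataclass
class ModelComparison:
    """BICs and pairwise log-Bayes factors over response measures."""

    bics: dict[str, float]
    log_bf: pd.DataFrame           # log_bf.loc[m1, m2] = BIC(m1) - BIC(m2)
    reference: str

    def relative_to_reference(self) -> dict[str, float]:
        return {m: float(self.log_bf.loc[m, self.reference])
                for m in self.bics if m != self.reference}


def compare_measures(measures: MeasureTable, reference: str | None = None) -> ModelComparison:
    """Condition-prediction BIC for every method plus pairwise log-BFs."""
    methods = measures.methods()
    fits = {m: condition_prediction_glm(measures, m) for m in methods}
    bics = {m: bic(f.sigma_e2, f.k, f.n) for m, f in fits.items()}
    mat = pd.DataFrame(
        [[bics[m1] - bics[m2] for m2 in methods] for m1 in methods],
        index=methods, columns=methods,
    )
    reference = reference or methods[0]
    return ModelComparison(bics=bics, log_bf=mat, reference=reference)


# ---------------------------------------------------------------------------
# CS main effect


@dataclass
class CsEffect:
    F: float
    p: float
    df: tuple[int, int]
    capped: bool = False  # True when within-subject variance was zero


def cs_main_effect(cs_minus_means, cs_plus_means, groups=None) -> CsEffect:
    """Within-subject main effect of CS from per-subject condition means.

    Implemented as the paired-contrast F (the square of the paired t).
    When ``groups`` labels subjects (e.g. SOA arms), group means are removed
    from the paired differences first, mirroring a mixed-design main effect.
    """
    a = np.asarray(cs_minus_means, dtype=float)
    b = np.asarray(cs_plus_means, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("condition mean vectors must be 1-D and equal length")
    n = len(a)
    if n < 2:
        raise ValidationError("need at least 2 subjects")
    diff = b - a
    df_err = n - 1
    if groups is not None:
        groups = np.asarray(groups)
        levels = np.unique(groups)
        centred = diff.copy()
        for g in levels:
            centred[groups == g] -= diff[groups == g].mean() - diff.mean()
        # grand-mean effect tested against residual within-group variation
        df_err = n - len(levels)
        resid_var = np.sum((centred - diff.mean()) ** 2) / df_err
    else:
        resid_var = np.var(diff, ddof=1)
    mean_d = diff.mean()
    if resid_var <= 1e-12 * max(mean_d**2, np.finfo(float).tiny):
        if mean_d == 0:
            return CsEffect(F=0.0, p=1.0, df=(1, df_err))
        return CsEffect(F=np.inf, p=0.0, df=(1, df_err), capped=True)
    F = n * mean_d**2 / resid_var
    p = float(sps.f.sf(F, 1, df_err))
    return CsEffect(F=float(F), p=p, df=(1, df_err))


# ---------------------------------------------------------------------------
# Rescorla-Wagner


def rw_update(v_prev: float, alpha: float, lam: float) -> float:
    """One error-driven update: V + alpha * (lambda - V)."""
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    if lam not in (0, 1, 0.0, 1.0):
        raise ParameterError(f"lambda must be 0 or 1, got {lam}")
    return v_prev + alpha * (lam - v_prev)


def rw_trace(alpha: float, lam: np.ndarray, v0: float = 0.5) -> np.ndarray:
    """Post-update associative strengths for one CS's trial sequence."""
    lam = np.asarray(lam, dtype=float)
    out = np.empty(len(lam))
    v = v0
    for t, l in enumerate(lam):
        v = rw_update(v, alpha, l)
        out[t] = v
    return out


@dataclass
class LearningTrace:
    """Associative strengths per trial for a whole session.

    ``pre`` holds the value entering each trial (what anticipation should
    track); ``post`` the value after that trial's outcome.
    """

    pre: np.ndarray
    post: np.ndarray
    alphas: dict[str, float]
    v0: float = 0.5


def session_rw_trace(alphas: dict[str, float], lam: np.ndarray,
                     cs_labels: np.ndarray, v0: float = 0.5) -> LearningTrace:
    """Interleaved per-CS updates over a session's trial sequence."""
    lam = np.asarray(lam, dtype=float)
    cs_labels = np.asarray(cs_labels)
    pre = np.empty(len(lam))
    post = np.empty(len(lam))
    v = {c: v0 for c in np.unique(cs_labels)}
    for t, (c, l) in enumerate(zip(cs_labels, lam)):
        pre[t] = v[c]
        v[c] = rw_update(v[c], alphas[c], l)
        post[t] = v[c]
    return LearningTrace(pre=pre, post=post, alphas=dict(alphas), v0=v0)


@dataclass
class RWFit:
    alphas: dict[str, float]
    intercept: float
    slope: float
    r2: float
    sse: float
    alpha_identified: bool = True


def _profile_ab(v: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    X = np.column_stack([np.ones(len(v)), v])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_rw(estimates, lam, cs_labels, v0: float = 0.5,
           grid: np.ndarray | None = None, refine: bool = True) -> RWFit:
    """Fit per-CS learning rates linking trial estimates to RW values.

    Minimises the SSE of ``estimates ~ a + b * V_pre(alpha)`` jointly over
    one learning rate per CS, with the linear map (a, b) profiled out by
    OLS at each candidate.  A coarse grid initialises a bounded gradient
    refinement.  Returns R^2 of the best fit.
    """
    y = np.asarray(estimates, dtype=float)
    lam = np.asarray(lam, dtype=float)
    cs_labels = np.asarray(cs_labels)
    if not (len(y) == len(lam) == len(cs_labels)):
        raise ValidationError("estimates, lambda and CS labels must align")
    cs_types = sorted(np.unique(cs_labels).tolist())
    for c in cs_types:
        if np.sum(cs_labels == c) < 10:
            raise ValidationError(f"need >= 10 trials per CS, {c!r} has fewer")
    grid = np.arange(0.05, 0.96, 0.1) if grid is None else np.asarray(grid)

    def objective(alpha_vec: np.ndarray) -> tuple[float, tuple[float, float]]:
        alphas = {c: float(np.clip(a, 0.0, 1.0)) for c, a in zip(cs_types, alpha_vec)}
        v = session_rw_trace(alphas, lam, cs_labels, v0).pre
        a_, b_, sse = _profile_ab(v, y)
        return sse, (a_, b_)

    best_vec, best_sse = None, np.inf
    from itertools import product

    for combo in product(grid, repeat=len(cs_types)):
        sse, _ = objective(np.asarray(combo))
        if sse < best_sse:
            best_sse, best_vec = sse, np.asarray(combo, dtype=float)

    if refine:
        res = minimize(lambda x: objective(x)[0], best_vec, method="L-BFGS-B",
                       bounds=[(0.0, 1.0)] * len(cs_types),
                       options={"maxiter": 200})
        if res.fun <= best_sse:
            best_vec, best_sse = np.clip(res.x, 0.0, 1.0), float(res.fun)

    sse, (a_, b_) = objective(best_vec)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    identified = abs(b_) > 1e-8 and sst > 0 and r2 > 1e-10
    return RWFit(
        alphas={c: float(a) for c, a in zip(cs_types, best_vec)},
        intercept=a_, slope=b_, r2=float(max(r2, 0.0)), sse=sse,
        alpha_identified=bool(identified),
    )


def ph_update(v_prev: float, assoc_prev: float, kappa: float, lam: float,
              eta: float = 0.5) -> tuple[float, float]:
    """Pearce-Hall variant: associability-gated update (optional extension).

    Returns (new value, new associability).
    """
    if not 0.0 <= kappa <= 1.0:
        raise ParameterError(f"kappa must be in [0, 1], got {kappa}")
    v = v_prev + kappa * assoc_prev * (lam - v_prev)
    assoc = (1 - eta) * assoc_prev + eta * abs(lam - v_prev)
    return v, assoc
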