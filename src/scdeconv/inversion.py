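"""Inversion of the forward model: most likely neural inputs given a trace.

Estimation is maximum a posteriori under Gaussian priors with hard bounds.
All amplitudes enter the model linearly, so they are profiled out with a
bounded ridge least-squares solve; the nonlinear per-trial parameters
(anticipatory bump timing and dispersion) are optimised block-wise, one
trial at a time against the residual of everything else, over a small
number of coordinate passes.  Spontaneous and drift events live on fixed
candidate grids in the inter-trial intervals (amplitude-only, shrunk to
zero by their priors), which keeps the problem fixed-dimension while
honouring the 0.5/s spontaneous-rate cap.

The approximate log-evidence is the Gaussian log-likelihood at the MAP
point minus a BIC-style complexity penalty, matching the downstream
model-comparison machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .design import COND_CS_MINUS, COND_CS_PLUS_NOUS, COND_CS_PLUS_US, TrialDesign
from .model_core import (
    GaussianBump,
    NeuralInputSet,
    ParameterError,
    ResponseFunction,
    SCTimeSeries,
    TimeGrid,
    ValidationError,
    forward_model,
)

__all__ = [
    "InversionConfig",
    "PriorSet",
    "InversionResult",
    "build_priors",
    "invert",
    "summarize_conditions",
    "EVENT_REPORT_THRESHOLD",
]

log = logging.getLogger(__name__)

#: Spontaneous/drift events are reported when their amplitude exceeds this.
EVENT_REPORT_THRESHOLD = 0.1


@dataclass
class InversionConfig:
    escr_delay: float = 1.9          # s, event-to-input delay (from RF fit)
    escr_dispersion: float = 0.3     # s, fixed evoked bump width
    sf_dispersion: float = 0.3       # s, fixed spontaneous bump width
    scl_dispersion: float = 1.0      # s, fixed drift bump width
    sf_spacing: float = 2.0          # s, candidate grid step (>= 2 enforces rate cap)
    iti_buffer: float = 3.0          # s after US excluded from ITI windows
    n_ascr_bumps: int = 1            # anticipatory bumps per window (1 or 2)
    ascr_amp_prior: tuple[float, float] = (0.3, 1.0)
    escr_amp_prior: tuple[float, float] = (1.9, 2.0)
    omission_amp_prior: tuple[float, float] = (0.2, 2.0)
    sf_amp_sd: float = 0.3
    scl_amp_sd: float = 0.3
    noise_sd: float = 0.1            # assumed observation noise scale
    disp_min: float = 0.1            # s, lower dispersion bound
    n_passes: int = 2                # minimum coordinate passes
    max_passes: int = 6              # stop early once SSE stops improving
    pass_tol: float = 1e-3           # relative SSE improvement to keep going
    n_starts: int = 2
    maxiter: int = 60


@dataclass
class AscrSlot:
    center_bounds: tuple[float, float]
    disp_bounds: tuple[float, float]
    center_prior: tuple[float, float]
    disp_prior: tuple[float, float]


@dataclass
class TrialPriors:
    ascr_slots: list[AscrSlot]
    amp_prior: tuple[float, float]
    escr_center: float
    escr_amp_prior: tuple[float, float]


@dataclass
class PriorSet:
    trials: list[TrialPriors]
    sf_centers: np.ndarray
    sf_amp_prior: tuple[float, float]
    sf_dispersion: float
    scl_centers: np.ndarray
    scl_amp_prior: tuple[float, float]
    scl_dispersion: float
    noise_sd: float
    config: InversionConfig = field(default_factory=InversionConfig)


def build_priors(design: TrialDesign, cfg: InversionConfig | None = None,
                 min_window_samples: int = 2,
                 sampling_rate: float = 10.0) -> PriorSet:
    """Design-derived priors: anticipatory windows, evoked delays, and
    candidate grids for spontaneous and drift events."""
    cfg = cfg or InversionConfig()
    if cfg.sf_spacing < 2.0:
        raise ParameterError(
            f"SF candidate spacing must be >= 2 s (0.5/s rate cap), got {cfg.sf_spacing}"
        )
    if cfg.n_ascr_bumps not in (1, 2):
        raise ParameterError("n_ascr_bumps must be 1 or 2")
    trial_priors = []
    for trial in design.trials:
        cs, us = trial.anticipation_window
        if (us - cs) * sampling_rate < min_window_samples:
            raise ValidationError(
                f"anticipation window of trial {trial.index} shorter than "
                f"{min_window_samples} samples"
            )
        disp_hi = max(trial.soa / 2.0, cfg.disp_min * 1.5)
        slots = []
        edges = np.linspace(cs, us, cfg.n_ascr_bumps + 1)
        for j in range(cfg.n_ascr_bumps):
            lo, hi = float(edges[j]), float(edges[j + 1])
            slots.append(AscrSlot(
                center_bounds=(lo, hi),
                disp_bounds=(cfg.disp_min, disp_hi),
                center_prior=((lo + hi) / 2.0, max((hi - lo) / 4.0, 0.25)),
                disp_prior=(float(np.sqrt(cfg.disp_min * disp_hi)), disp_hi),
            ))
        amp_prior = cfg.ascr_amp_prior
        escr_prior = cfg.escr_amp_prior if trial.reinforced else cfg.omission_amp_prior
        trial_priors.append(TrialPriors(
            ascr_slots=slots,
            amp_prior=amp_prior,
            escr_center=trial.us_onset + cfg.escr_delay,
            escr_amp_prior=escr_prior,
        ))
    sf_centers, scl_centers = [], []
    for (s, e) in design.iti_windows(buffer=cfg.iti_buffer):
        sf_centers.extend(np.arange(s + cfg.sf_spacing / 2.0, e, cfg.sf_spacing))
        if e - s >= 2.0 * cfg.scl_dispersion:
            scl_centers.append((s + e) / 2.0)
    return PriorSet(
        trials=trial_priors,
        sf_centers=np.asarray(sf_centers),
        sf_amp_prior=(0.0, cfg.sf_amp_sd),
        sf_dispersion=cfg.sf_dispersion,
        scl_centers=np.asarray(scl_centers),
        scl_amp_prior=(0.0, cfg.scl_amp_sd),
        scl_dispersion=cfg.scl_dispersion,
        noise_sd=cfg.noise_sd,
        config=cfg,
    )


@dataclass
class InversionResult:
    ascr: list[list[GaussianBump]]      # per trial, one bump per slot
    escr: list[GaussianBump]            # per trial
    sf_all: list[GaussianBump]          # every candidate with its amplitude
    scl_all: list[GaussianBump]
    sigma_e2: float
    n: int
    k: int
    fitted: SCTimeSeries
    log_evidence: float
    converged: bool = True

    def ascr_amplitudes(self) -> np.ndarray:
        """Total anticipatory amplitude per trial (summed over slots)."""
        return np.array([sum(b.amplitude for b in bumps) for bumps in self.ascr])

    def escr_amplitudes(self) -> np.ndarray:
        return np.array([b.amplitude for b in self.escr])

    def sf_events(self, threshold: float = EVENT_REPORT_THRESHOLD) -> list[GaussianBump]:
        return [b for b in self.sf_all if b.amplitude > threshold]

    def scl_events(self, threshold: float = EVENT_REPORT_THRESHOLD) -> list[GaussianBump]:
        return [b for b in self.scl_all if abs(b.amplitude) > threshold]

    def neural_inputs(self) -> NeuralInputSet:
        return NeuralInputSet(
            ascr=[b for bumps in self.ascr for b in bumps if b.amplitude != 0],
            escr=[b for b in self.escr if b.amplitude != 0],
            sf=[b for b in self.sf_all if b.amplitude != 0],
            scl=[b for b in self.scl_all if b.amplitude != 0],
        )


# ---------------------------------------------------------------------------
# internals


def _unit_response_segment(center: float, dispersion: float, kernel: np.ndarray,
                           grid: TimeGrid) -> tuple[int, np.ndarray]:
    """Trace response to a unit bump, as (start index, nonzero segment)."""
    fs = grid.sampling_rate
    lo = center - 6.0 * dispersion
    hi = center + 6.0 * dispersion
    i0 = max(int(np.floor((lo - grid.t0) * fs)), 0)
    i1 = min(int(np.ceil((hi - grid.t0) * fs)) + 1, grid.n_samples)
    if i1 <= i0:
        return 0, np.zeros(0)
    t = grid.t0 + np.arange(i0, i1) / fs
    bump = np.exp(-((t - center) ** 2) / (2 * dispersion**2))
    seg = np.convolve(bump, kernel) / fs
    return i0, seg[: grid.n_samples - i0]


def _dense_column(center: float, dispersion: float, kernel: np.ndarray,
                  grid: TimeGrid) -> np.ndarray:
    i0, seg = _unit_response_segment(center, dispersion, kernel, grid)
    col = np.zeros(grid.n_samples)
    col[i0:i0 + len(seg)] = seg
    return col


def _scl_column(center: float, dispersion: float, grid: TimeGrid) -> np.ndarray:
    t = grid.times()
    bump = np.exp(-((t - center) ** 2) / (2 * dispersion**2))
    return np.cumsum(bump) * grid.dt


def _gram_nnls(G: np.ndarray, b: np.ndarray, nonneg: np.ndarray,
               max_iter: int | None = None, tol: float = 1e-10) -> np.ndarray:
    """Lawson-Hanson active set on the normal equations.

    Minimises ``0.5 x' G x - b' x`` subject to ``x_j >= 0`` for ``j`` with
    ``nonneg[j]``; other coordinates are unconstrained.  ``G`` must be
    symmetric positive definite (ridge-augmented here, so it is).
    """
    m = len(b)
    if max_iter is None:
        max_iter = 3 * m + 30
    x = np.zeros(m)
    free = ~nonneg.copy()  # unconstrained coordinates are always in the passive set
    scale = max(np.abs(b).max(), 1.0)

    def solve_passive() -> np.ndarray:
        z = np.zeros(m)
        idx = np.where(free)[0]
        if len(idx):
            z[idx] = np.linalg.solve(G[np.ix_(idx, idx)], b[idx])
        return z

    if free.any():
        x = solve_passive()
    for _ in range(max_iter):
        grad = b - G @ x
        cand = np.where(nonneg & ~free & (grad > tol * scale))[0]
        if len(cand) == 0:
            break
        free[cand[np.argmax(grad[cand])]] = True
        while True:
            z = solve_passive()
            neg = free & nonneg & (z < 0)
            if not neg.any():
                x = z
                break
            idx = np.where(neg)[0]
            with np.errstate(divide="ignore", invalid="ignore"):
                steps = x[idx] / (x[idx] - z[idx])
            alpha = np.nanmin(steps)
            x = x + alpha * (z - x)
            drop = free & nonneg & (x <= tol)
            x[drop] = 0.0
            free[drop] = False
    return x


def _ridge_bounded_lstsq(A: np.ndarray, y: np.ndarray, mu: np.ndarray,
                         w: np.ndarray, lower: np.ndarray) -> np.ndarray:
    """min ||A x - y||^2 + sum w_j (x_j - mu_j)^2  s.t.  x >= lower."""
    G = A.T @ A + np.diag(w)
    b = A.T @ y + w * mu
    return _gram_nnls(G, b, nonneg=np.isfinite(lower))


def invert(series: SCTimeSeries, design: TrialDesign, rf_scr: ResponseFunction,
           rf_sf: ResponseFunction, priors: PriorSet | None = None,
           cfg: InversionConfig | None = None, seed: int = 0) -> InversionResult:
    """MAP estimate of the neural inputs generating ``series``.

    Deterministic given ``seed`` (which only orders the multi-start
    perturbations of the nonlinear block optimiser).
    """
    grid = series.grid
    if abs(grid.sampling_rate - rf_scr.sampling_rate) > 1e-9:
        raise ValidationError("series and rf_scr sampling rates differ")
    if priors is None:
        priors = build_priors(design, cfg, sampling_rate=grid.sampling_rate)
    cfg = priors.config
    y = series.values
    n = len(y)
    rng = np.random.default_rng(seed)

    n_trials = len(priors.trials)
    slots_per_trial = [len(tp.ascr_slots) for tp in priors.trials]
    n_slots = sum(slots_per_trial)

    # fixed linear columns: evoked, spontaneous, drift
    escr_cols = np.column_stack([
        _dense_column(tp.escr_center, cfg.escr_dispersion, rf_scr.samples, grid)
        for tp in priors.trials
    ]) if n_trials else np.zeros((n, 0))
    sf_cols = np.column_stack([
        _dense_column(c, priors.sf_dispersion, rf_sf.samples, grid)
        for c in priors.sf_centers
    ]) if len(priors.sf_centers) else np.zeros((n, 0))
    scl_cols = np.column_stack([
        _scl_column(c, priors.scl_dispersion, grid) for c in priors.scl_centers
    ]) if len(priors.scl_centers) else np.zeros((n, 0))

    # nonlinear state: (center, dispersion) per aSCR slot
    theta: list[list[tuple[float, float]]] = []
    for tp in priors.trials:
        theta.append([(s.center_prior[0], s.disp_prior[0]) for s in tp.ascr_slots])

    nv = priors.noise_sd**2

    def prior_vectors() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mu, w, lo = [], [], []
        for tp in priors.trials:                    # aSCR amplitudes
            for _ in tp.ascr_slots:
                mu.append(tp.amp_prior[0]); w.append(nv / tp.amp_prior[1] ** 2); lo.append(0.0)
        for tp in priors.trials:                    # eSCR amplitudes
            mu.append(tp.escr_amp_prior[0])
            w.append(nv / tp.escr_amp_prior[1] ** 2)
            lo.append(0.0)
        for _ in priors.sf_centers:
            mu.append(priors.sf_amp_prior[0]); w.append(nv / priors.sf_amp_prior[1] ** 2); lo.append(0.0)
        for _ in priors.scl_centers:
            mu.append(priors.scl_amp_prior[0]); w.append(nv / priors.scl_amp_prior[1] ** 2)
            lo.append(-np.inf)
        return np.asarray(mu), np.asarray(w), np.asarray(lo)

    mu_all, w_all, lo_all = prior_vectors()

    def ascr_cols_matrix() -> np.ndarray:
        if n_slots == 0:
            return np.zeros((n, 0))
        return np.column_stack([
            _dense_column(c, d, rf_scr.samples, grid)
            for slots in theta for (c, d) in slots
        ])

    def global_solve() -> tuple[np.ndarray, np.ndarray]:
        A = np.hstack([ascr_cols_matrix(), escr_cols, sf_cols, scl_cols])
        if A.shape[1] == 0:
            return np.zeros(0), np.zeros((n, 0))
        x = _ridge_bounded_lstsq(A, y, mu_all, w_all, lo_all)
        return x, A

    amps, A = global_solve()

    def slot_offsets() -> list[int]:
        offs, acc = [], 0
        for s in slots_per_trial:
            offs.append(acc)
            acc += s
        return offs

    offs = slot_offsets()

    def optimise_trial(i: int, amps: np.ndarray, A: np.ndarray) -> None:
        tp = priors.trials[i]
        n_loc = slots_per_trial[i]
        idx = list(range(offs[i], offs[i] + n_loc))
        others = A @ amps - A[:, idx] @ amps[idx]
        resid = y - others
        amp_mu = np.full(n_loc, tp.amp_prior[0])
        amp_w = np.full(n_loc, nv / tp.amp_prior[1] ** 2)

        def profile_amps(cols: list[tuple[int, np.ndarray]]) -> tuple[np.ndarray, float]:
            m = len(cols)
            G = np.zeros((m, m))
            b = np.zeros(m)
            for a_ in range(m):
                ia, sa = cols[a_]
                b[a_] = sa @ resid[ia:ia + len(sa)]
                for b_ in range(a_, m):
                    ib, sb = cols[b_]
                    lo_ = max(ia, ib)
                    hi_ = min(ia + len(sa), ib + len(sb))
                    if hi_ > lo_:
                        G[a_, b_] = G[b_, a_] = (
                            sa[lo_ - ia:hi_ - ia] @ sb[lo_ - ib:hi_ - ib]
                        )
            Gp = G + np.diag(amp_w)
            bp = b + amp_w * amp_mu
            try:
                a = np.linalg.solve(Gp, bp)
            except np.linalg.LinAlgError:
                a = np.zeros(m)
            if np.any(a < 0):  # tiny active-set fallback
                a = np.clip(a, 0.0, None)
                for j in range(m):
                    free = a > 0
                    if not free.any():
                        break
                    a_free = np.linalg.solve(Gp[np.ix_(free, free)], bp[free])
                    if np.all(a_free >= 0):
                        a[free] = a_free
                        break
                    a[np.where(free)[0][a_free < 0]] = 0.0
            q = a @ Gp @ a - 2 * a @ bp  # SSE shift + amp prior (constant dropped)
            return a, q

        def objective(x: np.ndarray) -> float:
            cols = []
            pen = 0.0
            for j in range(n_loc):
                c, d = x[2 * j], x[2 * j + 1]
                slot = tp.ascr_slots[j]
                cols.append(_unit_response_segment(c, d, rf_scr.samples, grid))
                pen += nv * ((c - slot.center_prior[0]) / slot.center_prior[1]) ** 2
                pen += nv * ((d - slot.disp_prior[0]) / slot.disp_prior[1]) ** 2
            _, q = profile_amps(cols)
            return q + pen

        bounds = []
        for slot in tp.ascr_slots:
            lo_c, hi_c = slot.center_bounds
            bounds.append((lo_c, hi_c - 1e-6))
            bounds.append(slot.disp_bounds)

        x_starts = [np.array([v for (c, d) in theta[i] for v in (c, d)])]
        for _ in range(max(cfg.n_starts - 1, 0)):
            xs = []
            for slot in tp.ascr_slots:
                lo_c, hi_c = slot.center_bounds
                xs.append(rng.uniform(lo_c + 0.1 * (hi_c - lo_c), hi_c - 0.1 * (hi_c - lo_c)))
                xs.append(rng.uniform(*slot.disp_bounds))
            x_starts.append(np.array(xs))

        best_x, best_f = None, np.inf
        for x0 in x_starts:
            res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": cfg.maxiter, "ftol": 1e-12})
            if res.fun < best_f:
                best_f, best_x = res.fun, res.x
        theta[i] = [(float(best_x[2 * j]), float(best_x[2 * j + 1])) for j in range(n_loc)]

    prev_sse = np.inf
    for _pass in range(cfg.max_passes):
        for i in range(n_trials):
            optimise_trial(i, amps, A)
        amps, A = global_solve()
        sse_now = float(np.sum((y - A @ amps) ** 2)) if A.shape[1] else 0.0
        if _pass + 1 >= cfg.n_passes:
            if prev_sse - sse_now <= cfg.pass_tol * max(sse_now, 1e-12):
                break
        prev_sse = sse_now

    fitted_values = A @ amps if A.shape[1] else np.zeros(n)
    sse = float(np.sum((y - fitted_values) ** 2))
    sigma_e2 = sse / n
    k = 3 * n_slots + n_trials + len(priors.sf_centers) + len(priors.scl_centers)
    if sigma_e2 <= 0:
        sigma_e2 = np.finfo(float).tiny
    log_evidence = -0.5 * n * np.log(sigma_e2) - 0.5 * k * np.log(n)

    # unpack amplitudes
    ascr_bumps: list[list[GaussianBump]] = []
    pos = 0
    for i in range(n_trials):
        bumps = []
        for (c, d) in theta[i]:
            bumps.append(GaussianBump(amplitude=float(amps[pos]), center=c, dispersion=d))
            pos += 1
        ascr_bumps.append(bumps)
    escr_bumps = []
    for i, tp in enumerate(priors.trials):
        escr_bumps.append(GaussianBump(amplitude=float(amps[pos]),
                                       center=tp.escr_center,
                                       dispersion=cfg.escr_dispersion))
        pos += 1
    sf_bumps = []
    for c in priors.sf_centers:
        sf_bumps.append(GaussianBump(amplitude=float(amps[pos]), center=float(c),
                                     dispersion=priors.sf_dispersion))
        pos += 1
    scl_bumps = []
    for c in priors.scl_centers:
        scl_bumps.append(GaussianBump(amplitude=float(amps[pos]), center=float(c),
                                      dispersion=priors.scl_dispersion))
        pos += 1

    fitted = SCTimeSeries(grid=grid, values=fitted_values, units=series.units)
    return InversionResult(
        ascr=ascr_bumps, escr=escr_bumps, sf_all=sf_bumps, scl_all=scl_bumps,
        sigma_e2=sigma_e2, n=n, k=k, fitted=fitted, log_evidence=float(log_evidence),
    )


def summarize_conditions(result: InversionResult, design: TrialDesign) -> dict[str, float]:
    """Mean anticipatory amplitude for CS- and for non-reinforced CS+ trials.

    Reinforced CS+ trials are excluded from the CS+ mean.
    """
    amps = result.ascr_amplitudes()
    by_cond = design.condition_indices()
    out = {}
    for cond in (COND_CS_MINUS, COND_CS_PLUS_NOUS):
        idx = by_cond[cond]
        if not idx:
            raise ValidationError(f"no trials in condition {cond}")
        out[cond] = float(np.mean(amps[idx]))
    return out


def refit_forward(result: InversionResult, rf_scr: ResponseFunction,
                  rf_sf: ResponseFunction) -> SCTimeSeries:
    """Forward-model trace of the estimated inputs (consistency check)."""
    return forward_model(result.neural_inputs(), rf_scr, rf_sf, result.fitted.grid)
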