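"""Comparison estimators: peak scoring and the convolution GLM.

Peak scoring reads the maximum of the trace inside an anticipation
window, baseline-corrected by the second before CS onset.  The GLM models
event onsets as stick functions convolved with a canonical kernel
(optionally plus its latency and dispersion partial derivatives) and reads
amplitudes off the regression coefficients, or off per-trial response
reconstructions when the derivative basis is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import Trial, TrialDesign
from .model_core import (
    ParameterError,
    ResponseFunction,
    SCTimeSeries,
    TimeGrid,
    ValidationError,
    canonical_rf,
)

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "peak_score",
    "peak_scores",
    "build_glm_design",
    "fit_glm",
    "reconstruct_trial_peak",
    "kernel_with_partials",
]

PEAK_MODES = ("EIR", "FIR", "SIR")
MIN_PEAK_WINDOW = 5.0  # s; EIR window is extended to this for short SOAs


def _peak_window(trial: Trial, mode: str) -> tuple[float, float]:
    cs, us = trial.anticipation_window
    if mode == "EIR":
        end = max(us, cs + MIN_PEAK_WINDOW) if trial.soa < MIN_PEAK_WINDOW else us
        return (cs, end)
    mid = cs + trial.soa / 2.0
    if mode == "FIR":
        return (cs, mid)
    if mode == "SIR":
        return (mid, us)
    raise ParameterError(f"mode must be one of {PEAK_MODES}, got {mode!r}")


def peak_score(series: SCTimeSeries, trial: Trial, mode: str = "EIR") -> float:
    """Window maximum minus the mean of the 1 s pre-CS baseline."""
    grid = series.grid
    base_sl = grid.window_slice(trial.cs_onset - 1.0, trial.cs_onset)
    if trial.cs_onset - 1.0 < grid.t0 - 1e-9 or base_sl.stop <= base_sl.start:
        raise ValidationError(
            f"baseline window of trial {trial.index} precedes the recording start"
        )
    w0, w1 = _peak_window(trial, mode)
    win_sl = grid.window_slice(w0, w1)
    if win_sl.stop > grid.n_samples or win_sl.stop <= win_sl.start:
        raise ValidationError(f"peak window of trial {trial.index} overruns the recording")
    baseline = float(series.values[base_sl].mean())
    window = series.values[win_sl]
    # ties: earliest sample wins (np.max is value-only so this is moot here)
    return float(window.max() - baseline)


def peak_scores(series: SCTimeSeries, design: TrialDesign, mode: str = "EIR") -> np.ndarray:
    return np.array([peak_score(series, t, mode) for t in design.trials])


# ---------------------------------------------------------------------------
# convolution GLM


@dataclass
class DesignMatrix:
    X: np.ndarray                      # (n, k)
    labels: list[tuple[str, int | None, str]]  # (event label, trial index, basis name)
    grid: TimeGrid
    basis_names: tuple[str, ...]

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.X, axis=0)
        if np.any(norms == 0):
            bad = [self.labels[i] for i in np.where(norms == 0)[0]]
            raise ValidationError(f"all-zero design columns: {bad}")
        if self.X.shape[1] >= self.X.shape[0]:
            raise ValidationError("design must have fewer columns than rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def columns_for_trial(self, trial_index: int, event: str = "CS") -> list[int]:
        return [i for i, (ev, tr, _) in enumerate(self.labels)
                if tr == trial_index and ev.startswith(event)]


@dataclass
class GLMFit:
    betas: np.ndarray
    sigma_e2: float      # SSE / n  (ML convention, feeds the BIC)
    k: int
    n: int
    fitted: np.ndarray
    dm: DesignMatrix | None = None


def kernel_with_partials(rf: ResponseFunction, rel_step: float = 1e-3) -> list[np.ndarray]:
    """Canonical kernel plus numerical partials w.r.t. latency and dispersion.

    Latency derivative: central difference of the kernel under an onset
    shift; dispersion derivative: central difference under a smoothing-width
    change.  Steps are ``rel_step`` relative to the respective parameter.
    """
    from .model_core import smoothed_biexponential

    p = rf.shape_params
    base = rf.samples
    t = np.arange(0.0, rf.support, 1.0 / rf.sampling_rate)

    def raw(**over) -> np.ndarray:
        params = dict(p)
        params.update(over)
        # raw (un-renormalised) kernel so the finite differences are not
        # contaminated by per-kernel normalisation ripple
        return np.clip(smoothed_biexponential(t, **params), 0.0, None) / rf.norm_constant

    h_lat = rel_step * max(p["onset"], 1.0)
    d_lat = (raw(onset=p["onset"] + h_lat) - raw(onset=p["onset"] - h_lat)) / (2 * h_lat)
    h_disp = rel_step * p["smooth_sd"]
    d_disp = (raw(smooth_sd=p["smooth_sd"] + h_disp)
              - raw(smooth_sd=p["smooth_sd"] - h_disp)) / (2 * h_disp)
    return [base, d_lat, d_disp]


BASIS_NAMES = {"canonical": ("canonical",),
               "canonical+derivatives": ("canonical", "d_latency", "d_dispersion")}


def _stick_column(onset: float, kernel: np.ndarray, grid: TimeGrid) -> np.ndarray:
    idx = int(round((onset - grid.t0) * grid.sampling_rate))
    col = np.zeros(grid.n_samples)
    if 0 <= idx < grid.n_samples:
        seg = kernel[: grid.n_samples - idx]
        col[idx:idx + len(seg)] = seg
    return col


def _events(design: TrialDesign, mode: str):
    """Yield (label, trial index or None, onset) per regressor group."""
    if mode == "conditions":
        groups: dict[str, list[float]] = {"CS-": [], "CS+noUS": [], "CS+US": [], "US": []}
        for t in design.trials:
            groups[t.condition].append(t.cs_onset)
            if t.reinforced:
                groups["US"].append(t.us_onset)
        for label, onsets in groups.items():
            if onsets:
                yield label, None, onsets
    elif mode == "trials":
        for i, t in enumerate(design.trials):
            yield f"CS:{t.condition}", i, [t.cs_onset]
            if t.reinforced:
                yield "US", i, [t.us_onset]
    else:
        raise ParameterError(f"mode must be 'conditions' or 'trials', got {mode!r}")


def build_glm_design(design: TrialDesign, rf: ResponseFunction, grid: TimeGrid,
                     mode: str = "conditions", basis: str = "canonical") -> DesignMatrix:
    """Stick-function design convolved with the kernel basis.

    ``conditions``: one column per event type (CS-, CS+noUS, CS+US, US) and
    basis function.  ``trials``: one column per event per basis function.
    """
    if basis not in BASIS_NAMES:
        raise ParameterError(f"basis must be one of {sorted(BASIS_NAMES)}, got {basis!r}")
    onset_seen: set[float] = set()
    for t in design.trials:
        for onset in ((t.cs_onset, t.us_onset) if t.reinforced else (t.cs_onset,)):
            if onset in onset_seen:
                raise ValidationError(f"duplicate event onset at {onset} s")
            onset_seen.add(onset)
    kernels = ([rf.samples] if basis == "canonical" else kernel_with_partials(rf))
    names = BASIS_NAMES[basis]
    cols, labels = [], []
    for label, trial_idx, onsets in _events(design, mode):
        for kern, bname in zip(kernels, names):
            col = np.zeros(grid.n_samples)
            for onset in onsets:
                col += _stick_column(onset, kern, grid)
            cols.append(col)
            labels.append((label, trial_idx, bname))
    return DesignMatrix(X=np.column_stack(cols), labels=labels, grid=grid,
                        basis_names=names)


def fit_glm(series: SCTimeSeries | np.ndarray, dm: DesignMatrix) -> GLMFit:
    """Ordinary least squares; residual variance is SSE/n."""
    y = series.values if isinstance(series, SCTimeSeries) else np.asarray(series, float)
    if len(y) != dm.n:
        raise ValidationError(f"data length {len(y)} does not match design rows {dm.n}")
    rank = np.linalg.matrix_rank(dm.X)
    if rank < dm.k:
        corr = np.corrcoef(dm.X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValidationError(
            f"design is rank deficient (rank {rank} < k {dm.k}); most collinear "
            f"columns: {dm.labels[i]} and {dm.labels[j]}"
        )
    betas, _, _, _ = np.linalg.lstsq(dm.X, y, rcond=None)
    fitted = dm.X @ betas
    sse = float(np.sum((y - fitted) ** 2))
    return GLMFit(betas=betas, sigma_e2=sse / dm.n, k=dm.k, n=dm.n, fitted=fitted, dm=dm)


def reconstruct_trial_peak(fit: GLMFit, trial_index: int, event: str = "CS") -> float:
    """Peak of the beta-weighted basis reconstruction for one trial's event.

    Requires a trials-mode fit with the derivative basis attached.
    """
    if fit.dm is None:
        raise ValidationError("fit carries no design matrix")
    if "d_latency" not in fit.dm.basis_names:
        raise ValidationError("reconstruction requires the canonical+derivatives basis")
    idx = fit.dm.columns_for_trial(trial_index, event)
    if not idx:
        raise ValidationError(f"no {event} columns for trial {trial_index}")
    response = fit.dm.X[:, idx] @ fit.betas[idx]
    return float(response.max()) if len(response) else 0.0
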