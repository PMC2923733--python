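"""Response-function estimation from event-locked epochs.

Responses to reinforcement (and its omission) are epoch-extracted,
summarised by their first principal component, and the parametric kernel
family is least-squares fitted to the component together with an
event-to-response latency.  The fitted latency is later used as the fixed
evoked-input delay during inversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .model_core import (
    DEFAULT_SCR_SHAPE,
    ParameterError,
    ResponseFunction,
    SCTimeSeries,
    ValidationError,
    canonical_rf,
    smoothed_biexponential,
)

__all__ = ["EpochMatrix", "RFFitResult", "extract_epochs", "first_pc", "fit_rf"]

log = logging.getLogger(__name__)

DEFAULT_EPOCH_WINDOW = (0.0, 20.0)


@dataclass
class EpochMatrix:
    """Event-locked epochs: one row per event, columns on a common grid."""

    data: np.ndarray            # (n_events, n_samples)
    window: tuple[float, float]  # seconds relative to event onset, half-open
    rate: float                  # Hz
    n_dropped: int = 0           # events whose window overran the recording

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("epoch matrix must be two-dimensional")

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.data.shape[1]) / self.rate


def extract_epochs(series: SCTimeSeries, onsets, window=DEFAULT_EPOCH_WINDOW,
                   baseline: tuple[float, float] | None = None) -> EpochMatrix:
    """Slice the series around each onset; out-of-range events are dropped
    (and counted) rather than zero-padded.

    When ``baseline`` is given (a window relative to the onset, e.g.
    ``(-1.0, 0.0)``), its mean is subtracted from each epoch, which stops
    between-epoch level offsets from dominating a subsequent PCA.
    """
    onsets = np.asarray(onsets, dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise ValidationError("onsets must be sorted")
    rate = series.grid.sampling_rate
    w0, w1 = window
    n_cols = int(round((w1 - w0) * rate))
    if n_cols < 2:
        raise ValidationError("epoch window too short for the sampling rate")
    rows, dropped = [], 0
    for onset in onsets:
        i0 = int(round((onset + w0 - series.grid.t0) * rate))
        i1 = i0 + n_cols
        if i0 < 0 or i1 > series.grid.n_samples:
            dropped += 1
            continue
        row = series.values[i0:i1]
        if baseline is not None:
            sl = series.grid.window_slice(onset + baseline[0], onset + baseline[1])
            if sl.stop > sl.start:
                row = row - series.values[sl].mean()
        rows.append(row)
    if dropped:
        log.info("extract_epochs: dropped %d of %d events (window out of range)",
                 dropped, len(onsets))
    if not rows:
        raise ValidationError("no epoch fits inside the recording")
    return EpochMatrix(data=np.vstack(rows), window=(w0, w1), rate=rate, n_dropped=dropped)


def first_pc(epochs: EpochMatrix) -> tuple[np.ndarray, float]:
    """First principal component of the column-centred epoch matrix.

    Returns a unit-norm component (sign fixed so its largest-magnitude
    element is positive) and the fraction of variance it explains.
    """
    if epochs.n_events < 2:
        raise ValidationError("need at least 2 epochs for a principal component")
    centred = epochs.data - epochs.data.mean(axis=0, keepdims=True)
    # SVD of the centred matrix == eigendecomposition of its covariance
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] <= 1e-12 * max(1.0, np.abs(epochs.data).max()):
        raise ValidationError("epoch matrix has rank 0 after centring")
    pc = vt[0]
    if pc[np.argmax(np.abs(pc))] < 0:
        pc = -pc
    explained = float(s[0] ** 2 / np.sum(s**2))
    return pc, explained


@dataclass
class RFFitResult:
    rf: ResponseFunction
    latency: float      # event-to-response shift, seconds
    scale: float        # amplitude of the component in kernel units
    residual_rms: float
    n_starts_used: int


def _kernel_on(t: np.ndarray, tau_decay: float, tau_rise: float, smooth_sd: float,
               latency: float, base_onset: float) -> np.ndarray:
    k = smoothed_biexponential(t, tau_decay, tau_rise, smooth_sd,
                               onset=base_onset + latency)
    return np.clip(k, 0.0, None)


def fit_rf(pc: np.ndarray, rate: float, family: str = "scr",
           window_start: float = 0.0, n_starts: int = 8,
           seed: int = 0) -> RFFitResult:
    """Fit kernel shape, latency and scale to a principal component.

    The scale is profiled out by least squares at every evaluation, so the
    fit is invariant to the component's normalisation.  Multi-start over
    log-spaced time constants guards against the multimodal surface.
    """
    if family != "scr":
        raise ParameterError(f"unsupported kernel family {family!r}")
    pc = np.asarray(pc, dtype=float)
    if len(pc) < 10:
        raise ValidationError("component too short to fit a kernel")
    t = window_start + np.arange(len(pc)) / rate
    base_onset = DEFAULT_SCR_SHAPE["onset"]
    pc_scale = np.abs(pc).max()
    if pc_scale == 0:
        raise ValidationError("component is identically zero")

    def residual(theta: np.ndarray) -> np.ndarray:
        tau_d, tau_r, sd = np.exp(theta[:3])
        lat = theta[3]
        if tau_d <= tau_r * 1.01:
            tau_d = tau_r * 1.01
        k = _kernel_on(t, tau_d, tau_r, sd, lat, base_onset)
        denom = float(k @ k)
        scale = float(k @ pc) / denom if denom > 1e-30 else 0.0
        return scale * k - pc

    rng = np.random.default_rng(seed)
    # initial latency from peak alignment: where the component peaks minus
    # where the default kernel peaks
    default_rf = canonical_rf(family, sampling_rate=rate)
    lat0 = float(t[np.argmax(pc)] - window_start - default_rf.peak_latency())
    tau_d_grid = np.geomspace(1.5, 8.0, 4)
    lat0 = float(np.clip(lat0, -2.0, min(10.0, t[-1] / 2)))
    lat_grid = [lat0, min(lat0 + 0.5, 10.0)]
    starts = [np.array([np.log(td), np.log(td / 4.0), np.log(0.3), la])
              for td in tau_d_grid for la in lat_grid]
    order = rng.permutation(len(starts))
    starts = [starts[i] for i in order[:n_starts]]
    starts.insert(0, np.array([np.log(DEFAULT_SCR_SHAPE["tau_decay"]),
                               np.log(DEFAULT_SCR_SHAPE["tau_rise"]),
                               np.log(DEFAULT_SCR_SHAPE["smooth_sd"]), lat0]))

    # latency bounded to a physiological range; unconstrained fits on
    # overlap-contaminated components otherwise run away to the bounds
    lat_lo, lat_hi = -2.0, min(10.0, t[-1] / 2)
    lower = [np.log(0.3), np.log(0.05), np.log(0.05), lat_lo]
    upper = [np.log(20.0), np.log(10.0), np.log(3.0), lat_hi]
    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        try:
            sol = least_squares(residual, x0, bounds=(lower, upper),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:  # pragma: no cover - optimiser edge cases
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < (1e-6 * pc_scale) ** 2 * len(pc):
            break
    if best is None:
        raise RuntimeError("kernel fit failed to converge from any start")

    tau_d, tau_r, sd = np.exp(best.x[:3])
    tau_d = max(tau_d, tau_r * 1.01)
    lat = float(best.x[3])
    k = _kernel_on(t, tau_d, tau_r, sd, lat, base_onset)
    scale = float(k @ pc) / float(k @ k)
    rms = float(np.sqrt(np.mean((scale * k - pc) ** 2)))
    # support long enough for the fitted decay (< 1e-3 of peak at the end)
    support = max(30.0, float(np.ceil(12.0 * tau_d + base_onset + 6.0 * sd)))
    rf = canonical_rf("scr", {"tau_decay": tau_d, "tau_rise": tau_r, "smooth_sd": sd},
                      sampling_rate=rate, support=support)
    return RFFitResult(rf=rf, latency=lat, scale=scale, residual_rms=rms,
                       n_starts_used=n_used)
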