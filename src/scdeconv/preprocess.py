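"""Signal conditioning: band-pass filter, downsample, z-transform.

The pipeline order is fixed: band-pass -> downsample -> z-transform.
The band-pass is built from cascaded first-order Butterworth high- and
low-pass sections, each applied forward-backward (zero phase), so the
quoted cut-offs are the -3 dB points of the single-pass design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .model_core import ParameterError, SCTimeSeries, TimeGrid, ValidationError

__all__ = [
    "PreprocessConfig",
    "time_constant_to_cutoff",
    "bandpass",
    "downsample",
    "ztransform",
    "preprocess_pipeline",
]


def time_constant_to_cutoff(time_constant: float) -> float:
    """First-order filter cut-off frequency (Hz) for a time constant (s)."""
    if time_constant <= 0:
        raise ParameterError(f"time constant must be positive, got {time_constant}")
    return 1.0 / (2.0 * np.pi * time_constant)


@dataclass
class PreprocessConfig:
    high_cutoff: float = 5.0        # Hz, low-pass edge of the band
    time_constant: float = 10.0     # s, sets the high-pass edge 1/(2*pi*tau)
    target_rate: float = 10.0       # Hz
    filter_order: int = 1
    bidirectional: bool = True
    ddof: int = 1                   # z-transform SD denominator n - ddof

    @property
    def low_cutoff(self) -> float:
        return time_constant_to_cutoff(self.time_constant)

    def validate_for_rate(self, rate: float) -> None:
        nyquist = rate / 2.0
        if not 0 < self.low_cutoff < self.high_cutoff:
            raise ParameterError(
                f"need 0 < low cutoff ({self.low_cutoff:.4g}) < high cutoff "
                f"({self.high_cutoff:.4g})"
            )
        if self.low_cutoff >= nyquist:
            raise ParameterError(
                f"low cutoff {self.low_cutoff:.4g} Hz is not below Nyquist ({nyquist:.4g} Hz)"
            )
        if self.target_rate > rate:
            raise ParameterError(
                f"target rate {self.target_rate} Hz exceeds input rate {rate} Hz"
            )

    def lowpass_active(self, rate: float) -> bool:
        """The low-pass edge is skipped when it sits at/above Nyquist
        (the input is then already band-limited to the passband)."""
        return self.high_cutoff < 0.99 * (rate / 2.0)


def _apply(b: np.ndarray, a: np.ndarray, x: np.ndarray, padlen: int,
           bidirectional: bool) -> np.ndarray:
    if bidirectional:
        return filtfilt(b, a, x, padtype="even", padlen=min(padlen, len(x) - 2))
    from scipy.signal import lfilter

    return lfilter(b, a, x)


def bandpass(series: SCTimeSeries, cfg: PreprocessConfig | None = None) -> SCTimeSeries:
    """Cascaded first-order Butterworth high-pass + low-pass, zero phase.

    Edge transients are suppressed by reflect-padding three time constants
    of samples before filtering.
    """
    cfg = cfg or PreprocessConfig()
    rate = series.grid.sampling_rate
    cfg.validate_for_rate(rate)
    padlen = int(3 * cfg.time_constant * rate)
    b_hp, a_hp = butter(cfg.filter_order, cfg.low_cutoff, btype="highpass", fs=rate)
    y = _apply(b_hp, a_hp, series.values, padlen, cfg.bidirectional)
    if cfg.lowpass_active(rate):
        b_lp, a_lp = butter(cfg.filter_order, cfg.high_cutoff, btype="lowpass", fs=rate)
        y = _apply(b_lp, a_lp, y, padlen, cfg.bidirectional)
    return series.copy_with(values=y)


def downsample(series: SCTimeSeries, target_rate: float) -> SCTimeSeries:
    """Decimate by sample picking; input rate must be an integer multiple."""
    rate = series.grid.sampling_rate
    ratio = rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ParameterError(
            f"input rate {rate} Hz is not an integer multiple of target {target_rate} Hz"
        )
    step = int(round(ratio))
    if step == 1:
        return series.copy_with(values=series.values.copy())
    values = series.values[::step]
    grid = TimeGrid(sampling_rate=target_rate, n_samples=len(values), t0=series.grid.t0)
    return series.copy_with(values=values, grid=grid)


def ztransform(series: SCTimeSeries, ddof: int = 1) -> SCTimeSeries:
    """Whole-series z-transform; flips the unit flag to z-units."""
    sd = float(np.std(series.values, ddof=ddof))
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError("cannot z-transform a zero-variance series")
    z = (series.values - series.values.mean()) / sd
    return series.copy_with(values=z, units="z-units")


def preprocess_pipeline(series: SCTimeSeries,
                        cfg: PreprocessConfig | None = None) -> SCTimeSeries:
    """Run the full conditioning chain in its fixed order."""
    cfg = cfg or PreprocessConfig()
    out = bandpass(series, cfg)
    out = downsample(out, cfg.target_rate)
    return ztransform(out, ddof=cfg.ddof)
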