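"""Forward model of skin conductance generation.

Sudomotor nerve activity is parameterised as sets of Gaussian bumps per
input class (anticipatory, evoked, spontaneous, level drift).  Anticipatory
and evoked inputs are summed and convolved with the SCR response kernel;
spontaneous inputs are convolved with their own kernel; level-drift inputs
are integrated.  The sum of the three pathways is the modelled conductance
trace.

Amplitudes are expressed in "sudomotor units": the kernels are normalised
so that a reference bump of unit amplitude (dispersion
``REFERENCE_DISPERSION``) produces a trace with peak exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erfcx

__all__ = [
    "TimeGrid",
    "GaussianBump",
    "NeuralInputSet",
    "ResponseFunction",
    "SCTimeSeries",
    "ParameterError",
    "ValidationError",
    "bump_timecourse",
    "component_input",
    "convolve_rf",
    "integrate_scl",
    "forward_model",
    "simulate_observation",
    "canonical_rf",
    "smoothed_biexponential",
    "REFERENCE_DISPERSION",
    "DEFAULT_SCR_SHAPE",
    "DEFAULT_SF_SHAPE",
]

#: Dispersion (s) of the reference bump that defines one sudomotor unit.
REFERENCE_DISPERSION = 0.3

#: Default kernel shapes: (tau_decay, tau_rise, smooth_sd, onset), seconds.
DEFAULT_SCR_SHAPE = {"tau_decay": 3.0, "tau_rise": 0.8, "smooth_sd": 0.3, "onset": 1.2}
DEFAULT_SF_SHAPE = {"tau_decay": 2.0, "tau_rise": 0.5, "smooth_sd": 0.25, "onset": 1.0}

DEFAULT_SUPPORT = 30.0  # s; covers kernel decay to < 1e-3 of peak
DEFAULT_RATE = 10.0  # Hz; all model computation happens at this rate


class ParameterError(ValueError):
    """Invalid parameter value for a model primitive."""


class ValidationError(ValueError):
    """A structural constraint on model inputs is violated."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid; sample ``k`` sits at ``t0 + k / sampling_rate``.

    All windows expressed on a grid are half-open ``[start, end)`` in
    seconds; indices are 0-based.
    """

    sampling_rate: float
    n_samples: int
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ParameterError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.n_samples < 0:
            raise ParameterError(f"n_samples must be non-negative, got {self.n_samples}")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (clipped to the grid)."""
        k = int(round((t - self.t0) * self.sampling_rate))
        return min(max(k, 0), self.n_samples - 1)

    def window_slice(self, start: float, end: float) -> slice:
        """Index slice for the half-open window ``[start, end)`` seconds."""
        i0 = int(np.ceil((start - self.t0) * self.sampling_rate - 1e-9))
        i1 = int(np.ceil((end - self.t0) * self.sampling_rate - 1e-9))
        return slice(max(i0, 0), min(max(i1, 0), self.n_samples))


@dataclass(frozen=True)
class GaussianBump:
    """One sudomotor burst: ``amplitude * exp(-(t - center)^2 / (2 d^2))``."""

    amplitude: float
    center: float
    dispersion: float

    def __post_init__(self) -> None:
        if not self.dispersion > 0:
            raise ParameterError(f"dispersion must be > 0, got {self.dispersion}")
        if not np.isfinite(self.amplitude) or not np.isfinite(self.center):
            raise ParameterError("bump amplitude and center must be finite")


@dataclass
class NeuralInputSet:
    """Bump lists per input class.

    Amplitudes must be non-negative for ``ascr``, ``escr`` and ``sf``;
    ``scl`` amplitudes may be signed (drifts can go down).
    """

    ascr: list[GaussianBump] = field(default_factory=list)
    escr: list[GaussianBump] = field(default_factory=list)
    sf: list[GaussianBump] = field(default_factory=list)
    scl: list[GaussianBump] = field(default_factory=list)

    CLASSES = ("ascr", "escr", "sf", "scl")

    def bumps(self, which: str) -> list[GaussianBump]:
        if which not in self.CLASSES:
            raise ValidationError(f"unknown input class {which!r}; expected one of {self.CLASSES}")
        return getattr(self, which)

    def scaled(self, factor: float) -> "NeuralInputSet":
        """New input set with every amplitude multiplied by ``factor``."""
        return NeuralInputSet(
            **{
                cls: [replace(b, amplitude=b.amplitude * factor) for b in self.bumps(cls)]
                for cls in self.CLASSES
            }
        )

    def validate(self, design=None) -> None:
        """Check sign constraints and, when a design is given, windows.

        ``design`` is a :class:`scdeconv.design.TrialDesign`; aSCR centers
        must then lie in anticipation windows, SF/SCL centers in ITI
        windows, and the SF count per ITI may not exceed 0.5/s of the ITI
        duration.
        """
        for cls in ("ascr", "escr", "sf"):
            for b in self.bumps(cls):
                if b.amplitude < 0:
                    raise ValidationError(f"{cls} amplitude must be >= 0, got {b.amplitude}")
        if design is None:
            return
        windows = [t.anticipation_window for t in design.trials]
        for b in self.ascr:
            if not any(w[0] <= b.center < w[1] for w in windows):
                raise ValidationError(
                    f"aSCR bump at {b.center:.2f}s lies outside every anticipation window"
                )
        itis = design.iti_windows()
        for cls in ("sf", "scl"):
            for b in self.bumps(cls):
                if not any(w[0] <= b.center < w[1] for w in itis):
                    raise ValidationError(
                        f"{cls} bump at {b.center:.2f}s lies outside every inter-trial interval"
                    )
        for w in itis:
            count = sum(1 for b in self.sf if w[0] <= b.center < w[1])
            if count > 0.5 * (w[1] - w[0]):
                raise ValidationError(
                    f"{count} SF in ITI [{w[0]:.1f}, {w[1]:.1f}) exceeds the 0.5/s rate cap"
                )


@dataclass(frozen=True)
class ResponseFunction:
    """Causal impulse-response kernel on a fixed grid.

    ``samples`` holds the kernel values; convolution uses the continuous
    convention (discrete convolution scaled by ``dt``).  The kernel is
    normalised so that the reference unit bump yields a peak of exactly 1.
    """

    kind: str  # 'scr' or 'sf'
    shape_params: dict
    support: float
    sampling_rate: float
    samples: np.ndarray
    norm_constant: float

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def peak_latency(self) -> float:
        return float(np.argmax(self.samples)) * self.dt


@dataclass
class SCTimeSeries:
    """A sampled conductance trace with unit bookkeeping."""

    grid: TimeGrid
    values: np.ndarray
    units: str = "microsiemens"  # 'microsiemens' | 'z-units' | 'arbitrary'

    _ALLOWED_UNITS = ("microsiemens", "z-units", "arbitrary")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("trace values must be one-dimensional")
        if len(self.values) != self.grid.n_samples:
            raise ValidationError(
                f"trace length {len(self.values)} does not match grid ({self.grid.n_samples})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("trace contains non-finite values")
        if self.units not in self._ALLOWED_UNITS:
            raise ValidationError(f"unknown units {self.units!r}")

    def copy_with(self, values: np.ndarray, units: str | None = None,
                  grid: TimeGrid | None = None) -> "SCTimeSeries":
        return SCTimeSeries(grid=grid or self.grid, values=values, units=units or self.units)


# ---------------------------------------------------------------------------
# kernel family


def smoothed_biexponential(t: np.ndarray, tau_decay: float, tau_rise: float,
                           smooth_sd: float, onset: float = 0.0) -> np.ndarray:
    """Biexponential difference convolved with a Gaussian, closed form.

    ``(exp(-x/tau_decay) - exp(-x/tau_rise))`` for ``x = t - onset >= 0``,
    smoothed with ``N(0, smooth_sd^2)``.  Evaluated via the exponentially
    modified Gaussian with the scaled complementary error function for
    numerical stability at both tails.
    """
    if tau_decay <= tau_rise:
        raise ParameterError(
            f"tau_decay ({tau_decay}) must exceed tau_rise ({tau_rise})"
        )
    if tau_rise <= 0 or smooth_sd <= 0:
        raise ParameterError("tau_rise and smooth_sd must be positive")
    x = np.asarray(t, dtype=float) - onset

    def emg(tau: float) -> np.ndarray:
        z = (smooth_sd / tau - x / smooth_sd) / np.sqrt(2.0)
        out = np.empty_like(x)
        deep = z < -5.0  # far past onset: erfc(z) ~ 2, avoid erfcx overflow
        out[deep] = np.exp(smooth_sd**2 / (2 * tau**2) - x[deep] / tau)
        zn = z[~deep]
        out[~deep] = 0.5 * erfcx(zn) * np.exp(-x[~deep] ** 2 / (2 * smooth_sd**2))
        return out

    return emg(tau_decay) - emg(tau_rise)


def _reference_bump_samples(dt: float, dispersion: float = REFERENCE_DISPERSION) -> np.ndarray:
    half = 6.0 * dispersion
    t = np.arange(0.0, 2 * half + dt / 2, dt)
    return np.exp(-((t - half) ** 2) / (2 * dispersion**2))


def canonical_rf(kind: str, shape_params: dict | None = None,
                 sampling_rate: float = DEFAULT_RATE,
                 support: float = DEFAULT_SUPPORT) -> ResponseFunction:
    """Build a normalised causal response kernel of the given kind.

    Parameters default to :data:`DEFAULT_SCR_SHAPE` / :data:`DEFAULT_SF_SHAPE`.
    Raises :class:`ParameterError` when the kernel has not decayed below
    1e-3 of its peak by the end of its support.
    """
    if kind not in ("scr", "sf"):
        raise ParameterError(f"kind must be 'scr' or 'sf', got {kind!r}")
    defaults = DEFAULT_SCR_SHAPE if kind == "scr" else DEFAULT_SF_SHAPE
    params = dict(defaults)
    if shape_params:
        unknown = set(shape_params) - set(defaults)
        if unknown:
            raise ParameterError(f"unknown shape parameters: {sorted(unknown)}")
        params.update(shape_params)

    dt = 1.0 / sampling_rate
    t = np.arange(0.0, support, dt)
    raw = smoothed_biexponential(t, **params)
    raw = np.clip(raw, 0.0, None)
    peak = raw.max()
    if peak <= 0:
        raise ParameterError("kernel is identically zero for these parameters")
    if raw[-1] >= 1e-3 * peak:
        raise ParameterError(
            f"kernel has not decayed at end of support ({raw[-1] / peak:.2e} of peak); "
            "increase support or shorten tau_decay"
        )
    raw[raw < 1e-6 * peak] = 0.0  # hard zero-tail floor
    raw[0] = 0.0  # lag-0 convention: the kernel starts strictly after the impulse

    ref = _reference_bump_samples(dt)
    response = np.convolve(ref, raw) * dt
    norm = response.max()
    return ResponseFunction(
        kind=kind,
        shape_params=params,
        support=support,
        sampling_rate=sampling_rate,
        samples=raw / norm,
        norm_constant=norm,
    )


# ---------------------------------------------------------------------------
# forward operations


def bump_timecourse(bump: GaussianBump, grid: TimeGrid) -> np.ndarray:
    """Sample a Gaussian bump on the grid."""
    t = grid.times()
    return bump.amplitude * np.exp(-((t - bump.center) ** 2) / (2 * bump.dispersion**2))


def component_input(inputs: NeuralInputSet, which: str, grid: TimeGrid) -> np.ndarray:
    """Pointwise sum of the bump time courses of one input class."""
    out = np.zeros(grid.n_samples)
    for bump in inputs.bumps(which):
        out += bump_timecourse(bump, grid)
    return out


def convolve_rf(signal: np.ndarray | SCTimeSeries, rf: ResponseFunction,
                sampling_rate: float | None = None) -> np.ndarray:
    """Causal convolution of a sampled signal with a response kernel.

    Output is truncated to the input length; sample ``k`` depends only on
    input samples ``0..k``.  Uses the continuous convention (scaled by dt).
    """
    if isinstance(signal, SCTimeSeries):
        sampling_rate = signal.grid.sampling_rate
        x = signal.values
    else:
        x = np.asarray(signal, dtype=float)
        if sampling_rate is None:
            sampling_rate = rf.sampling_rate
    if abs(sampling_rate - rf.sampling_rate) > 1e-9:
        raise ValidationError(
            f"signal rate {sampling_rate} Hz does not match kernel rate {rf.sampling_rate} Hz"
        )
    from scipy.signal import fftconvolve

    full = fftconvolve(x, rf.samples)
    return full[: len(x)] / sampling_rate


def integrate_scl(signal: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """Cumulative integral of the level-drift input (rectangle rule)."""
    return np.cumsum(np.asarray(signal, dtype=float)) * grid.dt


def forward_model(inputs: NeuralInputSet, rf_scr: ResponseFunction,
                  rf_sf: ResponseFunction, grid: TimeGrid) -> SCTimeSeries:
    """Map a neural input set to a clean conductance trace.

    Anticipatory and evoked inputs are summed before convolution with the
    SCR kernel; spontaneous inputs use the SF kernel; drift inputs are
    integrated.  The three pathways add.
    """
    if rf_scr.kind != "scr":
        raise ValidationError(f"rf_scr must have kind 'scr', got {rf_scr.kind!r}")
    if rf_sf.kind != "sf":
        raise ValidationError(f"rf_sf must have kind 'sf', got {rf_sf.kind!r}")
    scr_input = component_input(inputs, "ascr", grid) + component_input(inputs, "escr", grid)
    trace = convolve_rf(scr_input, rf_scr, grid.sampling_rate)
    trace += convolve_rf(component_input(inputs, "sf", grid), rf_sf, grid.sampling_rate)
    trace += integrate_scl(component_input(inputs, "scl", grid), grid)
    return SCTimeSeries(grid=grid, values=trace, units="arbitrary")


def simulate_observation(clean: SCTimeSeries, noise_sd: float,
                         seed: int | np.random.Generator | None = None) -> SCTimeSeries:
    """Add iid zero-mean Gaussian observation noise; reproducible per seed."""
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    if noise_sd == 0:
        return clean.copy_with(values=clean.values.copy())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = clean.values + rng.normal(0.0, noise_sd, size=clean.values.shape)
    return clean.copy_with(values=noisy)
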