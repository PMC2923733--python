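"""Ground-truthed synthetic conditioning sessions.

Generates discriminant delay-conditioning designs (two CS types, 50%
reinforcement of CS+, randomised ITIs) together with the sudomotor inputs
that produced each trace, so parameter-recovery and method-comparison
studies need no external recordings.  Two named presets mirror the common
long-ITI (exp1) and short-ITI/overlap (exp2) regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .design import CS_MINUS, CS_PLUS, Trial, TrialDesign
from .model_core import (
    GaussianBump,
    NeuralInputSet,
    ParameterError,
    ResponseFunction,
    SCTimeSeries,
    TimeGrid,
    canonical_rf,
    forward_model,
    simulate_observation,
)
from .stats import LearningTrace, session_rw_trace

__all__ = ["ExperimentSpec", "GroundTruth", "SubjectBundle", "generate_design",
           "generate_subject", "generate_cohort", "EXP1_PRESET", "EXP2_PRESET", "preset"]


@dataclass
class ExperimentSpec:
    n_trials_per_cs: int = 90
    soa: float = 3.5                      # s
    iti_choices: tuple[float, ...] = (7.0, 9.0, 11.0)
    reinforcement_rate: float = 0.5
    lead_in: float = 10.0                 # s before the first CS
    tail: float = 20.0                    # s after the last US
    sampling_rate: float = 10.0

    # subject-level response parameters (sudomotor units unless noted)
    cr_minus_amp: tuple[float, float] = (1.02, 0.3)   # mean, SD across trials
    cr_plus_amp: tuple[float, float] = (1.24, 0.3)
    ur_amp: tuple[float, float] = (1.9, 0.4)
    omission_amp: tuple[float, float] = (0.2, 0.1)
    ur_latency: float = 1.9               # s after US onset
    escr_dispersion: float = 0.3
    ascr_center_jitter: tuple[float, float] = (0.35, 0.65)  # fraction of SOA
    ascr_dispersion_range: tuple[float, float] = (0.4, 1.2)  # s
    sf_rate: float = 0.1                  # Hz within ITIs (must be <= 0.5)
    sf_amp: tuple[float, float] = (0.29, 0.08)
    sf_min_spacing: float = 2.0           # s, enforces the 0.5/s cap
    scl_rate_per_trial: float = 0.12
    scl_amp_sd: float = 0.2
    noise_sd: float = 0.1

    # learning mode: amplitudes follow an RW process mapped through (a, b)
    learning: bool = False
    alpha_plus: float = 0.2
    alpha_minus: float = 0.2
    rw_offset: float = 0.3
    rw_gain: float = 1.5
    v0: float = 0.5

    seed: int = 0

    def validate(self) -> None:
        n_reinforced = self.reinforcement_rate * self.n_trials_per_cs
        if abs(n_reinforced - round(n_reinforced)) > 1e-9:
            raise ParameterError(
                f"reinforcement_rate x n_trials_per_cs = {n_reinforced} is not integral"
            )
        if self.sf_rate > 0.5:
            raise ParameterError(f"SF rate {self.sf_rate}/s exceeds the 0.5/s cap")
        if self.soa <= 0 or self.n_trials_per_cs < 1:
            raise ParameterError("invalid SOA or trial count")


EXP1_PRESET = dict(n_trials_per_cs=32, soa=4.0, iti_choices=(14.0, 19.0, 23.0),
                   cr_minus_amp=(1.19, 0.3), cr_plus_amp=(1.30, 0.3), sf_rate=0.067)
EXP2_PRESET = dict(n_trials_per_cs=90, soa=3.5, iti_choices=(7.0, 9.0, 11.0),
                   cr_minus_amp=(1.02, 0.3), cr_plus_amp=(1.24, 0.3), sf_rate=0.135)


def preset(name: str, **overrides) -> ExperimentSpec:
    base = {"exp1": EXP1_PRESET, "exp2": EXP2_PRESET}.get(name)
    if base is None:
        raise ParameterError(f"unknown preset {name!r}; expected 'exp1' or 'exp2'")
    kw = dict(base)
    kw.update(overrides)
    return ExperimentSpec(**kw)


@dataclass
class GroundTruth:
    inputs: NeuralInputSet
    ascr_amplitudes: np.ndarray           # per trial
    escr_amplitudes: np.ndarray           # per trial (0 where no evoked bump)
    learning_trace: LearningTrace | None = None


@dataclass
class SubjectBundle:
    design: TrialDesign
    clean: SCTimeSeries
    noisy: SCTimeSeries
    truth: GroundTruth
    seed: int


def generate_design(spec: ExperimentSpec, rng: np.random.Generator | None = None) -> TrialDesign:
    """Randomised trial order with an exact reinforcement count.

    Reinforced CS+ trials are chosen by permutation (exactly
    ``reinforcement_rate`` of CS+), not by coin flips.
    """
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_trials_per_cs
    cs_types = np.array([CS_PLUS] * n + [CS_MINUS] * n)
    rng.shuffle(cs_types)
    n_reinforced = int(round(spec.reinforcement_rate * n))
    plus_positions = np.where(cs_types == CS_PLUS)[0]
    reinforced_at = set(rng.permutation(plus_positions)[:n_reinforced].tolist())

    trials = []
    t = spec.lead_in
    for i, cs in enumerate(cs_types):
        trials.append(Trial(index=i, cs_onset=float(t), soa=spec.soa, cs_type=str(cs),
                            reinforced=i in reinforced_at))
        iti = float(rng.choice(spec.iti_choices))
        t += spec.soa + iti
    session_end = trials[-1].us_onset + spec.tail
    return TrialDesign(trials=trials, session_end=session_end)


def _sf_point_process(windows, rate: float, min_spacing: float,
                      rng: np.random.Generator) -> list[float]:
    """Poisson events in the given windows, thinned to a hard min spacing."""
    events: list[float] = []
    for (s, e) in windows:
        dur = e - s
        n = rng.poisson(rate * dur)
        times = np.sort(rng.uniform(s, e, size=n))
        kept: list[float] = []
        for t in times:
            if not kept or t - kept[-1] >= min_spacing:
                kept.append(float(t))
        cap = int(np.floor(0.5 * dur))
        events.extend(kept[:max(cap, 0)])
    return events


def generate_subject(spec: ExperimentSpec, design: TrialDesign | None = None,
                     rf_scr: ResponseFunction | None = None,
                     rf_sf: ResponseFunction | None = None,
                     rng: np.random.Generator | None = None) -> SubjectBundle:
    """One session: design, ground-truth inputs, clean and noisy traces."""
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed)
    seed_echo = spec.seed
    design = design or generate_design(spec, rng)
    rf_scr = rf_scr or canonical_rf("scr", sampling_rate=spec.sampling_rate)
    rf_sf = rf_sf or canonical_rf("sf", sampling_rate=spec.sampling_rate)

    n_trials = len(design)
    learning_trace = None
    if spec.learning:
        cs_labels = np.array([t.cs_type for t in design.trials])
        lam = np.array([1.0 if t.reinforced else 0.0 for t in design.trials])
        learning_trace = session_rw_trace(
            {CS_PLUS: spec.alpha_plus, CS_MINUS: spec.alpha_minus},
            lam, cs_labels, v0=spec.v0)
        ascr_amps = spec.rw_offset + spec.rw_gain * learning_trace.pre
    else:
        means = np.array([
            spec.cr_plus_amp[0] if t.cs_type == CS_PLUS else spec.cr_minus_amp[0]
            for t in design.trials
        ])
        sds = np.array([
            spec.cr_plus_amp[1] if t.cs_type == CS_PLUS else spec.cr_minus_amp[1]
            for t in design.trials
        ])
        ascr_amps = np.clip(rng.normal(means, sds), 0.0, None)

    ascr_bumps, escr_bumps = [], []
    escr_amps = np.zeros(n_trials)
    for i, trial in enumerate(design.trials):
        frac = rng.uniform(*spec.ascr_center_jitter)
        center = trial.cs_onset + frac * trial.soa
        disp_hi = min(spec.ascr_dispersion_range[1], trial.soa / 2.0)
        disp_lo = min(spec.ascr_dispersion_range[0], disp_hi)
        disp = rng.uniform(disp_lo, disp_hi)
        ascr_bumps.append(GaussianBump(float(ascr_amps[i]), float(center), float(disp)))
        amp_spec = spec.ur_amp if trial.reinforced else spec.omission_amp
        amp = float(np.clip(rng.normal(*amp_spec), 0.0, None))
        escr_amps[i] = amp
        escr_bumps.append(GaussianBump(amp, trial.us_onset + spec.ur_latency,
                                       spec.escr_dispersion))

    itis = design.iti_windows()
    sf_bumps = [
        GaussianBump(float(np.clip(rng.normal(*spec.sf_amp), 0.01, None)), t, 0.3)
        for t in _sf_point_process(itis, spec.sf_rate, spec.sf_min_spacing, rng)
    ]
    scl_bumps = []
    for (s, e) in itis:
        if rng.random() < spec.scl_rate_per_trial and e - s > 2.0:
            scl_bumps.append(GaussianBump(float(rng.normal(0.0, spec.scl_amp_sd)),
                                          float((s + e) / 2.0), 1.0))

    inputs = NeuralInputSet(ascr=ascr_bumps, escr=escr_bumps, sf=sf_bumps, scl=scl_bumps)
    inputs.validate(design)

    n_samples = int(np.ceil(design.session_end * spec.sampling_rate))
    grid = TimeGrid(sampling_rate=spec.sampling_rate, n_samples=n_samples)
    clean = forward_model(inputs, rf_scr, rf_sf, grid)
    noisy = simulate_observation(clean, spec.noise_sd, seed=rng)
    truth = GroundTruth(inputs=inputs, ascr_amplitudes=ascr_amps,
                        escr_amplitudes=escr_amps, learning_trace=learning_trace)
    return SubjectBundle(design=design, clean=clean, noisy=noisy, truth=truth,
                         seed=seed_echo)


@dataclass
class Cohort:
    subjects: list[SubjectBundle]
    manifest: dict = field(default_factory=dict)


def generate_cohort(spec: ExperimentSpec, n_subjects: int,
                    master_seed: int | None = None) -> Cohort:
    """Independent subjects with per-subject seeds spawned from a master seed."""
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    master_seed = spec.seed if master_seed is None else master_seed
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_subjects)
    subjects = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        bundle = generate_subject(spec, rng=rng)
        bundle.seed = master_seed
        subjects.append(bundle)
    manifest = {
        "master_seed": master_seed,
        "n_subjects": n_subjects,
        "spec": asdict(spec),
    }
    return Cohort(subjects=subjects, manifest=manifest)
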