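"""Trial structure of a conditioning session.

A session is a sequence of trials.  Each trial has a CS onset, an SOA
(CS-to-US delay), a CS type and a reinforcement flag; the anticipation
window is ``[cs_onset, us_onset)`` and inter-trial intervals are the gaps
between a trial's US time (plus a post-event buffer) and the next CS onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model_core import ValidationError

CS_MINUS = "CS-"
CS_PLUS = "CS+"

#: Condition labels used for summaries and statistics.
COND_CS_MINUS = "CS-"
COND_CS_PLUS_US = "CS+US"
COND_CS_PLUS_NOUS = "CS+noUS"

#: Seconds after US onset excluded from ITI windows (lets the evoked
#: response input play out before spontaneous candidates are allowed).
DEFAULT_ITI_BUFFER = 3.0


@dataclass(frozen=True)
class Trial:
    index: int
    cs_onset: float
    soa: float
    cs_type: str  # 'CS-' or 'CS+'
    reinforced: bool = False

    def __post_init__(self) -> None:
        if self.cs_type not in (CS_MINUS, CS_PLUS):
            raise ValidationError(f"cs_type must be 'CS-' or 'CS+', got {self.cs_type!r}")
        if self.cs_type == CS_MINUS and self.reinforced:
            raise ValidationError("CS- trials are never reinforced")
        if self.soa <= 0:
            raise ValidationError(f"SOA must be positive, got {self.soa}")

    @property
    def us_onset(self) -> float:
        """US delivery (or omission) time."""
        return self.cs_onset + self.soa

    @property
    def anticipation_window(self) -> tuple[float, float]:
        return (self.cs_onset, self.us_onset)

    @property
    def condition(self) -> str:
        if self.cs_type == CS_MINUS:
            return COND_CS_MINUS
        return COND_CS_PLUS_US if self.reinforced else COND_CS_PLUS_NOUS


@dataclass
class TrialDesign:
    trials: list[Trial] = field(default_factory=list)
    session_end: float = 0.0

    def __post_init__(self) -> None:
        onsets = [t.cs_onset for t in self.trials]
        if onsets != sorted(onsets):
            raise ValidationError("trials must be sorted by CS onset")
        for a, b in zip(self.trials, self.trials[1:]):
            if b.cs_onset < a.us_onset:
                raise ValidationError(
                    f"trial {b.index} starts before trial {a.index}'s US time"
                )
        if self.trials and self.session_end < self.trials[-1].us_onset:
            raise ValidationError("session_end precedes the last trial's US time")

    def __len__(self) -> int:
        return len(self.trials)

    def iti_windows(self, buffer: float = DEFAULT_ITI_BUFFER,
                    include_lead: bool = True) -> list[tuple[float, float]]:
        """Half-open inter-trial windows, including trailing (and optionally
        leading) stretches of the session."""
        windows: list[tuple[float, float]] = []
        if not self.trials:
            return [(0.0, self.session_end)] if self.session_end > 0 else []
        if include_lead and self.trials[0].cs_onset > 0:
            windows.append((0.0, self.trials[0].cs_onset))
        for a, b in zip(self.trials, self.trials[1:]):
            start = a.us_onset + buffer
            if b.cs_onset > start:
                windows.append((start, b.cs_onset))
        tail_start = self.trials[-1].us_onset + buffer
        if self.session_end > tail_start:
            windows.append((tail_start, self.session_end))
        return windows

    def condition_indices(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {COND_CS_MINUS: [], COND_CS_PLUS_US: [], COND_CS_PLUS_NOUS: []}
        for i, t in enumerate(self.trials):
            out[t.condition].append(i)
        return out

    def us_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.reinforced]
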