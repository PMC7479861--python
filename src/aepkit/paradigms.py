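"""Auditory stimulus schedules: paired-pulse gating and oddball (MMN) sessions.

Two session types are generated as ordered event tables:

* **Paired pulse** — identical tone pairs (S1, S2) separated by a short
  intra-pair gap, used to quantify sensory gating as the S2/S1 response
  ratio.
* **Oddball / mismatch negativity (MMN)** — trains of frequent ``standard``
  tones with one rare ``deviant`` tone of a different pitch per trial.

Events carry onset (seconds from session start), kind, tone frequency,
level and duration, plus the trial index, and round-trip through a TSV
event table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StimulusEvent",
    "StimulusSchedule",
    "make_paired_pulse_schedule",
    "make_mmn_schedule",
    "read_schedule",
    "write_schedule",
]

EVENT_KINDS = ("S1", "S2", "standard", "deviant")

#: Column order of the on-disk event table.
SCHEDULE_COLUMNS = ("onset_s", "kind", "tone_hz", "level_db", "duration_s", "trial")


@dataclass(frozen=True)
class StimulusEvent:
    """One auditory event within a session."""

    onset: float  # seconds from session start
    kind: str  # one of EVENT_KINDS
    tone_hz: float
    level_db: float
    duration: float  # seconds
    trial_index: int

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset}")
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.tone_hz <= 0:
            raise ValueError("tone frequency must be positive")
        if self.duration <= 0:
            raise ValueError("tone duration must be positive")


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered auditory events for one recording session."""

    paradigm: str  # "paired_pulse" | "mmn"
    events: tuple[StimulusEvent, ...]
    n_trials: int

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    def onsets(self, kind: str | None = None) -> np.ndarray:
        """Event onsets in seconds, optionally restricted to one kind."""
        return np.array(
            [e.onset for e in self.events if kind is None or e.kind == kind]
        )

    def kinds(self) -> np.ndarray:
        return np.array([e.kind for e in self.events])

    def count(self, kind: str) -> int:
        return sum(e.kind == kind for e in self.events)

    @property
    def duration(self) -> float:
        """Time of the last event offset, 0.0 for an empty schedule."""
        if not self.events:
            return 0.0
        last = self.events[-1]
        return last.onset + last.duration

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [e.onset for e in self.events],
                "kind": [e.kind for e in self.events],
                "tone_hz": [e.tone_hz for e in self.events],
                "level_db": [e.level_db for e in self.events],
                "duration_s": [e.duration for e in self.events],
                "trial": [e.trial_index for e in self.events],
            }
        )


def _check_positive(**params: float) -> None:
    for name, value in params.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


def make_paired_pulse_schedule(
    n_trials: int = 1250,
    s1_s2_gap: float = 0.5,
    inter_trial_gap: float = 10.0,
    tone_hz: float = 1500.0,
    level_db: float = 90.0,
    tone_duration: float = 0.010,
    iti_from_offset: bool = False,
) -> StimulusSchedule:
    """Build a paired-pulse session: S1 then S2 per trial, identical tones.

    Parameters
    ----------
    n_trials
        Number of S1/S2 pairs (default 1250, one full session).
    s1_s2_gap
        Onset-to-onset separation of S1 and S2 within a pair (default 0.5 s).
    inter_trial_gap
        Separation between S2 of one trial and S1 of the next, measured
        onset-to-onset by default; set ``iti_from_offset=True`` to measure it
        from the S2 tone offset instead.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    _check_positive(
        s1_s2_gap=s1_s2_gap,
        inter_trial_gap=inter_trial_gap,
        tone_duration=tone_duration,
    )
    events: list[StimulusEvent] = []
    t = 0.0
    pad = tone_duration if iti_from_offset else 0.0
    for k in range(n_trials):
        events.append(
            StimulusEvent(t, "S1", tone_hz, level_db, tone_duration, k)
        )
        events.append(
            StimulusEvent(t + s1_s2_gap, "S2", tone_hz, level_db, tone_duration, k)
        )
        t = t + s1_s2_gap + pad + inter_trial_gap
    return StimulusSchedule("paired_pulse", tuple(events), n_trials)


def make_mmn_schedule(
    n_trials: int = 360,
    n_standard: int = 24,
    sound_onset_asynchrony: float = 0.5,
    inter_trial_gap: float = 5.0,
    standard_hz: float = 1500.0,
    deviant_hz: float = 2000.0,
    level_db: float = 90.0,
    tone_duration: float = 0.010,
    deviant_position: str = "last",
    seed: int | None = None,
    iti_from_offset: bool = False,
) -> StimulusSchedule:
    """Build an oddball session: per trial, ``n_standard`` standards plus one deviant.

    The deviant is the last tone of each trial by default
    (``deviant_position="last"``); ``"random"`` places it uniformly at random
    within the trial (requires ``seed``). Successive tone onsets within a
    trial are ``sound_onset_asynchrony`` apart; the next trial starts
    ``inter_trial_gap`` after the last tone's onset (or offset if
    ``iti_from_offset``).
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    if n_standard < 1:
        raise ValueError("a trial must contain at least one standard tone")
    _check_positive(
        sound_onset_asynchrony=sound_onset_asynchrony,
        inter_trial_gap=inter_trial_gap,
        tone_duration=tone_duration,
    )
    if deviant_position not in ("last", "random"):
        raise ValueError("deviant_position must be 'last' or 'random'")
    rng = None
    if deviant_position == "random":
        if seed is None:
            raise ValueError("random deviant position requires a seed")
        rng = np.random.default_rng(seed)

    n_tones = n_standard + 1
    events: list[StimulusEvent] = []
    t = 0.0
    pad = tone_duration if iti_from_offset else 0.0
    for k in range(n_trials):
        dev_pos = n_tones - 1 if rng is None else int(rng.integers(n_tones))
        for j in range(n_tones):
            if j == dev_pos:
                kind, hz = "deviant", deviant_hz
            else:
                kind, hz = "standard", standard_hz
            events.append(
                StimulusEvent(
                    t + j * sound_onset_asynchrony, kind, hz, level_db,
                    tone_duration, k,
                )
            )
        t = t + (n_tones - 1) * sound_onset_asynchrony + pad + inter_trial_gap
    return StimulusSchedule("mmn", tuple(events), n_trials)


def write_schedule(schedule: StimulusSchedule, path) -> None:
    """Write an event table as TSV (onsets with 9 decimal places)."""
    frame = schedule.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# paradigm={schedule.paradigm}\tn_trials={schedule.n_trials}\n")
        fh.write("\t".join(SCHEDULE_COLUMNS) + "\n")
        for _, row in frame.iterrows():
            # shortest-repr serialisation round-trips IEEE doubles exactly
            # (and carries >= 6 significant decimals whenever they matter)
            fh.write(
                f"{row.onset_s!r}\t{row.kind}\t{row.tone_hz!r}\t"
                f"{row.level_db!r}\t{row.duration_s!r}\t{int(row.trial)}\n"
            )


def read_schedule(path) -> StimulusSchedule:
    """Read an event table written by :func:`write_schedule`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("missing schedule header line")
        meta = dict(
            item.split("=", 1) for item in header.lstrip("# ").split("\t")
        )
        frame = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    events = tuple(
        StimulusEvent(
            float(r.onset_s), str(r.kind), float(r.tone_hz), float(r.level_db),
            float(r.duration_s), int(r.trial),
        )
        for r in frame.itertuples()
    )
    return StimulusSchedule(meta["paradigm"], events, int(meta["n_trials"]))
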