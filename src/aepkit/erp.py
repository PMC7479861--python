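"""Epoching, trace centering, grand-average ERPs and P1/N1 extraction.

The centering convention follows the analysis this package reproduces:
each trial is *anchor-point* centred — the sample value at each anchor
time (tone onsets, e.g. 0 and 500 ms in a paired-pulse epoch) is
subtracted from the stretch of trace that anchor governs, forcing the
trace through 0 μV at every anchor. A conventional pre-stimulus-mean
baseline is available as an alternative mode.

P1 is the maximal positive deflection in its search window, N1 the
maximal negative deflection in its window; ties resolve to the earliest
latency. The S2/S1 ratio of N1 amplitudes quantifies sensory gating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .paradigms import StimulusSchedule
from .synth import ContinuousRecording

__all__ = [
    "EpochedTrials",
    "ErpWaveform",
    "ErpComponents",
    "epoch_and_centre",
    "grand_average",
    "find_components",
    "gating_ratio",
    "bandpass",
]

CENTERING_MODES = ("anchor_point", "prestim_mean", "none")

# Default epoch windows (s): paired-pulse spans S1 and S2; oddball spans
# a single tone at 500-ms onset asynchrony.
DEFAULT_WINDOWS = {"paired_pulse": (-0.1, 1.0), "mmn": (-0.1, 0.45)}
# Default component search windows (s post-anchor). The N1 window covers
# the ~40 ms peak and the longer-latency 40-70 ms deviant response.
DEFAULT_P1_WINDOW = (0.010, 0.030)
DEFAULT_N1_WINDOW = (0.025, 0.080)


@dataclass
class EpochedTrials:
    """Trials x channels x samples cut around event anchors."""

    data: np.ndarray  # (n_trials, n_channels, n_samples), μV
    time_axis: np.ndarray  # s relative to the event anchor
    fs: float
    event_kinds: np.ndarray  # per-trial label
    n_dropped: int = 0
    channel_labels: list[str] | None = None
    centering: str = "none"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be trials x channels x samples")
        if self.data.shape[2] != self.time_axis.size:
            raise ValueError("time axis does not match sample count")
        if len(self.event_kinds) != self.data.shape[0]:
            raise ValueError("one event kind per trial required")
        self.event_kinds = np.asarray(self.event_kinds)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, kind: str) -> "EpochedTrials":
        """Subset of trials whose event kind equals ``kind``."""
        mask = self.event_kinds == kind
        return EpochedTrials(
            self.data[mask], self.time_axis, self.fs, self.event_kinds[mask],
            self.n_dropped, self.channel_labels, self.centering,
        )

    def channel_index(self, channel: str | int | None) -> int:
        if channel is None:
            return 0
        if isinstance(channel, (int, np.integer)):
            return int(channel)
        if self.channel_labels is None or channel not in self.channel_labels:
            raise ValueError(f"unknown channel {channel!r}")
        return self.channel_labels.index(channel)


@dataclass
class ErpWaveform:
    """Trial-averaged (grand-average) ERP."""

    mean: np.ndarray  # (n_channels, n_samples), μV
    time_axis: np.ndarray
    fs: float
    n_trials: int
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=float))
        if self.n_trials < 1:
            raise ValueError("an ERP requires at least one trial")


@dataclass(frozen=True)
class ErpComponents:
    p1_amplitude: float  # μV
    p1_latency: float  # s
    n1_amplitude: float  # μV
    n1_latency: float  # s


def _sample_index(t: float, fs: float) -> int:
    return int(round(t * fs))


def epoch_and_centre(
    recording: ContinuousRecording,
    schedule: StimulusSchedule,
    window: tuple[float, float] = (-0.1, 0.45),
    anchor_times: tuple[float, ...] = (0.0,),
    centering: str = "anchor_point",
    kind: str | None = None,
) -> EpochedTrials:
    """Cut one epoch per event (optionally one kind only) and centre it.

    ``window`` is (start, end) in seconds relative to the event onset,
    inclusive at both ends; ``anchor_times`` are the within-epoch times
    (same reference) forced to 0 μV under ``anchor_point`` centering —
    each sample is offset by the trace value at the latest anchor not
    after it (samples before the first anchor use the first).  Events
    whose window falls outside the recording are dropped and counted.
    """
    if window[0] >= window[1]:
        raise ValueError("epoch window start must precede its end")
    if centering not in CENTERING_MODES:
        raise ValueError(f"unknown centering mode {centering!r}")
    fs = recording.fs
    i0 = _sample_index(window[0], fs)
    i1 = _sample_index(window[1], fs)
    time_axis = np.arange(i0, i1 + 1) / fs
    n_samp = time_axis.size

    anchors = sorted(anchor_times)
    if centering == "anchor_point":
        for a in anchors:
            if not (window[0] <= a <= window[1]):
                raise ValueError("epoch window must cover all anchor times")

    trials, kinds = [], []
    n_dropped = 0
    for ev in schedule.events:
        if kind is not None and ev.kind != kind:
            continue
        c = _sample_index(ev.onset, fs)
        lo, hi = c + i0, c + i1
        if lo < 0 or hi >= recording.n_samples:
            n_dropped += 1
            continue
        trials.append(recording.samples[:, lo:hi + 1])
        kinds.append(ev.kind)

    if trials:
        data = np.stack(trials)
    else:
        data = np.empty((0, recording.samples.shape[0], n_samp))
    data = _centre(data, time_axis, fs, anchors, centering, i0)
    return EpochedTrials(
        data, time_axis, fs, np.array(kinds, dtype=object), n_dropped,
        list(recording.channel_labels), centering,
    )


def _centre(
    data: np.ndarray,
    time_axis: np.ndarray,
    fs: float,
    anchors: list[float],
    mode: str,
    i0: int,
) -> np.ndarray:
    if mode == "none" or data.size == 0:
        return data
    if mode == "prestim_mean":
        pre = time_axis < 0
        if not pre.any():
            raise ValueError("prestim_mean centering needs samples before 0 s")
        return data - data[:, :, pre].mean(axis=2, keepdims=True)
    # anchor_point: piecewise offset, one segment per anchor
    anchor_idx = [_sample_index(a, fs) - i0 for a in anchors]
    out = data.copy()
    bounds = anchor_idx[1:] + [data.shape[2]]
    start = 0
    for j, stop in zip(anchor_idx, bounds):
        out[:, :, start:stop] -= data[:, :, j:j + 1]
        start = stop
    return out


def grand_average(trials: EpochedTrials, kind_filter: str | None = None) -> ErpWaveform:
    """Pointwise mean over trials, optionally restricted to one event kind."""
    sel = trials if kind_filter is None else trials.select(kind_filter)
    if sel.n_trials == 0:
        raise ValueError("no trials to average after filtering")
    return ErpWaveform(
        sel.data.mean(axis=0), sel.time_axis, sel.fs, sel.n_trials,
        sel.channel_labels,
    )


def find_components(
    waveform: ErpWaveform,
    p1_window: tuple[float, float] = DEFAULT_P1_WINDOW,
    n1_window: tuple[float, float] = DEFAULT_N1_WINDOW,
    channel: str | int | None = None,
) -> ErpComponents:
    """Extract P1 (max) and N1 (min) amplitude/latency in their windows."""
    t = waveform.time_axis
    if isinstance(channel, str):
        if waveform.channel_labels is None or channel not in waveform.channel_labels:
            raise ValueError(f"unknown channel {channel!r}")
        ch = waveform.channel_labels.index(channel)
    else:
        ch = int(channel or 0)
    trace = waveform.mean[ch]

    def window_mask(win: tuple[float, float]) -> np.ndarray:
        if win[0] >= win[1]:
            raise ValueError("component window start must precede its end")
        if win[0] < t[0] - 1e-12 or win[1] > t[-1] + 1e-12:
            raise ValueError("component window lies outside the epoch")
        return (t >= win[0] - 1e-12) & (t <= win[1] + 1e-12)

    m_p1 = window_mask(p1_window)
    m_n1 = window_mask(n1_window)
    # argmax/argmin return the first occurrence -> earliest-latency tie-break
    i_p1 = np.flatnonzero(m_p1)[np.argmax(trace[m_p1])]
    i_n1 = np.flatnonzero(m_n1)[np.argmin(trace[m_n1])]
    return ErpComponents(
        p1_amplitude=float(trace[i_p1]), p1_latency=float(t[i_p1]),
        n1_amplitude=float(trace[i_n1]), n1_latency=float(t[i_n1]),
    )


def gating_ratio(n1_s2: float, n1_s1: float) -> float:
    """S2/S1 amplitude ratio; smaller means stronger sensory gating."""
    if n1_s1 == 0:
        raise ValueError("gating ratio undefined for zero S1 amplitude")
    return n1_s2 / n1_s1


def bandpass(
    recording: ContinuousRecording,
    low: float = 1.0,
    high: float = 100.0,
    order: int = 4,
) -> ContinuousRecording:
    """Optional zero-phase Butterworth band-pass (off by default upstream)."""
    sos = sp_signal.butter(order, [low, high], btype="bandpass", fs=recording.fs,
                           output="sos")
    filtered = sp_signal.sosfiltfilt(sos, recording.samples, axis=1)
    return ContinuousRecording(filtered, recording.fs,
                               list(recording.channel_labels),
                               recording.start_time)
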