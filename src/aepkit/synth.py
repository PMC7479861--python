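"""Synthetic EEG sessions and behavioural tables with known ground truth.

The generator writes a continuous single-channel (per region) recording as
the sum of:

* pink (1/f) background noise, scaled to a target standard deviation, with
  a 4-Hz delta rhythm whose amplitude dips after each tone (the late
  delta-band power decrease seen in auditory sessions);
* per-event response templates — a positive P1 deflection peaking ~20 ms
  post-tone, a negative N1 peaking ~40 ms, a ~30-Hz burst at 30–50 ms whose
  trial-to-trial phase is von-Mises distributed (concentration ``plf_kappa``;
  large kappa = phase-locked/evoked, kappa 0 = fully induced), a broadband
  10–100 Hz non-phase-locked burst, and an extra longer-latency (~55 ms)
  negative component on deviant tones.

Effect sizes of interest (genotype or drug contrasts) enter as multipliers
in :class:`EffectParams`: halving ``n1_scale`` halves the recovered N1;
``deviant_gain = 1`` makes deviants indistinguishable from standards (the
NMDA-antagonist condition); lowering ``plf_kappa`` reduces the
phase-locking factor without changing total burst power.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .paradigms import StimulusSchedule

__all__ = [
    "EffectParams",
    "SubjectRecord",
    "ContinuousRecording",
    "TemplateShapes",
    "synthesize_session",
    "make_cohort",
    "synthesize_behaviour",
    "BehaviourSpread",
]


@dataclass(frozen=True)
class TemplateShapes:
    """Deterministic shapes of the per-event response templates.

    Amplitudes in μV, latencies/widths in seconds. Only the N1 latency
    (~40 ms) and the deviant extra-component latency (40–70 ms band) are
    anchored to the auditory-evoked-potential literature; the rest are
    plausible fixed defaults.
    """

    p1_amp: float = 15.0
    p1_latency: float = 0.020
    p1_width: float = 0.005
    n1_amp: float = -30.0
    n1_latency: float = 0.040
    n1_width: float = 0.008
    burst_amp: float = 8.0
    burst_hz: float = 30.0
    burst_latency: float = 0.040
    burst_width: float = 0.008
    induced_amp: float = 8.0
    induced_band: tuple[float, float] = (10.0, 100.0)
    deviant_amp: float = -15.0
    deviant_latency: float = 0.055
    deviant_width: float = 0.010
    delta_hz: float = 4.0
    delta_rel_amp: float = 0.4  # relative to noise_sd
    delta_drop_centre: float = 0.325  # s post-event
    delta_drop_width: float = 0.060


@dataclass(frozen=True)
class EffectParams:
    """Per-subject multipliers on the response templates.

    ``s2_gain`` scales the whole response to the second tone of a pair
    (sensory gating); ``evoked_gain``/``induced_gain`` scale the
    phase-locked and non-phase-locked bursts; ``plf_kappa`` is the
    von-Mises concentration of the evoked-burst phase (np.inf allowed);
    ``late_delta_drop`` in [0, 1] is the fractional delta-amplitude dip
    after each tone.
    """

    p1_scale: float = 1.0
    n1_scale: float = 1.0
    s2_gain: float = 0.5
    plf_kappa: float = 5.0
    evoked_gain: float = 1.0
    induced_gain: float = 1.0
    deviant_gain: float = 2.0
    noise_sd: float = 5.0
    late_delta_drop: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p1_scale", "n1_scale", "s2_gain", "plf_kappa",
                     "evoked_gain", "induced_gain", "deviant_gain", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.late_delta_drop <= 1.0:
            raise ValueError("late_delta_drop must lie in [0, 1]")


#: Ketamine is modelled purely as "deviant response equals standard".
def ketamine(params: EffectParams) -> EffectParams:
    return replace(params, deviant_gain=1.0)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str  # "control" | "mutant"
    drug: str = "saline"  # "saline" | "ketamine"
    effect_params: EffectParams = field(default_factory=EffectParams)


@dataclass
class ContinuousRecording:
    """Channels x samples of μV signal with sampling-rate metadata."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_labels: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** -0.5  # amplitude ~ f^-1/2 -> power ~ 1/f
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def synthesize_session(
    schedule: StimulusSchedule,
    subject: SubjectRecord,
    fs: float = 1000.0,
    seed: int = 0,
    templates: TemplateShapes | None = None,
    channel_label: str = "frontal",
    tail: float = 1.0,
) -> ContinuousRecording:
    """Simulate one continuous recording for a stimulus schedule.

    ``fs`` must be at least 250 Hz so the 10–100 Hz induced band is
    representable. Identical arguments (including ``seed``) give a
    bit-identical recording.
    """
    if fs < 250.0:
        raise ValueError("fs must be >= 250 Hz to represent 100 Hz activity")
    tpl = templates or TemplateShapes()
    p = subject.effect_params
    if subject.drug == "ketamine":
        p = ketamine(p)
    rng = np.random.default_rng(seed)

    n = int(round((schedule.duration + tail) * fs))
    n = max(n, int(round(tail * fs)))
    time = np.arange(n) / fs
    x = np.zeros(n)

    # --- background: pink noise + delta rhythm with post-event dips -------
    if p.noise_sd > 0:
        x += p.noise_sd * _pink_noise(n, rng)
        delta_phase = rng.uniform(0, 2 * np.pi)
        delta = (tpl.delta_rel_amp * p.noise_sd
                 * np.sin(2 * np.pi * tpl.delta_hz * time + delta_phase))
        dip = np.zeros(n)
        reach = int(round(5 * tpl.delta_drop_width * fs))
        for ev in schedule.events:
            c = int(round((ev.onset + tpl.delta_drop_centre) * fs))
            lo, hi = max(c - reach, 0), min(c + reach, n)
            if hi > lo:
                dip[lo:hi] += _gauss(time[lo:hi],
                                     ev.onset + tpl.delta_drop_centre,
                                     tpl.delta_drop_width)
        np.clip(dip, 0.0, 1.0, out=dip)
        x += delta * (1.0 - p.late_delta_drop * dip)

    # --- per-event responses ---------------------------------------------
    # local template support: 0.5 s after each event covers every component
    half = int(round(0.5 * fs))
    t_local = np.arange(half) / fs
    p1 = tpl.p1_amp * _gauss(t_local, tpl.p1_latency, tpl.p1_width)
    n1 = tpl.n1_amp * _gauss(t_local, tpl.n1_latency, tpl.n1_width)
    burst_env = _gauss(t_local, tpl.burst_latency, tpl.burst_width)
    dev = tpl.deviant_amp * _gauss(t_local, tpl.deviant_latency,
                                   tpl.deviant_width)
    lo, hi = tpl.induced_band

    for ev in schedule.events:
        i0 = int(round(ev.onset * fs))
        i1 = min(i0 + half, n)
        m = i1 - i0
        if m <= 0:
            continue
        gain = p.s2_gain if ev.kind == "S2" else 1.0
        resp = gain * (p.p1_scale * p1[:m] + p.n1_scale * n1[:m])
        # phase-locked burst: sin carrier so the 40-ms sample is untouched
        if p.evoked_gain > 0:
            phi = 0.0 if np.isinf(p.plf_kappa) else rng.vonmises(0.0, p.plf_kappa)
            carrier = np.sin(
                2 * np.pi * tpl.burst_hz * (t_local[:m] - tpl.burst_latency) + phi
            )
            resp = resp + gain * p.evoked_gain * tpl.burst_amp * burst_env[:m] * carrier
        # non-phase-locked broadband burst: random tone in 10-100 Hz,
        # uniform phase -> averages out across trials
        if p.induced_gain > 0:
            f_ind = rng.uniform(lo, min(hi, 0.45 * fs))
            phi_ind = rng.uniform(0, 2 * np.pi)
            carrier = np.cos(
                2 * np.pi * f_ind * (t_local[:m] - tpl.burst_latency) + phi_ind
            )
            resp = resp + gain * p.induced_gain * tpl.induced_amp * burst_env[:m] * carrier
        if ev.kind == "deviant" and p.deviant_gain != 1.0:
            resp = resp + (p.deviant_gain - 1.0) * dev[:m]
        x[i0:i1] += resp

    return ContinuousRecording(x[None, :], fs, [channel_label])


def make_cohort(
    n_per_group: int,
    schedule: StimulusSchedule,
    control_params: EffectParams,
    mutant_params: EffectParams,
    fs: float = 1000.0,
    seed: int = 0,
    drug: str = "saline",
    templates: TemplateShapes | None = None,
) -> list[tuple[SubjectRecord, ContinuousRecording, StimulusSchedule]]:
    """Simulate ``2 * n_per_group`` sessions (control then mutant).

    Per-subject seeds are spawned deterministically from ``seed``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    children = np.random.SeedSequence(seed).spawn(2 * n_per_group)
    sessions = []
    for i in range(2 * n_per_group):
        group = "control" if i < n_per_group else "mutant"
        params = control_params if group == "control" else mutant_params
        subject = SubjectRecord(f"{group}{i % n_per_group + 1:02d}", group,
                                drug, params)
        sub_seed = int(children[i].generate_state(1)[0] % (2**31))
        rec = synthesize_session(schedule, subject, fs, sub_seed, templates)
        sessions.append((subject, rec, schedule))
    return sessions


@dataclass(frozen=True)
class BehaviourSpread:
    """Noise parameters for the behavioural generator (0 = deterministic)."""

    startle_cv: float = 0.2  # trial-to-trial CV of startle Vmax
    weight_sd: float = 2.0  # g
    exploration_sd: float = 3.0  # s
    ct_sd: float = 0.15  # cycles

    @classmethod
    def none(cls) -> "BehaviourSpread":
        return cls(0.0, 0.0, 0.0, 0.0)


_QPCR_GENES = {"Grin1": 25.0, "Grin2a": 26.0, "Grin2b": 26.5, "Grin2c": 28.0}
_HK_BASE = (20.0, 21.0, 19.0)  # B2m, beta-actin, Gapdh baseline cycles


def synthesize_behaviour(
    n_per_group: int = 7,
    true_ppi_by_prepulse: dict[str, tuple[float, float, float]] | None = None,
    startle_mean: dict[str, float] | None = None,
    exploration_ri: dict[str, dict[int, float]] | None = None,
    grin1_fold: dict[str, float] | None = None,
    spread: BehaviourSpread | None = None,
    n_trials_per_kind: int = 10,
    body_weight_mean: float = 30.0,
    total_exploration: float = 30.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate startle, object-exploration and qPCR tables for two groups.

    Defaults emulate the study conditions: mutants startle about twice as
    hard, show a ~30% relative reduction in prepulse inhibition at each
    prepulse level, explore the novel object at chance, and express Grin1
    at 0.6-fold the control level; the other NMDA-receptor subunits are
    unchanged.

    Returns ``(startle, exploration, qpcr)`` DataFrames. With
    ``spread=BehaviourSpread.none()`` every per-subject metric equals its
    configured truth exactly.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    ppi = true_ppi_by_prepulse or {
        "control": (50.0, 60.0, 70.0),
        "mutant": (35.0, 42.0, 49.0),
    }
    for levels in ppi.values():
        for v in levels:
            if not (-100.0 < v <= 100.0):
                raise ValueError("true %PPI values must lie in (-100, 100]")
    startle = startle_mean or {"control": 500.0, "mutant": 1000.0}
    ri = exploration_ri or {
        "control": {15: 60.0, 90: 67.0},
        "mutant": {15: 52.0, 90: 50.0},
    }
    fold = grin1_fold or {"control": 1.0, "mutant": 0.6}
    sp = spread or BehaviourSpread()
    rng = np.random.default_rng(seed)

    prepulse_kinds = ("prepulse4", "prepulse8", "prepulse16")
    startle_rows, explore_rows, qpcr_rows = [], [], []
    for group in ("control", "mutant"):
        for s in range(n_per_group):
            sid = f"{group}{s + 1:02d}"
            weight = body_weight_mean + sp.weight_sd * rng.standard_normal()
            weight = max(weight, 10.0)
            base = startle[group] * weight / body_weight_mean
            for kind, true_ppi in zip(
                ("pulse_alone", *prepulse_kinds), (0.0, *ppi[group])
            ):
                mean_vmax = base * (1.0 - true_ppi / 100.0)
                for _ in range(n_trials_per_kind):
                    vmax = mean_vmax * (1.0 + sp.startle_cv * rng.standard_normal())
                    startle_rows.append(
                        (sid, group, kind, max(vmax, 0.0), weight)
                    )
            # half the cohort per retention delay
            delay = 15 if s < (n_per_group + 1) // 2 else 90
            t_novel = (ri[group][delay] / 100.0) * total_exploration
            t_fam = total_exploration - t_novel
            t_novel = max(t_novel + sp.exploration_sd * rng.standard_normal(), 0.0)
            t_fam = max(t_fam + sp.exploration_sd * rng.standard_normal(), 0.0)
            explore_rows.append((sid, group, delay, t_novel, t_fam))
            hk = tuple(
                c + sp.ct_sd * rng.standard_normal() for c in _HK_BASE
            )
            for gene, base_ct in _QPCR_GENES.items():
                shift = -np.log2(fold[group]) if gene == "Grin1" else 0.0
                ct = base_ct + shift + sp.ct_sd * rng.standard_normal()
                qpcr_rows.append((sid, group, gene, ct, *hk))

    startle_df = pd.DataFrame(
        startle_rows,
        columns=["subject_id", "group", "trial_kind", "vmax", "body_weight"],
    )
    explore_df = pd.DataFrame(
        explore_rows,
        columns=["subject_id", "group", "delay_min", "t_novel", "t_familiar"],
    )
    qpcr_df = pd.DataFrame(
        qpcr_rows,
        columns=["subject_id", "group", "gene", "ct", "hk_ct1", "hk_ct2", "hk_ct3"],
    )
    return startle_df, explore_df, qpcr_df
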