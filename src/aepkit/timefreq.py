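"""Complex Morlet wavelet maps: total power, evoked power, phase locking.

The wavelet at central frequency f0 is

    w(t, f0) = A exp(-t^2 / (2 sigma_t^2)) exp(2 i pi f0 t),

a Gaussian of SD ``sigma_t`` in time and, by the Fourier pair of a
Gaussian, of SD ``sigma_f = 1 / (2 pi sigma_t)`` around f0 in frequency.
The family is fixed by the ratio f0/sigma_f = 1 (a very broadband,
single-cycle-class wavelet) with central frequencies log-spaced from
0.5 to 100 Hz, and unit-energy normalisation A = (sigma_t sqrt(pi))^(-1/2)
so power is comparable across frequencies.

Three trial-set summaries are produced per pixel (frequency x time):

* **total power** — mean over trials of |coefficient|^2; phase-locked plus
  induced activity.
* **evoked power** — |coefficient|^2 of the trial-averaged waveform; only
  activity phase-locked to the event survives the average.
* **phase-locking factor (PLF)** — modulus of the mean unit-magnitude
  coefficient across trials; 0 = random phase, 1 = perfect synchrony.

Power maps may be normalised per frequency by a pre-stimulus baseline
(ratio units; 1 = no change). Pixels whose wavelet support overlaps an
epoch edge are flagged in a cone-of-influence mask, not trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .erp import EpochedTrials, ErpWaveform, grand_average

__all__ = [
    "WaveletFamily",
    "TFCoefficients",
    "TimeFrequencyMap",
    "make_wavelet_family",
    "wavelet_transform",
    "total_power",
    "evoked_power",
    "phase_locking_factor",
    "BANDS",
]

#: Reporting band edges (Hz): delta ~4 Hz, beta 13-30, gamma 30-70.
BANDS = {"delta": (2.0, 6.0), "beta": (13.0, 30.0), "gamma": (30.0, 70.0)}

MAP_KINDS = ("total", "evoked", "plf", "difference", "pvalue")


@dataclass
class WaveletFamily:
    """Log-spaced complex Morlet kernels with f0/sigma_f = 1."""

    f0: np.ndarray  # Hz, strictly increasing, constant ratio
    sigma_f: np.ndarray  # Hz (spectral SD; equals f0)
    sigma_t: np.ndarray  # s
    amplitude: np.ndarray  # unit-energy normalisation A per f0
    fs: float
    n_sigma: float  # kernel support is +- n_sigma * sigma_t
    kernels: list[np.ndarray]  # complex, odd length, centred

    @property
    def n_freqs(self) -> int:
        return self.f0.size

    def half_widths(self) -> np.ndarray:
        """Kernel half-width in samples per frequency."""
        return np.array([(k.size - 1) // 2 for k in self.kernels])

    def nearest(self, f: float) -> int:
        """Index of the central frequency nearest ``f``."""
        return int(np.argmin(np.abs(self.f0 - f)))


@dataclass
class TFCoefficients:
    """Per-trial complex wavelet coefficients (trials x freqs x times)."""

    values: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    fs: float
    coi: np.ndarray  # (freqs, times) bool; True = within edge influence

    def __post_init__(self) -> None:
        if self.values.shape[1:] != (self.freq_axis.size, self.time_axis.size):
            raise ValueError("coefficient axes do not match value dimensions")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


@dataclass
class TimeFrequencyMap:
    """Real-valued frequencies x times map of one kind."""

    values: np.ndarray
    kind: str
    freq_axis: np.ndarray
    time_axis: np.ndarray
    n_trials: int
    baseline_window: tuple[float, float] | None = None
    coi: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if self.values.shape != (self.freq_axis.size, self.time_axis.size):
            raise ValueError("map axes do not match value dimensions")

    def pixel(self, f: float, t: float) -> float:
        """Value at the pixel nearest (f Hz, t s)."""
        i = int(np.argmin(np.abs(self.freq_axis - f)))
        j = int(np.argmin(np.abs(self.time_axis - t)))
        return float(self.values[i, j])

    def band_window_mean(self, band: tuple[float, float],
                         window: tuple[float, float]) -> float:
        fm = (self.freq_axis >= band[0]) & (self.freq_axis <= band[1])
        tm = (self.time_axis >= window[0]) & (self.time_axis <= window[1])
        if not fm.any() or not tm.any():
            raise ValueError("empty band or window selection")
        return float(np.nanmean(self.values[np.ix_(fm, tm)]))


def make_wavelet_family(
    f_min: float = 0.5,
    f_max: float = 100.0,
    n_steps: int = 81,
    fs: float = 1000.0,
    n_sigma: float = 5.0,
) -> WaveletFamily:
    """Construct the default Morlet family (f0/sigma_f = 1, unit energy).

    ``n_steps`` central frequencies are geometrically spaced from ``f_min``
    to ``f_max`` inclusive. Kernels are truncated at ``n_sigma`` time-SDs.
    """
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    if f_max > fs / 2:
        raise ValueError(f"f_max={f_max} Hz exceeds the Nyquist frequency {fs / 2} Hz")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    f0 = np.geomspace(f_min, f_max, n_steps)
    sigma_f = f0.copy()  # the f0/sigma_f = 1 family contract
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    amplitude = (sigma_t * np.sqrt(np.pi)) ** -0.5
    kernels = []
    for f, st, a in zip(f0, sigma_t, amplitude):
        half = int(np.ceil(n_sigma * st * fs))
        t = np.arange(-half, half + 1) / fs
        kernels.append(a * np.exp(-t**2 / (2 * st**2)) * np.exp(2j * np.pi * f * t))
    return WaveletFamily(f0, sigma_f, sigma_t, amplitude, fs, n_sigma, kernels)


def _transform_array(data: np.ndarray, family: WaveletFamily) -> np.ndarray:
    """Wavelet transform of (n_series, n_samples) -> (n_series, n_freqs, n_samples).

    Coefficient(t) = integral x(tau) conj(w(tau - t)) dtau, approximated by
    discrete correlation times the sample period.
    """
    n_series, n_samp = data.shape
    out = np.empty((n_series, family.n_freqs, n_samp), dtype=complex)
    dt = 1.0 / family.fs
    for i, kernel in enumerate(family.kernels):
        # correlation with w == convolution with conj(w) reversed
        out[:, i, :] = sp_signal.fftconvolve(
            data, np.conj(kernel)[::-1][None, :], mode="same", axes=1
        ) * dt
    return out


def _coi_mask(family: WaveletFamily, n_samp: int) -> np.ndarray:
    coi = np.zeros((family.n_freqs, n_samp), dtype=bool)
    idx = np.arange(n_samp)
    for i, hw in enumerate(family.half_widths()):
        coi[i] = (idx < hw) | (idx >= n_samp - hw)
    return coi


def wavelet_transform(
    trials: EpochedTrials,
    family: WaveletFamily,
    channel: str | int | None = None,
) -> TFCoefficients:
    """Per-trial complex Morlet transform of one channel."""
    if abs(trials.fs - family.fs) > 1e-9:
        raise ValueError("trial and wavelet-family sampling rates differ")
    ch = trials.channel_index(channel)
    values = _transform_array(trials.data[:, ch, :], family)
    return TFCoefficients(values, family.f0.copy(), trials.time_axis.copy(),
                          family.fs, _coi_mask(family, trials.time_axis.size))


def _baseline_normalise(
    power: np.ndarray,
    time_axis: np.ndarray,
    baseline_window: tuple[float, float],
) -> np.ndarray:
    lo, hi = baseline_window
    if not lo < hi:
        raise ValueError("baseline window must have positive length")
    mask = (time_axis >= lo) & (time_axis <= hi)
    if not mask.any():
        raise ValueError("baseline window lies outside the time axis")
    base = power[:, mask].mean(axis=1, keepdims=True)
    return power / base


def total_power(
    coeffs: TFCoefficients,
    baseline_window: tuple[float, float] | None = None,
) -> TimeFrequencyMap:
    """Trial-mean |coefficient|^2 per pixel, optionally baseline-ratioed."""
    if coeffs.n_trials < 1:
        raise ValueError("total power requires at least one trial")
    power = np.mean(np.abs(coeffs.values) ** 2, axis=0)
    if baseline_window is not None:
        power = _baseline_normalise(power, coeffs.time_axis, baseline_window)
    return TimeFrequencyMap(power, "total", coeffs.freq_axis, coeffs.time_axis,
                            coeffs.n_trials, baseline_window, coeffs.coi)


def evoked_power(
    trials: EpochedTrials,
    family: WaveletFamily,
    channel: str | int | None = None,
    baseline_window: tuple[float, float] | None = None,
) -> TimeFrequencyMap:
    """Wavelet power of the trial-averaged waveform (phase-locked activity)."""
    avg: ErpWaveform = grand_average(trials)
    ch = trials.channel_index(channel)
    coeff = _transform_array(avg.mean[ch][None, :], family)[0]
    power = np.abs(coeff) ** 2
    if baseline_window is not None:
        power = _baseline_normalise(power, trials.time_axis, baseline_window)
    return TimeFrequencyMap(power, "evoked", family.f0.copy(),
                            trials.time_axis.copy(), avg.n_trials,
                            baseline_window, _coi_mask(family, trials.time_axis.size))


def phase_locking_factor(coeffs: TFCoefficients) -> TimeFrequencyMap:
    """Modulus of the trial-mean unit-magnitude coefficient, in [0, 1].

    Trials with zero magnitude at a pixel carry no phase and are excluded
    there; pixels undefined in every trial are NaN (their count is exposed
    as ``map.n_undefined``). No small-sample bias correction is applied.
    """
    if coeffs.n_trials < 1:
        raise ValueError("PLF requires at least one trial")
    mag = np.abs(coeffs.values)
    defined = mag > 0
    unit = np.zeros_like(coeffs.values)
    np.divide(coeffs.values, mag, out=unit, where=defined)
    counts = defined.sum(axis=0)
    with np.errstate(invalid="ignore"):
        plf = np.abs(unit.sum(axis=0)) / counts
    plf[counts == 0] = np.nan
    result = TimeFrequencyMap(plf, "plf", coeffs.freq_axis, coeffs.time_axis,
                              coeffs.n_trials, None, coeffs.coi)
    result.n_undefined = int((counts == 0).sum())
    return result
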