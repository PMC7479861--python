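# Methods

This note records the models implemented in `aepkit`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data can and cannot establish about real recordings.

## Stimulus paradigms

Paired-pulse sessions place S1 at trial start and S2 `s1_s2_gap` later
(default 0.5 s, onset-to-onset); the next trial's S1 follows the previous
S2 by `inter_trial_gap` (default 10 s), also onset-to-onset. An
offset-to-onset reading of the inter-trial gap (adding the 10-ms tone
duration) is available via `iti_from_offset=True`; the two differ by one
tone duration per trial and have no effect on any downstream measure.
Oddball trials contain `n_standard` standards (default 24) and one
deviant at 500-ms onset asynchrony; the deviant is placed last by default
because gating of the position is immaterial to the per-kind analyses,
with a seeded uniformly-random position available
(`deviant_position="random"`). Trial 1 starts at 0 s by convention.

## Synthetic EEG

One channel per region is generated at `fs` (default 1000 Hz; 500 Hz is
used for the large test cohorts — both are comfortably above twice the
100-Hz analysis band). The signal is a sum of:

* **1/f background** — spectrally shaped Gaussian noise (power ∝ 1/f),
  scaled to `noise_sd` μV (default 5 μV, roughly a 6:1 N1-to-noise
  amplitude ratio, which leaves single trials visibly noisy but
  100-trial averages clean);
* **delta rhythm** — a 4-Hz sinusoid at 0.4·`noise_sd` whose amplitude
  dips by `late_delta_drop` (default 0.5) inside a Gaussian window
  centred 325 ms after each tone, emulating the late delta-band power
  decrease. The amplitude is tied to `noise_sd` so a noise-free
  simulation is fully deterministic;
* **event templates** — Gaussian-windowed deflections: P1 (+15 μV, peak
  20 ms, SD 5 ms), N1 (−30 μV, peak 40 ms, SD 8 ms; only the ~40-ms
  latency is anchored to the auditory-evoked-potential literature, the
  amplitudes are plausible fixed defaults), and on deviants an extra
  negative component (−15 μV, peak 55 ms, SD 10 ms) scaled by
  `deviant_gain − 1`, so `deviant_gain = 1` makes deviants identical to
  standards — this single switch is the entire model of the
  NMDA-antagonist (ketamine) condition;
* **phase-locked burst** — a 30-Hz sine carrier under the same Gaussian
  envelope as N1, amplitude 8 μV × `evoked_gain`, whose per-trial phase
  is von-Mises distributed with concentration `plf_kappa`. κ → ∞ gives a
  fully evoked (deterministic) burst, κ = 0 a fully induced one, so one
  parameter spans the total/evoked/PLF contrasts. The sine carrier is
  zero at its envelope centre, so the burst never contaminates the
  40-ms N1 sample;
* **induced burst** — a tone drawn uniformly from 10–100 Hz with uniform
  phase, same envelope, amplitude 8 μV × `induced_gain`; it contributes
  to total but (in expectation) not to evoked power or PLF. No value for
  the induced effect size is anchored anywhere; its default (1.0) is a
  free choice.

Responses to S2 are scaled by `s2_gain` (default 0.5, i.e. healthy
gating). Every generator is a pure function of its inputs and a seed;
cohorts derive per-subject seeds from one master seed via
`numpy.random.SeedSequence.spawn`.

**What the simulator does not model:** volume conduction and electrode
montage (the five-electrode layout exists only as channel labels),
artefacts (blinks, movement, mains hum), non-stationary background state,
latency jitter of the templates, and any pharmacokinetics. Passing tests
therefore establish that the *analysis* recovers effects of the assumed
shape at realistic SNR — not that real mouse EEG has that shape.

## Epoching and centering

Epochs are inclusive sample ranges `round(start·fs) … round(end·fs)`
around `round(onset·fs)`; events whose window leaves the recording are
dropped and counted (`n_dropped`). The default centering is
*anchor-point*: the trace value at each anchor is subtracted from the
segment that anchor governs (samples before the second anchor use the
first anchor's offset, and so on), which forces the trace through 0 μV at
every anchor exactly. This is a literal implementation of centering a
paired-pulse epoch "at 0 and 500 ms to 0 μV"; a conventional
pre-stimulus-mean baseline (`prestim_mean`) and raw mode (`none`) are
provided, and the mode is recorded on the epochs object. Inputs are
assumed band-limited already; an optional zero-phase 1–100 Hz Butterworth
band-pass (`aepkit.erp.bandpass`) is off by default.

P1/N1 are the windowed maximum/minimum (defaults 10–30 ms and 25–80 ms;
the N1 window covers both the 40-ms peak and the 40–70-ms deviant
component), ties broken to the earliest latency. Components are computed
per subject, and group summaries are taken over per-subject values —
consistent with rank-based group tests on N1.

## Wavelet family

The family contract is f₀/σ_f = 1 with σ_f the *spectral* standard
deviation of the kernel. Since the Fourier transform of a Gaussian with
time SD σt is a Gaussian with frequency SD 1/(2πσt), the implementation
uses σt = 1/(2πσ_f); a Gaussian fit to any implemented kernel's magnitude
spectrum recovers σ_f = f₀ to well under 1%. A is the unit-energy
normalisation (σt√π)^(−1/2), making power comparable across frequencies.
Defaults: 81 log-spaced frequencies from 0.5 to 100 Hz, kernels truncated
at ±5σt, convolution by FFT with edge pixels inside the cone of influence
flagged (not trimmed).

Two consequences of this very broadband (σ_f = f₀) family are worth
knowing: a pure sinusoid's response across f₀ peaks *below* the stimulus
frequency (the unit-energy prefactor scales as f₀^(−1/2)), and the
negative-frequency line of a real sinusoid contributes measurably at high
f₀. The test suite asserts the closed-form Gaussian spectral response
including both effects. No zero-mean (admissibility) correction is
applied: at one cycle the kernel has a DC leak, which baseline
normalisation and within-family comparisons absorb.

Power maps may be normalised per frequency row by its mean over a
pre-stimulus baseline window (default −200 to −50 ms scaled to the epoch;
ratio units, 1 = no change); whether to normalise per frequency or
globally was an open choice — per frequency was chosen because the 1/f
background otherwise dominates the display range. PLF applies no
small-sample bias correction; its null expectation at N trials is
~1/√N, which the tests use explicitly. Pixels where a trial has zero
magnitude are excluded from that pixel's average; pixels undefined in
every trial are NaN with a count exposed on the map.

## Permutation inference

The exchangeable unit is the subject (whole map) — matching a
between-genotype design; trials are never permuted. The statistic is the
pixelwise difference of group means. With B sampled relabelings the
add-one estimator p = (1+k)/(B+1) is used (minimum p = 1/(B+1), default
B = 999); when the number of distinct relabelings M = C(n, n_a) ≤ B the
null is enumerated exhaustively and p = k/M with the identity included
(minimum 1/M). Ties count toward the tail, with a 10⁻⁹ relative
tolerance so that exact ties (complement relabelings at equal group
sizes) are counted regardless of float round-off. The default output is
the uncorrected pixelwise p map (as in significance heat maps thresholded
at p < 0.05); an optional max-statistic mode provides familywise control
and is clearly a departure from that convention.

The Wilcoxon rank-sum test reports the first sample's rank sum with
midranks. For combined n ≤ 20 the p value is exact by enumeration of all
C(n, n₁) label assignments conditional on the observed (possibly tied)
ranks; above that, a tie-corrected normal approximation without
continuity correction is used.

## Behavioural metrics

Startle amplitudes are normalised as Vmax/body-weight before any PPI
computation (the functional form of "normalised for body weight" is not
fixed anywhere; a ratio is the simplest choice and cancels exactly in
%PPI). Per-subject %PPI at each prepulse level is the mean over trials of
trial-level %PPI against the subject's mean pulse-alone response
(`mean_of_trials`); computing one %PPI from mean responses (`of_means`)
is also available — the two agree when trial noise is symmetric.
Negative %PPI (facilitation) is preserved, never clipped. ΔΔCt
fold-change tables reference each gene's mean ΔCt in a designated
reference group, so that group's mean fold is 1 by construction.

## Problem sizes in the test suite

The statistical acceptance checks use cohort sizes chosen to make their
targets meaningful at desk scale: 500 null cohorts of 2×5 subjects
(6 trials, 21 frequencies, 0.4-s epochs at 500 Hz, exhaustive 252-way
enumeration — null p is then uniform on {1/252, …, 1} and the expected
pixelwise rate below 0.05 is 12/252 ≈ 0.048) for the type-I-error check,
and 50 replicate cohorts of 7 vs 7 subjects with 200 trials each for
effect recovery. Long inter-trial gaps carry no information once epochs
do not overlap, so these simulations shorten the gap to 1 s.

## Known limitations

* Single synthetic channel per region; no spatial structure.
* The exact-enumeration Wilcoxon path materialises C(n, n₁) index rows;
  fine to n = 20, not meant beyond.
* The EDF path is read-only (via `mne`); recordings are written as flat
  binary float32 + JSON sidecar.
* Cluster-based permutation correction is out of scope; the max-statistic
  option is the only familywise control offered.
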