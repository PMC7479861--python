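# aepkit

Analysis of auditory evoked potentials (AEPs) from rodent EEG, built for
studies of sensory gating and deviance detection: paired-pulse and
oddball (mismatch-negativity, MMN) stimulus paradigms, event-related
potential (ERP) averaging with P1/N1 component extraction, complex Morlet
wavelet time-frequency decomposition (total power, evoked power and the
phase-locking factor), nonparametric permutation inference on
time-frequency maps, and the behavioural statistics that usually
accompany such studies (%PPI, recognition index, ΔΔCt fold change).

Because raw animal recordings are rarely shareable, the package ships a
synthetic-EEG and behaviour generator with known ground truth. Every
analysis stage is exercised end to end on simulated cohorts in which the
injected effects (N1 amplitude reduction, phase-locking suppression,
abolished deviant response, PPI deficits, reduced Grin1 expression) are
recoverable by construction, so the pipeline's statistical behaviour —
not just its plumbing — is tested.

## The model and statistics

**Paradigms.** A paired-pulse session presents identical tone pairs
(S1, S2; 1500 Hz, 90 dB, 10 ms) separated by 500 ms, one pair per trial,
1250 trials per session. An oddball session presents 24 `standard` tones
(1500 Hz) and one `deviant` (2000 Hz) per trial at 500-ms onset
asynchrony, 360 trials per session.

**ERP components.** Epochs are cut around tone onsets and anchor-point
centred (the trace value at each anchor — 0 and 500 ms for a pair — is
forced to 0 μV). P1 is the maximal positive and N1 the maximal negative
deflection in configurable windows; N1 peaks near 40 ms. Sensory gating
is the ratio N1(S2)/N1(S1); smaller means stronger gating.

**Time-frequency maps.** The wavelet at central frequency f₀ is

```
w(t, f0) = A · exp(−t² / 2σt²) · exp(2iπ f0 t)
```

with spectral SD σ_f, time SD σt = 1/(2π σ_f), the family fixed by
f₀/σ_f = 1 over 81 log-spaced frequencies from 0.5 to 100 Hz, and A
chosen for unit energy. Per pixel (frequency × time):

* total power — mean over trials of |coefficient|²,
* evoked power — |coefficient|² of the trial-averaged waveform,
* phase-locking factor — PLF = |⟨c/|c|⟩_trials| ∈ [0, 1]; magnitudes are
  set to 1 so only phase synchrony across trials survives.

**Inference.** Group maps are compared by a subject-level permutation
test (statistic: pixelwise difference of group means; 999 relabelings by
default, exhaustive enumeration when possible; add-one p estimator for
sampled runs). Scalar components use the Wilcoxon rank-sum test with
exact enumeration for combined n ≤ 20.

**Behaviour.** %PPI = 100 · (ASR_pulse-alone − ASR_prepulse+pulse) /
ASR_pulse-alone on weight-normalised startle amplitudes;
RI = T_novel/(T_novel + T_familiar) · 100; ΔCt normalises a target Ct to
the geometric mean of three housekeeping Cts and fold change is
2^(−ΔΔCt).

## Worked example

```python
import aepkit as ak

config = ak.load_config(overrides={
    "seed": 7,
    "paradigm": {"n_trials": 100, "inter_trial_gap": 1.5},
    "simulator": {"n_per_group": 5},   # mutants: n1_scale 0.5, kappa 1
})
manifest = ak.run_pipeline(config, "runs/example")
print(manifest["significant_pixel_fraction"])
```

which prints

```
{'total': 0.05859476276899144, 'evoked': 0.0622245268343272, 'plf': 0.07363235675395385}
```

the fraction of map pixels with permutation p < 0.05 for each measure
(with only 5 subjects per group and exhaustive enumeration over 252
relabelings, the smallest attainable p is 1/252 ≈ 0.004, so power is
limited at this size). `runs/example/components.tsv` holds the
per-subject ERP components; `summary.tsv` aggregates them:

```
n1_uV        control   -31.52772401
n1_uV        mutant    -17.38022719
s2_s1_ratio  control   0.5297248314
s2_s1_ratio  mutant    0.5233615605
```

The mutant/control N1 ratio (−17.4/−31.5 ≈ 0.55) recovers the injected
`n1_scale = 0.5` — the "nearly twofold lower N1" regime — while the
S2/S1 gating ratio matches the simulated gating gain of 0.5 in both
groups. Per-group total/evoked/PLF maps, difference maps and p maps are
written as TSV matrices alongside.

The same stages run from the shell:

```sh
aepkit run-all  --seed 7 --out runs/full
aepkit simulate --seed 7 --out runs/sim
aepkit erp      --in runs/sim --out runs/erp
aepkit tfr      --in runs/sim --out runs/tfr
aepkit permtest --in runs/tfr --out runs/perm --measure plf
aepkit behaviour --seed 7 --out runs/beh
```

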