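"""On-disk formats: recordings (flat binary + JSON sidecar, or EDF input),
time-frequency maps and ERP tables as TSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import ContinuousRecording
from .timefreq import TimeFrequencyMap

__all__ = [
    "write_recording",
    "read_recording",
    "read_recording_edf",
    "write_map",
    "read_map",
    "write_erp_waveform",
]


def write_recording(rec: ContinuousRecording, prefix) -> tuple[Path, Path]:
    """Write μV samples as float32 little-endian raw + a JSON sidecar."""
    prefix = Path(prefix)
    dat = prefix.with_suffix(".dat")
    meta = prefix.with_suffix(".json")
    rec.samples.astype("<f4").tofile(dat)
    meta.write_text(json.dumps({
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "n_channels": rec.samples.shape[0],
        "n_samples": rec.samples.shape[1],
        "units": "uV",
        "dtype": "<f4",
        "start_time": rec.start_time,
    }, indent=1))
    return dat, meta


def read_recording(prefix) -> ContinuousRecording:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.fromfile(prefix.with_suffix(".dat"), dtype=meta["dtype"])
    data = data.reshape(meta["n_channels"], meta["n_samples"]).astype(float)
    return ContinuousRecording(data, meta["fs"], meta["channel_labels"],
                               meta.get("start_time", 0.0))


def read_recording_edf(path) -> ContinuousRecording:
    """Read an EDF recording (requires the optional ``mne`` dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF input requires mne (pip install aepkit[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return ContinuousRecording(raw.get_data() * 1e6, float(raw.info["sfreq"]),
                               list(raw.ch_names))


def write_map(tfmap: TimeFrequencyMap, path) -> Path:
    """Write a map as TSV: metadata comments, time header row, freq column."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# kind={tfmap.kind}\tn_trials={tfmap.n_trials}\n")
        if tfmap.baseline_window is not None:
            lo, hi = tfmap.baseline_window
            fh.write(f"# baseline_window={lo:.17g},{hi:.17g}\n")
        fh.write("freq_hz\t" + "\t".join(f"{t:.17g}" for t in tfmap.time_axis) + "\n")
        for f, row in zip(tfmap.freq_axis, tfmap.values):
            fh.write(f"{f:.17g}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    return path


def read_map(path) -> TimeFrequencyMap:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            for item in line.lstrip("# ").strip().split("\t"):
                k, v = item.split("=", 1)
                meta[k] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t")
    freq = frame["freq_hz"].to_numpy(float)
    times = np.array([float(c) for c in frame.columns[1:]])
    values = frame.iloc[:, 1:].to_numpy(float)
    baseline = None
    if "baseline_window" in meta:
        lo, hi = meta["baseline_window"].split(",")
        baseline = (float(lo), float(hi))
    return TimeFrequencyMap(values, meta["kind"], freq, times,
                            int(meta["n_trials"]), baseline)


def write_erp_waveform(waveform, path) -> Path:
    """Write an ERP as TSV: time plus one μV column per channel."""
    path = Path(path)
    labels = waveform.channel_labels or [
        f"ch{i}" for i in range(waveform.mean.shape[0])
    ]
    frame = pd.DataFrame({"time_s": waveform.time_axis})
    for label, row in zip(labels, waveform.mean):
        frame[f"{label}_uV"] = row
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path
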