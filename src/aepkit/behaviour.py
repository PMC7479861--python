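"""Behavioural and expression statistics as pure functions.

* %PPI — prepulse inhibition of the acoustic startle response,
  ``100 * (ASR_pulse_alone - ASR_prepulse_pulse) / ASR_pulse_alone``,
  computed on weight-normalised startle amplitudes (Vmax / body weight).
  Negative values (prepulse facilitation) are preserved.
* RI — novel-object recognition index, ``T_novel / (T_novel + T_familiar)
  * 100``; 50% is chance.
* ddCt — relative qPCR expression: dCt normalises the target Ct to the
  geometric mean of three housekeeping Cts, ddCt subtracts a reference
  dCt, and fold change is 2^(-ddCt).

Table-level wrappers aggregate trial rows to per-subject metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean

__all__ = [
    "FoldChange",
    "percent_ppi",
    "recognition_index",
    "delta_delta_ct",
    "ppi_table",
    "recognition_table",
    "fold_change_table",
]

PREPULSE_LEVELS = {"prepulse4": 4, "prepulse8": 8, "prepulse16": 16}


@dataclass(frozen=True)
class FoldChange:
    gene: str
    delta_ct: float  # cycles
    delta_delta_ct: float  # cycles
    fold: float  # 2^(-ddCt), > 0


def percent_ppi(asr_pulse_alone: float, asr_prepulse_pulse: float) -> float:
    """Percent prepulse inhibition of the startle response.

    May be negative (facilitation); equals 100% when the prepulse trial
    shows no startle at all.
    """
    if asr_pulse_alone <= 0:
        raise ValueError("pulse-alone startle must be positive")
    return 100.0 * (asr_pulse_alone - asr_prepulse_pulse) / asr_pulse_alone


def recognition_index(t_novel: float, t_familiar: float) -> float:
    """Novel-object time as a percentage of total object time (50% = chance)."""
    if t_novel < 0 or t_familiar < 0:
        raise ValueError("exploration times must be non-negative")
    total = t_novel + t_familiar
    if total == 0:
        raise ValueError("recognition index undefined without any exploration")
    return 100.0 * t_novel / total


def delta_delta_ct(
    ct_target: float,
    hk_cts: tuple[float, float, float],
    reference_delta_ct: float,
    gene: str = "",
) -> FoldChange:
    """ddCt relative expression against three housekeeping genes."""
    if ct_target <= 0 or any(c <= 0 for c in hk_cts):
        raise ValueError("Ct values must be positive")
    d_ct = float(ct_target - gmean(hk_cts))
    dd_ct = d_ct - reference_delta_ct
    return FoldChange(gene, d_ct, dd_ct, float(2.0 ** (-dd_ct)))


def ppi_table(
    startle: pd.DataFrame,
    mode: str = "mean_of_trials",
) -> pd.DataFrame:
    """Per-subject %PPI per prepulse level from a startle-trial table.

    Expects columns ``subject_id, trial_kind, vmax, body_weight`` (and
    optionally ``group``). Vmax is weight-normalised before anything else.
    ``mode="mean_of_trials"`` averages trial-level %PPI values against the
    subject's mean pulse-alone response; ``"of_means"`` computes a single
    %PPI from the mean prepulse-trial response.
    """
    if mode not in ("mean_of_trials", "of_means"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    df = startle.copy()
    df["asr"] = df["vmax"] / df["body_weight"]
    rows = []
    for sid, sub in df.groupby("subject_id", sort=False):
        alone = sub.loc[sub["trial_kind"] == "pulse_alone", "asr"]
        if alone.empty:
            raise ValueError(f"subject {sid!r} has no pulse-alone trials")
        ref = float(alone.mean())
        group = sub["group"].iloc[0] if "group" in sub else None
        for kind, level in PREPULSE_LEVELS.items():
            pp = sub.loc[sub["trial_kind"] == kind, "asr"]
            if pp.empty:
                continue
            if mode == "mean_of_trials":
                value = float(np.mean([percent_ppi(ref, v) for v in pp]))
            else:
                value = percent_ppi(ref, float(pp.mean()))
            row = {"subject_id": sid, "prepulse_level": level,
                   "percent_ppi": value}
            if group is not None:
                row["group"] = group
            rows.append(row)
    return pd.DataFrame(rows)


def recognition_table(exploration: pd.DataFrame) -> pd.DataFrame:
    """Per-subject recognition index from an object-exploration table."""
    out = exploration.copy()
    out["recognition_index"] = [
        recognition_index(r.t_novel, r.t_familiar) for r in out.itertuples()
    ]
    return out.drop(columns=["t_novel", "t_familiar"])


def fold_change_table(
    qpcr: pd.DataFrame,
    reference_group: str = "control",
) -> pd.DataFrame:
    """Per-subject ddCt fold changes, referenced to a group's mean dCt.

    Expects columns ``subject_id, group, gene, ct, hk_ct1, hk_ct2, hk_ct3``.
    The reference dCt per gene is the mean dCt across reference-group
    subjects, so the reference group's mean ddCt is 0 (fold 1).
    """
    df = qpcr.copy()
    df["delta_ct"] = [
        r.ct - gmean((r.hk_ct1, r.hk_ct2, r.hk_ct3)) for r in df.itertuples()
    ]
    ref = df[df["group"] == reference_group].groupby("gene")["delta_ct"].mean()
    if ref.empty:
        raise ValueError(f"no rows for reference group {reference_group!r}")
    df["delta_delta_ct"] = df["delta_ct"] - df["gene"].map(ref)
    df["fold"] = 2.0 ** (-df["delta_delta_ct"])
    return df[["subject_id", "group", "gene", "delta_ct", "delta_delta_ct", "fold"]]
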