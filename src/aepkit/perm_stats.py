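"""Group-difference inference: subject-level permutation tests and the
Wilcoxon rank-sum test.

The permutation test relabels whole subjects (their maps) across the two
groups — the exchangeable unit in a between-genotype design — and uses the
pixelwise difference of group means as the statistic.  When the number of
distinct relabelings is no larger than the requested iteration count the
null is enumerated exhaustively (p = k/M, minimum 1/M); otherwise random
relabelings are drawn and the add-one estimator p = (1+k)/(B+1) is used.
Ties between a permuted and the observed statistic count toward the tail
(conservative).  The default output is the uncorrected pixelwise p map,
matching significance heat maps thresholded at p < 0.05; an optional
max-statistic mode gives familywise control (not part of the original
analysis).

The Wilcoxon rank-sum test reports the rank sum of the first sample
(midranks for ties) with an exact conditional p for combined n <= 20 and a
tie-corrected normal approximation above.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sp_stats

from .timefreq import TimeFrequencyMap

__all__ = ["PermutationResult", "permutation_test", "wilcoxon_rank_sum"]

ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass
class PermutationResult:
    observed_diff: TimeFrequencyMap  # group A mean - group B mean
    p_map: TimeFrequencyMap
    n_iterations: int  # relabelings actually evaluated
    seed: int | None
    exhaustive: bool


def _as_arrays(maps: Sequence) -> tuple[np.ndarray, TimeFrequencyMap | None]:
    """Stack a list of TimeFrequencyMap or ndarray into (n, F, T)."""
    template = None
    arrays = []
    for m in maps:
        if isinstance(m, TimeFrequencyMap):
            if template is None:
                template = m
            else:
                if (m.kind != template.kind
                        or not np.allclose(m.freq_axis, template.freq_axis)
                        or not np.allclose(m.time_axis, template.time_axis)):
                    raise ValueError("maps must share axes and kind")
            arrays.append(m.values)
        else:
            arrays.append(np.atleast_2d(np.asarray(m, dtype=float)))
    stacked = np.stack(arrays)
    if template is not None and stacked.shape[1:] != template.values.shape:
        raise ValueError("maps must share dimensions")
    return stacked, template


def _tail_count(perm: np.ndarray, obs: np.ndarray, alternative: str) -> np.ndarray:
    # ties count toward the tail; a small relative tolerance keeps exact
    # ties (e.g. complement relabelings with equal group sizes) counted
    # despite float round-off
    tol = 1e-9 * np.abs(obs) + 1e-12
    if alternative == "two_sided":
        return (np.abs(perm) >= np.abs(obs) - tol).sum(axis=0)
    if alternative == "greater":
        return (perm >= obs - tol).sum(axis=0)
    return (perm <= obs + tol).sum(axis=0)


def permutation_test(
    maps_a: Sequence,
    maps_b: Sequence,
    n_iterations: int = 999,
    seed: int | None = 0,
    alternative: str = "two_sided",
    max_statistic: bool = False,
) -> PermutationResult:
    """Pixelwise permutation test of group A vs group B subject maps.

    ``max_statistic=True`` replaces each permuted pixel statistic by the
    map-wide maximum, giving familywise-corrected p values.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("each group needs at least two subjects")
    a, template = _as_arrays(list(maps_a) + list(maps_b))
    na, nb = len(maps_a), len(maps_b)
    pooled = a.reshape(na + nb, -1)
    obs = pooled[:na].mean(axis=0) - pooled[na:].mean(axis=0)

    n = na + nb
    total = comb(n, na)
    exhaustive = total <= n_iterations
    if exhaustive:
        idx = np.array(list(combinations(range(n), na)))
        n_done = total
    else:
        rng = np.random.default_rng(seed)
        idx = np.empty((n_iterations, na), dtype=int)
        for b in range(n_iterations):
            idx[b] = rng.permutation(n)[:na]
        n_done = n_iterations

    grand = pooled.sum(axis=0)
    counts = np.zeros(pooled.shape[1], dtype=int)
    chunk = max(1, int(2e7 // max(pooled.shape[1], 1)))
    for s in range(0, idx.shape[0], chunk):
        block = idx[s:s + chunk]
        sums_a = pooled[block].sum(axis=1)  # (b, P)
        diffs = sums_a / na - (grand - sums_a) / nb
        if max_statistic:
            if alternative == "two_sided":
                stat = np.abs(diffs).max(axis=1, keepdims=True)
                counts += (stat >= np.abs(obs)).sum(axis=0)
                continue
            elif alternative == "greater":
                diffs = diffs.max(axis=1, keepdims=True) * np.ones_like(diffs)
            else:
                diffs = diffs.min(axis=1, keepdims=True) * np.ones_like(diffs)
        counts += _tail_count(diffs, obs, alternative)

    if exhaustive:
        p = counts / total  # identity relabeling included -> p >= 1/M
    else:
        p = (1.0 + counts) / (n_iterations + 1.0)

    shape = a.shape[1:]
    if template is not None:
        freq_axis, time_axis = template.freq_axis, template.time_axis
        coi = template.coi
    else:
        freq_axis = np.arange(shape[0], dtype=float)
        time_axis = np.arange(shape[1], dtype=float)
        coi = None
    observed = TimeFrequencyMap(obs.reshape(shape), "difference", freq_axis,
                                time_axis, na + nb, None, coi)
    p_map = TimeFrequencyMap(p.reshape(shape), "pvalue", freq_axis, time_axis,
                             na + nb, None, coi)
    return PermutationResult(observed, p_map, n_done, seed, exhaustive)


class RankSumResult(NamedTuple):
    rank_sum: float
    p_value: float


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    exact_max_n: int = 20,
) -> RankSumResult:
    """Rank sum of ``x`` (midranks for ties) and its two-group p value.

    Exact p by enumeration of all label assignments when the combined
    sample size is at most ``exact_max_n``; tie-corrected normal
    approximation (no continuity correction) otherwise.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = sp_stats.rankdata(np.concatenate([x, y]))
    r = float(ranks[:n1].sum())

    if n <= exact_max_n:
        idx = np.array(list(combinations(range(n), n1)))
        null = ranks[idx].sum(axis=1)
        eps = 1e-9
        p_le = np.mean(null <= r + eps)
        p_ge = np.mean(null >= r - eps)
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankSumResult(r, float(p))

    # normal approximation with tie correction
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return RankSumResult(r, 1.0)
    z = (r - mu) / np.sqrt(var)
    if alternative == "greater":
        p = sp_stats.norm.sf(z)
    elif alternative == "less":
        p = sp_stats.norm.cdf(z)
    else:
        p = 2.0 * sp_stats.norm.sf(abs(z))
    return RankSumResult(r, float(min(p, 1.0)))
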