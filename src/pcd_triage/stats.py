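"""Per-cluster summary statistics and the tie-corrected Kruskal-Wallis H test."""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Sequence

import numpy as np
from scipy.stats import chi2, rankdata

__all__ = ["GroupStats", "KruskalResult", "group_summary", "kruskal_wallis"]


@dataclasses.dataclass(frozen=True)
class GroupStats:
    n: int
    mean: float
    sd: float       # sample SD (n-1 denominator); 0 with sd_undefined for n=1
    median: float
    sd_undefined: bool = False


def group_summary(
    values: Sequence[float], labels: Sequence[str]
) -> dict[str, GroupStats]:
    """Mean, sample SD and median of ``values`` within each label group."""
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels differ in length")
    out: dict[str, GroupStats] = {}
    for lab in dict.fromkeys(labels):  # preserve first-seen order
        group = values[[l == lab for l in labels]]
        if len(group) == 0:
            raise ValueError(f"empty group {lab!r}")
        sd_undefined = len(group) == 1
        out[lab] = GroupStats(
            n=int(len(group)),
            mean=float(group.mean()),
            sd=0.0 if sd_undefined else float(group.std(ddof=1)),
            median=float(np.median(group)),
            sd_undefined=sd_undefined,
        )
    return out


@dataclasses.dataclass(frozen=True)
class KruskalResult:
    H: float             # uncorrected statistic
    H_corrected: float   # H divided by the tie-correction factor
    df: int
    p_value: float
    tie_correction: float


def kruskal_wallis(values: Sequence[float], labels: Sequence[str]) -> KruskalResult:
    """Kruskal-Wallis H test across label groups with mid-rank tie handling.

    H = 12/(N(N+1)) * sum_i n_i * Rbar_i^2 - 3(N+1) on mid-ranks, corrected
    by C = 1 - sum(t^3 - t)/(N^3 - N) over tie groups; the p-value is the
    chi-square upper tail with k-1 degrees of freedom. When every value is
    identical the correction degenerates and the test reports H=0, p=1.
    """
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels differ in length")
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    N = len(values)
    if N < 3:
        raise ValueError("need at least 3 observations")
    ranks = rankdata(values)  # mid-ranks for ties
    H = 0.0
    for lab in groups:
        r = ranks[[l == lab for l in labels]]
        if len(r) == 0:
            raise ValueError(f"empty group {lab!r}")
        H += len(r) * r.mean() ** 2
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    ties = Counter(values.tolist())
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (N**3 - N)
    df = len(groups) - 1
    if correction <= 0.0:  # all values tied
        return KruskalResult(H=0.0, H_corrected=0.0, df=df, p_value=1.0, tie_correction=0.0)
    H_corrected = H / correction
    p = float(chi2.sf(H_corrected, df))
    return KruskalResult(
        H=float(H), H_corrected=float(H_corrected), df=df, p_value=p,
        tie_correction=float(correction),
    )
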