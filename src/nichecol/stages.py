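"""Assignment of samples to colonization stages.

Stages can come from configured day windows (the default windows being
initial colonization 3-6 d, community formation 12-18 d, primary
succession 24-27 d) or from an exact dynamic-programming segmentation of
the day-ordered community series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import UNASSIGNED
from .data import Bundle


@dataclass(frozen=True)
class StagePartition:
    """Mapping of sample ids to stage labels.

    ``labels`` maps every sample to a stage label or ``"unassigned"``;
    ``day_ranges`` records the inclusive day window per stage when the
    partition came from windows (empty for automatic segmentation).
    """

    labels: dict[str, str]
    day_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def stages(self) -> list[str]:
        seen = [l for l in dict.fromkeys(self.labels.values()) if l != UNASSIGNED]
        return sorted(seen)

    def to_frame(self, meta: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sample": list(self.labels), "stage": list(self.labels.values())}
        ).set_index("sample")
        if meta is not None:
            df.insert(0, "day", meta.loc[df.index, "day"])
        return df


def assign_stages(
    meta: pd.DataFrame, day_ranges: dict[str, tuple[int, int]]
) -> StagePartition:
    """Label each sample by membership of its day in a stage window.

    Windows are inclusive and must not overlap; days outside every window
    are labeled unassigned.
    """
    labels_sorted = sorted(day_ranges)
    for i, la in enumerate(labels_sorted):
        for lb in labels_sorted[i + 1 :]:
            (a0, a1), (b0, b1) = day_ranges[la], day_ranges[lb]
            if a0 <= b1 and b0 <= a1:
                raise ValueError(f"stage windows {la} and {lb} overlap")
    labels = {}
    for sample, day in meta["day"].items():
        hit = UNASSIGNED
        for stage, (lo, hi) in day_ranges.items():
            if lo <= day <= hi:
                hit = stage
                break
        labels[sample] = hit
    return StagePartition(labels=labels, day_ranges=dict(day_ranges))


def _block_costs(sq: np.ndarray, day_groups: list[np.ndarray]) -> np.ndarray:
    """cost[i, j] = sum of squared distances among samples of days i..j."""
    m = len(day_groups)
    cost = np.zeros((m, m))
    for i in range(m):
        idx = np.array([], dtype=int)
        for j in range(i, m):
            idx = np.concatenate([idx, day_groups[j]])
            cost[i, j] = sq[np.ix_(idx, idx)].sum() / 2.0
    return cost


def auto_segment(bundle: Bundle, k: int, distance: np.ndarray | None = None) -> StagePartition:
    """Time-contiguous k-way segmentation of the colonization series.

    Partitions the day-ordered samples into ``k`` contiguous blocks
    minimizing the total within-block sum of squared Bray-Curtis
    distances, by exact dynamic programming over block boundaries.
    Replicates sampled on the same day are never split. Ties are broken
    toward the earliest boundaries. Stages are labeled S1..Sk in time
    order.
    """
    from .diversity import bray_curtis

    if k < 2:
        raise ValueError("k must be >= 2")
    days = np.sort(bundle.meta["day"].unique())
    m = len(days)
    if k > m:
        raise ValueError(f"k={k} exceeds the {m} distinct sampling days")

    samples = list(bundle.counts.columns)
    pos = {s: i for i, s in enumerate(samples)}
    day_groups = [
        np.array([pos[s] for s in bundle.meta.index[bundle.meta["day"] == d]])
        for d in days
    ]
    if distance is None:
        distance = bray_curtis(bundle).matrix
    sq = distance**2
    cost = _block_costs(sq, day_groups)

    # dp[b, j]: best objective for the first j+1 days split into b+1 blocks.
    dp = np.full((k, m), np.inf)
    back = np.zeros((k, m), dtype=int)
    dp[0, :] = cost[0, :]
    for b in range(1, k):
        for j in range(b, m):
            # strict improvement only => earliest feasible split is kept
            best, arg = np.inf, b
            for s in range(b, j + 1):  # block b covers days s..j
                v = dp[b - 1, s - 1] + cost[s, j]
                if v < best - 1e-15:
                    best, arg = v, s
            dp[b, j], back[b, j] = best, arg

    bounds = []
    j = m - 1
    for b in range(k - 1, 0, -1):
        s = back[b, j]
        bounds.append(s)
        j = s - 1
    bounds = bounds[::-1]  # start day-index of blocks 2..k

    stage_of_day = {}
    starts, ends = [0] + bounds, bounds + [m]
    for b, (s0, s1) in enumerate(zip(starts, ends)):
        for di in range(s0, s1):
            stage_of_day[days[di]] = f"S{b + 1}"
    labels = {s: stage_of_day[bundle.meta.loc[s, "day"]] for s in samples}
    part = StagePartition(labels=labels)
    object.__setattr__(part, "objective", float(dp[k - 1, m - 1]))
    object.__setattr__(part, "boundaries", [int(days[b]) for b in bounds])
    return part
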