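"""Driving-performance measures and the composite driving-quality score.

Five per-block measures — acceleration RMSSD, steering-rate RMSSD, mean
brake actuation, mean absolute lane deviation (excluding ±2 s around each
lane change), and the traffic-violation count — are min-max normalised
across a subject's blocks, averaged, inverted (higher = better) and
min-max rescaled once more to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["DrivingMeasures", "rmssd", "lane_deviation", "count_violations",
           "composite_score", "driving_measures"]

MEASURE_NAMES = ("accel_rmssd", "steer_rmssd", "brake_mean",
                 "lane_dev_mean", "violations")


@dataclass
class DrivingMeasures:
    accel_rmssd: float     # m/s^2
    steer_rmssd: float     # rad/s
    brake_mean: float      # [0, 1]
    lane_dev_mean: float   # m
    violations: int

    def as_array(self) -> np.ndarray:
        return np.array([self.accel_rmssd, self.steer_rmssd,
                         self.brake_mean, self.lane_dev_mean,
                         float(self.violations)])


def rmssd(x) -> float:
    """Root mean square of successive differences."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples for RMSSD")
    return float(np.sqrt(np.mean(np.diff(x) ** 2)))


def lane_deviation(lane_pos, sfreq: float, lane_change_times=(),
                   exclusion_s: float = 2.0) -> float:
    """Mean |lane position| outside ±``exclusion_s`` of each lane change."""
    lane_pos = np.asarray(lane_pos, dtype=float)
    if exclusion_s < 0:
        raise ValueError("exclusion window must be non-negative")
    t = np.arange(lane_pos.size) / sfreq
    keep = np.ones(lane_pos.size, dtype=bool)
    for tc in np.atleast_1d(np.asarray(lane_change_times, dtype=float)):
        keep &= ~((t >= tc - exclusion_s) & (t <= tc + exclusion_s))
    if not keep.any():
        raise ValueError("lane-change exclusion windows cover the whole block")
    return float(np.abs(lane_pos[keep]).mean())


def count_violations(events: pd.DataFrame) -> int:
    """Count radar flashes and collisions; other event kinds are ignored."""
    if len(events) == 0:
        return 0
    return int(events["kind"].isin(["radar", "collision"]).sum())


def driving_measures(block) -> DrivingMeasures:
    """All five measures for one :class:`~drivemeg.simulate.TelemetryBlock`."""
    return DrivingMeasures(
        accel_rmssd=rmssd(block.accel),
        steer_rmssd=rmssd(block.steer),
        brake_mean=float(np.mean(block.brake)),
        lane_dev_mean=lane_deviation(block.lane_pos, block.sfreq,
                                     block.lane_change_times),
        violations=count_violations(block.violations),
    )


def composite_score(measures_by_block: dict[str, DrivingMeasures]
                    ) -> dict[str, float]:
    """Composite driving-performance score in [0, 1] per block.

    Each measure is min-max normalised across the subject's blocks; the five
    normalised measures are averaged per block, inverted (1 - x, so that
    higher = better driving), and min-max rescaled once more.  A measure
    constant across blocks contributes 0 for every block (flagged).
    """
    if len(measures_by_block) < 2:
        raise ValueError("need at least 2 blocks for min-max normalisation")
    blocks = list(measures_by_block)
    M = np.stack([measures_by_block[b].as_array() for b in blocks])
    lo, hi = M.min(axis=0), M.max(axis=0)
    span = hi - lo
    norm = np.zeros_like(M)
    for j, name in enumerate(MEASURE_NAMES):
        if span[j] == 0:
            logger.info("measure %s constant across blocks; normalised "
                        "value set to 0", name)
            continue
        norm[:, j] = (M[:, j] - lo[j]) / span[j]
    agg = 1.0 - norm.mean(axis=1)
    span_agg = agg.max() - agg.min()
    if span_agg == 0:
        scores = np.zeros_like(agg)
    else:
        scores = (agg - agg.min()) / span_agg
    return dict(zip(blocks, scores.tolist()))
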