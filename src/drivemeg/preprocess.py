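"""Epoch segmentation, amplitude rejection, trial-count equalization and
FIR band-pass filtering of continuous sensor blocks."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal

logger = logging.getLogger(__name__)

__all__ = ["EpochSet", "segment_epochs", "reject_amplitude",
           "equalize_counts", "bandpass_fir"]


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one continuous block.

    data has shape (n_epochs, n_channels, n_samples); ``onsets`` are epoch
    start times in seconds, strictly increasing; ``labels`` carries the
    block's condition tag for every epoch.
    """

    data: np.ndarray
    onsets: np.ndarray
    sfreq: float
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs, channels, samples)")
        if len(self.onsets) != len(self.data):
            raise ValueError("one onset per epoch required")
        if len(self.onsets) > 1 and not (np.diff(self.onsets) > 0).all():
            raise ValueError("epoch onsets must be strictly increasing")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.data):
                raise ValueError("one label per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx], onsets=self.onsets[idx], sfreq=self.sfreq,
            labels=None if self.labels is None else self.labels[idx],
        )


def segment_epochs(block: np.ndarray, sfreq: float, length_s: float,
                   overlap_s: float = 0.0, label=None) -> EpochSet:
    """Cut a (channels, samples) block into fixed windows.

    Windows advance by ``length_s - overlap_s``; a trailing partial window is
    discarded, so a block of duration T yields
    ``floor((T - length) / (length - overlap)) + 1`` epochs.
    """
    block = np.atleast_2d(np.asarray(block, dtype=float))
    if length_s <= 0:
        raise ValueError("epoch length must be positive")
    if overlap_s < 0 or overlap_s >= length_s:
        raise ValueError("overlap must satisfy 0 <= overlap < length")
    n_len = int(round(length_s * sfreq))
    step = int(round((length_s - overlap_s) * sfreq))
    n_samples = block.shape[1]
    if n_samples < n_len:
        logger.warning("block shorter than one epoch (%d < %d samples); "
                       "returning empty EpochSet", n_samples, n_len)
        return EpochSet(
            data=np.empty((0, block.shape[0], n_len)),
            onsets=np.empty(0), sfreq=sfreq,
            labels=None if label is None else np.empty(0, dtype=object),
        )
    n_epochs = (n_samples - n_len) // step + 1
    starts = np.arange(n_epochs) * step
    data = np.stack([block[:, s:s + n_len] for s in starts])
    labels = None if label is None else np.full(n_epochs, label, dtype=object)
    return EpochSet(data=data, onsets=starts / sfreq, sfreq=sfreq,
                    labels=labels)


def reject_amplitude(epochs: EpochSet, threshold: float | dict,
                     channel_groups: dict | None = None,
                     statistic: str = "absmax"):
    """Drop epochs whose amplitude exceeds a threshold on any channel.

    ``threshold`` may be a scalar (one sensor type) or a mapping from group
    name to threshold, with ``channel_groups`` mapping group names to channel
    indices — mirroring per-sensor-type rejection (e.g. 4,000 fT for
    magnetometers).  ``statistic`` is ``"absmax"`` (default) or ``"ptp"``.

    Returns ``(kept EpochSet, rejected mask)`` where mask[i] is True for
    rejected epochs.
    """
    if statistic not in {"absmax", "ptp"}:
        raise ValueError("statistic must be 'absmax' or 'ptp'")
    if np.isscalar(threshold):
        thresholds = {"all": float(threshold)}
        channel_groups = {"all": np.arange(epochs.data.shape[1])}
    else:
        thresholds = dict(threshold)
        if channel_groups is None or set(channel_groups) != set(thresholds):
            raise ValueError("channel_groups must name every threshold group")
    for name, thr in thresholds.items():
        if thr <= 0:
            raise ValueError(f"threshold for group {name!r} must be positive")

    reject = np.zeros(epochs.n_epochs, dtype=bool)
    for name, thr in thresholds.items():
        sub = epochs.data[:, np.asarray(channel_groups[name])]
        if statistic == "absmax":
            stat = np.abs(sub).max(axis=(1, 2))
        else:
            stat = (sub.max(axis=2) - sub.min(axis=2)).max(axis=1)
        reject |= stat > thr
    if reject.all() and epochs.n_epochs > 0:
        label = epochs.labels[0] if epochs.labels is not None else "<unlabelled>"
        raise ValueError(f"all {epochs.n_epochs} epochs rejected in block "
                         f"{label}")
    return epochs.subset(~reject), reject


def equalize_counts(epoch_sets: dict[str, EpochSet]) -> dict[str, EpochSet]:
    """Equalize trial counts across conditions, minimising timing mismatch.

    Every condition is reduced to the minimum count by greedy deletion: at
    each step the epoch whose removal most reduces the summed pairwise
    absolute difference of matched-rank onset times across conditions is
    dropped (ties broken toward the later onset).
    """
    if len(epoch_sets) < 2:
        raise ValueError("need at least two conditions to equalize")
    for cond, es in epoch_sets.items():
        if es.n_epochs == 0:
            raise ValueError(f"condition {cond!r} has no epochs")
    target = min(es.n_epochs for es in epoch_sets.values())
    keep_idx = {c: list(range(es.n_epochs)) for c, es in epoch_sets.items()}

    def mismatch(onsets_by_cond: dict[str, np.ndarray]) -> float:
        total = 0.0
        conds = list(onsets_by_cond)
        m = min(len(o) for o in onsets_by_cond.values())
        for a in range(len(conds)):
            for b in range(a + 1, len(conds)):
                oa = onsets_by_cond[conds[a]][:m]
                ob = onsets_by_cond[conds[b]][:m]
                total += np.abs(oa - ob).sum()
        return total

    for cond, es in epoch_sets.items():
        while len(keep_idx[cond]) > target:
            onsets = {c: epoch_sets[c].onsets[keep_idx[c]]
                      for c in epoch_sets}
            best_cost, best_drop = np.inf, None
            for pos in range(len(keep_idx[cond])):
                trial = list(keep_idx[cond])
                dropped_onset = epoch_sets[cond].onsets[trial.pop(pos)]
                cand = dict(onsets)
                cand[cond] = epoch_sets[cond].onsets[trial]
                cost = mismatch(cand)
                # tie-break toward dropping the later-onset epoch
                if cost < best_cost - 1e-12 or (
                        abs(cost - best_cost) <= 1e-12 and best_drop is not None
                        and dropped_onset >
                        epoch_sets[cond].onsets[keep_idx[cond][best_drop]]):
                    best_cost, best_drop = cost, pos
            keep_idx[cond].pop(best_drop)

    return {c: epoch_sets[c].subset(np.asarray(keep_idx[c]))
            for c in epoch_sets}


def bandpass_fir(block: np.ndarray, sfreq: float, lo_hz: float, hi_hz: float,
                 width_hz: float | None = None) -> np.ndarray:
    """Linear-phase windowed FIR band-pass with group-delay compensation.

    A Hamming-window FIR (stop-band attenuation ~53 dB, i.e. >= 40 dB) is
    applied in a single forward pass on the zero-padded signal and the group
    delay of (n_taps - 1)/2 samples removed, preserving phase.
    """
    block = np.atleast_2d(np.asarray(block, dtype=float))
    nyq = sfreq / 2.0
    if not (0 < lo_hz < hi_hz < nyq):
        raise ValueError(f"band ({lo_hz}, {hi_hz}) invalid for sfreq {sfreq}")
    if width_hz is None:
        width_hz = max(lo_hz / 4.0, 1.0)
    # Hamming-window design: ~3.3 / (width / sfreq) taps for the transition
    n_taps = int(np.ceil(3.3 * sfreq / width_hz)) | 1  # force odd
    taps = scipy.signal.firwin(n_taps, [lo_hz, hi_hz], pass_zero=False,
                               fs=sfreq, window="hamming")
    delay = (n_taps - 1) // 2
    padded = np.pad(block, [(0, 0), (delay, delay)])
    out = scipy.signal.lfilter(taps, 1.0, padded, axis=1)
    return out[:, 2 * delay:]
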