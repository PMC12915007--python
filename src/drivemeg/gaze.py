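"""Pupil/gaze preprocessing and gaze-derived workload measures.

Preprocessing order is fixed: blink-gap spline interpolation (50 ms pad,
500 ms maximum tolerated gap) -> 20 ms rolling-median filter ->
physiological masking outside 1-9 mm.  Measures: duration-weighted RMS
gaze dispersion, blink rate, median pupil diameter during fixations, and
the Index of Pupillary Activity (IPA) — abrupt pupil-diameter
discontinuities per second, detected as thresholded wavelet modulus maxima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
import scipy.interpolate

logger = logging.getLogger(__name__)

__all__ = [
    "PupilSeries", "GazeMetrics",
    "interpolate_gaps", "median_roll", "clip_physiological",
    "median_pupil_fixations", "ipa", "gaze_dispersion", "blink_rate",
    "baseline_correct", "preprocess_pupil", "gaze_metrics",
]


@dataclass
class PupilSeries:
    """Uniformly sampled pupil-diameter series with a validity mask."""

    diameter_mm: np.ndarray
    sfreq: float
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.diameter_mm = np.asarray(self.diameter_mm, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.diameter_mm)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.diameter_mm.shape:
            raise ValueError("validity mask must match the series shape")

    @property
    def n(self) -> int:
        return self.diameter_mm.size


@dataclass
class GazeMetrics:
    dispersion: float            # screen units, duration-weighted RMS
    blink_rate: float            # events / s
    pupil_median_mm: float
    ipa: float                   # events / s


def _gap_runs(invalid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of invalid samples."""
    d = np.diff(invalid.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if invalid[0]:
        starts = np.r_[0, starts]
    if invalid[-1]:
        stops = np.r_[stops, invalid.size]
    return list(zip(starts, stops))


def interpolate_gaps(series: PupilSeries, pad_ms: float = 50.0,
                     max_gap_ms: float = 500.0) -> PupilSeries:
    """Cubic-spline interpolation across blink/artefact gaps.

    Each gap is widened by ``pad_ms`` on both sides (blink edges distort the
    pupil trace) and filled with a cubic spline through the flanking valid
    samples; gaps longer than ``max_gap_ms`` stay masked.  Gaps touching a
    series boundary are filled with the nearest valid value and flagged.
    """
    x = series.diameter_mm.copy()
    valid = series.valid.copy()
    pad = int(round(pad_ms / 1000.0 * series.sfreq))
    max_gap = int(round(max_gap_ms / 1000.0 * series.sfreq))
    if not (~valid).any():
        return PupilSeries(x, series.sfreq, valid)
    if not valid.any():
        raise ValueError("series contains no valid samples")

    for start, stop in _gap_runs(~valid):
        if stop - start > max_gap:
            continue  # intolerable loss: leave masked
        lo = max(0, start - pad)
        hi = min(x.size, stop + pad)
        if start == 0 or stop == x.size:
            fill_from = stop if start == 0 else start - 1
            while not valid[fill_from] and 0 <= fill_from < x.size:
                fill_from += 1 if start == 0 else -1
            x[lo:hi] = x[fill_from]
            valid[lo:hi] = True
            logger.info("boundary gap [%d, %d) filled with nearest valid "
                        "value", start, stop)
            continue
        left = np.arange(max(0, lo - 4 * pad - 4), lo)
        right = np.arange(hi, min(x.size, hi + 4 * pad + 4))
        anchors = np.r_[left, right]
        anchors = anchors[valid[anchors]]
        if anchors.size < 4:
            continue
        spline = scipy.interpolate.CubicSpline(anchors, x[anchors])
        x[lo:hi] = spline(np.arange(lo, hi))
        valid[lo:hi] = True
    return PupilSeries(x, series.sfreq, valid)


def median_roll(series: PupilSeries, window_ms: float = 20.0) -> PupilSeries:
    """Centered rolling median; edges use shrunken windows; NaNs ignored."""
    w = max(1, int(round(window_ms / 1000.0 * series.sfreq)))
    if w % 2 == 0:
        w += 1
    filtered = (
        pd.Series(np.where(series.valid, series.diameter_mm, np.nan))
        .rolling(window=w, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    filtered = np.where(series.valid, filtered, series.diameter_mm)
    return PupilSeries(filtered, series.sfreq, series.valid.copy())


def clip_physiological(series: PupilSeries, lo_mm: float = 1.0,
                       hi_mm: float = 9.0) -> PupilSeries:
    """Mask (not clamp) samples outside the physiologically valid range."""
    out_of_range = series.valid & (
        (series.diameter_mm < lo_mm) | (series.diameter_mm > hi_mm))
    return PupilSeries(series.diameter_mm.copy(), series.sfreq,
                       series.valid & ~out_of_range)


def preprocess_pupil(series: PupilSeries, pad_ms: float = 50.0,
                     max_gap_ms: float = 500.0, window_ms: float = 20.0,
                     lo_mm: float = 1.0, hi_mm: float = 9.0) -> PupilSeries:
    """Fixed-order pipeline: interpolate gaps -> rolling median -> mask
    out-of-range samples."""
    out = interpolate_gaps(series, pad_ms=pad_ms, max_gap_ms=max_gap_ms)
    out = median_roll(out, window_ms=window_ms)
    return clip_physiological(out, lo_mm=lo_mm, hi_mm=hi_mm)


def median_pupil_fixations(series: PupilSeries, fixations: pd.DataFrame
                           ) -> float:
    """Median diameter over valid samples inside fixation intervals (mm)."""
    sel = np.zeros(series.n, dtype=bool)
    for _, row in fixations.iterrows():
        a = int(np.ceil(row["onset_s"] * series.sfreq))
        b = int(np.floor(row["offset_s"] * series.sfreq))
        sel[a:b + 1] = True
    sel &= series.valid
    if not sel.any():
        raise ValueError("no valid pupil samples inside fixations")
    return float(np.median(series.diameter_mm[sel]))


def ipa(series: PupilSeries, wavelet: str = "sym16", level: int = 2,
        min_segment_s: float = 2.0) -> float:
    """Index of Pupillary Activity: abrupt-discontinuity events per second.

    The detail coefficients of a ``level``-level discrete wavelet transform
    (Symlet-16) are screened for modulus maxima; maxima surviving the hard
    universal threshold ``lambda = sigma * sqrt(2 ln n)`` with the robust
    noise estimate ``sigma = MAD(detail) / 0.6745`` are counted.  Runs of
    masked samples split the series; segments are processed independently
    and event counts summed over the total valid duration.
    """
    counts = 0
    total_s = 0.0
    filt_len = pywt.Wavelet(wavelet).dec_len
    for start, stop in _valid_runs(series.valid):
        seg = series.diameter_mm[start:stop]
        seg_s = seg.size / series.sfreq
        if seg_s < min_segment_s or seg.size < filt_len * 2 ** level:
            continue
        total_s += seg_s
        detail = pywt.wavedec(seg, wavelet, level=level)[1]  # coarsest detail
        # boundary-extension artefacts span ~one filter length per edge;
        # exclude them from both the noise estimate and the maxima
        margin = filt_len
        if detail.size <= 2 * margin + 3:
            continue
        interior = detail[margin:-margin]
        mag = np.abs(interior)
        maxima = np.flatnonzero(
            (mag[1:-1] > mag[:-2]) & (mag[1:-1] >= mag[2:])) + 1
        sigma = np.median(np.abs(interior - np.median(interior))) / 0.6745
        lam = sigma * np.sqrt(2.0 * np.log(mag.size))
        counts += int((mag[maxima] > lam).sum())
    if total_s == 0:
        raise ValueError("no valid segment long enough for the IPA "
                         "wavelet support")
    return counts / total_s


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    return _gap_runs(valid) if valid.any() else []


def gaze_dispersion(fixations: pd.DataFrame) -> float:
    """Duration-weighted RMS distance of fixations from the gaze centroid.

    The centroid is the duration-weighted mean of fixation x/y positions;
    a single fixation yields dispersion 0 with a logged flag.
    """
    if len(fixations) == 0:
        raise ValueError("need at least one fixation")
    d = fixations["duration_s"].to_numpy(dtype=float)
    x = fixations["x"].to_numpy(dtype=float)
    y = fixations["y"].to_numpy(dtype=float)
    if (d <= 0).any():
        raise ValueError("fixation durations must be positive")
    if len(fixations) == 1:
        logger.info("single fixation: dispersion defined as 0")
        return 0.0
    wsum = d.sum()
    cx, cy = (d * x).sum() / wsum, (d * y).sum() / wsum
    sq = (x - cx) ** 2 + (y - cy) ** 2
    return float(np.sqrt((d * sq).sum() / wsum))


def blink_rate(blinks: pd.DataFrame | int, duration_s: float) -> float:
    """Blink count normalised by block duration (events per second)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    count = blinks if isinstance(blinks, (int, np.integer)) else len(blinks)
    return count / duration_s


def baseline_correct(value: float, baseline_value: float) -> float:
    """Experimental-block value minus the preceding baseline-block value."""
    if not (np.isfinite(value) and np.isfinite(baseline_value)):
        raise ValueError("both values must be finite")
    return value - baseline_value


def gaze_metrics(block) -> GazeMetrics:
    """All four gaze measures for one :class:`~drivemeg.simulate.GazeBlock`."""
    series = PupilSeries(block.pupil_mm, block.sfreq)
    clean = preprocess_pupil(series)
    return GazeMetrics(
        dispersion=gaze_dispersion(block.fixations),
        blink_rate=blink_rate(block.blinks, block.duration_s),
        pupil_median_mm=median_pupil_fixations(clean, block.fixations),
        ipa=ipa(clean),
    )
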