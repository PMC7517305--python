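"""QRS detection, beat-agreement signal quality and RR-series construction.

Two detectors are provided.  The primary one follows the Hamilton--Tompkins
scheme: band-pass emphasis around the QRS band, differentiation,
rectification, moving-window integration and adaptive peak/noise thresholds
with a refractory period and searchback.  The secondary detector applies a
curve-length transform, which trades specificity for sensitivity at low
signal-to-noise ratios.  Agreement between the two detectors within a
matching tolerance yields the beat-agreement signal quality index (bSQI).

A variance-based correction guards the primary detector against large spike
artifacts: windows of anomalously high variance are amplitude-clipped, the
detector is re-run on the clipped trace, and the annotation sets merged.
This rescues beats that a spike would otherwise suppress through threshold
inflation, while acting as the identity on clean signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sig

from .preprocess import AnalysisSegment

#: physiological RR range (s); intervals outside are treated as artifacts
RR_RANGE = (0.2, 3.0)
#: minimum separation between annotated beats (s)
REFRACTORY = 0.2
#: default beat-matching tolerance for the agreement SQI (s)
SQI_TOLERANCE = 0.15


@dataclass
class BeatAnnotations:
    """R-peak sample indices from one detector run."""

    peak_indices: np.ndarray
    detector_id: str = "primary"
    fs: float = 250.0

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)

    @property
    def n_beats(self) -> int:
        return int(self.peak_indices.size)

    @property
    def times(self) -> np.ndarray:
        """Beat times in seconds."""
        return self.peak_indices / self.fs


@dataclass
class RRSeries:
    """Beat times and the physiologically valid inter-beat intervals.

    ``rr_intervals`` holds successive beat-time differences restricted to the
    physiological range; ``rr_times`` tags each interval with the time of its
    terminating beat (the convention used for spectral analysis of the
    unevenly sampled series).
    """

    beat_times: np.ndarray
    rr_intervals: np.ndarray
    rr_times: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr_intervals = np.asarray(self.rr_intervals, dtype=float)
        self.rr_times = np.asarray(self.rr_times, dtype=float)

    @property
    def n_intervals(self) -> int:
        return int(self.rr_intervals.size)

    @property
    def empty(self) -> bool:
        return self.rr_intervals.size == 0


@dataclass
class SqiResult:
    """Beat-agreement signal quality: matched beats over the union."""

    bsqi: float
    n_matched: int
    n_union: int


#: detections this close to a segment edge are discarded: a partially
#: rendered complex at the window boundary is not scoreable
EDGE_GUARD = 0.2


def _drop_edge_beats(indices: np.ndarray, n_samples: int, fs: float) -> np.ndarray:
    guard = EDGE_GUARD * fs
    return indices[(indices >= guard) & (indices <= n_samples - 1 - guard)]


def _refine_peaks(segment: AnalysisSegment, indices: np.ndarray, window_s: float = 0.04
                  ) -> np.ndarray:
    """Snap each index to the local |ECG| extremum within +/- window_s."""
    x = segment.samples
    w = int(round(window_s * segment.fs))
    refined = []
    for idx in indices:
        lo = max(idx - w, 0)
        hi = min(idx + w + 1, x.size)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    out = np.unique(np.asarray(refined, dtype=int))
    return out


def _enforce_refractory(indices: np.ndarray, fs: float) -> np.ndarray:
    """Drop beats closer than the refractory period, keeping the earlier one."""
    if indices.size == 0:
        return indices
    keep = [int(indices[0])]
    min_gap = REFRACTORY * fs
    for idx in indices[1:]:
        if idx - keep[-1] >= min_gap:
            keep.append(int(idx))
    return np.asarray(keep, dtype=int)


def _adaptive_peak_search(det: np.ndarray, fs: float, th_frac: float = 0.3125
                          ) -> np.ndarray:
    """Adaptive peak/noise thresholding on a non-negative detection signal.

    Classic running-estimate scheme: candidate local maxima update a signal
    peak estimate (spki) when above threshold, a noise estimate (npki)
    otherwise; threshold = npki + th_frac * (spki - npki).  A 200 ms
    refractory period suppresses double fires.  When no beat arrives within
    1.5x the running mean RR, one searchback pass over the gap at half
    threshold is attempted per candidate.  The signal estimate has no
    passive decay: a large in-band artifact inflates the threshold and
    suppresses subsequent beats, which is the failure mode the
    variance-based correction repairs.
    """
    n = det.size
    refr = int(REFRACTORY * fs)
    # candidate peaks: local maxima separated by the refractory period
    cand, _ = sig.find_peaks(det, distance=refr)
    if cand.size == 0:
        return np.asarray([], dtype=int)

    init_n = min(int(2 * fs), n)
    spki = float(np.max(det[:init_n]))
    npki = float(np.mean(det[:init_n]))
    if spki <= 0:
        return np.asarray([], dtype=int)

    beats: list[int] = []
    recent_rr: list[float] = []

    def threshold() -> float:
        return npki + th_frac * (spki - npki)

    def accept(idx: int, weight: float) -> None:
        nonlocal spki
        if beats:
            recent_rr.append((idx - beats[-1]) / fs)
        beats.append(int(idx))
        spki = (1 - weight) * spki + weight * float(det[idx])

    for idx in cand:
        val = det[idx]
        if beats and recent_rr:
            mean_rr = float(np.mean(recent_rr[-8:]))
            if idx - beats[-1] > 1.5 * mean_rr * fs:
                # one searchback attempt over the gap at half threshold
                gap = cand[(cand >= beats[-1] + refr) & (cand < idx - refr)]
                if gap.size:
                    best = int(gap[np.argmax(det[gap])])
                    if det[best] > 0.5 * threshold():
                        accept(best, 0.25)
        if val > threshold():
            if not beats or idx - beats[-1] >= refr:
                accept(int(idx), 0.125)
        else:
            npki = 0.875 * npki + 0.125 * float(val)
    return np.asarray(sorted(set(beats)), dtype=int)


def _qrs_emphasis(segment: AnalysisSegment) -> np.ndarray:
    """Band-pass emphasis, derivative, rectify, 80 ms integration."""
    fs = segment.fs
    sos = sig.butter(3, [8.0, 16.0], btype="bandpass", fs=fs, output="sos")
    f = sig.sosfiltfilt(sos, segment.samples)
    d = np.diff(f, prepend=f[0])
    r = np.abs(d)
    w = max(int(round(0.08 * fs)), 1)
    kernel = np.ones(w) / w
    return np.convolve(r, kernel, mode="same")


def detect_qrs_primary(segment: AnalysisSegment) -> BeatAnnotations:
    """Hamilton--Tompkins R-peak detection.

    Returns peak indices refined to the local ECG extremum within +/-40 ms.
    Fewer than two detected beats yields an empty annotation set (downstream
    HRV features then flag as missing).
    """
    if segment.duration < 5.0:
        raise ValueError("segment must be at least 5 s long")
    det = _qrs_emphasis(segment)
    raw = _adaptive_peak_search(det, segment.fs, th_frac=0.3125)
    if raw.size < 2:
        return BeatAnnotations(np.asarray([], dtype=int), "primary", segment.fs)
    refined = _refine_peaks(segment, raw)
    refined = _enforce_refractory(refined, segment.fs)
    refined = _drop_edge_beats(refined, segment.samples.size, segment.fs)
    return BeatAnnotations(refined, "primary", segment.fs)


def detect_qrs_secondary(segment: AnalysisSegment) -> BeatAnnotations:
    """Curve-length-transform R-peak detection.

    The transform accumulates arc length ``sqrt(c^2 + dy^2)`` over a 130 ms
    sliding window (baseline subtracted so a flatline maps to zero); adaptive
    thresholding and refinement mirror the primary detector, with a lower
    threshold fraction making it more sensitive at low SNR.
    """
    fs = segment.fs
    sos = sig.butter(4, 16.0, btype="lowpass", fs=fs, output="sos")
    smoothed = sig.sosfiltfilt(sos, segment.samples)
    dy = np.diff(smoothed, prepend=smoothed[0])
    c = 1000.0 / fs  # scale constant balancing time vs amplitude terms
    arc = np.sqrt(c * c + dy * dy) - c
    w = max(int(round(0.13 * fs)), 1)
    kernel = np.ones(w)
    det = np.convolve(arc, kernel, mode="same")
    raw = _adaptive_peak_search(det, fs, th_frac=0.2)
    if raw.size < 2:
        return BeatAnnotations(np.asarray([], dtype=int), "secondary", fs)
    refined = _refine_peaks(segment, raw)
    refined = _enforce_refractory(refined, fs)
    refined = _drop_edge_beats(refined, segment.samples.size, segment.fs)
    return BeatAnnotations(refined, "secondary", fs)


def _merge_annotations(original: BeatAnnotations, extra: np.ndarray, fs: float
                       ) -> BeatAnnotations:
    """Union with 200 ms deduplication, keeping original indices on collision."""
    merged = list(original.peak_indices)
    tol = REFRACTORY * fs
    for idx in extra:
        if original.peak_indices.size == 0 or np.min(
            np.abs(original.peak_indices - idx)
        ) >= tol:
            merged.append(int(idx))
    merged = np.asarray(sorted(set(merged)), dtype=int)
    merged = _enforce_refractory(merged, fs)
    return BeatAnnotations(merged, original.detector_id, fs)


def high_variance_mask(x: np.ndarray, fs: float) -> tuple[np.ndarray, float]:
    """Samples inside sliding 1 s windows whose variance exceeds 5x the median.

    Returns the boolean mask and the median window variance.
    """
    w = int(round(1.0 * fs))
    kernel = np.ones(w) / w
    m1 = np.convolve(x, kernel, mode="same")
    m2 = np.convolve(x * x, kernel, mode="same")
    var = np.maximum(m2 - m1 * m1, 0.0)
    med = float(np.median(var))
    return var > 5.0 * med, med


def apply_variance_correction(
    segment: AnalysisSegment, beats: BeatAnnotations
) -> BeatAnnotations:
    """Rescue beats suppressed by spike-inflated detection thresholds.

    A sliding 1 s variance is computed; samples inside windows whose variance
    exceeds 5x the record's median window variance are clipped to the 99th
    amplitude percentile of the remaining signal.  The detector is re-run on
    the clipped trace and the annotations merged (union, 200 ms
    deduplication, original kept on collision).  On clean signals no window
    crosses the threshold and the result is identical to the input; a merged
    union can never lose an original beat.
    """
    x = segment.samples
    fs = segment.fs
    mask, med = high_variance_mask(x, fs)
    if not mask.any() or med == 0.0:
        return BeatAnnotations(beats.peak_indices.copy(), beats.detector_id, fs)
    clip_level = float(np.percentile(np.abs(x[~mask]), 99)) if (~mask).any() else float(
        np.percentile(np.abs(x), 99)
    )
    clipped = np.clip(x, -clip_level, clip_level)
    re_seg = AnalysisSegment(samples=clipped, fs=fs, tw=segment.tw, origin=segment.origin)
    redetected = detect_qrs_primary(re_seg)
    return _merge_annotations(beats, redetected.peak_indices, fs)


def compute_sqi(
    a: BeatAnnotations, b: BeatAnnotations, tol: float = SQI_TOLERANCE
) -> Optional[SqiResult]:
    """Beat-agreement SQI: matched beats over the union of both detections.

    Greedy nearest-neighbour one-to-one matching within ``tol`` seconds;
    ``bsqi = matched / (|a| + |b| - matched)``.  Returns ``None`` when both
    annotation sets are empty (quality undefined).
    """
    ta, tb = a.times, b.times
    if ta.size == 0 and tb.size == 0:
        return None
    if ta.size == 0 or tb.size == 0:
        return SqiResult(0.0, 0, int(ta.size + tb.size))
    # greedy: sort all candidate pairs by |dt|, accept one-to-one
    diff = np.abs(ta[:, None] - tb[None, :])
    pairs = np.argwhere(diff <= tol)
    order = np.argsort(diff[pairs[:, 0], pairs[:, 1]]) if pairs.size else []
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = 0
    for k in order:
        i, j = pairs[k]
        if i not in used_a and j not in used_b:
            used_a.add(int(i))
            used_b.add(int(j))
            matched += 1
    union = int(ta.size + tb.size - matched)
    return SqiResult(matched / union if union else 1.0, matched, union)


def build_rr_series(beats: BeatAnnotations, fs: Optional[float] = None) -> RRSeries:
    """Convert beat annotations to an RR series with the physiological range rule.

    Intervals outside [0.2, 3.0] s are dropped (the series is bridged by
    removing that interval only; neighbouring intervals are kept).
    """
    fs = fs if fs is not None else beats.fs
    if beats.n_beats < 2:
        return RRSeries(
            beat_times=beats.peak_indices / fs,
            rr_intervals=np.asarray([]),
            rr_times=np.asarray([]),
        )
    beat_times = beats.peak_indices / fs
    rr = np.diff(beat_times)
    valid = (rr >= RR_RANGE[0]) & (rr <= RR_RANGE[1])
    return RRSeries(
        beat_times=beat_times,
        rr_intervals=rr[valid],
        rr_times=beat_times[1:][valid],
    )
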