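"""ECG waveform features v18--v21 computed on the filtered analysis segment.

* v18 -- centroid frequency of the Welch power spectral density
  (12 s Hann windows, 50% overlap, 4096-point FFT);
* v19 -- mean absolute amplitude of the segment (uV);
* v20 -- fraction of spectral power inside the QRS band (5--14 Hz);
* v21 -- standard deviation of per-beat QRS durations obtained by a
  quadratic-spline wavelet delineator (a-trous dyadic decomposition, scales
  2^1..2^4; onset/offset from the modulus-maxima pair around each R peak at
  scale 2^2 with a 10%-of-maximum threshold crossing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import signal as sig

from .hrv import Spectrum
from .preprocess import AnalysisSegment
from .qrs import BeatAnnotations

QRS_BAND = (5.0, 14.0)
WELCH_WINDOW_S = 12.0
WELCH_NFFT = 4096

#: modulus-maxima threshold fraction for onset/offset crossing
DELINEATION_THRESHOLD = 0.1
#: search window around the R peak (s)
DELINEATION_WINDOW = 0.12


@dataclass
class QrsDelineation:
    """Per-beat QRS onset/offset times (s) and durations."""

    onsets: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)

    @property
    def widths(self) -> np.ndarray:
        return self.offsets - self.onsets

    @property
    def n_beats(self) -> int:
        return int(self.onsets.size)


def compute_welch_psd(segment: AnalysisSegment) -> Spectrum:
    """Welch PSD with 12 s Hann windows, 50% overlap and a 4096-point FFT."""
    if segment.duration < WELCH_WINDOW_S:
        raise ValueError("segment must be at least 12 s for Welch estimation")
    nperseg = int(round(WELCH_WINDOW_S * segment.fs))
    freqs, psd = sig.welch(
        segment.samples,
        fs=segment.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=max(WELCH_NFFT, nperseg),
        detrend="constant",
    )
    return Spectrum(freqs=freqs, psd=psd)


def compute_centroid_frequency(spec: Spectrum) -> float:
    """Power-weighted mean frequency of the PSD (NaN for zero total power)."""
    total = float(np.sum(spec.psd))
    if total <= 0:
        return np.nan
    return float(np.sum(spec.psd * spec.freqs) / total)


def compute_mean_abs_amplitude(segment: AnalysisSegment) -> float:
    """Mean of the absolute sample values, in uV."""
    return float(np.mean(np.abs(segment.samples)))


def compute_relative_qrs_power(spec: Spectrum) -> float:
    """Fraction of PSD bin power inside the 5--14 Hz QRS band (edges inclusive)."""
    total = float(np.sum(spec.psd))
    if total <= 0:
        return np.nan
    mask = (spec.freqs >= QRS_BAND[0]) & (spec.freqs <= QRS_BAND[1])
    return float(np.sum(spec.psd[mask]) / total)


def _quadratic_spline_swt(x: np.ndarray, levels: int = 4) -> List[np.ndarray]:
    """A-trous dyadic wavelet transform with the quadratic-spline pair.

    Lowpass h = [1, 3, 3, 1]/8, highpass g = [2, -2]; at level j the filters
    are upsampled by 2^(j-1).  The details approximate the derivative of the
    signal smoothed at scale 2^j.  Constant group delays cancel in width
    (offset - onset) measurements.
    """
    h = np.array([1.0, 3.0, 3.0, 1.0]) / 8.0
    g = np.array([2.0, -2.0])
    details = []
    approx = x.astype(float)
    for j in range(levels):
        up = 2**j
        hj = np.zeros((h.size - 1) * up + 1)
        hj[::up] = h
        gj = np.zeros((g.size - 1) * up + 1)
        gj[::up] = g
        pad = max(hj.size, gj.size)
        padded = np.pad(approx, pad, mode="edge")
        w = np.convolve(padded, gj, mode="same")[pad:-pad]
        approx = np.convolve(padded, hj, mode="same")[pad:-pad]
        details.append(w)
    return details


def delineate_qrs(
    segment: AnalysisSegment, beats: BeatAnnotations
) -> Optional[QrsDelineation]:
    """Locate QRS onset/offset around each annotated R peak.

    Uses the scale-2^2 wavelet detail: the QRS produces a modulus-maxima pair
    (maximum positive and negative slope) flanking the R peak; the onset
    (offset) is where |W| drops below 10% of the pre- (post-) peak modulus
    maximum, searched within +/-120 ms of the R peak.  Beats whose
    delineation fails or falls outside (0, 0.3] s are excluded; ``None`` is
    returned when fewer than 3 beats or fewer than half of all beats
    delineate successfully.
    """
    if beats.n_beats < 3:
        return None
    fs = segment.fs
    w2 = _quadratic_spline_swt(segment.samples, levels=2)[1]
    win = int(round(DELINEATION_WINDOW * fs))
    onsets: list[float] = []
    offsets: list[float] = []
    n = w2.size
    for r in beats.peak_indices:
        lo = max(r - win, 0)
        hi = min(r + win + 1, n)
        if hi - lo < 5:
            continue
        pre = w2[lo : r + 1]
        post = w2[r:hi]
        if pre.size < 3 or post.size < 3:
            continue
        i_pre = lo + int(np.argmax(np.abs(pre)))
        i_post = r + int(np.argmax(np.abs(post)))
        m_pre = abs(w2[i_pre])
        m_post = abs(w2[i_post])
        if m_pre == 0 or m_post == 0:
            continue
        if np.sign(w2[i_pre]) == np.sign(w2[i_post]):
            continue  # not a modulus-maxima pair
        # onset: walk left from the pre-peak maximum until |W| < 0.1 * m_pre
        i = i_pre
        lo_stop = max(i_pre - win, 0)
        while i > lo_stop and abs(w2[i]) >= DELINEATION_THRESHOLD * m_pre:
            i -= 1
        onset = i
        j = i_post
        hi_stop = min(i_post + win, n - 1)
        while j < hi_stop and abs(w2[j]) >= DELINEATION_THRESHOLD * m_post:
            j += 1
        offset = j
        width = (offset - onset) / fs
        if 0 < width <= 0.3:
            onsets.append(onset / fs)
            offsets.append(offset / fs)
    if len(onsets) < 3 or len(onsets) < 0.5 * beats.n_beats:
        return None
    return QrsDelineation(onsets=np.asarray(onsets), offsets=np.asarray(offsets))


def qrs_width_sd(delineation: Optional[QrsDelineation]) -> float:
    """v21: sample SD of delineated QRS durations (NaN when unavailable)."""
    if delineation is None or delineation.n_beats < 3:
        return np.nan
    return float(np.std(delineation.widths, ddof=1))


def compute_waveform_features(
    segment: AnalysisSegment, beats: BeatAnnotations
) -> dict:
    """Waveform features v18--v21 as a name -> value dict (NaN = missing)."""
    out = {"v18": np.nan, "v19": np.nan, "v20": np.nan, "v21": np.nan}
    out["v19"] = compute_mean_abs_amplitude(segment)
    if segment.duration >= WELCH_WINDOW_S:
        spec = compute_welch_psd(segment)
        out["v18"] = compute_centroid_frequency(spec)
        out["v20"] = compute_relative_qrs_power(spec)
    out["v21"] = qrs_width_sd(delineate_qrs(segment, beats))
    return out
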