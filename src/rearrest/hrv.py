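"""Heart-rate-variability features v1--v17 from a short RR series.

Three groups are computed:

* time domain (v1--v6): mean RR, SDNN, RMSSD, coefficient of variation,
  NN50 count and interquartile range;
* frequency domain (v7--v13): absolute/relative power and peak frequency in
  the LF (0.04--0.15 Hz) and HF (0.15--0.4 Hz) bands of the Lomb--Scargle
  periodogram of the unevenly sampled RR sequence, plus the LF/HF ratio;
* nonlinear (v14--v17): squared Poincare descriptors SD1^2 and SD2^2, their
  ratio, and the sample entropy of the 10 Hz cubic-interpolated RR series
  with m=1 and r=0.2 times the interpolated series' SD.

Missing values are returned as NaN; callers treat NaN as a per-feature
missing flag.  Sample (n-1) variance conventions are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate

from .qrs import RRSeries

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: Lomb-Scargle evaluation grid (Hz): resolves the LF lower edge for 1-min
#: segments while keeping peak-frequency quantization at the grid step
LOMB_GRID = np.arange(0.005, 0.5 + 1e-12, 0.0025)

NN50_THRESHOLD = 0.050  # seconds


@dataclass
class Spectrum:
    """A one-sided power spectral density estimate."""

    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs.size != self.psd.size:
            raise ValueError("freqs and psd must have equal length")

    def total_power(self) -> float:
        return float(np.trapezoid(self.psd, self.freqs))


@dataclass
class SampEnParams:
    """Sample-entropy settings: embedding m, tolerance fraction r, grid rate."""

    m: int = 1
    r: float = 0.2
    interp_fs: float = 10.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be at least 1")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.interp_fs <= 0:
            raise ValueError("interp_fs must be positive")


def compute_time_domain(rr: RRSeries) -> dict:
    """Time-domain features v1--v6.

    v1 mean RR, v2 SDNN (sample SD), v3 RMSSD, v4 = v2/v1, v5 count of
    successive differences exceeding 50 ms, v6 interquartile range.
    """
    out = {k: np.nan for k in ("v1", "v2", "v3", "v4", "v5", "v6")}
    x = rr.rr_intervals
    if x.size < 2:
        return out
    out["v1"] = float(np.mean(x))
    out["v2"] = float(np.std(x, ddof=1))
    out["v4"] = out["v2"] / out["v1"] if out["v1"] > 0 else np.nan
    out["v6"] = float(np.percentile(x, 75) - np.percentile(x, 25))
    if x.size >= 3:
        d = np.diff(x)
        out["v3"] = float(np.sqrt(np.mean(d * d)))
        out["v5"] = float(np.sum(np.abs(d) > NN50_THRESHOLD))
    return out


def compute_lomb_psd(rr: RRSeries, grid: np.ndarray = LOMB_GRID) -> Spectrum | None:
    """Lomb--Scargle periodogram of the mean-subtracted RR values.

    Evaluated at the unevenly spaced beat times on a fixed 0.005--0.5 Hz
    grid.  The raw periodogram is rescaled to a one-sided density
    ``P * 2T/N`` (T = time span, N = number of intervals), so grid-integrated
    power approximates the series' variance.  Returns ``None`` when fewer
    than 8 intervals are available.
    """
    if rr.n_intervals < 8:
        return None
    t = rr.rr_times
    y = rr.rr_intervals - np.mean(rr.rr_intervals)
    span = float(t[-1] - t[0])
    if span <= 0:
        return None
    from scipy.signal import lombscargle

    power = lombscargle(t, y, 2 * np.pi * grid)
    psd = power * 2.0 * span / y.size
    return Spectrum(freqs=grid.copy(), psd=psd)


def _band_power(spec: Spectrum, band: tuple[float, float]) -> float:
    mask = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(spec.psd[mask], spec.freqs[mask]))


def _band_peak(spec: Spectrum, band: tuple[float, float]) -> float:
    mask = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    if not mask.any():
        return np.nan
    f = spec.freqs[mask]
    p = spec.psd[mask]
    return float(f[np.argmax(p)])


def compute_freq_domain(spec: Spectrum | None) -> dict:
    """Frequency-domain features v7--v13 from an RR spectrum.

    Absolute powers are trapezoid-integrated over the LF and HF bands;
    relative powers are normalized by LF+HF so v8 + v10 = 1.
    """
    keys = ("v7", "v8", "v9", "v10", "v11", "v12", "v13")
    out = {k: np.nan for k in keys}
    if spec is None:
        return out
    lf = _band_power(spec, LF_BAND)
    hf = _band_power(spec, HF_BAND)
    out["v7"] = lf
    out["v9"] = hf
    total = lf + hf
    if total > 0:
        out["v8"] = lf / total
        out["v10"] = hf / total
        out["v11"] = lf / hf if hf > 0 else np.nan
    out["v12"] = _band_peak(spec, LF_BAND)
    out["v13"] = _band_peak(spec, HF_BAND)
    return out


def compute_poincare(rr: RRSeries) -> dict:
    """Squared Poincare descriptors from successive interval pairs.

    v14 = SD1^2 = var((RR_{k+1} - RR_k)/sqrt(2)) measures short-term
    (width-of-ellipse) variability; v15 = SD2^2 = var((RR_{k+1} + RR_k)/sqrt(2))
    the long-term (depth) variability; v16 = v14/v15.
    """
    out = {"v14": np.nan, "v15": np.nan, "v16": np.nan}
    x = rr.rr_intervals
    if x.size < 3:
        return out
    a, b = x[:-1], x[1:]
    out["v14"] = float(np.var((b - a) / np.sqrt(2), ddof=1))
    out["v15"] = float(np.var((b + a) / np.sqrt(2), ddof=1))
    # variances at float-rounding scale are an effectively constant series
    if out["v15"] > 1e-14:
        out["v16"] = out["v14"] / out["v15"]
    else:
        out["v16"] = np.nan
    return out


def _interpolate_rr(rr: RRSeries, interp_fs: float) -> np.ndarray | None:
    """Cubic interpolation of (time, RR) onto a uniform grid."""
    t, y = rr.rr_times, rr.rr_intervals
    if t.size < 4:
        return None
    span = t[-1] - t[0]
    if span < 10.0:
        return None
    grid = np.arange(t[0], t[-1] + 1e-12, 1.0 / interp_fs)
    spline = interpolate.CubicSpline(t, y)
    return np.asarray(spline(grid))


def sample_entropy(x: np.ndarray, m: int, r: float) -> float:
    """SampEn of a uniformly sampled series with Chebyshev distance.

    ``-ln(A/B)`` where B counts m-length template pairs within tolerance r
    and A counts (m+1)-length pairs, both over templates i = 0..N-m-1 and
    unordered pairs i < j (self-matches excluded).  NaN when either count
    is zero.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        return np.nan
    n_templates = n - m
    # Chebyshev distances between m-templates, computed incrementally
    emb_m = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    emb_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    d_m = np.max(np.abs(emb_m[:, None, :] - emb_m[None, :, :]), axis=-1)
    d_m1 = np.max(np.abs(emb_m1[:, None, :] - emb_m1[None, :, :]), axis=-1)
    iu = np.triu_indices(n_templates, k=1)
    b = int(np.sum(d_m[iu] <= r))
    iu1 = np.triu_indices(emb_m1.shape[0], k=1)
    a = int(np.sum(d_m1[iu1] <= r))
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def compute_sample_entropy(rr: RRSeries, params: SampEnParams | None = None) -> float:
    """Sample entropy v17 of the 10 Hz cubic-interpolated RR series.

    The tolerance is ``r`` times the interpolated series' sample SD, so the
    feature is invariant to an overall rescaling of the RR series.  Constant
    series yield exactly 0; NaN flags an undefined value.
    """
    params = params or SampEnParams()
    y = _interpolate_rr(rr, params.interp_fs)
    if y is None:
        return np.nan
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        return 0.0  # perfectly regular: every template matches
    return sample_entropy(y, params.m, params.r * sd)


def compute_hrv_features(rr: RRSeries, sampen: SampEnParams | None = None) -> dict:
    """All 17 HRV features as a name -> value dict (NaN = missing)."""
    out = {}
    out.update(compute_time_domain(rr))
    out.update(compute_freq_domain(compute_lomb_psd(rr)))
    out.update(compute_poincare(rr))
    out["v17"] = compute_sample_entropy(rr, sampen)
    return out
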