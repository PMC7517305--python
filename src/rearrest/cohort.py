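"""Synthetic post-ROSC ECG cohort simulator.

Generates labeled single-channel ECG records whose RR dynamics and waveform
statistics are controllable, so every downstream stage (QRS detection, HRV
features, classification) can be tested without clinical data.

The RR series is built beat by beat: each interval is the sum of a mean rate,
sinusoidal low-frequency (LF, ~0.1 Hz) and high-frequency (HF, ~0.3 Hz)
modulations sampled at the cumulative beat times, and white jitter.  Ectopic
beats are modeled as a single-interval shortening with a compensatory
lengthening of the next interval.  The ECG waveform places a
difference-of-Gaussians beat template (narrow positive QRS bump plus a lower,
slower T bump) at each beat time and adds baseline wander, broadband noise
and transient spike artifacts.

Rearrest (RA) records differ from no-rearrest (NoRA) records by a set of
class-effect multipliers (default: RR modulation amplitudes, jitter and QRS
width jitter all doubled), emulating the higher RR variability and wider
Poincare dispersion observed in patients that go on to rearrest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

from .preprocess import EcgRecord
from .qrs import RRSeries

#: "width" of the template QRS bump is the interval between the two points
#: where the slope magnitude falls to 10% of its extremum; for a Gaussian of
#: scale sigma that interval is 5.46*sigma (x*exp(-x^2/2) = 0.1*exp(-1/2)).
WIDTH_TO_SIGMA = 1.0 / 5.46

#: default class-effect multipliers applied to RA patients.  The increase in
#: RA variability is predominantly structured (sinusoidal LF/HF modulation)
#: rather than white: this reproduces the clinically observed pattern of a
#: more variable (higher SDNN / SD2^2) yet more regular (lower sample
#: entropy) RR series in patients that go on to rearrest.
DEFAULT_CLASS_EFFECT: Dict[str, float] = {
    "lf_amp": 2.5,
    "hf_amp": 2.5,
    "jitter_sd": 1.2,
    "sdnn_target": 2.0,
    "qrs_width_sd": 2.0,
}


@dataclass
class RrModelParams:
    """Parameters of the beat-interval generator.

    ``mean_rr`` is the base interval (s); ``lf_amp``/``hf_amp`` are the
    amplitudes (s) of sinusoidal modulations at ``lf_freq``/``hf_freq`` (Hz);
    ``jitter_sd`` is white beat-to-beat noise (s); ``ectopic_rate`` is the
    per-beat probability of a -30% shortening with compensatory lengthening.
    If ``sdnn_target`` is set, ``jitter_sd`` is recomputed so the expected
    overall RR standard deviation matches it.
    """

    mean_rr: float = 0.60
    sdnn_target: Optional[float] = None
    lf_amp: float = 0.035
    lf_freq: float = 0.10
    hf_amp: float = 0.025
    hf_freq: float = 0.30
    jitter_sd: float = 0.025
    ectopic_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.mean_rr <= 0.25:
            raise ValueError("mean_rr must exceed 0.25 s")
        for name in ("lf_amp", "hf_amp", "jitter_sd", "ectopic_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.04 <= self.lf_freq < 0.15):
            raise ValueError("lf_freq must lie in [0.04, 0.15) Hz")
        if not (0.15 <= self.hf_freq <= 0.40):
            raise ValueError("hf_freq must lie in [0.15, 0.4] Hz")

    def effective_jitter_sd(self) -> float:
        """White-noise SD, honouring ``sdnn_target`` when set.

        Sinusoidal components contribute amp^2/2 each to the RR variance, so
        the jitter needed for a total SD target is the residual root.
        """
        if self.sdnn_target is None:
            return self.jitter_sd
        resid = self.sdnn_target**2 - 0.5 * self.lf_amp**2 - 0.5 * self.hf_amp**2
        return float(np.sqrt(max(resid, 0.0)))


@dataclass
class MorphologyParams:
    """Beat-template shape: QRS bump amplitude/width and T bump amplitude."""

    qrs_width: float = 0.08
    qrs_amp: float = 800.0
    t_amp: float = 150.0
    qrs_width_sd: float = 0.004

    def __post_init__(self) -> None:
        if not (0.02 <= self.qrs_width <= 0.2):
            raise ValueError("qrs_width must lie in [0.02, 0.2] s")
        for name in ("qrs_amp", "t_amp", "qrs_width_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class NoiseParams:
    """Additive disturbances: baseline wander, white noise, spike artifacts."""

    baseline_amp: float = 80.0
    baseline_freq: float = 0.25
    white_sd: float = 20.0
    spike_rate: float = 0.5  # events per minute
    spike_amp: float = 1200.0

    def __post_init__(self) -> None:
        for name in ("baseline_amp", "baseline_freq", "white_sd", "spike_rate", "spike_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.baseline_freq >= 0.5:
            raise ValueError("baseline_freq must be below 0.5 Hz")

    @classmethod
    def none(cls) -> "NoiseParams":
        """Noise-free configuration (useful for oracle tests)."""
        return cls(baseline_amp=0.0, white_sd=0.0, spike_rate=0.0, spike_amp=0.0)


@dataclass
class CohortConfig:
    """Study-level knobs for a simulated cohort.

    Defaults follow the reference study conditions: 162 patients with a
    55/107 RA/NoRA split (prevalence 0.3395) and a 2-minute analysis window
    at 250 Hz.
    """

    n_patients: int = 162
    prevalence: float = 55.0 / 162.0
    tw: float = 2.0
    fs: float = 250.0
    class_effect: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_EFFECT)
    )
    rr_params: RrModelParams = field(default_factory=RrModelParams)
    morph_params: MorphologyParams = field(default_factory=MorphologyParams)
    noise_params: NoiseParams = field(default_factory=NoiseParams)
    rosc_lead_in: float = 5.0  # seconds of record before ROSC onset
    seed: int = 0

    # between-patient heterogeneity (lognormal sigma on amplitudes, normal
    # sd on mean RR); zero gives identical parameters for every patient
    mean_rr_sd: float = 0.08
    param_spread: float = 0.35

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie strictly between 0 and 1")
        n_pos = int(round(self.n_patients * self.prevalence))
        if n_pos == 0 or n_pos == self.n_patients:
            raise ValueError("prevalence yields an empty class")


def generate_rr_series(
    params: RrModelParams, duration: float, seed: int | np.random.SeedSequence = 0
) -> RRSeries:
    """Generate ground-truth beat times covering ``[0, duration]``.

    Each interval is sampled at the running beat time (integral-pulse style):
    ``RR_k = mean_rr + lf_amp*sin(2*pi*lf_freq*t_k) + hf_amp*sin(2*pi*hf_freq*t_k)
    + jitter``, after which ectopic shorten/compensate perturbations are
    applied.  Jitter draws violating the 0.2 s physiological floor are
    resampled.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    jitter_sd = params.effective_jitter_sd()

    times = [0.0]
    rr: List[float] = []
    while True:
        t = times[-1]
        base = (
            params.mean_rr
            + params.lf_amp * np.sin(2 * np.pi * params.lf_freq * t)
            + params.hf_amp * np.sin(2 * np.pi * params.hf_freq * t)
        )
        interval = base + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
        tries = 0
        while interval <= 0.2 and tries < 1000:
            interval = base + rng.normal(0.0, jitter_sd)
            tries += 1
        interval = max(interval, 0.201)
        if t + interval > duration + 1e-9:
            break
        rr.append(interval)
        times.append(t + interval)

    rr_arr = np.asarray(rr)
    if params.ectopic_rate > 0 and rr_arr.size >= 2:
        ect = rng.random(rr_arr.size - 1) < params.ectopic_rate
        for i in np.nonzero(ect)[0]:
            delta = 0.3 * rr_arr[i]
            if rr_arr[i] - delta > 0.2:
                rr_arr[i] -= delta
                rr_arr[i + 1] += delta
    beat_times = np.concatenate([[0.0], np.cumsum(rr_arr)])
    return RRSeries(
        beat_times=beat_times,
        rr_intervals=rr_arr,
        rr_times=beat_times[1:],
    )


def _beat_template(t: np.ndarray, center: float, sigma: float, morph: MorphologyParams,
                   rr_next: float) -> np.ndarray:
    """Difference-of-Gaussians beat: QRS bump + lower, slower T bump."""
    qrs = morph.qrs_amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    t_center = center + 0.30 * rr_next
    t_sigma = 0.04 + 0.02 * rr_next
    t_wave = morph.t_amp * np.exp(-0.5 * ((t - t_center) / t_sigma) ** 2)
    return qrs + t_wave


def synthesize_ecg(
    rr: RRSeries,
    morph: MorphologyParams,
    noise: NoiseParams,
    fs: float,
    seed: int | np.random.SeedSequence = 0,
    duration: Optional[float] = None,
) -> EcgRecord:
    """Render an RR series into a sampled ECG trace.

    One beat template is centered at each beat time; baseline-wander
    sinusoid, white noise and random spike artifacts are added on top.  The
    ground-truth R-peak sample indices are stored on the returned record.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if rr.beat_times.size == 0:
        raise ValueError("rr series is empty")
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = float(rr.beat_times[-1]) + float(np.mean(rr.rr_intervals)) if rr.rr_intervals.size else float(rr.beat_times[-1]) + 1.0
    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)

    widths = morph.qrs_width + (
        rng.normal(0.0, morph.qrs_width_sd, size=rr.beat_times.size)
        if morph.qrs_width_sd > 0
        else np.zeros(rr.beat_times.size)
    )
    widths = np.clip(widths, 0.02, 0.2)
    mean_rr = float(np.mean(rr.rr_intervals)) if rr.rr_intervals.size else 0.8
    for k, bt in enumerate(rr.beat_times):
        sigma = widths[k] * WIDTH_TO_SIGMA
        rr_next = rr.rr_intervals[k] if k < rr.rr_intervals.size else mean_rr
        lo = max(int((bt - 0.25) * fs), 0)
        hi = min(int((bt + 0.8 * rr_next + 0.25) * fs), n)
        if hi > lo:
            x[lo:hi] += _beat_template(t[lo:hi], bt, sigma, morph, rr_next)

    if noise.baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += noise.baseline_amp * np.sin(2 * np.pi * noise.baseline_freq * t + phase)
    if noise.white_sd > 0:
        x += rng.normal(0.0, noise.white_sd, size=n)
    if noise.spike_rate > 0 and noise.spike_amp > 0:
        n_spikes = rng.poisson(noise.spike_rate * duration / 60.0)
        for _ in range(n_spikes):
            idx = rng.integers(1, n - 1)
            sign = rng.choice([-1.0, 1.0])
            x[idx] += sign * noise.spike_amp
            x[idx - 1] += 0.5 * sign * noise.spike_amp
            x[idx + 1] += 0.5 * sign * noise.spike_amp

    peaks = np.round(rr.beat_times * fs).astype(int)
    peaks = peaks[peaks < n]
    return EcgRecord(
        patient_id="synthetic",
        samples=x,
        fs=fs,
        rosc_time=0.0,
        label=0,
        ground_truth_peaks=peaks,
    )


def _apply_class_effect(
    rr_params: RrModelParams, morph: MorphologyParams, effect: Dict[str, float]
) -> tuple[RrModelParams, MorphologyParams]:
    rr_kw = {}
    for name in ("lf_amp", "hf_amp", "jitter_sd", "ectopic_rate", "mean_rr"):
        if name in effect:
            rr_kw[name] = getattr(rr_params, name) * effect[name]
    if "sdnn_target" in effect and rr_params.sdnn_target is not None:
        rr_kw["sdnn_target"] = rr_params.sdnn_target * effect["sdnn_target"]
    morph_kw = {}
    for name in ("qrs_width", "qrs_amp", "t_amp", "qrs_width_sd"):
        if name in effect:
            morph_kw[name] = getattr(morph, name) * effect[name]
    return replace(rr_params, **rr_kw), replace(morph, **morph_kw)


def _jitter_patient_params(
    rr_params: RrModelParams, morph: MorphologyParams, cfg: CohortConfig,
    rng: np.random.Generator
) -> tuple[RrModelParams, MorphologyParams]:
    """Between-patient heterogeneity: lognormal scale on amplitudes."""
    s = cfg.param_spread
    def ln() -> float:
        return float(np.exp(rng.normal(0.0, s))) if s > 0 else 1.0

    mean_rr = max(rr_params.mean_rr + rng.normal(0.0, cfg.mean_rr_sd), 0.30)
    rr_p = replace(
        rr_params,
        mean_rr=mean_rr,
        lf_amp=rr_params.lf_amp * ln(),
        hf_amp=rr_params.hf_amp * ln(),
        jitter_sd=rr_params.jitter_sd * ln(),
        sdnn_target=None if rr_params.sdnn_target is None else rr_params.sdnn_target * ln(),
    )
    morph_p = replace(
        morph,
        qrs_amp=morph.qrs_amp * ln(),
        qrs_width=float(np.clip(morph.qrs_width * ln() ** 0.3, 0.04, 0.16)),
    )
    return rr_p, morph_p


def generate_cohort(config: CohortConfig) -> List[EcgRecord]:
    """Simulate a labeled cohort of post-ROSC ECG records.

    Exactly ``round(n_patients * prevalence)`` records are RA; RA records are
    generated with the class-effect multipliers applied.  One master seed
    spawns per-patient substreams, so the cohort is reproducible regardless
    of patient order.
    """
    n_pos = int(round(config.n_patients * config.prevalence))
    labels = np.zeros(config.n_patients, dtype=int)
    labels[:n_pos] = 1

    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_patients)
    duration = config.rosc_lead_in + config.tw * 60.0 + 2.0

    records: List[EcgRecord] = []
    for i, (label, stream) in enumerate(zip(labels, streams)):
        sub_param, sub_rr, sub_ecg, sub_meta = stream.spawn(4)
        rng_param = np.random.default_rng(sub_param)
        rr_params, morph = _jitter_patient_params(
            config.rr_params, config.morph_params, config, rng_param
        )
        if label == 1:
            rr_params, morph = _apply_class_effect(rr_params, morph, config.class_effect)
        rr = generate_rr_series(rr_params, duration, seed=sub_rr)
        rec = synthesize_ecg(
            rr, morph, config.noise_params, config.fs, seed=sub_ecg, duration=duration
        )
        rec.patient_id = f"p{i:04d}"
        rec.rosc_time = config.rosc_lead_in
        rec.label = int(label)
        if label == 1:
            rng_meta = np.random.default_rng(sub_meta)
            rec.rearrest_time = config.rosc_lead_in + config.tw * 60.0 + float(
                rng_meta.exponential(180.0)
            )
        records.append(rec)
    return records
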