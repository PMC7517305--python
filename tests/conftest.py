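"""Shared fixtures: synthetic records and cohorts reused across test modules."""

import numpy as np
import pytest

from rearrest.cohort import (
    CohortConfig,
    MorphologyParams,
    NoiseParams,
    RrModelParams,
    generate_cohort,
    generate_rr_series,
    synthesize_ecg,
)
from rearrest.preprocess import AnalysisSegment, bandpass_filter, extract_segment


@pytest.fixture(scope="session")
def clean_morph() -> MorphologyParams:
    return MorphologyParams(qrs_amp=800.0, qrs_width_sd=0.0)


@pytest.fixture(scope="session")
def steady_rr_params() -> RrModelParams:
    """Modulated but ectopic-free RR dynamics (deterministic spectral content)."""
    return RrModelParams(ectopic_rate=0.0)


@pytest.fixture(scope="session")
def clean_record(steady_rr_params, clean_morph):
    """Noiseless 2-minute synthetic record with ground-truth peaks."""
    rr = generate_rr_series(steady_rr_params, 125.0, seed=7)
    return synthesize_ecg(rr, clean_morph, NoiseParams.none(), 250.0, seed=7)


@pytest.fixture(scope="session")
def clean_segment(clean_record):
    seg = AnalysisSegment(
        clean_record.samples, clean_record.fs, 2.0,
        ground_truth_peaks=clean_record.ground_truth_peaks,
    )
    return bandpass_filter(seg)


@pytest.fixture(scope="session")
def noiseless_cohort20():
    """20 noiseless 1-minute patients (both classes) for detector QA."""
    cfg = CohortConfig(
        n_patients=20, prevalence=0.5, tw=1.0, seed=42,
        noise_params=NoiseParams.none(),
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort20():
    """20 patients with white noise at 10% of the QRS amplitude.

    Parameter heterogeneity is disabled so the noise-to-QRS ratio is the
    same for every patient.
    """
    noise = NoiseParams(baseline_amp=80.0, white_sd=80.0, spike_rate=0.0, spike_amp=0.0)
    cfg = CohortConfig(
        n_patients=20, prevalence=0.5, tw=1.0, seed=43, noise_params=noise,
        param_spread=0.0, mean_rr_sd=0.08,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_cohort_table():
    """Feature table of the default 162-patient cohort (RA effect applied)."""
    from rearrest.pipeline import build_feature_table

    records = generate_cohort(CohortConfig(seed=20))
    return build_feature_table(records)


@pytest.fixture(scope="session")
def small_cohort16():
    """16-patient cohort for fast end-to-end pipeline checks."""
    cfg = CohortConfig(n_patients=16, prevalence=0.5, tw=1.0, seed=55,
                       noise_params=NoiseParams(spike_rate=0.0))
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort16):
    from rearrest.config import PipelineConfig
    from rearrest.pipeline import build_feature_table

    return build_feature_table(small_cohort16, PipelineConfig(tw=1.0))


def filtered_segment_of(record, tw: float) -> AnalysisSegment:
    """Cut and band-pass the post-ROSC window of a synthetic record."""
    seg = extract_segment(record, tw)
    assert seg is not None
    return bandpass_filter(seg)


def interior_truth(record, segment) -> np.ndarray:
    """Ground-truth peaks away from the segment edges (scoreable beats)."""
    gt = segment.ground_truth_peaks
    guard = 0.2 * segment.fs
    return gt[(gt >= guard) & (gt <= segment.samples.size - 1 - guard)]
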