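"""Pipeline configuration with auditable defaults.

Every numeric default corresponds to the published analysis settings: a
2-minute (or 1-minute) window at 250 Hz, a 0.5--40 Hz order-4 zero-phase
band-pass, sample entropy with m=1, r=0.2 on a 10 Hz interpolated series,
Welch estimation with 12 s windows / 50% overlap / 4096-point FFT, a
300-tree forest on 5% balanced bootstraps, and 100 repetitions of
stratified 5-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import yaml

HRV_FEATURES = [f"v{i}" for i in range(1, 18)]
ALL_FEATURES = [f"v{i}" for i in range(1, 22)]


@dataclass
class PipelineConfig:
    """End-to-end settings for simulation, feature extraction and evaluation."""

    tw: float = 2.0
    fs: float = 250.0
    filter_band: tuple = (0.5, 40.0)
    filter_order: int = 4
    sampen_m: int = 1
    sampen_r: float = 0.2
    sampen_interp_fs: float = 10.0
    lomb_fmin: float = 0.005
    lomb_fmax: float = 0.5
    lomb_df: float = 0.0025
    welch_window_s: float = 12.0
    welch_overlap: float = 0.5
    welch_nfft: int = 4096
    n_trees: int = 300
    per_tree_fraction: float = 0.05
    nf: Optional[int] = None
    cv_k: int = 5
    cv_reps: int = 100
    feature_mode: str = "all"  # "all" (21 features) or "hrv_only" (17)
    seed: int = 0

    def feature_columns(self) -> list:
        if self.feature_mode == "hrv_only":
            return list(HRV_FEATURES)
        if self.feature_mode == "all":
            return list(ALL_FEATURES)
        raise ValueError(f"unknown feature_mode {self.feature_mode!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["filter_band"] = list(d["filter_band"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "filter_band" in d:
            d["filter_band"] = tuple(d["filter_band"])
        return cls(**d)
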