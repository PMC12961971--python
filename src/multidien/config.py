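"""Pipeline configuration with TOML round-trip.

Every numeric default of the analysis chain lives here: the multidien
period search range and red-noise confidence, the phase-bin geometry is
fixed (quadrants), band edges, spike-detector thresholds, the
post-stimulation guard/window, the inclusion minimum of 200 analysis
windows, PCA retained variance, SVM regularisation and permutation count.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    # dIEA preprocessing
    max_gap_hours: float = 24.0
    min_segment_days: float = 90.0
    initial_discard_days: float = 28.0
    # periodogram
    min_period_days: float = 3.0
    max_period_days: float = 60.0
    voices_per_octave: int = 24
    wavelet_omega0: float = 6.0
    rednoise_confidence: float = 0.99
    reconstruction_bandwidth_octaves: float = 0.3333333333333333
    # features
    band_edges_hz: dict = field(
        default_factory=lambda: {
            "theta": [4.0, 8.0],
            "alpha": [8.0, 13.0],
            "beta": [13.0, 30.0],
            "gamma": [33.0, 100.0],
        }
    )
    spike_threshold_z: float = 6.0
    spike_sharpness_z: float = 2.0
    spike_width_ms: list = field(default_factory=lambda: [20.0, 200.0])
    post_stim_guard_s: float = 2.0
    post_stim_window_s: float = 10.0
    day_start_hour: int = 8
    day_end_hour: int = 20
    min_feature_rows: int = 200
    # classifier
    pca_variance: float = 0.95
    svm_c: float = 1.0
    n_folds: int = 10
    n_perm: int = 1000
    seed: int = 0

    def to_toml(self, path=None) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name} = {_toml_value(v)}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_toml(cls, source) -> "PipelineConfig":
        """Load from a TOML file path or a TOML text string."""
        text = str(source)
        if "\n" not in text and "=" not in text:
            text = Path(source).read_text()
        data = tomllib.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    if isinstance(v, dict):
        inner = ", ".join(f"{k} = {_toml_value(x)}" for k, x in v.items())
        return "{" + inner + "}"
    raise TypeError(f"unsupported config value: {v!r}")
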