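"""Run configuration: every tunable of the simulation, feature extraction,
detector and statistics in one serialisable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
import yaml

from .detector import DetectorConfig
from .features import FeatureConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full simulate→detect→compare run."""

    # cohort
    n_subjects: int = 18
    seed: int = 0
    sampling_rate: float = 250.0
    record_duration_s: float = 1200.0
    max_seizures_per_subject: int | None = 6
    seizure_count_p: float = 0.15
    seizure_count_range: tuple[int, int] = (1, 68)
    amplitude_median_uV: float = 123.0
    amplitude_sigma_ln: float = 0.95
    duration_median_s: float = 103.0
    duration_sigma_ln: float = 0.7
    # drug effect
    amplitude_scale: float = 0.435
    channel_delta: int = 1
    # detector
    threshold: float = 0.3
    n_training_subjects: int = 5
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    # feature surrogates
    features: FeatureConfig = field(default_factory=FeatureConfig)
    # outputs
    out_dir: str = "neoictal_run"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["seizure_count_range"] = list(self.seizure_count_range)
        d["features"]["freq_band"] = list(self.features.freq_band)
        d["features"]["ictal_band"] = list(self.features.ictal_band)
        d["detector"]["svm_gamma_grid"] = list(self.detector.svm_gamma_grid)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        det = d.pop("detector", {})
        feat = d.pop("features", {})
        if "svm_gamma_grid" in det:
            det["svm_gamma_grid"] = tuple(det["svm_gamma_grid"])
        for key in ("freq_band", "ictal_band"):
            if key in feat:
                feat[key] = tuple(feat[key])
        if "seizure_count_range" in d:
            d["seizure_count_range"] = tuple(d["seizure_count_range"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(detector=DetectorConfig(**det), features=FeatureConfig(**feat), **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
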