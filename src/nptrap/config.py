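"""Pipeline configuration: defaults, validation, YAML loading."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end pipeline, with module defaults.

    Unknown keys in a config file are rejected rather than ignored, so typos
    fail loudly.  The effective configuration is echoed into the run manifest.
    """

    # simulation
    n_genes: int = 400
    utr_length_range: tuple = (250, 800)
    u_content_range: tuple = (0.15, 0.35)
    orf_length_range: tuple = (300, 3000)
    read_length: int = 50
    conditions: tuple = ("control", "stress")
    n_replicates: int = 3
    assays: tuple = ("rna", "ptrap")
    labeling_time: float = 3.0
    library_size: float = 200_000.0
    dispersion: float = 0.05
    p_conv: float = 0.1
    p_err: float = 0.001
    kinetics: str = "step"
    k_deg_range: tuple = (0.1, 1.0)
    loading_lag: float = 1.0
    loading_lag_orf_range: tuple | None = None
    mode_fractions: dict = dataclasses.field(default_factory=lambda: {
        "null": 0.6, "forwarded": 0.1, "exclusive": 0.1,
        "intensified": 0.1, "buffered": 0.1})
    effect_size_log2: float = 2.0
    # conversion counting
    trim5: int = 12
    max_polya_keep: int = 4
    min_base_quality: int = 27
    min_tc: int = 1
    # decomposition
    top_k: int = 3
    min_support: int = 20
    formulation: str = "excess"
    # differential expression
    alpha: float = 0.05
    lfc_threshold: float = 1.5
    min_filter_mean: float = 5.0
    # deltaTE
    deltate_alpha: float = 0.05
    deltate_lfc_threshold: float = 0.0
    # category statistics
    min_set_size: int = 5
    n_length_bins: int = 4
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.kinetics not in ("steady_state", "step"):
            raise ConfigError(f"unknown kinetics {self.kinetics!r}")
        if self.formulation not in ("excess", "treated"):
            raise ConfigError(f"unknown formulation {self.formulation!r}")
        if not 0 < self.alpha < 1 or not 0 < self.deltate_alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        for name in ("utr_length_range", "u_content_range", "orf_length_range",
                     "k_deg_range", "conditions", "assays"):
            value = getattr(self, name)
            if value is not None:
                object.__setattr__(self, name, tuple(value))
        if self.loading_lag_orf_range is not None:
            object.__setattr__(self, "loading_lag_orf_range",
                               tuple(self.loading_lag_orf_range))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if isinstance(value, tuple):
                out[key] = list(value)
        return out
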