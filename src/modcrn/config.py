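"""Pipeline configuration.

One structured document collects every stage parameter.  Defaults are the
reference parameterization of the motivating two-organ study wherever it
states one (confidence filter 0.7; DEG thresholds p < 0.05 and |log2FC| >=
0.5; 2,000,000 clique iterations; 10,000 random sets; alpha 0.01; 100
bootstrap samples; 12-fold CV repeated 1000 times).  ``synthetic_defaults``
returns a copy with analysis sizes scaled to the bundled synthetic study so
an end-to-end run completes in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["SynthConfig", "PipelineConfig"]


@dataclass
class SynthConfig:
    """Synthetic-study shape: network, planted truth, design, effects."""

    n_background: int = 300
    background_density: float = 0.02
    clique_sizes: list[int] = field(default_factory=lambda: [6] * 8)
    n_per_cell: int = 6
    baseline_mean: float = 8.0
    effect_size: float = 2.0
    organ_effect: float = 1.0
    noise_sd: float = 0.5
    deg_rate_in: float = 0.7
    deg_rate_out: float = 0.05
    n_decoys: int = 5
    decoy_size: int = 10


@dataclass
class PipelineConfig:
    seed: int = 0
    # network input
    score_threshold: float = 0.7
    # DEG calling
    p_threshold: float = 0.05
    lfc_threshold: float = 0.5
    # module discovery
    iterations: int = 2_000_000
    min_clique_size: int = 3
    random_sets: int = 10_000
    alpha: float = 0.01
    bootstraps: int = 100
    smoothing: bool = True
    # clustering
    gtom_m: int = 1
    linkage: str = "average"
    k: int | None = None
    cut_height: float | None = None
    top_n_hubs: int = 5
    # CRN
    k_folds: int = 12
    n_runs: int = 1000
    lambda_grid_size: int = 100
    lambda_min_ratio: float = 1e-4
    nonzero_tol: float = 1e-8
    # synthetic study
    synth: SynthConfig = field(default_factory=SynthConfig)

    @classmethod
    def synthetic_defaults(cls) -> "PipelineConfig":
        """Scaled parameterization for the bundled synthetic study."""
        return cls(iterations=15_000, random_sets=500, bootstraps=20, n_runs=50)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        synth = data.pop("synth", {})
        cfg = cls(**data)
        return replace(cfg, synth=SynthConfig(**synth))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def override(self, **kwargs) -> "PipelineConfig":
        """Copy with non-None keyword overrides applied (CLI flags)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)
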