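"""Run configuration with the study's stated stage defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All stage parameters; defaults are the published analysis settings."""

    # randomness
    seed: int = 0
    # synthetic inputs
    n_nodes: int = 150
    edges_per_node: int = 3
    n_receptors: int = 3
    n_paths: int = 3
    path_length: int = 4
    replicates: int = 3
    effect_size: float = 2.0
    noise_sd: float = 0.5
    missing_rate: float = 0.1
    support_mode: str = "shared"
    # preprocessing
    cpm_threshold: float = 2.0
    qc_min_quantified: int = 50
    impute_min_quantified: int = 3
    anova_phospho: dict = field(default_factory=lambda: {
        "fdr_threshold": 0.1, "effect_threshold": 0.5,
        "adjust": True, "zscore": True})
    anova_strict: dict = field(default_factory=lambda: {
        "fdr_threshold": 0.001, "effect_threshold": 1.0,
        "adjust": False, "zscore": True})
    # factor model
    n_factors: int = 3
    seed_quantile: float = 0.05
    # propagation
    damping: float = 0.95
    rwr_threshold: float = 0.01
    kde_cutoff: float = 0.5
    n_null: int = 1000
    # subnetwork extraction
    n_terminals: int = 50
    pcsf_beta: float = 1.0
    pcsf_iters: int = 4000
    pcsf_noise: float = 0.05
    pcsf_freq_cutoff: float = 0.5
    # cross-talk and flow
    receptor_alpha: float = 0.01
    kinomics_threshold: float = 1.0
    crosstalk_n_perm: int = 10_000
    flow_percentile: float = 95.0
    # TF activity
    min_count: int = 10
    min_targets: int = 5

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
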