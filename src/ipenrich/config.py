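"""Tunable parameters of the enrichment pipeline.

The defaults are the constants of the published procedure this package
implements: proteins with fewer than two razor+unique peptides are dismissed;
missing control intensities are imputed from a normal distribution centred at
the 5% quantile of the pooled log10 LFQ intensities with SD 0.1 (requiring at
least three peptides for imputed proteins); boxplot outliers are called in
intensity bins of at least 300 proteins, at 1.5x IQR (significance 1) and
3x IQR (significance 2).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    """Raised for an invalid or unknown configuration setting."""


@dataclass
class AnalysisConfig:
    """All tunables of the enrichment pipeline.

    Parameters
    ----------
    min_peptides_observed:
        Minimum razor+unique peptide count for any protein to be retained.
    min_peptides_imputed:
        Stricter minimum applied to proteins whose control intensity is
        imputed rather than measured.
    imputation_quantile_level:
        Quantile of the pooled log10 intensity distribution used as the
        imputation baseline (mean of the imputation normal).
    imputation_sd:
        SD of the imputation normal, in log10-intensity units.
    min_bin_size:
        Minimum number of proteins per intensity bin for outlier calling.
    iqr_multiplier_sig1, iqr_multiplier_sig2:
        IQR multiples defining the significance-1 and significance-2 fences.
    rng_seed:
        Seed for the imputation draws; identical seeds give identical output.
    drop_site_only:
        Whether to remove proteins identified only by a modification site.
    """

    min_peptides_observed: int = 2
    min_peptides_imputed: int = 3
    imputation_quantile_level: float = 0.05
    imputation_sd: float = 0.1
    min_bin_size: int = 300
    iqr_multiplier_sig1: float = 1.5
    iqr_multiplier_sig2: float = 3.0
    rng_seed: int = 0
    drop_site_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.imputation_quantile_level < 1.0:
            raise ConfigError(
                "imputation_quantile_level must lie strictly between 0 and 1, "
                f"got {self.imputation_quantile_level}"
            )
        if not 0.0 < self.iqr_multiplier_sig1 < self.iqr_multiplier_sig2:
            raise ConfigError(
                "require 0 < iqr_multiplier_sig1 < iqr_multiplier_sig2, got "
                f"{self.iqr_multiplier_sig1} and {self.iqr_multiplier_sig2}"
            )
        if self.min_bin_size < 1:
            raise ConfigError(f"min_bin_size must be >= 1, got {self.min_bin_size}")
        if self.imputation_sd <= 0:
            raise ConfigError(f"imputation_sd must be > 0, got {self.imputation_sd}")
        if self.min_peptides_observed < 0 or self.min_peptides_imputed < 0:
            raise ConfigError("peptide thresholds must be non-negative")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(
                "unknown configuration key(s): " + ", ".join(sorted(unknown))
            )
        return cls(**dict(mapping))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a flat YAML mapping; unknown keys are errors."""
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=False)
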