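"""Synthetic single-run AP-MS experiments with known ground truth.

The generator emulates the structure a bait-vs-control LFQ comparison
assumes: log-normally distributed protein intensities, bait/control ratios
that are null for the background proteome and shifted for a configurable set
of spiked-in true interactors, peptide counts that grow with abundance, and
control intensities that go missing by left-censoring at a detection
threshold — so missingness concentrates near the baseline for background
proteins and is frequent for interactors depleted from the control IP.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .config import ConfigError
from .enrichment import EnrichmentRecord
from .io_tables import DEFAULT_COLUMN_MAP, ProteinRecord, ProteinTable

#: Truth labels.
BACKGROUND = "background"
INTERACTOR = "interactor"


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic AP-MS experiment.

    ``control_missing_baseline_prob`` / ``control_missing_interactor_prob``
    are the marginal probabilities that a background / interactor protein
    lacks a control intensity.  Missingness is implemented as censoring
    below the matching normal quantile of the control-intensity
    distribution, so missing controls sit at the low-intensity baseline.
    """

    n_background: int = 2000
    n_true_interactors: int = 30
    log10_mean: float = 6.5
    log10_sd: float = 1.0
    ratio_noise_sd: float = 0.35
    effect_size_log2: float = 4.0
    control_missing_baseline_prob: float = 0.05
    control_missing_interactor_prob: float = 0.6
    peptide_rate_per_log10: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("control_missing_baseline_prob", "control_missing_interactor_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        if self.n_background < 0 or self.n_true_interactors < 0:
            raise ConfigError("protein counts must be non-negative")
        if self.n_background + self.n_true_interactors < 1:
            raise ConfigError("simulate at least one protein")
        if self.effect_size_log2 < 0:
            raise ConfigError("effect_size_log2 must be >= 0")
        if self.log10_sd <= 0 or self.ratio_noise_sd < 0:
            raise ConfigError("spread parameters must be positive")
        if self.peptide_rate_per_log10 <= 0:
            raise ConfigError("peptide_rate_per_log10 must be > 0")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(
                "unknown simulation key(s): " + ", ".join(sorted(unknown))
            )
        return cls(**dict(mapping))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"simulation config {path} must contain a mapping")
        return cls.from_mapping(data)


@dataclass
class RecoveryCounts:
    """Confusion counts and derived rates at one call threshold."""

    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float


@dataclass
class RecoveryReport:
    """Precision/recall of enriched calls at significance >= 1 and == 2."""

    at_least_1: RecoveryCounts
    exactly_2: RecoveryCounts


def _censoring_threshold(mean: float, sd: float, prob: float) -> float:
    # Detection limit placed so that P(log10 control < threshold) == prob.
    if prob <= 0.0:
        return -np.inf
    if prob >= 1.0:
        return np.inf
    return mean + sd * float(norm.ppf(prob))


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ProteinTable, dict[str, str]]:
    """Generate one synthetic bait-vs-control proteinGroups table.

    Returns the table (flags all false) and a truth table mapping
    protein_ids to ``background`` or ``interactor``.  Deterministic per
    ``config.seed``.

    Per protein: log10 control intensity ~ Normal(log10_mean, log10_sd);
    log2 bait/control ratio ~ Normal(0, ratio_noise_sd) for background and
    Normal(effect_size_log2, ratio_noise_sd) for interactors; the control is
    censored to missing below the class-specific detection threshold;
    razor+unique peptides ~ 1 + Poisson(rate * max(0, log10 bait -
    (log10_mean - 2 log10_sd))).
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_background + config.n_true_interactors
    labels = np.array(
        [BACKGROUND] * config.n_background + [INTERACTOR] * config.n_true_interactors
    )
    log10_control = rng.normal(config.log10_mean, config.log10_sd, size=n_total)
    ratio_means = np.where(labels == INTERACTOR, config.effect_size_log2, 0.0)
    log2_ratio = rng.normal(ratio_means, config.ratio_noise_sd)
    log10_bait = log10_control + log2_ratio * np.log10(2.0)

    thresholds = np.where(
        labels == INTERACTOR,
        _censoring_threshold(
            config.log10_mean, config.log10_sd, config.control_missing_interactor_prob
        ),
        _censoring_threshold(
            config.log10_mean, config.log10_sd, config.control_missing_baseline_prob
        ),
    )
    control_missing = log10_control < thresholds

    floor = config.log10_mean - 2.0 * config.log10_sd
    rates = config.peptide_rate_per_log10 * np.maximum(0.0, log10_bait - floor)
    peptides = 1 + rng.poisson(rates)

    width = len(str(n_total))
    records = []
    truth: dict[str, str] = {}
    for i in range(n_total):
        prefix = "INT" if labels[i] == INTERACTOR else "BG"
        protein_id = f"{prefix}{i:0{width}d}"
        records.append(
            ProteinRecord(
                protein_ids=protein_id,
                gene_names=f"{prefix.lower()}{i}",
                peptides_razor_unique=int(peptides[i]),
                lfq_bait=float(10.0 ** log10_bait[i]),
                lfq_control=(
                    None if control_missing[i] else float(10.0 ** log10_control[i])
                ),
            )
        )
        truth[protein_id] = str(labels[i])
    table = ProteinTable(records=records, column_map=dict(DEFAULT_COLUMN_MAP))
    return table, truth


def write_truth_table(path: str | Path, truth: Mapping[str, str]) -> None:
    """Write the truth labels as a two-column TSV (protein_ids, label)."""
    pd.DataFrame(
        {"protein_ids": list(truth), "label": [truth[k] for k in truth]}
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(frame["protein_ids"], frame["label"]))


def _counts(called: set[str], positives: set[str]) -> RecoveryCounts:
    tp = len(called & positives)
    fp = len(called - positives)
    fn = len(positives - called)
    precision = 1.0 if tp + fp == 0 else tp / (tp + fp)
    recall = 0.0 if not positives else tp / (tp + fn)
    return RecoveryCounts(tp, fp, fn, precision, recall)


def evaluate_recovery(
    results: Sequence[EnrichmentRecord], truth: Mapping[str, str]
) -> RecoveryReport:
    """Score enriched-direction significance calls against simulation truth.

    Proteins present in the truth table but dismissed before calling count
    as not-called (they can only be false negatives).  Precision is defined
    as 1 when there are no calls; recall as TP/(TP+FN).

    Raises
    ------
    ValueError
        If a result protein is absent from the truth table.
    """
    unknown = [rec.protein_ids for rec in results if rec.protein_ids not in truth]
    if unknown:
        raise ValueError(
            f"protein(s) absent from truth table: {', '.join(unknown[:5])}"
        )
    positives = {pid for pid, label in truth.items() if label == INTERACTOR}
    enriched = [rec for rec in results if rec.direction == "enriched"]
    called_1 = {rec.protein_ids for rec in enriched if rec.significance >= 1}
    called_2 = {rec.protein_ids for rec in enriched if rec.significance == 2}
    return RecoveryReport(
        at_least_1=_counts(called_1, positives),
        exactly_2=_counts(called_2, positives),
    )
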