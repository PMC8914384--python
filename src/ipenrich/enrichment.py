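"""Bait-vs-control enrichment statistics for single-run AP-MS experiments.

The procedure, applied to one bait immunoprecipitation and one control
immunoprecipitation quantified by LFQ:

1. dismiss contaminants, decoys and proteins with fewer than two
   razor+unique peptides or no bait intensity;
2. impute missing control intensities from a normal distribution centred at
   the 5% quantile of the pooled log10 intensities (SD 0.1 log10 units),
   requiring at least three peptides for imputed proteins;
3. compute log2 bait/control ratios;
4. partition proteins into consecutive bait-intensity bins of at least 300;
5. call boxplot outliers per bin: ratios strictly outside Q1/Q3 -/+ 1.5x IQR
   are significance 1, outside 3x IQR significance 2.

Quartiles use the linear-interpolation convention (the default of mainstream
statistical environments).  Every dismissed protein is logged with its stage
and reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .config import AnalysisConfig
from .io_tables import ProteinRecord, ProteinTable

LOG10_2 = math.log10(2.0)

Direction = Literal["enriched", "depleted", "none"]


@dataclass
class Dismissal:
    """One protein removed from the analysis, with stage and reason."""

    protein_ids: str
    stage: str
    reason: str


@dataclass
class EnrichmentRecord:
    """Per-protein derived quantities of the enrichment analysis."""

    protein_ids: str
    gene_names: str
    peptides_razor_unique: int
    log10_bait: float
    log10_control: float
    control_imputed: bool
    log2_ratio: float
    bin_index: int = -1
    significance: int = 0
    direction: Direction = "none"


@dataclass
class PipelineResult:
    """Output of :func:`run_pipeline`: surviving records, the dismissal log,
    and the pooled-quantile baseline used for imputation (NaN if nothing
    needed imputing and no observed intensities existed)."""

    records: list[EnrichmentRecord]
    dismissals: list[Dismissal]
    imputation_baseline: float


def filter_identifications(
    table: ProteinTable, config: AnalysisConfig
) -> tuple[ProteinTable, list[Dismissal]]:
    """Remove contaminants, decoys, low-evidence and bait-missing proteins.

    Order is preserved.  A protein absent from the bait IP cannot be an
    enriched interactor, so records with missing bait intensity are dropped
    here; missing *control* intensities are handled later by imputation.
    """
    kept: list[ProteinRecord] = []
    dismissed: list[Dismissal] = []

    def _dismiss(rec: ProteinRecord, reason: str) -> None:
        dismissed.append(Dismissal(rec.protein_ids, "filter", reason))

    for rec in table:
        if rec.is_reverse:
            _dismiss(rec, "reverse decoy")
        elif rec.is_contaminant:
            _dismiss(rec, "potential contaminant")
        elif config.drop_site_only and rec.is_site_only:
            _dismiss(rec, "only identified by site")
        elif rec.peptides_razor_unique < config.min_peptides_observed:
            _dismiss(
                rec,
                f"fewer than {config.min_peptides_observed} razor+unique peptides",
            )
        elif rec.lfq_bait is None:
            _dismiss(rec, "missing bait intensity")
        else:
            kept.append(rec)
    return ProteinTable(records=kept, column_map=dict(table.column_map)), dismissed


def pooled_log10_quantile(table: ProteinTable, level: float) -> float:
    """Quantile of the pooled log10 bait and control intensities.

    Pools every observed (non-missing) intensity from both conditions and
    returns the ``level`` quantile under linear interpolation.

    Raises
    ------
    ValueError
        If the table holds no observed intensity at all.
    """
    pooled = [
        math.log10(value)
        for rec in table
        for value in (rec.lfq_bait, rec.lfq_control)
        if value is not None
    ]
    if not pooled:
        raise ValueError("no observed intensities to pool for the quantile")
    return float(np.quantile(np.asarray(pooled), level))


def sample_imputed_log10(
    n: int,
    pooled_log10: Sequence[float] | np.ndarray,
    config: AnalysisConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` imputed log10 control intensities.

    Values come from Normal(mean, sd) with mean the
    ``config.imputation_quantile_level`` quantile of ``pooled_log10`` and
    sd ``config.imputation_sd`` — i.e. values close to the detection
    baseline of the experiment.
    """
    pooled = np.asarray(pooled_log10, dtype=float)
    if pooled.size == 0:
        raise ValueError("empty pooled distribution")
    baseline = float(np.quantile(pooled, config.imputation_quantile_level))
    return rng.normal(loc=baseline, scale=config.imputation_sd, size=n)


@dataclass
class ImputationResult:
    table: ProteinTable
    imputed_ids: set[str]
    dismissals: list[Dismissal]
    baseline: float


def impute_missing_controls(
    table: ProteinTable,
    config: AnalysisConfig,
    rng: Optional[np.random.Generator] = None,
) -> ImputationResult:
    """Impute missing control intensities at the detection baseline.

    Each record with a missing control either is dismissed (peptide count
    below ``config.min_peptides_imputed``) or receives a control intensity
    drawn from Normal(pooled 5% quantile, 0.1) on the log10 scale.  Records
    with observed controls are untouched.  Identical seeds give identical
    draws; draws are made in table order.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    needs_imputation = [
        rec
        for rec in table
        if rec.lfq_control is None
        and rec.peptides_razor_unique >= config.min_peptides_imputed
    ]
    baseline = math.nan
    if needs_imputation:
        pooled = [
            math.log10(value)
            for rec in table
            for value in (rec.lfq_bait, rec.lfq_control)
            if value is not None
        ]
        draws = sample_imputed_log10(len(needs_imputation), pooled, config, rng)
        baseline = float(
            np.quantile(np.asarray(pooled), config.imputation_quantile_level)
        )
        draw_by_id = {
            rec.protein_ids: value for rec, value in zip(needs_imputation, draws)
        }
    else:
        draw_by_id = {}

    kept: list[ProteinRecord] = []
    imputed_ids: set[str] = set()
    dismissed: list[Dismissal] = []
    for rec in table:
        if rec.lfq_control is not None:
            kept.append(rec)
        elif rec.protein_ids in draw_by_id:
            kept.append(replace(rec, lfq_control=10.0 ** draw_by_id[rec.protein_ids]))
            imputed_ids.add(rec.protein_ids)
        else:
            dismissed.append(
                Dismissal(
                    rec.protein_ids,
                    "imputation",
                    "missing control with fewer than "
                    f"{config.min_peptides_imputed} razor+unique peptides",
                )
            )
    return ImputationResult(
        table=ProteinTable(records=kept, column_map=dict(table.column_map)),
        imputed_ids=imputed_ids,
        dismissals=dismissed,
        baseline=baseline,
    )


def compute_log2_ratios(
    table: ProteinTable, imputed_ids: Iterable[str] = ()
) -> list[EnrichmentRecord]:
    """Turn an imputed table into enrichment records with log2 ratios.

    log2(bait/control) is computed as (log10 bait - log10 control)/log10(2);
    bins and significance are left unset.
    """
    imputed = set(imputed_ids)
    records: list[EnrichmentRecord] = []
    for rec in table:
        if rec.lfq_bait is None or rec.lfq_control is None:
            raise ValueError(
                f"record {rec.protein_ids!r} reached ratio computation with a "
                "missing intensity; filter and impute first"
            )
        log10_bait = math.log10(rec.lfq_bait)
        log10_control = math.log10(rec.lfq_control)
        records.append(
            EnrichmentRecord(
                protein_ids=rec.protein_ids,
                gene_names=rec.gene_names,
                peptides_razor_unique=rec.peptides_razor_unique,
                log10_bait=log10_bait,
                log10_control=log10_control,
                control_imputed=rec.protein_ids in imputed,
                log2_ratio=(log10_bait - log10_control) / LOG10_2,
            )
        )
    return records


def assign_intensity_bins(
    records: list[EnrichmentRecord], config: AnalysisConfig
) -> list[EnrichmentRecord]:
    """Partition records into consecutive bait-intensity bins.

    Records are sorted by log10 bait intensity (ties broken by stable input
    order) and split into k = max(1, floor(N / min_bin_size)) contiguous bins
    whose sizes differ by at most one; bin 0 holds the lowest intensities.
    With fewer than ``min_bin_size`` records a single bin holds everything.
    The input list is returned with ``bin_index`` set; order is unchanged.
    """
    n = len(records)
    if n == 0:
        return records
    order = np.argsort([rec.log10_bait for rec in records], kind="stable")
    k = max(1, n // config.min_bin_size)
    for bin_index, chunk in enumerate(np.array_split(order, k)):
        for position in chunk:
            records[int(position)].bin_index = bin_index
    return records


def bin_fences(
    ratios_in_bin: Sequence[float] | np.ndarray, multiplier: float
) -> tuple[float, float]:
    """Boxplot fences (Q1 - m*IQR, Q3 + m*IQR) of a bin's log2 ratios.

    Quartiles use linear interpolation between order statistics.
    """
    ratios = np.asarray(ratios_in_bin, dtype=float)
    if ratios.size == 0:
        raise ValueError("bin is empty")
    q1, q3 = np.quantile(ratios, [0.25, 0.75])
    iqr = q3 - q1
    return float(q1 - multiplier * iqr), float(q3 + multiplier * iqr)


def call_significance(
    records: list[EnrichmentRecord], config: AnalysisConfig
) -> list[EnrichmentRecord]:
    """Assign significance classes from per-bin boxplot fences.

    Within its own bin (own ratio included in the quartiles), a protein
    strictly outside the ``iqr_multiplier_sig2`` fences gets significance 2,
    else strictly outside the ``iqr_multiplier_sig1`` fences significance 1,
    else 0.  Direction records which fence was crossed.
    """
    if not records:
        return records
    bins: dict[int, list[float]] = {}
    for rec in records:
        if rec.bin_index < 0:
            raise ValueError(
                f"record {rec.protein_ids!r} has no bin; assign bins first"
            )
        bins.setdefault(rec.bin_index, []).append(rec.log2_ratio)
    fences = {
        index: (
            bin_fences(ratios, config.iqr_multiplier_sig1),
            bin_fences(ratios, config.iqr_multiplier_sig2),
        )
        for index, ratios in bins.items()
    }
    for rec in records:
        (lo1, hi1), (lo2, hi2) = fences[rec.bin_index]
        ratio = rec.log2_ratio
        if ratio > hi2:
            rec.significance, rec.direction = 2, "enriched"
        elif ratio < lo2:
            rec.significance, rec.direction = 2, "depleted"
        elif ratio > hi1:
            rec.significance, rec.direction = 1, "enriched"
        elif ratio < lo1:
            rec.significance, rec.direction = 1, "depleted"
        else:
            rec.significance, rec.direction = 0, "none"
    return records


def run_pipeline(table: ProteinTable, config: AnalysisConfig) -> PipelineResult:
    """Run filter -> impute -> ratios -> bins -> significance.

    Deterministic given the table and the config (the imputation RNG is
    seeded from ``config.rng_seed``).
    """
    filtered, dismissed = filter_identifications(table, config)
    imputation = impute_missing_controls(filtered, config)
    records = compute_log2_ratios(imputation.table, imputation.imputed_ids)
    records = assign_intensity_bins(records, config)
    records = call_significance(records, config)
    return PipelineResult(
        records=records,
        dismissals=dismissed + imputation.dismissals,
        imputation_baseline=imputation.baseline,
    )
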