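"""End-to-end orchestration of the scoring pipeline (library level).

The stages mirror the CLI verbs: annotate (enumerate the variant space
and join observations + meta-positions), expect (mutability model and
synonymous calibration), score (per-column aggregation and per-variant
scores). Each stage is a pure function over DataFrames so the CLI stays
a thin wrapper and tests can run any slice in memory.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import hmc_core, nullmodel, varspace
from .nullmodel import CalibrationResult, CoverageModel, RateTable


@dataclass
class ScoreParams:
    maf_threshold: float = 0.001
    alpha: float = hmc_core.DEFAULT_ALPHA
    quantile: float = hmc_core.DEFAULT_QUANTILE
    bins: tuple = hmc_core.DEFAULT_BINS
    min_copies: int = 2
    neighbor_columns: int = 0  # sensitivity hook; the released score uses 0


def annotate_stage(
    transcripts,
    meta_table: pd.DataFrame,
    observed: pd.DataFrame,
    genome=None,
    coverage: pd.DataFrame | None = None,
    methylation: pd.DataFrame | None = None,
    maf_threshold: float = 0.001,
) -> pd.DataFrame:
    """Enumerate all possible SNVs and join sites, observations and domains."""
    variants = varspace.enumerate_all(transcripts, genome)
    variants = nullmodel.attach_site_annotations(variants, coverage, methylation)
    variants = varspace.apply_rarity_filter(variants, observed, maf_threshold)
    variants = varspace.join_meta_positions(variants, meta_table)
    return variants


def expect_stage(
    variants: pd.DataFrame,
    rates: RateTable,
    cov_model: CoverageModel | None = None,
) -> tuple[pd.DataFrame, CalibrationResult]:
    """Adjusted mutability, synonymous calibration and per-variant Expected."""
    variants = nullmodel.adjusted_mu(variants, rates, cov_model)
    calib = nullmodel.calibrate(variants)
    variants = nullmodel.add_expected(variants, calib)
    return variants, calib


def score_stage(
    variants: pd.DataFrame,
    meta_table: pd.DataFrame,
    params: ScoreParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per meta-position and project scores onto variants."""
    params = params or ScoreParams()
    records = hmc_core.aggregate(
        variants,
        meta_table,
        quantile=params.quantile,
        alpha=params.alpha,
        bins=params.bins,
        min_copies=params.min_copies,
        neighbor_columns=params.neighbor_columns,
    )
    scores = hmc_core.score_variants(records, variants)
    return records, scores


def run_all(
    transcripts,
    meta_table: pd.DataFrame,
    observed: pd.DataFrame,
    rates: RateTable,
    genome=None,
    coverage: pd.DataFrame | None = None,
    methylation: pd.DataFrame | None = None,
    cov_model: CoverageModel | None = None,
    params: ScoreParams | None = None,
):
    """Full pipeline; returns (variants, calibration, records, scores)."""
    params = params or ScoreParams()
    variants = annotate_stage(
        transcripts, meta_table, observed, genome, coverage, methylation,
        params.maf_threshold,
    )
    variants, calib = expect_stage(variants, rates, cov_model)
    records, scores = score_stage(variants, meta_table, params)
    return variants, calib, records, scores
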