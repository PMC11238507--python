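"""Neutral expectation model: trinucleotide mutability, CpG methylation,
coverage correction and synonymous calibration.

The expected number of rare variants at a possible SNV is

    Expected = k * mu(context, alt, methyl) * c(depth)

where ``mu`` is the relative mutability of the substitution in its
trinucleotide context (stratified into three methylation bins at CpG
sites), ``c`` is a coverage correction in [0, 1], and ``k`` is a single
global scale fixed so that the summed expectation over synonymous
candidates equals the number of synonymous variants actually observed as
rare in the cohort — synonymous sites being the within-region proxy for
neutral evolution. Conservation of the synonymous count is therefore
exact by construction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, CompletenessError, DataError

logger = logging.getLogger(__name__)

BASES = "ACGT"
ALL_CONTEXTS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

METHYL_LEVELS = (0, 1, 2)


def is_cpg_context(context: str) -> bool:
    """True if the central base sits in a CpG dinucleotide (coding strand).

    Covers both the C of a CpG (context[1:3] == 'CG') and the G
    (context[0:2] == 'CG'): contexts are not collapsed to the pyrimidine
    strand, so methylation-accelerated mutation must be visible from
    either side.
    """
    return context[1:3] == "CG" or context[0:2] == "CG"


@dataclass
class RateTable:
    """(context, alt, methyl_level) -> relative mutability mu."""

    rates: dict[tuple[str, str, int], float]

    def __post_init__(self) -> None:
        bad = [k for k, v in self.rates.items() if not v > 0]
        if bad:
            raise DataError(f"rate table has non-positive mu for {bad[:5]}")
        missing = [
            (ctx, alt)
            for ctx in ALL_CONTEXTS
            for alt in BASES
            if alt != ctx[1] and (ctx, alt, 0) not in self.rates
        ]
        if missing:
            raise CompletenessError(
                f"rate table missing {len(missing)} (context, alt) pairs at "
                f"methylation level 0, e.g. {missing[:5]}"
            )
        # CpG contexts should carry methylation strata; fall back to the
        # unmethylated rate where they do not.
        n_fallback = 0
        for ctx in ALL_CONTEXTS:
            if not is_cpg_context(ctx):
                continue
            for alt in BASES:
                if alt == ctx[1]:
                    continue
                for lvl in (1, 2):
                    if (ctx, alt, lvl) not in self.rates:
                        self.rates[(ctx, alt, lvl)] = self.rates[(ctx, alt, 0)]
                        n_fallback += 1
        if n_fallback:
            logger.warning(
                "rate table: %d missing CpG methylation entries fall back to level 0",
                n_fallback,
            )

    def mu(self, context: str, alt: str, methyl_level: int = 0) -> float:
        if not is_cpg_context(context):
            methyl_level = 0
        return self.rates[(context, alt, methyl_level)]

    def lookup(
        self,
        contexts: Sequence[str],
        alts: Sequence[str],
        methyl_levels: Sequence[int],
    ) -> np.ndarray:
        """Vectorised mu lookup; NaN where the context is unusable ('N')."""
        out = np.empty(len(contexts))
        for i, (ctx, alt, lvl) in enumerate(zip(contexts, alts, methyl_levels)):
            if "N" in ctx:
                out[i] = np.nan
            else:
                out[i] = self.mu(ctx, alt, int(lvl))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, a, l, m) for (c, a, l), m in sorted(self.rates.items())]
        return pd.DataFrame(rows, columns=["context", "alt", "methyl_level", "mu"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_rate_table(path: str | Path) -> RateTable:
    """Load a rate table TSV with columns context, alt, methyl_level, mu."""
    df = pd.read_csv(path, sep="\t")
    required = {"context", "alt", "methyl_level", "mu"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: rate table needs columns {sorted(required)}")
    rates = {
        (str(r.context), str(r.alt), int(r.methyl_level)): float(r.mu)
        for r in df.itertuples()
    }
    return RateTable(rates)


@dataclass
class CoverageModel:
    """Piecewise coverage correction c(depth) in [0, 1], non-decreasing.

    Sites below ``min_depth`` are dropped (c = 0); at or above
    ``full_depth`` no correction applies (c = 1). In between, ``table``
    (sorted (depth, factor) breakpoints, step function) is used when
    supplied, else a linear ramp. Defaults leave typical well-covered
    data (depth >= 30) uncorrected.
    """

    min_depth: float = 10.0
    full_depth: float = 30.0
    table: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.full_depth < self.min_depth:
            raise DataError("full_depth must be >= min_depth")
        facs = [f for _, f in self.table]
        if any(f < 0 or f > 1 for f in facs):
            raise DataError("coverage factors must lie in [0, 1]")
        if any(b < a for a, b in zip(facs, facs[1:])):
            raise DataError("coverage factors must be non-decreasing in depth")
        self.table = sorted(self.table)

    def factor(self, depth) -> np.ndarray:
        d = np.asarray(depth, dtype=float)
        if self.table:
            depths = np.array([t for t, _ in self.table])
            facs = np.array([f for _, f in self.table])
            idx = np.searchsorted(depths, d, side="right") - 1
            c = np.where(idx >= 0, facs[np.clip(idx, 0, None)], 0.0)
        else:
            span = max(self.full_depth - self.min_depth, np.finfo(float).tiny)
            c = (d - self.min_depth) / span
        c = np.clip(c, 0.0, 1.0)
        c = np.where(d < self.min_depth, 0.0, c)
        c = np.where(d >= self.full_depth, 1.0, c)
        return c


def read_coverage(path: str | Path) -> pd.DataFrame:
    """BED-like coverage TSV: chrom, start (0-based), end, median_depth."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "median_depth"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: coverage table needs columns {sorted(required)}")
    return df


def read_methylation(path: str | Path) -> pd.DataFrame:
    """Methylation TSV: chrom, pos (1-based), level in {0,1,2}."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "level"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: methylation table needs columns {sorted(required)}")
    if not df["level"].isin(METHYL_LEVELS).all():
        raise DataError("methylation levels must be 0, 1 or 2")
    return df


def attach_site_annotations(
    variants: pd.DataFrame,
    coverage: pd.DataFrame | None = None,
    methylation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach per-site median depth and CpG methylation level to variants.

    Missing coverage defaults to +inf (no correction); missing methylation
    and non-CpG contexts default to level 0.
    """
    out = variants.copy()
    if coverage is not None and len(coverage):
        depth = np.full(len(out), np.inf)
        for chrom, grp in coverage.groupby("chrom"):
            mask = (out["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            pos0 = out.loc[mask, "pos"].to_numpy() - 1
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            depths = grp["median_depth"].to_numpy()
            d = np.full(mask.sum(), np.inf)
            order = np.argsort(starts)
            starts, ends, depths = starts[order], ends[order], depths[order]
            idx = np.searchsorted(starts, pos0, side="right") - 1
            ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
            d[ok] = depths[idx[ok]]
            depth[mask] = d
        out["coverage"] = depth
    elif "coverage" not in out.columns:
        out["coverage"] = np.inf

    is_cpg = out["context"].map(lambda c: is_cpg_context(c) if "N" not in c else False)
    if methylation is not None and len(methylation):
        meth = methylation.rename(columns={"level": "methyl_level"})
        out = out.merge(meth[["chrom", "pos", "methyl_level"]], on=["chrom", "pos"], how="left")
        out["methyl_level"] = out["methyl_level"].fillna(0).astype(int)
    elif "methyl_level" not in out.columns:
        out["methyl_level"] = 0
    out.loc[~is_cpg, "methyl_level"] = 0
    return out


def adjusted_mu(
    variants: pd.DataFrame,
    rates: RateTable,
    cov: CoverageModel | None = None,
) -> pd.DataFrame:
    """Compute per-variant adjusted mutability mu_adj = mu * c(depth).

    Adds ``mu``, ``cov_factor``, ``mu_adj`` and ``assessable`` columns.
    A variant is unassessable (not an error) when its context contains
    'N' or its site is effectively uncovered (c = 0).
    """
    cov = cov or CoverageModel()
    out = variants.copy()
    if "methyl_level" not in out.columns or "coverage" not in out.columns:
        out = attach_site_annotations(out)
    # mutability is looked up on the coding strand: context and alt both
    # refer to the coding strand of the transcript
    alts = out["alt"].to_numpy(dtype=object)
    minus = (out["strand"] == "-").to_numpy()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    coding_alt = np.where(minus, [comp[a] for a in alts], alts)
    out["mu"] = rates.lookup(
        out["context"].tolist(), list(coding_alt), out["methyl_level"].tolist()
    )
    out["cov_factor"] = cov.factor(out["coverage"].to_numpy())
    out["mu_adj"] = out["mu"] * out["cov_factor"]
    out["assessable"] = out["mu_adj"].notna() & (out["mu_adj"] > 0)
    if "common" in out.columns:
        out.loc[out["common"].fillna(False), "assessable"] = False
    return out


@dataclass(frozen=True)
class CalibrationResult:
    """Global scale k tying relative mutability to expected rare counts."""

    k: float
    n_syn_observed: int
    sum_mu_syn: float

    def __post_init__(self) -> None:
        assert self.k > 0


def calibrate(variants: pd.DataFrame) -> CalibrationResult:
    """Fix the global scale on synonymous candidates within assessed regions.

    k = (# synonymous candidates observed as rare) / (sum of mu_adj over
    all assessable synonymous candidates). Requires ``consequence``,
    ``observed_rare``, ``mu_adj`` and ``assessable`` columns.
    """
    syn = variants[(variants["consequence"] == "synonymous") & variants["assessable"]]
    if syn.empty:
        raise CalibrationError("no assessable synonymous candidates to calibrate on")
    sum_mu = float(syn["mu_adj"].sum())
    n_obs = int(syn["observed_rare"].sum())
    if n_obs == 0:
        raise CalibrationError("no synonymous variants observed as rare")
    return CalibrationResult(k=n_obs / sum_mu, n_syn_observed=n_obs, sum_mu_syn=sum_mu)


def add_expected(variants: pd.DataFrame, calib: CalibrationResult) -> pd.DataFrame:
    """Per-variant expected rare-variant count: Expected = k * mu_adj."""
    out = variants.copy()
    out["expected"] = np.where(out["assessable"], calib.k * out["mu_adj"], 0.0)
    return out
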