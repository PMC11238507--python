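"""The constraint score itself: Poisson-Gamma credible bounds per
meta-position, power filtering, classification, and per-variant scoring.

At each meta-position (one match column of one domain family) let O be
the number of distinct rare missense variants observed across all
homologous residues and E the summed neutral expectation over every
possible missense SNV at those residues. Under O ~ Poisson(lambda * E)
with an (improper) flat prior on the rate ratio lambda, the posterior is
Gamma(shape = O + 1, rate = E). The constraint score is the upper bound
of the equal-tailed 90% credible interval of lambda — i.e. the 0.95
posterior quantile — and the accompanying point estimate is the MLE
O / E. A score below 1 means the posterior tail mass at lambda >= 1 is
below 0.05: missense variation is significantly depleted, and by the
same algebra a score below 1 at O = 0 is only reachable when
E > -ln(0.05) ~ 2.996, which is exactly the power (assessability)
condition.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

DEFAULT_QUANTILE = 0.95  # upper bound of the equal-tailed 90% credible interval
DEFAULT_ALPHA = 0.05
DEFAULT_BINS = (0.5, 0.6, 0.8, 1.0)

CLASSES = ("highly_constrained", "constrained", "unconstrained", "unassessable")

#: columns of the per-meta-position constraint table
CONSTRAINT_COLUMNS = [
    "family_id", "column", "observed", "expected", "n_copies", "mle", "hmc",
    "powered", "constraint_class", "hmc_bin",
]


def hmc_score(observed, expected, quantile: float = DEFAULT_QUANTILE):
    """Posterior 0.95 quantile of the O/E rate ratio (vectorised).

    Gamma(O + 1, rate = E) quantile; at O = 0 this reduces to the closed
    form -ln(1 - q) / E. Strictly exceeds the MLE O/E for every O >= 0,
    E > 0.
    """
    observed = np.asarray(observed)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected <= 0):
        raise ValueError("expected must be positive")
    if np.any(observed < 0):
        raise ValueError("observed must be non-negative")
    q = stats.gamma.ppf(quantile, np.asarray(observed) + 1.0, scale=1.0 / expected)
    return q if q.shape else float(q)


def significance(hmc) -> np.ndarray | bool:
    """One-sided call: score < 1 <=> posterior P(lambda >= 1) < 0.05."""
    hmc = np.asarray(hmc)
    sig = hmc < 1.0
    return sig if sig.shape else bool(sig)


def power_filter(expected, alpha: float = DEFAULT_ALPHA):
    """A position is powered iff full depletion (O = 0) could score < 1.

    hmc_score(0, E) = -ln(alpha) / E < 1  <=>  E > -ln(alpha).
    """
    if not 0 < alpha < 1:
        raise ConfigError("alpha must be in (0, 1)")
    expected = np.asarray(expected, dtype=float)
    powered = expected > -np.log(alpha)
    return powered if powered.shape else bool(powered)


def classify(hmc, powered, bins=DEFAULT_BINS) -> tuple[np.ndarray, np.ndarray]:
    """Assign constraint class and score bin.

    Classes (strict thresholds, half-open bins): ``highly_constrained``
    (score < 0.8), ``constrained`` (0.8 <= score < 1), ``unconstrained``
    (score >= 1); unpowered positions are ``unassessable`` regardless of
    score. Bins partition [0, inf) at the given edges.
    """
    bins = tuple(bins)
    if list(bins) != sorted(bins) or len(set(bins)) != len(bins):
        raise ConfigError("bins must be strictly ascending")
    hmc = np.atleast_1d(np.asarray(hmc, dtype=float))
    powered = np.atleast_1d(np.asarray(powered, dtype=bool))

    cls = np.where(hmc < 0.8, "highly_constrained",
                   np.where(hmc < 1.0, "constrained", "unconstrained"))
    cls = np.where(powered & np.isfinite(hmc), cls, "unassessable").astype(object)

    edges = (0.0,) + bins
    labels = [f"[{a:g},{b:g})" for a, b in zip(edges, edges[1:])] + [f"[{edges[-1]:g},inf)"]
    idx = np.searchsorted(bins, hmc, side="right")
    bin_lab = np.array(labels, dtype=object)[idx]
    bin_lab = np.where(powered & np.isfinite(hmc), bin_lab, "unassessable").astype(object)
    return cls, bin_lab


def aggregate(
    variants: pd.DataFrame,
    meta_table: pd.DataFrame,
    quantile: float = DEFAULT_QUANTILE,
    alpha: float = DEFAULT_ALPHA,
    bins=DEFAULT_BINS,
    min_copies: int = 2,
    neighbor_columns: int = 0,
) -> pd.DataFrame:
    """Per-meta-position constraint records from annotated variants.

    ``variants`` must carry family_id/column (from
    :func:`~hmconstraint.varspace.join_meta_positions`), ``observed_rare``
    flags and per-variant ``expected``. Observed counts distinct
    (chrom, pos, ref, alt) missense alleles; expectation sums over every
    assessable missense candidate at the column's residues. Common
    variants were already excluded from both sides by the rarity filter.

    A record is powered when its expectation clears the detectability
    bound -ln(alpha) *and* at least ``min_copies`` domain copies
    contribute. Positions with candidates but zero expectation are
    unassessable.

    ``neighbor_columns`` pools observed and expected counts from the n
    nearest match columns on each side before scoring (a sensitivity
    hook that trades precision for power; the released score uses 0).
    """
    mis = variants[
        variants["family_id"].notna() & (variants["consequence"] == "missense")
    ].copy()

    n_copies = (
        meta_table.groupby(["family_id", "column"])["n_copies"].first()
        if len(meta_table)
        else pd.Series(dtype=int)
    )

    records = []
    if len(mis):
        grouped = mis.groupby(["family_id", "column"], sort=True)
        for (fam, col), grp in grouped:
            assess = grp[grp["assessable"]]
            obs = int(
                assess.loc[assess["observed_rare"], ["chrom", "pos", "ref", "alt"]]
                .drop_duplicates()
                .shape[0]
            )
            exp = float(assess["expected"].sum())
            nc = int(n_copies.get((fam, col), grp["n_copies"].max()))
            records.append((fam, int(col), obs, exp, nc))

    df = pd.DataFrame(
        records, columns=["family_id", "column", "observed", "expected", "n_copies"]
    )
    if df.empty:
        return pd.DataFrame(columns=CONSTRAINT_COLUMNS)

    if neighbor_columns > 0:
        pooled = []
        for _, fam_df in df.groupby("family_id", sort=False):
            fam_df = fam_df.sort_values("column")
            w = 2 * neighbor_columns + 1
            obs = fam_df["observed"].rolling(w, center=True, min_periods=1).sum()
            exp = fam_df["expected"].rolling(w, center=True, min_periods=1).sum()
            fam_df = fam_df.assign(observed=obs.astype(int), expected=exp)
            pooled.append(fam_df)
        df = pd.concat(pooled, ignore_index=True)

    ok = df["expected"] > 0
    df["mle"] = np.where(ok, df["observed"] / df["expected"].where(ok), np.nan)
    df["hmc"] = np.nan
    df.loc[ok, "hmc"] = hmc_score(
        df.loc[ok, "observed"].to_numpy(), df.loc[ok, "expected"].to_numpy(), quantile
    )
    df["powered"] = (
        ok & power_filter(df["expected"].to_numpy(), alpha) & (df["n_copies"] >= min_copies)
    )
    cls, bin_lab = classify(df["hmc"].to_numpy(), df["powered"].to_numpy(), bins)
    df["constraint_class"] = cls
    df["hmc_bin"] = bin_lab
    return df.sort_values(["family_id", "column"]).reset_index(drop=True)


def null_calibration_fraction(
    n_positions: int,
    expected_range: tuple[float, float] = (3.0, 50.0),
    seed: int = 0,
    quantile: float = DEFAULT_QUANTILE,
) -> float:
    """Fraction of neutral positions called constrained (score < 1).

    Simulates powered meta-positions under the null: expected counts
    uniform over ``expected_range``, observed ~ Poisson(expected). Under
    correct calibration this fraction stays at or below the significance
    level implied by the quantile (score < 1 <=> one-sided P < 1 -
    quantile); the flat-prior bound is conservative, so typical values
    fall somewhat below it.
    """
    rng = np.random.default_rng(seed)
    expected = rng.uniform(*expected_range, size=n_positions)
    observed = rng.poisson(expected)
    return float(np.mean(hmc_score(observed, expected, quantile) < 1.0))


def score_variants(
    records: pd.DataFrame, variants: pd.DataFrame, powered_only: bool = True
) -> pd.DataFrame:
    """Project meta-position scores onto every possible missense SNV.

    Every missense variant at a powered meta-position inherits that
    position's score, MLE and class; all variants at one meta-position
    share one score by construction. Returns the score table.
    """
    mis = variants[
        variants["family_id"].notna() & (variants["consequence"] == "missense")
    ].copy()
    cols = ["family_id", "column", "observed", "expected", "mle", "hmc",
            "powered", "constraint_class", "hmc_bin"]
    if records.empty or mis.empty:
        base = mis.drop(columns=[c for c in cols[2:] if c in mis.columns], errors="ignore")
        for c in cols[2:]:
            base[c] = pd.Series(dtype=float)
        return base.iloc[0:0] if powered_only else base
    out = mis.merge(records[cols], on=["family_id", "column"], how="left")
    if powered_only:
        out = out[out["powered"].fillna(False)]
    return out.reset_index(drop=True)


def assessable_fraction_by_gene(
    variants: pd.DataFrame, scores: pd.DataFrame
) -> pd.DataFrame:
    """Fraction of each gene's possible missense SNVs that received a score."""
    mis = variants[variants["consequence"] == "missense"]
    total = mis.groupby("gene_id").size().rename("n_missense")
    key = ["chrom", "pos", "ref", "alt", "gene_id"]
    scored = (
        scores.drop_duplicates(subset=key).groupby("gene_id").size().rename("n_assessable")
        if len(scores)
        else pd.Series(dtype=int, name="n_assessable")
    )
    out = pd.concat([total, scored], axis=1).fillna(0)
    out["n_assessable"] = out["n_assessable"].astype(int)
    out["fraction_assessable"] = out["n_assessable"] / out["n_missense"]
    return out.reset_index()
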