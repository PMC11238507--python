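"""Evaluation statistics for constraint scores.

The harness mirrors how residue-level constraint scores are normally
benchmarked against clinical labels and trio data:

* risk ratios of pathogenic vs benign variant rates across score bins
  (Katz log-normal confidence intervals, 0.5 continuity correction for
  zero cells);
* de novo mutation (DNM) burden — observed over mutability-model
  expectation — with exact (Garwood) Poisson confidence intervals and a
  one-sided Poisson enrichment p-value;
* case-control odds ratios with Woolf intervals and Haldane-Anscombe
  correction;
* precision-sensitivity curves over arbitrary score columns with grouped
  tie handling, for comparing constraint to third-party predictors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

logger = logging.getLogger(__name__)

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class RateComparison:
    """An effect estimate with its 95% CI, p-value and underlying counts."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    counts: tuple

    def __post_init__(self) -> None:
        if np.isfinite(self.estimate):
            assert self.ci_low <= self.estimate <= self.ci_high

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def rate_ratio(
    a: int, n1: int, b: int, n2: int, ci_level: float = 0.95
) -> RateComparison:
    """Ratio of two proportions (a/N1) / (b/N2) with a Katz log-normal CI.

    Zero numerators get a 0.5 continuity correction (applied to both
    counts, logged). The p-value is the two-sided normal test on the log
    ratio.
    """
    if n1 <= 0 or n2 <= 0:
        raise DataError("rate_ratio: both totals must be positive")
    if a > n1 or b > n2:
        raise DataError("rate_ratio: count exceeds its total")
    counts = (a, n1, b, n2)
    if a == 0 and b == 0:
        return RateComparison(np.nan, np.nan, np.nan, np.nan, counts)
    aa, bb = float(a), float(b)
    if a == 0 or b == 0:
        logger.info("rate_ratio: zero cell in %s, applying 0.5 correction", counts)
        aa += 0.5
        bb += 0.5
    est = (aa / n1) / (bb / n2)
    se = np.sqrt(1.0 / aa - 1.0 / n1 + 1.0 / bb - 1.0 / n2)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    lo, hi = est * np.exp(-z * se), est * np.exp(z * se)
    p = 2.0 * stats.norm.sf(abs(np.log(est)) / se) if se > 0 else np.nan
    return RateComparison(est, lo, hi, min(p, 1.0), counts)


def dnm_burden(
    observed: int, expected: float, ci_level: float = 0.95
) -> RateComparison:
    """Observed/expected DNM burden with an exact (Garwood) Poisson CI.

    The CI comes from the chi-square/Gamma identity for Poisson counts:
    lower = qgamma(alpha/2, O) / E (0 when O = 0), upper =
    qgamma(1 - alpha/2, O + 1) / E. The p-value is the one-sided
    enrichment tail P(X >= O | E).
    """
    if expected <= 0:
        raise DataError("dnm_burden: expected must be positive")
    if observed < 0:
        raise DataError("dnm_burden: observed must be non-negative")
    alpha = 1.0 - ci_level
    est = observed / expected
    lo = stats.gamma.ppf(alpha / 2.0, observed) / expected if observed > 0 else 0.0
    hi = stats.gamma.ppf(1.0 - alpha / 2.0, observed + 1.0) / expected
    p = stats.poisson.sf(observed - 1, expected)
    return RateComparison(est, lo, hi, float(p), (observed, expected))


def odds_ratio_2x2(
    case_carriers: int,
    case_noncarriers: int,
    control_carriers: int,
    control_noncarriers: int,
    ci_level: float = 0.95,
) -> RateComparison:
    """Odds ratio (a*d)/(b*c) with Woolf CI; 0.5 added to every cell
    (Haldane-Anscombe) when any cell is zero."""
    cells = (case_carriers, case_noncarriers, control_carriers, control_noncarriers)
    if any(c < 0 for c in cells):
        raise DataError("odds_ratio_2x2: counts must be non-negative")
    a, b, c, d = cells
    if (a + b) == 0 or (c + d) == 0:
        raise DataError("odds_ratio_2x2: a whole group is empty")
    af, bf, cf, df = (float(x) for x in cells)
    if min(cells) == 0:
        logger.info("odds_ratio_2x2: zero cell in %s, Haldane-Anscombe correction", cells)
        af, bf, cf, df = af + 0.5, bf + 0.5, cf + 0.5, df + 0.5
    est = (af * df) / (bf * cf)
    se = np.sqrt(1 / af + 1 / bf + 1 / cf + 1 / df)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    lo, hi = est * np.exp(-z * se), est * np.exp(z * se)
    p = 2.0 * stats.norm.sf(abs(np.log(est)) / se)
    return RateComparison(est, lo, hi, min(p, 1.0), cells)


@dataclass
class PrecisionSensitivityCurve:
    """Precision/sensitivity swept over distinct score thresholds."""

    thresholds: np.ndarray
    precision: np.ndarray
    sensitivity: np.ndarray
    direction: str
    area: float

    def point_at(self, threshold: float) -> tuple[float, float]:
        """(precision, sensitivity) of the classifier at a named threshold.

        ``lower_is_deleterious`` predicts positive at score < threshold
        (strict, matching how constraint thresholds are quoted);
        ``higher_is_deleterious`` at score >= threshold.
        """
        if self.direction == "lower_is_deleterious":
            idx = np.nonzero(self.thresholds < threshold)[0]
        else:
            idx = np.nonzero(self.thresholds >= threshold)[0]
        if idx.size == 0:
            return (np.nan, 0.0)
        i = idx[-1]
        return (float(self.precision[i]), float(self.sensitivity[i]))


def precision_sensitivity(
    scores, labels, direction: str = "lower_is_deleterious"
) -> PrecisionSensitivityCurve:
    """Precision-sensitivity curve with grouped tie handling.

    Thresholds are the distinct score values, swept from most to least
    deleterious; all variants sharing a score enter together (no
    intra-tie interpolation). ``labels`` are 1 for
    pathogenic/deleterious, 0 for benign. Area is the trapezoid over the
    sensitivity axis.
    """
    if direction not in {"lower_is_deleterious", "higher_is_deleterious"}:
        raise DataError(f"unknown direction {direction!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DataError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DataError("precision-sensitivity curve undefined for single-class input")

    sign = 1.0 if direction == "lower_is_deleterious" else -1.0
    order = np.argsort(sign * scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # group ties: last index of each distinct score value
    distinct = np.nonzero(np.diff(s_sorted * sign, append=np.inf) > 0)[0]
    cum_tp = np.cumsum(l_sorted)[distinct]
    cum_n = distinct + 1
    precision = cum_tp / cum_n
    sensitivity = cum_tp / n_pos
    thresholds = s_sorted[distinct]
    area = float(np.trapezoid(precision, sensitivity))
    return PrecisionSensitivityCurve(
        thresholds=thresholds,
        precision=precision,
        sensitivity=sensitivity,
        direction=direction,
        area=area,
    )


def _bin_edges_labels(bins) -> list[tuple[str, float, float]]:
    edges = [0.0, *bins, np.inf]
    out = []
    for a, b in zip(edges, edges[1:]):
        lab = f"[{a:g},{b:g})" if np.isfinite(b) else f"[{a:g},inf)"
        out.append((lab, a, b))
    return out


def bin_report(
    score_table: pd.DataFrame,
    labeled_set: pd.DataFrame,
    bins=(0.5, 0.6, 0.8, 1.0),
    score_column: str = "hmc",
    cumulative: bool = False,
) -> pd.DataFrame:
    """Per-bin risk ratios of positive- vs negative-labelled variants.

    ``labeled_set`` needs the variant key columns plus a binary ``label``
    (1 = pathogenic/case). Variants absent from the score table (or
    unscored) form their own ``unassessable`` stratum. With
    ``cumulative=True`` the strata are nested upper bounds (score < edge
    for each bin edge, plus score >= last edge), mirroring how tightening
    constraint thresholds are usually reported.
    """
    lab = labeled_set.drop_duplicates(subset=VARIANT_KEY).copy()
    if not set(lab["label"].unique()) <= {0, 1}:
        raise DataError("labels must be binary 0/1")
    sc = score_table.drop_duplicates(subset=VARIANT_KEY)[VARIANT_KEY + [score_column]]
    joined = lab.merge(sc, on=VARIANT_KEY, how="left")
    if joined[score_column].notna().sum() == 0:
        logger.warning("bin_report: no labelled variant matches the score table")
    n1 = int((joined["label"] == 1).sum())
    n2 = int((joined["label"] == 0).sum())
    if n1 == 0 or n2 == 0:
        raise DataError("bin_report requires both label classes")

    strata: list[tuple[str, pd.Series]] = []
    s = joined[score_column]
    if cumulative:
        for edge in bins:
            strata.append((f"<{edge:g}", s < edge))
        strata.append((f">={bins[-1]:g}", s >= bins[-1]))
    else:
        for lab_name, a, b in _bin_edges_labels(bins):
            strata.append((lab_name, (s >= a) & (s < b)))
    strata.append(("unassessable", s.isna()))

    rows = []
    for name, mask in strata:
        a = int((mask & (joined["label"] == 1)).sum())
        b = int((mask & (joined["label"] == 0)).sum())
        if a == 0 and b == 0:
            rows.append((name, a, n1, b, n2, np.nan, np.nan, np.nan, np.nan))
            continue
        rc = rate_ratio(a, n1, b, n2)
        rows.append((name, a, n1, b, n2, rc.estimate, rc.ci_low, rc.ci_high, rc.p_value))
    return pd.DataFrame(
        rows,
        columns=["bin", "n_pos", "total_pos", "n_neg", "total_neg",
                 "risk_ratio", "ci_low", "ci_high", "p_value"],
    )


def read_labeled_variants(path) -> pd.DataFrame:
    """Label TSV: chrom, pos, ref, alt, label (binary), optional score columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(VARIANT_KEY + ["label"]) - set(df.columns)
    if missing:
        raise DataError(f"{path}: label table missing columns {sorted(missing)}")
    return df
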