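"""The constraint score: credible bound, power, classes, aggregation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hmconstraint import hmc_core
from hmconstraint.errors import ConfigError
from hmconstraint.hmc_core import (
    aggregate,
    assessable_fraction_by_gene,
    classify,
    hmc_score,
    power_filter,
    score_variants,
    significance,
)


class TestHmcScore:
    def test_closed_form_at_zero_observed(self):
        for e in (0.5, 1.0, 2.9957, 10.0):
            assert hmc_score(0, e) == pytest.approx(-np.log(0.05) / e, abs=1e-12)
        # expectation of exactly -ln(0.05) puts the bound exactly at 1
        assert hmc_score(0, -np.log(0.05)) == pytest.approx(1.0, abs=1e-12)

    def test_matches_monte_carlo_posterior_quantile(self):
        rng = np.random.default_rng(2024)
        draws = rng.gamma(shape=6.0, size=10_000_000)  # O=5 -> Gamma(6, E)
        mc = np.quantile(draws, 0.95) / 10.0
        assert hmc_score(5, 10.0) == pytest.approx(mc, abs=1e-3)

    @given(
        o=st.integers(min_value=0, max_value=200),
        e=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(deadline=None, max_examples=200)
    def test_exceeds_mle(self, o, e):
        assert hmc_score(o, e) > o / e

    def test_monotone_in_observed_and_expected(self):
        os = np.arange(0, 30)
        assert (np.diff(hmc_score(os, np.full_like(os, 5.0, dtype=float))) > 0).all()
        es = np.linspace(0.5, 50, 100)
        assert (np.diff(hmc_score(np.full_like(es, 3), es)) < 0).all()

    def test_invalid_domain(self):
        with pytest.raises(ValueError):
            hmc_score(1, 0.0)
        with pytest.raises(ValueError):
            hmc_score(-1, 1.0)


class TestSignificance:
    def test_boundary_exclusive(self):
        assert significance(0.99)
        assert not significance(1.0)

    def test_zero_observed_closed_form(self):
        # E = 3.1 > -ln(0.05): full depletion is significant
        assert significance(hmc_score(0, 3.1))
        assert not significance(hmc_score(0, 2.9))

    def test_consistent_with_posterior_tail(self):
        # score < 1 must coincide with posterior P(lambda >= 1) < 0.05
        for o in (0, 2, 5, 20):
            for e in (1.0, 3.5, 8.0, 30.0):
                tail = stats.gamma.sf(1.0, o + 1, scale=1.0 / e)
                assert significance(hmc_score(o, e)) == (tail < 0.05)


class TestPowerFilter:
    def test_examples(self):
        assert not power_filter(1.0)
        assert power_filter(3.5)
        assert hmc_score(0, 1.0) == pytest.approx(2.996, abs=1e-3)
        assert hmc_score(0, 3.5) == pytest.approx(0.856, abs=1e-3)

    def test_threshold_is_detectability_bound(self):
        e = -np.log(0.05)
        assert not power_filter(e)
        assert power_filter(e + 1e-9)

    def test_alpha_to_one_limit(self):
        assert power_filter(np.array([0.01, 1.0, 100.0]), alpha=0.999999).all()

    def test_invalid_alpha(self):
        with pytest.raises(ConfigError):
            power_filter(1.0, alpha=0.0)


class TestClassify:
    def test_bins_and_classes(self):
        cls, bins = classify([0.608, 1.2, 0.3], [True, True, True])
        assert cls.tolist() == ["highly_constrained", "unconstrained", "highly_constrained"]
        assert bins.tolist() == ["[0.6,0.8)", "[1,inf)", "[0,0.5)"]

    def test_strict_thresholds(self):
        cls, _ = classify([0.8, 1.0, 0.79999], [True] * 3)
        assert cls.tolist() == ["constrained", "unconstrained", "highly_constrained"]

    def test_unpowered_is_unassessable(self):
        cls, bins = classify([0.2], [False])
        assert cls.tolist() == ["unassessable"]
        assert bins.tolist() == ["unassessable"]

    def test_unsorted_bins_rejected(self):
        with pytest.raises(ConfigError):
            classify([0.5], [True], bins=(0.8, 0.5))


def _toy_variants():
    """3 copies of a 1-column family; hand-tallied observed/expected."""
    rows = []
    # copy residues at (chrom c{i}, pos 10/11/12); 2 missense candidates each,
    # expected 0.7 per candidate; observed rare at copy 0 and copy 2
    for i in range(3):
        for j, alt in enumerate("AC"):
            rows.append(
                dict(chrom=f"c{i}", pos=10 + j, ref="G", alt=alt,
                     gene_id=f"G{i}", consequence="missense",
                     family_id="F", column=4, n_copies=3,
                     observed_rare=(j == 0 and i in (0, 2)), common=False,
                     assessable=True, expected=0.7)
            )
    # one common variant: contributes to neither side
    rows.append(
        dict(chrom="c0", pos=12, ref="G", alt="T", gene_id="G0",
             consequence="missense", family_id="F", column=4, n_copies=3,
             observed_rare=False, common=True, assessable=False, expected=0.0)
    )
    return pd.DataFrame(rows)


class TestAggregate:
    def test_hand_tally(self):
        variants = _toy_variants()
        meta = pd.DataFrame(
            {"family_id": ["F"] * 3, "column": [4] * 3,
             "protein_id": list("abc"), "protein_position": [1, 1, 1],
             "n_copies": [3] * 3}
        )
        rec = aggregate(variants, meta, min_copies=2)
        assert len(rec) == 1
        r = rec.iloc[0]
        assert r["observed"] == 2
        assert r["expected"] == pytest.approx(6 * 0.7)
        assert r["n_copies"] == 3
        assert r["mle"] == pytest.approx(2 / 4.2)
        assert r["hmc"] == pytest.approx(hmc_score(2, 4.2))
        assert r["powered"]  # 4.2 > 2.996 and 3 copies

    def test_no_observed_variants(self):
        variants = _toy_variants().assign(observed_rare=False)
        meta = pd.DataFrame(
            {"family_id": ["F"], "column": [4], "protein_id": ["a"],
             "protein_position": [1], "n_copies": [3]}
        )
        rec = aggregate(variants, meta)
        assert rec.iloc[0]["observed"] == 0
        assert rec.iloc[0]["expected"] == pytest.approx(4.2)

    def test_neighbor_pooling_sums_adjacent_columns(self):
        variants = _toy_variants()
        shifted = variants.assign(column=5, observed_rare=False,
                                  chrom=variants["chrom"] + "x")
        both = pd.concat([variants, shifted], ignore_index=True)
        meta = pd.DataFrame(
            {"family_id": ["F"] * 2, "column": [4, 5], "protein_id": ["a", "a"],
             "protein_position": [1, 2], "n_copies": [3, 3]}
        )
        rec = aggregate(both, meta, neighbor_columns=1).set_index("column")
        # each column now carries the sum over both columns
        assert rec.loc[4, "observed"] == 2 and rec.loc[5, "observed"] == 2
        assert rec.loc[4, "expected"] == pytest.approx(2 * 4.2)
        plain = aggregate(both, meta).set_index("column")
        assert plain.loc[5, "observed"] == 0

    def test_min_copies_gate(self):
        variants = _toy_variants()
        meta = pd.DataFrame(
            {"family_id": ["F"], "column": [4], "protein_id": ["a"],
             "protein_position": [1], "n_copies": [3]}
        )
        rec = aggregate(variants, meta, min_copies=4)
        assert not rec.iloc[0]["powered"]
        assert rec.iloc[0]["constraint_class"] == "unassessable"


class TestScoreVariants:
    def test_shared_scores_and_gene_fractions(self):
        variants = _toy_variants()
        meta = pd.DataFrame(
            {"family_id": ["F"], "column": [4], "protein_id": ["a"],
             "protein_position": [1], "n_copies": [3]}
        )
        rec = aggregate(variants, meta)
        scored = score_variants(rec, variants)
        # the common variant is still a possible missense SNV at the column
        assert len(scored) == 7
        assert scored["hmc"].nunique() == 1
        frac = assessable_fraction_by_gene(variants, scored)
        g0 = frac[frac["gene_id"] == "G0"].iloc[0]
        assert g0["n_missense"] == 3 and g0["n_assessable"] == 3

    def test_gene_without_domains_zero_assessable(self):
        variants = _toy_variants()
        extra = variants.iloc[[0]].assign(gene_id="G9", family_id=np.nan, column=np.nan)
        variants = pd.concat([variants, extra], ignore_index=True)
        meta = pd.DataFrame(
            {"family_id": ["F"], "column": [4], "protein_id": ["a"],
             "protein_position": [1], "n_copies": [3]}
        )
        rec = aggregate(variants, meta)
        frac = assessable_fraction_by_gene(variants, score_variants(rec, variants))
        assert frac.set_index("gene_id").loc["G9", "n_assessable"] == 0

    def test_no_powered_positions_empty_table(self):
        variants = _toy_variants().assign(expected=0.1)
        meta = pd.DataFrame(
            {"family_id": ["F"], "column": [4], "protein_id": ["a"],
             "protein_position": [1], "n_copies": [3]}
        )
        rec = aggregate(variants, meta)
        assert not rec.iloc[0]["powered"]
        assert score_variants(rec, variants).empty


class TestCalibrationUnderNull:
    def test_false_positive_rate_bounded(self):
        # Poisson-null observed counts at powered positions: the fraction
        # called constrained must not exceed the nominal 5% (the flat-prior
        # credible bound is conservative)
        rng = np.random.default_rng(7)
        n = 5000
        e = rng.uniform(3.1, 40.0, size=n)
        o = rng.poisson(e)
        frac = np.mean(hmc_score(o, e) < 1.0)
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)
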