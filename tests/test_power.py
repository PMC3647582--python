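"""Tests for the exact Fisher power engine and its asymptotic cross-check."""

import numpy as np
import pytest
from scipy.stats import binom
from scipy.stats import fisher_exact as scipy_fisher

from tcrstrat import (
    PowerSpec,
    StratumScenario,
    ValidationError,
    case_freq_from_or,
    fisher_power_exact,
    fisher_power_normal,
    scaled_case_freq,
    stratified_power_report,
)
from tcrstrat.power import rejection_bounds


def brute_force_power(n1, n2, p0, p1, alpha=0.05, alternative="two-sided"):
    """Full double-binomial enumeration with scipy's Fisher test as oracle."""
    power = 0.0
    for a in range(n1 + 1):
        for c in range(n2 + 1):
            if scipy_fisher([[a, n1 - a], [c, n2 - c]], alternative=alternative)[1] <= alpha:
                power += binom.pmf(a, n1, p1) * binom.pmf(c, n2, p0)
    return power


class TestPowerSpec:
    def test_validation(self):
        with pytest.raises(ValidationError):
            PowerSpec(n_cases=0, n_controls=10)
        with pytest.raises(ValidationError):
            PowerSpec(n_cases=10, n_controls=10, alpha=1.5)
        with pytest.raises(ValidationError):
            PowerSpec(n_cases=10, n_controls=10, sidedness="both")
        with pytest.raises(ValidationError):
            # the windowing tolerance must sit far below alpha
            PowerSpec(n_cases=10, n_controls=10, alpha=0.05, tail_mass_tolerance=0.01)


class TestExactEngine:
    @pytest.mark.parametrize(
        "n1, n2, p0, p1",
        [
            (10, 10, 0.10, 0.90),
            (12, 8, 0.20, 0.60),
            (25, 25, 0.10, 0.40),
            (15, 15, 0.30, 0.30),
            (5, 25, 0.15, 0.50),
            (25, 7, 0.40, 0.05),
        ],
    )
    def test_matches_brute_force_enumeration(self, n1, n2, p0, p1):
        spec = PowerSpec(n_cases=n1, n_controls=n2, alpha=0.05)
        assert fisher_power_exact(spec, p0, p1) == pytest.approx(
            brute_force_power(n1, n2, p0, p1), abs=1e-10
        )

    def test_matches_brute_force_one_sided(self):
        spec = PowerSpec(n_cases=12, n_controls=12, alpha=0.05, sidedness="one-sided")
        assert fisher_power_exact(spec, 0.2, 0.6) == pytest.approx(
            brute_force_power(12, 12, 0.2, 0.6, alternative="greater"), abs=1e-10
        )

    def test_size_never_exceeds_alpha(self):
        """Fisher's conditional test is valid: rejection rate at the null <= alpha."""
        for spec in [
            PowerSpec(n_cases=20, n_controls=20, alpha=0.05),
            PowerSpec(n_cases=2000, n_controls=2000, alpha=0.05),
            PowerSpec(n_cases=50, n_controls=200, alpha=0.01),
        ]:
            assert fisher_power_exact(spec, 0.10, 0.10) <= spec.alpha

    def test_monotone_in_effect_size(self):
        spec = PowerSpec(n_cases=50, n_controls=50, alpha=0.05)
        powers = [
            fisher_power_exact(spec, 0.2, case_freq_from_or(0.2, odds))
            for odds in [1.0, 1.5, 2.0, 3.0, 5.0, 8.0]
        ]
        assert all(b >= a - 1e-9 for a, b in zip(powers, powers[1:]))

    def test_monotone_in_sample_size_up_to_discreteness(self):
        for n in (25, 50, 100):
            small = PowerSpec(n_cases=n, n_controls=n)
            large = PowerSpec(n_cases=2 * n, n_controls=2 * n)
            assert fisher_power_exact(large, 0.2, 0.4) >= fisher_power_exact(small, 0.2, 0.4) - 0.01

    def test_allele_mode_doubles_trials(self):
        carrier = PowerSpec(n_cases=100, n_controls=100)
        doubled = PowerSpec(n_cases=200, n_controls=200)
        assert fisher_power_exact(carrier, 0.1, 0.2, mode="allele") == pytest.approx(
            fisher_power_exact(doubled, 0.1, 0.2, mode="carrier"), abs=1e-12
        )

    def test_frequency_validation(self):
        spec = PowerSpec(n_cases=10, n_controls=10)
        with pytest.raises(ValidationError):
            fisher_power_exact(spec, 0.0, 0.5)
        with pytest.raises(ValidationError):
            fisher_power_exact(spec, 0.5, 1.0)


class TestRejectionBounds:
    def test_bounds_reproduce_per_table_decisions(self):
        n1 = n2 = 30
        for s in (5, 15, 30, 45):
            a_lo, a_hi = rejection_bounds(n1, n2, s, alpha=0.05)
            for a in range(max(0, s - n2), min(n1, s) + 1):
                c = s - a
                p = scipy_fisher([[a, n1 - a], [c, n2 - c]])[1]
                assert (p <= 0.05) == (a <= a_lo or a >= a_hi)


class TestNormalApproximation:
    def test_published_design_unstratified(self, paper_spec):
        """z-approximation at p1 implied by cohort OR 1.1: ~0.15."""
        p1 = case_freq_from_or(0.10, 1.1)
        assert fisher_power_normal(paper_spec, 0.10, p1) == pytest.approx(0.15, abs=0.005)

    def test_asymptotic_size(self, paper_spec):
        assert fisher_power_normal(paper_spec, 0.10, 0.10) == pytest.approx(
            paper_spec.alpha, abs=0.002
        )

    def test_published_design_stratified_saturates(self, paper_spec):
        p1 = case_freq_from_or(0.10, 2.315789473684211)
        assert fisher_power_normal(paper_spec, 0.10, p1) > 0.999

    def test_close_to_exact_at_large_n(self, paper_spec):
        """Exact and asymptotic powers agree within 0.03 on the published design."""
        for odds in (1.1, 2.315789473684211):
            for convert in (case_freq_from_or, scaled_case_freq):
                p1 = convert(0.10, odds)
                gap = abs(
                    fisher_power_exact(paper_spec, 0.10, p1)
                    - fisher_power_normal(paper_spec, 0.10, p1)
                )
                assert gap < 0.03


class TestStratifiedReport:
    def test_dr33_report(self, dr33_scenario, paper_spec):
        """Stratification lifts exact power from ~16% to 100% for DR3/3."""
        rows = stratified_power_report(
            dr33_scenario, paper_spec, freq_convention="multiplicative"
        )
        by_analysis = rows.set_index("analysis")
        assert round(100 * by_analysis.loc["stratified", "power_exact"]) == 100
        assert by_analysis.loc["stratified", "odds_ratio"] == pytest.approx(
            2.315789473684211, rel=1e-12
        )
        assert by_analysis.loc["unstratified", "power_exact"] < 0.2

    def test_null_cohort_or_gives_size_in_both_rows(self, paper_spec):
        scenario = StratumScenario(name="null", f=0.076, p0=0.10, or_all=1.0)
        rows = stratified_power_report(scenario, paper_spec)
        assert (rows.power_exact <= paper_spec.alpha).all()

    def test_vacuous_stratification(self, paper_spec):
        scenario = StratumScenario(name="all", f=1.0, p0=0.10, or_all=1.5)
        rows = stratified_power_report(scenario, paper_spec)
        assert rows.power_exact.iloc[0] == pytest.approx(rows.power_exact.iloc[1], abs=1e-12)

    def test_reduced_case_count_option(self, dr33_scenario, paper_spec):
        rows = stratified_power_report(dr33_scenario, paper_spec, reduce_cases=True)
        by_analysis = rows.set_index("analysis")
        assert by_analysis.loc["stratified", "n_cases"] == round(0.076 * 2000)
        assert (
            by_analysis.loc["stratified", "power_exact"]
            < stratified_power_report(dr33_scenario, paper_spec)
            .set_index("analysis")
            .loc["stratified", "power_exact"]
        )

    def test_requires_or_all(self, paper_spec):
        scenario = StratumScenario(name="x", f=0.076, p0=0.10, or_stratum=2.3)
        with pytest.raises(ValidationError):
            stratified_power_report(scenario, paper_spec)
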