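"""Shared fixtures and independent oracles for the test suite."""

from fractions import Fraction
from math import comb

import pytest

from tcrstrat import ContingencyTable, PowerSpec, StratumScenario


def fisher_pvalue_oracle(a: int, b: int, c: int, d: int, sidedness: str) -> Fraction:
    """Exact-rational Fisher p-value by full hypergeometric enumeration.

    Independent of the package implementation: integer binomials and
    Fraction arithmetic, no log-space tricks, exact tie comparison.
    """
    n1, n2, s = a + b, c + d, a + c
    total = comb(n1 + n2, s)
    support = range(max(0, s - n2), min(n1, s) + 1)
    probs = {k: Fraction(comb(n1, k) * comb(n2, s - k), total) for k in support}
    observed = probs[a]
    if sidedness == "less":
        return sum(p for k, p in probs.items() if k <= a)
    if sidedness == "greater":
        return sum(p for k, p in probs.items() if k >= a)
    return sum(p for p in probs.values() if p <= observed)


@pytest.fixture
def rat_tables():
    """The two rat V-beta-13 depletion outcome tables (treated vs control)."""
    return {
        "induced": ContingencyTable(2, 18, 34, 6),  # 2/20 vs 34/40 diabetic
        "virus": ContingencyTable(3, 7, 8, 2),  # 3/10 vs 8/10 diabetic
    }


@pytest.fixture
def dr33_scenario():
    """DR3/3 stratification scenario: f=7.6%, p0=10%, cohort OR 1.1."""
    return StratumScenario(name="DR3/3", f=0.076, p0=0.10, or_all=1.1)


@pytest.fixture
def paper_spec():
    """2000 cases / 2000 controls, two-tailed alpha 0.05."""
    return PowerSpec(n_cases=2000, n_controls=2000, alpha=0.05, sidedness="two-sided")
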