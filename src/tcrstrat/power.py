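"""Exact power of Fisher's exact test for two independent binomial samples.

The sampling model is unconditional — carrier counts in cases and
controls are independent binomials — while the rejection rule is the
conditional Fisher exact test.  Power is the total joint binomial
probability of the outcome pairs the test rejects:

    power = sum_{(a, c) : p_Fisher(a, c) <= alpha}  Bin(a; n1, p1) * Bin(c; n2, p0)

The double sum is organised by the conditional margin s = a + c: within a
margin the rejection region is an interval complement {a <= a_lo(s)} or
{a >= a_hi(s)} located once per margin from the unimodal hypergeometric
point probabilities.  Each binomial is restricted to a window carrying
all but ``tail_mass_tolerance`` of its mass, which keeps n = 2000 per
group well under a second.

A closed-form normal-approximation power (pooled variance under the null,
unpooled under the alternative) is provided as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import binom, norm

from .errors import ValidationError
from .stratify import StratumScenario, case_freq_from_or, concentrate_or, scaled_case_freq
from .tables2x2 import conditional_pvalues

__all__ = [
    "PowerSpec",
    "fisher_power_exact",
    "fisher_power_normal",
    "rejection_bounds",
    "stratified_power_report",
]

POWER_SIDEDNESS = ("one-sided", "two-sided")
FREQ_CONVENTIONS = ("odds", "multiplicative")


@dataclass(frozen=True)
class PowerSpec:
    """Design of a power computation.

    ``sidedness`` is ``"two-sided"`` or ``"one-sided"`` (the one-sided
    test rejects for excess exposure among cases when p1 > p0).
    ``tail_mass_tolerance`` bounds the binomial mass excluded by the
    summation window; it must be far below alpha so windowing cannot
    perturb a power at the scale alpha resolves.
    """

    n_cases: int
    n_controls: int
    alpha: float = 0.05
    sidedness: str = "two-sided"
    tail_mass_tolerance: float = 1e-12

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls"):
            n = getattr(self, name)
            if not isinstance(n, (int, np.integer)) or isinstance(n, bool) or n < 1:
                raise ValidationError(f"{name} must be a positive integer, got {n!r}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.sidedness not in POWER_SIDEDNESS:
            raise ValidationError(
                f"sidedness must be one of {POWER_SIDEDNESS}, got {self.sidedness!r}"
            )
        if not 0 < self.tail_mass_tolerance < self.alpha / 100:
            raise ValidationError(
                "tail_mass_tolerance must be positive and < alpha/100, got "
                f"{self.tail_mass_tolerance}"
            )


def _check_freq(p: float, name: str) -> None:
    if not 0 < p < 1:
        raise ValidationError(f"{name} must be in (0,1), got {p}")


def _fisher_sidedness(spec_sidedness: str, p0: float, p1: float) -> str:
    if spec_sidedness == "two-sided":
        return "two-sided"
    return "greater" if p1 >= p0 else "less"


def rejection_bounds(
    n_cases: int,
    n_controls: int,
    s: int,
    alpha: float,
    sidedness: str = "two-sided",
) -> tuple[int, int]:
    """Per-margin rejection boundaries of the Fisher test.

    For margin ``s`` (total exposed), returns ``(a_lo, a_hi)`` such that
    the test rejects exactly when the exposed-case count a satisfies
    a <= a_lo or a >= a_hi.  An empty tail is signalled by a_lo below the
    support minimum / a_hi above its maximum.  Relies on the unimodality
    of the hypergeometric point probabilities, which makes the rejection
    region a union of the two outer tails.
    """
    support, pvalues = conditional_pvalues(n_cases, n_controls, s, sidedness)
    reject = pvalues <= alpha
    a_lo = int(support[0]) - 1
    i = 0
    while i < reject.size and reject[i]:
        a_lo = int(support[i])
        i += 1
    a_hi = int(support[-1]) + 1
    j = reject.size - 1
    while j >= i and reject[j]:
        a_hi = int(support[j])
        j -= 1
    if int(reject.sum()) != (a_lo - support[0] + 1) + (support[-1] - a_hi + 1):
        raise AssertionError("rejection region is not a two-tail union")  # pragma: no cover
    return a_lo, a_hi


def _binomial_window(n: int, p: float, tail_mass: float) -> tuple[int, int]:
    lo = int(binom.ppf(tail_mass / 2, n, p))
    hi = int(binom.isf(tail_mass / 2, n, p))
    return max(0, lo - 2), min(n, hi + 2)


def fisher_power_exact(
    spec: PowerSpec, p0: float, p1: float, mode: str = "carrier"
) -> float:
    """Exact unconditional power of Fisher's exact test.

    ``p0``/``p1`` are the control and case carrier frequencies.  With
    ``mode="allele"`` each subject contributes two chromosomes, i.e. the
    binomial trial counts are doubled and the frequencies are read as
    per-chromosome allele frequencies.
    """
    _check_freq(p0, "p0")
    _check_freq(p1, "p1")
    if mode not in ("carrier", "allele"):
        raise ValidationError(f"mode must be 'carrier' or 'allele', got {mode!r}")
    n1, n2 = spec.n_cases, spec.n_controls
    if mode == "allele":
        n1, n2 = 2 * n1, 2 * n2
    fisher_side = _fisher_sidedness(spec.sidedness, p0, p1)

    a_lo_w, a_hi_w = _binomial_window(n1, p1, spec.tail_mass_tolerance)
    c_lo_w, c_hi_w = _binomial_window(n2, p0, spec.tail_mass_tolerance)
    log_pa = binom.logpmf(np.arange(a_lo_w, a_hi_w + 1), n1, p1)
    log_pc = binom.logpmf(np.arange(c_lo_w, c_hi_w + 1), n2, p0)

    power = 0.0
    for s in range(a_lo_w + c_lo_w, a_hi_w + c_hi_w + 1):
        a_lo, a_hi = rejection_bounds(n1, n2, s, spec.alpha, fisher_side)
        k_min = max(a_lo_w, s - c_hi_w)
        k_max = min(a_hi_w, s - c_lo_w)
        if k_min > k_max:
            continue
        k = np.arange(k_min, k_max + 1)
        in_region = (k <= a_lo) | (k >= a_hi)
        k = k[in_region]
        if k.size:
            power += float(np.exp(log_pa[k - a_lo_w] + log_pc[s - k - c_lo_w]).sum())
    return min(power, 1.0)


def fisher_power_normal(
    spec: PowerSpec, p0: float, p1: float, mode: str = "carrier"
) -> float:
    """Two-proportion z-test power as an asymptotic cross-check.

    Pooled variance under the null, unpooled under the alternative;
    two-sided power sums both rejection directions.
    """
    _check_freq(p0, "p0")
    _check_freq(p1, "p1")
    n1, n2 = spec.n_cases, spec.n_controls
    if mode == "allele":
        n1, n2 = 2 * n1, 2 * n2
    elif mode != "carrier":
        raise ValidationError(f"mode must be 'carrier' or 'allele', got {mode!r}")
    diff = p1 - p0
    p_bar = (n1 * p1 + n2 * p0) / (n1 + n2)
    se0 = np.sqrt(p_bar * (1 - p_bar) * (1 / n1 + 1 / n2))
    se1 = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n2)
    if spec.sidedness == "two-sided":
        z = norm.ppf(1 - spec.alpha / 2)
        power = norm.cdf((diff - z * se0) / se1) + norm.cdf((-diff - z * se0) / se1)
    else:
        z = norm.ppf(1 - spec.alpha)
        direction = 1.0 if p1 >= p0 else -1.0
        power = norm.cdf((direction * diff - z * se0) / se1)
    return float(min(max(power, 0.0), 1.0))


def stratified_power_report(
    scenario: StratumScenario,
    spec: PowerSpec,
    freq_convention: str = "odds",
    mode: str = "carrier",
    reduce_cases: bool = False,
) -> pd.DataFrame:
    """Unstratified vs stratified power for one diplotype scenario.

    The scenario's cohort-level OR gives the unstratified case frequency;
    inverting the linear dilution model gives the stratum OR and hence
    the stratified case frequency.  ``freq_convention`` selects how an OR
    becomes a case frequency: ``"odds"`` uses the odds-scale identity
    p1 = OR*p0/(1-p0+OR*p0); ``"multiplicative"`` scales the frequency
    directly, p1 = OR*p0 (the convention that reproduces published
    G*Power-style figures; see docs/methods.md).

    By default the stratified analysis keeps the full case count — a
    cohort enriched to the stratum.  With ``reduce_cases=True`` the case
    count is instead round(f * n_cases), modelling stratification within
    a fixed cohort.
    """
    if scenario.or_all is None:
        raise ValidationError("scenario must have or_all set")
    if freq_convention not in FREQ_CONVENTIONS:
        raise ValidationError(
            f"freq_convention must be one of {FREQ_CONVENTIONS}, got {freq_convention!r}"
        )
    convert = case_freq_from_or if freq_convention == "odds" else scaled_case_freq
    or_stratum = concentrate_or(scenario.or_all, scenario.f)

    rows = []
    for analysis, or_used in (("unstratified", scenario.or_all), ("stratified", or_stratum)):
        row_spec = spec
        if analysis == "stratified" and reduce_cases:
            n_strat = max(1, round(scenario.f * spec.n_cases))
            row_spec = replace(spec, n_cases=n_strat)
        p1 = convert(scenario.p0, or_used)
        rows.append(
            {
                "scenario": scenario.name,
                "analysis": analysis,
                "f": scenario.f,
                "p0": scenario.p0,
                "odds_ratio": or_used,
                "p1": p1,
                "n_cases": row_spec.n_cases,
                "n_controls": row_spec.n_controls,
                "alpha": row_spec.alpha,
                "sidedness": row_spec.sidedness,
                "freq_convention": freq_convention,
                "power_exact": fisher_power_exact(row_spec, scenario.p0, p1, mode=mode),
                "power_normal": fisher_power_normal(row_spec, scenario.p0, p1, mode=mode),
            }
        )
    return pd.DataFrame(rows)
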