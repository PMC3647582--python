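"""Odds-ratio dilution under HLA-diplotype stratification.

A candidate TCR risk allele that acts only within one HLA diplotype
stratum of cases appears attenuated when the whole cohort is analysed.
The published linear dilution model mixes odds ratios with case-fraction
weights::

    OR_all = f * OR_stratum + (1 - f)

where ``f`` is the fraction of cases carrying the diplotype.  This module
implements that model literally, its inversion, and the exact
carrier-frequency mixing counterpart (the generative truth of the cohort
simulator), so the approximation error of the linear form is visible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import pandas as pd

from .errors import InfeasibleDilutionError, ValidationError

__all__ = [
    "StratumScenario",
    "dilute_or",
    "concentrate_or",
    "dilute_or_multi",
    "case_freq_from_or",
    "scaled_case_freq",
    "mixing_or",
    "or_curve",
]

logger = logging.getLogger(__name__)


def _check_fraction(f: float, name: str = "f") -> None:
    if not 0 < f <= 1:
        raise ValidationError(f"{name} must be in (0, 1], got {f}")


def _check_frequency(p: float, name: str = "p0") -> None:
    if not 0 < p < 1:
        raise ValidationError(f"{name} must be in (0, 1), got {p}")


def _check_or(value: float, name: str = "odds ratio") -> None:
    if not value > 0:
        raise ValidationError(f"{name} must be > 0, got {value}")


@dataclass
class StratumScenario:
    """One HLA-diplotype stratum within a case-control design.

    Parameters
    ----------
    name:
        Label, e.g. ``"DR3/3"``.
    f:
        Fraction of cases carrying the diplotype, in (0, 1].
    p0:
        Control carrier frequency of the candidate allele, in (0, 1).
    or_stratum, or_all:
        Within-stratum and whole-cohort odds ratios.  Exactly one may be
        left unset; :meth:`solve` fills it in via the linear model.
    """

    name: str
    f: float
    p0: float
    or_stratum: float | None = None
    or_all: float | None = None

    def __post_init__(self) -> None:
        _check_fraction(self.f)
        _check_frequency(self.p0)
        if self.or_stratum is None and self.or_all is None:
            raise ValidationError("one of or_stratum / or_all must be set")
        if self.or_stratum is not None:
            _check_or(self.or_stratum, "or_stratum")
        if self.or_all is not None:
            _check_or(self.or_all, "or_all")

    def solve(self) -> "StratumScenario":
        """Return a copy with the missing OR filled in via the linear model."""
        or_stratum, or_all = self.or_stratum, self.or_all
        if or_stratum is None:
            or_stratum = concentrate_or(or_all, self.f)
        elif or_all is None:
            or_all = dilute_or(or_stratum, self.f)
        return StratumScenario(self.name, self.f, self.p0, or_stratum, or_all)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "StratumScenario":
        data = json.loads(text)
        allowed = {"name", "f", "p0", "or_stratum", "or_all"}
        unknown = set(data) - allowed
        if unknown:
            raise ValidationError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**data)


def dilute_or(or_stratum: float, f: float) -> float:
    """Whole-cohort OR implied by a stratum OR under the linear model."""
    _check_or(or_stratum, "or_stratum")
    _check_fraction(f)
    return f * or_stratum + (1.0 - f)


def concentrate_or(or_all: float, f: float) -> float:
    """Invert the linear dilution: stratum OR from the whole-cohort OR."""
    _check_or(or_all, "or_all")
    _check_fraction(f)
    if or_all <= 1.0 - f:
        raise InfeasibleDilutionError(
            f"or_all={or_all} is not achievable by dilution at f={f}: "
            f"the linear model requires or_all > {1.0 - f}"
        )
    return (or_all - (1.0 - f)) / f


def dilute_or_multi(fractions: Sequence[float], stratum_ors: Sequence[float]) -> float:
    """Multi-stratum extension OR_all = sum(f_i * OR_i) + (1 - sum(f_i)).

    The residual weight 1 - sum(f_i) carries a null OR of 1.
    """
    if len(fractions) != len(stratum_ors) or not fractions:
        raise ValidationError("fractions and stratum_ors must be equal-length, non-empty")
    for f in fractions:
        _check_fraction(f)
    for value in stratum_ors:
        _check_or(value)
    total = sum(fractions)
    if total > 1.0 + 1e-12:
        raise ValidationError(f"case fractions sum to {total} > 1")
    return sum(f * o for f, o in zip(fractions, stratum_ors)) + (1.0 - min(total, 1.0))


def case_freq_from_or(p0: float, odds_ratio: float) -> float:
    """Case carrier frequency implied by an odds ratio on a control frequency.

    Solves odds(p1) = OR * odds(p0):  p1 = OR*p0 / (1 - p0 + OR*p0).
    """
    _check_frequency(p0)
    _check_or(odds_ratio)
    return odds_ratio * p0 / (1.0 - p0 + odds_ratio * p0)


def scaled_case_freq(p0: float, ratio: float) -> float:
    """Case carrier frequency from a multiplicative frequency scaling, p1 = ratio*p0.

    This treats the effect size as a ratio of carrier frequencies rather
    than of odds.  For small p0 the two conversions nearly coincide; the
    distinction matters when matching power figures computed by software
    fed proportions directly (see docs/methods.md).
    """
    _check_frequency(p0)
    _check_or(ratio, "ratio")
    p1 = ratio * p0
    if not p1 < 1:
        raise ValidationError(f"scaled frequency ratio*p0 = {p1} must be < 1")
    return p1


def mixing_or(f: float, p0: float, or_stratum: float) -> float:
    """Exact whole-cohort OR under carrier-frequency mixing.

    The generative model puts carrier frequency p1 = case_freq_from_or(p0,
    or_stratum) in the risk-stratum cases and p0 elsewhere, so the pooled
    case frequency is pc = f*p1 + (1-f)*p0 and the cohort OR is
    odds(pc)/odds(p0).  Slightly below the linear model's prediction for
    or_stratum > 1; equal at the null.
    """
    _check_fraction(f)
    _check_frequency(p0)
    _check_or(or_stratum, "or_stratum")
    p1 = case_freq_from_or(p0, or_stratum)
    pc = f * p1 + (1.0 - f) * p0
    return (pc / (1.0 - pc)) / (p0 / (1.0 - p0))


def or_curve(f_values: Iterable[float], or_all_grid: Iterable[float]) -> pd.DataFrame:
    """Stratified-vs-unstratified OR table, one row per (f, or_all) pair.

    Pairs infeasible under the linear model (or_all <= 1 - f) are omitted
    with a logged notice.  Columns: f, or_all, or_stratum.
    """
    f_values = list(f_values)
    or_all_grid = list(or_all_grid)
    if not f_values or not or_all_grid:
        raise ValidationError("f_values and or_all_grid must be non-empty")
    rows = []
    for f in f_values:
        _check_fraction(f)
        for or_all in or_all_grid:
            try:
                rows.append((f, or_all, concentrate_or(or_all, f)))
            except InfeasibleDilutionError:
                logger.info("omitting infeasible pair f=%s or_all=%s", f, or_all)
    return pd.DataFrame(rows, columns=["f", "or_all", "or_stratum"])
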