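"""First-principles 2x2 association statistics.

A case-control table is laid out exposure-by-status::

              exposed  unexposed
    cases        a         b
    controls     c         d

The module provides the cross-product odds ratio and Fisher's exact test
computed by direct hypergeometric enumeration in log space.  These two
primitives underpin every downstream stage (power engine, simulator,
report generation), so they are implemented from scratch here rather than
delegated to a statistics library; the test suite cross-checks them
against independent oracles.

Conventions
-----------
* ``odds_ratio`` returns ``inf`` when only the denominator cross product
  vanishes and ``nan`` when both do; no continuity correction is applied
  unless requested explicitly.
* The two-sided Fisher p-value follows the minimum-likelihood rule: the
  sum of the point probabilities of all tables in the conditional support
  whose probability does not exceed that of the observed table (with a
  small relative slack for floating-point ties).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ContingencyTable",
    "odds_ratio",
    "fisher_exact",
    "wald_log_or_ci",
    "read_tables_tsv",
    "write_tables_tsv",
]

SIDEDNESS = ("less", "greater", "two-sided")

#: Relative slack used when comparing point probabilities for the
#: two-sided minimum-likelihood rule, so that exact ties that differ only
#: in the last floating-point bits are counted as ties.
TIE_TOLERANCE = 1e-7

TSV_COLUMNS = [
    "exposed_cases",
    "unexposed_cases",
    "exposed_controls",
    "unexposed_controls",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Four non-negative integer cell counts of a 2x2 exposure-by-status table."""

    a: int  #: exposed cases
    b: int  #: unexposed cases
    c: int  #: exposed controls
    d: int  #: unexposed controls

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
                raise ValidationError(f"cell {name!r} must be an integer, got {value!r}")
            if value < 0:
                raise ValidationError(f"cell {name!r} must be non-negative, got {value}")
            object.__setattr__(self, name, int(value))

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def n_exposed(self) -> int:
        return self.a + self.c

    @property
    def n_unexposed(self) -> int:
        return self.b + self.d

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


# ---------------------------------------------------------------------------
# Cached log-factorials
# ---------------------------------------------------------------------------

_LOGFACT = np.zeros(1)


def _logfact(n: int) -> np.ndarray:
    """Return log-factorials 0..n from a growing module-level cache."""
    global _LOGFACT
    if n >= _LOGFACT.size:
        size = max(n + 1, 2 * _LOGFACT.size, 1024)
        values = np.arange(size, dtype=np.float64)
        values[0] = 1.0
        _LOGFACT = np.cumsum(np.log(values))
        _LOGFACT[0] = 0.0
    return _LOGFACT


def hypergeom_logpmf_vector(n_cases: int, n_controls: int, s: int) -> tuple[np.ndarray, np.ndarray]:
    """Log point probabilities of the conditional 2x2 distribution.

    Given fixed group sizes and ``s`` exposed subjects in total, the number
    of exposed cases ``K`` is hypergeometric.  Returns ``(support, logpmf)``
    where support runs over ``max(0, s - n_controls) .. min(n_cases, s)``.
    """
    total = n_cases + n_controls
    lf = _logfact(total)
    k = np.arange(max(0, s - n_controls), min(n_cases, s) + 1)
    logpmf = (
        lf[n_cases] - lf[k] - lf[n_cases - k]
        + lf[n_controls] - lf[s - k] - lf[n_controls - s + k]
        - (lf[total] - lf[s] - lf[total - s])
    )
    return k, logpmf


def _logcumsumexp(log_values: np.ndarray) -> np.ndarray:
    m = log_values.max()
    with np.errstate(divide="ignore"):  # log(0) = -inf is the right answer here
        return np.log(np.cumsum(np.exp(log_values - m))) + m


def conditional_pvalues(
    n_cases: int,
    n_controls: int,
    s: int,
    sidedness: str = "two-sided",
    tie_tolerance: float = TIE_TOLERANCE,
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher p-values for every table on a fixed margin.

    Returns ``(support, pvalues)`` where ``pvalues[i]`` is the Fisher exact
    p-value of observing ``support[i]`` exposed cases given ``s`` exposed
    subjects in total.  Shared by :func:`fisher_exact` (which needs one
    entry) and the power engine (which needs the whole rejection region of
    each margin at once).
    """
    if sidedness not in SIDEDNESS:
        raise ValidationError(f"sidedness must be one of {SIDEDNESS}, got {sidedness!r}")
    k, logpmf = hypergeom_logpmf_vector(n_cases, n_controls, s)
    if sidedness == "less":
        tails = _logcumsumexp(logpmf)
        p = np.exp(np.minimum(tails, 0.0))
    elif sidedness == "greater":
        tails = _logcumsumexp(logpmf[::-1])[::-1]
        p = np.exp(np.minimum(tails, 0.0))
    else:
        order = np.argsort(logpmf, kind="stable")
        sorted_lp = logpmf[order]
        cumulative = _logcumsumexp(sorted_lp)
        # p(k) = total mass of tables no more likely than k, up to tie slack
        idx = np.searchsorted(sorted_lp, logpmf + math.log1p(tie_tolerance), side="right") - 1
        p = np.exp(np.minimum(cumulative[idx], 0.0))
    return k, p


def fisher_exact(table: ContingencyTable, sidedness: str = "two-sided") -> float:
    """Fisher's exact test by hypergeometric enumeration.

    ``sidedness`` is ``"less"`` (case exposure lower than expected),
    ``"greater"``, or ``"two-sided"`` (minimum-likelihood rule).  A table
    with an empty row or column carries no information about association;
    it yields p = 1 with a warning rather than an exception.
    """
    if sidedness not in SIDEDNESS:
        raise ValidationError(f"sidedness must be one of {SIDEDNESS}, got {sidedness!r}")
    if min(table.n_cases, table.n_controls, table.n_exposed, table.n_unexposed) == 0:
        warnings.warn(
            "degenerate margins (empty row or column): Fisher test is uninformative, p = 1",
            stacklevel=2,
        )
        return 1.0
    support, pvalues = conditional_pvalues(
        table.n_cases, table.n_controls, table.n_exposed, sidedness
    )
    return float(pvalues[table.a - support[0]])


def odds_ratio(table: ContingencyTable, continuity: bool = False) -> float:
    """Cross-product odds ratio (a*d)/(b*c).

    Returns ``inf`` if only the denominator vanishes and ``nan`` if both
    cross products are zero.  With ``continuity=True``, 0.5 is added to
    every cell (Haldane-Anscombe) before forming the ratio.
    """
    if continuity:
        return ((table.a + 0.5) * (table.d + 0.5)) / ((table.b + 0.5) * (table.c + 0.5))
    num = table.a * table.d
    den = table.b * table.c
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def wald_log_or_ci(table: ContingencyTable, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for the odds ratio on the log scale.

    Requires all four cells positive; this is the only interval the
    package offers.
    """
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0,1), got {level}")
    if min(table.a, table.b, table.c, table.d) == 0:
        raise ValidationError("Wald log-OR interval requires all cells > 0")
    from scipy.stats import norm

    log_or = math.log(odds_ratio(table))
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    z = norm.ppf(0.5 + level / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_tables_tsv(source) -> list[ContingencyTable]:
    """Read tables from TSV with one scenario per row.

    Expected header: exposed_cases, unexposed_cases, exposed_controls,
    unexposed_controls.
    """
    frame = pd.read_csv(source, sep="\t")
    missing = [col for col in TSV_COLUMNS if col not in frame.columns]
    if missing:
        raise ValidationError(f"missing TSV columns: {missing}")
    return [
        ContingencyTable(int(row.exposed_cases), int(row.unexposed_cases),
                         int(row.exposed_controls), int(row.unexposed_controls))
        for row in frame.itertuples()
    ]


def write_tables_tsv(tables: Iterable[ContingencyTable], target) -> None:
    frame = pd.DataFrame(
        [(t.a, t.b, t.c, t.d) for t in tables], columns=TSV_COLUMNS
    )
    frame.to_csv(target, sep="\t", index=False)
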