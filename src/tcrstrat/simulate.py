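"""Synthetic case-control cohorts with an HLA-stratum-contingent marker.

The generative model mirrors the stratified-susceptibility hypothesis:
a binary "risk TCR carrier" marker has frequency p0 in every control,
and an elevated frequency p1 — implied by a within-stratum odds ratio —
only among cases carrying the risk HLA diplotype.  Case stratum
membership is Bernoulli(f).  Controls' stratum labels are drawn from the
same (or a user-supplied) frequency but never influence their carrier
probability.

Randomness: every cohort is generated by ``numpy.random.default_rng``
seeded from the config seed; replicate r of a Monte-Carlo run uses the
stream ``default_rng([seed, r])`` so each replicate is reproducible in
isolation, independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .power import PowerSpec, _fisher_sidedness
from .stratify import case_freq_from_or
from .tables2x2 import ContingencyTable, fisher_exact, odds_ratio

__all__ = ["CohortConfig", "Cohort", "simulate_cohort", "estimate_ors", "empirical_power"]


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic case-control cohort.

    ``control_f`` is the risk-diplotype frequency among controls used
    only for labelling (carrier probability in controls is p0 in every
    stratum); it defaults to ``f``.
    """

    f: float
    p0: float
    or_stratum: float
    n_cases: int
    n_controls: int
    seed: int
    control_f: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.f <= 1:
            raise ValidationError(f"f must be in (0,1], got {self.f}")
        if not 0 < self.p0 < 1:
            raise ValidationError(f"p0 must be in (0,1), got {self.p0}")
        if not self.or_stratum > 0:
            raise ValidationError(f"or_stratum must be > 0, got {self.or_stratum}")
        for name in ("n_cases", "n_controls"):
            n = getattr(self, name)
            if not isinstance(n, (int, np.integer)) or isinstance(n, bool) or n < 1:
                raise ValidationError(f"{name} must be a positive integer, got {n!r}")
        if self.control_f is not None and not 0 <= self.control_f <= 1:
            raise ValidationError(f"control_f must be in [0,1], got {self.control_f}")

    @property
    def p1(self) -> float:
        """Carrier frequency among risk-stratum cases."""
        return case_freq_from_or(self.p0, self.or_stratum)


@dataclass
class Cohort:
    """Per-subject records as parallel boolean arrays."""

    is_case: np.ndarray
    in_risk_stratum: np.ndarray
    carrier: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.is_case)
        if not (len(self.in_risk_stratum) == n and len(self.carrier) == n):
            raise ValidationError("cohort arrays must have equal length")

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "status": np.where(self.is_case, "case", "control"),
                "stratum": np.where(self.in_risk_stratum, "risk-diplotype", "other"),
                "carrier": np.where(self.carrier, "yes", "no"),
            }
        )

    def to_tsv(self, target) -> None:
        self.to_frame().to_csv(target, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, source) -> "Cohort":
        frame = pd.read_csv(source, sep="\t")
        return cls(
            is_case=(frame["status"] == "case").to_numpy(),
            in_risk_stratum=(frame["stratum"] == "risk-diplotype").to_numpy(),
            carrier=(frame["carrier"] == "yes").to_numpy(),
        )


def simulate_cohort(config: CohortConfig, rng: np.random.Generator | None = None) -> Cohort:
    """Draw one cohort; identical configs (and hence seeds) give identical cohorts."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_cases, config.n_controls
    control_f = config.f if config.control_f is None else config.control_f

    case_stratum = rng.random(n1) < config.f
    control_stratum = rng.random(n2) < control_f
    p_case = np.where(case_stratum, config.p1, config.p0)
    case_carrier = rng.random(n1) < p_case
    control_carrier = rng.random(n2) < config.p0

    return Cohort(
        is_case=np.concatenate([np.ones(n1, dtype=bool), np.zeros(n2, dtype=bool)]),
        in_risk_stratum=np.concatenate([case_stratum, control_stratum]),
        carrier=np.concatenate([case_carrier, control_carrier]),
    )


def _table_from_masks(case_mask: np.ndarray, control_mask: np.ndarray,
                      carrier: np.ndarray) -> ContingencyTable:
    a = int(carrier[case_mask].sum())
    b = int(case_mask.sum()) - a
    c = int(carrier[control_mask].sum())
    d = int(control_mask.sum()) - c
    return ContingencyTable(a, b, c, d)


def estimate_ors(cohort: Cohort, sidedness: str = "two-sided") -> dict:
    """Overall and risk-stratum association estimates from one cohort.

    The overall table pools all strata; the stratum table restricts cases
    to the risk diplotype but keeps all controls, matching the stratified
    analysis the dilution argument contemplates.  Returns tables, odds
    ratios (with the usual inf/nan zero-cell sentinels) and Fisher
    p-values.
    """
    if cohort.n_cases < 1 or cohort.n_controls < 1:
        raise ValidationError("cohort must contain at least one case and one control")
    case_mask = cohort.is_case
    control_mask = ~cohort.is_case
    overall = _table_from_masks(case_mask, control_mask, cohort.carrier)
    stratum = _table_from_masks(
        case_mask & cohort.in_risk_stratum, control_mask, cohort.carrier
    )
    return {
        "overall_table": overall,
        "overall_or": odds_ratio(overall),
        "overall_p": fisher_exact(overall, sidedness),
        "stratum_table": stratum,
        "stratum_or": odds_ratio(stratum),
        "stratum_p": fisher_exact(stratum, sidedness),
    }


def empirical_power(
    config: CohortConfig,
    spec: PowerSpec,
    replicates: int,
    analysis: str = "overall",
) -> float:
    """Monte-Carlo rejection rate of the chosen analysis at spec.alpha.

    ``analysis`` is ``"overall"`` (pooled cohort test) or ``"stratified"``
    (risk-stratum cases vs all controls).  Replicate r draws from the
    stream ``default_rng([config.seed, r])``.
    """
    if not isinstance(replicates, (int, np.integer)) or replicates < 1:
        raise ValidationError(f"replicates must be a positive integer, got {replicates!r}")
    if analysis not in ("overall", "stratified"):
        raise ValidationError(f"analysis must be 'overall' or 'stratified', got {analysis!r}")
    fisher_side = _fisher_sidedness(spec.sidedness, config.p0, config.p1)
    rejected = 0
    for r in range(replicates):
        rng = np.random.default_rng([config.seed, r])
        cohort = simulate_cohort(config, rng=rng)
        if analysis == "overall":
            table = _table_from_masks(cohort.is_case, ~cohort.is_case, cohort.carrier)
        else:
            table = _table_from_masks(
                cohort.is_case & cohort.in_risk_stratum, ~cohort.is_case, cohort.carrier
            )
        if fisher_exact(table, fisher_side) <= spec.alpha:
            rejected += 1
    return rejected / replicates
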