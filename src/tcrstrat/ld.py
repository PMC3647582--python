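"""Power attenuation from imperfect tag-SNP linkage disequilibrium.

An indirect association test typed at a tag SNP with correlation r^2 to
the causal variant behaves like a direct test on an effectively smaller
sample: n_eff = r^2 * n.  The module applies that mapping to the exact
power engine and summarises empirical r^2 coverage lists (mean, fraction
above a threshold) as supplied by the user — it does not compute r^2
from genotypes or query any external LD resource.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .power import PowerSpec, fisher_power_exact

__all__ = ["CoverageSet", "attenuated_power", "coverage_summary", "read_r2_tsv"]


@dataclass
class CoverageSet:
    """A list of tag-SNP r^2 values with a free-text label."""

    r2_values: list[float] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        for value in self.r2_values:
            if not (isinstance(value, (int, float)) and 0 <= value <= 1) or math.isnan(value):
                raise ValidationError(f"r2 value out of [0,1]: {value!r}")


def attenuated_power(
    r2: float, spec: PowerSpec, p0: float, p1: float, mode: str = "carrier"
) -> float:
    """Exact Fisher power at LD-reduced effective sample sizes.

    Effective counts are floor(r2 * n), floored at 1 subject per arm;
    r2 = 0 carries no information and returns alpha by convention.
    """
    if not 0 <= r2 <= 1:
        raise ValidationError(f"r2 must be in [0,1], got {r2}")
    if r2 == 0:
        return spec.alpha
    eff = PowerSpec(
        n_cases=max(1, math.floor(r2 * spec.n_cases)),
        n_controls=max(1, math.floor(r2 * spec.n_controls)),
        alpha=spec.alpha,
        sidedness=spec.sidedness,
        tail_mass_tolerance=spec.tail_mass_tolerance,
    )
    return fisher_power_exact(eff, p0, p1, mode=mode)


def coverage_summary(coverage: CoverageSet, threshold: float) -> dict:
    """Mean r^2, fraction at or above ``threshold``, and count.

    Missing values must be filtered out upstream; they are never imputed.
    """
    if not coverage.r2_values:
        raise ValidationError("coverage set is empty")
    if not 0 <= threshold <= 1:
        raise ValidationError(f"threshold must be in [0,1], got {threshold}")
    values = coverage.r2_values
    return {
        "label": coverage.label,
        "mean_r2": sum(values) / len(values),
        "fraction_at_or_above": sum(v >= threshold for v in values) / len(values),
        "threshold": threshold,
        "n": len(values),
    }


def read_r2_tsv(source, label: str = "") -> CoverageSet:
    """Read a coverage table (columns snp_id, r2); drops rows with missing r2."""
    frame = pd.read_csv(source, sep="\t")
    if "r2" not in frame.columns:
        raise ValidationError("r2 column missing from coverage TSV")
    values = frame["r2"].dropna().astype(float).tolist()
    return CoverageSet(values, label=label)


def summary_to_json(summary: dict) -> str:
    return json.dumps(summary, indent=2)
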