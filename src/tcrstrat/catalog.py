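"""Catalog of germline TRAV/TRBV interface polymorphisms.

Nonsynonymous variants in the germline-encoded, pMHC-facing regions of
human TCR variable genes — the N-terminus, CDR1, CDR2 (extended one
residue N-terminally to cover an additional contact position) and HV4 —
are the candidate "risk TCR alleles" whose detectability the rest of the
package analyses.  A transcription of the compiled catalog ships as a
packaged TSV fixture; positions use IMGT residue numbering.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import pandas as pd

from .errors import CatalogFormatError, ValidationError

__all__ = [
    "PolymorphismRecord",
    "load_catalog",
    "default_catalog",
    "count_distinct_positions",
    "count_distinct_genes",
    "region_breakdown",
]

logger = logging.getLogger(__name__)

CHAINS = ("alpha", "beta")
REGIONS = ("N-term", "CDR1", "CDR2", "HV4")
PROVENANCES = ("reference-catalog", "supplementary-literature")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
COLUMNS = ["chain", "region", "position", "substitution", "genes", "provenance"]

FIXTURE_NAME = "table2_polymorphisms.tsv"


@dataclass(frozen=True)
class PolymorphismRecord:
    """One nonsynonymous germline variant at a pMHC-interface position.

    ``substitution`` is "X/Y" (from-residue/to-residue, one-letter codes);
    ``genes`` lists every gene the source row names for the variant.
    """

    chain: str
    region: str
    position: int
    substitution: str
    genes: tuple[str, ...]
    provenance: str = "reference-catalog"

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValidationError(f"chain must be one of {CHAINS}, got {self.chain!r}")
        if self.region not in REGIONS:
            raise ValidationError(f"region must be one of {REGIONS}, got {self.region!r}")
        if not isinstance(self.position, int) or self.position < 1:
            raise ValidationError(f"position must be a positive integer, got {self.position!r}")
        parts = self.substitution.split("/")
        if len(parts) != 2 or any(p not in AMINO_ACIDS for p in parts):
            raise ValidationError(
                f"substitution must be 'X/Y' with one-letter amino-acid codes, "
                f"got {self.substitution!r}"
            )
        if not self.genes:
            raise ValidationError("record must list at least one gene")
        object.__setattr__(self, "genes", tuple(self.genes))
        if self.provenance not in PROVENANCES:
            raise ValidationError(
                f"provenance must be one of {PROVENANCES}, got {self.provenance!r}"
            )


def _parse_row(row, line_no: int) -> PolymorphismRecord:
    try:
        position = int(row["position"])
    except (TypeError, ValueError):
        raise ValidationError(f"line {line_no}: non-integer position {row['position']!r}")
    genes = tuple(g.strip() for g in str(row["genes"]).split(";") if g.strip())
    try:
        return PolymorphismRecord(
            chain=str(row["chain"]).strip(),
            region=str(row["region"]).strip(),
            position=position,
            substitution=str(row["substitution"]).strip(),
            genes=genes,
            provenance=str(row["provenance"]).strip(),
        )
    except ValidationError as exc:
        raise ValidationError(f"line {line_no}: {exc}") from exc


def load_catalog(source, lenient: bool = False) -> list[PolymorphismRecord]:
    """Read polymorphism records from a TSV stream.

    Header: chain, region, position, substitution, genes (semicolon-
    separated), provenance.  In strict mode (default) any malformed row
    aborts the load with a :class:`CatalogFormatError` naming the
    offending line numbers; with ``lenient=True`` bad rows are skipped
    with a warning.  An empty file yields an empty list with a warning.
    """
    frame = pd.read_csv(source, sep="\t", dtype=str)
    missing = [col for col in COLUMNS if col not in frame.columns]
    if missing:
        raise CatalogFormatError(f"missing catalog columns: {missing}", lines=[])
    if frame.empty:
        warnings.warn("catalog stream contains no records", stacklevel=2)
        return []
    records: list[PolymorphismRecord] = []
    bad: list[tuple[int, str]] = []
    for idx, row in frame.iterrows():
        line_no = idx + 2  # 1-based, after the header line
        try:
            records.append(_parse_row(row, line_no))
        except ValidationError as exc:
            bad.append((line_no, str(exc)))
    if bad:
        if not lenient:
            detail = "; ".join(msg for _, msg in bad)
            raise CatalogFormatError(
                f"malformed catalog rows: {detail}", lines=[ln for ln, _ in bad]
            )
        for line_no, msg in bad:
            logger.warning("skipping malformed catalog row: %s", msg)
    return records


def default_catalog() -> list[PolymorphismRecord]:
    """Load the packaged interface-polymorphism fixture."""
    ref = resources.files("tcrstrat.data").joinpath(FIXTURE_NAME)
    with ref.open("r") as handle:
        return load_catalog(handle)


def count_distinct_positions(records: Iterable[PolymorphismRecord]) -> int:
    """Number of distinct (chain, region, IMGT position) triples."""
    return len({(r.chain, r.region, r.position) for r in records})


def count_distinct_genes(records: Iterable[PolymorphismRecord]) -> int:
    """Number of distinct gene names across all records."""
    return len({gene for r in records for gene in r.genes})


def region_breakdown(records: Iterable[PolymorphismRecord]) -> dict:
    """Per-(chain, region) distinct-position counts plus the global totals."""
    records = list(records)
    by_region: dict[str, set] = {}
    for r in records:
        by_region.setdefault(f"{r.region}-{r.chain}", set()).add((r.chain, r.region, r.position))
    return {
        "positions": count_distinct_positions(records),
        "genes": count_distinct_genes(records),
        "records": len(records),
        "positions_by_region": {k: len(v) for k, v in sorted(by_region.items())},
    }


def breakdown_to_json(records: Iterable[PolymorphismRecord]) -> str:
    return json.dumps(region_breakdown(records), indent=2)
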