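"""TFClass-style family harmonization.

Transcription factors are grouped by shared DNA-binding domain into a
three-level hierarchy encoded as a dotted barcode ``superclass.class.family``
(e.g. ``1.2.6`` for bHLH-ZIP factors).  Because homologous family members
recognise the same sequence logo, sequence-level evidence cannot tell them
apart; results are therefore aggregated per family by the minimum member
adjusted p-value ("any member's logo detects the family").  Member p-values
are already BH-adjusted within their branch, so no extra family-level
correction is applied.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .enrichment import EnrichmentRecord

logger = logging.getLogger(__name__)

_BARCODE_RE = re.compile(r"^\d+\.\d+\.\d+$")
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class FamilyEntry:
    barcode: str
    family_name: str
    members: frozenset[str]


class TFClassTable:
    """Barcode -> family-name -> member-symbol table.

    Every TF symbol must belong to exactly one family and every family must
    have at least one member; violations are rejected at load time.
    """

    def __init__(self, entries: Iterable[FamilyEntry]):
        self.entries = sorted(entries, key=lambda e: tuple(map(int, e.barcode.split("."))))
        self._member_to_barcode: dict[str, str] = {}
        seen_barcodes: set[str] = set()
        for e in self.entries:
            if not _BARCODE_RE.match(e.barcode):
                raise ValueError(
                    f"barcode {e.barcode!r} must be three dot-separated integers"
                )
            if e.barcode in seen_barcodes:
                raise ValueError(f"duplicate family barcode {e.barcode!r}")
            seen_barcodes.add(e.barcode)
            if not e.members:
                raise ValueError(f"family {e.barcode} has no members")
            for m in e.members:
                if m in self._member_to_barcode:
                    raise ValueError(
                        f"TF {m!r} belongs to two families "
                        f"({self._member_to_barcode[m]} and {e.barcode})"
                    )
                self._member_to_barcode[m] = e.barcode
        self._names = {e.barcode: e.family_name for e in self.entries}

    @property
    def barcodes(self) -> list[str]:
        return [e.barcode for e in self.entries]

    @property
    def n_members(self) -> int:
        return len(self._member_to_barcode)

    def family_name(self, barcode: str) -> str:
        return self._names[barcode]

    def members(self, barcode: str) -> frozenset[str]:
        for e in self.entries:
            if e.barcode == barcode:
                return e.members
        raise KeyError(barcode)


def map_to_family(unit: str, table: TFClassTable) -> str:
    """Barcode of the family containing ``unit``, or ``"unmapped"``."""
    barcode = table._member_to_barcode.get(unit)
    if barcode is None:
        logger.info("symbol %r not present in the TFClass table", unit)
        return UNMAPPED
    return barcode


@dataclass(frozen=True)
class FamilyResult:
    barcode: str
    family_name: str
    branch: str
    best_adj_p: float
    n_members_tested: int
    n_members_significant: int
    significant: bool


def aggregate_family(
    records: Sequence[EnrichmentRecord],
    table: TFClassTable,
    alpha: float = 0.05,
) -> list[FamilyResult]:
    """Aggregate one branch's BH-adjusted records to family resolution.

    The family statistic is the minimum member adjusted p; a family is
    significant iff any member is.  Records whose unit is not in the table
    are skipped with a logged note.  Output order follows the table.
    """
    branches = {r.branch for r in records}
    if len(branches) > 1:
        raise ValueError(f"records span multiple branches: {sorted(branches)}")
    if any(r.adj_pvalue is None for r in records):
        raise ValueError("records must be BH-adjusted before family aggregation")
    per_family: dict[str, list[EnrichmentRecord]] = {}
    for r in records:
        barcode = map_to_family(r.unit, table)
        if barcode == UNMAPPED:
            continue
        per_family.setdefault(barcode, []).append(r)
    branch = branches.pop() if branches else ""
    out = []
    for barcode in table.barcodes:
        recs = per_family.get(barcode)
        if not recs:
            continue
        best = min(r.adj_pvalue for r in recs)
        n_sig = sum(r.adj_pvalue < alpha for r in recs)
        out.append(
            FamilyResult(
                barcode=barcode,
                family_name=table.family_name(barcode),
                branch=branch,
                best_adj_p=float(best),
                n_members_tested=len(recs),
                n_members_significant=n_sig,
                significant=best < alpha,
            )
        )
    return out


def family_size_report(table: TFClassTable) -> pd.DataFrame:
    """Member counts per family and fractions of all classified TFs."""
    total = table.n_members
    rows = [
        {
            "barcode": e.barcode,
            "family_name": e.family_name,
            "n_members": len(e.members),
            "fraction": len(e.members) / total,
        }
        for e in table.entries
    ]
    return pd.DataFrame(rows, columns=["barcode", "family_name", "n_members", "fraction"])
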