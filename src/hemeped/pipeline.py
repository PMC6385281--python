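"""End-to-end analysis over a pedigree: links -> Ps -> four-group table.

Thin orchestration shared by the CLI, the examples and the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from hemeped.pedigree import MALE, Pedigree
from hemeped.segregation import (
    ProbandRecord,
    PsRecord,
    build_proband_records,
    standardize,
)
from hemeped.fourgroup import (
    FourGroupTable,
    PairCensus,
    build_four_group_table,
    pair_census,
)


@dataclass
class FourGroupAnalysis:
    records: list[ProbandRecord]
    ps_records: list[PsRecord]
    table: FourGroupTable
    census: dict[str, PairCensus]

    @property
    def pattern(self) -> str:
        return self.table.pattern

    @property
    def n_probands(self) -> int:
        return len(self.records)


def analyze_four_group(
    ped: Pedigree,
    max_intermediates: int = 5,
    include_descendants: bool = True,
    yates: bool = False,
    parity: int = 0,
) -> FourGroupAnalysis:
    """Full proband -> Ps -> four-group pipeline for one pedigree."""
    records = build_proband_records(
        ped,
        max_intermediates=max_intermediates,
        include_descendants=include_descendants,
    )
    ps = standardize(records, parity=parity)
    table = build_four_group_table(ps, ped, yates=yates)
    links = [l for r in records for l in r.links]
    return FourGroupAnalysis(
        records=records,
        ps_records=ps,
        table=table,
        census=pair_census(links),
    )


def links_frame(records: list[ProbandRecord]) -> pd.DataFrame:
    """The proband-AR link table as a DataFrame (one row per registration)."""
    rows = [
        {
            "proband": l.proband_id,
            "relative": l.relative_id,
            "line": l.line,
            "intermediates": l.intermediates,
            "relationship": l.relationship,
            "ambiguous": l.ambiguous,
        }
        for r in records
        for l in r.links
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "proband", "relative", "line", "intermediates",
            "relationship", "ambiguous",
        ],
    )


def ps_frame(ps: list[PsRecord]) -> pd.DataFrame:
    rows = [
        {
            "proband": r.derived_from,
            "sex": "m" if r.sex == MALE else "f",
            "line": r.line,
            "diagnosis": r.diagnosis or "",
            "n_links": len(r.links),
        }
        for r in ps
    ]
    return pd.DataFrame(rows, columns=["proband", "sex", "line", "diagnosis", "n_links"])
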