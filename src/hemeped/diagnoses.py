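"""ICD-10 diagnosis grouping for malignant blood disorders.

Every diagnosis code used in the familial cohorts maps to exactly one of the
two disease groups — LPD (lymphoproliferative disorders, C81-C91/D47.2) or
MPD (myeloproliferative disorders, C92/D45-D47) — or to OTHER for the
residual malignancies (C95.9, C96.1).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

LPD = "LPD"
MPD = "MPD"
OTHER_GROUP = "OTHER"

#: united non-Hodgkin lymphoma, ICD-10 C82-C85
NHL_ABBREVS = frozenset({"FL", "MCL", "DLBCL", "TNHL", "MONOC", "NHL NOS"})
HL_ABBREV = "HL"


@dataclass(frozen=True)
class DiagnosisRow:
    icd10: str
    label: str
    abbrev: str
    group: str


class DiagnosisMap:
    """Mapping icd10 code -> (label, abbreviation, LPD/MPD/OTHER group)."""

    def __init__(self, rows: list[DiagnosisRow]):
        self._by_code: dict[str, DiagnosisRow] = {}
        self._by_abbrev: dict[str, DiagnosisRow] = {}
        for r in rows:
            if r.icd10 in self._by_code:
                raise ValueError(f"code {r.icd10!r} mapped twice")
            if r.group not in (LPD, MPD, OTHER_GROUP):
                raise ValueError(f"unknown group {r.group!r} for {r.icd10!r}")
            self._by_code[r.icd10] = r
            self._by_abbrev.setdefault(r.abbrev, r)
        self.rows = list(rows)

    def group_of(self, icd10: str) -> str:
        return self.lookup(icd10).group

    def abbrev_of(self, icd10: str) -> str:
        return self.lookup(icd10).abbrev

    def lookup(self, icd10: str) -> DiagnosisRow:
        """Match a code, falling back to its 3-character category (C83.1 -> C83)."""
        r = self._by_code.get(icd10)
        if r is None and "." in icd10:
            r = self._by_code.get(icd10.split(".", 1)[0])
        if r is None:
            raise KeyError(f"ICD-10 code {icd10!r} is not in the diagnosis map")
        return r

    def by_abbrev(self, abbrev: str) -> DiagnosisRow:
        return self._by_abbrev[abbrev]

    def abbrevs(self, group: str | None = None) -> list[str]:
        return [r.abbrev for r in self.rows if group is None or r.group == group]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiagnosisMap":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            rows = [
                DiagnosisRow(
                    r["icd10"].strip(),
                    r["label"].strip(),
                    r["abbrev"].strip(),
                    r["group"].strip(),
                )
                for r in reader
            ]
        return cls(rows)


def load_default_diagnosis_map() -> DiagnosisMap:
    """The bundled MBD diagnosis table (all C81-C96 / D45-D47 cohort codes)."""
    with resources.as_file(
        resources.files("hemeped.data").joinpath("diagnosis_groups.tsv")
    ) as p:
        return DiagnosisMap.from_tsv(p)
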