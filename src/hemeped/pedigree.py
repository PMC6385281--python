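"""Pedigree data model, PED-dialect I/O and kinship-path primitives.

The on-disk dialect is the 6-column LINKAGE/PED layout
``FID IID PAT MAT SEX PHENO`` (tab-separated; founder parents coded ``0``;
sex 1 = male / 2 = female; phenotype 1 = unaffected / 2 = affected /
0 = unknown), with diagnoses, birth years and onset years in a companion
phenotype TSV keyed by individual id.

A *kinship path* between two individuals runs up through ancestors and may
descend at most once (a single apex): parent-offspring, grandparent,
sibling, uncle/aunt, cousin and the longer oblique connections all have this
shape, while zig-zag paths through marriages do not and are excluded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

MALE = "male"
FEMALE = "female"

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

_SEX_CODES = {"1": MALE, "2": FEMALE}
_PHENO_CODES = {"1": UNAFFECTED, "2": AFFECTED, "0": UNKNOWN}


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class MalformedLineError(PedigreeError):
    """A PED or phenotype line does not parse under the dialect."""


class DuplicateIdError(PedigreeError):
    """The same individual id occurs twice."""


class MissingParentError(PedigreeError):
    """A referenced parent id is absent and not the founder marker '0'."""


class SexInconsistentParentError(PedigreeError):
    """A father is not male, or a mother is not female."""


class CycleError(PedigreeError):
    """The child-parent links contain a directed cycle."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member with phenotype annotations.

    ``affected`` is one of ``affected``/``unaffected``/``unknown``;
    ``diagnosis`` holds an ICD-10 code (e.g. ``C91.1``) once phenotypes are
    attached.
    """

    id: str
    family_id: str = "0"
    sex: str = MALE
    father_id: str | None = None
    mother_id: str | None = None
    affected: str = UNKNOWN
    diagnosis: str | None = None
    birth_year: int | None = None
    onset_year: int | None = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """An acyclic two-parent kinship graph over :class:`Individual`."""

    def __init__(self, individuals: Iterable[Individual]):
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._members:
                raise DuplicateIdError(f"duplicate individual id {ind.id!r}")
            self._members[ind.id] = ind
        self._children: dict[str, list[str]] = {i: [] for i in self._members}
        self._validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        return self._members[iid]

    @property
    def ids(self) -> list[str]:
        return sorted(self._members)

    def parents(self, iid: str) -> list[str]:
        ind = self._members[iid]
        return [p for p in (ind.father_id, ind.mother_id) if p is not None]

    def children(self, iid: str) -> list[str]:
        return list(self._children[iid])

    def affected_ids(self) -> list[str]:
        return sorted(i.id for i in self if i.affected == AFFECTED)

    def with_phenotypes(self, rows: dict[str, dict]) -> "Pedigree":
        """Return a copy with diagnosis/birth/onset columns attached."""
        out = []
        for ind in self:
            r = rows.get(ind.id)
            if r is None:
                out.append(ind)
            else:
                out.append(
                    replace(
                        ind,
                        diagnosis=r.get("icd10") or ind.diagnosis,
                        birth_year=r.get("birth_year", ind.birth_year),
                        onset_year=r.get("onset_year", ind.onset_year),
                    )
                )
        return Pedigree(out)

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        for ind in self._members.values():
            for pid, role, want in (
                (ind.father_id, "father", MALE),
                (ind.mother_id, "mother", FEMALE),
            ):
                if pid is None:
                    continue
                parent = self._members.get(pid)
                if parent is None:
                    raise MissingParentError(
                        f"{role} {pid!r} of {ind.id!r} is not in the pedigree"
                    )
                if parent.sex != want:
                    raise SexInconsistentParentError(
                        f"{role} {pid!r} of {ind.id!r} is coded {parent.sex}"
                    )
                self._children[pid].append(ind.id)
        for pid in self._children:
            self._children[pid].sort()
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # iterative three-color DFS on child -> parent edges
        WHITE, GREY, BLACK = 0, 1, 2
        color = {i: WHITE for i in self._members}
        for start in self._members:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            while stack:
                node, pi = stack[-1]
                if pi == 0:
                    color[node] = GREY
                parents = self.parents(node)
                if pi < len(parents):
                    stack[-1] = (node, pi + 1)
                    nxt = parents[pi]
                    if color[nxt] == GREY:
                        raise CycleError(
                            f"ancestry cycle through {nxt!r}"
                        )
                    if color[nxt] == WHITE:
                        stack.append((nxt, 0))
                else:
                    color[node] = BLACK
                    stack.pop()


# ---------------------------------------------------------------------------
# kinship paths


@dataclass(frozen=True)
class KinshipPath:
    """A simple up-then-down genealogical connection.

    ``vertices`` runs from one endpoint to the other; ``ups`` child->parent
    steps are followed by ``downs`` parent->child steps, so the apex (most
    ancestral vertex) is ``vertices[ups]``.
    """

    vertices: tuple[str, ...]
    ups: int
    downs: int

    @property
    def length(self) -> int:
        return len(self.vertices) - 1

    @property
    def apex(self) -> str:
        return self.vertices[self.ups]

    @property
    def interior(self) -> tuple[str, ...]:
        return self.vertices[1:-1]

    def unaffected_intermediates(self, ped: Pedigree) -> int:
        return sum(1 for v in self.interior if ped[v].affected != AFFECTED)


def connecting_paths(
    ped: Pedigree, a: str, b: str, max_len: int
) -> list[KinshipPath]:
    """All simple kinship paths between ``a`` and ``b`` of length <= max_len.

    Every path ascends from ``a`` through ancestors and descends at most once
    toward ``b``; multiple distinct connections (as arise under inbreeding)
    are all returned, sorted by (length, vertex sequence).
    """
    if a == b:
        raise ValueError("endpoints must differ")
    if a not in ped or b not in ped:
        raise KeyError("both endpoints must be in the pedigree")
    found: list[KinshipPath] = []

    def descend(path: list[str], ups: int) -> None:
        node = path[-1]
        if node == b:
            found.append(
                KinshipPath(tuple(path), ups, len(path) - 1 - ups)
            )
            return
        if len(path) - 1 >= max_len:
            return
        for c in ped.children(node):
            if c not in path:
                path.append(c)
                descend(path, ups)
                path.pop()

    def ascend(path: list[str]) -> None:
        node = path[-1]
        ups = len(path) - 1
        # switch to the descending phase here (including ups == 0 for
        # pure-descendant connections)
        descend(path, ups)
        if ups >= max_len:
            return
        for p in ped.parents(node):
            if p not in path:
                path.append(p)
                ascend(path)
                path.pop()

    # descend() is also called with the start vertex itself as apex, which
    # would record a zero-length path; guard by requiring b != a (checked).
    ascend([a])
    # ascend(...) -> descend at every prefix; a path that is purely ascending
    # is recorded when descend() sees node == b at the apex itself.
    uniq = {p.vertices: p for p in found}
    return sorted(uniq.values(), key=lambda p: (p.length, p.vertices))


PARENT_OFFSPRING = "parent-offspring"
SIBLING = "sibling"
GRANDPARENT_LINE = "grandparent-line"
UNCLE_AUNT = "uncle-aunt"
COUSIN = "cousin"
OTHER = "other"


def relationship_label(path: KinshipPath) -> str:
    """Deterministic relationship label from the (ups, downs) path shape."""
    u, d = path.ups, path.downs
    if u + d != path.length or u < 0 or d < 0 or path.length < 1:
        raise ValueError("malformed kinship path")
    if u + d == 1:
        return PARENT_OFFSPRING
    if min(u, d) == 0:
        return GRANDPARENT_LINE
    if u == 1 and d == 1:
        return SIBLING
    if {u, d} == {1, 2}:
        return UNCLE_AUNT
    if u == 2 and d == 2:
        return COUSIN
    return OTHER


# ---------------------------------------------------------------------------
# file I/O


def _parse_year(tok: str) -> int | None:
    if tok in ("", ".", "0", "NA", "na", "None"):
        return None
    try:
        return int(tok)
    except ValueError as e:
        raise MalformedLineError(f"bad year field {tok!r}") from e


def read_phenotypes(phenotype_path: str | Path) -> dict[str, dict]:
    """Read the companion phenotype TSV (header: iid icd10 birth_year onset_year)."""
    rows: dict[str, dict] = {}
    with open(phenotype_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        need = {"iid", "icd10"}
        if reader.fieldnames is None or not need.issubset(reader.fieldnames):
            raise MalformedLineError(
                f"phenotype file {phenotype_path} lacks the iid/icd10 header"
            )
        for r in reader:
            iid = r["iid"]
            if iid in rows:
                raise DuplicateIdError(f"duplicate phenotype row for {iid!r}")
            rows[iid] = {
                "icd10": (r.get("icd10") or "").strip() or None,
                "birth_year": _parse_year((r.get("birth_year") or "").strip()),
                "onset_year": _parse_year((r.get("onset_year") or "").strip()),
            }
    return rows


def read_pedigree(
    ped_path: str | Path, phenotype_path: str | Path | None = None
) -> Pedigree:
    """Read and validate a PED file, optionally attaching phenotypes.

    Raises :class:`MalformedLineError`, :class:`DuplicateIdError`,
    :class:`MissingParentError`, :class:`SexInconsistentParentError` or
    :class:`CycleError` on the corresponding defect.
    """
    inds: list[Individual] = []
    with open(ped_path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split("\t") if "\t" in line else line.split()
            if len(toks) != 6:
                raise MalformedLineError(
                    f"{ped_path}:{ln}: expected 6 columns, got {len(toks)}"
                )
            fid, iid, pat, mat, sex, pheno = toks
            if sex not in _SEX_CODES:
                raise MalformedLineError(
                    f"{ped_path}:{ln}: bad sex code {sex!r}"
                )
            if pheno not in _PHENO_CODES:
                raise MalformedLineError(
                    f"{ped_path}:{ln}: bad phenotype code {pheno!r}"
                )
            inds.append(
                Individual(
                    id=iid,
                    family_id=fid,
                    sex=_SEX_CODES[sex],
                    father_id=None if pat == "0" else pat,
                    mother_id=None if mat == "0" else mat,
                    affected=_PHENO_CODES[pheno],
                )
            )
    ped = Pedigree(inds)
    if phenotype_path is not None:
        ped = ped.with_phenotypes(read_phenotypes(phenotype_path))
    return ped


def write_pedigree(
    ped: Pedigree,
    ped_path: str | Path,
    phenotype_path: str | Path | None = None,
) -> None:
    """Write the PED file (and optionally the phenotype TSV) back to disk."""
    sex_out = {MALE: "1", FEMALE: "2"}
    ph_out = {UNAFFECTED: "1", AFFECTED: "2", UNKNOWN: "0"}
    with open(ped_path, "w") as fh:
        for iid in ped.ids:
            ind = ped[iid]
            fh.write(
                "\t".join(
                    [
                        ind.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        sex_out[ind.sex],
                        ph_out[ind.affected],
                    ]
                )
                + "\n"
            )
    if phenotype_path is not None:
        with open(phenotype_path, "w") as fh:
            fh.write("iid\ticd10\tbirth_year\tonset_year\n")
            for iid in ped.ids:
                ind = ped[iid]
                fh.write(
                    "\t".join(
                        [
                            ind.id,
                            ind.diagnosis or "",
                            "" if ind.birth_year is None else str(ind.birth_year),
                            "" if ind.onset_year is None else str(ind.onset_year),
                        ]
                    )
                    + "\n"
                )
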