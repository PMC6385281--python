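"""Affected-relative enumeration, parental-line affiliation and the
crude-to-standard proband conversion.

Every affected patient acts as a *crude proband* (Pc).  Its affected
relatives (AR) are the affected individuals reachable by a kinship path with
at most ``max_intermediates`` *unaffected* interior individuals (affected
interiors do not consume the budget).  Each AR is registered once per
proband, on the line of its closest qualifying path: patrilineal (PA) when
the first step out of the proband is to the father, matrilineal (MA) via the
mother.  Relatives whose closest PA and MA connections tie (full siblings
and other two-apex-symmetric kin) are line-ambiguous; pure descendants have
no parental line at all.

Probands are then allocated to affiliation groups — PA+MA (unambiguous AR in
both lines), PA, MA, PA=MA (only mixed/ambiguous AR) or none-visible (no AR
in the ancestral direction) — and converted to *standard probands* (Ps),
each carrying a single parental line: PA+MA probands yield two Ps, single
line probands one, PA=MA probands one on the line that brings the majority
of their AR closest, and none-visible probands are split equally between the
lines (deterministically, alternating over sorted proband ids).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from hemeped.pedigree import (
    AFFECTED,
    Pedigree,
    KinshipPath,
    relationship_label,
)

PA = "PA"
MA = "MA"
OWN = "OWN"  # pure-descendant connection: no parental line

PA_MA = "PA+MA"
PA_EQ_MA = "PA=MA"
NONE_VISIBLE = "none-visible"


class NotAffectedError(ValueError):
    """The designated proband is not an affected individual."""


@dataclass(frozen=True)
class AffectedRelativeLink:
    """One proband-AR registration (each AR appears once per proband)."""

    proband_id: str
    relative_id: str
    line: str  # PA, MA or OWN (descendant), ties resolved toward PA
    intermediates: int  # unaffected interiors on the chosen path
    relationship: str
    ambiguous: bool = False  # equally close paths in more than one line
    pa_intermediates: int | None = None  # best per-line distances, if any
    ma_intermediates: int | None = None


@dataclass(frozen=True)
class ProbandRecord:
    """A crude proband (Pc) with its registered AR and affiliation group."""

    proband_id: str
    sex: str
    diagnosis: str | None
    links: tuple[AffectedRelativeLink, ...]
    affiliation: str | None = None


@dataclass(frozen=True)
class PsRecord:
    """A standard proband: one parental line, carrying the AR it counts.

    ``links`` holds exactly the AR registrations tallied under this Ps's
    line: every AR of the crude proband appears in exactly one of its Ps
    records, so the four-group table conserves the total AR count.
    """

    derived_from: str
    sex: str
    diagnosis: str | None
    line: str
    links: tuple[AffectedRelativeLink, ...]


# ---------------------------------------------------------------------------
# AR enumeration


def _qualifying_paths(
    ped: Pedigree,
    proband: str,
    max_intermediates: int,
    include_descendants: bool,
) -> dict[str, list[KinshipPath]]:
    """All up-then-down simple paths from the proband to affected relatives
    whose unaffected interior count is within budget.

    Interior individuals that are themselves affected are free: the budget
    only counts healthy intermediates, so chains of patients extend the
    reach of the search.
    """
    out: dict[str, list[KinshipPath]] = {}

    def record(path: list[str], ups: int) -> None:
        node = path[-1]
        if ped[node].affected == AFFECTED:
            kp = KinshipPath(tuple(path), ups, len(path) - 1 - ups)
            out.setdefault(node, []).append(kp)

    def budget_left(budget: int, node: str) -> int:
        # stepping *through* node makes it interior
        return budget - (0 if ped[node].affected == AFFECTED else 1)

    def descend(path: list[str], ups: int, budget: int) -> None:
        node = path[-1]
        for c in ped.children(node):
            if c in path:
                continue
            path.append(c)
            record(path, ups)
            b = budget_left(budget, c)
            if b >= 0:
                descend(path, ups, b)
            path.pop()

    def ascend(path: list[str], budget: int) -> None:
        node = path[-1]
        ups = len(path) - 1
        if ups > 0 or include_descendants:
            descend(path, ups, budget)
        for p in ped.parents(node):
            if p in path:
                continue
            path.append(p)
            record(path, ups + 1)
            b = budget_left(budget, p)
            if b >= 0:
                ascend(path, b)
            path.pop()

    ascend([proband], max_intermediates)
    # deduplicate identical vertex sequences found through different phases
    for rid, paths in out.items():
        out[rid] = sorted(
            {p.vertices: p for p in paths}.values(),
            key=lambda p: (p.length, p.vertices),
        )
    return out


def _line_of(path: KinshipPath, ped: Pedigree) -> str:
    proband = path.vertices[0]
    if path.ups == 0:
        return OWN
    first = path.vertices[1]
    ind = ped[proband]
    if first == ind.father_id:
        return PA
    if first == ind.mother_id:
        return MA
    raise ValueError("first ascending step is not to a parent")


_LINE_PREFERENCE = {PA: 0, MA: 1, OWN: 2}


def enumerate_ar(
    ped: Pedigree,
    proband: str,
    max_intermediates: int = 5,
    include_descendants: bool = True,
) -> list[AffectedRelativeLink]:
    """Register each affected relative of a proband once, on its closest line.

    Closeness is (unaffected intermediates, path length); when the best PA
    and MA connections tie, the link is marked ambiguous and reported under
    PA.  ``include_descendants=False`` restricts the search to the ancestral
    and oblique directions only.
    """
    if proband not in ped:
        raise KeyError(f"proband {proband!r} not in pedigree")
    if ped[proband].affected != AFFECTED:
        raise NotAffectedError(f"proband {proband!r} is not affected")
    links = []
    for rid, paths in sorted(
        _qualifying_paths(ped, proband, max_intermediates, include_descendants).items()
    ):
        per_line: dict[str, tuple[int, int, KinshipPath]] = {}
        for p in paths:
            metric = (p.unaffected_intermediates(ped), p.length)
            line = _line_of(p, ped)
            if line not in per_line or metric < per_line[line][:2]:
                per_line[line] = (*metric, p)
        best = min(v[:2] for v in per_line.values())
        tied = sorted(
            (line for line, v in per_line.items() if v[:2] == best),
            key=_LINE_PREFERENCE.__getitem__,
        )
        chosen_line = tied[0]
        chosen = per_line[chosen_line][2]
        links.append(
            AffectedRelativeLink(
                proband_id=proband,
                relative_id=rid,
                line=chosen_line,
                intermediates=best[0],
                relationship=relationship_label(chosen),
                ambiguous=len(tied) > 1 or chosen_line == OWN,
                pa_intermediates=per_line[PA][0] if PA in per_line else None,
                ma_intermediates=per_line[MA][0] if MA in per_line else None,
            )
        )
    return links


# ---------------------------------------------------------------------------
# affiliation and standardization


def classify_affiliation(rec: ProbandRecord) -> str:
    """Allocate a proband to PA+MA / PA / MA / PA=MA / none-visible."""
    definite = {l.line for l in rec.links if not l.ambiguous and l.line in (PA, MA)}
    if definite == {PA, MA}:
        return PA_MA
    if definite == {PA}:
        return PA
    if definite == {MA}:
        return MA
    if any(l.line in (PA, MA) for l in rec.links):
        return PA_EQ_MA  # only mixed/ambiguous connections
    return NONE_VISIBLE  # no AR in the ancestral direction


def build_proband_records(
    ped: Pedigree,
    max_intermediates: int = 5,
    include_descendants: bool = True,
) -> list[ProbandRecord]:
    """Pc records (links + affiliation) for every affected individual."""
    records = []
    for pid in ped.affected_ids():
        links = tuple(
            enumerate_ar(ped, pid, max_intermediates, include_descendants)
        )
        rec = ProbandRecord(
            proband_id=pid,
            sex=ped[pid].sex,
            diagnosis=ped[pid].diagnosis,
            links=links,
        )
        records.append(replace(rec, affiliation=classify_affiliation(rec)))
    return records


def _majority_line(rec: ProbandRecord) -> str | None:
    """Group-4 allocation: the line bringing the majority of AR closest.

    Majority by per-AR closest-line vote; summed healthy-intermediate
    distance breaks ties; ``None`` signals a full tie (the caller shares
    fully tied probands equally between the lines).
    """
    votes = {PA: 0, MA: 0}
    dist = {PA: 0, MA: 0}
    for l in rec.links:
        pa, ma = l.pa_intermediates, l.ma_intermediates
        if pa is not None and (ma is None or pa < ma):
            votes[PA] += 1
        elif ma is not None and (pa is None or ma < pa):
            votes[MA] += 1
        for line, d in ((PA, pa), (MA, ma)):
            if d is not None:
                dist[line] += d
    if votes[PA] != votes[MA]:
        return PA if votes[PA] > votes[MA] else MA
    if dist[PA] != dist[MA]:
        return PA if dist[PA] < dist[MA] else MA
    return None


def standardize(records: list[ProbandRecord], parity: int = 0) -> list[PsRecord]:
    """Convert crude probands to standard (monoparental) probands.

    PA+MA probands yield one Ps per line, each carrying that line's AR
    (line-ambiguous AR ride with the PA record, the registration tie-break);
    PA / MA probands yield one Ps carrying all their AR; PA=MA probands one
    on their majority line (full ties, like none-visible probands, are
    shared equally between the lines, alternating deterministically over
    sorted proband ids with an odd remainder going to PA).

    ``parity`` offsets the alternating allocations; callers pooling many
    pedigrees into one cohort alternate it between pedigrees so the odd
    remainders do not all fall on the same line.
    """
    out: list[PsRecord] = []
    tied_seen = parity
    none_seen = parity
    amb_seen = parity  # global, so the equal share of line-less AR is exact
    for rec in sorted(records, key=lambda r: r.proband_id):
        aff = rec.affiliation or classify_affiliation(rec)
        if aff == PA_MA:
            # line-definite AR follow their line; line-less AR (siblings,
            # descendants) are shared equally, alternating deterministically
            pa_links, ma_links = [], []
            for l in rec.links:
                if not l.ambiguous and l.line == MA:
                    ma_links.append(l)
                elif not l.ambiguous and l.line == PA:
                    pa_links.append(l)
                else:
                    (pa_links if amb_seen % 2 == 0 else ma_links).append(l)
                    amb_seen += 1
            plan = [(PA, tuple(pa_links)), (MA, tuple(ma_links))]
        elif aff in (PA, MA):
            plan = [(aff, rec.links)]
        elif aff == PA_EQ_MA:
            line = _majority_line(rec)
            if line is None:
                line = PA if tied_seen % 2 == 0 else MA
                tied_seen += 1
            plan = [(line, rec.links)]
        else:  # none-visible: shared equally, PA first
            line = PA if none_seen % 2 == 0 else MA
            none_seen += 1
            plan = [(line, rec.links)]
        for line, links in plan:
            out.append(
                PsRecord(
                    derived_from=rec.proband_id,
                    sex=rec.sex,
                    diagnosis=rec.diagnosis,
                    line=line,
                    links=links,
                )
            )
    return out
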