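"""Shared fixtures: hand-built pedigrees and a brute-force path oracle."""

from __future__ import annotations

import networkx as nx
import pytest

from hemeped.pedigree import (
    AFFECTED,
    FEMALE,
    MALE,
    UNAFFECTED,
    Individual,
    Pedigree,
)


def ind(iid, sex=MALE, father=None, mother=None, affected=False, **kw):
    return Individual(
        id=iid,
        sex=sex,
        father_id=father,
        mother_id=mother,
        affected=AFFECTED if affected else UNAFFECTED,
        **kw,
    )


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        [
            ind("fa", MALE),
            ind("mo", FEMALE),
            ind("kid", MALE, father="fa", mother="mo", affected=True),
        ]
    )


@pytest.fixture
def three_generation() -> Pedigree:
    """Proband with parents, two grandpairs, a paternal uncle and a sister."""
    return Pedigree(
        [
            ind("gf_p", MALE),
            ind("gm_p", FEMALE),
            ind("gf_m", MALE),
            ind("gm_m", FEMALE),
            ind("fa", MALE, father="gf_p", mother="gm_p"),
            ind("uncle", MALE, father="gf_p", mother="gm_p"),
            ind("mo", FEMALE, father="gf_m", mother="gm_m"),
            ind("sis", FEMALE, father="fa", mother="mo"),
            ind("pro", MALE, father="fa", mother="mo", affected=True),
        ]
    )


# ---------------------------------------------------------------------------
# brute-force kinship-path oracle


def oracle_paths(ped: Pedigree, a: str, b: str, max_len: int) -> set[tuple[str, ...]]:
    """All simple up-then-down paths a->b of length <= max_len, by exhaustive
    enumeration over the undirected kinship graph."""
    g = nx.Graph()
    g.add_nodes_from(ped.ids)
    for i in ped:
        for p in ped.parents(i.id):
            g.add_edge(i.id, p)
    out = set()
    if not nx.has_path(g, a, b):
        return out
    for path in nx.all_simple_paths(g, a, b, cutoff=max_len):
        # classify each step as up (child->parent) or down (parent->child);
        # valid genealogical connections never go up again after going down
        went_down = False
        ok = True
        for x, y in zip(path, path[1:]):
            up = y in ped.parents(x)
            down = x in ped.parents(y)
            assert up != down
            if up and went_down:
                ok = False
                break
            if down:
                went_down = True
        if ok:
            out.add(tuple(path))
    return out


def oracle_enumerate_ar(ped: Pedigree, proband: str, max_intermediates: int = 5,
                        include_descendants: bool = True):
    """Literal re-derivation of the AR registration rules, independent of the
    implementation's search: enumerate every qualifying path per affected
    relative and apply the closest-line / tie rules directly."""
    n_aff = sum(1 for i in ped if i.affected == AFFECTED)
    cutoff = max_intermediates + 1 + n_aff  # any longer path must exceed budget
    results = {}
    for r in ped.affected_ids():
        if r == proband:
            continue
        per_line = {}
        for verts in oracle_paths(ped, proband, r, cutoff):
            interior = verts[1:-1]
            healthy = sum(1 for v in interior if ped[v].affected != AFFECTED)
            if healthy > max_intermediates:
                continue
            first = verts[1]
            me = ped[proband]
            if first == me.father_id:
                line = "PA"
            elif first == me.mother_id:
                line = "MA"
            else:
                if not include_descendants:
                    continue
                line = "OWN"
            metric = (healthy, len(verts) - 1)
            if line not in per_line or metric < per_line[line]:
                per_line[line] = metric
        if not per_line:
            continue
        best = min(per_line.values())
        tied = [l for l in ("PA", "MA", "OWN") if per_line.get(l) == best]
        results[r] = {
            "line": tied[0],
            "intermediates": best[0],
            "ambiguous": len(tied) > 1 or tied[0] == "OWN",
        }
    return results
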