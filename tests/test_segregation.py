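"""AR enumeration, parental-line affiliation, Pc -> Ps conversion."""

import pytest

from hemeped.pedigree import FEMALE, MALE, Pedigree
from hemeped.segregation import (
    MA,
    NONE_VISIBLE,
    NotAffectedError,
    PA,
    PA_EQ_MA,
    PA_MA,
    AffectedRelativeLink,
    ProbandRecord,
    build_proband_records,
    classify_affiliation,
    enumerate_ar,
    standardize,
)
from hemeped.simulate import SimulationConfig, simulate

from conftest import ind, oracle_enumerate_ar


@pytest.fixture
def uncle_chain() -> Pedigree:
    """Affected paternal uncle behind a healthy father and grandparents."""
    return Pedigree(
        [
            ind("gf", MALE),
            ind("gm", FEMALE),
            ind("fa", MALE, father="gf", mother="gm"),
            ind("uncle", MALE, father="gf", mother="gm", affected=True),
            ind("mo", FEMALE),
            ind("pro", MALE, father="fa", mother="mo", affected=True),
        ]
    )


def link_map(links):
    return {l.relative_id: l for l in links}


class TestEnumerateAr:
    def test_paternal_uncle_two_healthy_between(self, uncle_chain):
        links = link_map(enumerate_ar(uncle_chain, "pro"))
        assert set(links) == {"uncle"}
        l = links["uncle"]
        assert l.line == PA and l.intermediates == 2 and not l.ambiguous

    def test_relative_beyond_five_healthy_excluded(self):
        # chain of 6 healthy ancestors between proband and affected relative
        people = [ind("top_f", MALE, affected=True), ind("top_m", FEMALE)]
        prev_f, prev_m = "top_f", "top_m"
        for i in range(6):
            people += [
                ind(f"h{i}", MALE, father=prev_f, mother=prev_m),
                ind(f"w{i}", FEMALE),
            ]
            prev_f, prev_m = f"h{i}", f"w{i}"
        people.append(ind("pro", MALE, father=prev_f, mother=prev_m, affected=True))
        ped = Pedigree(people)
        assert enumerate_ar(ped, "pro", max_intermediates=5) == []
        assert link_map(enumerate_ar(ped, "pro", max_intermediates=6))["top_f"].intermediates == 6

    def test_full_sibling_registered_once_ambiguous(self, three_generation):
        ped = Pedigree(
            [i if i.id != "sis" else ind("sis", FEMALE, father="fa", mother="mo", affected=True)
             for i in three_generation]
        )
        links = link_map(enumerate_ar(ped, "pro"))
        assert set(links) == {"sis"}
        assert links["sis"].ambiguous and links["sis"].line == PA
        assert links["sis"].pa_intermediates == links["sis"].ma_intermediates == 1

    def test_affected_intermediates_do_not_consume_budget(self):
        # affected father chains the search upward for free
        ped = Pedigree(
            [
                ind("gf", MALE, affected=True),
                ind("gm", FEMALE),
                ind("fa", MALE, father="gf", mother="gm", affected=True),
                ind("mo", FEMALE),
                ind("pro", MALE, father="fa", mother="mo", affected=True),
            ]
        )
        links = link_map(enumerate_ar(ped, "pro", max_intermediates=0))
        assert set(links) == {"fa", "gf"}
        assert links["gf"].intermediates == 0

    def test_unaffected_proband_rejected(self, three_generation):
        with pytest.raises(NotAffectedError):
            enumerate_ar(three_generation, "sis")

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_literal_rule_oracle(self, seed):
        cfg = SimulationConfig(
            seed=seed, generations=3, founder_couples=2, mean_sibship=2.2,
            founder_carrier_rate=0.5, within_mating_fraction=0.6,
            founder_unit_mean=2.0, immigrant_marriage_fraction=0.4,
        )
        ped = simulate(cfg).pedigree
        if len(ped) > 45:
            pytest.skip("draw larger than the oracle budget")
        for pro in ped.affected_ids():
            got = {
                l.relative_id: {
                    "line": l.line,
                    "intermediates": l.intermediates,
                    "ambiguous": l.ambiguous,
                }
                for l in enumerate_ar(ped, pro)
            }
            assert got == oracle_enumerate_ar(ped, pro)


def mk_link(rel, line, ambiguous=False, inter=1):
    return AffectedRelativeLink(
        proband_id="p", relative_id=rel, line=line, intermediates=inter,
        relationship="uncle-aunt", ambiguous=ambiguous,
        pa_intermediates=inter if line == PA or ambiguous else None,
        ma_intermediates=inter if line == MA or ambiguous else None,
    )


def rec(links, sex=MALE, pid="p"):
    r = ProbandRecord(proband_id=pid, sex=sex, diagnosis="C91.1", links=tuple(links))
    return ProbandRecord(
        proband_id=pid, sex=sex, diagnosis="C91.1", links=tuple(links),
        affiliation=classify_affiliation(r),
    )


class TestAffiliation:
    def test_two_patrilineal_links_give_pa(self):
        assert rec([mk_link("a", PA), mk_link("b", PA)]).affiliation == PA

    def test_links_in_both_lines_give_pa_ma(self):
        assert rec([mk_link("a", PA), mk_link("b", MA)]).affiliation == PA_MA

    def test_all_ambiguous_links_give_pa_eq_ma(self):
        assert rec([mk_link("a", PA, ambiguous=True)]).affiliation == PA_EQ_MA

    def test_no_links_is_none_visible(self):
        assert rec([]).affiliation == NONE_VISIBLE


class TestStandardize:
    def test_both_lines_proband_yields_two_ps(self):
        ps = standardize([rec([mk_link("a", PA), mk_link("b", MA)])])
        assert [p.line for p in ps] == [PA, MA]
        assert [len(p.links) for p in ps] == [1, 1]

    def test_none_visible_split_equally_pa_first(self):
        records = [rec([], pid=f"p{i:02d}") for i in range(22)]
        lines = [p.line for p in standardize(records)]
        assert lines.count(PA) == 11 and lines.count(MA) == 11
        assert lines[0] == PA

    def test_group4_majority_closer_via_mother(self):
        links = [
            AffectedRelativeLink("p", f"r{i}", PA, 3, "uncle-aunt", True,
                                 pa_intermediates=3, ma_intermediates=1)
            for i in range(3)
        ]
        ps = standardize([rec(links)])
        assert [p.line for p in ps] == [MA]
        assert len(ps[0].links) == 3  # a mixed proband carries all its AR

    def test_count_conservation(self):
        records = [
            rec([mk_link("a", PA), mk_link("b", MA)], pid="p1"),       # group 1
            rec([mk_link("a", PA)], pid="p2"),                          # group 2
            rec([mk_link("b", MA)], pid="p3"),                          # group 3
            rec([mk_link("a", PA, ambiguous=True)], pid="p4"),          # group 4
            rec([], pid="p5"),                                          # none-visible
        ]
        ps = standardize(records)
        assert len(ps) == 2 + 1 + 1 + 1 + 1

    def test_every_link_counted_exactly_once(self):
        cfg = SimulationConfig.pattern_preset("PD2", seed=3, founder_couples=20)
        ped = simulate(cfg).pedigree
        records = build_proband_records(ped)
        ps = standardize(records)
        n_links = sum(len(r.links) for r in records)
        n_counted = sum(len(p.links) for p in ps)
        assert n_counted == n_links
        # and no relative appears twice among one proband's links
        for r in records:
            rels = [l.relative_id for l in r.links]
            assert len(rels) == len(set(rels))

    def test_deterministic_under_fixed_input(self):
        cfg = SimulationConfig.pattern_preset("PD2", seed=5, founder_couples=15)
        ped = simulate(cfg).pedigree
        a = standardize(build_proband_records(ped))
        b = standardize(build_proband_records(ped))
        assert a == b
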