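"""Four-group table machinery: ratios, expectations, scores, patterns."""

import pytest

from hemeped.fourgroup import (
    GROUPS,
    PD1,
    PD2,
    PD3,
    PD_OTHER,
    FourGroupTable,
    Score,
    ScoreMatrix,
    ar_pc_ratios,
    classify_pattern,
    expected_counts,
    pair_census,
    score_cell,
)
from hemeped.reference import load_four_group_table
from hemeped.segregation import AffectedRelativeLink


class TestArPcRatios:
    @pytest.mark.parametrize(
        "args,want",
        [
            ((146, 94, 29, 21), (5.0, 3.2, 7.0, 4.5)),
            ((68, 53, 12, 7), (5.7, 4.4, 9.7, 7.6)),
            ((0, 0, 5, 5), (0.0, 0.0, 0.0, 0.0)),
        ],
    )
    def test_published_and_degenerate_quads(self, args, want):
        assert ar_pc_ratios(*args).as_tuple() == want

    def test_zero_denominator_flagged_undefined(self):
        q = ar_pc_ratios(10, 5, 0, 4)
        assert q.mm is None and q.fm is None
        assert set(q.undefined) == {"mm", "fm"}
        assert q.mf == 2.5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ar_pc_ratios(-1, 0, 1, 1)


class TestExpectedCounts:
    @pytest.mark.parametrize(
        "tot,male,want",
        [
            ((121), 68, (30, 17, 13)),
            (240, 146, (60, 37, 23)),
            (4, 2, (1, 1, 0)),
            (134, 82, (34, 21, 13)),  # 33.5 and 20.5 round half-up
        ],
    )
    def test_display_triplets(self, tot, male, want):
        e = expected_counts(tot, male)
        assert (e.display_total, e.display_male, e.display_female) == want
        assert e.exact_total == tot / 4

    def test_male_total_cannot_exceed_grand_total(self):
        with pytest.raises(ValueError):
            expected_counts(10, 11)


class TestScoreCell:
    def test_large_excess_scores_plus_three(self):
        s = score_cell(65, 30)
        assert s.score == 3 and s.chi2 == pytest.approx(40.83, abs=0.01)

    def test_deficit_at_one_percent_level(self):
        s = score_cell(13, 30)
        assert s.score == -2 and s.p == pytest.approx(0.00191, abs=0.0001)

    def test_observed_equal_expected_is_zero(self):
        assert score_cell(30, 30).score == 0

    def test_nonpositive_expectation_rejected(self):
        with pytest.raises(ValueError):
            score_cell(5, 0)

    @pytest.mark.parametrize("obs,exp", [(10, 30), (25, 30), (44, 30), (0, 12)])
    def test_antisymmetry_around_expectation(self, obs, exp):
        mirrored = score_cell(2 * exp - obs, exp)
        assert mirrored.score == -score_cell(obs, exp).score

    def test_monotone_in_absolute_deviation(self):
        exp = 40
        scores = [abs(score_cell(obs, exp).score) for obs in range(40, 80)]
        assert scores == sorted(scores)

    def test_yates_correction_weakens_borderline_cell(self):
        assert score_cell(28, 40, yates=True).chi2 < score_cell(28, 40).chi2


def matrix_from_ints(vals: dict[str, tuple[int, int, int]]) -> ScoreMatrix:
    return ScoreMatrix(
        {
            g: {
                c: Score(v, 0.0, 1.0 if v == 0 else 0.01)
                for c, v in zip(("total", "male", "female"), vals[g])
            }
            for g in GROUPS
        }
    )


def reference_matrix(row_name: str) -> ScoreMatrix:
    df = load_four_group_table()
    row = df[df["row"] == row_name].iloc[0]
    return matrix_from_ints(
        {
            g: tuple(int(row[f"s{i}_{c}"]) for c in ("t", "m", "f"))
            for i, g in enumerate(GROUPS, start=1)
        }
    )


class TestClassifyPattern:
    def test_myeloma_row_is_pd1(self):
        assert classify_pattern(reference_matrix("LPD/MM")) == PD1

    def test_cll_row_is_pd2(self):
        assert classify_pattern(reference_matrix("LPD/CLL")) == PD2

    def test_all_zero_matrix_is_pd3(self):
        assert classify_pattern(reference_matrix("LPD/NHL NOS")) == PD3

    def test_partial_deviation_is_other(self):
        assert classify_pattern(reference_matrix("LPD/ALL")) == PD_OTHER


class TestFourGroupTable:
    def test_conservation_and_scores(self):
        obs = {
            "Psm-PA": {"total": 65, "male": 37, "female": 28},
            "Psm-MA": {"total": 25, "male": 13, "female": 12},
            "Psf-PA": {"total": 13, "male": 6, "female": 7},
            "Psf-MA": {"total": 18, "male": 12, "female": 6},
        }
        t = FourGroupTable.from_obs(obs)
        assert t.grand_total == 121 and t.grand_male == 68
        assert t.expected.display_total == 30
        assert t.scores.score("Psm-PA", "total") == 3
        assert t.scores.score("Psf-PA", "total") == -2

    def test_inconsistent_sex_split_rejected(self):
        obs = {g: {"total": 10, "male": 4, "female": 4} for g in GROUPS}
        with pytest.raises(ValueError):
            FourGroupTable.from_obs(obs)


def _link(rel_label, pid="p", rid="r"):
    return AffectedRelativeLink(pid, rid, "PA", 1, rel_label)


class TestPairCensus:
    def test_all_parent_offspring_zero_oblique(self):
        c = pair_census([_link("parent-offspring")])["all"]
        assert c.oblique_share == 0.0

    def test_one_in_fifty_gives_98_percent(self):
        links = [_link("parent-offspring")] + [
            _link("uncle-aunt", rid=f"r{i}") for i in range(49)
        ]
        assert pair_census(links)["all"].oblique_share == 98.0

    def test_empty_census_is_zeros(self):
        c = pair_census([])["all"]
        assert c.total == 0 and c.oblique_share is None

    def test_split_by_proband_group(self):
        links = [_link("uncle-aunt", pid="a"), _link("parent-offspring", pid="b")]
        census = pair_census(links, {"a": "LPD", "b": "MPD"})
        assert census["LPD"].oblique == 1 and census["MPD"].parent_offspring == 1
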