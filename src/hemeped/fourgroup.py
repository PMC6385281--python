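"""Four-group observed/expected tables, signed chi-square scores and the
PD1/PD2/PD3 pattern classifier.

Affected relatives (AR) of the standardized probands (Ps) are tallied into
four groups — male probands' patrilineal AR (Psm-PA), male probands'
matrilineal AR (Psm-MA), and the same two groups for female probands
(Psf-PA, Psf-MA) — each split into total/male/female counts.  The null
hypothesis is an equal distribution of the AR over the four groups (25% of
the grand total each); each cell is scored by a one-degree-of-freedom
chi-square of observed against that expectation, signed by the direction of
the deviation, with |score| 1/2/3 at p < 0.05/0.01/0.001.

Three patterns of distribution are defined on the male score column:

* PD1 — male-AR excess for male probands and deficit for female probands in
  patrilineal lines only (matrilineal male scores at zero),
* PD2 — the same excess/deficit in both parental lines,
* PD3 — no deviation anywhere (every score zero).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2 as _chi2

from hemeped._util import round_half_up
from hemeped.pedigree import MALE, PARENT_OFFSPRING, Pedigree
from hemeped.segregation import AffectedRelativeLink, PsRecord

GROUPS = ("Psm-PA", "Psm-MA", "Psf-PA", "Psf-MA")

PD1 = "PD1"
PD2 = "PD2"
PD3 = "PD3"
PD_OTHER = "other"


# ---------------------------------------------------------------------------
# AR/Pc ratios


@dataclass(frozen=True)
class RatioQuad:
    """Mean AR of each sex per proband of each sex (one decimal).

    ``mm`` = male AR per male proband, ``fm`` = female AR per male proband,
    ``mf`` = male AR per female proband, ``ff`` = female AR per female
    proband.  Entries whose proband denominator is zero are ``None`` and
    listed in ``undefined``.
    """

    mm: float | None
    fm: float | None
    mf: float | None
    ff: float | None
    undefined: tuple[str, ...] = ()

    def as_tuple(self):
        return (self.mm, self.fm, self.mf, self.ff)


def ar_pc_ratios(
    ar_males: int, ar_females: int, pc_males: int, pc_females: int
) -> RatioQuad:
    """AR-sex totals divided by proband-sex counts, rounded half-up to 1 dp."""
    if min(ar_males, ar_females, pc_males, pc_females) < 0:
        raise ValueError("counts must be non-negative")

    def div(num: int, den: int) -> float | None:
        return None if den == 0 else round_half_up(num / den, 1)

    undefined = []
    if pc_males == 0:
        undefined += ["mm", "fm"]
    if pc_females == 0:
        undefined += ["mf", "ff"]
    return RatioQuad(
        mm=div(ar_males, pc_males),
        fm=div(ar_females, pc_males),
        mf=div(ar_males, pc_females),
        ff=div(ar_females, pc_females),
        undefined=tuple(undefined),
    )


# ---------------------------------------------------------------------------
# expected counts


@dataclass(frozen=True)
class ExpectedCounts:
    """Per-group expectation under the equal-distribution null.

    ``exact_*`` are the true quarters; ``display_*`` follow the tabulation
    convention (half-up rounding of total and males, females by complement)
    and are what the scoring uses.
    """

    exact_total: float
    exact_male: float
    exact_female: float
    display_total: int
    display_male: int
    display_female: int


def expected_counts(grand_total: int, male_total: int) -> ExpectedCounts:
    """25%-of-OBS expectation for each of the four groups."""
    if grand_total < 0 or male_total < 0:
        raise ValueError("counts must be non-negative")
    if male_total > grand_total:
        raise ValueError("male_total cannot exceed grand_total")
    dt = int(round_half_up(grand_total / 4))
    dm = int(round_half_up(male_total / 4))
    return ExpectedCounts(
        exact_total=grand_total / 4,
        exact_male=male_total / 4,
        exact_female=(grand_total - male_total) / 4,
        display_total=dt,
        display_male=dm,
        display_female=dt - dm,
    )


# ---------------------------------------------------------------------------
# signed scores


@dataclass(frozen=True)
class Score:
    score: int
    chi2: float
    p: float


def score_cell(obs: int, exp: float, yates: bool = False) -> Score:
    """Signed significance score of an observed count against its expectation.

    One-cell chi-square (obs - exp)^2 / exp on 1 df (optionally with the
    Yates continuity correction), two-sided tail probability; |score| is
    1/2/3 for p < 0.05/0.01/0.001, signed by obs - exp, and 0 otherwise.
    """
    if exp <= 0:
        raise ValueError("exp must be positive")
    dev = abs(obs - exp)
    if yates:
        dev = max(dev - 0.5, 0.0)
    stat = dev * dev / exp
    p = float(_chi2.sf(stat, 1))
    if p < 0.001:
        level = 3
    elif p < 0.01:
        level = 2
    elif p < 0.05:
        level = 1
    else:
        level = 0
    sign = 1 if obs > exp else (-1 if obs < exp else 0)
    return Score(score=sign * level, chi2=stat, p=p)


@dataclass(frozen=True)
class ScoreMatrix:
    """Signed scores (total, male, female) for each of the four Ps groups."""

    cells: dict[str, dict[str, Score]]

    def score(self, group: str, column: str) -> int:
        return self.cells[group][column].score

    def male_scores(self) -> tuple[int, int, int, int]:
        return tuple(self.cells[g]["male"].score for g in GROUPS)

    def all_scores(self) -> list[int]:
        return [
            self.cells[g][c].score for g in GROUPS for c in ("total", "male", "female")
        ]


def classify_pattern(scores: ScoreMatrix) -> str:
    """Assign a score matrix to PD1, PD2, PD3 or other.

    PD1: patrilineal male-AR excess for male probands with a patrilineal
    deficit for female probands, matrilineal male scores at zero.  PD2: the
    male excess (Psm) / deficit (Psf) present in both parental lines.  PD3:
    every score in the matrix is zero.
    """
    m_pa, m_ma, f_pa, f_ma = scores.male_scores()
    if all(s == 0 for s in scores.all_scores()):
        return PD3
    if m_pa > 0 and f_pa < 0 and m_ma == 0 and f_ma == 0:
        return PD1
    if m_pa > 0 and m_ma > 0 and f_pa < 0 and f_ma < 0:
        return PD2
    return PD_OTHER


# ---------------------------------------------------------------------------
# the assembled table


@dataclass
class FourGroupTable:
    """OBS/EXP counts and scores for the four Ps groups of one proband set."""

    obs: dict[str, dict[str, int]]  # group -> {total, male, female}
    expected: ExpectedCounts
    scores: ScoreMatrix
    grand_total: int
    grand_male: int
    grand_female: int

    @classmethod
    def from_obs(
        cls, obs: dict[str, dict[str, int]], yates: bool = False
    ) -> "FourGroupTable":
        for g in GROUPS:
            if obs[g]["male"] + obs[g]["female"] != obs[g]["total"]:
                raise ValueError(f"group {g}: male + female != total")
        gt = sum(obs[g]["total"] for g in GROUPS)
        gm = sum(obs[g]["male"] for g in GROUPS)
        exp = expected_counts(gt, gm)
        disp = {
            "total": exp.display_total,
            "male": exp.display_male,
            "female": exp.display_female,
        }
        cells = {
            g: {
                c: score_cell(obs[g][c], disp[c], yates=yates)
                if disp[c] > 0
                else Score(0, 0.0, 1.0)
                for c in ("total", "male", "female")
            }
            for g in GROUPS
        }
        return cls(
            obs=obs,
            expected=exp,
            scores=ScoreMatrix(cells),
            grand_total=gt,
            grand_male=gm,
            grand_female=gt - gm,
        )

    @property
    def pattern(self) -> str:
        return classify_pattern(self.scores)


def build_four_group_table(
    ps_records: list[PsRecord], ped: Pedigree, yates: bool = False
) -> FourGroupTable:
    """Tally each Ps record's AR registrations into the four groups.

    Standardization already placed every AR of a crude proband on exactly
    one of its Ps records, so each registration counts once, under its Ps's
    line, and the grand totals conserve the AR count.
    """
    obs = {g: {"total": 0, "male": 0, "female": 0} for g in GROUPS}
    for rec in ps_records:
        gname = ("Psm-" if rec.sex == MALE else "Psf-") + rec.line
        for link in rec.links:
            obs[gname]["total"] += 1
            if ped[link.relative_id].sex == MALE:
                obs[gname]["male"] += 1
            else:
                obs[gname]["female"] += 1
    return FourGroupTable.from_obs(obs, yates=yates)


# ---------------------------------------------------------------------------
# pair census


@dataclass(frozen=True)
class PairCensus:
    parent_offspring: int
    oblique: int

    @property
    def total(self) -> int:
        return self.parent_offspring + self.oblique

    @property
    def oblique_share(self) -> float | None:
        """Percentage of proband-AR pairs that are not parent-offspring."""
        if self.total == 0:
            return None
        return round_half_up(100 * self.oblique / self.total, 1)


def pair_census(
    links: list[AffectedRelativeLink],
    group_of_proband: dict[str, str] | None = None,
) -> dict[str, PairCensus]:
    """Count parent-offspring versus other (oblique) affected pairs.

    Returns one census per proband diagnosis group (plus ``"all"``); each
    (proband, relative) link counts as one pair.
    """
    buckets: dict[str, list[int]] = {}
    for link in links:
        keys = ["all"]
        if group_of_proband is not None:
            keys.append(group_of_proband.get(link.proband_id, "ungrouped"))
        for k in keys:
            po, ob = buckets.get(k, (0, 0))
            if link.relationship == PARENT_OFFSPRING:
                po += 1
            else:
                ob += 1
            buckets[k] = [po, ob]
    if not buckets:
        buckets["all"] = [0, 0]
    return {k: PairCensus(po, ob) for k, (po, ob) in sorted(buckets.items())}
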