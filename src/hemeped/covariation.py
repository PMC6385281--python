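"""Systematic co-/contravariation screen of proband vs relative diagnoses.

For proband diagnosis ``d`` and relative diagnosis ``r``, the observed count
``O(d, r)`` is the number of registered proband-AR links whose proband has
diagnosis ``d`` and whose relative has diagnosis ``r`` (each link counted
once).  Under the proportional null the AR of ``d``-probands carry diagnosis
``r`` at the cohort's proband frequency, so

    E(d, r) = AR_total(d) x Pc(r) / Pc_group_total.

For the clustering diagonal (d = r) this is the familiar form
``Pc_d x AR_d / Pc_total``.  Cells are tested with a two-cell chi-square
goodness of fit (O vs the remaining AR of d) at 1 df; the one-cell
``(O - E)^2 / E`` is reported alongside, since published worked values of
this screen do not reconcile with either standard form exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2 as _chi2

COVARIATION = "covariation"
CONTRAVARIATION = "contravariation"
NONE_VERDICT = "none"


def expected_ar(pc_d: float, ar_r: float, pc_group_total: float) -> float:
    """Equal-distribution expectation ``Pc_d x AR_r / Pc_group_total``."""
    if pc_group_total <= 0:
        raise ValueError("group total must be positive")
    return pc_d * ar_r / pc_group_total


@dataclass(frozen=True)
class CovariationCell:
    proband_diagnosis: str
    relative_diagnosis: str
    observed: int
    expected: float
    chi2: float  # two-cell goodness of fit, 1 df
    chi2_one_cell: float
    p: float
    verdict: str


def _cell(
    d: str, r: str, obs: int, exp: float, row_total: int, alpha: float
) -> CovariationCell:
    one = (obs - exp) ** 2 / exp if exp > 0 else 0.0
    rest_exp = row_total - exp
    two = one + (
        ((row_total - obs) - rest_exp) ** 2 / rest_exp if rest_exp > 0 else 0.0
    )
    p = float(_chi2.sf(two, 1))
    if p < alpha and obs > exp:
        verdict = COVARIATION
    elif p < alpha and obs < exp:
        verdict = CONTRAVARIATION
    else:
        verdict = NONE_VERDICT
    return CovariationCell(d, r, obs, exp, two, one, p, verdict)


def covariation_table(
    pc_counts: dict[str, int],
    ar_counts: dict[tuple[str, str], int],
    alpha: float = 0.05,
) -> list[CovariationCell]:
    """Score every (proband diagnosis, relative diagnosis) pair.

    ``pc_counts`` maps diagnosis -> proband count within the group being
    screened; ``ar_counts`` maps (proband diagnosis, relative diagnosis) ->
    link count.  Cells where the proband diagnosis has no AR are skipped.
    """
    pc_total = sum(pc_counts.values())
    if pc_total <= 0:
        raise ValueError("zero proband group total")
    ar_row_total = {
        d: sum(c for (dd, _), c in ar_counts.items() if dd == d) for d in pc_counts
    }
    cells = []
    for d in sorted(pc_counts):
        row_total = ar_row_total[d]
        if row_total == 0:
            continue
        for r in sorted(pc_counts):
            exp = expected_ar(row_total, pc_counts[r], pc_total)
            obs = ar_counts.get((d, r), 0)
            if exp == 0 and obs == 0:
                continue
            cells.append(_cell(d, r, obs, exp, row_total, alpha))
    return cells
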