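"""Cohort-level diagnosis analytics.

Frequencies are expressed as percentages of the LPD or MPD group total
(half-up rounding to one decimal, the tabulation convention of the source
registries), together with male/female ratios, Hodgkin/non-Hodgkin lymphoma
shares, onset-age comparisons (two-sided Mann-Whitney) and an
observed-vs-registry chi-square enrichment screen used as an anticipation
proxy (familial counts against whole-population registry percentages).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2 as _chi2, mannwhitneyu

from hemeped._util import round_half_up
from hemeped.diagnoses import DiagnosisMap, HL_ABBREV, NHL_ABBREVS

ENRICHED = "enrichment"
DEPLETED = "depletion"
NO_VERDICT = "none"


def frequency_table(
    counts: pd.DataFrame, diagnosis_map: DiagnosisMap | None = None
) -> pd.DataFrame:
    """Per-diagnosis percentages and the per-group male/female ratio.

    ``counts`` needs columns ``group``, ``abbrev``, ``total``, ``males``,
    ``females`` (one row per diagnosis).  Returns the input augmented with a
    ``percent`` column (share of the group total, one decimal) plus per-group
    attributes in ``DataFrame.attrs['group_summary']``: totals, male/female
    ratio (one decimal) and the percent-column sum.
    """
    df = counts.copy()
    group_rows = {}
    percents = []
    for g, sub in df.groupby("group", sort=False):
        gt = int(sub["total"].sum())
        gm = int(sub["males"].sum())
        gf = int(sub["females"].sum())
        for _, r in sub.iterrows():
            percents.append(
                (r.name, round_half_up(100 * r["total"] / gt, 1) if gt else None)
            )
        group_rows[g] = {
            "total": gt,
            "males": gm,
            "females": gf,
            "mf_ratio": round_half_up(gm / gf, 1) if gf else None,
        }
    pmap = dict(percents)
    df["percent"] = [pmap[i] for i in df.index]
    for g, row in group_rows.items():
        nonzero = df[(df["group"] == g) & (df["total"] > 0)]
        row["percent_sum"] = round(float(nonzero["percent"].sum()), 1)
    df.attrs["group_summary"] = group_rows
    return df


def lymphoma_shares(counts: pd.DataFrame) -> dict[str, float]:
    """Hodgkin share of all malignant lymphomas and united-NHL share of LPD.

    United NHL is ICD-10 C82-C85 (FL, MCL, DLBCL, TNHL, MONOC, NHL NOS);
    malignant lymphomas are HL plus united NHL.  Percentages are half-up to
    one decimal.
    """
    lpd = counts[counts["group"] == "LPD"]
    hl = int(lpd.loc[lpd["abbrev"] == HL_ABBREV, "total"].sum())
    nhl = int(lpd.loc[lpd["abbrev"].isin(NHL_ABBREVS), "total"].sum())
    lpd_total = int(lpd["total"].sum())
    lymphomas = hl + nhl
    return {
        "hl_of_lymphomas": round_half_up(100 * hl / lymphomas, 1)
        if lymphomas
        else 100.0,
        "nhl_of_lpd": round_half_up(100 * nhl / lpd_total, 1) if lpd_total else 0.0,
    }


@dataclass(frozen=True)
class EnrichmentVerdict:
    abbrev: str
    observed: int
    expected: float
    chi2: float
    p: float
    verdict: str
    level: float | None  # 0.05 or 0.01 when significant
    registry_uncertain: bool = False  # registry share printed as "<1"


def anticipation_compare(
    familial: dict[str, int],
    registry_percent: dict[str, float | str],
    alpha_levels: tuple[float, float] = (0.05, 0.01),
) -> list[EnrichmentVerdict]:
    """Familial counts against registry percentages, per diagnosis.

    Registry shares act as fixed reference proportions scaled to the familial
    cohort size; each diagnosis is tested with a two-cell chi-square goodness
    of fit (1 df).  Registry entries printed as ``"<1"`` are taken as 0.5 and
    flagged uncertain.
    """
    n = sum(familial.values())
    if n == 0:
        raise ValueError("empty familial cohort")
    out = []
    for abbrev in sorted(registry_percent):
        raw = registry_percent[abbrev]
        uncertain = isinstance(raw, str) and raw.strip().startswith("<")
        pct = 0.5 if uncertain else float(raw)
        exp = n * pct / 100.0
        obs = familial.get(abbrev, 0)
        if exp <= 0 or exp >= n:
            continue
        stat = (obs - exp) ** 2 / exp + (obs - exp) ** 2 / (n - exp)
        p = float(_chi2.sf(stat, 1))
        loose, strict = alpha_levels
        if p < strict:
            level = strict
        elif p < loose:
            level = loose
        else:
            level = None
        if level is None or obs == exp:
            verdict = NO_VERDICT
            level = None
        else:
            verdict = ENRICHED if obs > exp else DEPLETED
        out.append(
            EnrichmentVerdict(abbrev, obs, exp, stat, p, verdict, level, uncertain)
        )
    return out


def onset_compare(
    ages_a: list[float], ages_b: list[float]
) -> dict[str, float]:
    """Two-sided Mann-Whitney comparison of onset ages, with medians."""
    if not ages_a or not ages_b:
        raise ValueError("both onset-age samples must be non-empty")
    sa, sb = pd.Series(ages_a, dtype=float), pd.Series(ages_b, dtype=float)
    res = mannwhitneyu(sa, sb, alternative="two-sided")
    return {
        "median_a": float(sa.median()),
        "median_b": float(sb.median()),
        "u": float(res.statistic),
        "p": float(res.pvalue),
    }
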