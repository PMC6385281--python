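"""Bundled reference tables of the two familial MBD cohorts.

The package ships transcriptions of the published summary tables for the
inbred Faroese cohort (one united multi-generation pedigree, 315 patients)
and the Norwegian/Danish cohort (112 nuclear families with unrelated
parents, 301 patients), plus the whole-population registry percentages used
as the comparison material:

* ``cohort_counts.tsv`` — proband (Pc) counts per diagnosis with the printed
  group percentages (a ``flagged`` column marks the single printed value
  that does not recompute from its own counts),
* ``cohort_summary.tsv`` — printed per-group male/female ratios and median
  onset ages,
* ``registry_reference.tsv`` — registry diagnosis shares ("<1" entries kept
  verbatim),
* ``four_group_faroe.tsv`` — the Faroese four-group AR table: AR/Pc ratio
  columns, OBS counts per Ps group, printed EXP triplets and printed signed
  scores, with documented printed anomalies flagged rather than silently
  corrected.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from hemeped._util import round_half_up

#: number of Norwegian/Danish families behind the nordic cohort counts
NORDIC_FAMILY_COUNT = 112

FOUR_GROUP_SCORE_COLUMNS = [
    f"s{g}_{c}" for g in (1, 2, 3, 4) for c in ("t", "m", "f")
]


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("hemeped.data").joinpath(name)) as p:
        return pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)


def load_cohort_counts() -> pd.DataFrame:
    df = _read("cohort_counts.tsv")
    for c in ("total", "males", "females"):
        df[c] = df[c].astype(int)
    df["printed_percent"] = pd.to_numeric(df["printed_percent"], errors="coerce")
    return df


def load_cohort_summary() -> pd.DataFrame:
    df = _read("cohort_summary.tsv")
    for c in df.columns[2:]:
        df[c] = pd.to_numeric(df[c])
    df["printed_ratio"] = pd.to_numeric(df["printed_ratio"])
    return df


def load_registry_reference() -> pd.DataFrame:
    return _read("registry_reference.tsv")


def load_four_group_table() -> pd.DataFrame:
    df = _read("four_group_faroe.tsv")
    int_cols = (
        ["pc_total", "pc_males", "pc_females"]
        + [f"obs{g}_{c}" for g in (1, 2, 3, 4) for c in ("t", "m", "f")]
        + ["tot_t", "tot_m", "tot_f", "exp_t", "exp_m", "exp_f", "scored"]
    )
    for c in int_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce").astype("Int64")
    for c in ("ratio_mm", "ratio_fm", "ratio_mf", "ratio_ff"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in FOUR_GROUP_SCORE_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="coerce").astype("Int64")
    return df


def nordic_patients_per_family() -> float:
    """Mean MBD patients per Norwegian/Danish family (one decimal)."""
    counts = load_cohort_counts()
    n = int(counts.loc[counts["cohort"] == "nordic", "total"].sum())
    return round_half_up(n / NORDIC_FAMILY_COUNT, 1)


def nordic_ar_per_pc() -> float:
    """Mean affected relatives per proband, (N - F) / F over the families."""
    counts = load_cohort_counts()
    n = int(counts.loc[counts["cohort"] == "nordic", "total"].sum())
    return round_half_up((n - NORDIC_FAMILY_COUNT) / NORDIC_FAMILY_COUNT, 1)
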