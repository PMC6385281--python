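"""Cohort analytics over the bundled reference tables.

Reproduces the per-diagnosis frequency percentages, male/female ratios and
lymphoma shares of the two familial MBD cohorts, and screens the familial
counts against whole-population registry shares.
"""

from hemeped.cohort import anticipation_compare, frequency_table, lymphoma_shares
from hemeped.reference import load_cohort_counts, load_registry_reference

counts = load_cohort_counts()
faroe = counts[counts["cohort"] == "faroe"].reset_index(drop=True)

table = frequency_table(faroe)
lpd = table[(table["group"] == "LPD") & (table["total"] > 0)]
print("inbred cohort, lymphoproliferative block:")
for _, r in lpd.iterrows():
    print(f"  {r['abbrev']:8s} {r['total']:3d} ({r['males']}, {r['females']})"
          f"  {r['percent']:5.1f}%")
g = table.attrs["group_summary"]["LPD"]
print(f"  total {g['total']} (m/f ratio {g['mf_ratio']})")

shares = lymphoma_shares(faroe)
print(f"Hodgkin share of all malignant lymphomas: {shares['hl_of_lymphomas']}%")
print(f"united-NHL share of LPD: {shares['nhl_of_lpd']}%")

registry = load_registry_reference()
reg = {r["abbrev"]: r["percent"] for _, r in
       registry[registry["group"] == "LPD"].iterrows()}
familial = {r["abbrev"]: int(r["total"]) for _, r in lpd.iterrows()}
print("\nfamilial vs registry shares (chi-square enrichment screen):")
for v in anticipation_compare(familial, reg):
    if v.verdict != "none":
        print(f"  {v.abbrev:8s} obs {v.observed:3d} exp {v.expected:6.1f}"
              f"  {v.verdict} (p < {v.level})")

# Enriched diagnoses appear in families far above their population share
# (the anticipation proxy); depleted ones, e.g. the indolent lymphomas,
# fall below it.
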