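"""Proband standardization and the four-group observed/expected table.

Simulates one inbred pedigree under the two-route imprinting preset, runs
the full analysis pipeline (affected-relative registration, parental-line
affiliation, crude-to-standard proband conversion) and prints the four-group
table with its signed chi-square scores.
"""

from hemeped.pipeline import analyze_four_group
from hemeped.simulate import SimulationConfig, simulate

cfg = SimulationConfig.pattern_preset("PD2", seed=1)
res = simulate(cfg)
print(f"pedigree: {len(res.pedigree)} members, {res.n_affected} affected")

ana = analyze_four_group(res.pedigree)
t = ana.table
print(f"{ana.n_probands} crude probands -> {len(ana.ps_records)} standard probands")
print(f"{'group':8s} {'obs (m,f)':>16s} {'exp (m,f)':>14s} {'score (t,m,f)':>14s}")
e = t.expected
for g in ("Psm-PA", "Psm-MA", "Psf-PA", "Psf-MA"):
    o = t.obs[g]
    s = t.scores
    print(
        f"{g:8s} {o['total']:6d} ({o['male']}, {o['female']})"
        f"  {e.display_total:6d} ({e.display_male}, {e.display_female})"
        f"   {s.score(g, 'total'):+d} ({s.score(g, 'male'):+d}, {s.score(g, 'female'):+d})"
    )
print("pattern of distribution:", ana.pattern)

# Positive scores for male probands and negative for female probands in both
# parental lines (male column) is the two-route pattern (PD2); the expected
# cell is always a quarter of the grand AR total.
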