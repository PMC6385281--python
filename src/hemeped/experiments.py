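"""Cohort-level pattern-recovery experiments.

A *cohort* pools several independently simulated pedigrees (same
configuration, derived subseeds) until a target number of probands is
reached, then builds one four-group table from the pooled per-Ps counts.
Pooling replicate pedigrees mirrors a multi-family study and averages the
strong clustered (shared-AR) noise a single inbred pedigree exhibits, so the
pattern of distribution emerges at cohort scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from hemeped.pedigree import MALE
from hemeped.fourgroup import GROUPS, FourGroupTable
from hemeped.pipeline import analyze_four_group
from hemeped.simulate import SimulationConfig, simulate


@dataclass
class CohortResult:
    table: FourGroupTable
    n_probands: int
    n_male_probands: int
    n_female_probands: int
    n_pedigrees: int
    n_individuals: int

    @property
    def pattern(self) -> str:
        return self.table.pattern


def simulate_pattern_cohort(
    pattern: str,
    seed: int,
    n_probands: int = 500,
    max_pedigrees: int = 600,
    max_intermediates: int = 5,
    **config_overrides,
) -> CohortResult:
    """Accumulate replicate pedigrees under a pattern preset into one cohort.

    Subseeds are derived deterministically from ``seed``; pedigrees are
    added until the pooled proband count reaches ``n_probands`` (or
    ``max_pedigrees`` is hit).
    """
    obs = {g: {"total": 0, "male": 0, "female": 0} for g in GROUPS}
    tot_p = tot_m = tot_ped = tot_n = 0
    for k in range(max_pedigrees):
        sub = (seed * 1_000 + k) % (2**31 - 1)
        cfg = SimulationConfig.pattern_preset(pattern, seed=sub, **config_overrides)
        res = simulate(cfg)
        tot_ped += 1
        tot_n += len(res.pedigree)
        if res.n_affected == 0:
            continue
        ana = analyze_four_group(
            res.pedigree, max_intermediates=max_intermediates, parity=k % 2
        )
        for g in GROUPS:
            for c in ("total", "male", "female"):
                obs[g][c] += ana.table.obs[g][c]
        tot_p += ana.n_probands
        tot_m += sum(1 for r in ana.records if r.sex == MALE)
        if tot_p >= n_probands:
            break
    table = FourGroupTable.from_obs(obs)
    return CohortResult(
        table=table,
        n_probands=tot_p,
        n_male_probands=tot_m,
        n_female_probands=tot_p - tot_m,
        n_pedigrees=tot_ped,
        n_individuals=tot_n,
    )
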