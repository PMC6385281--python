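# File formats

## Pedigree (`*.ped`)

Tab-separated, six columns, no header — the LINKAGE/PED layout:

| column | meaning |
| ------ | ------- |
| FID    | family identifier |
| IID    | individual identifier (unique) |
| PAT    | father's IID, `0` for a founder |
| MAT    | mother's IID, `0` for a founder |
| SEX    | `1` male, `2` female |
| PHENO  | `1` unaffected, `2` affected, `0` unknown |

Lines starting with `#` are ignored. Fathers must be male, mothers female;
parent links must be acyclic and refer to rows in the file.

## Phenotypes (`phenotypes.tsv`)

Tab-separated with header `iid  icd10  birth_year  onset_year`. Empty
fields (or `.`/`NA`) mean unknown. `icd10` is the diagnosis code resolved
through the bundled diagnosis map (`diagnosis_groups.tsv`: `icd10  label
abbrev  group` with group LPD/MPD/OTHER).

## Ground truth (`truth.tsv`, simulator output)

One row per simulated individual: `iid  sex  generation  carrier
from_father  from_mother  expressed  strong_units  weak_units  load
affected  onset_age`.

## Analysis outputs

* `links.tsv` — one row per proband-AR registration: `proband  relative
  line  intermediates  relationship  ambiguous` (line `PA`/`MA`/`OWN`).
* `ps.tsv` — one row per standard proband: `proband  sex  line  diagnosis
  n_links`.
* `four_group.tsv` — the four Ps groups with observed counts, display
  expectations and signed scores (total/male/female each).
* `report.json` — proband counts, pattern classification, pair census.
* `birth_order.tsv` — one row: `A  expectation  variance  z  p  ci95_low
  ci95_high  n_informative  wilcoxon_stat  wilcoxon_p`.
* `covariation.tsv` — one row per screened diagnosis pair with observed,
  expected, both chi-square forms, p and verdict.
* `manifest.json` — command, seed, configuration and SHA-256 digests of
  every output file.

## Simulator configuration (`--config`)

A JSON object of `SimulationConfig` fields (see `hemeped/simulate.py` for
the full list and defaults); unknown keys are reported by name.
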