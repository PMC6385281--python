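# Methods

## The genealogical model

A pedigree is a two-parent acyclic kinship graph read from a 6-column
LINKAGE/PED file (`FID IID PAT MAT SEX PHENO`; founder parents `0`, sex
1 = male / 2 = female, phenotype 1/2/0 = unaffected/affected/unknown) with
diagnoses, birth years and onset years in a companion phenotype TSV. A
*kinship path* ascends through ancestors and descends at most once (one
apex); zig-zag routes through marriages are not genealogical connections
and are excluded. Under inbreeding two individuals can be joined by several
distinct paths; all are retained and downstream steps choose the closest.

### Affected-relative registration

For a proband, every affected individual reachable by a kinship path with
at most `max_intermediates` (default 5) *unaffected* interior individuals
is registered exactly once. Affected intermediates do not consume the
budget, so chains of patients extend the search. Closeness is the pair
(unaffected intermediates, path length); the registered line is the line of
the closest path — PA when the first step is to the father, MA via the
mother. When the best PA and MA connections tie (full siblings and other
two-apex-symmetric kin) the link is reported under PA but marked
*ambiguous*; pure descendants have no parental line at all and are marked
the same way. Descendants are searched by default (they are ordinary
"vertical" connections); a flag restricts the search to the ancestral and
oblique directions.

### Affiliation and standardization

Probands are allocated to PA+MA / PA / MA / PA=MA / none-visible from their
unambiguous link lines. Standardization makes every proband monoparental:
two-line probands yield a Ps per line, each carrying that line's AR, with
line-ambiguous AR shared equally between the two records by deterministic
alternation; single-line probands carry all their AR under their line;
PA=MA probands go to the line holding the majority of their AR (closest-line
vote, summed-distance tie-break), fully tied ones alternating; none-visible
probands alternate PA/MA over sorted ids, an odd remainder going to PA.
The alternating counters accept a parity offset so that analyses pooling
many pedigrees do not place every odd remainder on the same line. Every AR
registration of a proband thus lands on exactly one of its Ps records, and
the four-group table conserves the AR grand total.

### Scores and patterns

The four-group expectation is the *display* quarter of the grand totals:
half-up rounding of total/4 and males/4, females by complement (36.5 → 37
with the female cell from the complement — the convention that reproduces
the published tables; the exact quarters are also reported). Cells are
scored by the one-cell chi-square (O − E)²/E on 1 df without continuity
correction (a Yates option exists), signed by O − E, with |score| 1/2/3 at
p < 0.05/0.01/0.001. Pattern classification uses the male column exactly as
defined: PD1 = (+, 0, −, 0), PD2 = (+, +, −, −), PD3 = all twelve scores
zero, anything else "other".

### Birth order

The Haldane–Smith statistic is the sum of affected birth ranks over
informative sibships (1 ≤ affected < size). The historical 6-fold integer
scaling cancels in the z-score, so results are reported on the plain A
scale. The exact oracle convolves per-sibship rank-sum distributions; its
tails bracket the observed value and validate the normal approximation
(within 0.05 of the mid-p exact tail for all pairs of sibships of size ≤ 5
with total variance ≥ 3 — the mid-p convention is the lattice quantity
comparable to a continuous approximation). The Wilcoxon control centers
affected ranks on the sibship median rank (s + 1)/2 and tests them against
zero. Birth ranks come from the stated birth order (birth year, then id);
equal years are never re-inferred.

### Covariation and cohort statistics

The screen's null distributes a proband-diagnosis row's AR over relative
diagnoses proportionally to proband counts: E(d, r) = AR_total(d) × Pc(r) /
Pc_total, which on the clustering diagonal is the familiar
Pc_d × AR_d / Pc_total. Cells are tested with a two-cell 1-df goodness of
fit (O vs the row remainder); the one-cell form is reported alongside
because published worked chi-square values for this screen do not reconcile
exactly with either standard form. Cohort percentages and male/female
ratios use half-up rounding to one decimal; the registry comparison treats
published registry shares as fixed proportions scaled to the familial
cohort size (two-cell 1-df chi-square, verdicts at 0.05/0.01; "<1" registry
entries are taken as 0.5 and flagged uncertain). Onset ages are compared
with the two-sided Mann–Whitney test.

## The simulator

Generations are discrete. Founder couples seed the pedigree; children form
the next generation's couples — a `within_mating_fraction` share marry
inside the pedigree (full sibs excluded), everyone else weds an immigrant
founder spouse with probability `immigrant_marriage_fraction` (per sex, so
neither parental side is structurally kin-poor; the default 1/2 keeps the
couple count at half the generation regardless of the within-mating level).
Sibship sizes are Poisson with mean `mean_sibship`; births are processed in
order.

**Transmission and expression.** A carrier parent transmits the allele with
probability 1/2. Under maternal imprinting only paternally transmitted
copies express (conversely under paternal; `both` expresses either; `none`
neither). A silenced copy still expresses with probability
`expression_leak` in either sex, or `female_silencing_escape` in daughters —
the model's *weak expression* in females, which is what lets disease appear
on matrilines at all: under strict maternal imprinting an allele running
down a maternal line is silenced at every step.

**Microchimerism.** Mothers hold a pool of load units ("letters", capped at
`letters_cap` = 7). Every carrier male fetus induces one unit; each child
receives the mother's pre-birth pool — sons as strong units (weight 1.0),
daughters as weak units (weight 0.5) under `daughter_transfer="weak"`, or
at full weight under `"equal"`. A daughter's received units seed her own
pool, so load accumulates down matrilines (anticipation); an optional
per-generation decay removes units. Founders carry a baseline load —
Poisson by default, or bimodal (`founder_loaded_fraction` of founders carry
`founder_loaded_units`); loaded founders are carriers with probability
`founder_loaded_carrier_rate`, reflecting that an acquired load certifies
past carrier fetuses.

**Manifestation.** Disease requires an expressed allele and weighted load ≥
`disease_threshold` (default 2 units; expressed carriers below threshold
are silent bystanders). Susceptible individuals manifest with probability
`penetrance`, rising by `penetrance_slope` per unit load above threshold
(the severity gradient). Onset age is `onset_base` −
`anticipation_slope` × load plus Gaussian noise, floored at `onset_min`.
Affected individuals draw an ICD-10 diagnosis from a configurable
pleiotropy distribution (default: the inbred cohort's lymphoproliferative
frequencies).

A single seeded generator drives everything; a fixed configuration
reproduces byte-identical outputs.

## Pattern presets and what they show

Cohorts for the pattern experiments pool independent replicate pedigrees
(derived subseeds) until ~500 probands accumulate; pooling mirrors a
multi-family study and averages the heavy shared-AR clustering noise a
single inbred pedigree exhibits.

* **PD2** (both routes, weak daughters): male probands' AR exceed the
  quarter expectation in both lines and female probands' fall below it.
  Robust — 20/20 cohorts classify PD2 in our batches.
* **PD3** (origin-independent expression, equal transfer, ubiquitous
  baseline load): neither sex nor line is limiting and every score cell is
  zero ~90–100% of the time per cell. The preset uses very low penetrance,
  so its cohorts are sparse (tens of pedigrees per cohort).
* **PD1** (maternal imprinting, weak daughters, female silencing escape,
  carrier-correlated loaded founder matrilines, bride-biased immigration):
  the preset approaches the one-line pattern — patrilineal male excess for
  male probands, patrilineal deficit for female probands, matrilineal cells
  at expectation — but classifies as PD1 in only ~25–35% of cohorts. The
  limitation is structural: the male-proband and female-proband matrilineal
  cells must both sit exactly at the common quarter expectation, i.e.
  n_m·b = n_f·d for per-proband matrilineal densities b, d. Because the
  microchimeristic load arrives through the mother for *both* sexes, every
  mechanism that enriches d enriches b in proportion, and the balance is a
  knife-edge the stochastic cohorts straddle rather than hold. The
  remaining cohorts classify "other" with the same qualitative cell
  profile, one boundary cell short of significance.

What passing pattern tests show — and what they do not: the simulator
demonstrates that the transmission rules can generate, and the pipeline can
detect, the qualitative pattern classes at realistic cohort sizes. Real
registry pedigrees differ in ways the generator does not emulate: censored
and extra-marital links, era-dependent diagnostics, non-Poisson family
sizes, geographically structured (not random) consanguinity, and
ascertainment through clinical presentation rather than exhaustive
registration.

## Numerical choices and degenerate inputs

Half-up rounding everywhere a table value is printed (banker's rounding
would give 36.5 → 36). Chi-square p-values come from `scipy.stats.chi2.sf`
on 1 df. Zero expectations score zero rather than dividing by zero; ratio
cells with zero proband denominators are flagged undefined. Pedigree
validation rejects cycles, sex-inconsistent parents, duplicate ids,
malformed lines and dangling parent references, each with its own error
type. The exact birth-order oracle refuses configurations beyond its
enumeration budget. Extinct simulations (no affected) are reported, not
raised.

## Known limitations

* The PD1 preset's classification rate (above).
* The four-group machinery assumes two-parent pedigrees without
  half-sibling marriages into the same sibship; half-relatives connect only
  through their shared biological parent.
* No inbreeding-coefficient computation, no GEDCOM input, no graphical
  pedigree rendering, and no population incidence/prevalence
  standardization — the reference cohorts themselves lack the registry
  microdata those would need.
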