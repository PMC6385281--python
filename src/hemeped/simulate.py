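"""Forward-time simulator of the imprinting + mother-son microchimerism
segregation model.

The model combines two mechanisms:

* **Parental genomic imprinting** of a susceptibility allele.  A carrier
  parent transmits the allele to each child with probability 1/2.  Under
  *maternal* imprinting the maternally transmitted copy is silenced, so the
  allele is expressed only when it arrives from the father (and conversely
  under *paternal* imprinting); ``both`` expresses either copy and ``none``
  expresses neither.  An optional ``expression_leak`` lets a silenced copy
  express anyway with the given probability (1.0 makes expression
  origin-independent — the "merged letters" limit).

* **Mother-son microchimerism.**  Mothers accumulate microchimeric load
  units ("letters", A-G): every *carrier male* fetus induces one unit
  (capped at ``letters_cap``).  Each child receives the mother's pre-birth
  accumulated units — sons as strongly expressed units, daughters as weakly
  expressed units when ``daughter_transfer="weak"`` (at
  ``weak_unit_weight`` per unit), or at full weight when ``"equal"``.
  Because the units a daughter receives seed her own transferable pool, load
  accumulates down matrilines (anticipation).

Disease manifests in individuals whose allele is expressed *and* whose
weighted unit load reaches ``disease_threshold``; expressed carriers below
the threshold are silent bystanders.  Onset age falls linearly with load
(anticipation in onset).

``inbreeding_mode="one-pedigree"`` grows a single connected multi-generation
pedigree with mostly within-pedigree marriages (a Faroese-like isolate);
``"nuclear-families"`` grows many small independent families whose spouses
are all unrelated founders (a Norway/Denmark-like collection).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from hemeped.pedigree import (
    AFFECTED,
    FEMALE,
    MALE,
    UNAFFECTED,
    Individual,
    Pedigree,
    write_pedigree,
)

MATERNAL = "maternal"
PATERNAL = "paternal"
BOTH = "both"
NONE_MODE = "none"

_MODES = (MATERNAL, PATERNAL, BOTH, NONE_MODE)

#: default diagnosis pleiotropy: the Faroese LPD proband frequencies
DEFAULT_DIAGNOSES = {
    "C81": 19,      # HL
    "C82": 14,      # FL
    "C83.3": 34,    # DLBCL
    "C84": 6,       # TNHL
    "C85.9": 25,    # NHL NOS
    "C88": 2,       # WA
    "C90": 50,      # MM
    "C91.0": 16,    # ALL
    "C91.1": 50,    # CLL
    "C91.3": 2,     # PLL
    "C91.4": 1,     # HCL
}


@dataclass
class SimulationConfig:
    """All knobs of the segregation simulator (defaults: Faroese-like PD1).

    ``founder_carrier_rate`` is the allele frequency among pedigree founders
    and immigrant spouses; ``mean_sibship`` the Poisson mean of completed
    sibship sizes; ``within_mating_fraction`` the probability that a
    pedigree member marries inside the pedigree rather than an immigrant.
    """

    seed: int = 0
    generations: int = 5
    founder_couples: int = 25
    founder_carrier_rate: float = 0.5
    spouse_carrier_rate: float | None = None  # defaults to founder rate
    mean_sibship: float = 4.0
    sex_ratio: float = 0.5
    imprinting_mode: str = MATERNAL
    expression_leak: float = 0.0
    female_silencing_escape: float = 0.0  # weak expression: silenced copies escape in females
    strong_unit_weight: float = 1.0
    weak_unit_weight: float = 0.5
    letters_cap: int = 7
    founder_unit_mean: float = 1.0  # Poisson baseline load of generation-0 founders
    founder_loaded_fraction: float = 0.0  # if > 0: bimodal founder load instead
    founder_loaded_units: int = 5  # letters carried by a loaded founder
    founder_loaded_carrier_rate: float | None = None  # carrier prob of loaded founders
    immigrant_unit_mean: float = 0.0  # baseline load of later immigrant spouses
    disease_threshold: float = 2.0
    penetrance: float = 1.0  # P(disease | expressed allele, load at threshold)
    penetrance_slope: float = 0.0  # added manifestation prob per unit load above threshold
    daughter_transfer: str = "weak"  # or "equal"
    inbreeding_mode: str = "one-pedigree"  # or "nuclear-families"
    within_mating_fraction: float = 0.85
    immigrant_marriage_fraction: float = 0.5  # P(unmatched man weds an immigrant bride)
    immigrant_marriage_fraction_female: float | None = None  # women, if different
    unit_decay_prob: float = 0.0
    onset_base: float = 70.0
    anticipation_slope: float = 4.0
    onset_sd: float = 8.0
    onset_min: float = 5.0
    diagnosis_distribution: dict[str, float] | None = None

    def __post_init__(self):
        if self.imprinting_mode not in _MODES:
            raise ValueError(f"imprinting_mode must be one of {_MODES}")
        if self.daughter_transfer not in ("weak", "equal"):
            raise ValueError("daughter_transfer must be 'weak' or 'equal'")
        if self.inbreeding_mode not in ("one-pedigree", "nuclear-families"):
            raise ValueError("unknown inbreeding_mode")
        if self.generations < 2:
            raise ValueError("need at least 2 generations")
        if self.disease_threshold < 1:
            raise ValueError("disease_threshold must be >= 1")
        for p in (
            self.founder_carrier_rate,
            self.sex_ratio,
            self.expression_leak,
            self.within_mating_fraction,
            self.unit_decay_prob,
            self.penetrance,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def pattern_preset(cls, pattern: str, seed: int = 0, **over) -> "SimulationConfig":
        """Named configurations generating the three patterns of distribution.

        ``PD1``: maternal imprinting with weak daughter transfer and a
        female silencing escape (weak expression in females), in an isolate
        where a carrier-correlated minority of founder matrilines carries a
        heavy microchimeric load and immigrant brides outnumber immigrant
        grooms.  ``PD2``: both imprinting routes active, weak daughter
        transfer, a denser inbred pedigree with a light Poisson founder
        load.  ``PD3``: origin-independent (fully leaky) expression with
        equal transfer to daughters and a ubiquitous baseline load, so
        neither sex nor line is limiting.  Keyword overrides are applied on
        top of the preset.
        """
        base = dict(seed=seed)
        if pattern == "PD1":
            base.update(
                imprinting_mode=MATERNAL,
                daughter_transfer="weak",
                generations=5,
                founder_couples=40,
                mean_sibship=3.2,
                founder_carrier_rate=0.10,
                within_mating_fraction=0.30,
                immigrant_marriage_fraction=0.60,
                immigrant_marriage_fraction_female=0.25,
                penetrance=0.55,
                penetrance_slope=0.05,
                founder_loaded_fraction=0.50,
                founder_loaded_units=5,
                founder_loaded_carrier_rate=0.90,
                female_silencing_escape=0.25,
            )
        elif pattern == "PD2":
            base.update(
                imprinting_mode=BOTH,
                daughter_transfer="weak",
                generations=5,
                founder_couples=75,
                mean_sibship=3.5,
                founder_carrier_rate=0.30,
                within_mating_fraction=0.50,
                penetrance=0.35,
                founder_unit_mean=1.0,
            )
        elif pattern == "PD3":
            base.update(
                imprinting_mode=BOTH,
                daughter_transfer="equal",
                expression_leak=1.0,
                generations=5,
                founder_couples=30,
                mean_sibship=2.4,
                founder_carrier_rate=0.30,
                within_mating_fraction=0.25,
                penetrance=0.04,
                founder_unit_mean=5.0,
                immigrant_unit_mean=5.0,
            )
        else:
            raise ValueError("pattern must be PD1, PD2 or PD3")
        base.update(over)
        return cls(**base)


@dataclass
class SimulationResult:
    pedigree: Pedigree
    truth: pd.DataFrame
    config: SimulationConfig

    @property
    def n_affected(self) -> int:
        return int(self.truth["affected"].sum())


class _Person:
    __slots__ = (
        "iid", "sex", "gen", "family", "father", "mother", "carrier",
        "from_father", "from_mother", "expressed", "strong", "weak",
        "affected", "onset", "birth_year", "diagnosis",
    )

    def __init__(self, iid, sex, gen, family, father=None, mother=None):
        self.iid = iid
        self.sex = sex
        self.gen = gen
        self.family = family
        self.father = father
        self.mother = mother
        self.carrier = False
        self.from_father = False
        self.from_mother = False
        self.expressed = False
        self.strong = 0
        self.weak = 0
        self.affected = False
        self.onset = None
        self.birth_year = None
        self.diagnosis = None

    @property
    def letters(self) -> int:
        return self.strong + self.weak

    def load(self, cfg: SimulationConfig) -> float:
        return (
            self.strong * cfg.strong_unit_weight
            + self.weak * cfg.weak_unit_weight
        )


def transmit_allele(
    father_carrier: bool,
    mother_carrier: bool,
    mode: str,
    rng: np.random.Generator,
    expression_leak: float = 0.0,
    child_sex: str = MALE,
    female_silencing_escape: float = 0.0,
) -> tuple[bool, bool, bool]:
    """One meiosis pair: (received from father, from mother, expressed).

    A carrier parent transmits with probability 1/2; the received copy is
    expressed according to the imprinting mode (paternal copies express
    under maternal imprinting and vice versa).  A silenced copy still leaks
    into expression with probability ``expression_leak`` in either sex, or
    ``female_silencing_escape`` in daughters — the weak, partial expression
    the model attributes to females.
    """
    from_father = bool(father_carrier and rng.random() < 0.5)
    from_mother = bool(mother_carrier and rng.random() < 0.5)
    escape = (
        female_silencing_escape if child_sex == FEMALE else 0.0
    )
    escape = max(escape, expression_leak)
    expressed = False
    for origin, got in ((PATERNAL, from_father), (MATERNAL, from_mother)):
        if not got:
            continue
        if mode == BOTH:
            active = True
        elif mode == MATERNAL:
            active = origin == PATERNAL  # maternal copy silenced
        elif mode == PATERNAL:
            active = origin == MATERNAL  # paternal copy silenced
        else:
            active = False
        if not active and escape > 0 and rng.random() < escape:
            active = True
        expressed = expressed or active
    return from_father, from_mother, expressed


def update_microchimerism(
    pool: int,
    child_sex: str,
    child_carrier: bool,
    cfg: SimulationConfig,
) -> tuple[int, int, int]:
    """One birth: (units to child strong, units to child weak, new pool).

    The child receives the mother's pre-birth pool — sons as strong units,
    daughters as weak units under ``daughter_transfer="weak"`` — and a
    carrier male fetus then induces one more unit in the mother (capped).
    """
    if child_sex == MALE or cfg.daughter_transfer == "equal":
        strong, weak = pool, 0
    else:
        strong, weak = 0, pool
    if child_sex == MALE and child_carrier:
        pool = min(pool + 1, cfg.letters_cap)
    return strong, weak, pool


def manifest(
    expressed: bool, load: float, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[bool, float | None]:
    """Affection status and onset age from expression state and unit load.

    Individuals who meet the genetic conditions manifest with probability
    ``penetrance`` at threshold load, rising by ``penetrance_slope`` per unit
    load above the threshold (the severity/anticipation gradient); the rest
    stay silent bystanders.
    """
    susceptible = bool(expressed and load >= cfg.disease_threshold)
    p_man = min(
        1.0,
        cfg.penetrance
        + cfg.penetrance_slope * max(0.0, load - cfg.disease_threshold),
    )
    affected = susceptible and (p_man >= 1.0 or rng.random() < p_man)
    if not affected:
        return False, None
    onset = cfg.onset_base - cfg.anticipation_slope * load
    onset += rng.normal(0.0, cfg.onset_sd)
    return True, float(max(cfg.onset_min, round(onset)))


def _draw_diagnosis(cfg: SimulationConfig, rng: np.random.Generator) -> str:
    dist = cfg.diagnosis_distribution or DEFAULT_DIAGNOSES
    codes = sorted(dist)
    w = np.array([dist[c] for c in codes], dtype=float)
    return codes[rng.choice(len(codes), p=w / w.sum())]


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the forward-time model and return pedigree + ground truth.

    Reproducible under a fixed config (single seeded generator, deterministic
    iteration order).  A run with no affected individuals is reported in the
    result, not an error.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    spouse_rate = (
        cfg.founder_carrier_rate
        if cfg.spouse_carrier_rate is None
        else cfg.spouse_carrier_rate
    )
    nuclear = cfg.inbreeding_mode == "nuclear-families"

    people: list[_Person] = []

    def add(sex, gen, family, father=None, mother=None) -> _Person:
        p = _Person(len(people) + 1, sex, gen, family, father, mother)
        p.birth_year = 1880 + 25 * gen
        people.append(p)
        return p

    def add_founder(sex, gen, family, rate) -> _Person:
        p = add(sex, gen, family)
        # baseline microchimeric load brought in from outside the pedigree
        if gen == 0 and cfg.founder_loaded_fraction > 0:
            units = (
                cfg.founder_loaded_units
                if rng.random() < cfg.founder_loaded_fraction
                else 0
            )
        else:
            mean = cfg.founder_unit_mean if gen == 0 else cfg.immigrant_unit_mean
            units = int(rng.poisson(mean)) if mean > 0 else 0
        units = min(units, cfg.letters_cap)
        if sex == MALE or cfg.daughter_transfer == "equal":
            p.strong = units
        else:
            p.weak = units
        # microchimeric load certifies past carrier fetuses, so loaded
        # founders sit in allele-segregating families
        if units > 0 and cfg.founder_loaded_carrier_rate is not None:
            rate = cfg.founder_loaded_carrier_rate
        p.carrier = bool(rng.random() < rate)
        if p.carrier:
            # founder's transmitting-parent sex is unobserved: uniform
            if rng.random() < 0.5:
                p.from_father = True
            else:
                p.from_mother = True
            mode = cfg.imprinting_mode
            esc = cfg.expression_leak
            if sex == FEMALE:
                esc = max(esc, cfg.female_silencing_escape)
            silenced_ok = rng.random() < esc
            if mode == BOTH:
                expressed = True
            elif mode == MATERNAL:
                expressed = p.from_father or silenced_ok
            elif mode == PATERNAL:
                expressed = p.from_mother or silenced_ok
            else:
                expressed = silenced_ok
            p.expressed = expressed
        p.affected, p.onset = manifest(p.expressed, p.load(cfg), cfg, rng)
        if p.affected:
            p.diagnosis = _draw_diagnosis(cfg, rng)
        return p

    couples: list[tuple[_Person, _Person]] = []
    for f in range(cfg.founder_couples):
        fam = f"F{f + 1}" if nuclear else "F1"
        h = add_founder(MALE, 0, fam, cfg.founder_carrier_rate)
        w = add_founder(FEMALE, 0, fam, cfg.founder_carrier_rate)
        couples.append((h, w))

    for gen in range(1, cfg.generations + 1):
        children: list[_Person] = []
        for fa, mo in couples:
            n = int(rng.poisson(cfg.mean_sibship))
            pool = mo.letters
            if cfg.unit_decay_prob > 0 and pool > 0:
                pool -= int(rng.binomial(pool, cfg.unit_decay_prob))
            for bi in range(n):
                sex = MALE if rng.random() < cfg.sex_ratio else FEMALE
                c = add(sex, gen, fa.family, father=fa, mother=mo)
                c.birth_year += bi  # sibs one year apart in birth order
                c.from_father, c.from_mother, c.expressed = transmit_allele(
                    fa.carrier, mo.carrier, cfg.imprinting_mode, rng,
                    cfg.expression_leak, sex, cfg.female_silencing_escape,
                )
                c.carrier = c.from_father or c.from_mother
                c.strong, c.weak, pool = update_microchimerism(
                    pool, sex, c.carrier, cfg
                )
                c.affected, c.onset = manifest(
                    c.expressed, c.load(cfg), cfg, rng
                )
                if c.affected:
                    c.diagnosis = _draw_diagnosis(cfg, rng)
                children.append(c)
        if gen == cfg.generations:
            break
        couples = _pair_off(children, cfg, rng, spouse_rate, add_founder)

    truth = pd.DataFrame(
        {
            "iid": [str(p.iid) for p in people],
            "sex": [p.sex for p in people],
            "generation": [p.gen for p in people],
            "carrier": [p.carrier for p in people],
            "from_father": [p.from_father for p in people],
            "from_mother": [p.from_mother for p in people],
            "expressed": [p.expressed for p in people],
            "strong_units": [p.strong for p in people],
            "weak_units": [p.weak for p in people],
            "load": [p.load(cfg) for p in people],
            "affected": [p.affected for p in people],
            "onset_age": [p.onset for p in people],
        }
    )
    individuals = [
        Individual(
            id=str(p.iid),
            family_id=p.family,
            sex=p.sex,
            father_id=None if p.father is None else str(p.father.iid),
            mother_id=None if p.mother is None else str(p.mother.iid),
            affected=AFFECTED if p.affected else UNAFFECTED,
            diagnosis=p.diagnosis,
            birth_year=p.birth_year,
            onset_year=None
            if p.onset is None
            else int(p.birth_year + p.onset),
        )
        for p in people
    ]
    return SimulationResult(Pedigree(individuals), truth, cfg)


def _pair_off(children, cfg, rng, spouse_rate, add_founder):
    """Form the next generation's couples.

    In one-pedigree mode a ``within_mating_fraction`` share of members marry
    inside the pedigree (avoiding full sibs); everyone left over — of either
    sex, so neither parental side is systematically kin-poor — weds an
    immigrant founder spouse with probability
    ``immigrant_marriage_fraction``.  With the default fraction of 1/2 the
    number of couples is half the generation size regardless of the
    within-mating level.
    """
    singles = list(children)
    rng.shuffle(singles)
    nuclear = cfg.inbreeding_mode == "nuclear-families"
    couples = []
    used: set[int] = set()
    for p in singles:
        if p.iid in used:
            continue
        used.add(p.iid)
        partner = None
        if not nuclear and rng.random() < cfg.within_mating_fraction:
            for q in singles:
                if q.iid in used or q.sex == p.sex:
                    continue
                if q.father is p.father and q.mother is p.mother:
                    continue  # no full-sib marriage
                partner = q
                used.add(q.iid)
                break
        if partner is None:
            imf = cfg.immigrant_marriage_fraction
            if p.sex == FEMALE and cfg.immigrant_marriage_fraction_female is not None:
                imf = cfg.immigrant_marriage_fraction_female
            if rng.random() >= imf:
                continue  # stays unmarried
            partner = add_founder(
                FEMALE if p.sex == MALE else MALE, p.gen, p.family, spouse_rate
            )
        couples.append((p, partner) if p.sex == MALE else (partner, p))
    return couples


# ---------------------------------------------------------------------------
# output files


def write_outputs(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write PED + phenotype + ground-truth TSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": outdir / "pedigree.ped",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_pedigree(result.pedigree, paths["ped"], paths["phenotypes"])
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
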