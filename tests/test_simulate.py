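"""Forward-time imprinting + microchimerism simulator."""

import numpy as np
import pandas as pd
import pytest

from hemeped.pedigree import AFFECTED, FEMALE, MALE, read_pedigree
from hemeped.simulate import (
    SimulationConfig,
    manifest,
    simulate,
    transmit_allele,
    update_microchimerism,
    write_outputs,
)


class TestConfigValidation:
    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(imprinting_mode="sideways")

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(founder_carrier_rate=1.5)

    def test_threshold_must_be_at_least_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(disease_threshold=0.5)

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig.pattern_preset("PD9")


class TestTransmitAllele:
    def test_non_carrier_parents_never_transmit(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ff, fm, expr = transmit_allele(False, False, "maternal", rng)
            assert not ff and not fm and not expr

    def test_maternal_mode_expresses_paternal_copy_only(self):
        rng = np.random.default_rng(1)
        saw_paternal = saw_maternal = False
        for _ in range(500):
            ff, fm, expr = transmit_allele(True, True, "maternal", rng)
            if ff and not fm:
                assert expr
                saw_paternal = True
            if fm and not ff:
                assert not expr
                saw_maternal = True
        assert saw_paternal and saw_maternal

    def test_female_escape_lets_silenced_copy_through(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(800):
            ff, fm, expr = transmit_allele(
                False, True, "maternal", rng,
                child_sex=FEMALE, female_silencing_escape=1.0,
            )
            if fm:
                assert expr
                hits += 1
        assert hits > 0

    def test_transmission_frequency_is_one_half(self):
        # carrier x non-carrier matings; binomial 99% CI over >= 10,000 draws
        rng = np.random.default_rng(3)
        n = 20_000
        got = sum(
            transmit_allele(True, False, "both", rng)[0] for _ in range(n)
        )
        se = (0.25 / n) ** 0.5
        assert abs(got / n - 0.5) < 2.58 * se


class TestMicrochimerism:
    def test_first_carrier_son_receives_nothing_then_induces(self):
        cfg = SimulationConfig()
        s1, w1, pool = update_microchimerism(0, MALE, True, cfg)
        assert (s1, w1) == (0, 0) and pool == 1
        s2, w2, pool = update_microchimerism(pool, MALE, False, cfg)
        assert (s2, w2) == (1, 0) and pool == 1  # non-carrier son: no induction

    def test_daughter_receives_weak_units_under_weak_transfer(self):
        cfg = SimulationConfig(daughter_transfer="weak")
        s, w, pool = update_microchimerism(4, FEMALE, True, cfg)
        assert (s, w) == (0, 4) and pool == 4  # daughters never induce

    def test_equal_transfer_gives_daughters_full_weight(self):
        cfg = SimulationConfig(daughter_transfer="equal")
        s, w, _ = update_microchimerism(4, FEMALE, False, cfg)
        assert (s, w) == (4, 0)

    def test_pool_capped_at_letters_cap(self):
        cfg = SimulationConfig(letters_cap=3)
        pool = 0
        for _ in range(10):
            _, _, pool = update_microchimerism(pool, MALE, True, cfg)
        assert pool == 3


class TestManifest:
    def test_threshold_rule(self):
        cfg = SimulationConfig(disease_threshold=2.0)
        rng = np.random.default_rng(0)
        affected, onset = manifest(True, 2.0, cfg, rng)
        assert affected and onset is not None
        assert manifest(True, 1.0, cfg, rng) == (False, None)   # silent bystander
        assert manifest(False, 5.0, cfg, rng) == (False, None)  # unexpressed carrier

    def test_onset_falls_with_load(self):
        cfg = SimulationConfig(onset_sd=0.0, onset_base=70, anticipation_slope=4)
        rng = np.random.default_rng(0)
        _, o2 = manifest(True, 2.0, cfg, rng)
        _, o6 = manifest(True, 6.0, cfg, rng)
        assert o6 == o2 - 16


class TestSimulate:
    def test_fixed_seed_reproducible_and_outputs_byte_identical(self, tmp_path):
        cfg = SimulationConfig.pattern_preset("PD2", seed=9, founder_couples=10)
        a, b = simulate(cfg), simulate(cfg)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pa = write_outputs(a, tmp_path / "a")
        pb = write_outputs(b, tmp_path / "b")
        for k in pa:
            assert pa[k].read_bytes() == pb[k].read_bytes()

    def test_mode_none_without_escape_has_no_affected(self):
        cfg = SimulationConfig(
            seed=4, imprinting_mode="none", generations=4, founder_couples=20,
            founder_unit_mean=3.0,
        )
        assert simulate(cfg).n_affected == 0

    def test_outputs_reload_as_valid_pedigree(self, tmp_path):
        cfg = SimulationConfig.pattern_preset("PD2", seed=2, founder_couples=10)
        res = simulate(cfg)
        paths = write_outputs(res, tmp_path)
        ped = read_pedigree(paths["ped"], paths["phenotypes"])
        assert len(ped) == len(res.pedigree)
        assert ped.affected_ids() == res.pedigree.affected_ids()
        for iid in ped.affected_ids():
            assert ped[iid].diagnosis is not None

    def test_strict_maternal_mode_affected_all_paternally_transmitted(self):
        cfg = SimulationConfig(
            seed=11, imprinting_mode="maternal", generations=5,
            founder_couples=30, mean_sibship=3.0, founder_carrier_rate=0.3,
            founder_unit_mean=3.0, within_mating_fraction=0.5,
        )
        res = simulate(cfg)
        aff = res.truth[res.truth["affected"]]
        # founders' transmitting parents are unobserved; check non-founders
        founder_ids = {i.id for i in res.pedigree if i.is_founder}
        aff = aff[~aff["iid"].isin(founder_ids)]
        assert len(aff) > 20
        assert aff["from_father"].all()

    def test_mother_pool_non_decreasing_along_births(self):
        cfg = SimulationConfig.pattern_preset("PD2", seed=6, founder_couples=15)
        res = simulate(cfg)
        truth = res.truth.set_index("iid")
        by_couple: dict[tuple, list] = {}
        for ind in res.pedigree:
            if ind.father_id and ind.mother_id:
                by_couple.setdefault((ind.father_id, ind.mother_id), []).append(ind)
        for kids in by_couple.values():
            kids.sort(key=lambda i: (i.birth_year, i.id))
            received = [
                truth.loc[k.id, "strong_units"] + truth.loc[k.id, "weak_units"]
                for k in kids
            ]
            assert received == sorted(received)

    def test_nuclear_mode_families_are_disconnected(self):
        cfg = SimulationConfig(
            seed=3, inbreeding_mode="nuclear-families", generations=3,
            founder_couples=8, founder_carrier_rate=0.5, founder_unit_mean=2.0,
        )
        ped = simulate(cfg).pedigree
        for ind in ped:
            for p in ped.parents(ind.id):
                assert ped[p].family_id == ind.family_id

    def test_extinct_run_reports_zero_not_error(self):
        cfg = SimulationConfig(
            seed=0, generations=2, founder_couples=2, founder_carrier_rate=0.0,
        )
        assert simulate(cfg).n_affected == 0

    def test_affected_get_diagnoses_from_pleiotropy_distribution(self):
        cfg = SimulationConfig.pattern_preset("PD2", seed=8, founder_couples=30)
        res = simulate(cfg)
        codes = {
            i.diagnosis for i in res.pedigree if i.affected == AFFECTED
        }
        assert codes and codes <= set(
            __import__("hemeped.simulate", fromlist=["DEFAULT_DIAGNOSES"]).DEFAULT_DIAGNOSES
        )
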