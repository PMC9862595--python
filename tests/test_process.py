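"""Unit-operation balances: frozen hand-computed oracles and invariants.

Per-stage expected values are on a 1 t dry-feed basis and were computed by
hand from the stage definitions (e.g. evaporation on the EUC base: liquor
water = 6 - 0.822 + 2.877 = 8.055 t, final water = 116.58 kg sugar / 200 g/L
= 0.5829 t, so 7.4721 t evaporated and 7.4721/2.6 = 2.8739 t steam).
"""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bioref as br
from bioref.process import ProcessStream

EUC_SUGAR_PER_TON = 1807.0 / 0.31 / 50.0 / 1000.0  # t sugar / t dry feed


def euc_params(builtins):
    return builtins["euc_without_acetate"].pretreatment


class TestAutohydrolysis:
    @pytest.mark.parametrize(
        "name,dry_solid", [("euc_without_acetate", 0.822), ("scb_without_acetate", 0.650)]
    )
    def test_residual_solid_split(self, builtins, name, dry_solid):
        cfg = builtins[name]
        stage = br.autohydrolysis(1.0, cfg.feedstock, cfg.pretreatment)
        solid, liquor = stage.outputs
        assert solid.solids == pytest.approx(dry_solid)
        assert solid.water == pytest.approx(dry_solid)  # 50 % moisture
        assert liquor.solids == pytest.approx(1.0 - dry_solid)

    def test_liquor_water_closes_the_balance(self, builtins):
        cfg = builtins["euc_without_acetate"]
        stage = br.autohydrolysis(1.0, cfg.feedstock, cfg.pretreatment)
        _, liquor = stage.outputs
        assert liquor.water == pytest.approx(6.0 - 0.822)
        assert stage.mass_closure() < 1e-12

    def test_heating_duty_from_slurry_sensible_heat(self, builtins):
        cfg = builtins["euc_without_acetate"]
        stage = br.autohydrolysis(1.0, cfg.feedstock, cfg.pretreatment)
        # 7 t slurry * 4 kJ/kgK * 155 K = 4340 MJ per dry t
        assert stage.steam_demand_MJ == pytest.approx(7.0 * 1000 * 4.0 * 155 / 1000)

    def test_degenerate_and_invalid_inputs(self, builtins):
        cfg = builtins["euc_without_acetate"]
        params = cfg.pretreatment.model_copy(update={"solid_yield": 1.0})
        with pytest.raises(ValueError):
            br.autohydrolysis(1.0, cfg.feedstock, params)
        with pytest.raises(ValueError):
            br.autohydrolysis(-1.0, cfg.feedstock, cfg.pretreatment)


class TestWashing:
    def test_wash_water_proportional_to_dry_pulp(self, builtins):
        params = euc_params(builtins)
        solid = ProcessStream("residual_solid", "solid", {"cellulose_lignin": 0.822}, water=0.822)
        stage = br.wash_solids(solid, params)
        assert stage.outputs[1].water == pytest.approx(2.877)
        assert stage.consumables["water_m3"] == pytest.approx(2.877)

    def test_zero_pulp_and_zero_factor(self, builtins):
        params = euc_params(builtins)
        empty = ProcessStream("residual_solid", "solid")
        assert br.wash_solids(empty, params).outputs[1].water == 0.0
        dry = ProcessStream("residual_solid", "solid", {"cellulose_lignin": 1.0}, water=1.0)
        nowash = params.model_copy(update={"wash_water_per_ton_pulp": 0.0})
        assert br.wash_solids(dry, nowash).outputs[1].water == 0.0

    def test_rejects_liquid_stream(self, builtins):
        liquid = ProcessStream("spent_liquor", "liquid", water=1.0)
        with pytest.raises(ValueError):
            br.wash_solids(liquid, euc_params(builtins))


class TestEvaporation:
    def test_euc_base_case_hand_oracle(self):
        liquor = ProcessStream(
            "liquor", "liquid",
            {"hemicellulosic_sugars": EUC_SUGAR_PER_TON, "other_solubles": 0.178 - EUC_SUGAR_PER_TON},
            water=8.055,
        )
        stage = br.evaporate(liquor, 200.0, 2.6)
        concentrated, condensate = stage.outputs
        assert concentrated.water == pytest.approx(0.5829032, abs=1e-6)
        assert condensate.water == pytest.approx(7.4720968, abs=1e-6)
        assert stage.steam_demand_MJ / 2244.0 == pytest.approx(2.8738834, abs=1e-6)
        assert stage.mass_closure() < 1e-12

    def test_infinite_steam_economy_limit(self):
        liquor = ProcessStream("liquor", "liquid", {"glucose": 0.1}, water=2.0)
        stage = br.evaporate(liquor, 200.0, 1e12)
        assert stage.steam_demand_MJ == pytest.approx(0.0, abs=1e-6)

    def test_already_at_target_is_a_warned_noop(self):
        liquor = ProcessStream("liquor", "liquid", {"glucose": 0.2}, water=1.0)  # 200 g/L
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            stage = br.evaporate(liquor, 200.0, 2.6)
        assert caught
        assert stage.outputs[1].water == 0.0

    def test_zero_sugars_rejected(self):
        liquor = ProcessStream("liquor", "liquid", {"other_solubles": 0.1}, water=1.0)
        with pytest.raises(ValueError):
            br.evaporate(liquor, 200.0, 2.6)


class TestPostHydrolysis:
    def test_euc_profile_sets_xylose_share(self, builtins):
        cfg = builtins["euc_without_acetate"]
        liquor = ProcessStream("liquor", "liquid", {"hemicellulosic_sugars": 0.1165806}, water=0.5829)
        stage = br.post_hydrolyze(liquor, 0.01, 121.0, 60.0, cfg.liquor_composition)
        out = stage.outputs[0]
        assert out.components["xylose"] == pytest.approx(0.1165806 * 153.0 / 172.3, rel=1e-9)
        assert out.sugar_mass() == pytest.approx(0.1165806)

    def test_scb_profile_sets_cellobiose_share(self, builtins):
        cfg = builtins["scb_without_acetate"]
        liquor = ProcessStream("liquor", "liquid", {"hemicellulosic_sugars": 1.0}, water=5.0)
        stage = br.post_hydrolyze(liquor, 0.01, 121.0, 60.0, cfg.liquor_composition)
        assert stage.outputs[0].components["cellobiose"] == pytest.approx(3.40 / 171.7, rel=1e-9)

    def test_acid_dose_is_weight_fraction_of_liquor(self, builtins):
        cfg = builtins["euc_without_acetate"]
        liquor = ProcessStream("liquor", "liquid", {"hemicellulosic_sugars": 0.1}, water=0.6)
        stage = br.post_hydrolyze(liquor, 0.01, 121.0, 60.0, cfg.liquor_composition)
        assert stage.consumables["h2so4_t"] == pytest.approx(0.007)  # 7 kg on 0.7 t

    def test_acid_outside_envelope_warns(self, builtins):
        cfg = builtins["euc_without_acetate"]
        liquor = ProcessStream("liquor", "liquid", {"hemicellulosic_sugars": 0.1}, water=0.6)
        with pytest.warns(UserWarning):
            br.post_hydrolyze(liquor, 0.2, 121.0, 60.0, cfg.liquor_composition)


class TestMicrobialCulture:
    def test_without_acetate_yields_on_sugars(self, builtins):
        conv = builtins["euc_without_acetate"].conversion
        liquor = ProcessStream("liquor", "liquid", {"hemicellulosic_sugars": 5829.0322580645}, water=29145.0)
        stage = br.microbial_culture(liquor, conv)
        broth = stage.outputs[0]
        assert broth.components["la"] == pytest.approx(1807.0)
        assert broth.components["phb"] == pytest.approx(174.871, abs=1e-3)
        assert stage.consumables["acetate_t"] == 0.0

    def test_with_acetate_doubles_the_carbon_source(self, builtins):
        conv = builtins["euc_with_acetate"].conversion
        liquor = ProcessStream("liquor", "liquid", {"hemicellulosic_sugars": 5829.0322580645}, water=29145.0)
        stage = br.microbial_culture(liquor, conv)
        broth = stage.outputs[0]
        assert stage.consumables["acetate_t"] == pytest.approx(5829.0322580645)
        assert broth.components["la"] == pytest.approx(0.07 * 11658.064516129, abs=1e-6)
        assert broth.components["phb"] == pytest.approx(0.09 * 11658.064516129, abs=1e-6)

    def test_zero_sugars_zero_products(self, builtins):
        conv = builtins["euc_without_acetate"].conversion
        liquor = ProcessStream("liquor", "liquid", {"hemicellulosic_sugars": 0.0}, water=1.0)
        stage = br.microbial_culture(liquor, conv)
        assert stage.outputs[0].components["la"] == 0.0
        assert stage.consumables["acetate_t"] == 0.0

    def test_full_acetate_fraction_rejected(self, builtins):
        conv = builtins["euc_with_acetate"].conversion.model_copy(
            update={"acetate_fraction_of_carbon": 1.0}
        )
        liquor = ProcessStream("liquor", "liquid", {"hemicellulosic_sugars": 1.0}, water=1.0)
        with pytest.raises(ValueError):
            br.microbial_culture(liquor, conv)


class TestRecovery:
    def _culture_stage(self, la_t, phb_t):
        broth = ProcessStream("culture_broth", "liquid", {"la": la_t, "phb": phb_t}, water=10.0)
        return br.StageResult(stage="microbial_culture", outputs=[broth], input_mass=broth.total_mass)

    def test_recovery_cost_and_energy_factors(self, builtins):
        params = builtins["euc_without_acetate"].recovery
        stage = br.recover_products(self._culture_stage(1807.0, 174.9), params)
        assert stage.consumables["phb_recovery_kg"] == pytest.approx(174_900.0)
        assert stage.steam_demand_MJ == pytest.approx(349_800.0)  # 2 MJ/kg PHB
        assert stage.electricity_demand_kWh == pytest.approx(14_456_000.0)  # 8 kWh/kg LA

    def test_zero_products_zero_cost(self, builtins):
        params = builtins["euc_without_acetate"].recovery
        stage = br.recover_products(self._culture_stage(0.0, 0.0), params)
        assert stage.steam_demand_MJ == 0.0
        assert stage.electricity_demand_kWh == 0.0


class TestPyrolysis:
    @pytest.mark.parametrize(
        "dry_kg,char_kg,tar_kg",
        [(822.0, 287.7, 205.5), (650.0, 227.5, 162.5)],
    )
    def test_per_ton_product_split(self, builtins, dry_kg, char_kg, tar_kg):
        params = builtins["euc_without_acetate"].pyrolysis
        solid = ProcessStream("washed_solid", "solid", {"cellulose_lignin": dry_kg / 1000.0}, water=dry_kg / 1000.0)
        stage = br.pyrolyze(solid, params)
        assert stage.outputs[0].components["char"] * 1000 == pytest.approx(char_kg)
        assert stage.outputs[1].components["tar"] * 1000 == pytest.approx(tar_kg)
        assert stage.outputs[2].components["gas"] * 1000 == pytest.approx(tar_kg)
        assert stage.mass_closure() < 1e-12

    def test_base_case_energy_self_supplied_by_gases(self, builtins):
        params = builtins["euc_without_acetate"].pyrolysis
        solid = ProcessStream("washed_solid", "solid", {"cellulose_lignin": 0.822}, water=0.822)
        stage = br.pyrolyze(solid, params)
        assert stage.steam_demand_MJ == 0.0

    def test_without_self_supply_demand_is_positive(self, builtins):
        params = builtins["euc_without_acetate"].pyrolysis.model_copy(
            update={"gas_self_supply": False}
        )
        solid = ProcessStream("washed_solid", "solid", {"cellulose_lignin": 0.822}, water=0.822)
        stage = br.pyrolyze(solid, params)
        # drying latent heat + specific pyrolysis energy
        assert stage.steam_demand_MJ == pytest.approx(0.822 * 2260.0 + 1.35 * 822.0)

    def test_zero_solid_and_bad_yields(self, builtins):
        params = builtins["euc_without_acetate"].pyrolysis
        empty = ProcessStream("washed_solid", "solid")
        stage = br.pyrolyze(empty, params)
        assert all(s.total_mass == 0.0 for s in stage.outputs)
        bad = params.model_copy(update={"loss_yield": 0.10})
        with pytest.raises(ValueError):
            br.pyrolyze(ProcessStream("s", "solid", {"x": 1.0}), bad)


class TestBoiler:
    @pytest.mark.parametrize("dry_t,kwh", [(0.822, 2740.0), (0.650, 2166.667)])
    def test_reference_energy_yields(self, dry_t, kwh):
        assert br.boiler_energy(dry_t, 15.0, 0.8) == pytest.approx(kwh, abs=1e-3)

    @given(
        mass=st.floats(0.0, 1e6),
        lhv=st.floats(0.0, 40.0),
        eff=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_in_every_factor(self, mass, lhv, eff):
        base = br.boiler_energy(mass, lhv, eff)
        assert br.boiler_energy(2.0 * mass, lhv, eff) == pytest.approx(2.0 * base, rel=1e-9, abs=1e-9)
        assert base == pytest.approx(mass * 1000.0 * lhv * eff / 3.6, rel=1e-12, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            br.boiler_energy(1.0, -1.0, 0.8)
        with pytest.raises(ValueError):
            br.boiler_energy(1.0, 15.0, 1.2)


class TestRunScenario:
    def test_products_scale_linearly_with_feed(self, builtins, evaluated):
        cfg = builtins["euc_without_acetate"]
        base = evaluated["euc_without_acetate"][0]
        double = br.run_scenario(br.set_by_path(cfg, "economics.annual_feed_t", 100_000.0))
        for key in base.products:
            assert double.products[key] == pytest.approx(2.0 * base.products[key], rel=1e-12)

    def test_acetate_only_affects_the_liquor_line(self, evaluated):
        woa = evaluated["euc_without_acetate"][0]
        wa = evaluated["euc_with_acetate"][0]
        assert wa.products["char"] == woa.products["char"]
        assert wa.products["tar"] == woa.products["tar"]

    def test_evaporation_is_the_largest_steam_consumer(self, evaluated):
        for result, _ in evaluated.values():
            steam = {name: s.steam_demand_MJ for name, s in result.stages.items()}
            assert max(steam, key=steam.get) == "evaporation"

    def test_zero_feed_gives_zero_products(self, builtins):
        cfg = br.set_by_path(builtins["euc_without_acetate"], "economics.annual_feed_t", 0.0)
        result = br.run_scenario(cfg)
        assert all(v == 0.0 for v in result.products.values())

    def test_invalid_config_rejected_with_stage_context(self, builtins):
        cfg = br.set_by_path(builtins["euc_without_acetate"], "pyrolysis.loss_yield", 0.10)
        with pytest.raises(br.ConfigValidationError):
            br.run_scenario(cfg)

    @pytest.mark.parametrize("seed", range(30))
    def test_mass_conservation_on_random_scenarios(self, seed):
        result = br.run_scenario(br.random_scenario(seed))
        for name, stage in result.stages.items():
            assert stage.mass_closure() < 1e-6, name

    def test_capacities_reported_for_capital_scaling(self, evaluated):
        result = evaluated["euc_without_acetate"][0]
        caps = result.capacities
        assert caps["slurry_t"] == pytest.approx(350_000.0)
        assert caps["pyrolysis_feed_t"] == pytest.approx(41_100.0)
        assert caps["sugars_t"] == pytest.approx(5829.032258, abs=1e-4)
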