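import numpy as np
import pandas as pd
import pytest

from clustercea import SimConfig, generate_cost_items, generate_trial, simulate_dataset
from clustercea.simulate import InpatientModel


class TestStructure:
    def test_default_design_dimensions(self):
        table = generate_trial(SimConfig(seed=1))
        villages = table.villages
        assert len(villages) == 50
        assert table.n_participants == 1299
        assert (villages["arm"] == "intervention").sum() == 25

    def test_stratified_balance_within_every_township(self):
        villages = generate_trial(SimConfig(seed=3)).villages
        counts = villages.groupby(["township", "arm"]).size()
        assert (counts == 5).all()

    def test_waves_at_baseline_and_one_year(self, small_dataset):
        table, _ = small_dataset
        assert set(np.round(table.data["wave_time_years"].unique(), 6)) == {0.0, 1.0}

    def test_deaths_have_no_later_waves(self):
        cfg = SimConfig(seed=5, mortality_year1=0.10)
        table = generate_trial(cfg)
        dead = table.participants.dropna(subset=["death_time_years"])
        assert len(dead) > 0
        assert ((dead["death_time_years"] > 0) & (dead["death_time_years"] < 1)).all()
        waves = table.data[table.data["participant_id"].isin(dead["participant_id"])]
        assert (waves["wave_time_years"] == 0.0).all()


class TestDeterminismAndTruncation:
    def test_same_seed_identical_output(self):
        cfg = SimConfig(seed=11)
        t1, c1 = simulate_dataset(cfg)
        t2, c2 = simulate_dataset(cfg)
        assert t1.data.to_csv(index=False) == t2.data.to_csv(index=False)
        assert c1.to_csv(index=False) == c2.to_csv(index=False)

    def test_different_seed_differs(self):
        a = generate_trial(SimConfig(seed=1)).data
        b = generate_trial(SimConfig(seed=2)).data
        assert not a["sbp"].equals(b["sbp"])

    def test_utilities_truncated(self, small_dataset):
        table, _ = small_dataset
        u = table.data["utility"]
        assert (u <= 1.0).all()
        assert (u >= SimConfig().utility_floor).all()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"icc_sbp": 1.5},
            {"villages_per_township": 9},
            {"prop_female": 1.2},
            {"baseline_sbp_sd": -1.0},
            {"inpatient_cost_effect": -1000.0},
        ],
    )
    def test_inconsistent_config_rejected(self, kwargs):
        with pytest.raises(Exception):
            SimConfig(**kwargs)


class TestCostItems:
    def test_full_zero_inflation_gives_no_inpatient_costs(self):
        inp = {
            k: InpatientModel(p_use_control=0.0, mean_given_use=300.0)
            for k in ("inpatient_stroke", "inpatient_cvd_nonstroke", "inpatient_other")
        }
        cfg = SimConfig(seed=2, inpatient=inp, inpatient_cost_effect=0.0)
        table, items = simulate_dataset(cfg)
        assert not items["category"].str.startswith("inpatient").any()

    def test_program_cost_only_in_intervention_arm(self, small_dataset):
        table, items = small_dataset
        prog = items[items["category"] == "program_component"]
        arm = table.participants.set_index("participant_id")["arm"]
        assert (arm.loc[prog["participant_id"]] == "intervention").all()
        assert (prog["amount"] == SimConfig().program_cost_per_participant).all()

    def test_medication_items_carry_price_quantity_adherence(self, small_dataset):
        _, items = small_dataset
        meds = items[items["category"].str.startswith("med_")]
        assert meds["adherence"].between(0, 1).all()
        assert (meds["quantity"] >= 0).all()
        assert np.allclose(
            meds["amount"], meds["quantity"] * meds["unit_price"] * meds["adherence"]
        )

    def test_equal_arm_parameters_give_null_cost_difference(self):
        # remove every configured arm difference, then the mean per-person
        # cost difference over seeds should be ~0 within Monte-Carlo error
        meds = SimConfig().medications
        for m in meds.values():
            m = m  # uptake equalized below via model_copy
        diffs = []
        for seed in range(40):
            cfg = SimConfig(
                seed=seed,
                program_cost_per_participant=0.0,
                inpatient_cost_effect=0.0,
                medications={
                    k: m.model_copy(
                        update={
                            "uptake_intervention": m.uptake_control,
                            "user_mean_intervention": m.user_mean_control,
                        }
                    )
                    for k, m in meds.items()
                },
                participants_total=1000,
            )
            table, items = simulate_dataset(cfg)
            per = items.groupby("participant_id")["amount"].sum()
            ppl = table.participants.set_index("participant_id")
            per = per.reindex(ppl.index, fill_value=0.0)
            means = per.groupby(ppl["arm"]).mean()
            diffs.append(means["intervention"] - means["control"])
        mean_diff = np.mean(diffs)
        mc_se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(mean_diff) < 3 * mc_se + 1e-9


class TestConfiguredTruths:
    def test_expected_incremental_cost_is_component_sum(self):
        cfg = SimConfig()
        meds = sum(
            m.uptake_intervention * m.user_mean_intervention
            - m.uptake_control * m.user_mean_control
            for m in cfg.medications.values()
        )
        expected = cfg.program_cost_per_participant + meds + cfg.inpatient_cost_effect
        assert cfg.expected_incremental_cost() == pytest.approx(expected)
        # defaults pin the medication component differences
        assert meds == pytest.approx(2.11 + 0.09 + 2.99, abs=1e-9)

    def test_calibrated_config_pins_total_incremental_cost(self):
        cfg = SimConfig.calibrated(target_incremental_cost=23.3)
        assert cfg.expected_incremental_cost() == pytest.approx(23.3)

    def test_null_sbp_effect_recovered_as_zero(self):
        from clustercea.effects import fast_adjusted_delta
        from clustercea.pipeline import participant_frame

        deltas = []
        for seed in range(40):
            cfg = SimConfig(seed=seed, true_effect_sbp=0.0, participants_total=1000)
            table, items = simulate_dataset(cfg)
            frame = participant_frame(table, items)
            deltas.append(fast_adjusted_delta(frame, "sbp_change", "sbp0"))
        mean = np.mean(deltas)
        mc_se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(mean) < 3 * mc_se
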