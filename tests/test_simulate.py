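import math
from statistics import NormalDist

import numpy as np
import pandas as pd
import pytest

from nlcsp import (
    NoduleClass,
    SimulationConfig,
    fit_vdt,
    run_program,
    simulate_cohort,
    summarize_run,
)
from nlcsp.simulate import TrueTrajectory, generate_truth, months_to_days


def single_class_config(cls: NoduleClass, **overrides) -> SimulationConfig:
    fields = dict(
        n_participants=20,
        seed=11,
        class_mix={cls: 1.0},
        volumetric_noise_cv=0.0,
    )
    fields.update(overrides)
    return SimulationConfig(**fields)


class TestConfig:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                n_participants=1, seed=0, class_mix={NoduleClass.no_nodule: 0.5}
            )

    def test_growing_classes_need_vdt_params(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                n_participants=1,
                seed=0,
                class_mix={NoduleClass.aggressive: 1.0},
                vdt_days={},
            )


class TestOpenLoop:
    def test_empty_cohort(self):
        obs, truth = simulate_cohort(
            SimulationConfig(n_participants=0, seed=0, scheduling="open_loop")
        )
        assert obs.empty and truth.empty
        assert "volume_mm3" in obs.columns

    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(n_participants=30, seed=42, scheduling="open_loop")
        obs1, truth1 = simulate_cohort(cfg)
        obs2, truth2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(obs1, obs2)
        pd.testing.assert_frame_equal(truth1, truth2)
        assert obs1.to_csv(index=False) == obs2.to_csv(index=False)

    def test_different_seed_differs(self):
        obs1, _ = simulate_cohort(
            SimulationConfig(n_participants=30, seed=1, scheduling="open_loop")
        )
        obs2, _ = simulate_cohort(
            SimulationConfig(n_participants=30, seed=2, scheduling="open_loop")
        )
        assert not obs1.equals(obs2)

    def test_noise_free_aggressive_follows_exponential_law(self):
        cfg = single_class_config(
            NoduleClass.aggressive, scheduling="open_loop", max_rounds=2
        )
        obs, truth = simulate_cohort(cfg)
        interval = months_to_days(cfg.open_interval_months)
        for nodule_id, grp in obs.groupby("nodule_id"):
            if len(grp) < 2:
                continue
            v = grp.sort_values("scan_date")["volume_mm3"].to_numpy()
            vdt = truth.set_index("nodule_id").loc[nodule_id, "vdt_days"]
            expected_ratio = 2 ** (interval / vdt)
            assert v[1] / v[0] == pytest.approx(expected_ratio, rel=1e-12)

    def test_exponential_law_exact_on_trajectory(self):
        traj = TrueTrajectory(
            participant_id="P",
            nodule_id="P-N1",
            nodule_class=NoduleClass.aggressive,
            baseline_volume_mm3=100.0,
            vdt_days=300.0,
            lobe="RUL",
            spiculation=False,
        )
        assert traj.volume_at(300) / traj.volume_at(0) == pytest.approx(2.0, rel=1e-14)
        assert traj.volume_at(900) / traj.volume_at(600) == pytest.approx(2.0, rel=1e-14)


class TestVDTRecovery:
    def test_noise_free_recovery_is_exact(self):
        cfg = single_class_config(
            NoduleClass.indolent, scheduling="open_loop", max_rounds=4,
            open_interval_months=12,
        )
        obs, truth = simulate_cohort(cfg)
        truth = truth.set_index("nodule_id")
        checked = 0
        for nodule_id, grp in obs.groupby("nodule_id"):
            if len(grp) < 2:
                continue
            grp = grp.sort_values("scan_date")
            days = np.arange(len(grp)) * months_to_days(12)
            recovered = fit_vdt(days, grp["volume_mm3"].to_numpy())
            assert recovered == pytest.approx(truth.loc[nodule_id, "vdt_days"], rel=1e-9)
            checked += 1
        assert checked >= 15

    def test_noisy_recovery_within_tolerance_at_4_scans(self):
        cfg = single_class_config(
            NoduleClass.aggressive,
            n_participants=60,
            seed=5,
            scheduling="open_loop",
            volumetric_noise_cv=0.10,
            max_rounds=4,
            open_interval_months=6,
        )
        obs, truth = simulate_cohort(cfg)
        truth = truth.set_index("nodule_id")
        rel_errors = []
        for nodule_id, grp in obs.groupby("nodule_id"):
            if len(grp) < 4:
                continue
            grp = grp.sort_values("scan_date")
            days = np.arange(len(grp)) * months_to_days(6)
            recovered = fit_vdt(days, grp["volume_mm3"].to_numpy())
            rel_errors.append(
                abs(recovered - truth.loc[nodule_id, "vdt_days"])
                / truth.loc[nodule_id, "vdt_days"]
            )
        assert len(rel_errors) >= 40
        assert np.median(rel_errors) < 0.25
        assert np.mean(np.array(rel_errors) < 0.5) > 0.9


class TestClosedLoop:
    def test_benign_stable_all_reach_category1(self):
        runs = run_program(single_class_config(NoduleClass.benign_stable, max_rounds=8))
        summary = summarize_run(runs)
        assert (summary["final_category"] == 1).all()
        assert not summary["referred"].any()

    def test_aggressive_referred_at_first_measurable_growth(self):
        """Fast-growing nodules are referred via the growing rule at the
        first follow-up whose measured volume change exceeds +25% (a short
        3-month interval may legitimately precede measurable growth)."""
        runs = run_program(single_class_config(NoduleClass.aggressive))
        summary = summarize_run(runs)
        assert summary["referred"].all()
        for run in runs:
            final_traces = [
                t for res in run.reports[-1].nodule_results for t in res.rule_trace
            ]
            assert "followup.growing" in final_traces or any(
                t.startswith("baseline.pancan_band:5") for t in final_traces
            )
            # every earlier follow-up was inside the +/-25% corridor
            for report in run.reports[1:-1]:
                for res in report.nodule_results:
                    # a nodule below the detection limit at baseline surfaces
                    # later as 'new', with no change to measure yet
                    if res.growth.relative_volume_change_pct is not None:
                        assert res.growth.relative_volume_change_pct <= 25.0

    def test_indolent_referred_only_by_slow_growth_rule(self):
        runs = run_program(single_class_config(NoduleClass.indolent, max_rounds=8))
        summary = summarize_run(runs)
        assert summary["referred"].all()
        for run in runs:
            final = run.reports[-1]
            traces = [
                t for res in final.nodule_results for t in res.rule_trace
            ]
            assert "followup.slowly_growing" in traces
            assert "followup.growing" not in traces

    def test_resolving_nodules_exit_management(self):
        runs = run_program(
            single_class_config(NoduleClass.benign_resolving, max_rounds=6)
        )
        summary = summarize_run(runs)
        assert not summary["referred"].any()
        assert (summary["final_category"] == 1).all()

    def test_stability_clock_never_exceeds_elapsed_time(self):
        runs = run_program(
            SimulationConfig(n_participants=40, seed=9, max_rounds=6)
        )
        for run in runs:
            for day, report in zip(run.scan_days, run.reports):
                for res in report.nodule_results:
                    if hasattr(res, "stability_clock_days"):
                        assert res.stability_clock_days <= day

    def test_closed_loop_deterministic(self):
        cfg = SimulationConfig(n_participants=25, seed=123)
        s1 = summarize_run(run_program(cfg))
        s2 = summarize_run(run_program(cfg))
        pd.testing.assert_frame_equal(s1, s2)


class TestSpuriousChangeRate:
    def test_false_change_rate_matches_lognormal_theory(self):
        """With CV 10% multiplicative noise, the probability that a truly
        static nodule's measured volume ratio leaves the [-25%, +25%]
        corridor has a closed form: the log-ratio of two independent
        log-normal measurement errors is normal with variance 2*sigma^2.
        Simulation must agree within Monte-Carlo error — this is the
        quantitative reason the 25% corridor exists."""
        cv = 0.10
        sigma = math.sqrt(math.log(1 + cv * cv))
        log_ratio_sd = math.sqrt(2) * sigma
        nd = NormalDist(0.0, log_ratio_sd)
        p_up = 1 - nd.cdf(math.log(1.25))
        p_down = nd.cdf(math.log(0.75))

        cfg = single_class_config(
            NoduleClass.benign_stable,
            n_participants=4000,
            seed=77,
            scheduling="open_loop",
            volumetric_noise_cv=cv,
            max_rounds=2,
        )
        obs, _ = simulate_cohort(cfg)
        ups = downs = pairs = 0
        for _, grp in obs.groupby("nodule_id"):
            v = grp.sort_values("scan_date")["volume_mm3"].to_numpy()
            if len(v) != 2:
                continue
            pairs += 1
            ratio = v[1] / v[0]
            if ratio > 1.25:
                ups += 1
            elif ratio < 0.75:
                downs += 1
        assert pairs > 3500
        for observed, expected in [(ups / pairs, p_up), (downs / pairs, p_down)]:
            mc_err = 3 * math.sqrt(expected * (1 - expected) / pairs)
            assert abs(observed - expected) < mc_err + 0.005


def test_truth_generation_deterministic():
    cfg = SimulationConfig(n_participants=15, seed=3)
    t1 = generate_truth(cfg)
    t2 = generate_truth(cfg)
    assert t1 == t2
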