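"""Monte Carlo engine, summaries, sensitivity, reporting, config I/O."""

import numpy as np
import pytest

from mprisk import (
    DistributionSpec,
    RiskResult,
    ScenarioConfig,
    ValidationError,
    exceedance_probability,
    percentile,
    run_simulation,
    sensitivity_analysis,
    write_report,
)
from mprisk.synthetic_data import baseline_scenario

from conftest import point, point_receptor, point_scenario


class TestEngineDeterministicCore:
    def test_point_scenario_reproduces_hand_composition(self):
        cfg = point_scenario(n_iterations=5)
        res = run_simulation(cfg)
        c_w = 10.0 * (1.38 * 1e6 * 1e-12 * 1e3) * 0.3 * 0.0025
        add = c_w * 1.95 * 345.0 * 25.0 / (70.0 * 9125.0)
        assert np.all(res.metrics["adult"]["ECR"] == res.metrics["adult"]["ECR"][0])
        assert res.metrics["adult"]["ECR"][0] == pytest.approx(0.014 * add, rel=1e-12)
        assert res.metrics["adult"]["HQ"][0] == pytest.approx(add / 0.02, rel=1e-12)
        # with every input point-valued, any percentile is the deterministic value
        assert percentile(res, "ECR", "adult", 0.95) == pytest.approx(
            0.014 * add, rel=1e-12
        )

    def test_literal_density_unit_scales_mass_by_one_thousand(self):
        res_g = run_simulation(point_scenario(density_unit="g/cm3"))
        res_mg = run_simulation(point_scenario(density_unit="mg/cm3"))
        assert res_g.metrics["adult"]["ECR"][0] == pytest.approx(
            1e3 * res_mg.metrics["adult"]["ECR"][0], rel=1e-12
        )

    def test_ecr_hq_identity_elementwise(self):
        cfg = baseline_scenario(n_iterations=2000, seed=5)
        res = run_simulation(cfg)
        for label in res.receptor_labels():
            np.testing.assert_allclose(
                res.metrics[label]["ECR"],
                0.014 * 0.02 * res.metrics[label]["HQ"],
                rtol=1e-12,
            )
            assert np.all(res.metrics[label]["ECR"] >= 0)

    def test_fixed_seed_is_bit_reproducible(self):
        cfg = baseline_scenario(n_iterations=2000, seed=11)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        for label in a.receptor_labels():
            np.testing.assert_array_equal(
                a.metrics[label]["ECR"], b.metrics[label]["ECR"]
            )
        for k in a.shared_inputs:
            np.testing.assert_array_equal(a.shared_inputs[k], b.shared_inputs[k])

    def test_different_seeds_differ_but_agree_statistically(self):
        q = [
            percentile(
                run_simulation(baseline_scenario(n_iterations=50_000, seed=s)),
                "ECR",
                "adult",
                0.95,
            )
            for s in (101, 202)
        ]
        assert q[0] != q[1]
        assert abs(q[0] - q[1]) / q[0] < 0.05

    def test_receptors_share_concentration_draws(self):
        cfg = baseline_scenario(n_iterations=500, seed=3)
        res = run_simulation(cfg)
        # per-iteration child/adult ECR ratio must not depend on C_w at all:
        # it equals the receptor intake-factor ratio exactly
        ratio = res.metrics["child"]["ECR"] / res.metrics["adult"]["ECR"]
        f_child = (
            res.receptor_inputs["child"]["CR_w"]
            * 6.0
            / (res.receptor_inputs["child"]["BW"] * 2190.0)
        )
        f_adult = (
            res.receptor_inputs["adult"]["CR_w"]
            * 25.0
            / (res.receptor_inputs["adult"]["BW"] * 9125.0)
        )
        np.testing.assert_allclose(ratio, f_child / f_adult, rtol=1e-12)

    def test_scaling_content_scales_every_percentile(self):
        base = baseline_scenario(n_iterations=5000, seed=7)
        from dataclasses import replace

        doubled = replace(
            base,
            dehp_content=DistributionSpec(
                "triangular", {"min": 0.2, "mode": 0.4, "max": 0.6}, label="R"
            ),
        )
        halved = replace(
            base,
            dehp_content=DistributionSpec(
                "triangular", {"min": 0.1, "mode": 0.2, "max": 0.3}, label="R"
            ),
        )
        r2, r1 = run_simulation(doubled), run_simulation(halved)
        for q in (0.05, 0.5, 0.95):
            assert percentile(r2, "ECR", "adult", q) == pytest.approx(
                2.0 * percentile(r1, "ECR", "adult", q), rel=1e-9
            )


class TestSummaries:
    def test_percentile_linear_interpolation(self, rng):
        res = run_simulation(point_scenario(n_iterations=3))
        res.metrics["adult"]["ECR"] = np.arange(1.0, 101.0)
        assert percentile(res, "ECR", "adult", 0.95) == pytest.approx(95.05)
        assert percentile(res, "ECR", "adult", 1.0) == 100.0

    def test_percentile_validates_arguments(self):
        res = run_simulation(point_scenario(n_iterations=3))
        with pytest.raises(ValidationError, match="metric"):
            percentile(res, "XYZ", "adult", 0.5)
        with pytest.raises(ValidationError, match="receptor"):
            percentile(res, "ECR", "nobody", 0.5)
        with pytest.raises(ValidationError, match="q"):
            percentile(res, "ECR", "adult", 1.5)

    def test_exceedance_probability_counts_strictly_above(self):
        res = run_simulation(point_scenario(n_iterations=4))
        res.metrics["adult"]["ECR"] = np.array([1.0, 2.0, 3.0, 4.0])
        assert exceedance_probability(res, "ECR", "adult", 2.5) == 0.5
        assert exceedance_probability(res, "ECR", "adult", 0.0) == 1.0
        assert exceedance_probability(res, "ECR", "adult", 10.0) == 0.0


class TestSensitivity:
    def test_single_varying_input_gets_full_contribution(self):
        cfg = point_scenario(n_iterations=400)
        from dataclasses import replace

        cfg = replace(
            cfg, c_mp=DistributionSpec("uniform", {"low": 1.0, "high": 20.0})
        )
        rep = sensitivity_analysis(run_simulation(cfg), "adult")
        assert rep.contribution_pct["C_mp"] == pytest.approx(100.0)
        assert rep.contribution_pct["BW"] == 0.0

    def test_iid_product_splits_fifty_fifty(self):
        cfg = point_scenario(n_iterations=20_000, seed=9)
        from dataclasses import replace

        u = {"low": 0.1, "high": 0.9}
        cfg = replace(
            cfg,
            c_mp=DistributionSpec("uniform", u, label="C_mp"),
            dehp_content=DistributionSpec("uniform", u, label="R"),
        )
        rep = sensitivity_analysis(run_simulation(cfg), "adult")
        assert rep.contribution_pct["C_mp"] == pytest.approx(50.0, abs=3.0)
        assert rep.contribution_pct["R"] == pytest.approx(50.0, abs=3.0)

    def test_contributions_sum_to_100_in_absolute_value(self):
        res = run_simulation(baseline_scenario(n_iterations=5000, seed=13))
        for label in res.receptor_labels():
            rep = sensitivity_analysis(res, label)
            assert sum(abs(v) for v in rep.contribution_pct.values()) == pytest.approx(
                100.0, abs=0.1
            )

    def test_rank_invariance_under_monotone_input_transform(self):
        res = run_simulation(baseline_scenario(n_iterations=3000, seed=17))
        before = sensitivity_analysis(res, "adult").contribution_pct["V"]
        res.shared_inputs["V"] = np.log(res.shared_inputs["V"])
        after = sensitivity_analysis(res, "adult").contribution_pct["V"]
        assert after == pytest.approx(before, abs=1e-9)

    def test_no_varying_inputs_rejected(self):
        res = run_simulation(point_scenario(n_iterations=50))
        with pytest.raises(ValidationError, match="varying"):
            sensitivity_analysis(res, "adult")


class TestConfigAndReport:
    def test_yaml_round_trip_preserves_results(self, tmp_path):
        cfg = baseline_scenario(n_iterations=500, seed=19)
        p = tmp_path / "scenario.yaml"
        cfg.to_yaml(p)
        cfg2 = ScenarioConfig.from_yaml(p)
        a, b = run_simulation(cfg), run_simulation(cfg2)
        np.testing.assert_array_equal(
            a.metrics["adult"]["ECR"], b.metrics["adult"]["ECR"]
        )

    def test_unbound_symbol_is_reported(self, tmp_path):
        from mprisk import ConfigurationError

        cfg = baseline_scenario(n_iterations=10)
        d = cfg.to_dict()
        del d["inputs"]["R"]
        with pytest.raises(ConfigurationError, match="R"):
            ScenarioConfig.from_dict(d)

    def test_report_round_trip_and_determinism(self, tmp_path):
        cfg = baseline_scenario(n_iterations=1000, seed=23)
        res = run_simulation(cfg)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        p1 = write_report(res, d1, config=cfg)
        p2 = write_report(run_simulation(cfg), d2, config=cfg)
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()
        import pandas as pd

        pct = pd.read_csv(p1["percentiles"])
        row = pct[(pct.metric == "ECR") & (pct.receptor == "adult")].iloc[0]
        assert row["q95"] == pytest.approx(percentile(res, "ECR", "adult", 0.95))

    def test_result_save_load_round_trip(self, tmp_path):
        cfg = baseline_scenario(n_iterations=300, seed=29)
        res = run_simulation(cfg)
        res.save(tmp_path / "run")
        back = RiskResult.load(tmp_path / "run")
        np.testing.assert_allclose(
            back.metrics["child"]["ECR"], res.metrics["child"]["ECR"], rtol=1e-12
        )
        rep_a = sensitivity_analysis(res, "adult").contribution_pct
        rep_b = sensitivity_analysis(back, "adult").contribution_pct
        assert rep_b["V"] == pytest.approx(rep_a["V"], abs=1e-6)

    def test_point_report_rows_all_equal_deterministic_value(self, tmp_path):
        res = run_simulation(point_scenario(n_iterations=20))
        paths = write_report(res, tmp_path / "rep")
        import pandas as pd

        pct = pd.read_csv(paths["percentiles"])
        ecr = pct[(pct.metric == "ECR") & (pct.receptor == "adult")].iloc[0]
        qcols = [c for c in pct.columns if c.startswith("q")]
        assert len(set(round(ecr[c], 20) for c in qcols)) == 1
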