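import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hotspot_assembly as ha
from hotspot_assembly.errors import ValidationError
from hotspot_assembly.synthetic_data import (
    NoiseModel,
    ScenarioConfig,
    StrainGroundTruth,
    expected_well_counts,
    logistic_od,
    simulate_growth_curve,
    simulate_isca,
    simulate_mock_calibration,
    simulate_pair_experiment,
)


def _solo(ic, mu=0.2, noise=None, **kw):
    truth = StrainGroundTruth("A", ic={"DMSP": ic}, mu={"DMSP": mu}, **kw)
    return ScenarioConfig(
        strains=[truth],
        initial_fractions=[1.0],
        noise=noise or NoiseModel.none(),
        rng_seed=0,
    )


class TestSimulateIsca:
    def test_zero_noise_ratio_is_exact_index(self, config):
        table, _ = simulate_isca(_solo(3.0), "DMSP", 3)
        est = ha.compute_ic(table.frame, config)
        assert est.ic_mean == pytest.approx(3.0, abs=1e-12)
        assert est.ic_sd == 0.0

    def test_indifferent_strain_converges_to_one(self, config):
        scen = _solo(1.0, noise=NoiseModel(read_depth=None))
        table, _ = simulate_isca(scen, "DMSP", 60, np.random.default_rng(5))
        est = ha.compute_ic(table.frame, config)
        # control expectation is 1000 cells: se of the mean ratio ~ 0.006
        assert est.ic_mean == pytest.approx(1.0, abs=0.03)

    def test_pooled_expectation_is_entry_weighted_mean(self):
        truths = [
            StrainGroundTruth("A", entry_rate=2e-3, ic={"DMSP": 2.0}),
            StrainGroundTruth("B", entry_rate=1e-3, ic={"DMSP": 4.0}),
        ]
        scen = ScenarioConfig(
            strains=truths,
            initial_fractions=[0.3, 0.7],
            noise=NoiseModel.none(),
            chemotaxis_modifiers={"A": 1.5},
        )
        ctl, met = expected_well_counts(scen, "DMSP")
        f, r = np.array([0.3, 0.7]), np.array([2e-3, 1e-3])
        ia = np.array([2.0 * 1.5, 4.0])
        expected = (f * r * ia).sum() / (f * r).sum()
        assert met.sum() / ctl.sum() == pytest.approx(expected, rel=1e-12)

    def test_replicate_count_validation(self):
        with pytest.raises(ValidationError):
            simulate_isca(_solo(2.0), "DMSP", 0)

    def test_fixed_seed_is_bit_identical(self, config):
        scen = ha.default_pair_scenario(seed=3)
        a = simulate_pair_experiment(scen, "DMSP", config)
        b = simulate_pair_experiment(scen, "DMSP", config)
        pd.testing.assert_frame_equal(a.asv, b.asv)
        pd.testing.assert_frame_equal(a.isca.frame, b.isca.frame)

    def test_noisy_counts_are_nonnegative_integers(self, config):
        scen = ha.default_pair_scenario(seed=11)
        bundle = simulate_pair_experiment(scen, "DMSP", config)
        reads = bundle.asv["reads"].to_numpy()
        assert (reads >= 0).all()
        assert np.allclose(reads, np.round(reads))
        cells = bundle.isca.frame["cells"].to_numpy()
        assert (cells >= 0).all()
        assert np.allclose(cells, np.round(cells))


class TestGrowthCurves:
    def test_no_growth_is_flat_at_inoculum(self):
        truth = StrainGroundTruth("A", ic={}, mu={"DMSP": 0.0})
        curve = simulate_growth_curve(truth, "DMSP", 10, 1, 0.0)
        assert np.allclose(curve["od600"], truth.od0, atol=1e-15)

    def test_pure_exponential_log_slope_is_mu(self):
        truth = StrainGroundTruth(
            "A", ic={}, mu={"DMSP": 0.3}, lag=0.0, carrying_od=float("inf")
        )
        curve = simulate_growth_curve(truth, "DMSP", 24, 1, 0.0)
        slopes = np.diff(np.log(curve["od600"]))
        assert np.allclose(slopes, 0.3, atol=1e-12)

    def test_logistic_saturates_at_carrying_capacity(self):
        od = logistic_od(np.array([1000.0]), 0.3, 0.0, 0.01, 0.5)
        assert od[0] == pytest.approx(0.5, rel=1e-9)

    def test_bad_sampling_arguments(self):
        truth = StrainGroundTruth("A", ic={}, mu={})
        with pytest.raises(ValidationError):
            simulate_growth_curve(truth, "DMSP", 10, 0)


class TestPairExperiment:
    def test_requires_exactly_two_strains(self, config):
        with pytest.raises(ValidationError):
            simulate_pair_experiment(_solo(2.0), "DMSP", config)

    def test_post_growth_is_exponential_amplification(self, config, zero_noise_scenario):
        bundle = simulate_pair_experiment(zero_noise_scenario, "DMSP", config)
        pc = bundle.truth_fractions["post_chemotaxis"]
        pg = bundle.truth_fractions["post_growth"]
        mus = np.array([s.mu["DMSP"] for s in zero_noise_scenario.strains])
        boosted = pc * np.exp(mus * config.grow_time)
        assert np.allclose(pg, boosted / boosted.sum(), atol=1e-12)

    def test_all_stage_fractions_on_simplex(self, config):
        scen = ha.default_pair_scenario(seed=2)
        bundle = simulate_pair_experiment(scen, "DMSP", config)
        for frac in bundle.truth_fractions.values():
            assert (frac >= 0).all()
            assert frac.sum() == pytest.approx(1.0, abs=1e-9)


class TestMockCalibration:
    def test_zero_noise_reads_proportional_to_cells(self):
        cal = simulate_mock_calibration(
            ["A", "B", "C"], rng=np.random.default_rng(0), zero_noise=True
        )
        # equal per-mock totals make reads/cells a single global constant
        ratio = cal["reads"] / cal["cells"]
        assert np.allclose(ratio, ratio.iloc[0], rtol=1e-9)

    def test_detection_efficiency_scales_reads(self):
        cal = simulate_mock_calibration(
            ["A", "B"],
            efficiencies={"A": 2.0},
            rng=np.random.default_rng(0),
            zero_noise=True,
        )
        a = cal[cal.strain_id == "A"]
        b = cal[cal.strain_id == "B"]
        assert (
            (a["reads"] / a["cells"]).iloc[0]
            == pytest.approx(2 * (b["reads"] / b["cells"]).iloc[0], rel=1e-9)
        )

    def test_low_depth_degrades_linearity(self, config):
        from hotspot_assembly.amplicon_calibration import fit_calibration

        sids = [t.strain_id for t in ha.study_strain_truths()]

        def mean_min_r2(depth, seeds=15):
            out = []
            for s in range(seeds):
                cal = simulate_mock_calibration(
                    sids, depth=depth, rng=np.random.default_rng(100 + s)
                )
                fits = fit_calibration(cal, config)
                out.append(min(f.r2 for f in fits.values()))
            return np.mean(out)

        assert mean_min_r2(100) < mean_min_r2(1_000_000)


@settings(max_examples=25, deadline=None)
@given(
    f=st.floats(0.05, 0.95),
    ic_a=st.floats(0.0, 8.0),
    ic_b=st.floats(0.1, 8.0),
    seed=st.integers(0, 2**20),
)
def test_generated_reads_stay_on_simplex_and_sum_to_depth(f, ic_a, ic_b, seed):
    truths = [
        StrainGroundTruth("A", ic={"DMSP": ic_a}, mu={"DMSP": 0.1}),
        StrainGroundTruth("B", ic={"DMSP": ic_b}, mu={"DMSP": 0.2}),
    ]
    scen = ScenarioConfig(
        strains=truths,
        initial_fractions=[f, 1 - f],
        noise=NoiseModel(read_depth=2000),
        rng_seed=seed,
    )
    bundle = simulate_pair_experiment(scen, "DMSP", ha.RunConfig())
    totals = bundle.asv.groupby("sample_id")["reads"].sum()
    assert (totals == 2000).all()
    assert (bundle.asv["reads"] >= 0).all()
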