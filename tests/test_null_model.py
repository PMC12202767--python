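import dataclasses

import numpy as np
import pytest

import hotspot_assembly as ha
from hotspot_assembly import (
    CommunityComposition,
    RunConfig,
    deviation,
    monte_carlo,
    predict_assembly,
)
from hotspot_assembly.amplicon_calibration import fit_calibration
from hotspot_assembly.chemotaxis import ChemotaxisIndex
from hotspot_assembly.errors import ValidationError
from hotspot_assembly.growth import GrowthRateEstimate, estimate_max_growth_rate
from hotspot_assembly.null_model import evaluate_pair


def _ic(strain, mean, sd=0.0, n=3, ratios=()):
    return ChemotaxisIndex(
        strain_set=(strain,),
        chemoattractant="DMSP",
        ic_mean=mean,
        ic_sd=sd,
        n=n,
        p_attraction=0.01,
        attracted=mean > 1,
        ratios=ratios,
    )


def _rate(strain, mu, reps=()):
    return GrowthRateEstimate(
        strain_id=strain,
        metabolite="DMSP",
        mu=mu,
        window=(3.0, 8.0),
        fit_r2=1.0,
        n_replicates=max(len(reps), 3),
        p_growth=0.01,
        grew=mu > 0,
        mu_replicates=reps,
    )


def _initial(fa=0.5):
    return CommunityComposition("initial", ("A", "B"), np.array([fa, 1 - fa]))


class TestPredictAssembly:
    def test_inert_strains_keep_initial_composition(self, config):
        pred = predict_assembly(
            {"A": _ic("A", 1.0), "B": _ic("B", 1.0)},
            {"A": _rate("A", 0.0), "B": _rate("B", 0.0)},
            _initial(0.37),
            config,
        )
        for stage in ("initial", "post_chemotaxis", "post_growth"):
            assert pred.trajectory[stage].fractions == pytest.approx([0.37, 0.63])

    def test_closed_form_worked_example(self, config):
        pred = predict_assembly(
            {"A": _ic("A", 2.0), "B": _ic("B", 4.0)},
            {"A": _rate("A", 0.1), "B": _rate("B", 0.2)},
            _initial(0.5),
            config,
        )
        assert pred.predicted_ic == pytest.approx(3.0, abs=1e-12)
        assert pred.trajectory["post_chemotaxis"].fractions == pytest.approx(
            [1 / 3, 2 / 3], rel=1e-12
        )
        assert pred.trajectory["post_growth"].fractions[0] == pytest.approx(
            0.0433908137, abs=1e-8
        )

    def test_missing_solo_measurement_names_gap(self, config):
        with pytest.raises(ValidationError, match="'B'"):
            predict_assembly(
                {"A": _ic("A", 2.0)},
                {"A": _rate("A", 0.1), "B": _rate("B", 0.2)},
                _initial(),
                config,
            )


class TestDeviation:
    def test_identical_compositions_have_zero_deviation(self, config):
        a = CommunityComposition("post_growth", ("A", "B"), np.array([0.7, 0.3]))
        call = deviation(a, a, config)
        assert call.deviation == 0.0
        assert not call.exceeds_threshold

    def test_fifteen_point_gap_flags_interaction(self, config):
        pred = CommunityComposition("post_growth", ("A", "B"), np.array([0.70, 0.30]))
        obs = CommunityComposition("post_growth", ("A", "B"), np.array([0.55, 0.45]))
        call = deviation(pred, obs, config)
        assert call.deviation == pytest.approx(15.0, abs=1e-12)
        assert call.exceeds_threshold

    def test_stage_mismatch_rejected(self, config):
        a = CommunityComposition("initial", ("A", "B"), np.array([0.5, 0.5]))
        b = CommunityComposition("post_growth", ("A", "B"), np.array([0.5, 0.5]))
        with pytest.raises(ValidationError):
            deviation(a, b, config)

    def test_symmetric_in_strain_order(self, config):
        pred = CommunityComposition("post_growth", ("A", "B"), np.array([0.7, 0.3]))
        obs = CommunityComposition("post_growth", ("A", "B"), np.array([0.52, 0.48]))
        d1 = deviation(pred, obs, config).deviation
        pred_r = CommunityComposition("post_growth", ("B", "A"), pred.fractions[::-1])
        obs_r = CommunityComposition("post_growth", ("B", "A"), obs.fractions[::-1])
        assert deviation(pred_r, obs_r, config).deviation == pytest.approx(d1)

    def test_abundance_vs_fraction_invariance(self, config):
        pred = CommunityComposition.from_abundances(
            "post_growth", ("A", "B"), [700, 300]
        )
        obs = CommunityComposition.from_abundances(
            "post_growth", ("A", "B"), [5200, 4800]
        )
        assert deviation(pred, obs, config).deviation == pytest.approx(18.0)


class TestMonteCarlo:
    def _inputs(self, sd_ic=0.2, sd_mu=0.01, n=3):
        ratios_a = (4.0 - sd_ic, 4.0, 4.0 + sd_ic)
        ratios_b = (2.5 - sd_ic, 2.5, 2.5 + sd_ic)
        ics = {
            "A": _ic("A", 4.0, np.std(ratios_a, ddof=1), n, ratios_a),
            "B": _ic("B", 2.5, np.std(ratios_b, ddof=1), n, ratios_b),
        }
        mus = {
            "A": _rate("A", 0.25, (0.25 - sd_mu, 0.25, 0.25 + sd_mu)),
            "B": _rate("B", 0.14, (0.14 - sd_mu, 0.14, 0.14 + sd_mu)),
        }
        return ics, mus

    def test_zero_variance_collapses_to_point_prediction(self, config):
        ics = {"A": _ic("A", 4.0), "B": _ic("B", 2.5)}
        mus = {"A": _rate("A", 0.25), "B": _rate("B", 0.14)}
        mc = monte_carlo(
            ics, mus, [600, 400], config, strains=("A", "B"), dirichlet=False
        )
        pred = predict_assembly(
            ics, mus, CommunityComposition("initial", ("A", "B"), [0.6, 0.4]), config
        )
        lo, hi = mc.interval("pooled_ic")
        assert hi - lo == pytest.approx(0.0, abs=1e-12)
        assert np.mean(mc.quantities["pooled_ic"]) == pytest.approx(
            pred.predicted_ic, abs=1e-9
        )
        assert np.mean(mc.quantities["frac_post_growth"]) == pytest.approx(
            pred.trajectory["post_growth"].fractions[0], abs=1e-9
        )

    def test_cdf_is_proper(self, config):
        ics, mus = self._inputs()
        mc = monte_carlo(ics, mus, [600, 400], config, strains=("A", "B"))
        for name, draws in mc.quantities.items():
            assert np.all(np.diff(draws) >= 0)
            assert mc.cdf(name, draws[0] - 1) == 0.0
            assert mc.cdf(name, draws[-1] + 1) == 1.0
            lo, hi = mc.interval(name)
            assert draws[0] <= lo <= hi <= draws[-1]

    def test_interval_shrinks_with_more_replicates(self, config):
        widths = []
        for n in (3, 6, 12):
            ics, mus = self._inputs(n=n)
            mc = monte_carlo(
                ics,
                mus,
                [600, 400],
                dataclasses.replace(config, rng_seed=42),
                strains=("A", "B"),
            )
            lo, hi = mc.interval("pooled_ic")
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_refuses_unstable_draw_count(self):
        # too few draws for a stable CDF is rejected at config construction
        with pytest.raises(ValidationError, match="mc_draws"):
            RunConfig(mc_draws=50)

    def test_draws_respect_nonnegativity(self, config):
        ics = {"A": _ic("A", 0.05, 0.5, 3), "B": _ic("B", 2.5, 0.2, 3)}
        mus = {"A": _rate("A", 0.01, (0.0, 0.01, 0.02)), "B": _rate("B", 0.14)}
        mc = monte_carlo(ics, mus, [600, 400], config, strains=("A", "B"))
        assert (mc.quantities["pooled_ic"] >= 0).all()

    def test_bootstrap_mode_resamples_replicates(self, config):
        ics, mus = self._inputs()
        mc = monte_carlo(
            ics, mus, [600, 400], config, strains=("A", "B"), mode="bootstrap"
        )
        draws = mc.quantities["pooled_ic"]
        # bootstrap support is bounded by the replicate extremes
        w_max = 0.6 * max(ics["A"].ratios) + 0.4 * max(ics["B"].ratios)
        assert draws[-1] <= w_max + 0.1


class TestEvaluatePair:
    def test_zero_noise_null_bundle_self_consistency(
        self, config, zero_noise_scenario
    ):
        rng = np.random.default_rng(0)
        solo_isca, curves = ha.simulate_solo_inputs(
            zero_noise_scenario, "DMSP", 3, rng
        )
        solo_ics = {
            s: ha.compute_ic(t.frame, config) for s, t in solo_isca.items()
        }
        rates = {
            s: estimate_max_growth_rate(sub, config)
            for s, sub in curves.groupby("strain_id")
        }
        cal = ha.simulate_mock_calibration(
            zero_noise_scenario.strain_ids, rng=rng, zero_noise=True
        )
        fits = fit_calibration(cal, config)
        bundle = ha.simulate_pair_experiment(
            zero_noise_scenario, "DMSP", config, 3, rng
        )
        ev = evaluate_pair(bundle, solo_ics, rates, fits, config, rng=rng)
        for call in ev.deviations:
            assert call.deviation == pytest.approx(0.0, abs=1e-9)
        assert not ev.interaction_detected
        assert ev.directions == {"HF66": "0", "HF9B": "0"}

    def test_summary_has_one_row_per_stage(self, config, null_scenario):
        rng = np.random.default_rng(1)
        solo_isca, curves = ha.simulate_solo_inputs(null_scenario, "DMSP", 3, rng)
        solo_ics = {s: ha.compute_ic(t.frame, config) for s, t in solo_isca.items()}
        rates = {
            s: estimate_max_growth_rate(sub, config)
            for s, sub in curves.groupby("strain_id")
        }
        fits = fit_calibration(
            ha.simulate_mock_calibration(null_scenario.strain_ids, rng=rng), config
        )
        bundle = ha.simulate_pair_experiment(null_scenario, "DMSP", config, 3, rng)
        ev = evaluate_pair(bundle, solo_ics, rates, fits, config, rng=rng)
        summary = ev.summary()
        assert list(summary["stage"]) == ["initial", "post_chemotaxis", "post_growth"]
        assert summary["p_value"].between(0, 1).all()
        assert (summary["ci_lo"] <= summary["ci_hi"]).all()
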