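import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hotspot_assembly import RunConfig, compute_ic, infer_member_ic, predict_pair_ic
from hotspot_assembly.chemotaxis import (
    ChemotaxisIndex,
    compare_pair_ic,
    compare_pair_ic_anova,
    read_ic_table,
    write_ic_table,
)
from hotspot_assembly.errors import (
    DegenerateCompositionError,
    UndefinedRatioError,
    ValidationError,
)


def _slice(pairs, strain_set="HF66", met="DMSP"):
    rows = []
    for rep, (m, c) in enumerate(pairs, start=1):
        rows.append(
            dict(
                experiment_id="E",
                strain_set=strain_set,
                chemoattractant=met,
                replicate=rep,
                well_type="metabolite",
                cells=m,
            )
        )
        rows.append(
            dict(
                experiment_id="E",
                strain_set=strain_set,
                chemoattractant=met,
                replicate=rep,
                well_type="control",
                cells=c,
            )
        )
    return pd.DataFrame(rows)


class TestComputeIc:
    def test_constant_ratio_has_zero_sd(self, config):
        est = compute_ic(_slice([(450, 150), (300, 100), (600, 200)]), config)
        assert est.ic_mean == pytest.approx(3.0, abs=1e-12)
        assert est.ic_sd == 0.0
        assert est.attracted  # identical ratios > 1 are unambiguous attraction

    def test_equal_wells_mean_one_not_attracted(self, config):
        est = compute_ic(_slice([(100, 100), (80, 80), (120, 120)]), config)
        assert est.ic_mean == pytest.approx(1.0)
        assert not est.attracted

    def test_hand_computed_t_statistic(self, config):
        # ratios 1.4, 1.6, 1.5: t = (1.5-1)/(0.1/sqrt(3)) = 8.6603, p = 0.0131
        est = compute_ic(_slice([(140, 100), (160, 100), (150, 100)]), config)
        assert est.ic_mean == pytest.approx(1.5)
        assert est.p_attraction == pytest.approx(0.013072457560, abs=1e-9)
        assert est.attracted

    def test_zero_control_names_replicate(self, config):
        with pytest.raises(UndefinedRatioError, match="2"):
            compute_ic(_slice([(100, 100), (50, 0)]), config)

    def test_zero_metabolite_is_valid_repulsion(self, config):
        est = compute_ic(_slice([(0, 100), (0, 120), (0, 90)]), config)
        assert est.ic_mean == 0.0
        assert not est.attracted

    def test_log_scale_variant(self, config):
        est = compute_ic(
            _slice([(140, 100), (160, 100), (150, 100)]), config, log_scale=True
        )
        assert est.attracted


class TestPredictPairIc:
    def test_symmetric_mixture(self):
        pred = predict_pair_ic(2.0, 4.0, [0.5, 0.5])
        assert pred.predicted_ic == pytest.approx(3.0, abs=1e-12)
        assert pred.predicted_well_fractions == pytest.approx([1 / 3, 2 / 3])

    def test_pure_mixture_reduces_to_solo(self):
        pred = predict_pair_ic(3.7, 1.1, [1.0, 0.0])
        assert pred.predicted_ic == pytest.approx(3.7)
        assert pred.predicted_well_fractions == pytest.approx([1.0, 0.0])

    def test_unequal_fractions_worked_example(self):
        pred = predict_pair_ic(3.0, 1.5, [0.6, 0.4])
        assert pred.predicted_ic == pytest.approx(2.4, abs=1e-12)
        assert pred.predicted_well_fractions == pytest.approx([0.75, 0.25])

    def test_entry_rate_weighting(self):
        # doubling strain A's motility doubles its weight
        pred = predict_pair_ic(2.0, 4.0, [0.5, 0.5], entry_rates=[2.0, 1.0])
        assert pred.weights == pytest.approx([2 / 3, 1 / 3])
        assert pred.predicted_ic == pytest.approx(2 / 3 * 2 + 1 / 3 * 4)

    def test_all_zero_indices_degenerate(self):
        with pytest.raises(DegenerateCompositionError):
            predict_pair_ic(0.0, 0.0, [0.5, 0.5])

    @settings(max_examples=50, deadline=None)
    @given(
        f=st.floats(0.01, 0.99),
        ia=st.floats(0.1, 8.0),
        ib=st.floats(0.1, 8.0),
    )
    def test_convexity_and_relabelling(self, f, ia, ib):
        pred = predict_pair_ic(ia, ib, [f, 1 - f])
        assert min(ia, ib) - 1e-12 <= pred.predicted_ic <= max(ia, ib) + 1e-12
        swapped = predict_pair_ic(ib, ia, [1 - f, f])
        assert swapped.predicted_ic == pytest.approx(pred.predicted_ic, rel=1e-12)
        assert swapped.predicted_well_fractions[::-1] == pytest.approx(
            pred.predicted_well_fractions, rel=1e-9
        )

    def test_equal_indices_leave_composition_at_inoculum(self):
        pred = predict_pair_ic(2.5, 2.5, [0.3, 0.7])
        assert pred.predicted_ic == pytest.approx(2.5)
        assert pred.predicted_well_fractions == pytest.approx([0.3, 0.7])


class TestInferMemberIc:
    def test_worked_example(self):
        ic = infer_member_ic(400, 100, [0.75, 0.25], [0.5, 0.5])
        assert ic == pytest.approx([6.0, 2.0])

    def test_identical_fractions_and_counts_give_unity(self):
        assert infer_member_ic(100, 100, [0.4, 0.6], [0.4, 0.6]) == pytest.approx(
            [1.0, 1.0]
        )

    def test_absent_strain_in_metabolite_well(self):
        assert infer_member_ic(400, 100, [1.0, 0.0], [0.5, 0.5]) == pytest.approx(
            [8.0, 0.0]
        )

    def test_zero_control_fraction_undefined(self):
        with pytest.raises(UndefinedRatioError):
            infer_member_ic(400, 100, [0.5, 0.5], [1.0, 0.0])

    @settings(max_examples=50, deadline=None)
    @given(
        fm=st.floats(0.0, 1.0),
        fc=st.floats(0.01, 0.99),
        met=st.floats(1.0, 1e5),
        ctl=st.floats(1.0, 1e5),
    )
    def test_pooled_identity(self, fm, fc, met, ctl):
        """sum_i fc_i I_i recovers the pooled ratio exactly (algebraic)."""
        members = infer_member_ic(met, ctl, [fm, 1 - fm], [fc, 1 - fc])
        pooled = np.dot([fc, 1 - fc], members)
        assert pooled == pytest.approx(met / ctl, rel=1e-12)


class TestComparePairIc:
    def _observed(self, ratios):
        r = np.asarray(ratios, float)
        return ChemotaxisIndex(
            strain_set=("HF66", "HF9B"),
            chemoattractant="DMSP",
            ic_mean=float(r.mean()),
            ic_sd=float(r.std(ddof=1)),
            n=len(r),
            p_attraction=0.0,
            attracted=True,
            ratios=tuple(r),
        )

    def test_observation_at_point_prediction_not_significant(self, config):
        draws = np.full(1000, 3.0)
        res = compare_pair_ic(draws, self._observed([3.0, 3.0, 3.0]), config)
        assert res.p_value == 1.0
        assert not res.significant

    def test_far_observation_is_significant(self, config, rng):
        draws = rng.normal(3.0, 0.05, 10_000)
        res = compare_pair_ic(draws, self._observed([4.5, 4.4, 4.6]), config)
        assert res.significant
        assert res.p_value == pytest.approx(1 / 10_000)

    def test_p_value_never_zero(self, config, rng):
        draws = rng.normal(3.0, 0.01, 500)
        res = compare_pair_ic(draws, self._observed([9.0, 9.1, 8.9]), config)
        assert res.p_value >= 1 / 500

    def test_anova_fallback_matches_direction(self, config):
        res = compare_pair_ic_anova(
            [3.0, 3.1, 2.9], self._observed([4.5, 4.4, 4.6]), config
        )
        assert res.significant
        res2 = compare_pair_ic_anova(
            [3.0, 3.1, 2.9], self._observed([3.05, 2.95, 3.0]), config
        )
        assert not res2.significant


def test_ic_table_round_trip(tmp_path, config):
    est = compute_ic(_slice([(140, 100), (160, 100), (150, 100)]), config)
    write_ic_table([est], tmp_path / "ic.csv")
    back = read_ic_table(tmp_path / "ic.csv")
    assert back[0] == est
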