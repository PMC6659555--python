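"""Four-step weight construction: inverse probability, stratum scaling,
calibration, mean-1 rescaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smokesurvey.population import BenchmarkTable
from smokesurvey.weights import (
    CalibrationError,
    CalibrationSpec,
    WeightSet,
    calibrate,
    design_weights,
    initial_weights,
    rescale_mean_one,
)
from smokesurvey.estimation import margin_audit
from smokesurvey.studies import weights_for_sample


def make_resp(ks, strata=None, sexes=None, ages=None, clusters=None):
    n = len(ks)
    return pd.DataFrame(
        {
            "person_id": np.arange(n),
            "household_id": np.arange(n),
            "cluster_id": clusters if clusters is not None else ["c0"] * n,
            "stratum_id": strata if strata is not None else ["A"] * n,
            "sex": sexes if sexes is not None else ["male"] * n,
            "age_group": ages if ages is not None else ["25-39"] * n,
            "same_sex_smokers_in_household": ks,
            "interview_complete": True,
        }
    )


def strata_frame(ids, pops, regions=None):
    return pd.DataFrame(
        {
            "stratum_id": ids,
            "region_id": regions if regions else ["R"] * len(ids),
            "urbanization": "urban",
            "adult_population": pops,
        }
    )


class TestInitialWeights:
    def test_weight_equals_same_sex_smoker_count(self):
        ws = initial_weights(make_resp([1, 5, 2]))
        assert ws.column("initial").tolist() == [1.0, 5.0, 2.0]

    def test_two_per_sex_selection_enumeration(self):
        # household with 2 male + 1 female smokers: the male respondent was
        # drawn from 2 candidates (weight 2), the female from 1 (weight 1)
        resp = make_resp([2, 1], sexes=["male", "female"])
        ws = initial_weights(resp)
        assert ws.column("initial").tolist() == [2.0, 1.0]

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            initial_weights(make_resp([1, 0]))


class TestDesignWeights:
    def test_single_stratum_single_scale_factor(self):
        ws = initial_weights(make_resp([1, 2, 4]))
        out = design_weights(ws, strata_frame(["A"], [7000]))
        ratio = out.column("design") / ws.column("initial")
        assert np.allclose(ratio, ratio[0])
        assert out.column("design").sum() == pytest.approx(7000)

    def test_equal_population_strata_weight_inverse_to_sample_size(self):
        resp = make_resp([1] * 30, strata=["A"] * 10 + ["B"] * 20)
        ws = design_weights(initial_weights(resp), strata_frame(["A", "B"], [5000, 5000]))
        w = ws.column("design")
        assert w[0] / w[10] == pytest.approx(2.0)

    def test_equal_everything_gives_equal_weights(self):
        resp = make_resp([1] * 20, strata=["A"] * 10 + ["B"] * 10)
        ws = design_weights(initial_weights(resp), strata_frame(["A", "B"], [3000, 3000]))
        assert np.allclose(ws.column("design"), ws.column("design")[0])

    def test_empty_stratum_population_merged_into_donor(self):
        resp = make_resp([1] * 10, strata=["A"] * 10)
        strata = strata_frame(["A", "B"], [4000, 1000])
        with pytest.warns(UserWarning, match="merged"):
            ws = design_weights(initial_weights(resp), strata)
        assert ws.column("design").sum() == pytest.approx(5000)


def bench_from_cells(cells):
    return BenchmarkTable(pd.DataFrame(cells))


class TestCalibrate:
    def test_proportional_benchmark_is_fixed_point(self):
        resp = make_resp([1] * 4, sexes=["male", "male", "female", "female"])
        ws = design_weights(initial_weights(resp), strata_frame(["A"], [100]))
        bench = bench_from_cells(
            [
                dict(stratum_id="A", sex="male", age_group="25-39", smokers=50),
                dict(stratum_id="A", sex="female", age_group="25-39", smokers=50),
            ]
        )
        out = calibrate(ws, bench)
        assert np.allclose(out.column("calibrated"), ws.column("design"))

    def test_two_by_two_ipf_worked_example(self):
        # one unit per sex x age cell, unit design weights,
        # sex targets (3, 1), age targets (2, 2) -> (1.5, 1.5, 0.5, 0.5)
        resp = make_resp(
            [1] * 4,
            sexes=["male", "male", "female", "female"],
            ages=["young", "old", "young", "old"],
        )
        ws = initial_weights(resp).with_column("design", np.ones(4))
        bench = bench_from_cells(
            [
                dict(stratum_id="A", sex="male", age_group="young", smokers=1.5),
                dict(stratum_id="A", sex="male", age_group="old", smokers=1.5),
                dict(stratum_id="A", sex="female", age_group="young", smokers=0.5),
                dict(stratum_id="A", sex="female", age_group="old", smokers=0.5),
            ]
        )
        spec = CalibrationSpec(margins=["sex", "age_group"])
        out = calibrate(ws, bench, spec)
        assert out.column("calibrated") == pytest.approx([1.5, 1.5, 0.5, 0.5])

    def test_single_cell_poststratification_ratio(self):
        resp = make_resp([1] * 5)
        ws = initial_weights(resp).with_column("design", np.full(5, 10.0))
        bench = bench_from_cells(
            [dict(stratum_id="A", sex="male", age_group="25-39", smokers=200)]
        )
        spec = CalibrationSpec(mode="cell_poststratification", min_cell_count=1)
        out = calibrate(ws, bench, spec)
        assert np.allclose(out.column("calibrated"), 40.0)  # 200/50 = 4x

    def test_small_cells_collapsed_with_warning(self):
        resp = make_resp(
            [1] * 6,
            sexes=["male"] * 6,
            ages=["young"] * 5 + ["old"],
        )
        ws = initial_weights(resp).with_column("design", np.ones(6))
        bench = bench_from_cells(
            [
                dict(stratum_id="A", sex="male", age_group="young", smokers=50),
                dict(stratum_id="A", sex="male", age_group="old", smokers=10),
            ]
        )
        spec = CalibrationSpec(mode="cell_poststratification", min_cell_count=5)
        with pytest.warns(UserWarning, match="collapsed"):
            out = calibrate(ws, bench, spec)
        # both cells share one collapsed group: uniform factor 60/6
        assert np.allclose(out.column("calibrated"), 10.0)

    def test_nonconvergence_raises_with_margin_errors(self):
        resp = make_resp(
            [1] * 4,
            sexes=["male", "male", "female", "female"],
            ages=["young", "old", "young", "old"],
        )
        # unequal starting weights: a single sweep cannot satisfy both margins
        ws = initial_weights(resp).with_column("design", np.array([1.0, 2.0, 3.0, 4.0]))
        bench = bench_from_cells(
            [
                dict(stratum_id="A", sex="male", age_group="young", smokers=30),
                dict(stratum_id="A", sex="male", age_group="old", smokers=1),
                dict(stratum_id="A", sex="female", age_group="young", smokers=1),
                dict(stratum_id="A", sex="female", age_group="old", smokers=30),
            ]
        )
        spec = CalibrationSpec(margins=["sex", "age_group"], max_iterations=1,
                               tolerance=1e-12)
        with pytest.raises(CalibrationError) as err:
            calibrate(ws, bench, spec)
        assert err.value.margin_errors  # final errors reported

    def test_margin_reproduction_on_simulated_sample(self, small_pop, small_sample):
        bench = small_pop.true_margins()
        ws = weights_for_sample(small_sample, small_pop, bench)
        audit = margin_audit(ws, bench)
        assert audit["rel_error"].max() < 1e-8


class TestRescale:
    def test_arithmetic_example(self):
        ws = initial_weights(make_resp([1, 1, 1])).with_column(
            "calibrated", np.array([2.0, 4.0, 6.0])
        )
        out = rescale_mean_one(ws)
        assert out.column("rescaled").tolist() == [0.5, 1.0, 1.5]

    def test_equal_weights_rescale_to_exactly_one(self):
        ws = initial_weights(make_resp([3, 3])).with_column(
            "calibrated", np.array([7.0, 7.0])
        )
        assert rescale_mean_one(ws).column("rescaled").tolist() == [1.0, 1.0]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        w=st.lists(st.floats(0.01, 100, allow_nan=False), min_size=2, max_size=40)
    )
    def test_mean_one_and_ratios_preserved(self, w):
        arr = np.array(w)
        ws = initial_weights(make_resp([1] * len(arr))).with_column("calibrated", arr)
        out = rescale_mean_one(ws).column("rescaled")
        assert out.mean() == pytest.approx(1.0, abs=1e-10)
        assert out / out.sum() == pytest.approx(arr / arr.sum())


def test_weight_chain_order_invariance(small_pop, small_sample):
    bench = small_pop.true_margins()
    ws = weights_for_sample(small_sample, small_pop, bench)
    resp_perm = small_sample.respondents.sample(frac=1, random_state=0).reset_index(drop=True)
    sample_perm = small_sample.__class__(
        respondents=resp_perm,
        dispositions=small_sample.dispositions,
        cluster_allocation=small_sample.cluster_allocation,
        sampled_clusters=small_sample.sampled_clusters,
        seed=small_sample.seed,
    )
    ws_perm = weights_for_sample(sample_perm, small_pop, bench)
    a = pd.Series(ws.column("rescaled"), index=ws.respondents["person_id"]).sort_index()
    b = pd.Series(ws_perm.column("rescaled"), index=ws_perm.respondents["person_id"]).sort_index()
    assert np.max(np.abs(a.to_numpy() - b.to_numpy())) < 1e-10


def test_all_stages_strictly_positive(small_pop, small_sample):
    ws = weights_for_sample(small_sample, small_pop)
    for stage in ("initial", "design", "calibrated", "rescaled"):
        assert (ws.column(stage) > 0).all()
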