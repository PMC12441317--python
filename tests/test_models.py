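import numpy as np
import pandas as pd
import pytest

import aalearn as a
from aalearn.models import (
    LATENT, TEACHER_FORCED, ModelSpec, SSEObjective, initial_value,
    prediction_error, step_value,
)

from conftest import random_histories


@pytest.mark.parametrize("model_id,k", [(1, 3), (2, 4), (3, 5), (4, 5), (5, 5), (6, 7)])
def test_param_counts(model_id, k):
    assert a.param_count(model_id) == k


def test_param_count_unknown_id():
    with pytest.raises(ValueError):
        a.param_count(7)


@pytest.mark.parametrize("r,v,expected", [
    (1, 0.7, 0.3), (0, 0.7, -0.7), (1, 1.0, 0.0), (0, 0.0, 0.0),
])
def test_prediction_error(r, v, expected):
    assert prediction_error(r, v) == pytest.approx(expected)


class TestWorkedExamples:
    """Hand-evaluated update steps for the documented model equations."""

    def test_model2_teacher_forced_trace(self, worked_example_trials):
        params = {"alpha": 0.4, "beta": 0.8, "v1_in": 0.5, "v1_out": 0.5}
        trace = a.predict_series(2, params, worked_example_trials)
        assert trace["prediction"].tolist() == pytest.approx([0.5, 0.608])
        assert trace["delta"].tolist() == pytest.approx([0.4, -0.5])
        assert a.sse(trace) == pytest.approx(0.021664, abs=1e-12)

    def test_model1_drops_beta(self, worked_example_trials):
        params = {"alpha": 0.4, "v1_in": 0.5, "v1_out": 0.5}
        trace = a.predict_series(1, params, worked_example_trials)
        assert trace["prediction"].iloc[1] == pytest.approx(0.76)

    def test_model5_negative_branch_step(self):
        params = {"alpha_pos": 0.38, "alpha_neg": 0.01, "beta": 0.67,
                  "v1_in": 0.5, "v1_out": 0.5}
        nxt = step_value(5, params, a.SYMBOL_OUT, prev_value=0.8, prev_outcome=0)
        assert nxt == pytest.approx(0.53064, abs=1e-12)

    def test_first_encounter_is_v1_without_beta(self):
        params = {"alpha": 0.4, "beta": 0.5, "v1_in": 0.9, "v1_out": 0.3}
        assert initial_value(params, a.SYMBOL_IN) == 0.9
        assert initial_value(params, a.SYMBOL_OUT) == 0.3


def _nested_param_sets(rng):
    """(rich model id, rich params, model-2 equivalent params)."""
    alpha, beta = rng.uniform(0, 1, 2)
    v1_in, v1_out = rng.uniform(0, 1, 2)
    m2 = {"alpha": alpha, "beta": beta, "v1_in": v1_in, "v1_out": v1_out}
    yield 3, {"alpha": alpha, "beta_in": beta, "beta_out": beta,
              "v1_in": v1_in, "v1_out": v1_out}, m2
    yield 4, {"alpha_in": alpha, "alpha_out": alpha, "beta": beta,
              "v1_in": v1_in, "v1_out": v1_out}, m2
    yield 5, {"alpha_pos": alpha, "alpha_neg": alpha, "beta": beta,
              "v1_in": v1_in, "v1_out": v1_out}, m2
    yield 6, {"alpha_pos_in": alpha, "alpha_pos_out": alpha,
              "alpha_neg_in": alpha, "alpha_neg_out": alpha, "beta": beta,
              "v1_in": v1_in, "v1_out": v1_out}, m2


@pytest.mark.parametrize("mode", [TEACHER_FORCED, LATENT])
def test_nesting_equivalences(mode):
    """Models 3-6 with tied parameters reproduce model 2; model 2 with
    beta = 1 reproduces model 1, on random data to 1e-12."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        trials = random_histories(rng)
        for rich_id, rich_params, m2 in _nested_param_sets(rng):
            t_rich = a.predict_series(rich_id, rich_params, trials, mode=mode)
            t_m2 = a.predict_series(2, m2, trials, mode=mode)
            np.testing.assert_allclose(
                t_rich["prediction"], t_m2["prediction"], atol=1e-12)
        m2_unit = {"alpha": rng.uniform(), "beta": 1.0,
                   "v1_in": rng.uniform(), "v1_out": rng.uniform()}
        m1 = {k: v for k, v in m2_unit.items() if k != "beta"}
        np.testing.assert_allclose(
            a.predict_series(2, m2_unit, trials, mode=mode)["prediction"],
            a.predict_series(1, m1, trials, mode=mode)["prediction"],
            atol=1e-12)


@pytest.mark.parametrize("model_id", list(a.MODEL_IDS))
def test_predictions_bounded(model_id):
    """With parameters, y and r all in [0,1] every prediction stays in [0,1]."""
    rng = np.random.default_rng(3)
    spec = ModelSpec(model_id)
    for _ in range(10):
        trials = random_histories(rng)
        params = spec.to_dict(rng.uniform(0, 1, spec.k))
        for mode in (TEACHER_FORCED, LATENT):
            pred = a.predict_series(model_id, params, trials, mode=mode)["prediction"]
            assert pred.between(0, 1).all()
            delta = a.predict_series(model_id, params, trials, mode=mode)["delta"]
            assert delta.between(-1, 1).all()


def test_teacher_forced_identity():
    """alpha = 0, beta = 1: the prediction is the previous same-symbol response."""
    rng = np.random.default_rng(9)
    trials = random_histories(rng)
    params = {"alpha": 0.0, "beta": 1.0, "v1_in": 0.5, "v1_out": 0.5}
    trace = a.predict_series(2, params, trials)
    for symbol in (a.SYMBOL_IN, a.SYMBOL_OUT):
        sub = trace[trace["symbol"] == symbol]
        np.testing.assert_allclose(
            sub["prediction"].to_numpy()[1:], sub["observed"].to_numpy()[:-1])


def _latent_oracle(model_id, params, trials):
    """Independent step-by-step recomputation of the latent-mode recursion."""
    values, outcomes = {}, {}
    preds = []
    for _, row in trials.iterrows():
        s = row["symbol"]
        if s not in values:
            v = params["v1_in"] if s == a.SYMBOL_IN else params["v1_out"]
        else:
            v_prev, r_prev = values[s], outcomes[s]
            d = r_prev - v_prev
            if model_id == 5:
                alpha = params["alpha_pos"] if d >= 0 else params["alpha_neg"]
                v = (v_prev + alpha * d) * params["beta"]
            elif model_id == 2:
                v = (v_prev + params["alpha"] * d) * params["beta"]
            else:
                raise NotImplementedError
        preds.append(v)
        values[s], outcomes[s] = v, row["outcome_r"]
    return np.array(preds)


@pytest.mark.parametrize("model_id,params", [
    (2, {"alpha": 0.35, "beta": 0.9, "v1_in": 0.6, "v1_out": 0.8}),
    (5, {"alpha_pos": 0.4, "alpha_neg": 0.05, "beta": 0.85,
         "v1_in": 0.7, "v1_out": 0.8}),
])
def test_latent_mode_matches_bruteforce(model_id, params):
    rng = np.random.default_rng(21)
    for _ in range(5):
        trials = random_histories(rng, n_trials=20)
        trace = a.predict_series(model_id, params, trials, mode=LATENT)
        np.testing.assert_allclose(
            trace["prediction"], _latent_oracle(model_id, params, trials),
            atol=1e-12)


def test_invalid_trials_skipped():
    rng = np.random.default_rng(5)
    trials = random_histories(rng).assign(valid=True, trial=range(1, 31))
    trials.loc[[4, 9], "valid"] = False
    trials.loc[[4, 9], ["y_value", "outcome_r"]] = np.nan
    params = {"alpha": 0.3, "beta": 0.9, "v1_in": 0.5, "v1_out": 0.5}
    trace = a.predict_series(2, params, trials)
    dropped = trials[trials["valid"]].drop(columns="valid")
    trace_dropped = a.predict_series(2, params, dropped)
    assert len(trace) == 28
    np.testing.assert_allclose(trace["prediction"], trace_dropped["prediction"])


def test_parameter_mismatch_and_order_errors(worked_example_trials):
    with pytest.raises(ValueError):
        a.predict_series(1, {"alpha": 0.1, "beta": 0.5, "v1_in": 0.5,
                             "v1_out": 0.5}, worked_example_trials)
    shuffled = worked_example_trials.assign(trial=[2, 1])
    with pytest.raises(ValueError):
        a.predict_series(1, {"alpha": 0.1, "v1_in": 0.5, "v1_out": 0.5}, shuffled)


def test_sse_empty_trace_raises():
    with pytest.raises(ValueError):
        a.sse(pd.DataFrame({"residual": []}))


@pytest.mark.parametrize("mode", [TEACHER_FORCED, LATENT])
@pytest.mark.parametrize("model_id", list(a.MODEL_IDS))
def test_objective_consistent_with_trace(model_id, mode):
    """The vectorised fitting objective equals SSE of the reference trace."""
    rng = np.random.default_rng(13)
    trials = random_histories(rng)
    spec = ModelSpec(model_id)
    obj = SSEObjective(model_id, trials, mode=mode)
    for _ in range(5):
        theta = rng.uniform(0, 1, spec.k)
        trace = a.predict_series(model_id, spec.to_dict(theta), trials, mode=mode)
        assert obj(theta) == pytest.approx(a.sse(trace), abs=1e-12)
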