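"""Six Rescorla-Wagner model variants for continuous oriented responses.

The observed response on each valid trial is the oriented, normalised
distance y in [0, 1].  All models treat the response as an expected value V
updated by the Rescorla-Wagner rule

    V(t) = [V(t-1) + alpha * delta(t)] * beta,      delta(t) = r(t) - V(t-1),

where r(t) in {0, 1} is the binary outcome (punishment/reward).  The model
space grows from a single learning rate with no response weight (model 1) to
four valence-by-symbol learning rates (model 6):

    1  alpha;                     V1_in, V1_out            (K = 3)
    2  alpha, beta;               V1_in, V1_out            (K = 4)
    3  alpha, beta_in, beta_out;  V1_in, V1_out            (K = 5)
    4  alpha_in, alpha_out, beta; V1_in, V1_out            (K = 5)
    5  alpha_pos, alpha_neg, beta; V1_in, V1_out           (K = 5)
    6  alpha_pos_in, alpha_pos_out, alpha_neg_in,
       alpha_neg_out, beta;       V1_in, V1_out            (K = 7)

Every model carries two free initial values V1 (one per symbol), the model's
prediction for the first encounter with that symbol; they encode the initial
in-group approach bias.  A prediction error of exactly zero takes the
positive-rate branch.  The value carried into each update is, per symbol,
either the participant's previous observed response (teacher-forced mode,
the default for fitting) or the model's own previous prediction (latent
mode).  Invalid trials produced no outcome and are skipped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import SYMBOL_IN, SYMBOL_OUT

TEACHER_FORCED = "teacher_forced"
LATENT = "latent"
MODES = (TEACHER_FORCED, LATENT)

#: Free parameters per model, in canonical order.
MODEL_PARAMS: dict[int, tuple[str, ...]] = {
    1: ("alpha", "v1_in", "v1_out"),
    2: ("alpha", "beta", "v1_in", "v1_out"),
    3: ("alpha", "beta_in", "beta_out", "v1_in", "v1_out"),
    4: ("alpha_in", "alpha_out", "beta", "v1_in", "v1_out"),
    5: ("alpha_pos", "alpha_neg", "beta", "v1_in", "v1_out"),
    6: ("alpha_pos_in", "alpha_pos_out", "alpha_neg_in", "alpha_neg_out",
        "beta", "v1_in", "v1_out"),
}

MODEL_IDS = tuple(MODEL_PARAMS)


@dataclass(frozen=True)
class ModelSpec:
    """One member of the model space: parameter names, bounds, K."""

    model_id: int

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_PARAMS:
            raise ValueError(f"unknown model id {self.model_id}; expected 1-6")

    @property
    def param_names(self) -> tuple[str, ...]:
        return MODEL_PARAMS[self.model_id]

    @property
    def k(self) -> int:
        return len(self.param_names)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [(0.0, 1.0)] * self.k

    def vector(self, params: dict[str, float]) -> np.ndarray:
        """Parameter dict -> array in canonical order (validates the keys)."""
        missing = set(self.param_names) - set(params)
        extra = set(params) - set(self.param_names)
        if missing or extra:
            raise ValueError(
                f"model {self.model_id} parameter mismatch: "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        return np.array([float(params[name]) for name in self.param_names])

    def to_dict(self, theta: np.ndarray) -> dict[str, float]:
        if len(theta) != self.k:
            raise ValueError(f"model {self.model_id} expects {self.k} values")
        return {name: float(v) for name, v in zip(self.param_names, theta)}


def param_count(model_id: int) -> int:
    """Number of free parameters K of a model (3, 4, 5, 5, 5, 7)."""
    if model_id not in MODEL_PARAMS:
        raise ValueError(f"unknown model id {model_id}; expected 1-6")
    return len(MODEL_PARAMS[model_id])


def prediction_error(outcome_r: float, prev_value: float) -> float:
    """delta = r - V(t-1): discrepancy between outcome and carried value."""
    return outcome_r - prev_value


def _rates(model_id: int, p: dict[str, float], is_in: bool, delta: float) -> tuple[float, float]:
    """(alpha*, beta*) selected by model rules for one update step.

    delta == 0 takes the positive-rate branch.
    """
    if model_id == 1:
        return p["alpha"], 1.0
    if model_id == 2:
        return p["alpha"], p["beta"]
    if model_id == 3:
        return p["alpha"], p["beta_in"] if is_in else p["beta_out"]
    if model_id == 4:
        return (p["alpha_in"] if is_in else p["alpha_out"]), p["beta"]
    if model_id == 5:
        return (p["alpha_pos"] if delta >= 0 else p["alpha_neg"]), p["beta"]
    if model_id == 6:
        if delta >= 0:
            alpha = p["alpha_pos_in"] if is_in else p["alpha_pos_out"]
        else:
            alpha = p["alpha_neg_in"] if is_in else p["alpha_neg_out"]
        return alpha, p["beta"]
    raise ValueError(f"unknown model id {model_id}")


def step_value(model_id: int, params: dict[str, float], symbol: str,
               prev_value: float, prev_outcome: float) -> float:
    """One Rescorla-Wagner update: the prediction for the next same-symbol
    encounter given the value and outcome carried out of the previous one."""
    is_in = symbol == SYMBOL_IN
    delta = prediction_error(prev_outcome, prev_value)
    alpha, beta = _rates(model_id, params, is_in, delta)
    return (prev_value + alpha * delta) * beta


def initial_value(params: dict[str, float], symbol: str) -> float:
    """First-encounter prediction: V1 of the symbol, without beta scaling."""
    return params["v1_in"] if symbol == SYMBOL_IN else params["v1_out"]


def _extract_arrays(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Validated (trial_index, is_in, y, r) arrays of the valid trials, in order."""
    required = {"symbol", "y_value", "outcome_r"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trials must carry columns {sorted(required)}")
    if "trial" in trials.columns:
        t = trials["trial"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("trials must be sorted by trial index, without duplicates")
    sub = trials
    if "valid" in trials.columns:
        sub = trials[trials["valid"].astype(bool)]
    idx = (sub["trial"].to_numpy(dtype=float) if "trial" in sub.columns
           else np.arange(1, len(sub) + 1, dtype=float))
    symbols = sub["symbol"].to_numpy()
    unknown = set(symbols) - {SYMBOL_IN, SYMBOL_OUT}
    if unknown:
        raise ValueError(f"unknown symbols {sorted(unknown)}")
    is_in = symbols == SYMBOL_IN
    y = sub["y_value"].to_numpy(dtype=float)
    r = sub["outcome_r"].to_numpy(dtype=float)
    if np.any(np.isnan(y)) or np.any(np.isnan(r)):
        raise ValueError("valid trials must have observed y_value and outcome_r")
    return idx, is_in, y, r


def predict_series(
    model_id: int,
    params: dict[str, float],
    trials: pd.DataFrame,
    mode: str = TEACHER_FORCED,
) -> pd.DataFrame:
    """Per-trial predictions, prediction errors and residuals for one participant.

    Parameters
    ----------
    model_id:
        1-6, selecting the learning-rate / response-weight structure.
    params:
        Parameter dict with exactly the model's free parameters.
    trials:
        Ordered trial table with ``symbol``, ``y_value``, ``outcome_r`` (and
        optionally ``trial``, ``valid``); invalid trials are skipped.
    mode:
        ``teacher_forced`` (default): the value carried into each update is
        the participant's previous observed response for that symbol.
        ``latent``: the model's own previous prediction is carried instead.

    Returns
    -------
    DataFrame with one row per valid trial: ``trial``, ``symbol``,
    ``encounter_k``, ``prediction``, ``delta`` (r minus the carried value on
    that trial), ``observed`` and ``residual`` (observed - prediction).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    spec = ModelSpec(model_id)
    spec.vector(params)  # validates names
    idx, is_in, y, r = _extract_arrays(trials)
    n = len(y)
    if n == 0:
        raise ValueError("no valid trials to predict")

    pred = np.empty(n)
    delta = np.empty(n)
    encounter = np.empty(n, dtype=int)
    # carried per-symbol state: (value carried out of last encounter, outcome, seen count)
    state: dict[bool, tuple[float, float]] = {}
    count = {True: 0, False: 0}
    symbols = np.where(is_in, SYMBOL_IN, SYMBOL_OUT)
    for i in range(n):
        key = bool(is_in[i])
        count[key] += 1
        encounter[i] = count[key]
        if key not in state:
            pred[i] = initial_value(params, symbols[i])
        else:
            v_prev, r_prev = state[key]
            pred[i] = step_value(model_id, params, symbols[i], v_prev, r_prev)
        carried = y[i] if mode == TEACHER_FORCED else pred[i]
        delta[i] = prediction_error(r[i], carried)
        state[key] = (carried, r[i])

    out = pd.DataFrame({
        "trial": idx.astype(int) if np.allclose(idx, np.round(idx)) else idx,
        "symbol": symbols,
        "encounter_k": encounter,
        "prediction": pred,
        "delta": delta,
        "observed": y,
        "residual": y - pred,
    })
    return out


def sse(trace: pd.DataFrame) -> float:
    """Sum of squared errors between observed responses and predictions.

    First-encounter residuals are included.  Raises on an empty trace.
    """
    if len(trace) == 0:
        raise ValueError("empty prediction trace")
    res = trace["residual"].to_numpy(dtype=float)
    return float(np.dot(res, res))


# -- fast SSE objective used by the fitting routines ------------------------

class SSEObjective:
    """Callable theta -> SSE for one participant's valid trials.

    In teacher-forced mode the carried values are observed data, so every
    prediction is an explicit function of the parameters and the objective
    is fully vectorised; latent mode falls back to the sequential recursion.
    """

    def __init__(self, model_id: int, trials: pd.DataFrame, mode: str = TEACHER_FORCED):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.spec = ModelSpec(model_id)
        self.mode = mode
        idx, is_in, y, r = _extract_arrays(trials)
        self.is_in, self.y, self.r = is_in, y, r
        self.n_obs = len(y)

        # positions of each symbol's encounters in chronological order
        order_in = np.flatnonzero(is_in)
        order_out = np.flatnonzero(~is_in)
        self._first = np.array([order_in[0] if len(order_in) else -1,
                                order_out[0] if len(order_out) else -1])
        # for encounters k>=2: current index, previous same-symbol index
        cur = np.concatenate([order_in[1:], order_out[1:]])
        prev = np.concatenate([order_in[:-1], order_out[:-1]])
        self._cur, self._prev = cur, prev
        if mode == TEACHER_FORCED:
            self._y_prev = y[prev]
            self._r_prev = r[prev]
            self._delta_prev = self._r_prev - self._y_prev
            self._pos = self._delta_prev >= 0
            self._in_prev = is_in[cur]

    def __call__(self, theta: np.ndarray) -> float:
        p = self.spec.to_dict(np.asarray(theta, dtype=float))
        if self.mode == TEACHER_FORCED:
            return self._sse_teacher(p)
        return self._sse_latent(p)

    def _alpha_beta_vec(self, p, is_in, pos):
        mid = self.spec.model_id
        if mid == 1:
            return p["alpha"], 1.0
        if mid == 2:
            return p["alpha"], p["beta"]
        if mid == 3:
            return p["alpha"], np.where(is_in, p["beta_in"], p["beta_out"])
        if mid == 4:
            return np.where(is_in, p["alpha_in"], p["alpha_out"]), p["beta"]
        if mid == 5:
            return np.where(pos, p["alpha_pos"], p["alpha_neg"]), p["beta"]
        alpha = np.where(
            pos,
            np.where(is_in, p["alpha_pos_in"], p["alpha_pos_out"]),
            np.where(is_in, p["alpha_neg_in"], p["alpha_neg_out"]),
        )
        return alpha, p["beta"]

    def _sse_teacher(self, p: dict[str, float]) -> float:
        pred = np.empty(self.n_obs)
        i_in, i_out = self._first
        if i_in >= 0:
            pred[i_in] = p["v1_in"]
        if i_out >= 0:
            pred[i_out] = p["v1_out"]
        alpha, beta = self._alpha_beta_vec(p, self._in_prev, self._pos)
        pred[self._cur] = (self._y_prev + alpha * self._delta_prev) * beta
        res = self.y - pred
        return float(np.dot(res, res))

    def _sse_latent(self, p: dict[str, float]) -> float:
        total = 0.0
        state: dict[bool, tuple[float, float]] = {}
        mid = self.spec.model_id
        for i in range(self.n_obs):
            key = bool(self.is_in[i])
            symbol = SYMBOL_IN if key else SYMBOL_OUT
            if key not in state:
                v = initial_value(p, symbol)
            else:
                v_prev, r_prev = state[key]
                v = step_value(mid, p, symbol, v_prev, r_prev)
            total += (self.y[i] - v) ** 2
            state[key] = (v, self.r[i])
        return total
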