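"""Synthetic participants for the approach-avoidance learning task.

Agents respond on the oriented [0, 1] scale with a Rescorla-Wagner policy:
on each valid trial the emitted response is the generating model's
teacher-forced prediction (carried value = the agent's own previous emitted
response) plus Gaussian noise, clamped to [0, 1].  The oriented response is
mapped back through the orientation and the affine normalisation to a signed
distance and a final manikin position, and the outcome is drawn from the
arm's reward schedule.  Invalid (no-movement) trials are injected with a
small per-trial probability; they yield no outcome and do not update the
agent.  Impression ratings carry a stable in-group bias and no pre/post
change beyond sampling noise.

Population defaults reproduce the structure of the conflict-arm cohort:
truncated-normal parameter distributions around the fitted valence-split
model means (alpha+ 0.38, alpha- 0.01, beta 0.67, V1 in-group 0.70,
V1 out-group 0.80).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import models, task
from .task import SYMBOL_IN, SYMBOL_OUT, TaskDesign

#: (mean, sd) of the truncated-normal parameter population, conflict arm,
#: valence-split model (id 5).
CONFLICT_PARAM_DISTS: dict[str, tuple[float, float]] = {
    "alpha_pos": (0.38, 0.39),
    "alpha_neg": (0.01, 0.02),
    "beta": (0.67, 0.18),
    "v1_in": (0.70, 0.24),
    "v1_out": (0.80, 0.21),
}

#: Non-social arm population for the single-rate baseline model (id 1):
#: near-zero learning and symmetric, centred initial values.
NONSOCIAL_MODEL1_PARAM_DISTS: dict[str, tuple[float, float]] = {
    "alpha": (0.01, 0.02),
    "v1_in": (0.53, 0.14),
    "v1_out": (0.53, 0.14),
}

#: Model-5 population with well-separated learning rates and a tight
#: positive-rate spread, used for model-recovery studies where the
#: generating structure should be clearly expressed in the data.
SEPARATED_MODEL5_PARAM_DISTS: dict[str, tuple[float, float]] = {
    "alpha_pos": (0.40, 0.10),
    "alpha_neg": (0.01, 0.02),
    "beta": (0.67, 0.18),
    "v1_in": (0.70, 0.24),
    "v1_out": (0.80, 0.21),
}

#: Social-control arm population: reinforcement is uninformative (50/50)
#: and the generated behaviour is flat — a single-rate learner with a small
#: alpha and equal initial values at the no-movement midpoint.  Centring V1
#: at 0.5 keeps the teacher-forced response policy symmetric under clamping,
#: so per-symbol drifts are null on average, matching the flat control
#: slopes the task is meant to emulate.
CONTROL_PARAM_DISTS: dict[str, tuple[float, float]] = {
    "alpha": (0.01, 0.02),
    "v1_in": (0.50, 0.14),
    "v1_out": (0.50, 0.14),
}

DEFAULT_PARAM_DISTS: dict[int, dict[str, tuple[float, float]]] = {
    1: NONSOCIAL_MODEL1_PARAM_DISTS,
    5: CONFLICT_PARAM_DISTS,
}

#: Default (generating model, parameter population) per study arm.
ARM_DEFAULT_GENERATORS: dict[str, tuple[int, dict[str, tuple[float, float]]]] = {
    task.SOCIAL_CONFLICT: (5, CONFLICT_PARAM_DISTS),
    task.SOCIAL_CONTROL: (1, CONTROL_PARAM_DISTS),
    task.NONSOCIAL_CONTROL: (1, NONSOCIAL_MODEL1_PARAM_DISTS),
}


@dataclass(frozen=True)
class AgentConfig:
    """One synthetic participant: generating model, true parameters, noise.

    ``noise_sd`` is the s.d. of the Gaussian response noise on the oriented
    [0, 1] scale; ``p_invalid`` the per-trial probability of a no-movement
    trial.  Impression means are on the 1-7 Likert scale, with the post-task
    means equal to the pre-task means by construction (null time effect).
    """

    generating_model: int = 5
    true_params: dict[str, float] = field(
        default_factory=lambda: {k: m for k, (m, _) in CONFLICT_PARAM_DISTS.items()}
    )
    noise_sd: float = 0.10
    p_invalid: float = 0.01
    impression_means: dict[str, float] = field(
        default_factory=lambda: {"ingroup": 4.2, "outgroup": 3.7}
    )
    impression_sd: float = 1.1
    identification_mean: float = 4.3
    identification_sd: float = 1.1
    round_ratings: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.p_invalid < 1:
            raise ValueError("p_invalid must be in [0, 1)")
        for g, m in self.impression_means.items():
            if not 1 <= m <= 7:
                raise ValueError(f"impression mean for {g} outside 1-7: {m}")
        spec = models.ModelSpec(self.generating_model)
        theta = spec.vector(self.true_params)
        if np.any(theta < 0) or np.any(theta > 1):
            raise ValueError("true_params outside the [0, 1] bounds")


def simulate_participant(
    agent: AgentConfig,
    design: TaskDesign,
    seed: int | np.random.SeedSequence,
    participant_id: str = "p001",
) -> dict[str, pd.DataFrame]:
    """Forward-simulate one participant through the full task.

    Returns a dict with ``trials`` (one row per decision trial, fixed CSV
    schema), ``ratings`` (pre/post impression ratings per group) and
    ``identification`` (single in-group identification score).
    """
    rng = np.random.default_rng(seed)
    seq_seed = int(rng.integers(2**31))
    blocks = task.build_trial_sequence(design, seq_seed)

    mid = agent.generating_model
    p = agent.true_params
    # carried per-symbol state for the teacher-forced policy
    state: dict[str, tuple[float, float]] = {}
    rows = []
    trial_no = 0
    for b, block in enumerate(blocks, start=1):
        for symbol in block:
            trial_no += 1
            start = rng.uniform(*design.start_jitter)
            invalid = rng.random() < agent.p_invalid
            if invalid:
                rows.append({
                    "participant_id": participant_id, "arm": design.arm,
                    "block": b, "trial": trial_no, "symbol": symbol,
                    "start_pos": start, "final_pos": start,
                    "raw_distance": 0.0, "y_value": np.nan, "valid": False,
                    "outcome_r": np.nan, "outcome_eur": 0.0,
                })
                continue
            if symbol not in state:
                pred = models.initial_value(p, symbol)
            else:
                v_prev, r_prev = state[symbol]
                pred = models.step_value(mid, p, symbol, v_prev, r_prev)
            y = pred if agent.noise_sd == 0 else float(
                np.clip(pred + rng.normal(0.0, agent.noise_sd), 0.0, 1.0)
            )
            unit = float(task.orient_value(y, symbol))  # involution: y -> unit
            raw = float(task.denormalize_distance(unit, design))
            r, eur = task.sample_outcome(design, symbol, raw, rng)
            state[symbol] = (y, float(r))
            rows.append({
                "participant_id": participant_id, "arm": design.arm,
                "block": b, "trial": trial_no, "symbol": symbol,
                "start_pos": start, "final_pos": start + raw,
                "raw_distance": raw, "y_value": y, "valid": True,
                "outcome_r": r, "outcome_eur": eur,
            })

    trials = pd.DataFrame(rows, columns=task.TRIAL_COLUMNS)
    ratings = simulate_impressions(agent, rng)
    ratings.insert(0, "participant_id", participant_id)
    ident = _likert(rng.normal(agent.identification_mean, agent.identification_sd),
                    agent.round_ratings)
    identification = pd.DataFrame(
        {"participant_id": [participant_id], "identification": [ident]}
    )
    return {"trials": trials, "ratings": ratings, "identification": identification}


def _likert(x: float, round_ratings: bool) -> float:
    x = float(np.clip(x, 1.0, 7.0))
    return float(np.round(x)) if round_ratings else x


def simulate_impressions(agent: AgentConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Pre/post impression ratings per group on the 1-7 scale.

    Post-task means equal pre-task means (only sampling noise differs), so
    any pre/post change in a simulated cohort is null by construction.
    """
    rows = []
    for group, mean in agent.impression_means.items():
        for time in ("pre", "post"):
            rating = mean if agent.impression_sd == 0 else rng.normal(mean, agent.impression_sd)
            rows.append({"group": group, "time": time,
                         "rating": _likert(rating, agent.round_ratings)})
    return pd.DataFrame(rows, columns=["group", "time", "rating"])


def draw_parameters(
    param_dists: dict[str, tuple[float, float]],
    rng: np.random.Generator,
    lo: float = 0.0,
    hi: float = 1.0,
) -> dict[str, float]:
    """One parameter vector from independent truncated normals on [lo, hi]."""
    out = {}
    for name, (mean, sd) in param_dists.items():
        if sd < 0:
            raise ValueError(f"negative sd for {name}")
        if sd == 0:
            out[name] = float(np.clip(mean, lo, hi))
            continue
        a, b = (lo - mean) / sd, (hi - mean) / sd
        out[name] = float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
    return out


def simulate_cohort(
    arm: str = task.SOCIAL_CONFLICT,
    n_participants: int = 47,
    param_dists: dict[str, tuple[float, float]] | None = None,
    seed: int | np.random.SeedSequence = 0,
    design: TaskDesign | None = None,
    generating_model: int | None = None,
    agent_template: AgentConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate an independent cohort of agents.

    The generating model and parameter population default per arm
    (:data:`ARM_DEFAULT_GENERATORS`): a valence-split learner under the
    conflict schedule, a near-static single-rate agent under the random
    control and non-social schedules.  Per-agent seeds are spawned
    deterministically from the cohort seed, so a cohort is bit-reproducible
    from ``(seed, config)``.  Returns ``trials`` (long format), ``ratings``,
    ``identification`` and ``true_params`` (one row per participant x
    parameter, for recovery studies).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    design = design or TaskDesign(arm=arm)
    if design.arm != arm:
        raise ValueError("design.arm does not match requested arm")
    if generating_model is None:
        generating_model, arm_dists = ARM_DEFAULT_GENERATORS[arm]
        param_dists = param_dists if param_dists is not None else arm_dists
    if param_dists is None:
        if generating_model not in DEFAULT_PARAM_DISTS:
            raise ValueError(
                f"no default parameter population for model {generating_model}; "
                "pass param_dists explicitly"
            )
        param_dists = DEFAULT_PARAM_DISTS[generating_model]
    template = agent_template or AgentConfig(
        generating_model=generating_model,
        true_params={k: m for k, (m, _) in param_dists.items()},
    )

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(n_participants)
    width = max(3, len(str(n_participants)))
    all_trials, all_ratings, all_ident, all_truth = [], [], [], []
    for i, child in enumerate(children, start=1):
        pid = f"{arm[:4]}_{i:0{width}d}"
        rng = np.random.default_rng(child)
        params = draw_parameters(param_dists, rng)
        agent = replace(template, generating_model=generating_model, true_params=params)
        sim_seed = int(rng.integers(2**31))
        out = simulate_participant(agent, design, sim_seed, participant_id=pid)
        all_trials.append(out["trials"])
        all_ratings.append(out["ratings"])
        all_ident.append(out["identification"])
        all_truth.extend(
            {"participant_id": pid, "model": generating_model, "param": k, "value": v}
            for k, v in params.items()
        )
    return {
        "trials": pd.concat(all_trials, ignore_index=True),
        "ratings": pd.concat(all_ratings, ignore_index=True),
        "identification": pd.concat(all_ident, ignore_index=True),
        "true_params": pd.DataFrame(all_truth,
                                    columns=["participant_id", "model", "param", "value"]),
    }
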