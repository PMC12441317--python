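"""Per-participant parameter estimation by bound-constrained SSE minimisation.

Each model is fitted separately to each participant's valid trials by
minimising the sum of squared errors between observed oriented responses and
model predictions, using L-BFGS-B within the unit box [0, 1]^K, restarted
from several uniformly drawn start vectors to escape local minima.  The
lowest-SSE solution wins; ties (within 1e-10) go to the lowest start index
so results are reproducible.  If the winning quasi-Newton run reports
non-convergence (typically a bound corner), a gradient-free Powell polish is
attempted and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from . import models, selection
from .models import ModelSpec, SSEObjective, TEACHER_FORCED
from .task import SYMBOL_IN, SYMBOL_OUT

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-10


@dataclass
class FitResult:
    """Outcome of fitting one model to one participant."""

    participant_id: str
    model_id: int
    estimates: dict[str, float]
    sse: float
    n_obs: int
    bic: float
    r2: float
    n_starts: int
    best_start_index: int
    converged: bool
    fallback_used: bool
    seed: int

    def to_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "model": self.model_id,
            **self.estimates,
            "sse": self.sse,
            "n_obs": self.n_obs,
            "bic": self.bic,
            "r2": self.r2,
            "n_starts": self.n_starts,
            "best_start_index": self.best_start_index,
            "converged": self.converged,
            "fallback_used": self.fallback_used,
        }
        return row


def _check_trials(trials: pd.DataFrame) -> pd.DataFrame:
    valid = trials[trials["valid"].astype(bool)] if "valid" in trials.columns else trials
    for symbol in (SYMBOL_IN, SYMBOL_OUT):
        n = int((valid["symbol"] == symbol).sum())
        if n < 2:
            raise ValueError(
                f"too few valid trials for {symbol}: {n} (need >= 2 to fit)"
            )
    return valid


def fit_participant(
    model_id: int,
    trials: pd.DataFrame,
    n_starts: int = 10,
    seed: int | np.random.SeedSequence = 0,
    mode: str = TEACHER_FORCED,
    participant_id: str | None = None,
) -> FitResult:
    """Multi-start bound-constrained SSE fit of one model to one participant.

    Deterministic given ``(data, seed, n_starts, mode)``.  Raises if every
    start fails outright or the participant has fewer than two valid trials
    for either symbol.
    """
    valid = _check_trials(trials)
    if participant_id is None:
        participant_id = str(valid["participant_id"].iloc[0]) if "participant_id" in valid else "?"
    spec = ModelSpec(model_id)
    objective = SSEObjective(model_id, valid, mode=mode)
    rng = np.random.default_rng(seed)
    seed_int = int(rng.integers(2**31))
    rng = np.random.default_rng(seed_int)
    starts = rng.uniform(0.0, 1.0, size=(n_starts, spec.k))

    results = []
    for x0 in starts:
        try:
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B", bounds=spec.bounds
            )
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover
            logger.debug("start failed for %s model %d: %s", participant_id, model_id, exc)
            res = None
        results.append(res)

    usable = [(i, r) for i, r in enumerate(results) if r is not None and np.isfinite(r.fun)]
    if not usable:
        raise RuntimeError(
            f"all {n_starts} optimisation starts failed for participant "
            f"{participant_id}, model {model_id}"
        )
    best_sse = min(r.fun for _, r in usable)
    best_index, best = next((i, r) for i, r in usable if r.fun <= best_sse + _TIE_TOL)

    fallback_used = False
    if not best.success:
        polish = optimize.minimize(
            objective, best.x, method="Powell", bounds=spec.bounds
        )
        if polish.fun <= best.fun:
            best = polish
            fallback_used = True

    theta = np.clip(best.x, 0.0, 1.0)
    final_sse = float(objective(theta))
    n_obs = objective.n_obs
    bic = selection.bic(final_sse, n_obs, spec.k) if final_sse > 0 else -np.inf
    y = objective.y
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - final_sse / sst if sst > 0 else np.nan
    return FitResult(
        participant_id=participant_id,
        model_id=model_id,
        estimates=spec.to_dict(theta),
        sse=final_sse,
        n_obs=n_obs,
        bic=float(bic),
        r2=float(r2),
        n_starts=n_starts,
        best_start_index=best_index,
        converged=bool(best.success),
        fallback_used=fallback_used,
        seed=seed_int,
    )


def fit_cohort(
    model_ids,
    cohort: pd.DataFrame,
    n_starts: int = 10,
    seed: int | np.random.SeedSequence = 0,
    mode: str = TEACHER_FORCED,
) -> pd.DataFrame:
    """Fit every model to every participant of a long-format cohort table.

    Per-cell seeds are spawned deterministically from the master seed.
    Failures in single cells are logged and flagged (``failed`` column, NaN
    statistics) without aborting the cohort.
    """
    model_ids = list(model_ids)
    pids = sorted(cohort["participant_id"].unique())
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = iter(ss.spawn(len(pids) * len(model_ids)))
    rows = []
    for pid in pids:
        sub = cohort[cohort["participant_id"] == pid].sort_values("trial")
        for mid in model_ids:
            child = next(children)
            try:
                fit = fit_participant(
                    mid, sub, n_starts=n_starts, seed=child, mode=mode,
                    participant_id=pid,
                )
                row = fit.to_row()
                row["failed"] = False
            except Exception as exc:
                logger.warning("fit failed for %s model %d: %s", pid, mid, exc)
                row = {"participant_id": pid, "model": mid, "failed": True,
                       "error": str(exc)}
            rows.append(row)
    table = pd.DataFrame(rows)
    # stable column order: ids, params, stats
    params = [p for mid in model_ids for p in models.MODEL_PARAMS[mid]]
    param_cols = list(dict.fromkeys(params))
    lead = ["participant_id", "model"]
    stats_cols = [c for c in ("sse", "n_obs", "bic", "r2", "n_starts",
                              "best_start_index", "converged", "fallback_used",
                              "failed", "error") if c in table.columns]
    cols = lead + [c for c in param_cols if c in table.columns] + stats_cols
    return table[cols]
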