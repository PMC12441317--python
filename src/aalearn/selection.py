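"""Model comparison, parameter contrasts, power analysis, recovery studies.

Fitted models are compared by the Bayesian information criterion computed
from the SSE,

    BIC = n * ln(SSE / n) + k * ln(n),

summed across participants (lower is better), alongside the mean
per-participant R^2 = 1 - SSE/SST.  Parameter contrasts use Welch two-sample
t-tests.  The design's a-priori sample size comes from the exact
noncentral-t power function of a two-sided paired t-test.  Parameter and
model recovery close the loop: simulate agents with known parameters, refit,
and check that truth is recovered and the generating model selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import models
from .models import MODEL_IDS, param_count
from .task import SYMBOL_IN, SYMBOL_OUT, TaskDesign


def bic(sse: float, n_obs: int, k: int) -> float:
    """Bayesian information criterion from a least-squares fit.

    ``n * ln(SSE/n) + k * ln(n)``.  A perfect fit (SSE = 0) diverges to
    minus infinity and is rejected here; callers may treat it as a
    perfect-fit sentinel.
    """
    if sse <= 0:
        raise ValueError("BIC undefined for SSE <= 0 (perfect fit)")
    if n_obs < 1 or k < 1:
        raise ValueError("need n_obs >= 1 and k >= 1")
    return float(n_obs * np.log(sse / n_obs) + k * np.log(n_obs))


def r_squared(observations, predictions) -> float:
    """Goodness of fit: 1 - SSE/SST, SST about the observation mean."""
    y = np.asarray(observations, dtype=float)
    pred = np.asarray(predictions, dtype=float)
    if y.shape != pred.shape or y.size < 2:
        raise ValueError("need >= 2 paired observations and predictions")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero variance in observations; R^2 undefined")
    sse = float(np.sum((y - pred) ** 2))
    return 1.0 - sse / sst


@dataclass
class ComparisonTable:
    """Per-model comparison: K, mean R^2, summed BIC, and the winner."""

    table: pd.DataFrame
    winner: int
    n_participants: int
    n_dropped: int = 0

    def to_markdown(self) -> str:
        lines = ["| model | K | mean R2 | summed BIC |", "| --- | --- | --- | --- |"]
        for mid, row in self.table.iterrows():
            mark = "**" if mid == self.winner else ""
            lines.append(
                f"| {mark}model {mid}{mark} | {int(row['K'])} | "
                f"{row['mean_r2']:.2f} | {row['summed_bic']:.0f} |"
            )
        lines.append(f"\nWinning model (lowest summed BIC): model {self.winner}; "
                     f"{self.n_participants} participants"
                     + (f", {self.n_dropped} dropped listwise" if self.n_dropped else "")
                     + ".")
        return "\n".join(lines)


def compare_models(fit_table: pd.DataFrame) -> ComparisonTable:
    """Summed-BIC model comparison over a participant x model fit table.

    Participants missing a (flagged) fit for any model are dropped listwise,
    with the count reported.  The winner has the smallest summed BIC; exact
    ties go to the smaller K.
    """
    tab = fit_table.copy()
    if "failed" in tab.columns:
        tab = tab[~tab["failed"].astype(bool)]
    model_ids = sorted(tab["model"].unique())
    counts = tab.groupby("participant_id")["model"].nunique()
    complete = set(counts[counts == len(model_ids)].index)
    incomplete = set(counts.index) - complete
    if incomplete and "failed" not in fit_table.columns:
        raise ValueError(
            f"ragged fit table without 'failed' flags: participants "
            f"{sorted(incomplete)} lack fits for some models"
        )
    tab = tab[tab["participant_id"].isin(complete)]
    if tab.empty:
        raise ValueError("no participant with complete fits across models")
    summary = tab.groupby("model").agg(
        mean_r2=("r2", "mean"), summed_bic=("bic", "sum")
    )
    summary["K"] = [param_count(int(m)) for m in summary.index]
    summary = summary[["K", "mean_r2", "summed_bic"]]
    best = summary["summed_bic"].min()
    tied = summary[summary["summed_bic"] == best]
    winner = int(tied["K"].idxmin()) if len(tied) > 1 else int(tied.index[0])
    return ComparisonTable(
        table=summary, winner=winner,
        n_participants=len(complete), n_dropped=len(incomplete),
    )


def welch_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch two-sample t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def power_paired_t(n: int, effect_size: float, alpha: float = 0.05) -> float:
    """Exact power of a two-sided paired t-test at n pairs.

    Noncentral t with df = n - 1 and noncentrality d * sqrt(n).
    """
    if n < 2:
        return 0.0
    df = n - 1
    nc = effect_size * np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def required_sample_size_paired_t(
    effect_size: float, alpha: float = 0.05, power: float = 0.80, n_max: int = 1_000_000
) -> int:
    """Smallest n with two-sided paired-t power >= target.

    With the pilot effect size d = 0.444, alpha = 0.05 and power 0.80 this
    returns 42 pairs.
    """
    if effect_size <= 0:
        raise ValueError("effect size must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if power_paired_t(n, effect_size, alpha) >= power:
            return n
    raise ValueError(f"no n <= {n_max} reaches the requested power")


def per_symbol_slopes(cohort: pd.DataFrame) -> pd.DataFrame:
    """OLS slope of raw distance on trial index, per participant x symbol.

    A lightweight descriptive of learning-related drift: under the conflict
    schedule the out-group slope is positive (approach learned) and the
    in-group slope negative; under the random control schedule both are flat.
    Cells with fewer than two valid trials are flagged and carry NaN.
    """
    rows = []
    valid = cohort[cohort["valid"].astype(bool)]
    for (pid, symbol), sub in valid.groupby(["participant_id", "symbol"]):
        if len(sub) < 2:
            rows.append({"participant_id": pid, "symbol": symbol,
                         "slope": np.nan, "intercept": np.nan, "n": len(sub)})
            continue
        slope, intercept = np.polyfit(sub["trial"].to_numpy(dtype=float),
                                      sub["raw_distance"].to_numpy(dtype=float), 1)
        rows.append({"participant_id": pid, "symbol": symbol,
                     "slope": float(slope), "intercept": float(intercept),
                     "n": len(sub)})
    return pd.DataFrame(rows, columns=["participant_id", "symbol", "slope",
                                       "intercept", "n"])


def slope_contrast(slopes: pd.DataFrame) -> tuple[float, float, float]:
    """Welch t of out-group vs in-group per-participant slopes."""
    pivot = slopes.pivot(index="participant_id", columns="symbol", values="slope").dropna()
    return welch_t(pivot[SYMBOL_OUT], pivot[SYMBOL_IN])


@dataclass
class RecoveryReport:
    """Simulate-refit validation results.

    ``params``: per-parameter truth vs recovered summary (bias, RMSE,
    Pearson correlation); ``pairs``: the underlying per-agent table;
    ``n_failed``: fits excluded from the summaries.
    """

    params: pd.DataFrame
    pairs: pd.DataFrame
    n_failed: int = 0


def parameter_recovery(
    model_id: int,
    design: TaskDesign,
    param_dists: dict[str, tuple[float, float]] | None = None,
    noise_sd: float = 0.10,
    n_agents: int = 50,
    seed: int = 0,
    n_starts: int = 10,
    p_invalid: float = 0.0,
) -> RecoveryReport:
    """Simulate agents with known parameters, refit, and tabulate recovery."""
    from . import cohort as cohort_mod
    from . import fitting

    ss = np.random.SeedSequence(seed)
    sim_ss, fit_ss = ss.spawn(2)
    template = cohort_mod.AgentConfig(
        generating_model=model_id,
        true_params=(
            {k: m for k, (m, _) in (param_dists or
                                    cohort_mod.DEFAULT_PARAM_DISTS[model_id]).items()}
        ),
        noise_sd=noise_sd, p_invalid=p_invalid,
    )
    sim = cohort_mod.simulate_cohort(
        arm=design.arm, n_participants=n_agents, param_dists=param_dists,
        seed=sim_ss, design=design, generating_model=model_id,
        agent_template=template,
    )
    fits = fitting.fit_cohort([model_id], sim["trials"], n_starts=n_starts, seed=fit_ss)
    n_failed = int(fits["failed"].sum()) if "failed" in fits.columns else 0
    ok = fits[~fits.get("failed", pd.Series(False, index=fits.index)).astype(bool)]

    truth = sim["true_params"].pivot(index="participant_id", columns="param",
                                     values="value")
    names = models.MODEL_PARAMS[model_id]
    merged = truth.add_suffix("_true").join(
        ok.set_index("participant_id")[list(names)].add_suffix("_rec"), how="inner"
    )
    rows = []
    for name in names:
        t = merged[f"{name}_true"].to_numpy()
        r = merged[f"{name}_rec"].to_numpy()
        corr = float(np.corrcoef(t, r)[0, 1]) if np.std(t) > 0 and np.std(r) > 0 else np.nan
        rows.append({
            "param": name,
            "true_mean": float(t.mean()),
            "recovered_mean": float(r.mean()),
            "bias": float((r - t).mean()),
            "rmse": float(np.sqrt(np.mean((r - t) ** 2))),
            "correlation": corr,
        })
    return RecoveryReport(
        params=pd.DataFrame(rows), pairs=merged.reset_index(), n_failed=n_failed
    )


def model_recovery(
    generating_models=(1, 5),
    design: TaskDesign | None = None,
    generator_dists: dict[int, dict[str, tuple[float, float]]] | None = None,
    noise_sd: float = 0.10,
    n_cohorts: int = 10,
    n_agents: int = 16,
    seed: int = 0,
    n_starts: int = 6,
    fit_models=MODEL_IDS,
    p_invalid: float = 0.0,
) -> pd.DataFrame:
    """Confusion matrix of generating model x summed-BIC-selected model.

    For each generating model, ``n_cohorts`` independent cohorts are
    simulated, all candidate models fitted to each, and the summed-BIC
    winner recorded.  Rows sum to ``n_cohorts``.
    """
    from . import cohort as cohort_mod
    from . import fitting

    design = design or TaskDesign()
    defaults = dict(cohort_mod.DEFAULT_PARAM_DISTS)
    defaults[5] = cohort_mod.SEPARATED_MODEL5_PARAM_DISTS
    generator_dists = {**defaults, **(generator_dists or {})}
    confusion = pd.DataFrame(
        0, index=list(generating_models), columns=list(fit_models), dtype=int
    )
    ss = np.random.SeedSequence(seed)
    for gen in generating_models:
        dists = generator_dists.get(gen)
        if dists is None:
            raise ValueError(f"no parameter population for generating model {gen}")
        template = cohort_mod.AgentConfig(
            generating_model=gen,
            true_params={k: m for k, (m, _) in dists.items()},
            noise_sd=noise_sd, p_invalid=p_invalid,
        )
        for rep_ss in ss.spawn(n_cohorts):
            sim_ss, fit_ss = rep_ss.spawn(2)
            sim = cohort_mod.simulate_cohort(
                arm=design.arm, n_participants=n_agents, param_dists=dists,
                seed=sim_ss, design=design, generating_model=gen,
                agent_template=template,
            )
            fits = fitting.fit_cohort(fit_models, sim["trials"],
                                      n_starts=n_starts, seed=fit_ss)
            winner = compare_models(fits).winner
            confusion.loc[gen, winner] += 1
    confusion.index.name = "generating_model"
    confusion.columns.name = "selected_model"
    return confusion
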