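"""Study designs and trial mechanics for the approach-avoidance learning task.

Participants move a manikin along a horizontal line toward (approach) or away
from (avoid) an abstract symbol shown at the right end of the line.  In the
two social arms the symbols stand for an in-group and an out-group individual;
in the non-social arm the same symbols carry no social meaning.  Approach and
avoidance are rewarded or punished (+-0.05 EUR) with probabilities that depend
on the study arm, symbol and movement direction.

This module encodes the three study designs (reward schedules, block/trial
counts, symbol-sequence constraints), the distance normalisation used for
modelling, the orientation (in-group inversion) of the response scale, and
the per-participant invalid-trial exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# Study arms
SOCIAL_CONFLICT = "social_conflict"
SOCIAL_CONTROL = "social_control"
NONSOCIAL_CONTROL = "nonsocial_control"
ARMS = (SOCIAL_CONFLICT, SOCIAL_CONTROL, NONSOCIAL_CONTROL)

# Symbols.  Symbol 1 plays the in-group role in the social arms and is the
# "inverted" symbol in all arms (see orient_value); symbol 2 plays the
# out-group role.
SYMBOL_IN = "s1_ingroup"
SYMBOL_OUT = "s2_outgroup"
SYMBOLS = (SYMBOL_IN, SYMBOL_OUT)

APPROACH = "approach"
AVOID = "avoid"

#: Fixed column order of the trial-level CSV interchange format.
TRIAL_COLUMNS = [
    "participant_id", "arm", "block", "trial", "symbol",
    "start_pos", "final_pos", "raw_distance", "y_value",
    "valid", "outcome_r", "outcome_eur",
]


def _default_schedule(arm: str) -> dict[tuple[str, str], float]:
    """Reward probability per (symbol, direction) cell for a study arm.

    Conflict and non-social arms: approaching symbol 2 (out-group) is
    rewarded on 80% of trials, approaching symbol 1 (in-group) on 20%;
    avoidance probabilities are complementary.  The social control arm pays
    rewards at 50% regardless of symbol and direction.
    """
    if arm == SOCIAL_CONTROL:
        return {(s, d): 0.5 for s in SYMBOLS for d in (APPROACH, AVOID)}
    return {
        (SYMBOL_IN, APPROACH): 0.2,
        (SYMBOL_IN, AVOID): 0.8,
        (SYMBOL_OUT, APPROACH): 0.8,
        (SYMBOL_OUT, AVOID): 0.2,
    }


@dataclass(frozen=True)
class TaskDesign:
    """Design contract for one study arm.

    Parameters
    ----------
    arm:
        One of ``social_conflict``, ``social_control``, ``nonsocial_control``.
    n_blocks, trials_per_block:
        3 blocks of 40 trials (20 per symbol) by default, i.e. 120 decision
        trials (60 per symbol) per participant.
    max_run:
        Maximum number of consecutive same-symbol trials (default 2).
    reward_schedule:
        Mapping ``(symbol, direction) -> P(reward)``; defaults per arm.
    outcome_magnitude:
        Reward/punishment size in EUR (default 0.05).
    start_jitter:
        Interval of line fractions from which the manikin's start position is
        drawn uniformly (default [0.40, 0.60]).
    max_excursion:
        Largest |signed distance| reachable from any jittered start, the
        half-width D of the affine distance normalisation (default 0.60).
    dictator_endowment:
        Endowment of the post-task one-shot allocation game in EUR; retained
        in full it contributes to the maximum variable payout.
    """

    arm: str = SOCIAL_CONFLICT
    n_blocks: int = 3
    trials_per_block: int = 40
    max_run: int = 2
    reward_schedule: Mapping[tuple[str, str], float] | None = None
    outcome_magnitude: float = 0.05
    start_jitter: tuple[float, float] = (0.40, 0.60)
    max_excursion: float = 0.60
    dictator_endowment: float = 1.0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.reward_schedule is None:
            object.__setattr__(self, "reward_schedule", _default_schedule(self.arm))
        if self.trials_per_block % 2:
            raise ValueError("trials_per_block must be even (equal per-symbol counts)")
        if self.max_run < 1:
            raise ValueError("max_run must be >= 1")
        for cell, p in self.reward_schedule.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"schedule probability out of [0,1] for {cell}: {p}")
        if self.arm == SOCIAL_CONTROL:
            if any(p != 0.5 for p in self.reward_schedule.values()):
                raise ValueError("social_control arm requires all probabilities = 0.5")
        else:
            for s in SYMBOLS:
                pa = self.reward_schedule[(s, APPROACH)]
                pv = self.reward_schedule[(s, AVOID)]
                if abs(pa + pv - 1.0) > 1e-12:
                    raise ValueError(
                        f"{self.arm}: P(reward|approach)+P(reward|avoid) must be 1 "
                        f"for {s}, got {pa}+{pv}"
                    )

    @property
    def trials_per_symbol_per_block(self) -> int:
        return self.trials_per_block // 2

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def max_variable_payout(self) -> float:
        """Largest achievable variable payout in EUR.

        All decision trials rewarded plus the allocation-game endowment
        retained in full: 120 x 0.05 + 1.00 = 7.00 EUR under defaults.
        """
        return self.n_trials * self.outcome_magnitude + self.dictator_endowment


def build_trial_sequence(design: TaskDesign, seed: int) -> list[list[str]]:
    """Pseudo-random symbol order per block under the run-length constraint.

    Each block contains exactly ``trials_per_block/2`` trials of each symbol
    and no more than ``max_run`` consecutive trials of the same symbol.
    Symbols are drawn position by position, uniformly among the admissible
    choices under a feasibility look-ahead, so generation never stalls on a
    satisfiable constraint; the same seed always yields the same sequence.

    Raises
    ------
    RuntimeError
        If the constraint is infeasible (no admissible symbol at some
        position, e.g. unequal counts that max_run cannot interleave).
    """
    rng = np.random.default_rng(seed)
    half = design.trials_per_symbol_per_block
    blocks = [
        _sample_block(half, design.max_run, rng) for _ in range(design.n_blocks)
    ]
    return blocks


def _completable(n_this: int, n_other: int, trailing: int, max_run: int) -> bool:
    """Can n_this more of the trailing symbol still be interleaved legally?

    The trailing symbol's items fill the gaps around the other symbol's
    items: the immediate gap takes at most ``max_run - trailing`` more, each
    of the ``n_other`` later gaps at most ``max_run``; the other symbol's
    runs are capped the same way with an unconstrained leading gap.
    """
    return (n_this <= (max_run - trailing) + n_other * max_run
            and n_other <= (n_this + 1) * max_run)


def _sample_block(half: int, max_run: int, rng: np.random.Generator) -> list[str]:
    counts = {SYMBOL_IN: half, SYMBOL_OUT: half}
    out: list[str] = []
    last, run = None, 0
    for pos in range(2 * half):
        candidates = []
        for sym in SYMBOLS:
            if counts[sym] == 0:
                continue
            new_run = run + 1 if sym == last else 1
            if new_run > max_run:
                continue
            other = SYMBOL_OUT if sym == SYMBOL_IN else SYMBOL_IN
            if _completable(counts[sym] - 1, counts[other], new_run, max_run):
                candidates.append(sym)
        if not candidates:
            raise RuntimeError(
                f"symbol sequence infeasible at position {pos}: max_run="
                f"{max_run} cannot interleave the remaining counts {counts}"
            )
        sym = candidates[int(rng.integers(len(candidates)))]
        out.append(sym)
        counts[sym] -= 1
        run = run + 1 if sym == last else 1
        last = sym
    return out


def longest_run(labels: Iterable[str]) -> int:
    """Length of the longest run of identical consecutive labels."""
    best = run = 0
    prev = object()
    for lab in labels:
        run = run + 1 if lab == prev else 1
        best = max(best, run)
        prev = lab
    return best


def direction_of(raw_distance: float) -> str:
    """Movement direction: approach iff the signed distance is > 0.

    A confirmed zero displacement is classified as avoidance (approach is
    defined strictly as distance > 0).
    """
    return APPROACH if raw_distance > 0 else AVOID


def sample_outcome(
    design: TaskDesign,
    symbol: str,
    raw_distance: float,
    rng: np.random.Generator,
    valid: bool = True,
) -> tuple[int, float]:
    """Draw the binary outcome for one valid trial.

    Returns ``(outcome_r, outcome_eur)`` with ``outcome_r`` 1 for reward and
    0 for punishment, and ``outcome_eur`` the signed payout.  Outcomes are
    undefined for invalid (no-movement) trials, which receive no feedback.
    """
    if not valid:
        raise ValueError("outcomes are undefined for invalid trials")
    p = design.reward_schedule[(symbol, direction_of(raw_distance))]
    r = int(rng.random() < p)
    eur = design.outcome_magnitude if r else -design.outcome_magnitude
    return r, eur


def normalize_distance(raw_distance: float, design: TaskDesign) -> float:
    """Affine map of the signed distance onto [0, 1].

    ``(raw + D) / (2D)`` with D = ``max_excursion``: -D maps to 0, no
    movement to 0.5, +D to 1.
    """
    d = design.max_excursion
    raw = np.asarray(raw_distance, dtype=float)
    if np.any(np.abs(raw) > d + 1e-12):
        raise ValueError(f"|raw_distance| exceeds max_excursion {d}")
    return (raw + d) / (2.0 * d)


def denormalize_distance(unit_value: float, design: TaskDesign) -> float:
    """Inverse of :func:`normalize_distance`: unit value in [0,1] -> signed distance."""
    u = np.asarray(unit_value, dtype=float)
    if np.any((u < -1e-12) | (u > 1 + 1e-12)):
        raise ValueError("unit value outside [0, 1]")
    d = design.max_excursion
    return u * 2.0 * d - d


def orient_value(unit_value, symbol: str):
    """Orient the normalised distance along the reward dimension.

    Symbol-1 (in-group) trials are reflected (``1 - u``) so that larger
    oriented values always point in the rewarded direction under the 80/20
    schedules; symbol-2 (out-group) trials pass through unchanged.  The map
    is an involution: applying it twice restores the input.
    """
    u = np.asarray(unit_value, dtype=float)
    if symbol == SYMBOL_IN:
        return 1.0 - u
    if symbol == SYMBOL_OUT:
        return u if u.ndim else float(u)
    raise ValueError(f"unknown symbol {symbol!r}")


def invalid_cells(trials: pd.DataFrame, max_invalid_per_cell: int = 1) -> list[tuple[int, str, int]]:
    """(block, symbol, n_invalid) for every block x symbol cell over the limit."""
    if not {"block", "symbol", "valid"}.issubset(trials.columns):
        raise ValueError("trials must carry 'block', 'symbol' and 'valid' columns")
    counts = (~trials["valid"].astype(bool)).groupby(
        [trials["block"], trials["symbol"]]
    ).sum()
    return [
        (int(block), str(symbol), int(n))
        for (block, symbol), n in counts.items()
        if n > max_invalid_per_cell
    ]


def apply_exclusion(trials: pd.DataFrame, max_invalid_per_cell: int = 1) -> tuple[bool, list[str]]:
    """Participant-level exclusion rule.

    A participant is dropped iff any block x symbol cell contains more than
    one invalid (no-movement) trial — more than 5% of the 20 trials per cell
    under the default design.  Returns ``(keep, reasons)``; ``reasons``
    names the offending cells.
    """
    offending = invalid_cells(trials, max_invalid_per_cell)
    reasons = [
        f"block {block}, {symbol}: {n} invalid trials (> {max_invalid_per_cell})"
        for block, symbol, n in offending
    ]
    return (len(offending) == 0, reasons)


def exclude_participants(
    cohort: pd.DataFrame, max_invalid_per_cell: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the exclusion rule to a long-format cohort table.

    Returns the retained trials and a per-participant report with columns
    ``participant_id``, ``keep``, ``reasons``.
    """
    reports = []
    for pid, sub in cohort.groupby("participant_id", sort=True):
        keep, reasons = apply_exclusion(sub, max_invalid_per_cell)
        reports.append({"participant_id": pid, "keep": keep, "reasons": "; ".join(reasons)})
    report = pd.DataFrame(reports, columns=["participant_id", "keep", "reasons"])
    kept_ids = set(report.loc[report["keep"], "participant_id"])
    return cohort[cohort["participant_id"].isin(kept_ids)].copy(), report
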