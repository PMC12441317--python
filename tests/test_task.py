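import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aalearn as a
from aalearn.task import (
    APPROACH, AVOID, TaskDesign, _completable, build_trial_sequence,
    direction_of, longest_run, sample_outcome,
)


class TestDesign:
    def test_control_schedule_is_flat(self, control_design):
        assert all(p == 0.5 for p in control_design.reward_schedule.values())

    @pytest.mark.parametrize("arm", [a.SOCIAL_CONFLICT, a.NONSOCIAL_CONTROL])
    def test_contingent_schedules_complementary(self, arm):
        d = TaskDesign(arm=arm)
        for s in (a.SYMBOL_IN, a.SYMBOL_OUT):
            assert d.reward_schedule[(s, APPROACH)] + d.reward_schedule[(s, AVOID)] == 1.0
        assert d.reward_schedule[(a.SYMBOL_OUT, APPROACH)] == 0.8
        assert d.reward_schedule[(a.SYMBOL_IN, APPROACH)] == 0.2

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            TaskDesign(arm="solo")
        with pytest.raises(ValueError):
            TaskDesign(trials_per_block=41)
        with pytest.raises(ValueError):
            TaskDesign(max_run=0)
        with pytest.raises(ValueError):
            TaskDesign(arm=a.SOCIAL_CONTROL,
                       reward_schedule={(s, dr): 0.6 for s in (a.SYMBOL_IN, a.SYMBOL_OUT)
                                        for dr in (APPROACH, AVOID)})

    def test_trial_counts(self, design):
        assert design.n_trials == 120
        assert design.trials_per_symbol_per_block == 20


class TestSequence:
    @given(seed=st.integers(0, 10_000), max_run=st.integers(1, 3))
    @settings(max_examples=60, deadline=None)
    def test_balanced_counts_and_run_limit(self, seed, max_run):
        d = TaskDesign(max_run=max_run)
        blocks = build_trial_sequence(d, seed)
        assert len(blocks) == d.n_blocks
        for block in blocks:
            assert len(block) == d.trials_per_block
            assert block.count(a.SYMBOL_IN) == block.count(a.SYMBOL_OUT) == 20
            assert longest_run(block) <= max_run

    def test_same_seed_identical(self, design):
        assert build_trial_sequence(design, 5) == build_trial_sequence(design, 5)
        assert build_trial_sequence(design, 5) != build_trial_sequence(design, 6)

    def test_completability_look_ahead(self):
        # 5 trailing-symbol items fit into 2 gaps of 2 plus the current gap of 1
        assert _completable(5, 2, 1, 2)
        # 6 do not
        assert not _completable(6, 2, 1, 2)
        # the other symbol is capped at (n_this + 1) * max_run
        assert not _completable(1, 5, 1, 2)


class TestOutcomes:
    @pytest.mark.parametrize("arm,symbol,raw,expected", [
        (a.SOCIAL_CONFLICT, a.SYMBOL_OUT, +0.3, 0.80),
        (a.SOCIAL_CONFLICT, a.SYMBOL_IN, +0.3, 0.20),
        (a.SOCIAL_CONFLICT, a.SYMBOL_IN, -0.3, 0.80),
        (a.SOCIAL_CONTROL, a.SYMBOL_OUT, +0.3, 0.50),
        (a.SOCIAL_CONTROL, a.SYMBOL_IN, -0.3, 0.50),
        (a.NONSOCIAL_CONTROL, a.SYMBOL_OUT, +0.3, 0.80),
    ])
    def test_empirical_rates_match_schedule(self, arm, symbol, raw, expected):
        d = TaskDesign(arm=arm)
        rng = np.random.default_rng(42)
        n = 10_000
        hits = sum(sample_outcome(d, symbol, raw, rng)[0] for _ in range(n))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) <= 3 * se

    def test_payout_signs(self, design):
        rng = np.random.default_rng(0)
        r, eur = sample_outcome(design, a.SYMBOL_OUT, 0.3, rng)
        assert eur == (0.05 if r else -0.05)

    def test_invalid_trial_rejected(self, design):
        with pytest.raises(ValueError):
            sample_outcome(design, a.SYMBOL_OUT, 0.0, np.random.default_rng(0),
                           valid=False)

    def test_zero_distance_is_avoidance(self):
        assert direction_of(0.0) == AVOID
        assert direction_of(1e-9) == APPROACH


class TestNormalisationAndOrientation:
    @pytest.mark.parametrize("raw,expected", [
        (0.0, 0.5), (0.6, 1.0), (-0.6, 0.0), (-0.3, 0.25),
    ])
    def test_affine_map(self, design, raw, expected):
        assert a.normalize_distance(raw, design) == pytest.approx(expected)

    def test_out_of_range_raises(self, design):
        with pytest.raises(ValueError):
            a.normalize_distance(0.61, design)
        with pytest.raises(ValueError):
            a.denormalize_distance(1.01, design)

    @pytest.mark.parametrize("symbol,u,expected", [
        (a.SYMBOL_IN, 0.8, 0.2), (a.SYMBOL_IN, 0.5, 0.5), (a.SYMBOL_OUT, 0.8, 0.8),
    ])
    def test_orientation(self, symbol, u, expected):
        assert a.orient_value(u, symbol) == pytest.approx(expected)

    @given(raw=st.floats(-0.6, 0.6), symbol=st.sampled_from([a.SYMBOL_IN, a.SYMBOL_OUT]))
    @settings(max_examples=100, deadline=None)
    def test_normalise_orient_bijection(self, raw, symbol):
        d = TaskDesign()
        y = a.orient_value(a.normalize_distance(raw, d), symbol)
        assert 0.0 <= y <= 1.0
        back = a.denormalize_distance(a.orient_value(y, symbol), d)
        assert back == pytest.approx(raw, abs=1e-12)


def _participant(invalid_cells):
    """3 blocks x 2 symbols x 20 trials with given per-cell invalid counts."""
    rows = []
    trial = 0
    for block in (1, 2, 3):
        for symbol in (a.SYMBOL_IN, a.SYMBOL_OUT):
            n_bad = invalid_cells.get((block, symbol), 0)
            for k in range(20):
                trial += 1
                rows.append({"participant_id": "p1", "block": block,
                             "trial": trial, "symbol": symbol,
                             "valid": k >= n_bad})
    return pd.DataFrame(rows)


class TestExclusion:
    def test_two_invalid_in_one_cell_drops(self):
        keep, reasons = a.apply_exclusion(_participant({(1, a.SYMBOL_IN): 2}))
        assert not keep
        assert "block 1" in reasons[0]

    def test_one_invalid_everywhere_keeps(self):
        cells = {(b, s): 1 for b in (1, 2, 3) for s in (a.SYMBOL_IN, a.SYMBOL_OUT)}
        keep, reasons = a.apply_exclusion(_participant(cells))
        assert keep and reasons == []

    def test_clean_participant_kept(self):
        keep, _ = a.apply_exclusion(_participant({}))
        assert keep

    def test_cohort_filtering(self):
        good = _participant({})
        bad = _participant({(2, a.SYMBOL_OUT): 3}).assign(participant_id="p2")
        cohort = pd.concat([good, bad], ignore_index=True)
        kept, report = a.exclude_participants(cohort)
        assert set(kept["participant_id"]) == {"p1"}
        assert report.set_index("participant_id")["keep"].to_dict() == {
            "p1": True, "p2": False}

    def test_missing_columns_error(self):
        with pytest.raises(ValueError):
            a.apply_exclusion(pd.DataFrame({"block": [1]}))
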