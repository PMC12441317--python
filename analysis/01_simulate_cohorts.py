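"""Simulate the three study arms and apply the invalid-trial exclusion.

Sixty participants are recruited per arm (the study's recruitment target);
each performs 3 blocks x 40 trials of the approach-avoidance task under the
arm's reward schedule.  Participants with more than one no-movement trial in
any block x symbol cell are excluded.  Writes per-arm trial, rating and
true-parameter CSVs under results/cohorts/.
"""

import aalearn as a
from aalearn import io

SEED = 20240901
N_RECRUITED = 60
OUT = io.ensure_dir("results/cohorts")


def main() -> None:
    for i, arm in enumerate(a.task.ARMS):
        sim = a.simulate_cohort(arm=arm, n_participants=N_RECRUITED,
                                seed=SEED + i)
        kept, report = a.exclude_participants(sim["trials"])
        arm_dir = io.ensure_dir(OUT / arm)
        io.write_trials(kept, arm_dir / "trials.csv")
        io.write_ratings(sim["ratings"], arm_dir / "ratings.csv")
        io.write_true_params(sim["true_params"], arm_dir / "true_params.csv")
        report.to_csv(arm_dir / "exclusion.csv", index=False)
        n_kept = int(report["keep"].sum())
        print(f"{arm}: recruited {N_RECRUITED}, kept {n_kept} "
              f"({N_RECRUITED - n_kept} excluded by the >1-invalid-per-cell rule)")


if __name__ == "__main__":
    main()
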