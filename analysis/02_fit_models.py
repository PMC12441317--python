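"""Fit the six Rescorla-Wagner variants to the learning arms' cohorts.

The social-control arm elicits no learning (random 50/50 outcomes) and is
not modelled, mirroring the analysis plan; the conflict and non-social arms
are fitted participant by participant with 10 random optimisation starts
per model.  Writes per-arm fit tables under results/fits/.
"""

import time

import aalearn as a
from aalearn import io

SEED = 20240902
ARMS = (a.SOCIAL_CONFLICT, a.NONSOCIAL_CONTROL)
OUT = io.ensure_dir("results/fits")


def main() -> None:
    for i, arm in enumerate(ARMS):
        trials = io.load_trials(f"results/cohorts/{arm}/trials.csv")
        t0 = time.perf_counter()
        fits = a.fit_cohort(a.MODEL_IDS, trials, n_starts=10, seed=SEED + i)
        io.write_fits(fits, OUT / f"{arm}.csv")
        n_part = fits["participant_id"].nunique()
        print(f"{arm}: fitted {len(a.MODEL_IDS)} models x {n_part} participants "
              f"({len(fits)} fits, {fits['failed'].sum()} failed) "
              f"in {time.perf_counter() - t0:.0f} s")


if __name__ == "__main__":
    main()
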