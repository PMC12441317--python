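"""Model comparison by summed BIC and parameter contrasts by Welch t-tests.

For each learning arm, sums each model's BIC over participants (lower is
better), averages per-participant R^2, and names the winner.  For the
conflict arm's winning valence-split model, contrasts the positive vs
negative learning rate and the two initial values across participants.
Writes results/model_comparison.md and per-arm comparison CSVs.
"""

import aalearn as a
from aalearn import io

ARMS = (a.SOCIAL_CONFLICT, a.NONSOCIAL_CONTROL)
OUT = io.ensure_dir("results")


def main() -> None:
    sections = ["# Model comparison\n"]
    for arm in ARMS:
        fits = io.load_fits(f"results/fits/{arm}.csv")
        comp = a.compare_models(fits)
        comp.table.to_csv(OUT / f"comparison_{arm}.csv")
        sections += [f"## {arm}\n", comp.to_markdown(), ""]
        print(f"{arm}: winner model {comp.winner}")

        if arm == a.SOCIAL_CONFLICT:
            m5 = fits[fits["model"] == 5]
            lines = ["", "### Conflict-arm parameter contrasts (model 5)", ""]
            for label, x, y in (
                ("alpha+ vs alpha-", m5["alpha_pos"], m5["alpha_neg"]),
                ("V1 in-group vs V1 out-group", m5["v1_in"], m5["v1_out"]),
            ):
                t, df, p = a.welch_t(x, y)
                lines.append(
                    f"- {label}: {x.mean():.2f} ± {x.std():.2f} vs "
                    f"{y.mean():.2f} ± {y.std():.2f}; Welch t = {t:.2f}, "
                    f"df = {df:.1f}, p = {p:.3g}")
                print(lines[-1])
            sections += lines

    (OUT / "model_comparison.md").write_text("\n".join(sections) + "\n")
    print(f"wrote {OUT / 'model_comparison.md'}")


if __name__ == "__main__":
    main()
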