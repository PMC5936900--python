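"""Fit the inferential models to the scored cohort.

For each of the four scores: a random-intercept mixed model with modality and
perceptual ability (MBEA) as 2-SD-standardized fixed effects, tested by
nested comparison, with percentile cluster-bootstrap CIs (1000 iterations).
Then partial correlations between singing and whistling scores controlling
for MBEA, and the post-hoc model of note inaccuracy against target pitch.
Also writes the summary figures (error distributions by modality;
per-target-degree inaccuracy profile).
"""

from pathlib import Path

import pandas as pd

from pitchmimic.pipeline import fit_all_models, _write_figures

SEED = 1
N_BOOT = 1000
OUT = Path("results/analysis")


def main() -> None:
    scores = pd.read_csv(OUT / "scores.csv")
    errs = pd.read_csv(OUT / "note_errors.csv")
    models = fit_all_models(scores, errs, n_boot=N_BOOT, seed=SEED)

    lmm = models["lmm"]
    lmm.to_csv(OUT / "lmm.csv", index=False)
    print("mixed-model effects (2-SD standardized estimates, cents):")
    print(lmm[["outcome", "effect", "f_stat", "df_den", "p_value",
               "estimate", "ci_low", "ci_high"]].round(3).to_string(index=False))

    pcor = models["partial_correlations"]
    pcor.to_csv(OUT / "partial_correlations.csv", index=False)
    print("\npartial correlations of sing vs whistle scores given MBEA:")
    print(pcor.round(3).to_string(index=False))

    ph = models["posthoc"]
    ph.to_csv(OUT / "posthoc.csv", index=False)
    print("\npost-hoc target-pitch model of note inaccuracy:")
    print(ph[["effect", "f_stat", "df_den", "p_value", "estimate"]]
          .round(3).to_string(index=False))

    _write_figures({"note_errors": errs}, OUT)
    print(f"\nfigures -> {OUT}/error_distributions.png, "
          f"{OUT}/inaccuracy_by_target.png")


if __name__ == "__main__":
    main()
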