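"""Parameter recovery: does the scoring pipeline see the generative truth?

Simulates replicate cohorts under the default study conditions and compares
ground-truth per-participant parameters with the pipeline's estimators:
regression of note error on target pitch for compression gamma and bias, and
c4-corrected imprecision for the effective noise SD
sqrt(sigma_perc^2 + sigma_motor^2). Errors are octave-corrected first (the
>1000-cent verification rule), so injected octave errors do not leak into
the noise estimates.
"""

from pathlib import Path

from pitchmimic.pipeline import RunConfig, recover_parameters

SEED = 1
N_REPLICATES = 10
OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = recover_parameters(RunConfig(seed=SEED),
                               n_replicates=N_REPLICATES)
    table.to_csv(OUT / "parameter_recovery.csv", index=False)
    print(f"recovery over {N_REPLICATES} replicate cohorts "
          f"(28 participants, 45 trials/modality):")
    print(table.round(4).to_string(index=False))
    worst = (table["bias"].abs() / table["se_of_bias"]).max()
    print(f"\nlargest |bias|/SE across estimators: {worst:.2f} "
          "(values < 3 indicate no detectable estimator bias)")


if __name__ == "__main__":
    main()
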