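"""Filter and score the simulated imitations.

Applies the two exclusion rules (wrong note count; target outside the
participant's producible range), converts produced frequencies to cents
against each task's register root, flags >1000-cent errors for octave
review, and computes the four per-participant scores: note/interval
inaccuracy and imprecision.
"""

from pathlib import Path

import pandas as pd

from pitchmimic.scoring import (filter_trials, flag_large_errors, note_errors,
                                score_participants)

OUT = Path("results/analysis")


def main() -> None:
    trials = pd.read_csv(OUT / "trials.csv")
    profiles = pd.read_csv(OUT / "participants.csv")
    kept, excluded = filter_trials(trials, profiles)
    n_trials = trials[["participant_id", "modality", "trial"]] \
        .drop_duplicates().shape[0]
    print(f"excluded {len(excluded)}/{n_trials} trials "
          f"({100 * len(excluded) / n_trials:.1f}%):")
    print(excluded["reason"].value_counts().to_string())

    errs = note_errors(kept, profiles)
    flagged = flag_large_errors(errs)
    print(f"\n{len(errs)} scored notes; {len(flagged)} flagged with "
          f"|error| > 1000 cents (kept, octave-annotated)")

    scores = score_participants(errs, profiles, excluded)
    errs.to_csv(OUT / "note_errors.csv", index=False)
    excluded.to_csv(OUT / "exclusions.csv", index=False)
    flagged.to_csv(OUT / "flagged_errors.csv", index=False)
    scores.to_csv(OUT / "scores.csv", index=False)
    print("\nscore means by modality (cents):")
    print(scores.groupby("modality")[
        ["note_inaccuracy", "interval_inaccuracy",
         "note_imprecision", "interval_imprecision"]].mean().round(1))


if __name__ == "__main__":
    main()
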