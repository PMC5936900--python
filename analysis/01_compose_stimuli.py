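"""Compose the two stimulus sets.

Draws two independent sets of 45 five-note melodies (one per imitation task)
under the composition constraints — intervals flat over ±4 semitones, all
notes within one octave — and writes them as tidy CSVs. Prints the interval
histogram so the flatness of the (rejection-biased) interval distribution can
be eyeballed.
"""

from collections import Counter
from pathlib import Path

from pitchmimic.compose import CompositionConfig
from pitchmimic.pipeline import compose_stimulus_sets
from pitchmimic import compose as cmp

SEED = 1
OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sets = compose_stimulus_sets(CompositionConfig(), SEED)
    for modality, melodies in sets.items():
        path = OUT / f"melodies_{modality}.csv"
        cmp.write_melodies(melodies, path)
        ivals = Counter(i for m in melodies for i in m.intervals())
        spans = [m.span() for m in melodies]
        print(f"{modality}: {len(melodies)} melodies -> {path}")
        print("  interval counts:",
              {k: ivals[k] for k in sorted(ivals)})
        print(f"  max span {max(spans)} semitones "
              f"(constraint: <= 12); max |interval| "
              f"{max(abs(k) for k in ivals)} (constraint: <= 4)")


if __name__ == "__main__":
    main()
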