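"""Random computerized composition of melodic stimuli.

Melodies are short sequences of chromatic scale degrees. The first note is
drawn uniformly from the chromatic scale; each subsequent note moves by an
interval drawn from a flat distribution over ``-max_interval .. +max_interval``
semitones. A candidate melody is accepted only if every note lies within a
single octave above the scale root; otherwise the whole melody is redrawn
(rejection sampling), which leaves the accepted melodies with a well-defined
stationary distribution.

Scale degrees are mapped to frequency by equal temperament:
``f = root * 2**(degree / 12)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Melody",
    "CompositionConfig",
    "PitchRange",
    "MALE_SUNG",
    "FEMALE_SUNG",
    "WHISTLED",
    "compose_melody",
    "compose_set",
    "degree_to_hz",
    "melodies_to_frame",
    "frame_to_melodies",
    "write_melodies",
    "read_melodies",
]


@dataclass(frozen=True)
class Melody:
    """An ordered sequence of chromatic scale degrees (semitones above root)."""

    notes: tuple[int, ...]
    id: str = ""

    def intervals(self) -> tuple[int, ...]:
        return tuple(b - a for a, b in zip(self.notes[:-1], self.notes[1:]))

    def span(self) -> int:
        return max(self.notes) - min(self.notes)


@dataclass(frozen=True)
class CompositionConfig:
    """Parameters of the random composer.

    Defaults reproduce the stimulus design: sets of 45 five-note melodies,
    intervals flat over ±4 semitones, all notes within one octave.
    """

    n_melodies: int = 45
    n_notes: int = 5
    max_interval: int = 4
    octave_span: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_melodies < 1:
            raise ValueError("n_melodies must be >= 1")
        if self.n_notes < 2:
            raise ValueError("n_notes must be >= 2")
        if self.max_interval < 1:
            raise ValueError("max_interval must be >= 1")
        if self.octave_span < self.max_interval:
            raise ValueError("octave_span must be >= max_interval")


@dataclass(frozen=True)
class PitchRange:
    """Equal-temperament register of a task, anchored at scale degree 0."""

    root_frequency: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.root_frequency > 0:
            raise ValueError("root_frequency must be positive")


#: Registers used in the imitation tasks: sung stimuli spanned A2-A3 for males
#: and A3-A4 for females; whistled stimuli spanned A5-A6.
MALE_SUNG = PitchRange(110.0, "male-sung")
FEMALE_SUNG = PitchRange(220.0, "female-sung")
WHISTLED = PitchRange(880.0, "whistled")


def degree_to_hz(degree: float, pitch_range: PitchRange) -> float:
    """Map a scale degree (semitones above the root) to Hz by equal temperament."""
    return float(pitch_range.root_frequency * 2.0 ** (degree / 12.0))


def compose_melody(
    config: CompositionConfig,
    rng: np.random.Generator,
    melody_id: str = "",
    max_tries: int = 1_000_000,
) -> Melody:
    """Draw one melody by rejection sampling.

    The first note is uniform over the chromatic degrees ``0..octave_span-1``;
    each interval is uniform over the integers ``-max_interval..+max_interval``.
    The whole melody is redrawn until all notes fall within ``[0, octave_span]``.
    """
    c = config
    for _ in range(max_tries):
        first = int(rng.integers(0, c.octave_span))
        steps = rng.integers(-c.max_interval, c.max_interval + 1, size=c.n_notes - 1)
        notes = first + np.concatenate([[0], np.cumsum(steps)])
        if notes.min() >= 0 and notes.max() <= c.octave_span:
            return Melody(tuple(int(n) for n in notes), melody_id)
    raise RuntimeError(
        f"rejection sampling failed to accept a melody in {max_tries} tries"
    )


def compose_set(config: CompositionConfig) -> list[Melody]:
    """Compose ``n_melodies`` melodies reproducibly.

    Each melody gets its own random substream derived from ``config.seed`` and
    the melody index, so melody *i* does not depend on how many melodies were
    drawn before it.
    """
    melodies = []
    for i in range(config.n_melodies):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(i,))
        )
        melodies.append(compose_melody(config, rng, melody_id=f"m{i:03d}"))
    return melodies


def melodies_to_frame(melodies: Iterable[Melody]) -> pd.DataFrame:
    rows = [
        {"melody_id": m.id, "position": p, "degree": d}
        for m in melodies
        for p, d in enumerate(m.notes)
    ]
    return pd.DataFrame(rows, columns=["melody_id", "position", "degree"])


def frame_to_melodies(df: pd.DataFrame) -> list[Melody]:
    out = []
    for mid, grp in df.groupby("melody_id", sort=True):
        grp = grp.sort_values("position")
        out.append(Melody(tuple(int(d) for d in grp["degree"]), str(mid)))
    return out


def write_melodies(melodies: Sequence[Melody], path) -> None:
    melodies_to_frame(melodies).to_csv(path, index=False)


def read_melodies(path) -> list[Melody]:
    return frame_to_melodies(pd.read_csv(path))
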