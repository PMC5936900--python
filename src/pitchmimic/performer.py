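"""Generative model of imitation performances.

Each simulated participant carries, per modality (singing, whistling), a
habitual pitch, a producible range, a constant flat/sharp bias, a motor-noise
SD, and a compression coefficient gamma that shrinks produced pitches toward
the habitual pitch ("vocal laziness"). A single perceptual-noise SD is shared
across both modalities within a participant — the shared perception/memory
stage of the propagation-of-error account — while motor noise is
modality-specific. A produced note is

    produced = target + bias_m + gamma_m * (habitual_m - target)
               + eps_perc + eps_motor_m            (all in cents)

with independent zero-mean Gaussian noise at the perceptual and motor stages,
plus a rare ±1200-cent octave error. Notes may occasionally be omitted or
duplicated, which later exercises the wrong-note-count exclusion filter.

All pitch parameters live on the task cents scale: 0 cents is the scale root
of the modality's register (degree 0), 1200 cents the octave above.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .compose import Melody, PitchRange, MALE_SUNG, FEMALE_SUNG, WHISTLED

__all__ = [
    "MODALITIES",
    "PerformerProfile",
    "CohortConfig",
    "ImitationTrial",
    "draw_profile",
    "simulate_note",
    "simulate_trial",
    "simulate_mbea",
    "simulate_study",
    "cents_to_hz",
]

MODALITIES = ("sing", "whistle")

#: MBEA pitch subscales: three sets of 30 same/different pairs of decreasing
#: difficulty. Transposition sizes (cents) stand in for the three difficulty
#: levels; detectability is modelled as d' = transposition / perceptual SD.
MBEA_TRANSPOSITIONS_CENTS = (300.0, 150.0, 50.0)


def cents_to_hz(cents: float, pitch_range: PitchRange) -> float:
    return float(pitch_range.root_frequency * 2.0 ** (cents / 1200.0))


@dataclass(frozen=True)
class PerformerProfile:
    """Ground-truth generative parameters of one simulated participant."""

    participant_id: str
    sex: str  # 'F' or 'M'; selects the sung register (A3-A4 vs A2-A3)
    habitual_pitch: dict[str, float]            # cents on the task scale
    producible_range: dict[str, tuple[float, float]]  # (low, high) cents
    motor_noise_sd: dict[str, float]            # cents
    bias: dict[str, float]                      # cents
    compression: dict[str, float]               # gamma in [0, 1)
    perceptual_noise_sd: float                  # cents, shared across modalities
    p_omit: float = 0.0
    p_duplicate: float = 0.0
    p_octave_error: float = 0.0
    mbea_trials: int = 90

    def __post_init__(self) -> None:
        for m in MODALITIES:
            if self.motor_noise_sd[m] < 0:
                raise ValueError("motor noise SD must be >= 0")
            if not 0 <= self.compression[m] < 1:
                raise ValueError("compression gamma must be in [0, 1)")
            lo, hi = self.producible_range[m]
            if not lo < hi:
                raise ValueError("producible range low must be < high")
        if self.perceptual_noise_sd < 0:
            raise ValueError("perceptual noise SD must be >= 0")
        for p in (self.p_omit, self.p_duplicate, self.p_octave_error):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")

    def pitch_range(self, modality: str) -> PitchRange:
        if modality == "whistle":
            return WHISTLED
        return FEMALE_SUNG if self.sex == "F" else MALE_SUNG


def _default_means_sds() -> dict:
    # Population (mean, sd) pairs, chosen to qualitatively match the study's
    # geometry: habitual singing pitches sit low in the stimulus octave and
    # habitual whistling pitches high; singing is noisier and more strongly
    # compressed toward habitual pitch than whistling; sung bias is flat,
    # whistled bias sharp. Documented defaults, not estimates.
    return {
        "habitual_pitch": {"sing": (300.0, 200.0), "whistle": (900.0, 200.0)},
        "range_low": {"sing": (-300.0, 200.0), "whistle": (-300.0, 200.0)},
        "range_high": {"sing": (1500.0, 200.0), "whistle": (1500.0, 200.0)},
        "motor_noise_sd": {"sing": (70.0, 18.0), "whistle": (25.0, 8.0)},
        "bias": {"sing": (-50.0, 30.0), "whistle": (30.0, 20.0)},
        "compression": {"sing": (0.25, 0.08), "whistle": (0.10, 0.05)},
        "perceptual_noise_sd": (60.0, 35.0),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Population distributions from which participant profiles are drawn.

    Every pitch-like parameter is Normal(mean, sd) on the cents scale;
    SD-like parameters are truncated below at a small positive floor and
    compression at [0, 0.95].
    """

    n_participants: int = 28
    p_female: float = 20.0 / 28.0
    population: dict = field(default_factory=_default_means_sds)
    p_omit: float = 0.0037
    p_duplicate: float = 0.0037
    p_octave_error: float = 0.002
    mbea_trials: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for key, per_mod in self.population.items():
            pairs = per_mod.values() if isinstance(per_mod, dict) else [per_mod]
            for mean, sd in pairs:
                if sd < 0:
                    raise ValueError(f"population sd for {key} must be >= 0")


def draw_profile(cohort: CohortConfig, rng: np.random.Generator,
                 participant_id: str = "p000") -> PerformerProfile:
    """Draw one participant's ground-truth parameters from the population."""
    pop = cohort.population

    def draw(key: str, m: str) -> float:
        mean, sd = pop[key][m]
        return float(rng.normal(mean, sd))

    sex = "F" if rng.random() < cohort.p_female else "M"
    habitual = {m: draw("habitual_pitch", m) for m in MODALITIES}
    ranges = {}
    for m in MODALITIES:
        lo, hi = draw("range_low", m), draw("range_high", m)
        if hi <= lo:  # degenerate draw; keep ordering with a minimal octave
            lo, hi = min(lo, hi), min(lo, hi) + 1200.0
        ranges[m] = (lo, hi)
    motor = {m: max(draw("motor_noise_sd", m), 0.0) for m in MODALITIES}
    bias = {m: draw("bias", m) for m in MODALITIES}
    gamma = {m: float(np.clip(draw("compression", m), 0.0, 0.95))
             for m in MODALITIES}
    mean, sd = pop["perceptual_noise_sd"]
    perc = max(float(rng.normal(mean, sd)), 0.0)
    return PerformerProfile(
        participant_id=participant_id,
        sex=sex,
        habitual_pitch=habitual,
        producible_range=ranges,
        motor_noise_sd=motor,
        bias=bias,
        compression=gamma,
        perceptual_noise_sd=perc,
        p_omit=cohort.p_omit,
        p_duplicate=cohort.p_duplicate,
        p_octave_error=cohort.p_octave_error,
        mbea_trials=cohort.mbea_trials,
    )


def simulate_note(target_cents: float, profile: PerformerProfile,
                  modality: str, rng: np.random.Generator) -> float:
    """Produce one note (cents) from the noise-propagation model."""
    m = modality
    out = (
        target_cents
        + profile.bias[m]
        + profile.compression[m] * (profile.habitual_pitch[m] - target_cents)
        + rng.normal(0.0, profile.perceptual_noise_sd)
        + rng.normal(0.0, profile.motor_noise_sd[m])
    )
    if profile.p_octave_error > 0 and rng.random() < profile.p_octave_error:
        out += 1200.0 * (1.0 if rng.random() < 0.5 else -1.0)
    return float(out)


@dataclass(frozen=True)
class ImitationTrial:
    participant_id: str
    modality: str
    melody_id: str
    target_cents: tuple[float, ...]     # the stimulus, one value per target note
    produced_hz: tuple[float, ...]      # possibly != n_notes values
    produced_target_cents: tuple[float, ...]  # generating target of each produced note
    flags: dict = field(default_factory=dict)


def simulate_trial(melody: Melody, profile: PerformerProfile, modality: str,
                   rng: np.random.Generator,
                   pitch_range: PitchRange | None = None) -> ImitationTrial:
    """Simulate the imitation of one melody.

    Per target note, the note is omitted with probability ``p_omit``, produced
    twice with probability ``p_duplicate`` (each copy independently noised),
    and otherwise produced once.
    """
    pr = pitch_range or profile.pitch_range(modality)
    targets = tuple(100.0 * d for d in melody.notes)
    produced, produced_targets = [], []
    n_omit = n_dup = 0
    for t in targets:
        u = rng.random()
        if u < profile.p_omit:
            n_omit += 1
            continue
        copies = 2 if u < profile.p_omit + profile.p_duplicate else 1
        n_dup += copies - 1
        for _ in range(copies):
            c = simulate_note(t, profile, modality, rng)
            produced.append(cents_to_hz(c, pr))
            produced_targets.append(t)
    return ImitationTrial(
        participant_id=profile.participant_id,
        modality=modality,
        melody_id=melody.id,
        target_cents=targets,
        produced_hz=tuple(produced),
        produced_target_cents=tuple(produced_targets),
        flags={"n_omitted": n_omit, "n_duplicated": n_dup},
    )


def simulate_mbea(profile: PerformerProfile, rng: np.random.Generator) -> float:
    """Percent correct on a simulated melodic-discrimination battery.

    Trials cycle over the three difficulty levels; the per-trial probability
    of a correct response is logistic(d') with d' = transposition size /
    perceptual noise SD, so it falls from 1 toward chance (0.5) as perceptual
    noise grows.
    """
    n = profile.mbea_trials
    deltas = np.array([MBEA_TRANSPOSITIONS_CENTS[i % 3] for i in range(n)])
    sd = max(profile.perceptual_noise_sd, 1e-9)
    p = 1.0 / (1.0 + np.exp(-deltas / sd))
    correct = rng.random(n) < p
    return float(100.0 * correct.mean())


def _profile_row(profile: PerformerProfile, mbea: float) -> dict:
    row = {
        "participant_id": profile.participant_id,
        "sex": profile.sex,
        "mbea_percent": mbea,
        "perceptual_noise_sd": profile.perceptual_noise_sd,
    }
    for m in MODALITIES:
        row[f"{m}_root_hz"] = profile.pitch_range(m).root_frequency
        row[f"{m}_habitual_cents"] = profile.habitual_pitch[m]
        row[f"{m}_range_low_cents"] = profile.producible_range[m][0]
        row[f"{m}_range_high_cents"] = profile.producible_range[m][1]
        row[f"{m}_motor_noise_sd"] = profile.motor_noise_sd[m]
        row[f"{m}_bias_cents"] = profile.bias[m]
        row[f"{m}_compression"] = profile.compression[m]
    return row


def simulate_study(cohort: CohortConfig, melodies: dict[str, list[Melody]],
                   seed: int | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full two-task study for a cohort.

    ``melodies`` maps each modality to its stimulus set (two sets of 45 in the
    default design). Returns a tidy note-level trial table and a participant
    table carrying MBEA scores and ground-truth profile parameters.

    Trial-table columns: participant_id, modality, melody_id, trial, position,
    n_notes_target, n_notes_produced, target_degree, target_cents,
    target_min_cents, target_max_cents, produced_hz.
    """
    root_seed = cohort.seed if seed is None else seed
    trial_rows, participant_rows = [], []
    for i in range(cohort.n_participants):
        rng = np.random.default_rng(
            np.random.SeedSequence(root_seed, spawn_key=(i,))
        )
        profile = draw_profile(cohort, rng, participant_id=f"p{i:03d}")
        mbea = simulate_mbea(profile, rng)
        participant_rows.append(_profile_row(profile, mbea))
        for modality in MODALITIES:
            order = rng.permutation(len(melodies[modality]))
            for trial_idx, mel_idx in enumerate(order):
                mel = melodies[modality][mel_idx]
                trial = simulate_trial(mel, profile, modality, rng)
                tmin, tmax = min(trial.target_cents), max(trial.target_cents)
                n_prod = len(trial.produced_hz)
                aligned = n_prod == len(trial.target_cents)
                for pos, hz in enumerate(trial.produced_hz):
                    t = trial.target_cents[pos] if aligned else np.nan
                    trial_rows.append({
                        "participant_id": profile.participant_id,
                        "modality": modality,
                        "melody_id": mel.id,
                        "trial": trial_idx,
                        "position": pos,
                        "n_notes_target": len(trial.target_cents),
                        "n_notes_produced": n_prod,
                        "target_degree": (t / 100.0 if aligned else np.nan),
                        "target_cents": t,
                        "target_min_cents": tmin,
                        "target_max_cents": tmax,
                        "produced_hz": hz,
                    })
                if n_prod == 0:  # fully omitted trial still counts as attempted
                    trial_rows.append({
                        "participant_id": profile.participant_id,
                        "modality": modality,
                        "melody_id": mel.id,
                        "trial": trial_idx,
                        "position": -1,
                        "n_notes_target": len(trial.target_cents),
                        "n_notes_produced": 0,
                        "target_degree": np.nan,
                        "target_cents": np.nan,
                        "target_min_cents": tmin,
                        "target_max_cents": tmax,
                        "produced_hz": np.nan,
                    })
    return pd.DataFrame(trial_rows), pd.DataFrame(participant_rows)
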