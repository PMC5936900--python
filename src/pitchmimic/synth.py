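"""Whistle-timbre stimulus synthesis and WAV I/O.

Stimuli are pure sine tones on the equal-temperament grid, shaped by an onset
amplitude envelope and separated by short silences. The envelope is a
parametric stand-in for the whistle onset: a raised-cosine attack, a sustained
body, and a short raised-cosine release; its defaults are documented choices,
not measurements. All notes are synthesized at equal peak level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

from .compose import Melody, PitchRange, degree_to_hz

__all__ = ["SynthConfig", "Waveform", "synthesize_note", "synthesize_melody",
           "write_wav", "read_wav"]

_PCM16_FULL_SCALE = 32767.0


@dataclass(frozen=True)
class SynthConfig:
    sample_rate: int = 44100
    bit_depth: int = 16
    note_duration_ms: float = 750.0
    gap_duration_ms: float = 50.0
    attack_ms: float = 40.0
    release_ms: float = 10.0
    level: float = 0.9  # linear peak amplitude

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.note_duration_ms <= 0:
            raise ValueError("note_duration_ms must be positive")
        if self.gap_duration_ms < 0:
            raise ValueError("gap_duration_ms must be >= 0")
        if not 0 < self.level <= 1:
            raise ValueError("level must be in (0, 1]")
        if self.bit_depth != 16:
            raise ValueError("only 16-bit PCM is supported")


@dataclass(frozen=True)
class Waveform:
    samples: np.ndarray
    sample_rate: int

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


def _envelope(n: int, sr: int, attack_ms: float, release_ms: float) -> np.ndarray:
    """Raised-cosine attack/release envelope with unit sustain."""
    env = np.ones(n)
    na = min(n, int(round(attack_ms * sr / 1000.0)))
    nr = min(n - na, int(round(release_ms * sr / 1000.0)))
    if na > 0:
        env[:na] = 0.5 * (1.0 - np.cos(np.pi * np.arange(na) / na))
    if nr > 0:
        env[n - nr:] = 0.5 * (1.0 + np.cos(np.pi * np.arange(nr) / nr))
    return env


def synthesize_note(frequency: float, cfg: SynthConfig) -> np.ndarray:
    """One envelope-shaped sine segment at ``frequency`` Hz."""
    if frequency >= cfg.sample_rate / 2:
        raise ValueError(
            f"note frequency {frequency:.1f} Hz is at or above Nyquist "
            f"({cfg.sample_rate / 2:.1f} Hz)"
        )
    n = int(round(cfg.note_duration_ms * cfg.sample_rate / 1000.0))
    t = np.arange(n) / cfg.sample_rate
    tone = np.sin(2.0 * np.pi * frequency * t)
    return cfg.level * _envelope(n, cfg.sample_rate, cfg.attack_ms, cfg.release_ms) * tone


def synthesize_melody(melody: Melody, pitch_range: PitchRange,
                      cfg: SynthConfig | None = None) -> Waveform:
    """Concatenate the melody's notes with silent gaps between them."""
    cfg = cfg or SynthConfig()
    gap = np.zeros(int(round(cfg.gap_duration_ms * cfg.sample_rate / 1000.0)))
    parts: list[np.ndarray] = []
    for i, degree in enumerate(melody.notes):
        if i > 0:
            parts.append(gap)
        parts.append(synthesize_note(degree_to_hz(degree, pitch_range), cfg))
    return Waveform(np.concatenate(parts), cfg.sample_rate)


def write_wav(w: Waveform, path, bit_depth: int = 16) -> None:
    """Write 16-bit PCM RIFF/WAV; quantization error is at most one LSB."""
    if bit_depth != 16:
        raise ValueError("only 16-bit PCM is supported")
    clipped = np.clip(w.samples, -1.0, 1.0)
    pcm = np.round(clipped * _PCM16_FULL_SCALE).astype(np.int16)
    wavfile.write(path, w.sample_rate, pcm)


def read_wav(path) -> Waveform:
    """Read a PCM WAV file, rescaling samples to [-1, 1]."""
    sr, data = wavfile.read(path)
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _PCM16_FULL_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 127.0
    else:
        raise ValueError(f"unsupported WAV encoding: {data.dtype}")
    if samples.ndim > 1:  # average channels
        samples = samples.mean(axis=1)
    return Waveform(np.clip(samples, -1.0, 1.0), int(sr))
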