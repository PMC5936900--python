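"""Acoustic analysis: F0 extraction, cents math, exclusion filters, and
per-participant inaccuracy / imprecision scores.

Frequencies are converted to cents relative to the lowest scale degree of the
stimulus set (the register root): ``cents = log2(f / ref) * 1200``, where 100
cents is one equal-temperament semitone and 1200 cents one octave. Note error
is produced minus target pitch; interval error is the difference between
adjacent-note intervals of the imitation and of the target.

Inaccuracy is the mean signed error (a consistent flat/sharp tendency).
Imprecision is the mean, across pitch classes, of the within-class sample SD
of errors (variability across repeated attempts at the same pitch). Pitch
class means the target note's chromatic scale degree within the task octave;
for intervals, the target interval in semitones plays the same role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import Waveform

__all__ = [
    "hz_to_cents",
    "F0Estimate",
    "estimate_f0",
    "filter_trials",
    "note_errors",
    "interval_errors",
    "flag_large_errors",
    "octave_correct_errors",
    "inaccuracy",
    "imprecision",
    "score_participants",
]


def hz_to_cents(f, ref):
    """Convert frequency to cents relative to ``ref``: log2(f/ref) * 1200."""
    f = np.asarray(f, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if np.any(f <= 0) or np.any(ref <= 0):
        raise ValueError("frequencies must be positive")
    out = np.log2(f / ref) * 1200.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# F0 estimation


@dataclass(frozen=True)
class F0Estimate:
    hz: float           # NaN when unvoiced
    confidence: float   # height of the normalized autocorrelation peak
    voiced: bool


def _parabolic_peak(y: np.ndarray, k: int) -> float:
    a, b, c = y[k - 1], y[k], y[k + 1]
    den = a - 2 * b + c
    return k + (0.0 if den == 0 else 0.5 * (a - c) / den)


def estimate_f0(w: Waveform, note_window: tuple[float, float],
                fmin: float = 50.0, fmax: float = 2500.0,
                analysis_ms: float = 250.0,
                confidence_threshold: float = 0.5) -> F0Estimate:
    """Autocorrelation F0 over the central ``analysis_ms`` of a note window.

    The unbiased (overlap-normalized) autocorrelation is searched for the
    first local maximum above threshold in the lag range of plausible pitch
    periods; the period is refined by parabolic interpolation at the highest
    in-range multiple of that peak, which keeps the relative error well below
    one cent for clean tones. Segments without a confident periodicity peak
    are flagged unvoiced.
    """
    sr = w.sample_rate
    start, end = note_window
    center = 0.5 * (start + end)
    half = analysis_ms / 2000.0
    i0 = max(0, int(round((center - half) * sr)))
    i1 = min(len(w.samples), int(round((center + half) * sr)))
    x = np.asarray(w.samples[i0:i1], dtype=float)
    if len(x) < int(2 * sr / fmin):
        # window too short to hold two periods of the lowest admissible pitch
        x = np.asarray(w.samples[max(0, i0 - len(x)):i1], dtype=float)
    x = x - x.mean()
    n = len(x)
    if n == 0 or not np.any(x):
        return F0Estimate(np.nan, 0.0, False)
    ac = np.correlate(x, x, "full")[n - 1:]
    lags = np.arange(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        acn = ac / (n - lags)
    acn = acn / acn[0]
    lo = max(2, int(sr / fmax))
    hi = min(n // 2, int(np.ceil(sr / fmin)))
    if hi - lo < 3:
        return F0Estimate(np.nan, 0.0, False)
    seg = acn[lo:hi]
    local_max = (seg[1:-1] >= seg[:-2]) & (seg[1:-1] > seg[2:])
    cand = np.nonzero(local_max & (seg[1:-1] > confidence_threshold))[0] + 1 + lo
    if len(cand) == 0:
        return F0Estimate(np.nan, float(np.nanmax(seg)), False)
    k = int(cand[0])
    period = _parabolic_peak(acn, k)
    confidence = float(acn[k])
    mult = int((n // 2 - 2) // period)
    if mult >= 2:
        kk = int(round(mult * period))
        wdw = max(2, int(0.3 * period))
        j0, j1 = max(2, kk - wdw), min(n - 2, kk + wdw + 1)
        j = j0 + int(np.argmax(acn[j0:j1]))
        period = _parabolic_peak(acn, j) / mult
    return F0Estimate(float(sr / period), confidence, True)


# ---------------------------------------------------------------------------
# Exclusion filters


def filter_trials(trials: pd.DataFrame, profiles: pd.DataFrame
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the trial-level exclusion rules.

    Excludes (a) trials produced with too few or too many notes — omitted or
    duplicated positions cannot be aligned with the target — and (b) trials
    whose target stimulus contains any note outside the participant's
    producible range for that modality. Returns ``(kept, excluded)`` where
    ``excluded`` has one row per trial with a machine-readable ``reason``.
    """
    required = {"participant_id", "modality", "melody_id", "trial",
                "n_notes_target", "n_notes_produced",
                "target_min_cents", "target_max_cents"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")

    prof = profiles.set_index("participant_id")
    keys = ["participant_id", "modality", "melody_id", "trial"]
    per_trial = trials.drop_duplicates(keys)[
        keys + ["n_notes_target", "n_notes_produced",
                "target_min_cents", "target_max_cents"]
    ].copy()

    lows, highs = [], []
    for pid, modality in zip(per_trial["participant_id"], per_trial["modality"]):
        if pid not in prof.index:
            raise ValueError(f"no producible range for participant {pid!r}")
        lows.append(prof.at[pid, f"{modality}_range_low_cents"])
        highs.append(prof.at[pid, f"{modality}_range_high_cents"])
    per_trial["range_low"] = lows
    per_trial["range_high"] = highs

    bad_count = per_trial["n_notes_produced"] != per_trial["n_notes_target"]
    out_of_range = (per_trial["target_min_cents"] < per_trial["range_low"]) | (
        per_trial["target_max_cents"] > per_trial["range_high"])

    reasons = []
    for bc, oor in zip(bad_count, out_of_range):
        r = []
        if bc:
            r.append("wrong_note_count")
        if oor:
            r.append("target_out_of_range")
        reasons.append(";".join(r))
    per_trial["reason"] = reasons
    excluded = per_trial[per_trial["reason"] != ""][keys + ["reason"]]

    merged = trials.merge(excluded[keys].assign(_drop=True), on=keys, how="left")
    kept = trials[merged["_drop"].isna().to_numpy()].copy()
    return kept, excluded.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Errors


def note_errors(kept: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-note signed errors in cents, positionally aligned with targets."""
    prof = profiles.set_index("participant_id")
    df = kept.copy()
    roots = np.array([
        prof.at[pid, f"{m}_root_hz"]
        for pid, m in zip(df["participant_id"], df["modality"])
    ])
    df["produced_cents"] = hz_to_cents(df["produced_hz"].to_numpy(), roots)
    df["error_cents"] = df["produced_cents"] - df["target_cents"]
    df["pitch_class"] = df["target_degree"].round().astype(int)
    cols = ["participant_id", "modality", "melody_id", "trial", "position",
            "pitch_class", "target_cents", "produced_cents", "error_cents"]
    return df[cols]


def interval_errors(note_err: pd.DataFrame) -> pd.DataFrame:
    """Adjacent-note interval errors within each kept trial."""
    keys = ["participant_id", "modality", "melody_id", "trial"]
    df = note_err.sort_values(keys + ["position"]).copy()
    g = df.groupby(keys, sort=False)
    df["target_interval"] = g["target_cents"].diff()
    df["produced_interval"] = g["produced_cents"].diff()
    out = df.dropna(subset=["target_interval"]).copy()
    out["error_cents"] = out["produced_interval"] - out["target_interval"]
    out["interval_class"] = (out["target_interval"] / 100.0).round().astype(int)
    cols = keys + ["position", "interval_class", "target_interval",
                   "produced_interval", "error_cents"]
    return out[cols]


def flag_large_errors(note_err: pd.DataFrame,
                      threshold: float = 1000.0) -> pd.DataFrame:
    """Notes with |error| above threshold, annotated for octave review.

    ``octave_corrected_cents`` is the residual after removing the nearest
    whole number of octaves — a large residual suggests a measurement problem
    rather than an octave error. Flagged notes are kept by default; see
    :func:`octave_correct_errors` for the correction policy.
    """
    flagged = note_err[note_err["error_cents"].abs() > threshold].copy()
    flagged["octave_corrected_cents"] = (
        flagged["error_cents"]
        - 1200.0 * np.round(flagged["error_cents"] / 1200.0)
    )
    return flagged


def octave_correct_errors(note_err: pd.DataFrame,
                          threshold: float = 1000.0) -> pd.DataFrame:
    """Fold errors beyond ``threshold`` to the nearest octave equivalent."""
    df = note_err.copy()
    big = df["error_cents"].abs() > threshold
    shift = 1200.0 * np.round(df.loc[big, "error_cents"] / 1200.0)
    df.loc[big, "error_cents"] = df.loc[big, "error_cents"] - shift
    df.loc[big, "produced_cents"] = df.loc[big, "produced_cents"] - shift
    return df


# ---------------------------------------------------------------------------
# Scores


def inaccuracy(errors) -> float:
    """Mean signed error in cents."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("inaccuracy requires at least one error")
    return float(e.mean())


def imprecision(errors, pitch_classes) -> float:
    """Mean over pitch classes of the within-class sample SD of errors.

    Classes with fewer than two observations are dropped (their SD is
    undefined); the average across classes is unweighted.
    """
    df = pd.DataFrame({"e": np.asarray(errors, dtype=float),
                       "c": np.asarray(pitch_classes)})
    sds = df.groupby("c")["e"].agg(["std", "count"])
    sds = sds[sds["count"] >= 2]["std"]
    if sds.empty:
        raise ValueError("imprecision requires a pitch class with >= 2 errors")
    return float(sds.mean())


def score_participants(note_err: pd.DataFrame, profiles: pd.DataFrame,
                       excluded: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per participant x modality score table.

    Computes note/interval inaccuracy and imprecision from the kept trials'
    errors; joins the MBEA covariate; counts trials used and (if the
    exclusion log is given) excluded. Participants with no usable trials in a
    modality get a row of NaN scores.
    """
    int_err = interval_errors(note_err)
    prof = profiles.set_index("participant_id")
    rows = []
    modalities = sorted(note_err["modality"].unique())
    for pid in profiles["participant_id"]:
        for m in modalities:
            ne = note_err[(note_err["participant_id"] == pid)
                          & (note_err["modality"] == m)]
            ie = int_err[(int_err["participant_id"] == pid)
                         & (int_err["modality"] == m)]
            row = {"participant_id": pid, "modality": m,
                   "mbea_percent": prof.at[pid, "mbea_percent"]
                   if "mbea_percent" in prof.columns else np.nan,
                   "n_trials_used": int(ne[["melody_id", "trial"]]
                                        .drop_duplicates().shape[0])}
            if excluded is not None:
                row["n_excluded"] = int(
                    ((excluded["participant_id"] == pid)
                     & (excluded["modality"] == m)).sum())
            if len(ne) == 0:
                row.update(note_inaccuracy=np.nan, interval_inaccuracy=np.nan,
                           note_imprecision=np.nan, interval_imprecision=np.nan)
            else:
                row["note_inaccuracy"] = inaccuracy(ne["error_cents"])
                row["interval_inaccuracy"] = inaccuracy(ie["error_cents"])
                row["note_imprecision"] = imprecision(ne["error_cents"],
                                                      ne["pitch_class"])
                row["interval_imprecision"] = imprecision(ie["error_cents"],
                                                          ie["interval_class"])
            rows.append(row)
    return pd.DataFrame(rows)
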