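"""End-to-end study driver and the parameter-recovery experiment.

``run_end_to_end`` chains the stages: compose the stimulus sets, simulate a
cohort's imitation performances, apply the exclusion filters and scoring, and
fit the inferential models. ``recover_parameters`` repeats
simulate-and-estimate over replicates and reports the bias and RMSE of the
pipeline's estimators of the generative parameters (per-modality bias,
compression gamma, and effective note-level noise SD).

All randomness flows from one root seed through named substreams, so every
stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import compose as cmp
from . import performer as perf
from . import scoring as sc
from . import stats as st

__all__ = ["RunConfig", "run_end_to_end", "recover_parameters",
           "estimate_profiles", "sd_unbiasing_factor"]

SCORE_OUTCOMES = ("note_inaccuracy", "interval_inaccuracy",
                  "note_imprecision", "interval_imprecision")


@dataclass
class RunConfig:
    """Hierarchical configuration of a full run."""

    composition: cmp.CompositionConfig = field(
        default_factory=cmp.CompositionConfig)
    cohort: perf.CohortConfig = field(default_factory=perf.CohortConfig)
    n_boot: int = 1000
    octave_correct: bool = False
    make_figures: bool = True
    seed: int = 0
    outdir: str = "results/run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "composition" in raw:
            kwargs["composition"] = cmp.CompositionConfig(**raw["composition"])
        if "cohort" in raw:
            kwargs["cohort"] = perf.CohortConfig(**raw["cohort"])
        for key in ("n_boot", "octave_correct", "make_figures", "seed",
                    "outdir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _substream_seed(root_seed: int, name: str) -> int:
    """A stable per-stage integer seed below 2**31."""
    key = sum(ord(c) * 31 ** i for i, c in enumerate(name)) % (2 ** 16)
    ss = np.random.SeedSequence(root_seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def compose_stimulus_sets(comp_cfg: cmp.CompositionConfig,
                          root_seed: int) -> dict[str, list[cmp.Melody]]:
    """Two independent melody sets, one per imitation task."""
    sets = {}
    for modality in perf.MODALITIES:
        cfg_m = cmp.CompositionConfig(
            n_melodies=comp_cfg.n_melodies, n_notes=comp_cfg.n_notes,
            max_interval=comp_cfg.max_interval,
            octave_span=comp_cfg.octave_span,
            seed=_substream_seed(root_seed, f"compose-{modality}"))
        melodies = cmp.compose_set(cfg_m)
        sets[modality] = [
            cmp.Melody(m.notes, f"{modality}-{m.id}") for m in melodies]
    return sets


def run_study(cfg: RunConfig) -> dict:
    """Compose, simulate, filter and score (no inference, no file output)."""
    melodies = compose_stimulus_sets(cfg.composition, cfg.seed)
    trials, participants = perf.simulate_study(
        cfg.cohort, melodies, seed=_substream_seed(cfg.seed, "cohort"))
    kept, excluded = sc.filter_trials(trials, participants)
    errs = sc.note_errors(kept, participants)
    if cfg.octave_correct:
        errs = sc.octave_correct_errors(errs)
    scores = sc.score_participants(errs, participants, excluded)
    return {"melodies": melodies, "trials": trials,
            "participants": participants, "kept": kept,
            "excluded": excluded, "note_errors": errs, "scores": scores}


def fit_all_models(scores: pd.DataFrame, note_err: pd.DataFrame,
                   n_boot: int = 1000, seed: int = 0) -> dict:
    """The full inferential battery on one scored cohort."""
    results = []
    for outcome in SCORE_OUTCOMES:
        for effect in ("modality", "mbea"):
            spec = st.ModelSpec(outcome=outcome, effect=effect)
            res = st.fit_nested_lmm(scores, spec)
            if n_boot > 0:
                lo, hi, nb = st.bootstrap_ci(
                    scores, spec, n_boot=n_boot,
                    seed=_substream_seed(seed, f"boot-{outcome}-{effect}"))
                res.ci_low, res.ci_high, res.n_boot = lo, hi, nb
            results.append(res)
    lmm = pd.DataFrame([r.to_dict() for r in results])

    wide = scores.pivot(index="participant_id", columns="modality")
    mbea = wide[("mbea_percent", "sing")].to_numpy()
    pcor_rows = []
    for outcome in SCORE_OUTCOMES:
        x = wide[(outcome, "sing")].to_numpy()
        y = wide[(outcome, "whistle")].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(mbea)
        pc = st.partial_correlation(x[ok], y[ok], mbea[ok],
                                    control_names=("mbea",))
        pcor_rows.append({"outcome": outcome, "r": pc.r,
                          "r_squared": pc.r_squared, "p_value": pc.p_value,
                          "n": pc.n})
    pcor = pd.DataFrame(pcor_rows)

    posthoc = st.posthoc_target_pitch_model(note_err)
    posthoc_df = pd.DataFrame([r.to_dict() for r in posthoc.values()])
    return {"lmm": lmm, "partial_correlations": pcor, "posthoc": posthoc_df,
            "posthoc_results": posthoc}


def _write_figures(bundle: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    errs = bundle["note_errors"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=False)
    for ax, m in zip(axes, perf.MODALITIES):
        e = errs.loc[errs["modality"] == m, "error_cents"]
        ax.hist(e, bins=60, color="tab:blue" if m == "sing" else "tab:orange")
        ax.axvline(0, color="k", lw=0.8)
        ax.set_title(f"{m} (SD {e.std():.0f} cents)")
        ax.set_xlabel("note error (cents)")
    fig.tight_layout()
    fig.savefig(outdir / "error_distributions.png", dpi=120)
    plt.close(fig)

    prof = (errs.groupby(["modality", "pitch_class"])["error_cents"]
            .median().reset_index())
    fig, ax = plt.subplots(figsize=(6, 4))
    for m in perf.MODALITIES:
        d = prof[prof["modality"] == m]
        ax.plot(d["pitch_class"], d["error_cents"], marker="o", label=m)
    ax.axhline(0, color="k", lw=0.8, ls=":")
    ax.set_xlabel("target scale degree")
    ax.set_ylabel("median note error (cents)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "inaccuracy_by_target.png", dpi=120)
    plt.close(fig)


def run_end_to_end(cfg: RunConfig) -> dict:
    """Full pipeline with file output: compose, simulate, score, analyze."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = run_study(cfg)
    models = fit_all_models(bundle["scores"], bundle["note_errors"],
                            n_boot=cfg.n_boot, seed=cfg.seed)
    bundle.update(models)

    for modality, mels in bundle["melodies"].items():
        cmp.write_melodies(mels, outdir / f"melodies_{modality}.csv")
    for name in ("trials", "participants", "excluded", "note_errors",
                 "scores", "lmm", "partial_correlations", "posthoc"):
        bundle[name].to_csv(outdir / f"{name}.csv", index=False)
    if cfg.make_figures:
        _write_figures(bundle, outdir)

    manifest = {
        "seed": cfg.seed,
        "n_boot": cfg.n_boot,
        "octave_correct": cfg.octave_correct,
        "composition": asdict(cfg.composition),
        "cohort": {"n_participants": cfg.cohort.n_participants,
                   "p_omit": cfg.cohort.p_omit,
                   "p_duplicate": cfg.cohort.p_duplicate,
                   "p_octave_error": cfg.cohort.p_octave_error,
                   "seed": cfg.cohort.seed},
        "n_trials": int(bundle["trials"][["participant_id", "modality",
                                          "trial"]].drop_duplicates().shape[0]),
        "n_excluded_trials": int(len(bundle["excluded"])),
        "n_notes_scored": int(len(bundle["note_errors"])),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle


# ---------------------------------------------------------------------------
# Parameter recovery


def sd_unbiasing_factor(n: int) -> float:
    """c4(n): E[sample SD] / sigma for Normal samples of size n."""
    if n < 2:
        raise ValueError("c4 requires n >= 2")
    return float(np.sqrt(2.0 / (n - 1))
                 * np.exp(gammaln(n / 2.0) - gammaln((n - 1) / 2.0)))


def estimate_profiles(note_err: pd.DataFrame,
                      participants: pd.DataFrame) -> pd.DataFrame:
    """Per participant x modality estimates of the generative parameters.

    gamma is minus the OLS slope of note error on target pitch; bias is the
    regression intercept minus gamma times the (known) habitual pitch; the
    effective noise SD sqrt(sigma_perc^2 + sigma_motor^2) is the imprecision
    score with each within-class SD divided by its small-sample c4 factor.
    """
    prof = participants.set_index("participant_id")
    rows = []
    for (pid, m), g in note_err.groupby(["participant_id", "modality"]):
        t = g["target_cents"].to_numpy()
        e = g["error_cents"].to_numpy()
        if len(g) < 10 or np.ptp(t) == 0:
            continue
        slope, intercept = np.polyfit(t, e, 1)
        gamma_hat = -slope
        habitual = prof.at[pid, f"{m}_habitual_cents"]
        bias_hat = intercept - gamma_hat * habitual
        cls = g.groupby("pitch_class")["error_cents"].agg(["std", "count"])
        cls = cls[cls["count"] >= 2]
        corrected = cls["std"] / [sd_unbiasing_factor(int(n))
                                  for n in cls["count"]]
        rows.append({
            "participant_id": pid, "modality": m,
            "gamma_hat": gamma_hat, "bias_hat": bias_hat,
            "sigma_eff_hat": float(corrected.mean()),
            "gamma_true": prof.at[pid, f"{m}_compression"],
            "bias_true": prof.at[pid, f"{m}_bias_cents"],
            "sigma_eff_true": float(np.hypot(
                prof.at[pid, "perceptual_noise_sd"],
                prof.at[pid, f"{m}_motor_noise_sd"])),
        })
    return pd.DataFrame(rows)


def recover_parameters(cfg: RunConfig, n_replicates: int = 1) -> pd.DataFrame:
    """Bias and RMSE of the pipeline's parameter estimators over replicates.

    Octave-corrected errors are used so that injected octave errors probe the
    verification rule without contaminating the noise-SD estimators.
    """
    per_rep = []
    for rep in range(n_replicates):
        rep_cfg = RunConfig(
            composition=cfg.composition, cohort=cfg.cohort,
            n_boot=0, octave_correct=True, make_figures=False,
            seed=_substream_seed(cfg.seed, f"recover-{rep}"))
        bundle = run_study(rep_cfg)
        est = estimate_profiles(bundle["note_errors"], bundle["participants"])
        est["replicate"] = rep
        per_rep.append(est)
    allest = pd.concat(per_rep, ignore_index=True)
    rows = []
    for param in ("bias", "gamma", "sigma_eff"):
        for m in perf.MODALITIES:
            d = allest[allest["modality"] == m]
            err = d[f"{param}_hat"] - d[f"{param}_true"]
            rows.append({
                "parameter": param, "modality": m,
                "n_estimates": len(d),
                "mean_true": float(d[f"{param}_true"].mean()),
                "mean_estimate": float(d[f"{param}_hat"].mean()),
                "bias": float(err.mean()),
                "rmse": float(np.sqrt((err ** 2).mean())),
                "se_of_bias": float(err.std(ddof=1) / np.sqrt(len(d))),
            })
    return pd.DataFrame(rows)
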