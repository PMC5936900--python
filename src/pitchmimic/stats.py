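"""Inferential stage: random-intercept mixed models with nested comparisons,
2-SD standardized estimates, cluster bootstrap CIs, and partial correlations.

The score table has one row per participant x modality. Each outcome is
modelled with fixed effects for production modality and perceptual ability
(MBEA percent correct) and a random intercept per participant. Effects are
tested by dropping one fixed effect at a time from the full model; the
reported F is the Wald F of the dropped (single-df) coefficient with a
between-within (containment) denominator df, and the likelihood-ratio
statistic of the nested ML fits is carried alongside as a diagnostic.

Standardized estimates follow the 2-SD convention: each input is centred and
divided by twice its SD, so the estimate reads as the expected outcome
difference between predictor levels 1 SD below and 1 SD above the mean. For a
balanced binary predictor this equals the raw between-condition difference.
Confidence intervals come from a percentile bootstrap that resamples whole
participants, respecting the within-participant correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelSpec",
    "ModelResult",
    "PartialCorrelationResult",
    "two_sd_standardize",
    "fit_nested_lmm",
    "bootstrap_ci",
    "partial_correlation",
    "posthoc_target_pitch_model",
]


@dataclass(frozen=True)
class ModelSpec:
    """One nested-model comparison: ``outcome ~ fixed_effects`` with a random
    intercept per participant, testing ``effect`` by dropping it."""

    outcome: str
    effect: str
    fixed_effects: tuple[str, ...] = ("modality", "mbea")
    group: str = "participant_id"

    def __post_init__(self) -> None:
        if self.effect not in self.fixed_effects:
            raise ValueError(f"tested effect {self.effect!r} not among fixed "
                             f"effects {self.fixed_effects}")


@dataclass
class ModelResult:
    outcome: str
    effect: str
    f_stat: float
    df_num: int
    df_den: float
    p_value: float
    estimate: float              # 2-SD standardized
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_boot: int = 0
    df_method: str = "between-within"
    lrt_chi2: float = np.nan
    lrt_p: float = np.nan
    singular: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "outcome", "effect", "f_stat", "df_num", "df_den", "p_value",
            "estimate", "ci_low", "ci_high", "n_boot", "df_method",
            "lrt_chi2", "lrt_p", "singular")}


@dataclass(frozen=True)
class PartialCorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int
    controlled_covariates: tuple[str, ...]


def two_sd_standardize(x) -> np.ndarray:
    """Centre and scale by twice the (population) SD."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance predictor")
    return (x - x.mean()) / (2.0 * sd)


def _prepare(scores: pd.DataFrame, terms: tuple[str, ...],
             group: str) -> pd.DataFrame:
    """Numeric-code and 2-SD standardize the model inputs."""
    df = scores.copy()
    if "modality" in terms:
        if df["modality"].dtype == object:
            df["modality_num"] = (df["modality"] == "whistle").astype(float)
        else:
            df["modality_num"] = df["modality"].astype(float)
    colmap = {}
    for t in terms:
        src = "modality_num" if t == "modality" else (
            "mbea_percent" if t == "mbea" else t)
        df[f"{t}_z"] = two_sd_standardize(df[src])
        colmap[t] = f"{t}_z"
    df["_group"] = df[group]
    return df


def _bw_df(df: pd.DataFrame, terms: tuple[str, ...], group: str) -> dict:
    """Between-within (containment) denominator df per fixed term."""
    n_obs = len(df)
    n_grp = df[group].nunique()
    within, between = [], []
    for t in terms:
        varies = (df.groupby(group)[f"{t}_z"].nunique() > 1).any()
        (within if varies else between).append(t)
    out = {}
    for t in terms:
        if t in within:
            out[t] = float(n_obs - n_grp - len(within))
        else:
            out[t] = float(n_grp - len(between) - 1)
    return out


def _fit_mixedlm(df: pd.DataFrame, outcome: str, terms: list[str],
                 reml: bool = True):
    rhs = " + ".join(terms) if terms else "1"
    model = smf.mixedlm(f"{outcome} ~ {rhs}", df, groups=df["_group"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            res = model.fit(reml=reml)
        except np.linalg.LinAlgError:
            res = model.fit(reml=reml, method="powell")
    return res


def fit_nested_lmm(scores: pd.DataFrame, spec: ModelSpec,
                   interaction: bool = False, lrt: bool = True) -> ModelResult:
    """Fit the full and reduced random-intercept models and test ``effect``.

    A near-zero random-intercept variance is reported via ``singular`` rather
    than raised. ``lrt=False`` skips the nested ML refits (used by the
    bootstrap, which only needs the standardized estimate).
    """
    df = _prepare(scores.dropna(subset=[spec.outcome]), spec.fixed_effects,
                  spec.group)
    if df[spec.group].nunique() < 2:
        raise ValueError("need at least 2 participants")
    terms = [f"{t}_z" for t in spec.fixed_effects]
    if interaction:
        terms = terms + [":".join(f"{t}_z" for t in spec.fixed_effects)]
    full = _fit_mixedlm(df, spec.outcome, terms, reml=True)
    coef = float(full.params[f"{spec.effect}_z"])
    se = float(full.bse[f"{spec.effect}_z"])
    f_stat = (coef / se) ** 2 if se > 0 else np.inf
    df_den = _bw_df(df, spec.fixed_effects, spec.group)[spec.effect]
    p = float(sps.f.sf(f_stat, 1, df_den))

    # nested ML comparison (diagnostic; asymptotically equivalent for 1 df)
    lrt_chi2, lrt_p = np.nan, np.nan
    if lrt:
        reduced_terms = [t for t in terms if t != f"{spec.effect}_z"]
        try:
            full_ml = _fit_mixedlm(df, spec.outcome, terms, reml=False)
            red_ml = _fit_mixedlm(df, spec.outcome, reduced_terms, reml=False)
            lrt_chi2 = max(0.0, 2.0 * (full_ml.llf - red_ml.llf))
            lrt_p = float(sps.chi2.sf(lrt_chi2, 1))
        except Exception:
            pass

    sigma_re = float(np.asarray(full.cov_re).ravel()[0])
    singular = sigma_re <= 1e-8 * max(float(full.scale), 1e-12)
    return ModelResult(
        outcome=spec.outcome, effect=spec.effect, f_stat=float(f_stat),
        df_num=1, df_den=df_den, p_value=p, estimate=coef,
        lrt_chi2=float(lrt_chi2), lrt_p=lrt_p, singular=singular)


def bootstrap_ci(scores: pd.DataFrame, spec: ModelSpec, n_boot: int = 1000,
                 seed: int = 0, alpha: float = 0.05
                 ) -> tuple[float, float, int]:
    """Percentile CI of the standardized estimate by cluster bootstrap.

    Participants (clusters) are resampled with replacement; each resample is
    refit with inputs re-standardized within the resample. Returns
    ``(low, high, n_successful_fits)``.
    """
    pids = scores[spec.group].unique()
    if len(pids) < 5:
        raise ValueError("cluster bootstrap requires at least 5 participants")
    rng = np.random.default_rng(seed)
    by_pid = {p: scores[scores[spec.group] == p] for p in pids}
    est = []
    for _ in range(n_boot):
        chosen = rng.choice(pids, size=len(pids), replace=True)
        parts = []
        for j, p in enumerate(chosen):
            d = by_pid[p].copy()
            d[spec.group] = f"b{j}"  # relabel so repeated draws are clusters
            parts.append(d)
        boot = pd.concat(parts, ignore_index=True)
        try:
            res = fit_nested_lmm(boot, spec, lrt=False)
            if np.isfinite(res.estimate):
                est.append(res.estimate)
        except (ValueError, np.linalg.LinAlgError):
            continue
    if not est:
        raise RuntimeError("all bootstrap refits failed")
    lo, hi = np.percentile(est, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi), len(est)


def partial_correlation(x, y, controls,
                        control_names: tuple[str, ...] = ()
                        ) -> PartialCorrelationResult:
    """Partial correlation of x and y given controls, by residualization.

    Both variables are regressed (with intercept) on the controls; the
    Pearson correlation of the residuals is returned with its t-test p-value
    on ``n - n_controls - 2`` df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.atleast_2d(np.asarray(controls, dtype=float))
    if z.shape[0] == len(x) and z.ndim == 2:
        pass
    elif z.shape[1] == len(x):
        z = z.T
    else:
        raise ValueError("controls must have the same length as x and y")
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    n, k = len(x), z.shape[1]
    if n <= k + 2:
        raise ValueError("need n > n_controls + 2 observations")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("controls are collinear")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - k - 2
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(dof / (1 - r_clip ** 2))
    p = float(2 * sps.t.sf(abs(t), dof))
    return PartialCorrelationResult(r=r, r_squared=r * r, p_value=p, n=n,
                                    controlled_covariates=tuple(control_names))


def posthoc_target_pitch_model(note_err: pd.DataFrame,
                               mbea: pd.DataFrame | None = None
                               ) -> dict[str, ModelResult]:
    """Inaccuracy as a function of target pitch, modality, and their
    interaction, on per-participant x modality x pitch-class mean errors.

    Returns one ModelResult per effect: ``modality``, ``target_pitch``,
    ``interaction``. A negative target-pitch estimate is the
    flat-at-high/sharp-at-low compression signature; a positive interaction
    (whistle coded high) means the compression is stronger for singing.
    """
    agg = (note_err.groupby(["participant_id", "modality", "pitch_class"],
                            as_index=False)["error_cents"].mean())
    df = agg.rename(columns={"error_cents": "mean_error"}).copy()
    df["modality_num"] = (df["modality"] == "whistle").astype(float)
    df["modality_z"] = two_sd_standardize(df["modality_num"])
    df["pitch_z"] = two_sd_standardize(df["pitch_class"].astype(float))
    df["interaction_z"] = df["modality_z"] * df["pitch_z"]
    df["_group"] = df["participant_id"]
    terms = ["modality_z", "pitch_z", "interaction_z"]
    full = _fit_mixedlm(df, "mean_error", terms, reml=True)
    n_obs, n_grp = len(df), df["participant_id"].nunique()
    df_den = float(n_obs - n_grp - len(terms))  # all three vary within cluster
    out = {}
    for name, term in (("modality", "modality_z"),
                       ("target_pitch", "pitch_z"),
                       ("interaction", "interaction_z")):
        coef, se = float(full.params[term]), float(full.bse[term])
        f_stat = (coef / se) ** 2 if se > 0 else np.inf
        out[name] = ModelResult(
            outcome="note_inaccuracy_by_target", effect=name,
            f_stat=float(f_stat), df_num=1, df_den=df_den,
            p_value=float(sps.f.sf(f_stat, 1, df_den)), estimate=coef)
    return out
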