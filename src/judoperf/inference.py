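"""Baseline-adjusted mixed-model inference for the two-group study.

For each outcome the analysis model is

    y_it = β0 + β_b·(baseline_i − b̄) + time_t + group_g + (time×group)_gt
           + u_i + ε_it

fitted by REML on the three post-training timepoints, with the pre-training
score as a covariate of no interest and a random intercept per subject.
The quantity of interest is the adjusted between-group contrast
(hypoxia − normoxia) at each post timepoint, taken from the estimated
marginal means with the baseline held at its grand mean.  Outcomes whose
residual spread scales with the fitted values are log-transformed and their
contrasts reported exponentiated (multiplicative effects).

Uncertainty is summarized estimation-style: 90% bias-corrected and
accelerated (BCa) bootstrap compatibility intervals with subject-level
resampling (stratified by group so both arms persist in every replicate),
standardized mean differences against the pooled baseline SD (log scale for
multiplicative outcomes) with magnitude labels, and Satterthwaite-df
p-values as a secondary summary.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import POST_TIMEPOINTS, StudyDataset
from .errors import DegenerateDataError, DesignError, FitError
from .mixedmodel import RandomInterceptREML, REMLResult

__all__ = [
    "AnalysisConfig",
    "ModelFit",
    "ContrastResult",
    "AdjustedEffect",
    "ContrastEngine",
    "choose_scale",
    "fit_adjusted_model",
    "adjusted_contrast",
    "bca_interval",
    "bca_bootstrap_ci",
    "bootstrap_contrast_ci",
    "pooled_baseline_sd",
    "standardized_mean_difference",
    "classify_effect_size",
    "geometric_summary",
    "run_outcome_analysis",
]

_ES_BINS = (
    (0.2, "trivial"),
    (0.6, "small"),
    (1.2, "moderate"),
    (2.0, "large"),
    (4.0, "very large"),
    (np.inf, "nearly perfect"),
)

_COLUMNS = [
    "Intercept",
    "baseline_c",
    "t_Post-1",
    "t_Post-2",
    "g_hypoxia",
    "g_hypoxia:t_Post-1",
    "g_hypoxia:t_Post-2",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the per-outcome analysis."""

    seed: int
    bootstrap_reps: int = 500
    level: float = 0.90
    scale_overrides: dict = field(default_factory=dict)
    scale_threshold: float = 0.3   # |residual|-vs-fitted Spearman ρ triggering log
    stratified: bool = True

    def __post_init__(self):
        if self.bootstrap_reps < 50:
            raise DesignError("bootstrap_reps must be at least 50")
        if not (0.5 < self.level < 1.0):
            raise DesignError("interval level must lie in (0.5, 1)")


@dataclass
class ContrastResult:
    estimate: float          # model-scale difference (log difference for log outcomes)
    se: float
    df: float
    p: float
    ratio: float | None      # exponentiated estimate, log scale only
    df_approximate: bool


@dataclass
class AdjustedEffect:
    """One row of the results table: outcome × post timepoint."""

    outcome: str
    timepoint: str
    estimate: float          # difference (raw) or ratio (log)
    ci90: tuple
    es: float
    es_label: str
    p: float
    scale: str

    def validate(self) -> "AdjustedEffect":
        lo, hi = self.ci90
        if not lo <= hi:
            raise ValueError("interval endpoints out of order")
        if self.scale == "log" and not (0 < lo and 0 < self.estimate):
            raise ValueError("ratio-scale estimate and interval must be positive")
        if classify_effect_size(self.es) != self.es_label:
            raise ValueError("magnitude label inconsistent with |es|")
        return self


# ---------------------------------------------------------------------------
# design preparation and the fast contrast engine


def _prepare(data: StudyDataset, outcome: str, scale: str):
    """Per-subject arrays for the adjusted model; drops subjects without Pre."""
    sub = data.subset(outcome)
    wide = sub.pivot_table(index=["subject", "group"], columns="timepoint",
                           values="value", aggfunc="mean")
    wide = wide.reset_index()
    missing_tp = [tp for tp in ("Pre",) + POST_TIMEPOINTS if tp not in wide.columns]
    if missing_tp:
        raise DesignError(f"outcome {outcome!r} lacks timepoints: {missing_tp}")
    n_dropped = int(wide["Pre"].isna().sum())
    wide = wide.dropna(subset=["Pre"])
    counts = wide.groupby("group").size()
    for g in ("hypoxia", "normoxia"):
        if counts.get(g, 0) < 2:
            raise DesignError(f"group {g!r} has fewer than 2 subjects with a baseline for {outcome!r}")

    long = wide.melt(id_vars=["subject", "group", "Pre"],
                     value_vars=list(POST_TIMEPOINTS),
                     var_name="timepoint", value_name="value").dropna(subset=["value"])
    vals = long["value"].to_numpy(dtype=float)
    base = long["Pre"].to_numpy(dtype=float)
    if scale == "log":
        if (vals <= 0).any() or (base <= 0).any():
            raise DesignError(f"outcome {outcome!r} has non-positive values; log scale unavailable")
        vals = np.log(vals)
        base = np.log(base)
    if np.allclose(vals.std(), 0):
        raise DegenerateDataError(f"outcome {outcome!r} has zero variance at the post timepoints")
    center = float(base.mean())
    hyp = (long["group"] == "hypoxia").to_numpy(dtype=float)
    t1 = (long["timepoint"] == "Post-1").to_numpy(dtype=float)
    t2 = (long["timepoint"] == "Post-2").to_numpy(dtype=float)
    X = np.column_stack([
        np.ones(len(long)), base - center, t1, t2, hyp, hyp * t1, hyp * t2,
    ])
    subjects = long["subject"].to_numpy()
    labels, cluster_idx = np.unique(subjects, return_inverse=True)
    groups = wide.set_index("subject")["group"].reindex(labels).to_numpy()
    return {
        "X": X, "y": vals, "clusters": cluster_idx, "labels": labels,
        "groups": groups, "center": center, "n_dropped": n_dropped,
        "timepoints": long["timepoint"].to_numpy(),
    }


def contrast_vector(timepoint: str) -> np.ndarray:
    """Hypoxia − normoxia EMM contrast at a post timepoint (baseline at mean)."""
    c = np.zeros(len(_COLUMNS))
    c[_COLUMNS.index("g_hypoxia")] = 1.0
    if timepoint == "Post-0":
        pass
    elif timepoint in ("Post-1", "Post-2"):
        c[_COLUMNS.index(f"g_hypoxia:t_{timepoint}")] = 1.0
    else:
        raise ValueError(f"unknown post timepoint {timepoint!r}")
    return c


class ContrastEngine:
    """Precomputed REML machinery for one outcome, reusable across resamples."""

    def __init__(self, data: StudyDataset, outcome: str, scale: str):
        self.outcome = outcome
        self.scale = scale
        prep = _prepare(data, outcome, scale)
        self.prep = prep
        self.reml = RandomInterceptREML(prep["X"], prep["y"], prep["clusters"])
        # subject order inside the REML engine follows np.unique of cluster idx,
        # which matches prep["labels"]
        self.group_of = prep["groups"]
        self.hyp_idx = np.nonzero(self.group_of == "hypoxia")[0]
        self.nor_idx = np.nonzero(self.group_of == "normoxia")[0]

    def fit(self, idx=None) -> REMLResult:
        return self.reml.fit(idx)

    def contrast_estimate(self, timepoint: str, idx=None) -> float:
        res = self.reml.fit(idx)
        est, _ = res.contrast(contrast_vector(timepoint))
        return est


# ---------------------------------------------------------------------------
# model fitting and contrasts


@dataclass
class ModelFit:
    """A fitted baseline-adjusted mixed model for one outcome."""

    outcome: str
    scale: str
    params: pd.Series
    cov_params: np.ndarray
    sigma2: float            # residual variance
    tau2: float              # subject random-intercept variance
    fitted: np.ndarray
    resid: np.ndarray
    response: np.ndarray     # model-scale response
    raw_positive: bool       # all raw values positive (log transform legal)
    n_obs: int
    n_subjects: int
    n_dropped_subjects: int
    converged: bool
    singular: bool
    engine: ContrastEngine | None = None

    @property
    def random_intercept_variance(self) -> float:
        return self.tau2

    @property
    def residual_variance(self) -> float:
        return self.sigma2


def fit_adjusted_model(
    data: StudyDataset,
    outcome: str,
    scale: str = "raw",
    engine: str = "reml",
) -> ModelFit:
    """Fit the baseline-adjusted model for one outcome.

    ``engine="reml"`` uses the package's profiled random-intercept REML
    solver; ``engine="mixedlm"`` delegates the fit to statsmodels MixedLM
    (identical model, REML) — useful as a cross-check, but without
    Satterthwaite df and far slower under resampling.
    """
    ce = ContrastEngine(data, outcome, scale)
    prep = ce.prep
    if engine == "mixedlm":
        import statsmodels.api as sm

        md = sm.MixedLM(prep["y"], prep["X"], groups=prep["clusters"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mr = md.fit(reml=True)
        beta = np.asarray(mr.fe_params)
        cov = np.asarray(mr.cov_params())[: len(beta), : len(beta)]
        sigma2 = float(mr.scale)
        tau2 = float(np.asarray(mr.cov_re).ravel()[0])
        singular = tau2 <= 1e-8
        converged = bool(mr.converged)
    elif engine == "reml":
        res = ce.fit()
        beta, cov = res.beta, res.cov_beta
        sigma2, tau2 = res.sigma2, res.tau2
        singular, converged = res.singular, res.converged
    else:
        raise ValueError("engine must be 'reml' or 'mixedlm'")
    fitted = prep["X"] @ beta
    resid = prep["y"] - fitted
    if scale == "log":
        raw_positive = True  # log fit already required positivity
    else:
        base_raw = prep["X"][:, 1] + prep["center"]
        raw_positive = bool((prep["y"] > 0).all() and (base_raw > 0).all())
    return ModelFit(
        outcome=outcome,
        scale=scale,
        params=pd.Series(beta, index=_COLUMNS),
        cov_params=cov,
        sigma2=sigma2,
        tau2=tau2,
        fitted=fitted,
        resid=resid,
        response=prep["y"],
        raw_positive=raw_positive,
        n_obs=len(prep["y"]),
        n_subjects=len(prep["labels"]),
        n_dropped_subjects=prep["n_dropped"],
        converged=converged,
        singular=singular,
        engine=ce,
    )


def choose_scale(fit: ModelFit, threshold: float = 0.3) -> str:
    """Raw-vs-log decision from the residual–fitted relationship.

    Computes Spearman's ρ between |residual| and fitted value on a raw-scale
    fit; heteroscedastic spread that grows with the level (ρ > threshold)
    selects the log scale, provided all values are positive.
    """
    rho = stats.spearmanr(np.abs(fit.resid), fit.fitted).statistic
    if np.isnan(rho):
        return "raw"
    if rho > threshold:
        if not fit.raw_positive:
            warnings.warn(
                f"outcome {fit.outcome!r} looks heteroscedastic (rho={rho:.2f}) but has "
                "non-positive values; keeping the raw scale"
            )
            return "raw"
        return "log"
    return "raw"


def adjusted_contrast(fit: ModelFit, timepoint: str) -> ContrastResult:
    """Adjusted hypoxia − normoxia contrast at one post timepoint.

    The p-value uses a t distribution with Satterthwaite-approximated
    degrees of freedom; when the approximation is unavailable the residual
    df is used and flagged.
    """
    c = contrast_vector(timepoint)
    est = float(c @ fit.params.to_numpy())
    se = float(np.sqrt(c @ fit.cov_params @ c))
    if se == 0 or not np.isfinite(se):
        raise DegenerateDataError("contrast standard error is zero; degenerate model")
    if fit.engine is not None and fit.engine.reml is not None:
        res = REMLResult(
            beta=fit.params.to_numpy(), cov_beta=fit.cov_params,
            sigma2=fit.sigma2, tau2=fit.tau2,
            lam=fit.tau2 / fit.sigma2 if fit.sigma2 > 0 else 0.0,
            loglik=np.nan, n_obs=fit.n_obs, n_clusters=fit.n_subjects,
            n_params=len(fit.params), converged=fit.converged, singular=fit.singular,
        )
        df, approx = fit.engine.reml.satterthwaite_df(res, c)
    else:
        df, approx = float(fit.n_obs - len(fit.params)), True
    tval = est / se
    p = float(2.0 * stats.t.sf(abs(tval), df))
    ratio = float(np.exp(est)) if fit.scale == "log" else None
    return ContrastResult(estimate=est, se=se, df=df, p=p, ratio=ratio, df_approximate=approx)


# ---------------------------------------------------------------------------
# BCa bootstrap


def bca_interval(theta_hat: float, boot, jack, level: float = 0.90):
    """BCa interval from a point estimate, replicates and jackknife values.

    z₀ = Φ⁻¹(fraction of replicates below the point estimate); the
    acceleration a comes from the jackknife skewness formula.  Degenerate
    replicate sets yield a zero-width interval with a warning.
    """
    boot = np.asarray(boot, dtype=float)
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        raise FitError("no usable bootstrap replicates")
    if np.allclose(boot, boot[0]):
        warnings.warn("all bootstrap replicates identical; zero-width interval")
        return float(boot[0]), float(boot[0])
    prop = np.mean(boot < theta_hat)
    prop = min(max(prop, 1.0 / (boot.size + 1)), boot.size / (boot.size + 1.0))
    z0 = stats.norm.ppf(prop)
    jack = np.asarray(jack, dtype=float)
    jack = jack[np.isfinite(jack)]
    d = jack.mean() - jack
    denom = (d @ d) ** 1.5
    a = float((d**3).sum() / (6.0 * denom)) if denom > 0 else 0.0
    alpha = (1.0 - level) / 2.0
    out = []
    for q in (alpha, 1.0 - alpha):
        z = z0 + stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + z / (1.0 - a * z))
        out.append(float(np.quantile(boot, adj)))
    return out[0], out[1]


def _resample_indices(rng, hyp_idx, nor_idx, stratified: bool):
    if stratified:
        h = rng.choice(hyp_idx, size=hyp_idx.size, replace=True)
        n = rng.choice(nor_idx, size=nor_idx.size, replace=True)
        return np.concatenate([h, n])
    pool = np.concatenate([hyp_idx, nor_idx])
    return rng.choice(pool, size=pool.size, replace=True)


def bootstrap_contrast_ci(
    data: StudyDataset,
    outcome: str,
    timepoint: str,
    scale: str = "raw",
    B: int = 500,
    level: float = 0.90,
    seed=None,
    stratified: bool = True,
    engine: ContrastEngine | None = None,
):
    """BCa CI of the adjusted contrast via subject-level refits.

    Resamples whole subjects with replacement (stratified by group), refits
    the mixed model on every replicate with the same scale decision, and
    applies the BCa correction with a delete-one-subject jackknife.
    Returns ``(low, high, diagnostics)`` on the model scale.
    """
    ce = engine or ContrastEngine(data, outcome, scale)
    rng = np.random.default_rng(seed)
    theta_hat = ce.contrast_estimate(timepoint)
    boot = np.empty(B)
    failures = 0
    for b in range(B):
        idx = _resample_indices(rng, ce.hyp_idx, ce.nor_idx, stratified)
        try:
            boot[b] = ce.contrast_estimate(timepoint, idx)
        except Exception:
            boot[b] = np.nan
            failures += 1
    if failures > 0.10 * B:
        raise FitError(f"bootstrap statistic failed on {failures}/{B} replicates")
    all_idx = np.arange(ce.group_of.size)
    jack = np.empty(all_idx.size)
    for j in range(all_idx.size):
        try:
            jack[j] = ce.contrast_estimate(timepoint, np.delete(all_idx, j))
        except Exception:
            jack[j] = np.nan
    lo, hi = bca_interval(theta_hat, boot, jack, level)
    diag = {"failures": failures, "B": B, "theta_hat": theta_hat}
    return lo, hi, diag


def bca_bootstrap_ci(
    data: StudyDataset,
    statistic,
    B: int = 500,
    level: float = 0.90,
    seed=None,
    stratified: bool = True,
):
    """Generic subject-level BCa interval for ``statistic(StudyDataset)``.

    Resampled subjects are re-labelled so duplicated subjects enter the
    statistic as distinct clusters.  Raises when the statistic fails on more
    than 10% of replicates.
    """
    if B < 50:
        raise DesignError("B must be at least 50")
    frame = data.frame
    subj_groups = frame.drop_duplicates("subject").set_index("subject")["group"]
    subjects = subj_groups.index.to_numpy()
    groups = subj_groups.to_numpy()
    hyp = subjects[groups == "hypoxia"]
    nor = subjects[groups == "normoxia"]
    blocks = {s: frame[frame["subject"] == s] for s in subjects}

    def rebuild(chosen):
        parts = []
        for k, s in enumerate(chosen):
            blk = blocks[s].copy()
            blk["subject"] = f"r{k:04d}"
            parts.append(blk)
        return StudyDataset(frame=pd.concat(parts, ignore_index=True), scales=dict(data.scales))

    theta_hat = float(statistic(data))
    rng = np.random.default_rng(seed)
    boot = np.empty(B)
    failures = 0
    for b in range(B):
        if stratified:
            chosen = np.concatenate([
                rng.choice(hyp, size=hyp.size, replace=True),
                rng.choice(nor, size=nor.size, replace=True),
            ])
        else:
            chosen = rng.choice(subjects, size=subjects.size, replace=True)
        try:
            boot[b] = float(statistic(rebuild(chosen)))
        except Exception:
            boot[b] = np.nan
            failures += 1
    if failures > 0.10 * B:
        raise FitError(f"bootstrap statistic failed on {failures}/{B} replicates")
    jack = np.empty(subjects.size)
    for j, s in enumerate(subjects):
        keep = [x for x in subjects if x != s]
        try:
            jack[j] = float(statistic(rebuild(keep)))
        except Exception:
            jack[j] = np.nan
    return bca_interval(theta_hat, boot, jack, level)


# ---------------------------------------------------------------------------
# effect sizes and descriptives


def pooled_baseline_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    """n−1-weighted pooled SD: sqrt(((n1−1)sd1² + (n2−1)sd2²)/(n1+n2−2))."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n ≥ 2 for a pooled SD")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    return float(np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)))


def standardized_mean_difference(
    effect: float, sd1: float, n1: int, sd2: float, n2: int, scale: str = "raw"
) -> float:
    """Adjusted effect divided by the pooled baseline SD.

    On the log scale ``effect`` is a multiplicative ratio and ``sd1``/``sd2``
    geometric SDs; the division happens on the additive (log) scale.
    """
    if scale == "log":
        if effect <= 0 or sd1 <= 0 or sd2 <= 0:
            raise ValueError("log-scale SMD needs a positive ratio and geometric SDs")
        pooled = pooled_baseline_sd(np.log(sd1), n1, np.log(sd2), n2)
        num = np.log(effect)
    elif scale == "raw":
        pooled = pooled_baseline_sd(sd1, n1, sd2, n2)
        num = effect
    else:
        raise ValueError("scale must be 'raw' or 'log'")
    if pooled == 0:
        raise ValueError("pooled baseline SD is zero; SMD undefined")
    return float(num / pooled)


def classify_effect_size(es: float) -> str:
    """Magnitude label of |es| on the 0.2/0.6/1.2/2.0/4.0 scale (lower-inclusive)."""
    if not np.isfinite(es):
        raise ValueError("effect size must be finite")
    mag = abs(es)
    for upper, label in _ES_BINS:
        if mag < upper:
            return label
    return _ES_BINS[-1][1]


def geometric_summary(values):
    """(geometric mean, geometric SD) of a strictly positive sample."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if (v <= 0).any():
        raise ValueError("geometric summaries require strictly positive values")
    logs = np.log(v)
    return float(np.exp(logs.mean())), float(np.exp(logs.std(ddof=1)))


# ---------------------------------------------------------------------------
# composition


def _baseline_descriptives(data: StudyDataset, outcome: str, scale: str):
    sub = data.subset(outcome)
    pre = sub[sub["timepoint"] == "Pre"]
    out = {}
    for g in ("hypoxia", "normoxia"):
        vals = pre.loc[pre["group"] == g, "value"].to_numpy(dtype=float)
        if vals.size < 2:
            raise DesignError(f"group {g!r} lacks baseline values for {outcome!r}")
        if scale == "log":
            _, gsd = geometric_summary(vals)
            out[g] = (gsd, vals.size)
        else:
            out[g] = (float(vals.std(ddof=1)), vals.size)
    return out


def run_outcome_analysis(data: StudyDataset, outcome: str, cfg: AnalysisConfig):
    """Full pipeline for one outcome: list of AdjustedEffect, one per post timepoint.

    Scale selection → REML fit → per-timepoint EMM contrasts →
    subject-level BCa intervals → SMDs against pooled baseline SDs →
    magnitude labels.  Log-scale outputs are exponentiated (estimate and
    interval endpoints as ratios).

    Scale precedence: an explicit override in ``cfg.scale_overrides``, then
    the dataset's scale registry (the analysis decision recorded with the
    data), then the :func:`choose_scale` residual-diagnostic rule.
    """
    try:
        scale = cfg.scale_overrides.get(outcome) or data.scales.get(outcome)
        if scale is None:
            raw_fit = fit_adjusted_model(data, outcome, "raw")
            scale = choose_scale(raw_fit, cfg.scale_threshold)
        fit = fit_adjusted_model(data, outcome, scale)
        sds = _baseline_descriptives(data, outcome, scale)
        (sd_h, n_h), (sd_n, n_n) = sds["hypoxia"], sds["normoxia"]
        ss = np.random.SeedSequence([cfg.seed, zlib.crc32(outcome.encode()) % (2**31)])
        seeds = ss.spawn(len(POST_TIMEPOINTS))
        effects = []
        for tp, tp_seed in zip(POST_TIMEPOINTS, seeds):
            con = adjusted_contrast(fit, tp)
            lo, hi, _ = bootstrap_contrast_ci(
                data, outcome, tp, scale=scale, B=cfg.bootstrap_reps,
                level=cfg.level, seed=tp_seed, stratified=cfg.stratified,
                engine=fit.engine,
            )
            if scale == "log":
                estimate = con.ratio
                ci = (float(np.exp(lo)), float(np.exp(hi)))
                es = standardized_mean_difference(estimate, sd_h, n_h, sd_n, n_n, "log")
            else:
                estimate = con.estimate
                ci = (lo, hi)
                es = standardized_mean_difference(estimate, sd_h, n_h, sd_n, n_n, "raw")
            effects.append(
                AdjustedEffect(
                    outcome=outcome, timepoint=tp, estimate=float(estimate),
                    ci90=ci, es=es, es_label=classify_effect_size(es),
                    p=con.p, scale=scale,
                ).validate()
            )
        return effects
    except (DesignError, DegenerateDataError, KeyError) as err:
        raise type(err)(f"outcome {outcome!r}: {err}") from err
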