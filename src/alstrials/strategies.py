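"""Analysis strategies for the ALSFRS-R: missing-data handling, outcome
summaries, model fits, and the estimand each combination targets.

A :class:`StrategySpec` names one complete analysis: how the longitudinal
score is summarized (change from baseline, slope, responder, ranks,
time-to-event, or the full longitudinal profile), which model tests the
treatment effect, whether baseline is adjusted for, and — separately for
death and for non-death dropout — which missing-data strategy (MDS) fills,
drops, or implicitly models the truncated assessments.  Every strategy maps
deterministically to one of the four estimand strategies for handling death:
*hypothetical* (impute as if patients survived), *principal stratum*
(restrict to survivors), *while alive* (model the pre-death data), and
*composite* (fold death into the outcome).

All strategies return a common :class:`MethodResult` whose two-sided p-value
is also expressed as a signed z-score (positive = benefit for the active arm)
so that disparate methods can be compared on one scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm
from scipy import stats

from . import trial_data as td
from .lmm import FitError, fit_lmm, fit_mmrm, mmrm_final_visit_contrast
from .trial_data import (
    DerivedSummary,
    Observation,
    PatientCourse,
    TrialDataset,
    ValidationError,
)

SUMMARIES = (
    "cfb_final",
    "cfb_visit",
    "slope",
    "responder",
    "longitudinal",
    "rank_composite",
    "tte_decline_death",
)
MODELS = (
    "t_test",
    "linreg",
    "wilcoxon",
    "rm_anova_gg",
    "re_intercept",
    "re_slopes",
    "mmrm",
    "logistic",
    "log_rank",
    "joint_rank",
)
MDS = ("implicit", "complete_case", "locf", "lcv", "worst_score", "mi")
ESTIMANDS = ("hypothetical", "principal_stratum", "while_alive", "composite")

_LONGITUDINAL_MODELS = {"rm_anova_gg", "re_intercept", "re_slopes", "mmrm"}
_IMPLICIT_OK = {"re_intercept", "re_slopes", "mmrm", "joint_rank", "log_rank"}
_VALUE_MODELS = {"t_test", "linreg", "wilcoxon", "logistic"}
_SE_MODELS = {"t_test", "linreg", "logistic", "re_intercept", "re_slopes", "mmrm"}


class DegenerateDataError(FitError):
    """The missing-data strategy left nothing analyzable."""


@dataclass(frozen=True)
class StrategySpec:
    """One analysis strategy as a composition of reusable components."""

    name: str
    summary: str
    model: str
    baseline_adjust: bool = False
    covariates: tuple[str, ...] = ()
    mds_death: str = "complete_case"
    mds_dropout: str = "complete_case"
    estimand: str | None = None
    visit: float | None = None            # cfb_visit / responder landmark
    responder_threshold: float = 6.0      # points of decline
    worst_score_value: float = 0.0        # imputed score at/after death
    decline_threshold: float = 6.0        # composite time-to-event threshold
    landmark: float | None = None         # joint-rank landmark (None = final)
    n_imputations: int = 10

    def __post_init__(self) -> None:
        if self.summary not in SUMMARIES:
            raise ValidationError(f"{self.name}: unknown summary {self.summary!r}")
        if self.model not in MODELS:
            raise ValidationError(f"{self.name}: unknown model {self.model!r}")
        for mds in (self.mds_death, self.mds_dropout):
            if mds not in MDS:
                raise ValidationError(f"{self.name}: unknown MDS {mds!r}")
        self._check_compat()
        label = classify_estimand(self)
        if self.estimand is None:
            object.__setattr__(self, "estimand", label)
        elif self.estimand != label:
            raise ValidationError(
                f"{self.name}: estimand {self.estimand!r} inconsistent with "
                f"components (expected {label!r})"
            )

    def _check_compat(self) -> None:
        ok = {
            "log_rank": {"tte_decline_death"},
            "joint_rank": {"rank_composite"},
            "logistic": {"responder"},
            "rm_anova_gg": {"longitudinal"},
            "re_intercept": {"longitudinal"},
            "re_slopes": {"longitudinal"},
            "mmrm": {"longitudinal"},
            "t_test": {"cfb_final", "cfb_visit", "slope"},
            "linreg": {"cfb_final", "cfb_visit", "slope"},
            "wilcoxon": {"cfb_final", "cfb_visit", "slope"},
        }[self.model]
        if self.summary not in ok:
            raise ValidationError(
                f"{self.name}: model {self.model!r} incompatible with "
                f"summary {self.summary!r}"
            )
        for mds in (self.mds_death, self.mds_dropout):
            if mds == "implicit" and self.model not in _IMPLICIT_OK:
                raise ValidationError(
                    f"{self.name}: implicit MDS requires a model that accounts "
                    "for missingness during estimation"
                )
            if mds == "mi" and self.model not in _SE_MODELS:
                raise ValidationError(
                    f"{self.name}: multiple imputation needs a model with a "
                    "standard error to pool"
                )
        if self.summary == "cfb_visit" and self.visit is None:
            raise ValidationError(f"{self.name}: cfb_visit needs a visit")


@dataclass(frozen=True)
class MethodResult:
    """Treatment-effect estimate on one strategy's scale.

    ``z_score`` is signed so that positive always means benefit for the
    active arm, whatever the estimate's native orientation.
    """

    estimate: float
    se: float | None
    p_value: float
    z_score: float
    n_analyzed: int
    strategy: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def pvalue_to_z(p: float, benefit_sign: float) -> float:
    """Map a two-sided p-value to a signed z-score: ``sign * Phi^-1(1-p/2)``."""
    if not (0 < p <= 1):
        raise ValidationError(f"p-value must be in (0, 1], got {p}")
    sign = 1.0 if benefit_sign >= 0 else -1.0
    return float(sign * stats.norm.ppf(1 - p / 2))


# ---------------------------------------------------------------------------
# Missing-data strategies
# ---------------------------------------------------------------------------


def _gap_causes(p: PatientCourse, schedule: td.VisitSchedule) -> dict[float, str]:
    """Cause of each missed scheduled visit: 'death', 'dropout', or
    'intermittent' (a recoverable skipped assessment)."""
    observed = {o.time for o in p.observations if o.observed}
    causes = {}
    for t in schedule.times:
        if t in observed:
            continue
        if p.death_time is not None and t >= p.death_time:
            causes[t] = "death"
        elif p.dropout_time is not None and t >= p.dropout_time:
            causes[t] = "dropout"
        else:
            causes[t] = "intermittent"
    return causes


def _fill_patient(
    p: PatientCourse, schedule: td.VisitSchedule, spec: StrategySpec
) -> PatientCourse:
    """Fill death- and dropout-caused gaps per the spec's explicit MDS;
    intermittent gaps follow the non-death (dropout) strategy."""
    causes = _gap_causes(p, schedule)
    if not causes:
        return p
    by_time = {o.time: o for o in p.observations}
    filled: dict[float, float] = {}
    last = p.baseline_score
    for t in schedule.times:
        obs = by_time.get(t)
        if obs is not None and obs.observed:
            last = obs.score
            continue
        cause = causes[t]
        mds = spec.mds_death if cause == "death" else spec.mds_dropout
        if mds == "locf":
            filled[t] = last
        elif mds == "worst_score" and cause == "death":
            filled[t] = spec.worst_score_value
        elif mds == "worst_score":
            filled[t] = spec.worst_score_value
        # complete_case / implicit / lcv / mi: leave missing here
    if not filled:
        return p
    observations = [
        Observation(p.patient_id, t, filled[t], True, imputed=True)
        if t in filled
        else by_time.get(t, Observation(p.patient_id, t, None, False))
        for t in schedule.times
    ]
    return replace(p, observations=observations)


def _lcv_truncate(ds: TrialDataset) -> TrialDataset:
    """Truncate the schedule to the last common visit: the latest visit at
    which every patient still alive and on study demonstrably remained under
    observation (has a recorded assessment at or after it)."""
    times = ds.schedule.times
    scores = ds.score_matrix()
    has_later = np.zeros_like(scores, dtype=bool)
    obs = ~np.isnan(scores)
    for j in range(len(times) - 1, -1, -1):
        has_later[:, j] = obs[:, j] | (has_later[:, j + 1] if j + 1 < len(times) else False)
    trunc = np.array(
        [np.inf if p.truncation_time is None else p.truncation_time for p in ds.patients]
    )
    on_study = np.asarray(times)[None, :] < trunc[:, None]
    on_study[:, 0] = True
    ok = (~on_study | has_later).all(axis=0)
    candidates = [j for j in range(1, len(times)) if ok[j]]
    if not candidates:
        raise DegenerateDataError("no common visit beyond baseline")
    j_star = max(candidates)
    new_sched = td.VisitSchedule(times[: j_star + 1])
    patients = [
        replace(p, observations=[o for o in p.observations if o.time <= times[j_star]])
        for p in ds.patients
    ]
    return TrialDataset(schedule=new_sched, patients=patients, meta=dict(ds.meta))


def apply_mds(
    ds: TrialDataset, spec: StrategySpec, rng: np.random.Generator | None = None
) -> TrialDataset | list[TrialDataset]:
    """Apply the spec's missing-data strategies.

    Returns a single dataset, or a list of ``spec.n_imputations`` completed
    datasets when either MDS is multiple imputation.
    """
    filled = TrialDataset(
        schedule=ds.schedule,
        patients=[_fill_patient(p, ds.schedule, spec) for p in ds.patients],
        meta=dict(ds.meta),
    )
    if "lcv" in (spec.mds_death, spec.mds_dropout):
        filled = _lcv_truncate(filled)
    if "mi" not in (spec.mds_death, spec.mds_dropout):
        return filled
    if rng is None:
        rng = np.random.default_rng(0)
    return _multiple_impute(filled, spec, rng)


def _multiple_impute(
    ds: TrialDataset, spec: StrategySpec, rng: np.random.Generator
) -> list[TrialDataset]:
    """Sequential conditional-normal imputation, visit by visit, of the gaps
    whose cause is covered by an 'mi' strategy; draws are from the posterior
    predictive under a noninformative prior."""
    times = ds.schedule.times
    k = len(times)
    scores = ds.score_matrix()
    arm = ds.arm_indicator()
    baseline = ds.baseline_scores()
    mi_mask = np.zeros_like(scores, dtype=bool)
    for i, p in enumerate(ds.patients):
        for t, cause in _gap_causes(p, ds.schedule).items():
            mds = spec.mds_death if cause == "death" else spec.mds_dropout
            if cause == "intermittent":
                mds = spec.mds_dropout
            if mds == "mi":
                mi_mask[i, times.index(t)] = True

    out = []
    for _ in range(spec.n_imputations):
        y = scores.copy()
        for j in range(1, k):
            need = mi_mask[:, j]
            have = ~np.isnan(y[:, j])
            X = np.column_stack([np.ones(len(y)), arm, baseline, y[:, 1:j]])
            fit_rows = have & ~np.isnan(X).any(axis=1)
            if fit_rows.sum() <= X.shape[1] + 1:
                raise DegenerateDataError(
                    f"too few observed values at week {times[j]:g} to impute"
                )
            Xo, yo = X[fit_rows], y[fit_rows, j]
            beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
            resid = yo - Xo @ beta
            dof = fit_rows.sum() - Xo.shape[1]
            sigma2 = float(resid @ resid) / rng.chisquare(dof)
            xtx_inv = np.linalg.pinv(Xo.T @ Xo)
            beta_star = rng.multivariate_normal(beta, sigma2 * xtx_inv, method="eigh")
            draw_rows = need & ~np.isnan(X).any(axis=1)
            draws = X[draw_rows] @ beta_star + rng.standard_normal(draw_rows.sum()) * math.sqrt(sigma2)
            y[draw_rows, j] = np.clip(draws, td.SCORE_MIN, td.SCORE_MAX)
        patients = []
        for i, p in enumerate(ds.patients):
            by_time = {o.time: o for o in p.observations}
            obs = []
            for jj, t in enumerate(times):
                if not np.isnan(y[i, jj]):
                    prior = by_time.get(t)
                    imput = prior is None or not prior.observed or prior.imputed
                    obs.append(
                        Observation(p.patient_id, t, float(y[i, jj]), True, imputed=imput)
                    )
                else:
                    obs.append(by_time.get(t, Observation(p.patient_id, t, None, False)))
            patients.append(replace(p, observations=obs))
        out.append(TrialDataset(schedule=ds.schedule, patients=patients, meta=dict(ds.meta)))
    return out


# ---------------------------------------------------------------------------
# Fits on per-patient summaries
# ---------------------------------------------------------------------------


def _split_arms(values: list[DerivedSummary]):
    keep = [v for v in values if not v.missing and np.isfinite(v.value)]
    a = np.array([v.value for v in keep if v.arm == td.ARM_ACTIVE])
    p = np.array([v.value for v in keep if v.arm == td.ARM_PLACEBO])
    return a, p, keep


def fit_group_comparison(
    values: list[DerivedSummary],
    model: str,
    covariates: np.ndarray | None = None,
    baseline_adjust: bool = False,
    baselines: dict[str, float] | None = None,
) -> MethodResult:
    """Two-group comparison of per-patient values.

    ``t_test`` is the pooled-variance two-sample t; ``linreg`` regresses the
    value on arm (plus baseline when ``baseline_adjust``); ``wilcoxon`` is the
    rank-sum test (exact for small untied samples, else the continuity- and
    tie-corrected normal approximation); ``logistic`` is a logit of a binary
    value on arm.  Missing values are assumed already resolved by the MDS and
    are simply excluded.
    """
    act, plc, keep = _split_arms(values)
    if len(act) < 2 or len(plc) < 2:
        raise FitError(f"fewer than 2 analyzable patients in an arm ({model})")
    n = len(keep)

    if model == "t_test":
        est = float(act.mean() - plc.mean())
        sp2 = (
            ((len(act) - 1) * act.var(ddof=1) + (len(plc) - 1) * plc.var(ddof=1))
            / (n - 2)
        )
        if sp2 == 0:
            if est == 0:
                return MethodResult(0.0, 0.0, 1.0, 0.0, n)
            raise FitError("zero variance with unequal means (t_test)")
        se = math.sqrt(sp2 * (1 / len(act) + 1 / len(plc)))
        tstat = est / se
        p = 2 * stats.t.sf(abs(tstat), n - 2)
        return MethodResult(est, se, float(p), pvalue_to_z(max(p, 1e-300), est), n)

    if model == "linreg":
        y = np.array([v.value for v in keep])
        arm = np.array([1.0 if v.arm == td.ARM_ACTIVE else 0.0 for v in keep])
        cols = [np.ones(n), arm]
        if baseline_adjust:
            if baselines is None:
                raise FitError("baseline adjustment requested without baselines")
            cols.append(np.array([baselines[v.patient_id] for v in keep]))
        if covariates is not None and covariates.size:
            cols.extend(covariates.T)
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = n - X.shape[1]
        if dof <= 0 or float(resid @ resid) == 0 and beta[1] != 0:
            raise FitError("degenerate linear regression")
        sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
        if sigma2 == 0:
            if beta[1] == 0:
                return MethodResult(0.0, 0.0, 1.0, 0.0, n)
            raise FitError("zero residual variance with nonzero effect (linreg)")
        cov = sigma2 * np.linalg.inv(X.T @ X)
        est = float(beta[1])
        se = math.sqrt(cov[1, 1])
        tstat = est / se
        p = 2 * stats.t.sf(abs(tstat), dof)
        return MethodResult(est, se, float(p), pvalue_to_z(max(p, 1e-300), est), n)

    if model == "wilcoxon":
        if act.var() == 0 and plc.var() == 0 and act.mean() == plc.mean():
            return MethodResult(0.0, None, 1.0, 0.0, n)
        res = stats.mannwhitneyu(act, plc, alternative="two-sided", method="auto")
        # Hodges-Lehmann shift: median of pairwise differences
        est = float(np.median(act[:, None] - plc[None, :]))
        direction = float(res.statistic - len(act) * len(plc) / 2)
        sign = direction if direction != 0 else est
        p = float(res.pvalue)
        return MethodResult(est, None, min(p, 1.0), pvalue_to_z(min(p, 1.0), sign), n)

    if model == "logistic":
        y = np.array([v.value for v in keep])
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise FitError("logistic model needs binary values")
        arm = np.array([1.0 if v.arm == td.ARM_ACTIVE else 0.0 for v in keep])
        tab = np.array(
            [
                [(y[arm == a_] == r).sum() for r in (0.0, 1.0)]
                for a_ in (0.0, 1.0)
            ],
            dtype=float,
        )
        if (tab == 0).any():
            raise FitError("separation: a cell of the 2x2 responder table is empty")
        X = np.column_stack([np.ones(n), arm])
        if covariates is not None and covariates.size:
            X = np.column_stack([X, covariates])
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        est = float(fit.params[1])
        se = float(fit.bse[1])
        if not np.isfinite(se) or se > 50:
            raise FitError("logistic fit did not stabilize (separation?)")
        p = float(fit.pvalues[1])
        return MethodResult(est, se, p, pvalue_to_z(max(p, 1e-300), est), n)

    raise FitError(f"unknown group-comparison model {model!r}")


# ---------------------------------------------------------------------------
# Longitudinal fits
# ---------------------------------------------------------------------------


def _long_arrays(ds: TrialDataset):
    scores = ds.score_matrix()
    times = np.asarray(ds.schedule.times)
    arm = ds.arm_indicator()
    n, k = scores.shape
    obs = ~np.isnan(scores)
    gi, vi = np.where(obs)
    return scores[gi, vi], times[vi], arm[gi], gi


def fit_random_effects(
    ds: TrialDataset, kind: str = "re_slopes", covariates: np.ndarray | None = None
) -> MethodResult:
    """Linear mixed model ``score ~ time + arm:time`` with a random intercept
    (``re_intercept``) or random intercept + slope with unstructured 2x2
    covariance (``re_slopes``); the treatment effect is the arm-by-time
    coefficient in points/week, tested by Wald z.  All observed pre-death
    data contribute (implicit missing-data handling)."""
    ds.require_both_arms()
    y, t, a, g = _long_arrays(ds)
    # compact group codes
    _, g = np.unique(g, return_inverse=True)
    cols = [np.ones_like(t), t, a * t]
    if covariates is not None and covariates.size:
        cols.extend(np.asarray(covariates)[g].T)
    X = np.column_stack(cols)
    fit = fit_lmm(y, X, g, times=t, random_slope=(kind == "re_slopes"))
    est, se, _, p = fit.wald(2)
    return MethodResult(est, se, p, pvalue_to_z(max(p, 1e-300), est), fit.n_groups)


def fit_mmrm_strategy(
    ds: TrialDataset, covariates: np.ndarray | None = None
) -> MethodResult:
    """MMRM on post-baseline change from baseline: visit-specific means and
    arm effects, baseline as covariate, unstructured within-patient
    covariance; the reported effect is the arm contrast at the final visit."""
    ds.require_both_arms()
    scores = ds.score_matrix()
    baseline = ds.baseline_scores()
    Y = scores[:, 1:] - baseline[:, None]
    fit = fit_mmrm(Y, ds.arm_indicator(), baseline, covariates)
    est, se, _, p = mmrm_final_visit_contrast(fit)
    return MethodResult(est, se, p, pvalue_to_z(max(p, 1e-300), est), fit.n_patients)


def gg_epsilon(sigma_c: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the covariance of orthonormal
    within-subject contrasts: ``(tr S)^2 / ((k-1) tr S^2)``."""
    k1 = sigma_c.shape[0]
    tr = float(np.trace(sigma_c))
    tr2 = float(np.trace(sigma_c @ sigma_c))
    if tr2 <= 0:
        return 1.0
    return min(1.0, tr ** 2 / (k1 * tr2))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal basis of the within-subject contrast space."""
    base = np.eye(k)[:, 1:] - 1.0 / k
    q, _ = np.linalg.qr(base - base.mean(axis=0, keepdims=True))
    return q[:, : k - 1]


def fit_rm_anova_gg(ds: TrialDataset) -> MethodResult:
    """Repeated-measures ANOVA (arm x visit) on the post-baseline scores of
    complete cases, with the arm-by-visit interaction F-test corrected by the
    Greenhouse-Geisser epsilon (both degrees of freedom multiplied by
    epsilon).  The reported estimate is the mean post-baseline score
    difference (active minus placebo); it carries the benefit sign but no
    standard error."""
    ds.require_both_arms()
    scores = ds.score_matrix()
    complete = ~np.isnan(scores).any(axis=1)
    arm = ds.arm_indicator()[complete]
    Y = scores[complete, 1:]
    n, kw = Y.shape
    for a_ in (0.0, 1.0):
        if (arm == a_).sum() < 2:
            raise FitError("fewer than 2 complete cases in an arm (rm_anova_gg)")
    if kw < 2:
        raise FitError("repeated-measures ANOVA needs >= 2 post-baseline visits")

    # Split-plot decomposition in the within-subject space.
    subj_mean = Y.mean(axis=1, keepdims=True)
    E = Y - subj_mean
    cell = np.stack([E[arm == a_].mean(axis=0) for a_ in (0.0, 1.0)])
    n_g = np.array([(arm == a_).sum() for a_ in (0.0, 1.0)], dtype=float)
    visit_mean = (n_g[:, None] * cell).sum(axis=0) / n
    ss_int = float((n_g[:, None] * (cell - visit_mean[None, :]) ** 2).sum())
    resid = E - cell[(arm == 1.0).astype(int)]
    ss_err = float((resid ** 2).sum())
    df1 = kw - 1
    df2 = (n - 2) * (kw - 1)
    if ss_err <= 0:
        raise FitError("zero within-subject error variance (rm_anova_gg)")
    F = (ss_int / df1) / (ss_err / df2)

    # Pooled within-arm covariance of the visits, projected onto contrasts.
    pooled = np.zeros((kw, kw))
    for a_ in (0.0, 1.0):
        Ya = Y[arm == a_]
        pooled += (len(Ya) - 1) * np.cov(Ya.T, ddof=1)
    pooled /= n - 2
    C = _orthonormal_contrasts(kw)
    eps = gg_epsilon(C.T @ pooled @ C)

    p = float(stats.f.sf(F, df1 * eps, df2 * eps))
    est = float(Y[arm == 1.0].mean() - Y[arm == 0.0].mean())
    return MethodResult(est, None, p, pvalue_to_z(max(p, 1e-300), est), n)


# ---------------------------------------------------------------------------
# Survival-aware fits
# ---------------------------------------------------------------------------


def fit_log_rank(values: list[DerivedSummary]) -> MethodResult:
    """Two-group log-rank test on composite event times.

    The statistic accumulates observed-minus-expected active-arm events over
    the hypergeometric risk sets; z is signed so that fewer active-arm events
    than expected is positive (benefit).  The estimate is the Peto log
    hazard ratio (O-E)/V for active vs placebo.
    """
    keep = [v for v in values if not v.missing]
    time = np.array([v.value for v in keep])
    event = np.array([bool(v.event_indicator) for v in keep])
    act = np.array([v.arm == td.ARM_ACTIVE for v in keep])
    if event.sum() == 0:
        raise DegenerateDataError("no events for the log-rank test")
    o_minus_e, var = logrank_terms(time, event, act)
    if var <= 0:
        return MethodResult(0.0, None, 1.0, 0.0, len(keep))
    chi2 = o_minus_e ** 2 / var
    p = float(stats.chi2.sf(chi2, 1))
    est = float(o_minus_e / var)  # Peto log-HR, active vs placebo
    z = pvalue_to_z(max(p, 1e-300), -o_minus_e)
    return MethodResult(est, float(1 / math.sqrt(var)), p, z, len(keep))


def logrank_terms(time, event, in_group) -> tuple[float, float]:
    """(O-E, V) for ``in_group`` over the distinct event times."""
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & in_group).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & in_group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e), float(var)


def joint_rank_scores(ds: TrialDataset, landmark: float) -> np.ndarray:
    """All-pairs joint-rank score per patient: survival to the landmark is
    compared first (later death or survival wins), change from baseline at
    the landmark second (the last available change when the landmark visit is
    missing); each won pair is +1, each lost pair -1."""
    times = np.asarray(ds.schedule.times)
    j_land = ds.schedule.index_of(landmark)
    scores = ds.score_matrix()
    cfb = scores - scores[:, [0]]
    death = ds.death_times()
    dead = np.isfinite(death) & (death <= landmark)
    dtime = np.where(dead, death, np.inf)
    # last available CFB at or before the landmark
    cfb_land = np.full(ds.n, np.nan)
    for j in range(j_land, 0, -1):
        take = np.isnan(cfb_land) & ~np.isnan(cfb[:, j])
        cfb_land[take] = cfb[take, j]

    n = ds.n
    dt_i = dtime[:, None]
    dt_j = dtime[None, :]
    with np.errstate(invalid="ignore"):
        surv = np.sign(dt_i - dt_j)      # +1 if i outlives j within landmark
    surv[np.isinf(dt_i) & np.isinf(dt_j)] = 0  # both survive: defer to function
    c_i = cfb_land[:, None]
    c_j = cfb_land[None, :]
    with np.errstate(invalid="ignore"):
        func = np.sign(c_i - c_j)
    func[np.isnan(c_i) | np.isnan(c_j)] = 0.0
    pair = np.where(surv != 0, surv, func)
    np.fill_diagonal(pair, 0.0)
    return pair.sum(axis=1)


def fit_joint_rank(ds: TrialDataset, landmark: float | None = None) -> MethodResult:
    """Joint-rank composite (survival first, function second) analyzed by a
    rank-sum test on the per-patient pairwise scores."""
    ds.require_both_arms()
    if landmark is None:
        landmark = ds.schedule.horizon
    sc = joint_rank_scores(ds, landmark)
    arm = ds.arm_indicator()
    act, plc = sc[arm == 1.0], sc[arm == 0.0]
    est = float(act.mean() - plc.mean())
    if np.all(sc == sc[0]):
        return MethodResult(0.0, None, 1.0, 0.0, ds.n)
    res = stats.mannwhitneyu(act, plc, alternative="two-sided", method="asymptotic")
    direction = float(res.statistic - len(act) * len(plc) / 2)
    p = float(res.pvalue)
    return MethodResult(est, None, p, pvalue_to_z(max(p, 1e-300), direction if direction else est), ds.n)


# ---------------------------------------------------------------------------
# Multiple-imputation pooling
# ---------------------------------------------------------------------------


def pool_mi(results: list[MethodResult], nu_complete: float | None = None) -> MethodResult:
    """Combine per-imputation results by Rubin's rules.

    Total variance is within + (1 + 1/M) between; the reference t
    distribution uses the Barnard-Rubin small-sample degrees of freedom when
    ``nu_complete`` is given, else the classical large-sample formula.
    """
    M = len(results)
    if M < 2:
        raise FitError("pooling needs at least 2 imputations")
    if any(r.se is None for r in results):
        raise FitError("pooling needs a standard error from every imputation")
    est = np.array([r.estimate for r in results])
    se = np.array([r.se for r in results])
    qbar = float(est.mean())
    within = float((se ** 2).mean())
    between = float(est.var(ddof=1))
    total = within + (1 + 1 / M) * between
    n_analyzed = int(round(np.mean([r.n_analyzed for r in results])))
    if total == 0:
        p = 1.0 if qbar == 0 else 0.0
        return MethodResult(qbar, 0.0, p, pvalue_to_z(max(p, 1e-300), qbar), n_analyzed)
    if between == 0:
        z = qbar / math.sqrt(total)
        p = 2 * stats.norm.sf(abs(z))
        return MethodResult(qbar, math.sqrt(total), float(p), pvalue_to_z(max(p, 1e-300), qbar), n_analyzed)
    r_incr = (1 + 1 / M) * between / within if within > 0 else np.inf
    nu = (M - 1) * (1 + 1 / r_incr) ** 2 if np.isfinite(r_incr) else M - 1
    if nu_complete is not None and within > 0:
        lam = (1 + 1 / M) * between / total
        nu_obs = (nu_complete + 1) / (nu_complete + 3) * nu_complete * (1 - lam)
        nu = 1 / (1 / nu + 1 / nu_obs)
    tstat = qbar / math.sqrt(total)
    p = float(2 * stats.t.sf(abs(tstat), nu))
    return MethodResult(qbar, math.sqrt(total), p, pvalue_to_z(max(p, 1e-300), qbar), n_analyzed)


# ---------------------------------------------------------------------------
# Estimand classification and the strategy pipeline
# ---------------------------------------------------------------------------


def classify_estimand(spec: StrategySpec) -> str:
    """Deterministic map from a strategy's components to the estimand
    strategy for handling death."""
    if spec.summary in ("rank_composite", "tte_decline_death"):
        return "composite"
    if spec.mds_death == "worst_score":
        return "composite"
    if spec.mds_death in ("mi", "locf"):
        return "hypothetical"
    if spec.mds_death == "implicit":
        if spec.model in ("re_intercept", "re_slopes"):
            return "while_alive"
        if spec.model == "mmrm":
            return "hypothetical"
        raise ValidationError(
            f"{spec.name}: implicit death handling undefined for {spec.model}"
        )
    if spec.mds_death in ("complete_case", "lcv"):
        if spec.summary == "slope" or spec.model in ("re_intercept", "re_slopes"):
            return "while_alive"
        return "principal_stratum"
    raise ValidationError(f"{spec.name}: cannot classify estimand")


def _summary_values(ds: TrialDataset, spec: StrategySpec) -> list[DerivedSummary]:
    if spec.summary == "cfb_final":
        return td.change_from_baseline(ds, ds.schedule.horizon)
    if spec.summary == "cfb_visit":
        visit = spec.visit if spec.visit in ds.schedule.times else ds.schedule.horizon
        return td.change_from_baseline(ds, visit)
    if spec.summary == "slope":
        return td.per_patient_slope(ds)
    if spec.summary == "responder":
        visit = spec.visit if spec.visit is not None else ds.schedule.horizon
        if visit not in ds.schedule.times:
            visit = ds.schedule.horizon
        return td.responder_flags(ds, spec.responder_threshold, visit)
    if spec.summary == "tte_decline_death":
        return td.event_times_decline_or_death(ds, spec.decline_threshold)
    raise FitError(f"summary {spec.summary!r} has no per-patient values")


def _fit_one(ds: TrialDataset, spec: StrategySpec) -> MethodResult:
    if spec.model in _VALUE_MODELS:
        values = _summary_values(ds, spec)
        baselines = {p.patient_id: p.baseline_score for p in ds.patients}
        res = fit_group_comparison(
            values,
            spec.model,
            baseline_adjust=spec.baseline_adjust,
            baselines=baselines,
        )
    elif spec.model in ("re_intercept", "re_slopes"):
        res = fit_random_effects(ds, spec.model)
    elif spec.model == "mmrm":
        res = fit_mmrm_strategy(ds)
    elif spec.model == "rm_anova_gg":
        res = fit_rm_anova_gg(ds)
    elif spec.model == "log_rank":
        res = fit_log_rank(_summary_values(ds, spec))
    elif spec.model == "joint_rank":
        res = fit_joint_rank(ds, spec.landmark)
    else:
        raise FitError(f"unknown model {spec.model!r}")
    return replace(res, strategy=spec.name)


def apply_strategy(ds: TrialDataset, spec: StrategySpec, seed: int = 0) -> MethodResult:
    """Run the full pipeline — missing-data strategy, outcome summary, model
    fit, and (for multiple imputation) Rubin pooling — for one strategy on
    one dataset.  Deterministic for fixed ``(ds, spec, seed)``."""
    try:
        prepared = apply_mds(ds, spec, rng=np.random.default_rng([seed, 0xA15]))
        if isinstance(prepared, list):
            parts = [_fit_one(d, spec) for d in prepared]
            pooled = pool_mi(parts, nu_complete=max(parts[0].n_analyzed - 2, 2))
            return replace(pooled, strategy=spec.name)
        return _fit_one(prepared, spec)
    except FitError as exc:
        raise FitError(f"{spec.name}: {exc}") from exc


# ---------------------------------------------------------------------------
# The preset catalog
# ---------------------------------------------------------------------------


def strategy_catalog() -> list[StrategySpec]:
    """Named presets spanning the component families seen across ALS trials:
    every estimand strategy, every model family, and every missing-data
    strategy appears at least once."""
    S = StrategySpec
    cat = [
        # -- change from baseline at the final visit, linear models
        S("CFB-CC lin-reg", "cfb_final", "linreg", True,
          mds_death="complete_case", mds_dropout="complete_case"),
        S("CFB-LOCF lin-reg", "cfb_final", "linreg", True,
          mds_death="locf", mds_dropout="locf"),
        S("CFB-worst-LOCF lin-reg", "cfb_final", "linreg", True,
          mds_death="worst_score", mds_dropout="locf"),
        S("CFB-MI lin-reg", "cfb_final", "linreg", True,
          mds_death="mi", mds_dropout="mi"),
        S("CFB-LCV lin-reg", "cfb_final", "linreg", True,
          mds_death="lcv", mds_dropout="lcv"),
        S("CFB-CC t-test", "cfb_final", "t_test",
          mds_death="complete_case", mds_dropout="complete_case"),
        S("CFB-LOCF t-test", "cfb_final", "t_test",
          mds_death="locf", mds_dropout="locf"),
        S("CFB-LCV t-test", "cfb_final", "t_test",
          mds_death="lcv", mds_dropout="lcv"),
        # -- nonparametric on CFB
        S("CFB-CC nonparam", "cfb_final", "wilcoxon",
          mds_death="complete_case", mds_dropout="complete_case"),
        S("CFB-LOCF nonparam", "cfb_final", "wilcoxon",
          mds_death="locf", mds_dropout="locf"),
        # -- per-patient slopes
        S("Slope-CC t-test", "slope", "t_test",
          mds_death="complete_case", mds_dropout="complete_case"),
        S("Slope-LOCF t-test", "slope", "t_test",
          mds_death="locf", mds_dropout="locf"),
        # -- responder analyses
        S("Responder-CC logistic", "responder", "logistic",
          mds_death="complete_case", mds_dropout="complete_case"),
        S("Responder-LOCF logistic", "responder", "logistic",
          mds_death="locf", mds_dropout="locf"),
        S("Responder-worst logistic", "responder", "logistic",
          mds_death="worst_score", mds_dropout="locf"),
        # -- repeated-measures ANOVA
        S("RM-ANOVA-CC", "longitudinal", "rm_anova_gg",
          mds_death="complete_case", mds_dropout="complete_case"),
        S("RM-ANOVA-LOCF", "longitudinal", "rm_anova_gg",
          mds_death="locf", mds_dropout="locf"),
        # -- mixed models
        S("RE-int", "longitudinal", "re_intercept",
          mds_death="implicit", mds_dropout="implicit"),
        S("RE-slope", "longitudinal", "re_slopes",
          mds_death="implicit", mds_dropout="implicit"),
        S("MMRM", "longitudinal", "mmrm",
          mds_death="implicit", mds_dropout="implicit"),
        S("MMRM-MI-death", "longitudinal", "mmrm",
          mds_death="mi", mds_dropout="implicit"),
        # -- composites
        S("Joint-rank", "rank_composite", "joint_rank",
          mds_death="implicit", mds_dropout="implicit"),
        S("Log-rank 6pt/death", "tte_decline_death", "log_rank",
          mds_death="implicit", mds_dropout="implicit"),
    ]
    return cat


def catalog_frame():
    """The preset catalog as a tidy table (name, components, estimand)."""
    import pandas as pd

    rows = [
        {
            "name": s.name,
            "summary": s.summary,
            "model": s.model,
            "baseline_adjust": s.baseline_adjust,
            "mds_death": s.mds_death,
            "mds_dropout": s.mds_dropout,
            "estimand": s.estimand,
        }
        for s in strategy_catalog()
    ]
    return pd.DataFrame(rows)
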