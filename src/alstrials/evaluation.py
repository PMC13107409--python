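"""Permutation/simulation engine for validity and precision of strategies.

The false-positive rate of a strategy is estimated by label permutation on a
fixed dataset: arm labels are reassigned at the original sizes, so both
"arms" are draws from one population and any significant result is a false
positive attributable to the method.  Power is estimated the same way after
injecting a proportional slowing of each active patient's observed
post-baseline change.  A differential-attrition scenario additionally pushes
the active arm's attrition to a target fraction by drawing extra dropout
times.  Rates carry Wilson score intervals; a strategy is *valid* when its
false-positive rate stays at or below the tolerance threshold (default 0.10,
twice the nominal two-sided 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import trial_data as td
from .lmm import FitError
from .strategies import MethodResult, StrategySpec, apply_strategy
from .trial_data import Observation, TrialDataset, ValidationError

SCENARIOS = ("null_balanced", "null_imbalanced", "alt_balanced", "alt_imbalanced")


class EvaluationAborted(RuntimeError):
    """Too many fit failures to report a rate for this strategy."""


@dataclass(frozen=True)
class EvaluationConfig:
    """Scenario knobs: replication count, significance level, the validity
    tolerance on the null false-positive rate, the injected slowing, and the
    active-arm attrition target for the imbalanced scenarios."""

    n_reps: int = 1000
    alpha: float = 0.05
    validity_threshold: float = 0.10
    delta_slope: float = 0.20
    attrition_target: float = 0.40
    seed: int = 0
    ci_level: float = 0.95
    max_failure_frac: float = 0.20
    warn_failure_frac: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.validity_threshold < 1):
            raise ValidationError("alpha and validity_threshold must be in (0,1)")
        if self.alpha > self.validity_threshold:
            raise ValidationError("alpha must not exceed validity_threshold")
        if not (0 <= self.delta_slope <= 1):
            raise ValidationError("delta_slope must be in [0, 1]")
        if not (0 < self.attrition_target < 1):
            raise ValidationError("attrition_target must be in (0, 1)")


@dataclass(frozen=True)
class EvaluationResult:
    strategy_name: str
    scenario: str
    rate: float
    ci_low: float
    ci_high: float
    n_reps_done: int
    n_fit_failures: int
    valid: bool | None  # null scenarios only

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.rate <= self.ci_high <= 1):
            raise ValidationError("rate must sit inside its confidence interval")


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValidationError("Wilson interval needs n >= 1")
    if not (0 <= successes <= n):
        raise ValidationError("successes must be between 0 and n")
    low, high = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    # the score interval is exactly [0, .] at 0 successes and [., 1] at n
    low = 0.0 if successes == 0 else float(np.clip(low, 0.0, 1.0))
    high = 1.0 if successes == n else float(np.clip(high, 0.0, 1.0))
    return low, high


def permute_labels(ds: TrialDataset, rng: np.random.Generator) -> TrialDataset:
    """Randomly reassign arm labels across patients, preserving arm sizes;
    all outcome and attrition data stay attached to their patients."""
    ds.require_both_arms()
    arms = [p.arm for p in ds.patients]
    perm = rng.permutation(len(arms))
    return ds.with_arms([arms[i] for i in perm])


def inject_effect(ds: TrialDataset, delta_slope: float) -> TrialDataset:
    """Slow each active-arm patient's observed post-baseline change by the
    fraction ``delta_slope``: y(t) -> y(0) + (1-delta)*(y(t)-y(0)), rounded
    and clamped; placebo data, baselines, and event times are untouched."""
    if not (0 <= delta_slope <= 1):
        raise ValidationError("delta_slope must be in [0, 1]")
    if delta_slope == 0:
        return ds
    patients = []
    for p in ds.patients:
        if p.arm != td.ARM_ACTIVE:
            patients.append(p)
            continue
        obs = []
        for o in p.observations:
            if o.observed and o.time > 0:
                y = p.baseline_score + (1 - delta_slope) * (o.score - p.baseline_score)
                y = float(np.clip(round(y), td.SCORE_MIN, td.SCORE_MAX))
                obs.append(replace(o, score=y))
            else:
                obs.append(o)
        patients.append(replace(p, observations=obs))
    return TrialDataset(schedule=ds.schedule, patients=patients, meta=dict(ds.meta))


def inflate_attrition(
    ds: TrialDataset, target: float, rng: np.random.Generator
) -> TrialDataset:
    """Raise the active arm's non-death dropout rate to ``target`` (the
    scale on which trial reports quote group attrition) by assigning new
    dropout times — drawn uniformly among post-baseline visit times — to
    randomly chosen active patients with neither death nor dropout;
    observations from the drawn visit onward are removed.  The placebo arm
    is untouched."""
    active_idx = [i for i, p in enumerate(ds.patients) if p.arm == td.ARM_ACTIVE]
    n_active = len(active_idx)
    with_attr = [
        i for i in active_idx if ds.patients[i].dropout_time is not None
    ]
    current = len(with_attr) / n_active if n_active else 0.0
    if current > target + 1e-12:
        raise ValidationError(
            f"active-arm attrition {current:.3f} already exceeds target {target:.3f}"
        )
    n_needed = int(round(target * n_active)) - len(with_attr)
    if n_needed <= 0:
        return ds
    candidates = [i for i in active_idx if ds.patients[i].truncation_time is None]
    chosen = rng.choice(len(candidates), size=n_needed, replace=False)
    chosen = {candidates[j] for j in chosen}
    post = ds.schedule.post_baseline
    patients = []
    for i, p in enumerate(ds.patients):
        if i not in chosen:
            patients.append(p)
            continue
        t_drop = float(post[rng.integers(len(post))])
        obs = [
            o if o.time < t_drop else Observation(p.patient_id, o.time, None, False)
            for o in p.observations
        ]
        patients.append(replace(p, observations=obs, dropout_time=t_drop))
    return TrialDataset(schedule=ds.schedule, patients=patients, meta=dict(ds.meta))


def run_scenario_once(
    ds: TrialDataset,
    spec: StrategySpec,
    scenario: str,
    config: EvaluationConfig,
    rng: np.random.Generator,
    rep_seed: int,
) -> MethodResult:
    """One permutation replicate of a scenario: permute, then (alt) inject
    the effect, then (imbalanced) inflate active-arm attrition, then fit."""
    if scenario not in SCENARIOS:
        raise ValidationError(f"unknown scenario {scenario!r}")
    work = permute_labels(ds, rng)
    if scenario.startswith("alt"):
        work = inject_effect(work, config.delta_slope)
    if scenario.endswith("imbalanced"):
        work = inflate_attrition(work, config.attrition_target, rng)
    return apply_strategy(work, spec, seed=rep_seed)


def estimate_rate(
    ds: TrialDataset,
    spec: StrategySpec,
    scenario: str,
    config: EvaluationConfig,
) -> EvaluationResult:
    """Fraction of replicates with a significant two-sided result.

    Fit failures are excluded from the denominator and counted; more than
    ``warn_failure_frac`` of them is reported in the result, and more than
    ``max_failure_frac`` aborts the cell.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _stable_hash(spec.name), _stable_hash(scenario)])
    )
    n_sig = 0
    n_done = 0
    n_fail = 0
    for rep in range(config.n_reps):
        try:
            res = run_scenario_once(
                ds, spec, scenario, config, rng, rep_seed=config.seed + rep
            )
        except FitError:
            n_fail += 1
            if n_fail > config.max_failure_frac * config.n_reps:
                raise EvaluationAborted(
                    f"{spec.name}/{scenario}: {n_fail} fit failures in "
                    f"{rep + 1} replicates"
                ) from None
            continue
        n_done += 1
        if res.p_value < config.alpha:
            n_sig += 1
    if n_done == 0:
        raise EvaluationAborted(f"{spec.name}/{scenario}: no successful fits")
    rate = n_sig / n_done
    low, high = wilson_ci(n_sig, n_done, config.ci_level)
    is_null = scenario.startswith("null")
    return EvaluationResult(
        strategy_name=spec.name,
        scenario=scenario,
        rate=rate,
        ci_low=low,
        ci_high=high,
        n_reps_done=n_done,
        n_fit_failures=n_fail,
        valid=(rate <= config.validity_threshold) if is_null else None,
    )


def classify_validity(result: EvaluationResult, config: EvaluationConfig) -> bool:
    """A null-scenario rate is valid iff it does not exceed the tolerance
    threshold (inclusive)."""
    if not result.scenario.startswith("null"):
        raise ValidationError("validity is defined for null scenarios only")
    return result.rate <= config.validity_threshold


def run_grid(
    catalog: list[StrategySpec],
    master_ds: TrialDataset,
    scenarios: tuple[str, ...] = SCENARIOS,
    config: EvaluationConfig = EvaluationConfig(),
) -> pd.DataFrame:
    """Full cross of strategies x scenarios as a tidy table.

    Per-cell errors are recorded (rate columns NaN), never aborting the grid.
    """
    if not catalog:
        raise ValidationError("catalog must be nonempty")
    rows = []
    for spec in catalog:
        for scenario in scenarios:
            base = {
                "strategy": spec.name,
                "estimand": spec.estimand,
                "scenario": scenario,
            }
            try:
                res = estimate_rate(master_ds, spec, scenario, config)
                rows.append(
                    base
                    | {
                        "rate": res.rate,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "n_reps_done": res.n_reps_done,
                        "n_fit_failures": res.n_fit_failures,
                        "valid": res.valid,
                        "error": "",
                    }
                )
            except (EvaluationAborted, FitError, ValidationError) as exc:
                rows.append(
                    base
                    | {
                        "rate": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "n_reps_done": 0,
                        "n_fit_failures": config.n_reps,
                        "valid": None,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)


def _stable_hash(text: str) -> int:
    """Deterministic 31-bit hash (process-independent, unlike ``hash``)."""
    h = 0
    for ch in text:
        h = (h * 1_000_003 + ord(ch)) % (2**31 - 1)
    return h
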