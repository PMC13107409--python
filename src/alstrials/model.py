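"""Model/Results surface over the strategy pipeline.

``StrategyModel`` binds one trial dataset to one analysis strategy, the way a
regression model binds data to a design; ``fit()`` runs the missing-data
strategy, the outcome summary, and the test, and returns a
:class:`StrategyResults` carrying the estimate, its uncertainty, and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .strategies import MethodResult, StrategySpec, apply_strategy
from .trial_data import TrialDataset, dataset_from_frame


class StrategyModel:
    """One analysis strategy bound to one trial dataset.

    Parameters
    ----------
    dataset : TrialDataset
        Long-format longitudinal trial data.
    spec : StrategySpec
        The analysis strategy (summary, model, missing-data handling).
    """

    def __init__(self, dataset: TrialDataset, spec: StrategySpec) -> None:
        dataset.require_both_arms()
        self.dataset = dataset
        self.spec = spec

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, spec: StrategySpec, meta: dict | None = None
    ) -> "StrategyModel":
        """Build from a long-format table (columns ``patient_id, arm,
        time_weeks, alsfrs_r, death_time_weeks, dropout_time_weeks``)."""
        return cls(dataset_from_frame(frame, meta=meta), spec)

    def fit(self, seed: int = 0) -> "StrategyResults":
        """Run the strategy; deterministic for fixed ``seed``."""
        result = apply_strategy(self.dataset, self.spec, seed=seed)
        return StrategyResults(self, result)


@dataclass(frozen=True)
class StrategyResults:
    """Fitted strategy: the treatment-effect estimate on the strategy's
    scale, its standard error where the method provides one, the two-sided
    p-value, and the signed z-score (positive = benefit)."""

    model: StrategyModel
    method_result: MethodResult

    @property
    def estimate(self) -> float:
        return self.method_result.estimate

    @property
    def se(self) -> float | None:
        return self.method_result.se

    @property
    def pvalue(self) -> float:
        return self.method_result.p_value

    @property
    def zscore(self) -> float:
        return self.method_result.z_score

    @property
    def nobs(self) -> int:
        return self.method_result.n_analyzed

    def summary(self) -> str:
        spec = self.model.spec
        sizes = self.model.dataset.arm_sizes()
        se = "---" if self.se is None else f"{self.se:.4f}"
        lines = [
            "Strategy fit",
            "=" * 58,
            f"strategy:        {spec.name}",
            f"estimand:        {spec.estimand}",
            f"summary/model:   {spec.summary} / {spec.model}",
            f"MDS death/drop:  {spec.mds_death} / {spec.mds_dropout}",
            f"randomized:      {sum(sizes.values())} "
            f"(active {sizes['active']}, placebo {sizes['placebo']})",
            f"analyzed:        {self.nobs}",
            "-" * 58,
            f"estimate:        {self.estimate:+.4f}",
            f"std. error:      {se}",
            f"p-value (2s):    {self.pvalue:.4f}",
            f"z-score:         {self.zscore:+.3f}   (positive = benefit)",
            "=" * 58,
        ]
        return "\n".join(lines)
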