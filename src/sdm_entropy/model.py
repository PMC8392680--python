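"""Model/Results front end for the full workflow.

`EntropyStepwiseSDM` bundles the species-specific variable screen
(correlation filter + FDR), the entropy-instrumented stepwise logistic
regression, the favourability transform, and the evaluation panel behind
a statsmodels-like interface::

    model = EntropyStepwiseSDM.from_dataframe(df, presence_col="sp")
    res = model.fit()
    print(res.summary())
    res.step_table()          # the per-step H / cor_P / cor_F / R / AIC trace
    res.min_entropy_step      # the efficient (minimum fuzzy entropy) model
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import OccurrenceDataset
from .entropy import FavourabilityMap, favourability
from .evaluation import EvaluationReport, evaluate
from .glm import LogisticModel
from .selection import SelectionReport, select_variables
from .stepwise import StepTrace, annotate_trace, select_min_entropy_model, stepwise_fit


class EntropyStepwiseSDM:
    """Entropy-instrumented stepwise species distribution model.

    Parameters
    ----------
    dataset : OccurrenceDataset
        Presence/absence grid with predictors.
    r_threshold : float
        Stage-1 pairwise |Pearson r| cutoff (strict), default 0.8.
    q : float
        Stage-2 false discovery rate, default 0.05.
    within_groups : bool
        Run the correlation filter within predictor sets when group labels
        are available (default) or globally.
    threshold : float
        Favourability classification threshold, default 0.5.
    n_bins : int
        Number of fixed-width Hosmer-Lemeshow / calibration bins, default 10.
    """

    def __init__(
        self,
        dataset: OccurrenceDataset,
        r_threshold: float = 0.8,
        q: float = 0.05,
        within_groups: bool = True,
        threshold: float = 0.5,
        n_bins: int = 10,
    ) -> None:
        self.dataset = dataset
        self.r_threshold = r_threshold
        self.q = q
        self.within_groups = within_groups
        self.threshold = threshold
        self.n_bins = n_bins

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        presence_col: str = "presence",
        id_col: str | None = None,
        group_map: dict[str, str] | None = None,
        **kwargs,
    ) -> "EntropyStepwiseSDM":
        """Build from a plain DataFrame (columns x/y treated as coordinates)."""
        df = df.reset_index(drop=True)
        cell_id = (
            df[id_col].to_numpy(dtype=str)
            if id_col is not None
            else np.array([f"c{i:06d}" for i in range(len(df))])
        )
        skip = {presence_col, id_col, "x", "y"}
        predictors = df[[c for c in df.columns if c not in skip]].astype(float)
        dataset = OccurrenceDataset(
            cell_id=cell_id,
            presence=df[presence_col].to_numpy(),
            predictors=predictors,
            variable_group=group_map,
            x=df["x"].to_numpy(dtype=float) if "x" in df.columns else None,
            y=df["y"].to_numpy(dtype=float) if "y" in df.columns else None,
        )
        return cls(dataset, **kwargs)

    def screen(self) -> SelectionReport:
        """Stages 1-2 only: correlation filter then FDR."""
        return select_variables(
            self.dataset,
            r_threshold=self.r_threshold,
            q=self.q,
            within_groups=self.within_groups,
        )

    def fit(self, candidates: list[str] | None = None) -> "EntropyStepwiseSDMResults":
        """Run screening (unless candidates are given) and the stepwise trace."""
        selection = None
        if candidates is None:
            selection = self.screen()
            candidates = selection.stage2_retained
        trace = annotate_trace(stepwise_fit(self.dataset, candidates), self.dataset)
        return EntropyStepwiseSDMResults(model=self, selection=selection, trace=trace)


@dataclass
class EntropyStepwiseSDMResults:
    """Fitted workflow: selection report, step trace, chosen models."""

    model: EntropyStepwiseSDM
    selection: SelectionReport | None
    trace: StepTrace
    _evaluations: dict[int, EvaluationReport] = field(default_factory=dict, repr=False)

    # -- chosen models ------------------------------------------------------

    @property
    def final_model(self) -> LogisticModel:
        return self.trace.final_model

    @property
    def min_entropy_step(self) -> int:
        step, _ = select_min_entropy_model(self.trace)
        return step

    @property
    def min_entropy_model(self) -> LogisticModel:
        _, m = select_min_entropy_model(self.trace)
        return m

    @property
    def params(self) -> pd.Series:
        """Final-model coefficients on the original predictor scale."""
        m = self.final_model
        return pd.Series(
            {"Intercept": m.intercept, **m.coefficients}, name="coefficient"
        )

    def favourability_map(self, step: int | None = None) -> FavourabilityMap:
        step = self.trace.final_step if step is None else step
        rec = self.trace.records[step]
        if rec.favourability is None:
            rec_f = favourability(
                rec.model.fitted_probability, self.model.dataset.n1, self.model.dataset.n0
            )
            rec.favourability = rec_f
        return rec.favourability

    # -- diagnostics --------------------------------------------------------

    def step_table(self) -> pd.DataFrame:
        return self.trace.to_frame()

    def evaluation(self, step: int | None = None) -> EvaluationReport:
        """Metric panel (kappa/sens/spec/CCR/AUC/HL/calibration) of one step."""
        step = self.trace.final_step if step is None else step
        if step not in self._evaluations:
            rec = self.trace.records[step]
            self._evaluations[step] = evaluate(
                rec.model.fitted_probability,
                self.favourability_map(step),
                self.model.dataset.presence,
                threshold=self.model.threshold,
                n_bins=self.model.n_bins,
            )
        return self._evaluations[step]

    def plot_entropy(self, ax=None):
        """Fuzzy entropy R against step index, min-R step marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        table = self.step_table()
        ax.plot(table["step"], table["R"], marker="o")
        ax.axvline(self.min_entropy_step, linestyle="--", color="grey")
        ax.set_xlabel("step")
        ax.set_ylabel("fuzzy entropy R")
        return ax

    def summary(self) -> str:
        """Human-readable account of the fitted workflow."""
        ds = self.model.dataset
        lines = [
            "Entropy-instrumented stepwise favourability model",
            "=" * 50,
            f"cells: {ds.n}   presences: {ds.n1}   prevalence: {ds.prevalence:.4f}",
        ]
        if self.selection is not None:
            lines += [
                f"candidates screened: {len(self.selection.screen)}",
                f"after correlation filter (|r| > {self.selection.r_threshold}): {self.selection.V}",
                f"after FDR (q = {self.selection.q}): {len(self.selection.stage2_retained)}",
            ]
        lines += [
            f"stepwise steps: {self.trace.final_step}",
            f"minimum fuzzy entropy at step {self.min_entropy_step} "
            f"(R = {self.trace.records[self.min_entropy_step].R:.4g})",
            "",
            "Step trace",
            "-" * 50,
            self.step_table().to_string(
                index=False, float_format=lambda v: f"{v:.4g}"
            ),
            "",
            "Final model coefficients",
            "-" * 50,
            self.params.to_string(float_format=lambda v: f"{v:.6g}"),
        ]
        ev = self.evaluation()
        lines += [
            "",
            "Final model evaluation",
            "-" * 50,
            f"AUC: {ev.auc:.3f}  kappa: {ev.kappa:.3f}  sensitivity: {ev.sensitivity:.3f}  "
            f"specificity: {ev.specificity:.3f}  CCR: {ev.ccr:.3f}",
            f"Hosmer-Lemeshow: {ev.hl_statistic:.3f} (df {ev.hl_df}, p {ev.hl_p:.3f})",
        ]
        return "\n".join(lines)
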