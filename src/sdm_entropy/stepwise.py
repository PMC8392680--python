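"""Entropy-instrumented forward-backwards stepwise selection by AIC.

Starting from the intercept-only model (step 0), each step scores every
legal single move — adding one candidate not in the model or dropping one
variable in it — and accepts the move with the lowest resulting AIC,
stopping when no move lowers the current AIC. Dropped variables remain
candidates and may re-enter.

Each accepted step yields a model; annotation attaches, per step, the
fitted probabilities P, the favourability map F, Shannon entropy H of
P/n1, fuzzy entropy R of F, and Pearson correlations of P and F with the
final step (cor_P, cor_F; undefined at step 0 where the fitted values are
constant). The step attaining the minimum R is the efficient model:
maximal reduction of uncertainty at maximal parsimony.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import OccurrenceDataset
from .entropy import FavourabilityMap, favourability, fuzzy_entropy, shannon_entropy_normalized
from .glm import LogisticModel, RankDeficientDesignError, fit_logistic


@dataclass
class StepRecord:
    """One accepted stepwise move and its instrumented model."""

    step_index: int
    action: str  # "start" | "add" | "drop"
    variable: str | None
    model: LogisticModel
    H: float | None = None
    R: float | None = None
    cor_P: float = float("nan")
    cor_F: float = float("nan")
    favourability: FavourabilityMap | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return self.model.aic

    @property
    def label(self) -> str:
        if self.action == "start":
            return "Intercept"
        sign = "+" if self.action == "add" else "-"
        return f"{sign}{self.variable}"


@dataclass
class StepTrace:
    """Ordered records of a stepwise run; index 0 is the null model."""

    records: list[StepRecord]
    min_R_step: int | None = None

    @property
    def final_step(self) -> int:
        return len(self.records) - 1

    @property
    def final_model(self) -> LogisticModel:
        return self.records[-1].model

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Step table: step, action, variable, H, cor_P, cor_F, R, aic, k, loglik."""
        return pd.DataFrame(
            {
                "step": [r.step_index for r in self.records],
                "action": [r.action for r in self.records],
                "variable": [r.variable if r.variable else "" for r in self.records],
                "H": [r.H for r in self.records],
                "cor_P": [r.cor_P for r in self.records],
                "cor_F": [r.cor_F for r in self.records],
                "R": [r.R for r in self.records],
                "aic": [r.aic for r in self.records],
                "k": [r.model.k for r in self.records],
                "loglik": [r.model.log_likelihood for r in self.records],
            }
        )


def stepwise_fit(dataset: OccurrenceDataset, candidates: list[str]) -> StepTrace:
    """Run the stepwise search; deterministic for a given dataset.

    Move ties are broken by candidate input order (additions scanned in
    candidate order before deletions in current-model order). Sub-models
    that fail to converge are skipped with a warning.
    """
    candidates = list(candidates)
    current = fit_logistic(dataset, [])
    records = [StepRecord(0, "start", None, current)]
    included: list[str] = []

    while True:
        moves: list[tuple[str, str, list[str]]] = []
        for v in candidates:
            if v not in included:
                moves.append(("add", v, included + [v]))
        for v in included:
            moves.append(("drop", v, [w for w in included if w != v]))

        best: tuple[float, int] | None = None
        best_fit: LogisticModel | None = None
        for idx, (action, v, varset) in enumerate(moves):
            try:
                candidate_model = fit_logistic(dataset, varset)
            except RankDeficientDesignError:
                continue
            if not candidate_model.converged:
                warnings.warn(f"skipping non-converged move {action} {v!r}")
                continue
            key = (candidate_model.aic, idx)
            if best is None or key < best:
                best = key
                best_fit = candidate_model
                best_move = (action, v, varset)
        if best is None or best[0] >= current.aic:
            break
        action, v, included = best_move
        current = best_fit
        records.append(StepRecord(len(records), action, v, current))

    return StepTrace(records=records)


def annotate_trace(trace: StepTrace, dataset: OccurrenceDataset) -> StepTrace:
    """Attach P-derived statistics (H, R, F, cor_P, cor_F) to every step.

    cor_P/cor_F compare each step with the final step and are reported as
    NaN wherever a side is constant (always the case at step 0); at the
    final step of a multi-step trace they are exactly 1.
    """
    n1, n0 = dataset.n1, dataset.n0
    P_final = trace.records[-1].model.fitted_probability
    F_final = favourability(P_final, n1, n0).values
    for rec in trace.records:
        P = rec.model.fitted_probability
        fmap = favourability(P, n1, n0, source_model=rec.model)
        rec.favourability = fmap
        rec.H = shannon_entropy_normalized(P, n1)
        rec.R = fuzzy_entropy(fmap)
        if rec.step_index == trace.final_step and trace.final_step > 0:
            rec.cor_P = rec.cor_F = 1.0
        else:
            rec.cor_P = _pearson(P, P_final)
            rec.cor_F = _pearson(fmap.values, F_final)
    rs = [rec.R for rec in trace.records]
    trace.min_R_step = int(np.argmin(rs))
    return trace


def select_min_entropy_model(trace: StepTrace) -> tuple[int, LogisticModel]:
    """Earliest step attaining the minimum fuzzy entropy, and its model."""
    if trace.min_R_step is None or any(r.R is None for r in trace.records):
        raise ValueError("trace must be annotated (run annotate_trace first)")
    return trace.min_R_step, trace.records[trace.min_R_step].model


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    # IRLS leaves last-bit jitter on constant fitted values; treat as constant
    if np.std(a) <= 1e-10 * (1.0 + abs(float(np.mean(a)))) or np.std(b) <= 1e-10 * (
        1.0 + abs(float(np.mean(b)))
    ):
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
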