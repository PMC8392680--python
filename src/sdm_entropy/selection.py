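"""Species-specific variable screening, stages 1 and 2.

Stage 1 controls predictor redundancy: within each predictor set (or
globally when no groups are given), while any retained pair of variables
has |Pearson r| above the threshold (default 0.8, strict), the most
correlated pair is taken and its member with the less significant
univariate relationship to the species (larger Rao score-test p-value) is
dropped.

Stage 2 controls the family-wise increase in type-I error with a false
discovery rate rule: order the V stage-1 survivors by increasing p-value
(rank I = 1..V) and retain positions 1..I* where I* is the largest rank
with p(I) < I * (q / V), q = 0.05 by default. This is the Benjamini-
Hochberg step-up procedure with a strict inequality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import OccurrenceDataset
from .glm import rao_score_test


@dataclass
class ScreenResult:
    """Univariate screen of one candidate variable."""

    variable: str
    group: str | None
    score_statistic: float
    p_value: float


@dataclass
class SelectionReport:
    """Outcome of the two screening stages for one species."""

    screen: list[ScreenResult]
    stage1_retained: list[str]
    stage1_dropped: list[tuple[str, str, float]]  # (dropped, kept_partner, r)
    V: int
    stage2_retained: list[str]
    q: float
    r_threshold: float = 0.8
    zero_variance: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """One row per candidate: screen values, fate at each stage."""
        drop_reason = {v: f"|r|={r:.3f} with {kept}" for v, kept, r in self.stage1_dropped}
        for v in self.zero_variance:
            drop_reason[v] = "zero variance"
        rows = []
        for s in self.screen:
            rows.append(
                {
                    "variable": s.variable,
                    "group": s.group if s.group is not None else "",
                    "score_statistic": s.score_statistic,
                    "p_value": s.p_value,
                    "stage1_kept": s.variable in self.stage1_retained,
                    "stage2_kept": s.variable in self.stage2_retained,
                    "drop_reason": drop_reason.get(s.variable, ""),
                }
            )
        return pd.DataFrame(rows)


def screen_variables(
    dataset: OccurrenceDataset, variables: list[str] | None = None
) -> list[ScreenResult]:
    """Rao score test of every candidate against the species distribution."""
    variables = list(variables or dataset.variable_names)
    out = []
    for v in variables:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = rao_score_test(dataset, v)
        out.append(ScreenResult(v, dataset.group_of(v), stat, p))
    return out


def correlation_filter(
    dataset: OccurrenceDataset,
    screen: list[ScreenResult],
    r_threshold: float = 0.8,
    within_groups: bool = True,
) -> SelectionReport:
    """Stage 1: iterative pairwise-correlation thinning.

    Deterministic order: the pair with the largest |r| is resolved first
    (ties by input column order); within a pair the larger-p member is
    dropped (p ties: the later column in input order).
    """
    p_of = {s.variable: s.p_value for s in screen}
    order = {s.variable: i for i, s in enumerate(screen)}
    candidates = [s.variable for s in screen]

    zero_variance = [
        v for v in candidates if dataset.predictors[v].std(ddof=0) == 0
    ]
    if zero_variance:
        warnings.warn(f"dropping zero-variance variable(s): {zero_variance}")

    if within_groups and dataset.variable_group is not None:
        groups: dict[str | None, list[str]] = {}
        for s in screen:
            groups.setdefault(s.group, []).append(s.variable)
        buckets = list(groups.values())
    else:
        buckets = [candidates]

    dropped: list[tuple[str, str, float]] = []
    retained_all: list[str] = []
    for bucket in buckets:
        retained = [v for v in bucket if v not in zero_variance]
        while len(retained) > 1:
            X = dataset.predictors[retained].to_numpy(dtype=float)
            r = np.corrcoef(X, rowvar=False)
            np.fill_diagonal(r, 0.0)
            absr = np.abs(r)
            if absr.max() <= r_threshold:
                break
            # largest |r| first; ties broken by input column order of the pair
            best = None
            for i in range(len(retained)):
                for j in range(i + 1, len(retained)):
                    key = (-absr[i, j], order[retained[i]], order[retained[j]])
                    if best is None or key < best[0]:
                        best = (key, i, j)
            _, i, j = best
            vi, vj = retained[i], retained[j]
            # drop the less significant one; p tie -> later input column
            if (p_of[vi], order[vi]) > (p_of[vj], order[vj]):
                drop, keep = vi, vj
            else:
                drop, keep = vj, vi
            dropped.append((drop, keep, float(r[i, j])))
            retained.remove(drop)
        retained_all.extend(retained)

    retained_all.sort(key=order.__getitem__)
    return SelectionReport(
        screen=screen,
        stage1_retained=retained_all,
        stage1_dropped=dropped,
        V=len(retained_all),
        stage2_retained=[],
        q=float("nan"),
        r_threshold=r_threshold,
        zero_variance=zero_variance,
    )


def fdr_filter(
    screen_survivors: list[ScreenResult], q: float = 0.05, V: int | None = None
) -> list[ScreenResult]:
    """Stage 2: retain ranks 1..I* where I* = max I with p(I) < I*(q/V)."""
    if V is None:
        V = len(screen_survivors)
    if V == 0 or not screen_survivors:
        return []
    ranked = sorted(enumerate(screen_survivors), key=lambda t: (t[1].p_value, t[0]))
    highest = 0
    for rank, (_, s) in enumerate(ranked, start=1):
        if s.p_value < rank * (q / V):
            highest = rank
    return [s for _, s in ranked[:highest]]


def select_variables(
    dataset: OccurrenceDataset,
    variables: list[str] | None = None,
    r_threshold: float = 0.8,
    q: float = 0.05,
    within_groups: bool = True,
) -> SelectionReport:
    """Run both screening stages and return the filled report.

    ``stage2_retained`` is ordered by increasing p-value, ready to hand to
    the stepwise search.
    """
    screen = screen_variables(dataset, variables)
    report = correlation_filter(dataset, screen, r_threshold, within_groups)
    survivors = [s for s in screen if s.variable in report.stage1_retained]
    stage2 = fdr_filter(survivors, q=q, V=report.V)
    report.stage2_retained = [s.variable for s in stage2]
    report.q = q
    return report
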