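"""Classification, discrimination and calibration metrics.

Classification uses the favourability threshold F = 0.5, which classifies
a cell as predicted presence exactly when its probability is at or above
the species prevalence. Discrimination is the rank-based AUC, invariant
under the monotone favourability transform. Calibration is assessed with
fixed-width probability bins of 0.1 via the Hosmer-Lemeshow chi-square
statistic and a calibration table of observed prevalence against mean
predicted probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .entropy import FavourabilityMap


@dataclass
class CalibrationBin:
    bin_low: float
    bin_high: float
    n_cells: int
    mean_predicted: float
    observed_prevalence: float


@dataclass
class EvaluationReport:
    """Full metric panel of one model on one dataset."""

    kappa: float
    sensitivity: float
    specificity: float
    ccr: float
    auc: float
    hl_statistic: float
    hl_df: int
    hl_p: float
    calibration_bins: list[CalibrationBin]
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def calibration_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(b) for b in self.calibration_bins])


def _check_both_classes(presence: np.ndarray) -> tuple[int, int]:
    n1 = int(np.sum(presence == 1))
    n0 = int(np.sum(presence == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("metrics undefined: presence vector has a single class")
    return n1, n0


def confusion_metrics(
    F, presence, threshold: float = 0.5
) -> tuple[float, float, float, float]:
    """(kappa, sensitivity, specificity, CCR) at F >= threshold.

    Ties at the threshold count as predicted presence.
    """
    values = F.values if isinstance(F, FavourabilityMap) else np.asarray(F, dtype=float)
    presence = np.asarray(presence)
    if len(values) != len(presence):
        raise ValueError("favourability and presence lengths differ")
    n1, n0 = _check_both_classes(presence)
    predicted = values >= threshold
    tp = int(np.sum(predicted & (presence == 1)))
    tn = int(np.sum(~predicted & (presence == 0)))
    fp = int(np.sum(predicted & (presence == 0)))
    fn = int(np.sum(~predicted & (presence == 1)))
    n = n1 + n0
    sensitivity = tp / n1
    specificity = tn / n0
    ccr = (tp + tn) / n
    # chance agreement from the marginals of the 2x2 table
    pe = ((tp + fp) * n1 + (tn + fn) * n0) / (n * n)
    kappa = (ccr - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    return kappa, sensitivity, specificity, ccr


def auc(score, presence) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    score = np.asarray(score, dtype=float)
    presence = np.asarray(presence)
    _check_both_classes(presence)
    return float(roc_auc_score(presence, score))


def hosmer_lemeshow(P, presence, n_bins: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow test over fixed-width probability bins.

    Bins [0, 0.1), ..., [0.9, 1.0]; empty bins are dropped; degrees of
    freedom are (number of nonempty bins) - 2.
    """
    P = np.asarray(P, dtype=float)
    presence = np.asarray(presence)
    if len(P) != len(presence):
        raise ValueError("probability and presence lengths differ")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(P, edges[1:-1]), 0, n_bins - 1)
    statistic = 0.0
    nonempty = 0
    for b in range(n_bins):
        mask = idx == b
        m = int(mask.sum())
        if m == 0:
            continue
        nonempty += 1
        o1 = float(presence[mask].sum())
        e1 = float(P[mask].sum())
        o0, e0 = m - o1, m - e1
        if e1 > 0:
            statistic += (o1 - e1) ** 2 / e1
        if e0 > 0:
            statistic += (o0 - e0) ** 2 / e0
    df = nonempty - 2
    if df <= 0:
        raise ValueError(f"only {nonempty} nonempty bins; need at least 3")
    return float(statistic), int(df), float(stats.chi2.sf(statistic, df=df))


def calibration_table(P, presence, n_bins: int = 10) -> list[CalibrationBin]:
    """Observed prevalence vs mean predicted probability per fixed bin."""
    P = np.asarray(P, dtype=float)
    presence = np.asarray(presence)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(P, edges[1:-1]), 0, n_bins - 1)
    bins = []
    for b in range(n_bins):
        mask = idx == b
        m = int(mask.sum())
        bins.append(
            CalibrationBin(
                bin_low=float(edges[b]),
                bin_high=float(edges[b + 1]),
                n_cells=m,
                mean_predicted=float(P[mask].mean()) if m else float("nan"),
                observed_prevalence=float(presence[mask].mean()) if m else float("nan"),
            )
        )
    return bins


def evaluate(P, F, presence, threshold: float = 0.5, n_bins: int = 10) -> EvaluationReport:
    """Assemble the full report for one model's P and F on a dataset."""
    kappa, sens, spec, ccr = confusion_metrics(F, presence, threshold)
    values = F.values if isinstance(F, FavourabilityMap) else np.asarray(F, dtype=float)
    hl_stat, hl_df, hl_p = hosmer_lemeshow(P, presence, n_bins)
    return EvaluationReport(
        kappa=kappa,
        sensitivity=sens,
        specificity=spec,
        ccr=ccr,
        auc=auc(values, presence),
        hl_statistic=hl_stat,
        hl_df=hl_df,
        hl_p=hl_p,
        calibration_bins=calibration_table(P, presence, n_bins),
        threshold=threshold,
    )
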