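"""Independent reference implementations used only to cross-check results.

These deliberately avoid the package's own code paths: the stepwise oracle
fits with statsmodels Logit (Newton on the raw scale), the AUC oracle
enumerates presence/absence pairs, and the FDR oracle delegates to
statsmodels' Benjamini-Hochberg step-up.
"""

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


def oracle_stepwise_moves(dataset, candidates: list[str]) -> list[tuple[str, str]]:
    """Explicitly score every legal single add/drop at every step."""
    y = dataset.presence.astype(float)

    def aic_of(varset):
        if varset:
            X = np.column_stack(
                [np.ones(dataset.n)]
                + [dataset.predictors[v].to_numpy(dtype=float) for v in varset]
            )
        else:
            X = np.ones((dataset.n, 1))
        res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=200)
        return 2 * (1 + len(varset)) - 2 * res.llf

    included: list[str] = []
    current = aic_of(included)
    moves: list[tuple[str, str]] = []
    while True:
        options = [("add", v, included + [v]) for v in candidates if v not in included]
        options += [("drop", v, [w for w in included if w != v]) for v in included]
        scored = [(aic_of(vs), i, a, v, vs) for i, (a, v, vs) in enumerate(options)]
        scored.sort()
        if not scored or scored[0][0] >= current:
            return moves
        current, _, action, var, included = scored[0]
        moves.append((action, var))


def oracle_auc_pairwise(score, presence) -> float:
    """Fraction of (presence, absence) pairs ranked correctly, ties = 1/2."""
    score = np.asarray(score, dtype=float)
    presence = np.asarray(presence)
    pos = score[presence == 1]
    neg = score[presence == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def oracle_bh_reject(p_values, q: float) -> np.ndarray:
    """Benjamini-Hochberg rejection mask from statsmodels."""
    reject, *_ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject
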