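"""Virtual species on synthetic environmental grids.

Generates occurrence datasets with a known logistic truth so every stage
of the workflow — univariate screening, correlation filtering, FDR,
stepwise selection, entropy tracing, calibration — can be exercised
against ground truth. The generator emulates the structure of a real
atlas-grid problem: a few informative environmental gradients, planted
highly correlated duplicates (|r| > 0.8, the redundancy the stage-1 filter
must remove), and pure-noise predictors (what the FDR stage must screen
out). Presence is Bernoulli with probability inverse-logit(alpha + beta'x)
per cell, independently across cells.

Predictors are continuous and standard-scale: informative gradients are
smooth functions of latent cell coordinates on a square lattice plus local
noise, mimicking spatially structured environmental surfaces without any
claim of realism; the workflow itself is aspatial given the predictor
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import OccurrenceDataset


@dataclass
class SyntheticSpec:
    """Recipe for one virtual species.

    ``true_coefficients`` names the informative predictors (nonzero beta on
    the standardized scale); ``n_noise`` independent standard-normal
    predictors carry zero coefficients; each ``correlated_pairs`` entry
    (source, target_r) plants a duplicate of an existing predictor with
    population correlation target_r in (0.8, 1).
    """

    n_cells: int = 5000
    true_intercept: float = -1.0
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: {"env1": 1.0, "env2": -0.8, "env3": 0.6}
    )
    n_noise: int = 5
    correlated_pairs: list[tuple[str, float]] = field(
        default_factory=lambda: [("env1", 0.9)]
    )
    predictor_groups: dict[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 100:
            raise ValueError("n_cells must be at least 100")
        if not any(b != 0 for b in self.true_coefficients.values()):
            raise ValueError("at least one nonzero true coefficient required")
        for src, r in self.correlated_pairs:
            if not 0.8 < r < 1.0:
                raise ValueError(f"target_r for {src!r} must be in (0.8, 1), got {r}")
            if src not in self.true_coefficients:
                raise ValueError(f"correlated-pair source {src!r} is not a predictor")


def _smooth_surface(rng: np.random.Generator, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Smooth pseudo-environmental gradient over lattice coordinates."""
    a, b = rng.normal(size=2)
    freq = rng.uniform(0.5, 2.0, size=2)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    surface = (
        a * x
        + b * y
        + np.sin(freq[0] * np.pi * x + phase[0])
        + np.cos(freq[1] * np.pi * y + phase[1])
    )
    surface = surface + 0.3 * rng.normal(size=len(x))
    return (surface - surface.mean()) / surface.std(ddof=0)


def generate_predictors(spec: SyntheticSpec) -> pd.DataFrame:
    """Deterministic (given seed) predictor matrix for the spec."""
    rng = np.random.default_rng(spec.seed)
    side = int(np.ceil(np.sqrt(spec.n_cells)))
    idx = np.arange(spec.n_cells)
    x = (idx % side) / side
    y = (idx // side) / side

    columns: dict[str, np.ndarray] = {}
    names = list(spec.true_coefficients)
    surfaces = np.column_stack([_smooth_surface(rng, x, y) for _ in names])
    # mutually orthogonalize: planted duplicates must be the only
    # high-correlation pairs, so the source gradients are decorrelated
    q, _ = np.linalg.qr(surfaces - surfaces.mean(axis=0))
    surfaces = q / q.std(axis=0, ddof=0)
    for j, name in enumerate(names):
        columns[name] = surfaces[:, j]
    for j in range(spec.n_noise):
        columns[f"noise{j + 1}"] = rng.normal(size=spec.n_cells)
    for src, r in spec.correlated_pairs:
        z = columns[src]
        dup = r * z + np.sqrt(1.0 - r * r) * rng.normal(size=spec.n_cells)
        columns[f"{src}_dup"] = (dup - dup.mean()) / dup.std(ddof=0)
    return pd.DataFrame(columns)


def coordinates(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    side = int(np.ceil(np.sqrt(spec.n_cells)))
    idx = np.arange(spec.n_cells)
    return (idx % side).astype(float), (idx // side).astype(float)


def generate_species(
    spec: SyntheticSpec, predictors: pd.DataFrame | None = None
) -> OccurrenceDataset:
    """Draw presences from the logistic truth over the predictor grid.

    The per-cell true probability is stored on the dataset
    (``true_probability``) for calibration tests. If the draw is degenerate
    (no presences or no absences) the intercept is nudged toward balance
    and the draw repeated, failing after 10 attempts.
    """
    if predictors is None:
        predictors = generate_predictors(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2**16 + 1]))
    eta = np.full(spec.n_cells, spec.true_intercept, dtype=float)
    for name, beta in spec.true_coefficients.items():
        eta += beta * predictors[name].to_numpy(dtype=float)

    intercept_shift = 0.0
    for _ in range(10):
        p_true = 1.0 / (1.0 + np.exp(-(eta + intercept_shift)))
        presence = rng.binomial(1, p_true)
        n1 = presence.sum()
        if 0 < n1 < spec.n_cells:
            x, y = coordinates(spec)
            return OccurrenceDataset(
                cell_id=np.array([f"c{i:06d}" for i in range(spec.n_cells)]),
                presence=presence,
                predictors=predictors,
                variable_group=spec.predictor_groups,
                x=x,
                y=y,
                true_probability=p_true,
            )
        intercept_shift += 1.0 if n1 == 0 else -1.0
    raise RuntimeError("could not draw a non-degenerate species in 10 attempts")


def default_groups(spec: SyntheticSpec) -> dict[str, str]:
    """Group map putting each duplicate with its source, noise apart."""
    groups = {name: "environment" for name in spec.true_coefficients}
    for src, _ in spec.correlated_pairs:
        groups[f"{src}_dup"] = "environment"
    for j in range(spec.n_noise):
        groups[f"noise{j + 1}"] = "noise"
    return groups


def reference_species(seed: int = 0, n_cells: int = 5000) -> OccurrenceDataset:
    """The standard test-bench species: 3 informative gradients with
    |beta| >= 0.5 on the standardized scale, 5 noise predictors, and one
    planted duplicate of the strongest gradient at r = 0.9."""
    spec = SyntheticSpec(n_cells=n_cells, seed=seed)
    spec.predictor_groups = default_groups(spec)
    return generate_species(spec)
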