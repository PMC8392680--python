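"""Presence/absence occurrence grids.

The modelling substrate is a table with one row per grid cell (e.g. a
10 km x 10 km UTM cell), a binary presence indicator and numeric
environmental predictors. Predictors may optionally carry a group label
(predictor set: climate, topography, lithology, human activity, ...) used
by the within-group correlation filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("cell_id", "x", "y")


class OccurrenceValidationError(ValueError):
    """Raised when an occurrence table violates the data contract."""


@dataclass
class OccurrenceDataset:
    """Cells x (presence, predictors) with optional coordinates and groups.

    Parameters
    ----------
    cell_id : array of str
        Unique identifier per cell.
    presence : array of int
        Binary 0/1 presence indicator; both classes must occur.
    predictors : pandas.DataFrame
        Numeric predictor matrix, one column per environmental variable.
    variable_group : dict, optional
        Mapping variable name -> predictor-set label.
    x, y : arrays, optional
        Cell coordinates, carried through I/O but never modelled.
    """

    cell_id: np.ndarray
    presence: np.ndarray
    predictors: pd.DataFrame
    variable_group: dict[str, str] | None = None
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    true_probability: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.cell_id = np.asarray(self.cell_id, dtype=str)
        self.presence = np.asarray(self.presence)
        if not isinstance(self.predictors, pd.DataFrame):
            self.predictors = pd.DataFrame(self.predictors)
        self.predictors = self.predictors.reset_index(drop=True)
        self.validate()
        self.presence = self.presence.astype(np.int64)

    # -- contract -----------------------------------------------------------

    def validate(self) -> None:
        n = len(self.cell_id)
        if self.predictors.shape[1] == 0:
            raise OccurrenceValidationError("dataset has no predictor columns")
        if len(np.unique(self.cell_id)) != n:
            raise OccurrenceValidationError("duplicated cell ids")
        if len(self.presence) != n or len(self.predictors) != n:
            raise OccurrenceValidationError(
                "cell_id, presence and predictors must have equal length"
            )
        pres = pd.Series(self.presence)
        if pres.isna().any():
            raise OccurrenceValidationError("missing values in presence")
        values = set(pd.unique(pres))
        if not values <= {0, 1}:
            raise OccurrenceValidationError(
                f"presence must be binary 0/1, found values {sorted(values - {0, 1})}"
            )
        if self.n1 == 0 or self.n0 == 0:
            raise OccurrenceValidationError(
                "need at least one presence and one absence"
            )
        if self.predictors.isna().any().any():
            bad = self.predictors.columns[self.predictors.isna().any()].tolist()
            raise OccurrenceValidationError(
                f"missing predictor values in columns {bad}; "
                "incomplete cells must be removed before loading"
            )
        if len(set(self.variable_names)) != len(self.variable_names):
            raise OccurrenceValidationError("variable names must be unique")
        for arr, name in ((self.x, "x"), (self.y, "y")):
            if arr is not None and len(arr) != n:
                raise OccurrenceValidationError(f"coordinate column {name} has wrong length")

    # -- convenience --------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.cell_id)

    @property
    def n1(self) -> int:
        return int(np.sum(self.presence == 1))

    @property
    def n0(self) -> int:
        return int(np.sum(self.presence == 0))

    @property
    def prevalence(self) -> float:
        return self.n1 / self.n

    @property
    def variable_names(self) -> list[str]:
        return list(self.predictors.columns)

    def group_of(self, variable: str) -> str | None:
        if self.variable_group is None:
            return None
        return self.variable_group.get(variable)


def read_occurrence_csv(
    path,
    presence_column: str,
    id_column: str = "cell_id",
    group_map: dict[str, str] | str | None = None,
    exclude_columns: tuple[str, ...] = (),
) -> OccurrenceDataset:
    """Load an occurrence grid from CSV.

    Every column that is not the id, the presence indicator, a coordinate
    (``x``/``y``) or explicitly excluded becomes a predictor, in file order.
    ``group_map`` is either a mapping variable -> group or the path of a
    two-column CSV (variable, group).
    """
    df = pd.read_csv(path)
    for col in (presence_column, id_column):
        if col not in df.columns:
            raise OccurrenceValidationError(f"required column {col!r} not in {path}")
    skip = {presence_column, id_column, "x", "y", *exclude_columns}
    predictor_cols = [c for c in df.columns if c not in skip]
    if group_map is not None and not isinstance(group_map, dict):
        group_map = read_group_map_csv(group_map)
    return OccurrenceDataset(
        cell_id=df[id_column].to_numpy(dtype=str),
        presence=df[presence_column].to_numpy(),
        predictors=df[predictor_cols].astype(float),
        variable_group=group_map,
        x=df["x"].to_numpy(dtype=float) if "x" in df.columns else None,
        y=df["y"].to_numpy(dtype=float) if "y" in df.columns else None,
    )


def write_occurrence_csv(dataset: OccurrenceDataset, path, presence_column: str = "presence") -> None:
    """Write an occurrence grid so that :func:`read_occurrence_csv` inverts it."""
    dataset.validate()
    out = {"cell_id": dataset.cell_id}
    if dataset.x is not None:
        out["x"] = dataset.x
    if dataset.y is not None:
        out["y"] = dataset.y
    out[presence_column] = dataset.presence
    frame = pd.DataFrame(out)
    frame = pd.concat([frame, dataset.predictors.reset_index(drop=True)], axis=1)
    frame.to_csv(path, index=False)


def read_group_map_csv(path) -> dict[str, str]:
    """Read a two-column (variable, group) CSV into a mapping."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise OccurrenceValidationError("group map needs columns (variable, group)")
    var_col, group_col = df.columns[:2]
    return dict(zip(df[var_col].astype(str), df[group_col].astype(str)))


def write_group_map_csv(group_map: dict[str, str], path) -> None:
    pd.DataFrame(
        {"variable": list(group_map), "group": [group_map[v] for v in group_map]}
    ).to_csv(path, index=False)
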