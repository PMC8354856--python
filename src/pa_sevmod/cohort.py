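"""Core tabular container for cohort data.

A cohort is a participants × variables matrix with per-variable metadata
(kind: clinical / biochemical / candidate; type: continuous / binary; units)
and an explicit missingness mask.  The mask is kept separate from the value
matrix so that generators can plant missingness without destroying the
underlying numbers and so that imputation can be checked cell-by-cell
against the original observations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VARIABLE_KINDS = ("clinical", "biochemical", "candidate")
VARIABLE_TYPES = ("continuous", "binary")


@dataclass
class CohortTable:
    """Participants × variables matrix with metadata and missingness mask.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix, index = participant ids, columns = variable names.
        Cells under a ``True`` mask entry are treated as missing regardless
        of the number stored there.
    meta : pandas.DataFrame
        Indexed by variable name with columns ``kind`` (clinical /
        biochemical / candidate), ``type`` (continuous / binary) and
        ``units`` (free text).
    mask : pandas.DataFrame, optional
        Boolean, same shape as ``values``; ``True`` marks a missing cell.
        Defaults to all-observed.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("variable names must be unique")
        if list(self.mask.index) != list(self.values.index) or list(
            self.mask.columns
        ) != list(self.values.columns):
            raise ValueError("mask must be aligned with values")
        missing_meta = set(self.values.columns) - set(self.meta.index)
        if missing_meta:
            raise ValueError(f"metadata missing for variables: {sorted(missing_meta)}")
        bad_kind = set(self.meta["kind"]) - set(VARIABLE_KINDS)
        bad_type = set(self.meta["type"]) - set(VARIABLE_TYPES)
        if bad_kind:
            raise ValueError(f"unknown variable kind(s): {sorted(bad_kind)}")
        if bad_type:
            raise ValueError(f"unknown variable type(s): {sorted(bad_type)}")
        observed = self.values.to_numpy(dtype=float)[~self.mask.to_numpy(bool)]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("observed cells must be finite")
        for name in self.binary_variables:
            col = self.values[name].to_numpy(dtype=float)
            obs = col[~self.mask[name].to_numpy(bool)]
            if obs.size and not np.isin(obs, (0.0, 1.0)).all():
                raise ValueError(f"binary variable {name!r} has non-0/1 values")

    # ------------------------------------------------------------------
    @property
    def participants(self) -> list:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_participants(self) -> int:
        return len(self.values.index)

    @property
    def continuous_variables(self) -> list[str]:
        m = self.meta.loc[self.variables]
        return [v for v in self.variables if m.at[v, "type"] == "continuous"]

    @property
    def binary_variables(self) -> list[str]:
        m = self.meta.loc[self.variables]
        return [v for v in self.variables if m.at[v, "type"] == "binary"]

    def variables_of_kind(self, kind: str) -> list[str]:
        if kind not in VARIABLE_KINDS:
            raise ValueError(f"unknown kind {kind!r}")
        m = self.meta.loc[self.variables]
        return [v for v in self.variables if m.at[v, "kind"] == kind]

    def missing_fraction(self) -> pd.Series:
        """Fraction of participants missing each variable."""
        return self.mask.mean(axis=0)

    def is_complete(self) -> bool:
        return not bool(self.mask.to_numpy().any())

    def copy(self) -> "CohortTable":
        return CohortTable(self.values.copy(), self.meta.copy(), self.mask.copy())

    def subset_variables(self, names: list[str]) -> "CohortTable":
        return CohortTable(
            self.values[names].copy(),
            self.meta.loc[names].copy(),
            self.mask[names].copy(),
        )

    def subset_participants(self, ids: list) -> "CohortTable":
        return CohortTable(
            self.values.loc[ids].copy(), self.meta.copy(), self.mask.loc[ids].copy()
        )

    # ------------------------------------------------------------------
    # CSV dialect: participants as rows, header row of variable names,
    # empty cell = missing; metadata sidecar as JSON.
    def to_csv(self, values_path: str | Path, meta_path: str | Path) -> None:
        out = self.values.astype(object).where(~self.mask, other="")
        out.to_csv(values_path, index_label="participant_id")
        records = [
            {
                "name": name,
                "kind": self.meta.at[name, "kind"],
                "type": self.meta.at[name, "type"],
                "units": self.meta.at[name, "units"],
            }
            for name in self.variables
        ]
        Path(meta_path).write_text(json.dumps(records, indent=1))

    @classmethod
    def from_csv(cls, values_path: str | Path, meta_path: str | Path) -> "CohortTable":
        values = pd.read_csv(values_path, index_col="participant_id")
        mask = values.isna()
        records = json.loads(Path(meta_path).read_text())
        meta = pd.DataFrame(records).set_index("name")
        return cls(values.fillna(0.0), meta, mask)
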