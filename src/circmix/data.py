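"""Reading, validating and writing long-format continuous-report trial tables.

A trial table has one row per trial: a participant identifier, the
response and target feature values, zero or more non-target values in
columns sharing a common name prefix, and optional set-size and condition
columns.  Angles may arrive in degrees (1-360), degrees_180 (1-180, for
axial stimuli) or radians; everything is converted to canonical radians
in (-pi, pi] at ingestion and the declared unit is kept as metadata.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import UNITS, convert_from_radians, convert_to_radians
from .models import TrialErrors

__all__ = ["ColumnMap", "TrialTable", "read_trial_table", "SchemaError", "ValidationError"]


class SchemaError(ValueError):
    """A mapped column is missing or the unit/column configuration is invalid."""


class ValidationError(ValueError):
    """The table parsed but violates a structural invariant (rows are 1-based)."""


@dataclass(frozen=True)
class ColumnMap:
    """Column-name configuration for a source table (defaults match the field's
    conventional long format)."""

    id_var: str = "id"
    response_var: str = "response"
    target_var: str = "target"
    non_target_prefix: str = "non_target"
    set_size_var: str | None = None
    condition_var: str | None = None

    def required(self):
        return [self.id_var, self.response_var, self.target_var]


def _coerce_numeric(df: pd.DataFrame, column: str) -> np.ndarray:
    raw = df[column]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.astype(str).str.strip().str.upper() != "NA")
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 1).tolist()
        raise ValidationError(
            f"non-numeric value(s) in column {column!r} at row(s) {rows}"
        )
    return out.to_numpy(dtype=float)


class TrialTable:
    """Validated trial table in canonical radians.

    Attributes
    ----------
    data : pandas.DataFrame
        Canonical columns ``id``, ``set_size``, optionally ``condition``,
        ``target``, ``response``, ``non_target_1`` ... ``non_target_k``
        (NaN where a trial has fewer non-targets).  All angles radians.
    unit : str
        The unit the source data were declared in (kept so linear error
        summaries can be reported on the native scale, and for writing).
    """

    def __init__(self, data: pd.DataFrame, unit: str = "radians", *, validate: bool = True):
        if unit not in UNITS:
            raise SchemaError(f"unknown angular unit {unit!r}; expected one of {UNITS}")
        self.data = data.reset_index(drop=True)
        self.unit = unit
        if validate:
            self._validate()

    # ------------------------------------------------------------------
    @property
    def non_target_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("non_target_")]

    @property
    def has_condition(self) -> bool:
        return "condition" in self.data.columns

    def __len__(self) -> int:
        return len(self.data)

    def _validate(self) -> None:
        for col in ("id", "target", "response", "set_size"):
            if col not in self.data.columns:
                raise SchemaError(f"canonical column {col!r} missing from table")
        nt = self.data[self.non_target_columns].to_numpy(dtype=float)
        n_nt = np.isfinite(nt).sum(axis=1) if nt.size else np.zeros(len(self.data))
        expected = self.data["set_size"].to_numpy(dtype=float) - 1
        bad = np.flatnonzero(n_nt != expected)
        if bad.size:
            raise ValidationError(
                "non-missing non-target count does not equal set_size - 1 at "
                f"row(s) {(bad + 1).tolist()[:20]}"
            )

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        column_map: ColumnMap | None = None,
        unit: str = "radians",
    ) -> "TrialTable":
        """Build a canonical table from a raw long-format frame."""
        cmap = column_map or ColumnMap()
        if unit not in UNITS:
            raise SchemaError(f"unknown angular unit {unit!r}; expected one of {UNITS}")
        for col in cmap.required():
            if col not in df.columns:
                raise SchemaError(f"mapped column {col!r} not found in table")
        for col in (cmap.set_size_var, cmap.condition_var):
            if col is not None and col not in df.columns:
                raise SchemaError(f"mapped column {col!r} not found in table")

        nt_cols = sorted(
            c
            for c in df.columns
            if c.startswith(cmap.non_target_prefix)
            and c not in cmap.required()
            and c not in (cmap.set_size_var, cmap.condition_var)
        )
        out = pd.DataFrame({"id": df[cmap.id_var].to_numpy()})
        with warnings.catch_warnings():
            warnings.simplefilter("once")
            out["target"] = convert_to_radians(_coerce_numeric(df, cmap.target_var), unit)
            out["response"] = convert_to_radians(
                _coerce_numeric(df, cmap.response_var), unit
            )
            for i, col in enumerate(nt_cols, start=1):
                out[f"non_target_{i}"] = convert_to_radians(
                    _coerce_numeric(df, col), unit
                )
        canon_nt = [c for c in out.columns if c.startswith("non_target_")]
        n_nt = (
            np.isfinite(out[canon_nt].to_numpy(dtype=float)).sum(axis=1)
            if canon_nt
            else np.zeros(len(out), dtype=int)
        )
        if cmap.set_size_var is not None:
            out["set_size"] = _coerce_numeric(df, cmap.set_size_var).astype(int)
        else:
            # no set-size column: infer 1 + number of non-missing non-targets
            out["set_size"] = n_nt.astype(int) + 1
        if cmap.condition_var is not None:
            out["condition"] = df[cmap.condition_var].to_numpy()
        order = ["id", "set_size"] + (["condition"] if cmap.condition_var else [])
        out = out[order + ["target", "response"] + canon_nt]
        return cls(out, unit=unit)

    # ------------------------------------------------------------------
    def to_csv(self, path, unit: str | None = None) -> None:
        """Write the table (angles converted back to ``unit``, default the
        table's declared unit); missing non-targets are written as NA."""
        unit = unit or self.unit
        out = self.data.copy()
        angle_cols = ["target", "response"] + self.non_target_columns
        for col in angle_cols:
            vals = out[col].to_numpy(dtype=float)
            conv = np.full_like(vals, np.nan)
            finite = np.isfinite(vals)
            conv[finite] = convert_from_radians(vals[finite], unit)
            out[col] = conv
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        out.to_csv(path, sep=sep, index=False, na_rep="NA")

    # ------------------------------------------------------------------
    def errors(self, rows=None) -> TrialErrors:
        """Wrapped response errors (to target and each non-target)."""
        df = self.data if rows is None else self.data.loc[rows]
        resp = df["response"].to_numpy(dtype=float)
        targ = df["target"].to_numpy(dtype=float)
        nt_cols = self.non_target_columns
        if nt_cols:
            nt = df[nt_cols].to_numpy(dtype=float)
            nte = resp[:, None] - nt
        else:
            nte = np.empty((len(df), 0))
        return TrialErrors(resp - targ, nte, set_size=df["set_size"].to_numpy(dtype=int))

    def group_cells(self, group_by=()):
        """Iterate ``(keys_dict, sub_table_index)`` over id x group cells."""
        cols = ["id"] + [c for c in group_by if c]
        for c in cols:
            if c not in self.data.columns:
                raise SchemaError(f"grouping column {c!r} not present in table")
        for keys, sub in self.data.groupby(cols, sort=True, observed=True):
            if not isinstance(keys, tuple):
                keys = (keys,)
            yield dict(zip(cols, keys)), sub.index


def read_trial_table(
    path,
    column_map: ColumnMap | None = None,
    unit: str = "degrees",
) -> TrialTable:
    """Read a CSV/TSV trial table (delimiter chosen by file extension)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=True)
    return TrialTable.from_dataframe(df, column_map=column_map, unit=unit)
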