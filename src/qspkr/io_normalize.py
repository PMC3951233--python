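"""Reading and min-max scaling of descriptor and pharmacokinetic tables.

A QSPkR study starts from two tables: a compound x descriptor matrix
(typically hundreds to thousands of numeric molecular descriptors) and a
single pharmacokinetic (PK) parameter per compound, e.g. systemic clearance
in mL/min/kg, volume of distribution in L/kg or plasma protein binding in %.
Both are mapped column-wise onto [0, 1] by min-max scaling before any
selection or modelling; the observed per-column minima and maxima are kept
so predictions can be reported back in original units and so the normalised
root-mean-square error (RMSE divided by the observed range) is computable.

By default the scaling is fitted on the full compound set, matching the
classical QSPkR workflow in which normalisation precedes the train/test
split; fitting on a training subset only is available via ``fit_indices``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: cell contents treated as missing when reading CSV tables
MISSING_TOKENS = ("", "NA")


class TableError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass
class RawTable:
    """A compound x column numeric table in original units.

    ``values`` is float64 with NaN marking missing entries; columns are
    descriptors or a single PK parameter.
    """

    compound_ids: list[str]
    column_names: list[str]
    values: np.ndarray
    units: list[str | None] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TableError("values must be a 2-D matrix")
        n_rows, n_cols = self.values.shape
        if n_rows != len(self.compound_ids):
            raise TableError(
                f"{n_rows} rows but {len(self.compound_ids)} compound ids"
            )
        if n_cols != len(self.column_names):
            raise TableError(
                f"{n_cols} columns but {len(self.column_names)} column names"
            )
        dup = _duplicates(self.compound_ids)
        if dup:
            raise TableError(f"duplicate compound ids: {sorted(dup)}")
        dup = _duplicates(self.column_names)
        if dup:
            raise TableError(f"duplicate column names: {sorted(dup)}")

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class ScaleInfo:
    """Observed per-column minima and maxima used for min-max scaling."""

    minimum: np.ndarray
    maximum: np.ndarray
    names: list[str] | None = None
    units: list[str | None] | None = None

    def __post_init__(self) -> None:
        self.minimum = np.atleast_1d(np.asarray(self.minimum, dtype=float))
        self.maximum = np.atleast_1d(np.asarray(self.maximum, dtype=float))
        if self.minimum.shape != self.maximum.shape:
            raise TableError("minimum and maximum must have equal shape")
        if np.any(self.maximum < self.minimum):
            raise TableError("maximum below minimum")

    @property
    def range(self) -> np.ndarray:
        return self.maximum - self.minimum

    @property
    def constant(self) -> np.ndarray:
        """True for columns with zero observed range."""
        return self.maximum == self.minimum


@dataclass
class QSPkRDataset:
    """Normalised descriptor matrix plus normalised PK vector.

    ``X[i, k]`` is compound *i*'s *k*-th descriptor mapped to [0, 1];
    ``dp[i]`` is the normalised PK value. Constant descriptor columns are
    mapped to zero and flagged so downstream selection can exclude them.
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    X: np.ndarray
    dp: np.ndarray
    descriptor_scale: ScaleInfo
    pk_scale: ScaleInfo
    constant_descriptors: np.ndarray
    pk_name: str = "pk"
    pk_unit: str | None = None
    strict: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.dp = np.asarray(self.dp, dtype=float).ravel()
        self.constant_descriptors = np.asarray(self.constant_descriptors, dtype=bool)
        if self.X.shape[0] != self.dp.shape[0]:
            raise TableError("descriptor matrix and PK vector disagree on row count")
        if self.X.shape[1] != len(self.descriptor_names):
            raise TableError("descriptor matrix and names disagree on column count")
        if self.strict:
            tol = 1e-12
            if self.X.min(initial=0.0) < -tol or self.X.max(initial=0.0) > 1 + tol:
                raise TableError("normalised descriptors fall outside [0, 1]")
            if self.dp.min(initial=0.0) < -tol or self.dp.max(initial=0.0) > 1 + tol:
                raise TableError("normalised PK values fall outside [0, 1]")

    @property
    def n_compounds(self) -> int:
        return self.X.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.X.shape[1]

    def selectable_descriptors(self) -> np.ndarray:
        """Indices of non-constant descriptors (eligible for selection)."""
        return np.flatnonzero(~self.constant_descriptors)


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


def _parse_cell(cell: str, missing_tokens: tuple[str, ...], row: str, col: str) -> float:
    if cell.strip() in missing_tokens:
        return np.nan
    try:
        return float(cell)
    except ValueError:
        raise TableError(
            f"non-numeric cell {cell!r} at row {row!r}, column {col!r}"
        ) from None


def read_descriptor_table(
    path, missing_tokens: tuple[str, ...] = MISSING_TOKENS
) -> RawTable:
    """Read a CSV descriptor table (first column = compound id, header row).

    Cells matching one of ``missing_tokens`` become NaN; any other
    non-numeric cell is a hard error naming the offending row and column.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TableError(f"empty file: {path}") from None
        names = [h.strip() for h in header[1:]]
        ids: list[str] = []
        rows: list[list[float]] = []
        for rec in reader:
            if not rec:
                continue
            cid = rec[0].strip()
            if len(rec) - 1 != len(names):
                raise TableError(
                    f"row {cid!r} has {len(rec) - 1} cells, expected {len(names)}"
                )
            ids.append(cid)
            rows.append(
                [
                    _parse_cell(c, missing_tokens, cid, names[j])
                    for j, c in enumerate(rec[1:])
                ]
            )
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(names)))
    return RawTable(compound_ids=ids, column_names=names, values=values)


def read_pk_table(path, missing_tokens: tuple[str, ...] = MISSING_TOKENS) -> RawTable:
    """Read a CSV PK table: compound id, value and an optional unit column."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise TableError("PK table needs at least an id and a value column")
    ids = [str(v).strip() for v in df.iloc[:, 0]]
    name = str(df.columns[1]).strip()
    vals = np.asarray(
        [_parse_cell(str(c), missing_tokens, ids[i], name) for i, c in enumerate(df.iloc[:, 1])]
    )
    unit: str | None = None
    if df.shape[1] >= 3:
        units = {str(u).strip() for u in df.iloc[:, 2] if str(u).strip()}
        if len(units) > 1:
            raise TableError(f"mixed units in PK table: {sorted(units)}")
        unit = next(iter(units), None)
    return RawTable(
        compound_ids=ids,
        column_names=[name],
        values=vals.reshape(-1, 1),
        units=[unit],
    )


def handle_missing(raw: RawTable, policy: str = "drop_columns") -> tuple[RawTable, dict]:
    """Resolve missing entries before normalisation.

    ``drop_columns`` removes every column containing a missing value;
    ``mean_impute`` replaces missing entries with the column mean. Either
    way the action is logged and reported — nothing is handled silently.
    """
    if policy not in ("drop_columns", "mean_impute"):
        raise ValueError(f"unknown missing-value policy {policy!r}")
    mask = raw.missing_mask
    report: dict = {"policy": policy, "n_missing": int(mask.sum())}
    if not mask.any():
        report["affected_columns"] = []
        return raw, report
    affected = np.flatnonzero(mask.any(axis=0))
    report["affected_columns"] = [raw.column_names[j] for j in affected]
    if policy == "drop_columns":
        keep = np.flatnonzero(~mask.any(axis=0))
        logger.info(
            "dropping %d column(s) with missing values: %s",
            len(affected), report["affected_columns"],
        )
        out = RawTable(
            compound_ids=list(raw.compound_ids),
            column_names=[raw.column_names[j] for j in keep],
            values=raw.values[:, keep],
            units=[raw.units[j] for j in keep] if raw.units else None,
        )
    elif policy == "mean_impute":
        vals = raw.values.copy()
        for j in affected:
            col = vals[:, j]
            m = np.nanmean(col)
            if np.isnan(m):
                raise TableError(
                    f"column {raw.column_names[j]!r} is entirely missing"
                )
            col[np.isnan(col)] = m
        logger.info(
            "mean-imputed %d missing value(s) in columns %s",
            report["n_missing"], report["affected_columns"],
        )
        out = RawTable(
            compound_ids=list(raw.compound_ids),
            column_names=list(raw.column_names),
            values=vals,
            units=list(raw.units) if raw.units else None,
        )
    return out, report


def minmax_normalize(
    raw: RawTable,
    pk: RawTable,
    fit_indices: np.ndarray | None = None,
) -> QSPkRDataset:
    """Min-max scale descriptors and the PK column onto [0, 1].

    Each column ``y`` maps to ``(y - min) / (max - min)`` with the min/max
    observed over ``fit_indices`` (all compounds by default). Constant
    descriptor columns map to zero and are flagged; a constant PK column is
    an error. With a restricted ``fit_indices`` the remaining rows may fall
    outside [0, 1], so the strict range check is relaxed.
    """
    if raw.compound_ids != pk.compound_ids:
        raise TableError("descriptor and PK tables disagree on compound ids/order")
    if pk.n_columns != 1:
        raise TableError("PK table must have exactly one value column")
    if raw.missing_mask.any() or pk.missing_mask.any():
        raise TableError(
            "missing values present; resolve them first with handle_missing()"
        )

    fit = np.arange(raw.n_compounds) if fit_indices is None else np.asarray(fit_indices)
    strict = fit_indices is None

    dmin = raw.values[fit].min(axis=0)
    dmax = raw.values[fit].max(axis=0)
    const = dmax == dmin
    rng = np.where(const, 1.0, dmax - dmin)
    X = (raw.values - dmin) / rng
    X[:, const] = 0.0

    pmin = float(pk.values[fit].min())
    pmax = float(pk.values[fit].max())
    if pmax == pmin:
        raise TableError("PK column is constant; nothing to model")
    dp = (pk.values[:, 0] - pmin) / (pmax - pmin)

    if const.any():
        logger.info(
            "%d constant descriptor column(s) mapped to 0 and flagged", int(const.sum())
        )
    return QSPkRDataset(
        compound_ids=list(raw.compound_ids),
        descriptor_names=list(raw.column_names),
        X=X,
        dp=dp,
        descriptor_scale=ScaleInfo(dmin, dmax, names=list(raw.column_names)),
        pk_scale=ScaleInfo(
            np.array([pmin]), np.array([pmax]),
            names=list(pk.column_names),
            units=list(pk.units) if pk.units else None,
        ),
        constant_descriptors=const,
        pk_name=pk.column_names[0],
        pk_unit=(pk.units[0] if pk.units else None),
        strict=strict,
    )


def denormalize(values: np.ndarray, scale: ScaleInfo) -> np.ndarray:
    """Map [0, 1]-scale values back to original units: ``v * (max - min) + min``.

    Exact inverse of min-max scaling on the fitted range; a constant scale
    has no inverse and raises.
    """
    if np.any(scale.constant):
        raise ValueError("cannot denormalize with a constant (zero-range) scale")
    return np.asarray(values, dtype=float) * scale.range + scale.minimum


def apply_scale(values: np.ndarray, scale: ScaleInfo) -> np.ndarray:
    """Forward min-max map using an existing scale (for held-out data)."""
    if np.any(scale.constant):
        raise ValueError("cannot normalize with a constant (zero-range) scale")
    return (np.asarray(values, dtype=float) - scale.minimum) / scale.range


def write_table_csv(raw: RawTable, path, id_header: str = "compound_id") -> None:
    """Write a RawTable back to the CSV dialect the readers accept.

    Values are written with ``repr`` so a read-back is lossless. A
    single-column table with a unit gains a third ``unit`` column, matching
    the (id, value, unit) PK layout.
    """
    unit = raw.units[0] if (raw.units and raw.n_columns == 1) else None
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        header = [id_header] + list(raw.column_names)
        if unit is not None:
            header.append("unit")
        w.writerow(header)
        for i, cid in enumerate(raw.compound_ids):
            row = [cid] + [repr(float(v)) for v in raw.values[i]]
            if unit is not None:
                row.append(unit)
            w.writerow(row)
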