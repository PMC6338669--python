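"""Per-cell tables and the standard flow-cytometry preprocessing steps.

The package's universal container is the *cell table*: a tidy
:class:`pandas.DataFrame` with one row per measured cell and columns

``expression``
    total STAT3 fluorescence (arbitrary units, > 0),
``response``
    STAT3 pY705 fluorescence (arbitrary units, >= 0),
``dose``
    cytokine concentration in ng/ml (0 = unstimulated),
``time``
    minutes post-stimulation,
``replicate``
    experiment identifier,
``line``
    cell-line label (e.g. ``"MEF"``, ``"MEF_STAT3high"``).

On top of it this module implements the three population operations the
analysis needs: per-experiment normalization of mean fluorescence to 100 %,
tail gating of extreme expressers, and symmetric truncation of expression
heterogeneity to a chosen residual variability.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import fcs as _fcs
from .exceptions import (
    DegenerateDataError,
    EmptyDataError,
    FormatError,
    ParameterError,
    SchemaError,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "ChannelDataset",
    "GateResult",
    "gate_extreme_expressers",
    "load_cells",
    "normalize_experiment",
    "truncate_heterogeneity",
    "validate_cells",
    "write_cells",
]

REQUIRED_COLUMNS = ("expression", "response", "dose", "time", "replicate", "line")

#: metadata defaults applied when a source carries no condition annotation
_DEFAULT_METADATA = {"dose": 0.0, "time": 15, "replicate": "r1", "line": "MEF"}


def validate_cells(cells: pd.DataFrame, require_positive_expression: bool = False) -> pd.DataFrame:
    """Check cell-table invariants; returns the (unmodified) frame.

    Raises :class:`SchemaError` on missing columns, :class:`EmptyDataError`
    on an empty table, and :class:`DegenerateDataError` on non-finite
    measurement values.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table is missing required columns: {missing}")
    if len(cells) == 0:
        raise EmptyDataError("cell table has no rows")
    vals = cells[["expression", "response"]].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise DegenerateDataError("expression/response contain non-finite values")
    if require_positive_expression and (vals[:, 0] <= 0).any():
        raise DegenerateDataError("expression must be strictly positive")
    return cells


def load_cells(
    path: str | os.PathLike,
    format: str | None = None,
    channel_map: Mapping[str, str] | None = None,
    metadata: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Load a cell table from CSV or FCS.

    Parameters
    ----------
    path : path
        Input file. Format is inferred from the extension when ``format``
        is None.
    format : {"csv", "fcs"}, optional
    channel_map : mapping, optional
        Maps instrument channel/column names to the roles ``expression``
        and ``response``, e.g. ``{"FL2-A": "expression", "FL1-A": "response"}``.
    metadata : mapping, optional
        Condition metadata (dose, time, replicate, line). For FCS input,
        values from the JSON sidecar are used first and ``metadata``
        overrides them; for CSV, existing columns win.

    Returns
    -------
    pandas.DataFrame
        Validated cell table. ``df.attrs["n_dropped"]`` records how many
        events were discarded for non-finite measurement values.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {"csv": "csv", ".csv": "csv", ".fcs": "fcs"}.get(ext)
        if format is None:
            raise FormatError(f"cannot infer format from extension {ext!r}")
    format = format.lower()

    if format == "csv":
        df = pd.read_csv(path)
        if channel_map:
            absent = [c for c in channel_map if c not in df.columns]
            if absent:
                raise SchemaError(f"mapped channels not present in CSV: {absent}")
            df = df.rename(columns=dict(channel_map))
        meta = {**_DEFAULT_METADATA, **(metadata or {})}
        for col in ("dose", "time", "replicate", "line"):
            if col not in df.columns:
                df[col] = meta[col]
    elif format == "fcs":
        data, names, _kw = _fcs.read_fcs(path)
        if not channel_map:
            raise SchemaError("FCS input requires a channel_map to name roles")
        absent = [c for c in channel_map if c not in names]
        if absent:
            raise SchemaError(f"mapped channels not present in FCS file: {absent}")
        cols = {role: data[:, names.index(ch)] for ch, role in channel_map.items()}
        df = pd.DataFrame(cols)
        meta = {**_DEFAULT_METADATA, **_fcs.read_sidecar(path), **(metadata or {})}
        for col in ("dose", "time", "replicate", "line"):
            df[col] = meta[col]
    else:
        raise FormatError(f"unknown format {format!r}")

    for role in ("expression", "response"):
        if role not in df.columns:
            raise SchemaError(f"no column mapped to role {role!r}")

    finite = np.isfinite(df["expression"].to_numpy(dtype=float)) & np.isfinite(
        df["response"].to_numpy(dtype=float)
    )
    n_dropped = int((~finite).sum())
    df = df.loc[finite].reset_index(drop=True)
    if len(df) == 0:
        raise EmptyDataError(f"{path}: zero events survive the finite-value filter")
    df.attrs["n_dropped"] = n_dropped
    return validate_cells(df)


def write_cells(cells: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a cell table as tidy CSV (UTF-8, '.' decimal).

    Normalization factors, when present in ``attrs``, go to a JSON sidecar
    ``<path>.json`` so a round-trip preserves provenance.
    """
    validate_cells(cells)
    cells.to_csv(path, index=False)
    factors = cells.attrs.get("normalization_factors")
    if factors:
        with open(str(path) + ".json", "w", encoding="utf-8") as fh:
            json.dump(factors, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# normalization


def normalize_experiment(
    cells: pd.DataFrame, by: Sequence[str] = ("replicate", "time", "line")
) -> pd.DataFrame:
    """Normalize maximal mean fluorescence per experiment to 100 %.

    Within each experiment (one ``replicate`` at one ``time`` for one
    ``line``), the mean response is computed per dose group and every
    response value is rescaled by ``100 / max_over_doses(mean response)``;
    expression is rescaled the same way, independently. Raw values are
    retained in ``response_raw`` / ``expression_raw`` and a ``normalized``
    flag column is set. The operation is idempotent.
    """
    validate_cells(cells)
    by = [k for k in by if k in cells.columns]
    out = cells.copy()
    if "response_raw" not in out.columns:
        out["response_raw"] = out["response"]
        out["expression_raw"] = out["expression"]
    factors: dict[str, dict[str, float]] = {}
    for key, idx in out.groupby(list(by)).groups.items():
        sub = out.loc[idx]
        entry = {}
        for role in ("response", "expression"):
            dose_means = sub.groupby("dose")[role].mean()
            top = float(dose_means.max())
            if top <= 0:
                raise DegenerateDataError(
                    f"degenerate normalization: all-zero {role} in group {key}"
                )
            factor = 100.0 / top
            out.loc[idx, role] = sub[role] * factor
            entry[role] = factor
        factors[str(key)] = entry
    out["normalized"] = True
    out.attrs["normalization_factors"] = factors
    return out


# ---------------------------------------------------------------------------
# gating and truncation


@dataclass
class GateResult:
    """Low/high extreme-expresser subpopulations from tail gating."""

    low_subset: pd.DataFrame
    high_subset: pd.DataFrame
    fraction: float
    threshold_low: float = field(default=np.nan)
    threshold_high: float = field(default=np.nan)


def gate_extreme_expressers(cells: pd.DataFrame, fraction: float = 0.10) -> GateResult:
    """Gate the lowest- and highest-expressing tails of the population.

    Selects the ``fraction`` of cells with the lowest and the highest
    expression (stable order on ties). ``fraction`` must lie in (0, 0.5];
    at least 10 cells are required.
    """
    if not 0 < fraction <= 0.5:
        raise ParameterError(f"fraction must be in (0, 0.5], got {fraction}")
    validate_cells(cells)
    n = len(cells)
    if n < 10:
        raise ParameterError(f"tail gating needs >= 10 cells, got {n}")
    k = int(round(fraction * n))
    k = max(k, 1)
    order = np.argsort(cells["expression"].to_numpy(), kind="stable")
    low = cells.iloc[order[:k]].assign(gate="low")
    high = cells.iloc[order[n - k :]].assign(gate="high")
    return GateResult(
        low_subset=low.reset_index(drop=True),
        high_subset=high.reset_index(drop=True),
        fraction=fraction,
        threshold_low=float(low["expression"].max()),
        threshold_high=float(high["expression"].min()),
    )


def truncate_heterogeneity(
    cells: pd.DataFrame, residual: float, method: str = "quantile"
) -> pd.DataFrame:
    """Reduce expression heterogeneity to a residual fraction of the cells.

    ``method="quantile"`` (default) trims the ``(1-residual)/2`` extreme
    tails of the expression distribution symmetrically, keeping the central
    ``residual`` fraction of cells by rank (linear-interpolation quantile
    convention; ties kept on the inclusive side via stable ordering).
    ``method="mean_window"`` keeps cells whose expression lies within
    ``mean * (1 ± residual/2)``.

    Returns the retained subset; ``attrs["n_retained"]`` records its size.
    """
    if not 0 < residual <= 1:
        raise ParameterError(f"residual must be in (0, 1], got {residual}")
    validate_cells(cells)
    n = len(cells)
    expr = cells["expression"].to_numpy(dtype=float)
    if method == "quantile":
        if residual == 1.0:
            out = cells.copy()
        else:
            cut = int(round(n * (1.0 - residual) / 2.0))
            order = np.argsort(expr, kind="stable")
            keep = np.sort(order[cut : n - cut])
            out = cells.iloc[keep].reset_index(drop=True)
    elif method == "mean_window":
        mu = expr.mean()
        lo, hi = mu * (1.0 - residual / 2.0), mu * (1.0 + residual / 2.0)
        out = cells.loc[(expr >= lo) & (expr <= hi)].reset_index(drop=True)
    else:
        raise ParameterError(f"unknown truncation method {method!r}")
    if len(out) == 0:
        raise EmptyDataError("no cells retained after heterogeneity truncation")
    out.attrs["n_retained"] = len(out)
    out.attrs["residual"] = residual
    return out


# ---------------------------------------------------------------------------
# channel view


@dataclass
class ChannelDataset:
    """A cell table viewed as samples from a dose -> response channel.

    One stratum (fixed time, line and optionally replicate) whose distinct
    doses form the channel input alphabet; the per-dose subsets are the
    empirical conditional response samples p(R | S = dose).
    """

    cells: pd.DataFrame
    input_levels: np.ndarray
    counts: np.ndarray

    @classmethod
    def from_cells(
        cls,
        cells: pd.DataFrame,
        time: float | None = None,
        line: str | None = None,
        replicate: object | None = None,
        include_zero_dose: bool = True,
    ) -> "ChannelDataset":
        validate_cells(cells)
        sub = cells
        if time is not None:
            sub = sub[sub["time"] == time]
        if line is not None:
            sub = sub[sub["line"] == line]
        if replicate is not None:
            sub = sub[sub["replicate"] == replicate]
        if not include_zero_dose:
            sub = sub[sub["dose"] > 0]
        if len(sub) == 0:
            raise EmptyDataError("stratum selects no cells")
        levels = np.sort(sub["dose"].unique())
        counts = np.array([(sub["dose"] == d).sum() for d in levels])
        return cls(cells=sub.reset_index(drop=True), input_levels=levels, counts=counts)

    def require_channel(self) -> None:
        if len(self.input_levels) < 2:
            raise ParameterError(
                "capacity computation needs >= 2 input levels, "
                f"got {len(self.input_levels)}"
            )

    def samples(self, features: Iterable[str] = ("response",)) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, y): feature matrix and integer input-level labels."""
        feats = list(features)
        X = self.cells[feats].to_numpy(dtype=float)
        lookup = {d: i for i, d in enumerate(self.input_levels)}
        y = self.cells["dose"].map(lookup).to_numpy(dtype=int)
        return X, y
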