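"""Site-by-time data container, ingestion and preprocessing.

The fundamental object is a matrix ``X`` of one landscape variable measured
in ``n_i`` patches (rows) at ``n_k`` time points (columns), together with a
boolean mask of missing cells.  All downstream statistics (variance
decomposition, CV indices, signatures) are computed from this container.

Axis convention, used everywhere in the package: **rows are patches, columns
are time points**.  Times need not be equally spaced; only their order is
used.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteTimeMatrix",
    "MissingDataPolicy",
    "DEFAULT_COLUMNS",
    "load_long_table",
    "load_wide_table",
    "to_long_frame",
    "apply_missing_policy",
    "rescale_min_zero",
    "occurrence_frequency",
]

#: default column names of the long-format CSV dialect
DEFAULT_COLUMNS = ("variable", "site", "time", "value")


class MissingDataPolicy(str, Enum):
    """How masked (blank) cells are handled before analysis.

    ``zero_fill``
        Replace blanks with zero.  Appropriate when a blank records a true
        absence (e.g. a desiccated pool holds no living adult invertebrates);
        absence zeros are data, not missing values.
    ``skip``
        Leave blanks masked; downstream statistics drop masked cells
        (pairwise for covariances, listwise per aggregate series), and the
        exact decomposition identities are then only guaranteed on complete
        matrices.
    ``patch_mean``
        Replace each blank with the mean of that patch's observed values
        (interpolation by site).
    """

    zero_fill = "zero_fill"
    skip = "skip"
    patch_mean = "patch_mean"


@dataclass
class SiteTimeMatrix:
    """One variable's values over patches (rows) x time points (columns).

    Parameters
    ----------
    variable_id : str
        Label of the measured variable.
    values : ndarray, shape (n_i, n_k)
        Measured values; entries under ``missing`` are ignored.
    missing : ndarray of bool, shape (n_i, n_k), optional
        True marks a missing cell.  Defaults to all-observed.
    sites, times : sequence, optional
        Row / column labels.  Defaults to integer indices.
    meta : dict
        Free-form annotations (units, variable class, generator metadata...).
    """

    variable_id: str
    values: np.ndarray
    missing: np.ndarray | None = None
    sites: Sequence | None = None
    times: Sequence | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(
                f"values must be a 2-D patch x time matrix, got ndim={self.values.ndim}"
            )
        if self.missing is None:
            self.missing = np.zeros(self.values.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.values.shape:
            raise ValueError(
                f"missing mask shape {self.missing.shape} does not match "
                f"values shape {self.values.shape}"
            )
        n_i, n_k = self.values.shape
        if self.sites is None:
            self.sites = list(range(n_i))
        if self.times is None:
            self.times = list(range(n_k))
        if len(self.sites) != n_i or len(self.times) != n_k:
            raise ValueError("sites/times labels do not match matrix shape")
        # unmasked NaNs are implicit blanks: absorb them into the mask
        nan_cells = np.isnan(self.values)
        if nan_cells.any():
            self.missing = self.missing | nan_cells

    @property
    def n_patches(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def is_complete(self) -> bool:
        return not self.missing.any()

    def observed(self) -> np.ma.MaskedArray:
        """Values as a masked array (mask = missing cells)."""
        return np.ma.MaskedArray(self.values, mask=self.missing)

    def copy(self) -> "SiteTimeMatrix":
        return replace(
            self,
            values=self.values.copy(),
            missing=self.missing.copy(),
            sites=list(self.sites),
            times=list(self.times),
            meta=dict(self.meta),
        )


def _coerce_value(raw, row_index: int) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    text = str(raw).strip()
    if text == "":
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise ValueError(
            f"non-numeric value {raw!r} in row {row_index}"
        ) from None


def load_long_table(
    source,
    columns: Sequence[str] = DEFAULT_COLUMNS,
) -> dict[str, SiteTimeMatrix]:
    """Read a long-format table into one :class:`SiteTimeMatrix` per variable.

    Parameters
    ----------
    source : path, file-like or DataFrame
        CSV with a header (UTF-8) or an already-parsed DataFrame.  Blank
        ``value`` fields become missing cells.
    columns : sequence of 4 str
        Names of the variable / site / time / value columns.

    Returns
    -------
    dict mapping variable id -> SiteTimeMatrix, with patches ordered by site
    label and times in ascending time order.

    Raises
    ------
    ValueError
        On a duplicate (variable, site, time) triple (named in the message)
        or a non-numeric value (reported with its row index).
    """
    var_col, site_col, time_col, val_col = columns
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, dtype={val_col: str}, skipinitialspace=True)
    for col in (var_col, site_col, time_col, val_col):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} not found in input")
    if len(df) == 0:
        raise ValueError("input table contains no data rows")

    dup = df.duplicated(subset=[var_col, site_col, time_col], keep=False)
    if dup.any():
        first = df.loc[dup, [var_col, site_col, time_col]].iloc[0]
        raise ValueError(
            "duplicate (variable, site, time) triple: "
            f"({first[var_col]!r}, {first[site_col]!r}, {first[time_col]!r})"
        )

    values = np.array(
        [_coerce_value(v, i) for i, v in zip(df.index, df[val_col])]
    )
    df = df.assign(__value=values)

    out: dict[str, SiteTimeMatrix] = {}
    for vid, grp in df.groupby(var_col, sort=True):
        wide = grp.pivot(index=site_col, columns=time_col, values="__value")
        wide = wide.sort_index(axis=0).sort_index(axis=1)
        vals = wide.to_numpy(dtype=float)
        out[str(vid)] = SiteTimeMatrix(
            variable_id=str(vid),
            values=np.nan_to_num(vals, nan=0.0),
            missing=np.isnan(vals),
            sites=list(wide.index),
            times=list(wide.columns),
        )
    return out


def load_wide_table(source, variable_id: str | None = None) -> SiteTimeMatrix:
    """Read a wide-format table: first column = site, remaining columns = times.

    One file per variable; ``variable_id`` defaults to the file stem.
    """
    if isinstance(source, (str, Path)):
        if variable_id is None:
            variable_id = Path(source).stem
        df = pd.read_csv(source)
    else:
        df = pd.read_csv(source) if not isinstance(source, pd.DataFrame) else source
    if variable_id is None:
        variable_id = "variable"
    df = df.set_index(df.columns[0]).sort_index()
    vals = df.to_numpy(dtype=float)
    return SiteTimeMatrix(
        variable_id=str(variable_id),
        values=np.nan_to_num(vals, nan=0.0),
        missing=np.isnan(vals),
        sites=list(df.index),
        times=list(df.columns),
    )


def to_long_frame(
    matrices: Mapping[str, SiteTimeMatrix] | Iterable[SiteTimeMatrix],
    columns: Sequence[str] = DEFAULT_COLUMNS,
) -> pd.DataFrame:
    """Serialize matrices back to long rows (masked cells become blank values).

    Round-trips exactly with :func:`load_long_table`.
    """
    var_col, site_col, time_col, val_col = columns
    if isinstance(matrices, Mapping):
        matrices = matrices.values()
    rows = []
    for m in matrices:
        for i, site in enumerate(m.sites):
            for k, t in enumerate(m.times):
                rows.append(
                    {
                        var_col: m.variable_id,
                        site_col: site,
                        time_col: t,
                        val_col: np.nan if m.missing[i, k] else m.values[i, k],
                    }
                )
    return pd.DataFrame(rows, columns=list(columns))


def apply_missing_policy(
    m: SiteTimeMatrix, policy: MissingDataPolicy | str
) -> SiteTimeMatrix:
    """Resolve masked cells according to ``policy`` (returns a new matrix)."""
    policy = MissingDataPolicy(policy)
    out = m.copy()
    out.meta["missing_policy"] = policy.value
    if policy is MissingDataPolicy.skip or m.is_complete:
        return out
    if policy is MissingDataPolicy.zero_fill:
        out.values[out.missing] = 0.0
        out.missing[:] = False
        return out
    # patch_mean
    for i in range(out.n_patches):
        row_mask = out.missing[i]
        if row_mask.all():
            raise ValueError(
                f"patch {out.sites[i]!r} has no observed values; "
                "patch_mean policy is undefined for it"
            )
        if row_mask.any():
            out.values[i, row_mask] = out.values[i, ~row_mask].mean()
    out.missing[:] = False
    return out


def rescale_min_zero(m: SiteTimeMatrix) -> SiteTimeMatrix:
    """Shift all observed values so the global minimum is exactly zero.

    Used to correct spatial and temporal CVs of variables that can take
    negative values (e.g. net primary production).  Idempotent.
    """
    if m.missing.all():
        raise ValueError("all cells are masked; nothing to rescale")
    out = m.copy()
    lo = out.values[~out.missing].min()
    out.values[~out.missing] -= lo
    out.meta["rescaled_min_zero"] = True
    return out


def occurrence_frequency(m: SiteTimeMatrix) -> float:
    """Fraction of time points at which at least one patch has a value > 0.

    Masked cells are ignored; a fully-masked column counts as absence.
    """
    present = ((m.values > 0) & ~m.missing).any(axis=0)
    return float(present.mean())
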