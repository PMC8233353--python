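"""Population-level descriptive aggregation and the shift-then-log transform.

Cells pool within mouse (the experimental unit); group summaries are mean ±
SEM over mice. No inferential statistics live here — the tidy outputs are
meant to feed standard mixed-model packages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError


def pct_locked(results: pd.DataFrame,
               mouse_col: str = "mouse_id",
               locked_col: str = "is_locked",
               group_cols: tuple[str, ...] = ()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stimulus-locked percentages pooled per mouse, summarized over mice.

    Parameters
    ----------
    results : per-cell DataFrame with one row per cell (any number of FOVs);
        must contain ``mouse_col`` and boolean ``locked_col``; optional
        ``group_cols`` (e.g. group, timepoint) stratify the summary.

    Returns
    -------
    per_mouse : DataFrame with n_cells, n_locked, pct_locked per mouse
        (and group columns).
    summary : DataFrame with mean_pct, sem_pct, n_mice per group stratum
        (single row when no group columns). SEM is over mice.
    """
    if results.empty:
        raise InputError("empty results table")
    for col in (mouse_col, locked_col):
        if col not in results.columns:
            raise InputError(f"missing column {col!r}")
    keys = list(group_cols) + [mouse_col]
    per_mouse = (results.groupby(keys, sort=True)[locked_col]
                 .agg(n_cells="size", n_locked="sum").reset_index())
    per_mouse["pct_locked"] = 100.0 * per_mouse["n_locked"] / per_mouse["n_cells"]

    def _summ(g: pd.DataFrame) -> pd.Series:
        vals = g["pct_locked"].to_numpy(dtype=float)
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        return pd.Series({"mean_pct": vals.mean(), "sem_pct": sem,
                          "n_mice": vals.size})

    if group_cols:
        summary = (per_mouse.groupby(list(group_cols), sort=True)
                   .apply(_summ, include_groups=False).reset_index())
    else:
        summary = _summ(per_mouse).to_frame().T
    return per_mouse, summary


def shift_log(values) -> tuple[np.ndarray, float]:
    """Natural log after shifting so the dataset minimum becomes 0.1.

    The shift (0.1 - min) applies whenever ``min(values) <= 0`` — i.e. whenever
    any value is incompatible with the logarithm; otherwise values are logged
    as-is with shift 0. The transform is strictly order-preserving.

    Returns
    -------
    (log_values, shift)
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InputError("empty dataset")
    if not np.all(np.isfinite(values)):
        raise InputError("non-finite values")
    vmin = values.min()
    shift = 0.1 - vmin if vmin <= 0 else 0.0
    shifted = values + shift
    assert np.all(shifted > 0), "shift rule guarantees positive arguments"
    return np.log(shifted), float(shift)


def normalize_to_baseline(series: pd.DataFrame,
                          mouse_col: str = "mouse_id",
                          timepoint_col: str = "timepoint",
                          value_col: str = "value",
                          baseline_label: str = "baseline") -> pd.DataFrame:
    """Divide each mouse's timepoint values by its own baseline value.

    Mice with a zero (or missing) baseline get NaN ratios and a flag rather
    than a silent division.
    """
    for col in (mouse_col, timepoint_col, value_col):
        if col not in series.columns:
            raise InputError(f"missing column {col!r}")
    out = series.copy()
    base = (series[series[timepoint_col] == baseline_label]
            .set_index(mouse_col)[value_col])
    if base.index.duplicated().any():
        raise InputError("multiple baseline rows for a mouse")
    b = out[mouse_col].map(base)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio"] = out[value_col] / b
    bad = b.isna() | (b == 0)
    out.loc[bad, "ratio"] = np.nan
    out["flag"] = np.where(bad, "no_baseline", "")
    return out
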