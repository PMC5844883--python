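"""Endpoint arithmetic and statistics for plate-based and clonogenic assays.

Implements the study's downstream endpoint calculations: control
normalization of plate readouts (optionally per cell via a Hoechst-type
surrogate), NAD(P)H/NAD(P)+ redox ratios, plating-efficiency-based
clonogenic surviving fractions, senescence (beta-gal) percentages, and the
two-tailed pooled Student's t-test used throughout for condition contrasts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "ttest_two_tailed",
    "normalize_to_control",
    "redox_ratio",
    "surviving_fraction",
    "senescence_fraction",
    "benjamini_hochberg",
    "DEFAULT_ALPHA",
]

#: Nominal significance cutoff used for flagging throughout the pipeline.
DEFAULT_ALPHA = 0.05


def ttest_two_tailed(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sample two-tailed Student's t-test.

    Pooled-variance by default; Welch's unequal-variance form behind the
    ``welch`` flag.  Degenerate inputs (zero variance in both groups) follow
    an explicit convention: equal means give ``(0.0, 1.0)``, unequal means
    give ``(inf-signed t, 0.0)``.

    Parameters
    ----------
    a, b : array-like
        Replicate measurements per group; each needs at least 2 values.

    Returns
    -------
    (t, p) : tuple of float
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("insufficient replicates: need >= 2 values per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("degenerate t-test: zero variance with unequal means",
                      RuntimeWarning, stacklevel=2)
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = _st.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def _summary_vs_control(values_by_cond: dict[str, np.ndarray], control: str,
                        alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Tidy per-condition table: mean, sd, n, relative-to-control, t, p, flag."""
    ctrl = values_by_cond[control]
    ctrl_mean = float(np.mean(ctrl))
    if ctrl_mean == 0.0:
        raise ValueError("control mean is zero; cannot normalize")
    rows = []
    for cond, vals in values_by_cond.items():
        vals = np.asarray(vals, dtype=float)
        if cond == control:
            t, p = 0.0, 1.0
        elif vals.size >= 2 and ctrl.size >= 2:
            t, p = ttest_two_tailed(vals, ctrl)
        else:
            t, p = np.nan, np.nan
        rows.append({
            "condition": cond,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
            "n": int(vals.size),
            "relative": float(vals.mean() / ctrl_mean) if cond != control else 1.0,
            "t": t,
            "p": p,
            "significant": bool(p < alpha) if np.isfinite(p) else False,
        })
    return pd.DataFrame(rows)


def normalize_to_control(plate: pd.DataFrame, control: str,
                         per_cell: bool = False,
                         alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Normalize plate readouts to the control-condition mean.

    Parameters
    ----------
    plate : DataFrame
        Columns ``condition``, ``readout`` and, when ``per_cell`` is set,
        ``cell_surrogate`` (a cell-number proxy such as Hoechst DNA signal).
    control : str
        Label of the control condition (relative value fixed at 1).
    per_cell : bool
        Divide each well's readout by its cell-number surrogate first.

    Returns
    -------
    DataFrame with per-condition mean, sd, n, relative value, and the
    two-tailed pooled t-test against control.
    """
    required = {"condition", "readout"}
    if not required.issubset(plate.columns):
        raise ValueError(f"plate table needs columns {sorted(required)}")
    if control not in set(plate["condition"]):
        raise ValueError(f"control condition {control!r} not present")
    values = plate["readout"].to_numpy(dtype=float)
    if per_cell:
        if "cell_surrogate" not in plate.columns:
            raise ValueError("per_cell normalization requires a 'cell_surrogate' column")
        surr = plate["cell_surrogate"].to_numpy(dtype=float)
        if np.any(surr <= 0):
            raise ValueError("cell_surrogate values must be > 0")
        values = values / surr
    by_cond = {c: values[plate["condition"].to_numpy() == c]
               for c in pd.unique(plate["condition"])}
    return _summary_vs_control(by_cond, control, alpha=alpha)


def redox_ratio(reduced, oxidized) -> np.ndarray:
    """Element-wise reduced/oxidized ratio for paired replicates.

    Models NADH/NAD+ or NADPH/NADP+ measurements where each replicate yields
    a paired (reduced, oxidized) readout.
    """
    reduced = np.asarray(reduced, dtype=float)
    oxidized = np.asarray(oxidized, dtype=float)
    if reduced.shape != oxidized.shape:
        raise ValueError("reduced and oxidized must have matching shapes")
    if np.any(oxidized == 0):
        raise ValueError("oxidized readout of zero: ratio undefined")
    return reduced / oxidized


def surviving_fraction(records: pd.DataFrame, control: str,
                       alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Clonogenic surviving fraction from plating efficiency of the control.

    PE = control colonies / control cells plated; SF(condition) =
    (colonies/plated) / PE, so SF(control) == 1 exactly.  ``records`` has
    columns ``condition``, ``cells_plated``, ``colonies`` (one row per dish;
    replicates allowed).
    """
    required = {"condition", "cells_plated", "colonies"}
    if not required.issubset(records.columns):
        raise ValueError(f"clonogenic table needs columns {sorted(required)}")
    if np.any(records["colonies"].to_numpy() > records["cells_plated"].to_numpy()):
        raise ValueError("colonies cannot exceed cells plated")
    ctrl = records[records["condition"] == control]
    if ctrl.empty:
        raise ValueError(f"control condition {control!r} not present")
    pe_per_dish = ctrl["colonies"].to_numpy(float) / ctrl["cells_plated"].to_numpy(float)
    pe = float(pe_per_dish.mean())
    if pe == 0.0:
        raise ValueError("control plating efficiency is zero")
    sf_all = records["colonies"].to_numpy(float) / records["cells_plated"].to_numpy(float) / pe
    by_cond = {c: sf_all[records["condition"].to_numpy() == c]
               for c in pd.unique(records["condition"])}
    out = _summary_vs_control({k: np.asarray(v) for k, v in by_cond.items()},
                              control, alpha=alpha)
    # SF is already expressed relative to control PE; report the mean SF itself
    out = out.rename(columns={"mean": "surviving_fraction"})
    out.loc[out["condition"] == control, "surviving_fraction"] = float(
        np.mean(by_cond[control]))
    return out.drop(columns=["relative"])


def senescence_fraction(fields: pd.DataFrame,
                        alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Percent senescent (beta-gal positive) cells per high-power field.

    ``fields`` has columns ``condition``, ``positive``, ``total`` (one row per
    field).  Fields with ``total == 0`` are excluded with a warning; if every
    field of a condition is excluded an error is raised.
    """
    required = {"condition", "positive", "total"}
    if not required.issubset(fields.columns):
        raise ValueError(f"field table needs columns {sorted(required)}")
    usable = fields[fields["total"] > 0].copy()
    n_dropped = len(fields) - len(usable)
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} field(s) with zero cells",
                      RuntimeWarning, stacklevel=2)
    if usable.empty or set(usable["condition"]) != set(fields["condition"]):
        missing = set(fields["condition"]) - set(usable["condition"])
        if missing:
            raise ValueError(f"all fields excluded for condition(s) {sorted(missing)}")
    usable["percent"] = 100.0 * usable["positive"] / usable["total"]
    rows = []
    for cond, grp in usable.groupby("condition", sort=False):
        pct = grp["percent"].to_numpy(float)
        rows.append({
            "condition": cond,
            "percent_senescent": float(pct.mean()),
            "sd": float(pct.std(ddof=1)) if pct.size > 1 else np.nan,
            "n_fields": int(pct.size),
        })
    return pd.DataFrame(rows)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted q-values. Extension: the study itself applies no
    multiple-testing correction, so nothing in the pipeline calls this by
    default."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.clip(q, 0, 1)
    return out
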