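"""ICP-MS platinum quantitation against an iridium internal standard.

Pt counts at the monitored masses (194, 195, 196) are ratioed to Ir counts
(mass 193) per run; standards at known ppb are fitted by weighted least
squares with weights 1/x^2 (x = nominal concentration), the convention that
equalizes *relative* error across a serial-dilution calibration spanning
more than two decades; samples are back-calculated from the fitted line.
DNA-bound fraction is the bound:total concentration ratio in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "PT_MASSES",
    "IR_MASS",
    "CALIBRATION_LEVELS_PPB",
    "PtCalibrator",
    "PtResult",
    "signal_ratio",
    "fit_calibration",
    "back_calculate",
    "dna_bound_fraction",
]

#: Monitored platinum isotopes.
PT_MASSES = (194, 195, 196)
#: Iridium internal-standard mass.
IR_MASS = 193
#: Serial-dilution calibration levels, in parts per billion.
CALIBRATION_LEVELS_PPB = (0.125, 1.25, 12.5, 25.0, 50.0)


def signal_ratio(pt_counts, ir_counts: float, policy: str = "sum") -> float:
    """Pt/Ir signal ratio for one run.

    Parameters
    ----------
    pt_counts : mapping or sequence
        Counts per monitored Pt mass (194, 195, 196), or a mapping from mass
        to counts.
    ir_counts : float
        Counts at the Ir internal-standard mass; must be positive.
    policy : {"sum", "194", "195", "196"}
        How to aggregate Pt masses; the default sums all three.
    """
    if ir_counts <= 0:
        raise ValueError("internal standard missing: Ir counts must be > 0")
    if isinstance(pt_counts, dict):
        counts = {int(k): float(v) for k, v in pt_counts.items()}
    else:
        counts = dict(zip(PT_MASSES, np.asarray(pt_counts, dtype=float)))
    if any(v < 0 for v in counts.values()):
        raise ValueError("Pt counts must be non-negative")
    if policy == "sum":
        pt = sum(counts[m] for m in PT_MASSES)
    else:
        mass = int(policy)
        if mass not in counts:
            raise ValueError(f"mass {mass} not monitored")
        pt = counts[mass]
    return pt / float(ir_counts)


class PtCalibrator(RegressorMixin, BaseEstimator):
    """Weighted linear calibration of Pt/Ir ratio against concentration.

    Parameters
    ----------
    weighting : {"1/x2", "1/x", "none"}, default "1/x2"
        Regression weights as a function of the nominal standard
        concentration x.
    fit_intercept : bool, default True
        Fit the intercept; set False to force the line through zero.

    Attributes
    ----------
    slope_ : float            ratio per ppb
    intercept_ : float        ratio
    levels_ : ndarray         nominal ppb of the standards used
    weights_ : ndarray        regression weights per standard
    residuals_ : ndarray      weighted residuals
    r2_ : float               weighted coefficient of determination
    """

    def __init__(self, weighting: str = "1/x2", fit_intercept: bool = True):
        self.weighting = weighting
        self.fit_intercept = fit_intercept

    def _weights(self, x: np.ndarray) -> np.ndarray:
        if self.weighting == "1/x2":
            return 1.0 / x**2
        if self.weighting == "1/x":
            return 1.0 / x
        if self.weighting == "none":
            return np.ones_like(x)
        raise ValueError(f"unknown weighting {self.weighting!r}")

    def fit(self, X, y):
        """Fit ratio = slope * ppb + intercept by weighted least squares."""
        x = np.ravel(np.asarray(X, dtype=float))
        r = np.ravel(np.asarray(y, dtype=float))
        if x.size != r.size:
            raise ValueError("concentrations and ratios must align")
        if np.any(x <= 0):
            raise ValueError("standard concentrations must be strictly positive")
        if np.unique(x).size < 2:
            raise ValueError("rank deficient: need >= 2 distinct standard levels")
        w = self._weights(x)
        sw = np.sqrt(w)
        if self.fit_intercept:
            design = np.column_stack([x, np.ones_like(x)])
        else:
            design = x[:, None]
        coef, *_ = np.linalg.lstsq(design * sw[:, None], r * sw, rcond=None)
        self.slope_ = float(coef[0])
        self.intercept_ = float(coef[1]) if self.fit_intercept else 0.0
        self.levels_ = x.copy()
        self.weights_ = w
        fitted = self.slope_ * x + self.intercept_
        self.residuals_ = sw * (r - fitted)
        wmean = np.average(r, weights=w)
        ss_res = float(np.sum(w * (r - fitted) ** 2))
        ss_tot = float(np.sum(w * (r - wmean) ** 2))
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted Pt/Ir ratio at the given concentrations."""
        x = np.asarray(X, dtype=float)
        return self.slope_ * x + self.intercept_

    def back_calculate(self, ratio) -> pd.DataFrame:
        """Invert the calibration line for sample ratios.

        Negative estimates (blanks scattering below the intercept) clip to
        0 ppb and are flagged ``clipped``; estimates below the lowest
        standard are flagged ``below_lowest_standard``.
        """
        if self.slope_ == 0:
            raise ValueError("zero calibration slope: cannot back-calculate")
        r = np.ravel(np.asarray(ratio, dtype=float))
        conc = (r - self.intercept_) / self.slope_
        clipped = conc < 0
        conc = np.where(clipped, 0.0, conc)
        return pd.DataFrame({
            "ratio": r,
            "concentration_ppb": conc,
            "below_lowest_standard": conc < self.levels_.min(),
            "clipped": clipped,
        })


@dataclass
class PtResult:
    """Back-calculated platinum concentration for one sample."""

    sample: str
    concentration_ppb: float
    below_lowest_standard: bool = False
    clipped: bool = False


def fit_calibration(standards, weighting: str = "1/x2",
                    fit_intercept: bool = True) -> PtCalibrator:
    """Fit a calibration from (nominal_ppb, ratio) pairs."""
    arr = np.asarray(list(standards), dtype=float)
    return PtCalibrator(weighting=weighting, fit_intercept=fit_intercept).fit(
        arr[:, 0], arr[:, 1])


def back_calculate(fit: PtCalibrator, ratio: float,
                   sample: str = "") -> PtResult:
    """Back-calculate one sample ratio through a fitted calibration."""
    row = fit.back_calculate([ratio]).iloc[0]
    return PtResult(sample=sample,
                    concentration_ppb=float(row["concentration_ppb"]),
                    below_lowest_standard=bool(row["below_lowest_standard"]),
                    clipped=bool(row["clipped"]))


def dna_bound_fraction(total: PtResult | float, dna_bound: PtResult | float,
                       normalizer: tuple[float, float] | None = None) -> float:
    """Percent of cellular platinum bound to DNA.

    Parameters
    ----------
    total, dna_bound : PtResult or float
        Whole-cell and DNA-extract concentrations (ppb).
    normalizer : (total_scale, bound_scale), optional
        Per-sample scales (e.g. cell-number equivalents) dividing each
        concentration before the ratio is taken.
    """
    t = total.concentration_ppb if isinstance(total, PtResult) else float(total)
    b = dna_bound.concentration_ppb if isinstance(dna_bound, PtResult) else float(dna_bound)
    if normalizer is not None:
        ts, bs = normalizer
        if ts <= 0 or bs <= 0:
            raise ValueError("normalizer scales must be positive")
        t, b = t / ts, b / bs
    if t <= 0:
        raise ValueError("total platinum is zero: fraction undefined")
    return 100.0 * b / t


def process_icpms_run(rows: pd.DataFrame, policy: str = "sum",
                      weighting: str = "1/x2",
                      fit_intercept: bool = True) -> tuple[PtCalibrator, pd.DataFrame]:
    """Calibrate from the standards in a run table and quantify its samples.

    ``rows`` columns: ``sample``, ``role`` ("standard"/"sample"),
    ``pt194``, ``pt195``, ``pt196``, ``ir193``, ``nominal_ppb`` (standards).
    """
    required = {"sample", "role", "pt194", "pt195", "pt196", "ir193"}
    if not required.issubset(rows.columns):
        raise ValueError(f"run table needs columns {sorted(required)}")
    ratios = np.array([
        signal_ratio({194: r.pt194, 195: r.pt195, 196: r.pt196}, r.ir193,
                     policy=policy)
        for r in rows.itertuples()
    ])
    std = rows["role"].to_numpy() == "standard"
    if std.sum() < 2:
        raise ValueError("need >= 2 standards in the run")
    cal = PtCalibrator(weighting=weighting, fit_intercept=fit_intercept).fit(
        rows.loc[std, "nominal_ppb"].to_numpy(float), ratios[std])
    out = cal.back_calculate(ratios[~std])
    out.insert(0, "sample", rows.loc[~std, "sample"].to_numpy())
    return cal, out
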