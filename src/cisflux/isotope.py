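"""Mass-isotopomer distribution (MID) mathematics for 13C tracing.

A metabolite with n carbons observed by unit-resolution SRM yields
intensities at mass shifts m+0 ... m+n.  With a U-13C6 glucose tracer the
shifts of interest are tracer-derived, but naturally occurring 13C
(~1.07% per carbon) smears each true isotopologue upward in mass.  The
forward model is linear: observed = C @ true, where column k of the
correction matrix C is the binomial mass-shift distribution of the n-k
non-tracer carbons, offset by k.  Correction inverts this by non-negative
least squares, which cannot produce the negative fractions plain matrix
inversion yields at low signal.

Two readings of "fractional incorporation" are exposed as distinct
quantities: the labeled-molecule fraction 100*(1 - m0) and the per-carbon
mean atom enrichment 100 * sum(k * f_k) / n.  The labeled-molecule
fraction is the default reported quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .assays import DEFAULT_ALPHA, ttest_two_tailed

__all__ = [
    "NATURAL_P13",
    "MID",
    "NaturalAbundanceCorrector",
    "natural_abundance_matrix",
    "correct_mid",
    "labeled_fraction",
    "mean_enrichment",
    "contrast_conditions",
    "tca_mid_shift",
]

#: Natural abundance of 13C per carbon atom.
NATURAL_P13 = 0.0107

_SUM_TOL = 1e-9


@dataclass
class MID:
    """Normalized mass-isotopomer distribution for one metabolite."""

    metabolite: str
    n_carbons: int
    fractions: np.ndarray
    condition: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.size != self.n_carbons + 1:
            raise ValueError("fractions must have length n_carbons + 1")
        if np.any(self.fractions < -_SUM_TOL):
            raise ValueError("MID fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-6:
            raise ValueError("MID fractions must sum to 1")

    @property
    def labeled_fraction(self) -> float:
        """Percent of molecules carrying any tracer label: 100*(1 - m0)."""
        return 100.0 * (1.0 - float(self.fractions[0]))

    @property
    def mean_enrichment(self) -> float:
        """Percent per-carbon atom enrichment: 100 * sum(k f_k) / n."""
        k = np.arange(self.n_carbons + 1)
        return 100.0 * float(k @ self.fractions) / self.n_carbons


def natural_abundance_matrix(n_carbons: int, p13: float) -> np.ndarray:
    """(n+1)x(n+1) matrix mapping true tracer MIDs to observed mass shifts.

    Column k: a molecule with k tracer 13C carbons has n-k carbons each
    carrying a natural heavy isotope with probability ``p13``, so its
    observed shift is k + Binomial(n-k, p13).  Columns sum to 1; with
    p13 = 0 the matrix is the identity.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    if not 0.0 <= p13 < 1.0:
        raise ValueError("p13 must satisfy 0 <= p13 < 1")
    n = n_carbons
    mat = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        extra = np.arange(n - k + 1)
        mat[k + extra, k] = _st.binom.pmf(extra, n - k, p13)
    return mat


class NaturalAbundanceCorrector(TransformerMixin, BaseEstimator):
    """Natural-abundance correction as a transformer over spectra rows.

    Parameters
    ----------
    p13 : float, default 0.0107
        Per-carbon probability of a natural heavy carbon.  Only carbon is
        corrected: at unit SRM resolution other elements' isotopes are
        unresolved.
    tracer_purity : float, default 1.0
        Isotopic purity of the tracer; accepted for completeness and applied
        as a second binomial convolution on the tracer carbons when < 1.

    Attributes
    ----------
    n_carbons_ : int
        Carbon count inferred from the training data width.
    matrix_ : ndarray of shape (n+1, n+1)
        Forward convolution matrix.
    """

    def __init__(self, p13: float = NATURAL_P13, tracer_purity: float = 1.0):
        self.p13 = p13
        self.tracer_purity = tracer_purity

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n_carbons_ = X.shape[1] - 1
        mat = natural_abundance_matrix(self.n_carbons_, self.p13)
        if self.tracer_purity < 1.0:
            mat = mat @ _purity_matrix(self.n_carbons_, self.tracer_purity)
        self.matrix_ = mat
        return self

    def transform(self, X) -> np.ndarray:
        """Correct rows of raw intensities; returns normalized fractions."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.matrix_.shape[0]:
            raise ValueError("spectrum length does not match correction matrix")
        out = np.empty_like(X)
        for i, row in enumerate(X):
            out[i] = _solve_one(row, self.matrix_)
        return out

    def inverse_transform(self, fractions) -> np.ndarray:
        """Forward-convolve true MIDs into observed-space fractions."""
        fractions = np.atleast_2d(np.asarray(fractions, dtype=float))
        return fractions @ self.matrix_.T


def _purity_matrix(n_carbons: int, purity: float) -> np.ndarray:
    # k nominal tracer carbons are truly heavy with probability `purity`
    n = n_carbons
    mat = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        j = np.arange(k + 1)
        mat[j, k] = _st.binom.pmf(j, k, purity)
    return mat


def _solve_one(intensities: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    if np.any(intensities < 0):
        raise ValueError("intensities must be non-negative")
    total = intensities.sum()
    if total <= 0:
        raise ValueError("no signal: all-zero spectrum")
    x, _ = nnls(matrix, intensities / total)
    s = x.sum()
    if s <= 0:  # pragma: no cover - NNLS of a positive vector is positive
        raise ValueError("correction produced an all-zero solution")
    return x / s


def correct_mid(intensities, n_carbons: int, metabolite: str = "",
                p13: float = NATURAL_P13, condition: str | None = None,
                replicate: int | None = None) -> MID:
    """Correct one observed spectrum for natural abundance and return a MID."""
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size != n_carbons + 1:
        raise ValueError("intensities must have length n_carbons + 1")
    mat = natural_abundance_matrix(n_carbons, p13)
    fractions = _solve_one(intensities, mat)
    return MID(metabolite=metabolite, n_carbons=n_carbons, fractions=fractions,
               condition=condition, replicate=replicate)


def labeled_fraction(mid: MID) -> float:
    """Percent labeled molecules, 100*(1 - m0). Default reported quantity."""
    return mid.labeled_fraction


def mean_enrichment(mid: MID) -> float:
    """Percent per-carbon atom enrichment, 100 * sum(k f_k) / n_carbons."""
    return mid.mean_enrichment


def _mid_frame(mids: list[MID]) -> pd.DataFrame:
    rows = []
    for m in mids:
        row = {"metabolite": m.metabolite, "n_carbons": m.n_carbons,
               "condition": m.condition, "replicate": m.replicate}
        for k, f in enumerate(m.fractions):
            row[f"m{k}"] = f
        rows.append(row)
    return pd.DataFrame(rows)


def contrast_conditions(mids: list[MID] | pd.DataFrame, condition_a: str,
                        condition_b: str,
                        alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-isotopologue condition contrast with pooled two-tailed t-tests.

    For every metabolite and every isotopologue index (plus the derived
    labeled fraction, index ``"labeled"``), compares replicate fractions
    between the two conditions.  Requires >= 2 replicates per side.

    Returns a tidy table: metabolite, isotopologue, mean_a, mean_b,
    difference (a - b), sem_a, sem_b, t, p, significant.
    """
    df = mids if isinstance(mids, pd.DataFrame) else _mid_frame(mids)
    for cond in (condition_a, condition_b):
        if cond not in set(df["condition"]):
            raise ValueError(f"condition {cond!r} not present")
    rows = []
    for met, grp in df.groupby("metabolite", sort=False):
        n_c = int(grp["n_carbons"].iloc[0])
        cols = [f"m{k}" for k in range(n_c + 1)]
        a = grp[grp["condition"] == condition_a]
        b = grp[grp["condition"] == condition_b]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"insufficient replicates for {met!r}: need >= 2 per condition")
        for key, va, vb in _iter_contrast_series(a, b, cols):
            t, p = ttest_two_tailed(va, vb)
            rows.append({
                "metabolite": met,
                "isotopologue": key,
                "mean_a": float(va.mean()),
                "mean_b": float(vb.mean()),
                "difference": float(va.mean() - vb.mean()),
                "sem_a": float(va.std(ddof=1) / np.sqrt(va.size)),
                "sem_b": float(vb.std(ddof=1) / np.sqrt(vb.size)),
                "t": t,
                "p": p,
                "significant": bool(p < alpha),
            })
    return pd.DataFrame(rows)


def _iter_contrast_series(a: pd.DataFrame, b: pd.DataFrame, cols: list[str]):
    for k, col in enumerate(cols):
        yield k, a[col].to_numpy(float), b[col].to_numpy(float)
    lf_a = 100.0 * (1.0 - a[cols[0]].to_numpy(float))
    lf_b = 100.0 * (1.0 - b[cols[0]].to_numpy(float))
    yield "labeled", lf_a, lf_b


#: Default isotopologue indices per TCA metabolite: m+2 from one acetyl-CoA
#: turn, m+4 after a second turn, m+5 for citrate via pyruvate carboxylase
#: plus acetyl-CoA.
DEFAULT_TCA_INDICES: dict[str, tuple[int, ...]] = {
    "citrate": (2, 4, 5),
    "alpha-ketoglutarate": (2, 4),
    "succinate": (2, 4),
    "fumarate": (2, 4),
    "malate": (2, 4),
}


def tca_mid_shift(mids: list[MID] | pd.DataFrame, condition_a: str,
                  condition_b: str,
                  metabolites: list[str] | None = None,
                  indices: dict[str, tuple[int, ...]] | None = None,
                  alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Condition contrast restricted to TCA metabolites and key isotopologues.

    Convenience view over :func:`contrast_conditions` for the
    reductive-carboxylation / cyclic-turn readout: by default m+2 and m+4
    (and m+5 for citrate).
    """
    df = mids if isinstance(mids, pd.DataFrame) else _mid_frame(mids)
    indices = dict(DEFAULT_TCA_INDICES) if indices is None else indices
    if metabolites is None:
        metabolites = [m for m in indices if m in set(df["metabolite"])]
    present = set(df["metabolite"])
    for met in metabolites:
        if met not in present:
            raise ValueError(f"unknown metabolite {met!r}")
        n_c = int(df.loc[df["metabolite"] == met, "n_carbons"].iloc[0])
        wanted = indices.get(met, (2, 4))
        if any(k > n_c for k in wanted):
            raise ValueError(
                f"isotopologue index out of range for {met!r} ({n_c} carbons)")
    sub = df[df["metabolite"].isin(metabolites)]
    full = contrast_conditions(sub, condition_a, condition_b, alpha=alpha)
    keep = full.apply(
        lambda r: r["isotopologue"] in indices.get(r["metabolite"], (2, 4)),
        axis=1,
    )
    return full[keep].reset_index(drop=True)
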