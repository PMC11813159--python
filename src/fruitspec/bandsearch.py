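"""Exhaustive two-band correlogram search for trait-optimal ratio indices.

For every ordered wavelength pair (l1, l2) on the grid, the coefficient of
determination R² between the two-band index (ratio R_l1/R_l2 by default, or
normalized difference) and a measured trait is computed, producing the
contour-map matrix used to locate optimal band pairs.  R² is the squared
Pearson correlation between index and trait, identical to the R² of the
simple linear regression trait ~ index and symmetric in regression direction.

Note the matrix is *not* symmetric: R²(l1, l2) != R²(l2, l1) in general for
ratio indices because the reciprocal transform is nonlinear; both triangles
are computed.  The diagonal (RSI(l, l) = 1, zero variance) and any pair whose
index has zero variance are flagged missing (NaN) rather than zero, so they
cannot masquerade as minima on a contour map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import SpectraSet, TraitTable, WavelengthGrid

__all__ = [
    "CorrelogramResult",
    "build_correlogram",
    "select_best_pairs",
    "export_correlogram",
    "read_correlogram",
    "BandPairCorrelogram",
]


@dataclass
class CorrelogramResult:
    """R²(l1, l2) matrix for one trait plus any selected best band pairs."""

    trait_name: str
    grid: WavelengthGrid
    r2: np.ndarray  # (n_bands, n_bands); r2[i, j] for index(l_i, l_j); NaN = missing
    family: str = "ratio"
    best_pairs: list[tuple[float, float, float]] | None = None

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def value_at(self, l1: float, l2: float) -> float:
        return float(self.r2[self.grid.index_of(l1), self.grid.index_of(l2)])

    def max_pair(self) -> tuple[float, float, float]:
        """(l1, l2, r2) of the single highest finite cell."""
        masked = np.where(np.isnan(self.r2), -np.inf, self.r2)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        return float(self.wavelengths[i]), float(self.wavelengths[j]), float(self.r2[i, j])


def _pair_r2_matrix(X: np.ndarray, y: np.ndarray, family: str) -> np.ndarray:
    """Vectorized R² between trait y and the two-band index for every ordered
    pair, computed one denominator column at a time to bound memory."""
    n, b = X.shape
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    r2 = np.full((b, b), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        for j in range(b):
            if family == "ratio":
                V = X / X[:, j][:, None]  # (n, b): column i is RSI(l_i, l_j)
            else:  # normalized difference
                V = (X - X[:, j][:, None]) / (X + X[:, j][:, None])
            Vc = V - np.nanmean(V, axis=0)
            ss_v = np.einsum("ij,ij->j", Vc, Vc)
            cov = yc @ Vc
            col = (cov * cov) / (ss_v * ss_y)
            bad = ~np.isfinite(V).all(axis=0) | (ss_v <= 0)
            col[bad] = np.nan
            col[j] = np.nan  # diagonal: zero-variance index
            r2[:, j] = col
    return r2


def build_correlogram(
    s: SpectraSet,
    t: TraitTable,
    trait: str,
    family: str = "ratio",
) -> CorrelogramResult:
    """R² between the two-band index and ``trait`` for every wavelength pair.

    Parameters
    ----------
    s, t
        Aligned spectra and trait table (same sample ids in the same order).
    trait
        Trait column to correlate against.
    family
        ``"ratio"`` (default, the family of the twelve new indices) or
        ``"normalized_difference"``.
    """
    if family not in ("ratio", "normalized_difference"):
        raise ValueError(f"unknown index family {family!r}")
    if not t.aligned_with(s):
        raise ValueError("spectra and trait table sample ids are not aligned")
    if s.n_samples < 3:
        raise ValueError("need at least 3 samples to compute R²")
    y = t.values(trait)
    if np.ptp(y) == 0:
        raise ValueError(f"zero trait variance for {trait!r}")
    r2 = _pair_r2_matrix(s.reflectance, y, family)
    return CorrelogramResult(trait_name=trait, grid=s.grid, r2=r2, family=family)


def select_best_pairs(
    c: CorrelogramResult,
    k: int = 12,
    min_separation: float = 10.0,
) -> list[tuple[float, float, float]]:
    """Greedy selection of the ``k`` highest-R² peaks with mutual separation.

    Cells are visited in decreasing R² (ties broken by smaller l1 then smaller
    l2); a cell is accepted iff its Chebyshev distance in the (l1, l2) plane to
    every already-accepted pair is >= ``min_separation`` nm.  With a positive
    separation this keeps one representative (the local maximum) per
    correlation ridge; the procedure is fully deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    wl = c.wavelengths
    finite = np.isfinite(c.r2)
    ii, jj = np.nonzero(finite)
    vals = c.r2[ii, jj]
    # sort: r2 descending, then l1 ascending, then l2 ascending
    order = np.lexsort((wl[jj], wl[ii], -vals))
    selected: list[tuple[float, float, float]] = []
    for idx in order:
        l1, l2 = float(wl[ii[idx]]), float(wl[jj[idx]])
        ok = all(
            max(abs(l1 - p1), abs(l2 - p2)) >= min_separation
            for p1, p2, _ in selected
        )
        if ok:
            selected.append((l1, l2, float(vals[idx])))
            if len(selected) == k:
                break
    if len(selected) < k:
        warnings.warn(
            f"only {len(selected)} separated pairs available (requested {k})",
            stacklevel=2,
        )
    c.best_pairs = selected
    return selected


def export_correlogram(c: CorrelogramResult, path, delimiter: str = ",",
                       figure_path=None) -> None:
    """Write the full R² matrix as delimited text with wavelength headers.

    Missing cells (diagonal, zero-variance pairs) are written as empty cells.
    Optionally renders a contour map to ``figure_path``.
    """
    wl = [f"{w:g}" for w in c.wavelengths]
    df = pd.DataFrame(c.r2, index=wl, columns=wl)
    df.index.name = "lambda1_nm"
    df.to_csv(path, sep=delimiter, float_format="%.17g", na_rep="")
    if figure_path is not None:
        _render_contour(c, figure_path)


def _render_contour(c: CorrelogramResult, figure_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    w = c.wavelengths
    mesh = ax.pcolormesh(w, w, c.r2.T, shading="auto", cmap="viridis", vmin=0, vmax=1)
    fig.colorbar(mesh, ax=ax, label=r"$R^2$")
    ax.set_xlabel(r"$\lambda_1$ (nm)")
    ax.set_ylabel(r"$\lambda_2$ (nm)")
    ax.set_title(f"{c.trait_name} vs {c.family} index")
    fig.tight_layout()
    fig.savefig(figure_path, dpi=150)
    plt.close(fig)


def read_correlogram(path, trait_name: str = "", delimiter: str = ",") -> CorrelogramResult:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    wl = np.array([float(w) for w in df.columns])
    return CorrelogramResult(trait_name=trait_name, grid=WavelengthGrid(wl),
                             r2=df.to_numpy(dtype=float))


class BandPairCorrelogram(TransformerMixin, BaseEstimator):
    """Trait-driven band-pair selector in sklearn transformer form.

    ``fit(X, y)`` computes the full two-band correlogram of ``y`` against the
    spectra ``X`` and selects the top band pairs; ``transform(X)`` returns the
    selected two-band indices as a feature matrix.

    Parameters
    ----------
    wavelengths : array-like
        Wavelength (nm) of each column of ``X``.
    k : int
        Number of band pairs to select.
    min_separation : float
        Minimum Chebyshev separation (nm) between selected pairs.
    family : str
        ``"ratio"`` or ``"normalized_difference"``.

    Attributes
    ----------
    r2_ : ndarray of shape (n_bands, n_bands)
        The correlogram matrix.
    best_pairs_ : list of (l1, l2, r2)
        Selected pairs in decreasing R².
    """

    def __init__(self, wavelengths=None, k=12, min_separation=10.0, family="ratio"):
        self.wavelengths = wavelengths
        self.k = k
        self.min_separation = min_separation
        self.family = family

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if self.wavelengths is None:
            raise ValueError("wavelengths must be provided to interpret columns")
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.size != X.shape[1]:
            raise ValueError("wavelengths length must equal number of columns")
        if X.shape[0] != y.size:
            raise ValueError("X and y have inconsistent sample counts")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 samples")
        if np.ptp(y) == 0:
            raise ValueError("zero trait variance")
        grid = WavelengthGrid(wl)
        self.r2_ = _pair_r2_matrix(X, y, self.family)
        result = CorrelogramResult("y", grid, self.r2_, family=self.family)
        self.best_pairs_ = select_best_pairs(result, k=self.k,
                                             min_separation=self.min_separation)
        self.grid_ = grid
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "best_pairs_"):
            raise ValueError("BandPairCorrelogram is not fitted")
        X = np.asarray(X, dtype=float)
        cols = []
        with np.errstate(divide="ignore", invalid="ignore"):
            for l1, l2, _ in self.best_pairs_:
                i, j = self.grid_.index_of(l1), self.grid_.index_of(l2)
                if self.family == "ratio":
                    cols.append(X[:, i] / X[:, j])
                else:
                    cols.append((X[:, i] - X[:, j]) / (X[:, i] + X[:, j]))
        return np.column_stack(cols)

    def get_feature_names_out(self, input_features=None):
        prefix = "RSI" if self.family == "ratio" else "ND"
        return np.asarray(
            [f"{prefix}_{l1:g},{l2:g}" for l1, l2, _ in self.best_pairs_], dtype=object
        )
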