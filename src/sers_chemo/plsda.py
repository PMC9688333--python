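"""PLS-DA binary classification with VIP-based band selection.

Partial least squares discriminant analysis regresses a 0/1 class coding on
the (column-centered) spectral matrix via PLS1/NIPALS, extracting latent
variables (LVs) that maximize covariance between spectra and class
membership.  The continuous regression response, thresholded at 0.5, gives
the class call.  Variable importance in projection (VIP) scores summarize
each wavenumber's contribution across LVs; wavenumbers with VIP > 1 are the
discriminative bands.

The module follows the statsmodels idiom: :class:`PLSDA` is the model
specification (data plus class coding), ``fit`` returns a
:class:`PLSDAResults` carrying estimates, diagnostics, ``predict``,
``vip`` and ``summary``.  Thin functional wrappers (:func:`fit_plsda`,
:func:`predict_plsda`, :func:`vip_scores`) expose the same operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SpectralDataset

__all__ = [
    "PLSDA",
    "PLSDAResults",
    "VipResult",
    "fit_plsda",
    "predict_plsda",
    "vip_scores",
    "extract_vip_bands",
    "group_mean_difference",
    "pca_lda_classify",
    "encode_labels",
]

VIP_THRESHOLD = 1.0


def encode_labels(class_labels: Sequence[str], case_labels: Sequence[str]) -> np.ndarray:
    """0/1 response coding: 1 for the case group, 0 otherwise."""
    case = set(case_labels)
    return np.array([1.0 if c in case else 0.0 for c in class_labels])


# ---------------------------------------------------------------------------
# model


class PLSDA:
    """PLS-DA model specification.

    Parameters
    ----------
    X : (n, p) array
        Spectral descriptor matrix, one row per spectrum.  Not yet
        centered; the model removes and stores column means.
    y : (n,) array of 0/1
        Class coding (1 = case, 0 = control); both classes must occur.
    wavenumbers : (p,) array, optional
        Raman-shift axis; enables band reporting on VIP results.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, wavenumbers: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
            raise ValueError("X must be (n, p) and y length n")
        classes = np.unique(y)
        if not np.all(np.isin(classes, [0.0, 1.0])):
            raise ValueError("y must be coded 0/1")
        if classes.size < 2:
            raise ValueError("y contains a single class; need both 0 and 1")
        self.X = X
        self.y = y
        self.wavenumbers = None if wavenumbers is None else np.asarray(wavenumbers, dtype=float)
        if self.wavenumbers is not None and self.wavenumbers.size != X.shape[1]:
            raise ValueError("wavenumbers length must equal n columns of X")

    @classmethod
    def from_dataset(cls, dataset: SpectralDataset, case_labels: Sequence[str]) -> "PLSDA":
        """Build the model from a preprocessed dataset and a case grouping."""
        y = encode_labels(dataset.class_labels, case_labels)
        return cls(dataset.X, y, wavenumbers=dataset.grid)

    def fit(self, n_components: int = 2) -> "PLSDAResults":
        """Fit by PLS1/NIPALS with *n_components* latent variables."""
        A = int(n_components)
        n, p = self.X.shape
        if A < 1:
            raise ValueError("n_components must be >= 1")
        if A > min(n - 1, p):
            raise ValueError(
                f"n_components={A} exceeds min(n-1, p)={min(n - 1, p)}"
            )
        x_mean = self.X.mean(axis=0)
        y_mean = self.y.mean()
        Xd = self.X - x_mean
        yd = self.y - y_mean

        W = np.empty((p, A))
        P = np.empty((p, A))
        T = np.empty((n, A))
        q = np.empty(A)
        for a in range(A):
            w = Xd.T @ yd
            nw = np.linalg.norm(w)
            if nw <= 1e-12 * max(1.0, np.abs(yd).max(initial=0.0)):
                raise ValueError(
                    f"X/y covariance exhausted after {a} components; "
                    f"achievable rank is {a}"
                )
            w /= nw
            t = Xd @ w
            tt = t @ t
            if tt <= 1e-24:
                raise ValueError(
                    f"degenerate score at component {a + 1}; achievable rank is {a}"
                )
            pl = Xd.T @ t / tt
            qa = (yd @ t) / tt
            Xd = Xd - np.outer(t, pl)
            yd = yd - qa * t
            W[:, a], P[:, a], T[:, a], q[a] = w, pl, t, qa

        return PLSDAResults(self, W=W, P=P, T=T, q=q, x_mean=x_mean, y_mean=y_mean)


@dataclass(frozen=True)
class VipResult:
    """Per-wavenumber VIP scores plus the contiguous VIP>1 bands."""

    grid: np.ndarray
    scores: np.ndarray
    bands: list[tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wavenumber_cm1": self.grid, "vip": self.scores})


class PLSDAResults:
    """Fitted PLS-DA model.

    Attributes
    ----------
    weights : (p, A)
        X weights, unit-norm columns.
    x_loadings : (p, A), y_loadings : (A,)
        NIPALS loadings.
    scores : (n, A)
        Training LV scores (mutually orthogonal).
    coef : (p,)
        Regression vector B with ``yhat = (X - x_mean) @ B + y_mean``.
    """

    decision_threshold = 0.5

    def __init__(self, model: PLSDA, W: np.ndarray, P: np.ndarray, T: np.ndarray,
                 q: np.ndarray, x_mean: np.ndarray, y_mean: float):
        self.model = model
        self.weights = W
        self.x_loadings = P
        self.scores = T
        self.y_loadings = q
        self.x_mean = x_mean
        self.y_mean = float(y_mean)
        # B = W (P'W)^-1 q maps centered X to centered response
        self.coef = W @ np.linalg.solve(P.T @ W, q)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    # -- prediction --------------------------------------------------------

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """Continuous decision scores for raw (uncentered) spectra."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if X_new.shape[1] != self.x_mean.size:
            raise ValueError(
                f"expected {self.x_mean.size} columns, got {X_new.shape[1]}"
            )
        return (X_new - self.x_mean) @ self.coef + self.y_mean

    def classify(self, X_new: np.ndarray) -> np.ndarray:
        """Class calls: 1 (case) iff score >= 0.5."""
        return (self.predict(X_new) >= self.decision_threshold).astype(int)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        """Project raw spectra onto the latent variables (R = W (P'W)^-1)."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        R = self.weights @ np.linalg.inv(self.x_loadings.T @ self.weights)
        return (X_new - self.x_mean) @ R

    # -- variable importance ----------------------------------------------

    def vip(self) -> VipResult:
        """VIP scores and the maximal contiguous bands exceeding 1.

        ``VIP_j = sqrt(p * sum_a SS_a w_aj^2 / sum_a SS_a)`` with
        ``SS_a = q_a^2 (t_a' t_a)`` the response variance captured by LV a.
        The identity ``mean(VIP^2) = 1`` holds for every fit.
        """
        W, T, q = self.weights, self.scores, self.y_loadings
        p = W.shape[0]
        ss = q**2 * np.einsum("ia,ia->a", T, T)
        vip = np.sqrt(p * (W**2 @ ss) / ss.sum())
        grid = self.model.wavenumbers
        if grid is None:
            grid = np.arange(p, dtype=float)
        bands = extract_vip_bands_from_scores(grid, vip)
        return VipResult(grid=grid, scores=vip, bands=bands)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        n, p = self.model.X.shape
        ss = self.y_loadings**2 * np.einsum("ia,ia->a", self.scores, self.scores)
        frac = ss / ss.sum()
        yhat = self.fittedvalues
        acc = float(np.mean((yhat >= 0.5) == (self.model.y == 1)))
        lines = [
            "PLS-DA Results",
            "=" * 46,
            f"n spectra          {n}",
            f"n wavenumbers      {p}",
            f"latent variables   {self.n_components}",
            f"in-sample accuracy {acc:.3f}",
            "",
            "LV   y-loading   share of Y sum-of-squares",
        ]
        for a in range(self.n_components):
            lines.append(f"{a + 1:<4d} {self.y_loadings[a]:>9.4f}   {frac[a]:.3f}")
        vip = self.vip()
        lines.append("")
        lines.append(f"VIP > 1 bands (cm^-1): "
                     + (", ".join(f"{lo:g}-{hi:g}" for lo, hi in vip.bands) or "none"))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface


def fit_plsda(X: np.ndarray, y: np.ndarray, n_components: int,
              wavenumbers: np.ndarray | None = None) -> PLSDAResults:
    """Fit PLS-DA on a descriptor matrix and 0/1 response."""
    return PLSDA(X, y, wavenumbers=wavenumbers).fit(n_components)


def predict_plsda(results: PLSDAResults, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous scores and 0/1 class calls for raw spectra."""
    scores = results.predict(X_new)
    return scores, (scores >= results.decision_threshold).astype(int)


def vip_scores(results: PLSDAResults) -> VipResult:
    return results.vip()


def extract_vip_bands_from_scores(grid: np.ndarray, scores: np.ndarray,
                                  threshold: float = VIP_THRESHOLD,
                                  min_width: float = 1.0) -> list[tuple[float, float]]:
    """Maximal contiguous runs of grid points with score > threshold.

    Intervals are closed and reported at grid resolution.  A run's width is
    counted as ``end - start + spacing`` (a single grid point on a 1 cm^-1
    grid has width 1); runs narrower than *min_width* are dropped.
    """
    grid = np.asarray(grid, dtype=float)
    above = np.asarray(scores) > threshold
    spacing = float(np.median(np.diff(grid))) if grid.size > 1 else 1.0
    bands: list[tuple[float, float]] = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            lo, hi = float(grid[i]), float(grid[j])
            if hi - lo + spacing >= min_width - 1e-9:
                bands.append((lo, hi))
            i = j + 1
        else:
            i += 1
    return bands


def extract_vip_bands(vip: VipResult, min_width: float = 1.0) -> list[tuple[float, float]]:
    """Re-extract bands from a VipResult with a width floor in cm^-1."""
    return extract_vip_bands_from_scores(vip.grid, vip.scores, min_width=min_width)


def band_jaccard(bands_a: Sequence[tuple[float, float]],
                 bands_b: Sequence[tuple[float, float]],
                 edge_tol: float = 0.0, resolution: float = 0.5) -> float:
    """Jaccard overlap between two sets of closed wavenumber intervals.

    Band edges are uncertain to roughly the linewidth, so both interval
    sets are dilated by *edge_tol* on each side before rasterizing at
    *resolution* and computing |A∩B| / |A∪B|.
    """
    if not bands_a and not bands_b:
        return 1.0
    if not bands_a or not bands_b:
        return 0.0
    lo = min(min(b[0] for b in bands_a), min(b[0] for b in bands_b)) - edge_tol
    hi = max(max(b[1] for b in bands_a), max(b[1] for b in bands_b)) + edge_tol
    grid = np.arange(lo, hi + resolution, resolution)

    def _raster(bands):
        m = np.zeros(grid.size, dtype=bool)
        for a, b in bands:
            m |= (grid >= a - edge_tol) & (grid <= b + edge_tol)
        return m

    ra, rb = _raster(bands_a), _raster(bands_b)
    return float((ra & rb).sum() / (ra | rb).sum())


# ---------------------------------------------------------------------------
# group means


def group_mean_difference(dataset: SpectralDataset, class_a: str | Sequence[str],
                          class_b: str | Sequence[str]) -> pd.DataFrame:
    """Per-wavenumber class mean spectra and their difference (a - b)."""
    def _mask(group):
        labels = [group] if isinstance(group, str) else list(group)
        m = np.isin(dataset.class_labels, labels)
        if not m.any():
            raise ValueError(f"no spectra with class in {labels}")
        return m

    mean_a = dataset.X[_mask(class_a)].mean(axis=0)
    mean_b = dataset.X[_mask(class_b)].mean(axis=0)
    return pd.DataFrame(
        {
            "wavenumber_cm1": dataset.grid,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "difference": mean_a - mean_b,
        }
    )


# ---------------------------------------------------------------------------
# optional comparator: PCA followed by Fisher LDA


def pca_lda_classify(X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray,
                     n_pcs: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Project on leading PCs of the training data, then 2-class Fisher LDA.

    Returns continuous discriminant scores (positive side = class 1) and
    0/1 labels for ``X_test``, thresholding at the midpoint of the
    projected class means.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training labels contain a single class")
    mu = X_train.mean(axis=0)
    Xc = X_train - mu
    # principal axes via thin SVD
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds training rank {rank}")
    V = Vt[:n_pcs].T
    Ztr = Xc @ V
    Zte = (X_test - mu) @ V

    m1 = Ztr[y_train == 1].mean(axis=0)
    m0 = Ztr[y_train == 0].mean(axis=0)
    S = np.zeros((n_pcs, n_pcs))
    for cls, m in ((1, m1), (0, m0)):
        D = Ztr[y_train == cls] - m
        S += D.T @ D
    S += np.eye(n_pcs) * 1e-10 * max(1.0, np.trace(S))
    d = np.linalg.solve(S, m1 - m0)
    thresh = 0.5 * (m1 + m0) @ d
    scores = Zte @ d - thresh
    return scores, (scores >= 0).astype(int)
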