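"""Spectral preprocessing: despiking, AsLS baseline removal, smoothing.

The standard chain for SERS biofluid spectra contaminated by
autofluorescence: per spectrum, remove single-bin cosmic spikes, estimate
and subtract the broad fluorescence background with asymmetric least
squares (AsLS), smooth with a Savitzky-Golay filter; then crop the dataset
to the 735-1700 cm^-1 fingerprint window and divide each spectrum by its
own mean intensity.  Column mean-centering is deliberately *not* part of
this chain — it must be fitted on training folds only (see
:mod:`sers_chemo.validation`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.signal

from .io import SpectralDataset

__all__ = [
    "PreprocessConfig",
    "asls_baseline",
    "savgol_smooth",
    "despike",
    "crop",
    "normalize_mean",
    "mean_center",
    "apply_centering",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the preprocessing chain.

    AsLS: ``asls_lambda`` controls baseline stiffness (larger = smoother),
    ``asls_p`` the asymmetry — points above the baseline (Raman peaks) get
    weight ``p``, points below get ``1 - p``, so the baseline hugs the lower
    envelope.  ``sg_window``/``sg_polyorder`` parametrise the
    Savitzky-Golay smoother.  ``normalize`` is per-spectrum mean
    normalization ("mean") or nothing ("none").
    """

    asls_lambda: float = 1e5
    asls_p: float = 0.01
    asls_max_iter: int = 15
    asls_tol: float = 1e-6
    sg_window: int = 11
    sg_polyorder: int = 3
    despike_z: float = 8.0
    crop_range: tuple[float, float] = (735.0, 1700.0)
    normalize: str = "mean"

    def __post_init__(self) -> None:
        if self.asls_lambda <= 0:
            raise ValueError("asls_lambda must be > 0")
        if not (0.0 < self.asls_p < 0.5):
            raise ValueError("asls_p must be in (0, 0.5)")
        if self.sg_window < 5 or self.sg_window % 2 == 0:
            raise ValueError("sg_window must be an odd integer >= 5")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be < sg_window")
        if self.normalize not in ("mean", "none"):
            raise ValueError("normalize must be 'mean' or 'none'")


# ---------------------------------------------------------------------------
# AsLS baseline


def _second_diff_penalty_banded(n: int, lam: float) -> np.ndarray:
    """Upper banded form (3 x n) of lam * D2' D2 for the symmetric solver."""
    d2 = np.zeros((3, n))
    # main diagonal of D'D: 1, 5, 6, ..., 6, 5, 1
    main = np.full(n, 6.0)
    main[[0, -1]] = 1.0
    if n > 2:
        main[[1, -2]] = 5.0
    # first off-diagonal: -2, -4, ..., -4, -2
    off1 = np.full(n - 1, -4.0)
    off1[[0, -1]] = -2.0
    off2 = np.ones(n - 2)
    d2[2, :] = main
    d2[1, 1:] = off1
    d2[0, 2:] = off2
    return lam * d2


def asls_baseline(intensities: np.ndarray, lam: float = 1e5, p: float = 0.01,
                  max_iter: int = 15, tol: float = 1e-6) -> np.ndarray:
    """Asymmetric least squares baseline estimate.

    Returns the vector z minimizing ``sum_i w_i (y_i - z_i)^2 +
    lam * sum (Delta^2 z)^2`` under the asymmetric reweighting
    ``w_i = p`` if ``y_i > z_i`` else ``1 - p``, starting from uniform
    weights.  Iteration stops when the weights stop changing, their relative
    change drops below *tol*, or *max_iter* is reached.  The pentadiagonal
    normal system is solved with a banded Cholesky factorization.
    """
    y = np.asarray(intensities, dtype=float)
    if y.ndim != 1 or y.size < 8:
        raise ValueError("intensities must be a 1-D vector of length >= 8")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if not (0.0 < p < 0.5):
        raise ValueError("p must be in (0, 0.5)")
    n = y.size
    penalty = _second_diff_penalty_banded(n, lam)
    w = np.ones(n)
    z = y.copy()

    def _banded_matvec(ab: np.ndarray, v: np.ndarray) -> np.ndarray:
        d0, d1, d2 = ab[2], ab[1, 1:], ab[0, 2:]
        out = d0 * v
        out[:-1] += d1 * v[1:]
        out[1:] += d1 * v[:-1]
        out[:-2] += d2 * v[2:]
        out[2:] += d2 * v[:-2]
        return out

    # Solve for the deviation e = z - y rather than z itself:
    # (W + lam D'D) e = -lam D'D y.  Rounding then scales with |e| (the
    # peak heights) instead of |y| (peaks plus background), and affine
    # inputs — for which D'D y = 0 — are reproduced exactly.
    rhs = -lam * np.convolve(np.diff(y, n=2), [1.0, -2.0, 1.0], mode="full")
    for _ in range(max_iter):
        ab = penalty.copy()
        ab[2, :] += w
        e = scipy.linalg.solveh_banded(ab, rhs, lower=False)
        # one refinement step against condition growth at small p
        r = rhs - _banded_matvec(ab, e)
        e += scipy.linalg.solveh_banded(ab, r, lower=False)
        z = y + e
        w_new = np.where(y > z, p, 1.0 - p)
        delta = np.abs(w_new - w).sum() / w.sum()
        w = w_new
        if delta < tol:
            break
    return z


# ---------------------------------------------------------------------------
# Savitzky-Golay


def savgol_smooth(intensities: np.ndarray, window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing (local least-squares polynomial).

    Edge bins take the value of the polynomial fitted over the terminal
    window (polynomial extrapolation), so degree-<=polyorder inputs are
    reproduced exactly everywhere.
    """
    y = np.asarray(intensities, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > y.shape[-1]:
        raise ValueError(f"window {window} exceeds vector length {y.shape[-1]}")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    return scipy.signal.savgol_filter(y, window, polyorder, mode="interp", axis=-1)


# ---------------------------------------------------------------------------
# despiking


def despike(intensities: np.ndarray, z_threshold: float = 8.0) -> np.ndarray:
    """Remove single-bin cosmic-ray spikes.

    Bins whose modified z-score (median/MAD based) of the second difference
    exceeds *z_threshold* are replaced by linear interpolation across
    unflagged neighbours.  If more than 5% of bins are flagged the input is
    considered pathological and an error is raised.
    """
    y = np.asarray(intensities, dtype=float)
    if y.ndim != 1 or y.size < 8:
        raise ValueError("intensities must be a 1-D vector of length >= 8")
    d2 = np.zeros_like(y)
    d2[1:-1] = np.diff(y, n=2)
    med = np.median(d2)
    mad = np.median(np.abs(d2 - med))
    if mad == 0:
        return y.copy()
    mz = 0.6745 * (d2 - med) / mad
    flagged = np.abs(mz) > z_threshold
    if not flagged.any():
        return y.copy()
    if flagged.sum() > 0.05 * y.size:
        raise ValueError(
            f"{flagged.sum()} of {y.size} bins flagged as spikes (> 5%); "
            "input looks pathological rather than spiked"
        )
    out = y.copy()
    idx = np.arange(y.size)
    out[flagged] = np.interp(idx[flagged], idx[~flagged], y[~flagged])
    return out


# ---------------------------------------------------------------------------
# dataset-level stages


def crop(dataset: SpectralDataset, crop_range: Sequence[float] = (735.0, 1700.0)) -> SpectralDataset:
    """Restrict the dataset to the closed wavenumber interval [lo, hi]."""
    lo, hi = float(crop_range[0]), float(crop_range[1])
    mask = (dataset.grid >= lo) & (dataset.grid <= hi)
    if not mask.any():
        raise ValueError(f"crop range [{lo:g}, {hi:g}] contains no grid points")
    out = dataset.copy()
    out.grid = dataset.grid[mask]
    out.X = dataset.X[:, mask]
    return out


def normalize_mean(dataset: SpectralDataset) -> SpectralDataset:
    """Divide each spectrum by its own mean intensity (row means become 1)."""
    means = dataset.X.mean(axis=1)
    if np.any(means <= 0):
        bad = dataset.spectrum_ids[means <= 0][:5].tolist()
        raise ValueError(f"nonpositive mean intensity for spectra {bad}")
    out = dataset.copy()
    out.X = dataset.X / means[:, None]
    return out


def mean_center(dataset: SpectralDataset) -> tuple[SpectralDataset, np.ndarray]:
    """Column mean-center; returns the removed mean for held-out data."""
    if dataset.n_spectra < 2:
        raise ValueError("mean centering needs >= 2 spectra")
    mu = dataset.X.mean(axis=0)
    out = dataset.copy()
    out.X = dataset.X - mu
    return out, mu


def apply_centering(dataset: SpectralDataset, mu: np.ndarray) -> SpectralDataset:
    """Center held-out spectra with a training-fold column mean."""
    out = dataset.copy()
    out.X = dataset.X - np.asarray(mu, dtype=float)
    return out


def preprocess_pipeline(dataset: SpectralDataset, config: PreprocessConfig | None = None) -> SpectralDataset:
    """Full per-spectrum chain, then crop and per-spectrum normalization.

    Per spectrum: despike -> AsLS baseline subtraction -> Savitzky-Golay
    smoothing.  Dataset-wise: crop to ``config.crop_range`` then (if
    ``config.normalize == 'mean'``) per-spectrum mean normalization.
    Column mean-centering is left to cross-validation so that held-out
    folds are centered with training means only.
    """
    config = config or PreprocessConfig()
    if dataset.n_spectra == 0:
        raise ValueError("empty dataset")
    X = np.empty_like(dataset.X)
    for i in range(dataset.n_spectra):
        y = despike(dataset.X[i], config.despike_z)
        y = y - asls_baseline(y, config.asls_lambda, config.asls_p,
                              config.asls_max_iter, config.asls_tol)
        X[i] = savgol_smooth(y, config.sg_window, config.sg_polyorder)
    out = dataset.copy()
    out.X = X
    out = crop(out, config.crop_range)
    if config.normalize == "mean":
        out = normalize_mean(out)
    return out
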