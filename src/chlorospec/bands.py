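"""Predictor-construction strategies: correlation screening, water-window
augmented screening, and eigenvalue-rule PCA reduction.

Correlation screening (CA) ranks every band by the absolute Pearson
correlation of its (possibly transformed) values with chlorophyll content
and keeps the top k (default 10).  The water-window variant (CA(W)) runs
two rounds: six bands over the whole grid, then the two strongest bands
inside each of the water-absorption windows 1390-1490 nm and
1870-1970 nm, for ten bands in total.  PCA reduction standardizes the
band matrix and retains every component with eigenvalue > 1 (the Kaiser
rule, which is only meaningful on the correlation scale).

Because |r| is invariant under strictly monotone affine maps of the band
values, the log-family transforms logR, log(1/R) and logSqrtR select
identical band sets (their profiles differ only in sign/scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, ShapeError
from .spectra import SpectraSet, WavelengthGrid

WATER_WINDOWS = ((1390.0, 1490.0), (1870.0, 1970.0))


@dataclass(frozen=True)
class CorrelationProfile:
    """Per-wavelength Pearson r between band values and chlorophyll."""

    wavelengths: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        if self.wavelengths.shape != self.r.shape:
            raise ShapeError("wavelengths and r must align")


@dataclass(frozen=True)
class BandSelection:
    """Ordered selected wavelengths with correlations and provenance.

    provenance tags: 'main' for the whole-grid round, 'window_lo_hi' for
    water-window rounds.
    """

    bands: tuple
    r_values: tuple
    provenance: tuple

    def __len__(self):
        return len(self.bands)

    @property
    def main_bands(self):
        return tuple(b for b, p in zip(self.bands, self.provenance) if p == "main")

    @property
    def window_bands(self):
        return tuple(b for b, p in zip(self.bands, self.provenance) if p != "main")


def _as_matrix(X):
    if isinstance(X, SpectraSet):
        return X.reflectance, X.grid.values
    X = np.asarray(X, float)
    return X, np.arange(X.shape[1], dtype=float)


def correlation_profile(X, y) -> CorrelationProfile:
    """Pearson r of every band against the response.

    Zero-variance bands get r = 0 with a warning rather than NaN.
    """
    M, wavelengths = _as_matrix(X)
    y = np.asarray(y, float)
    if M.shape[0] != y.size:
        raise ShapeError(f"{M.shape[0]} spectra but {y.size} responses")
    if M.shape[0] < 3:
        raise ParameterError("correlation needs at least 3 samples")
    Xc = M - M.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    dead = sx == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance band(s); r set to 0")
    denom = np.where(dead, 1.0, sx) * (sy if sy > 0 else 1.0)
    r = np.where(dead | (sy == 0), 0.0, (Xc.T @ yc) / denom)
    return CorrelationProfile(wavelengths.copy(), np.clip(r, -1.0, 1.0))


def _rank_order(profile: CorrelationProfile, mask=None) -> np.ndarray:
    """Indices sorted by descending |r|, ties broken by ascending nm."""
    idx = np.arange(profile.r.size) if mask is None else np.flatnonzero(mask)
    order = sorted(idx, key=lambda i: (-abs(profile.r[i]), profile.wavelengths[i]))
    return np.asarray(order, dtype=int)


def select_top_k(profile: CorrelationProfile, k: int = 10) -> BandSelection:
    """The k bands with largest |r| (CA screening)."""
    if k <= 0:
        raise ParameterError("k must be positive")
    if k > profile.r.size:
        raise ParameterError(f"k={k} exceeds {profile.r.size} bands")
    order = _rank_order(profile)[:k]
    return BandSelection(
        bands=tuple(float(profile.wavelengths[i]) for i in order),
        r_values=tuple(float(profile.r[i]) for i in order),
        provenance=("main",) * k,
    )


def select_with_water(profile: CorrelationProfile, k_main: int = 6,
                      windows=WATER_WINDOWS, k_per_window: int = 2) -> BandSelection:
    """Two-round CA(W) screening: k_main whole-grid bands plus
    k_per_window bands from each water window.

    If a window band was already taken in the main round it counts for the
    window and the next-best window band backfills, keeping the total at
    k_main + k_per_window * len(windows) whenever enough bands exist.
    """
    if k_main <= 0 or k_per_window <= 0:
        raise ParameterError("k_main and k_per_window must be positive")
    main = select_top_k(profile, k_main)
    bands = list(main.bands)
    rvals = list(main.r_values)
    prov = list(main.provenance)
    chosen = set(bands)
    for lo, hi in windows:
        mask = (profile.wavelengths >= lo) & (profile.wavelengths <= hi)
        if mask.sum() < k_per_window:
            raise ParameterError(f"window {lo}-{hi} nm has fewer than "
                                 f"{k_per_window} grid bands")
        tag = f"window_{lo:g}_{hi:g}"
        taken = 0
        # main-round duplicates are skipped and the next-best band backfills,
        # keeping the total selection size fixed
        for i in _rank_order(profile, mask):
            if taken >= k_per_window:
                break
            w = float(profile.wavelengths[i])
            if w in chosen:
                continue
            bands.append(w)
            rvals.append(float(profile.r[i]))
            prov.append(tag)
            chosen.add(w)
            taken += 1
    return BandSelection(tuple(bands), tuple(rvals), tuple(prov))


@dataclass
class PCAReduction:
    """PCA of the standardized band matrix with the eigenvalue > 1 rule.

    Stores the training standardization and rotation so held-out spectra
    are projected, never refit.
    """

    mean_: np.ndarray
    scale_: np.ndarray
    components_: np.ndarray  # k x p rotation
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    k: int
    cumulative_variance: float
    scores: np.ndarray  # n x k training scores

    def project(self, X) -> np.ndarray:
        M, _ = _as_matrix(X)
        return (M - self.mean_) / self.scale_ @ self.components_.T


def pca_reduce(X, eigenvalue_threshold: float = 1.0,
               standardize: bool = True) -> PCAReduction:
    """Principal components of the (by default standardized) band matrix,
    retaining components with eigenvalue above the threshold."""
    M, _ = _as_matrix(X)
    n, p = M.shape
    if n < 2:
        raise ParameterError("PCA needs at least 2 samples")
    mean = M.mean(axis=0)
    if standardize:
        scale = M.std(axis=0, ddof=1)
        scale = np.where(scale == 0, 1.0, scale)
    else:
        scale = np.ones(p)
    Z = (M - mean) / scale
    # SVD route: eigenvalues of Z'Z/(n-1) are s^2/(n-1)
    U, svals, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = svals**2 / (n - 1)
    k = max(int(np.sum(eig > eigenvalue_threshold)), 1)
    k = min(k, n - 1, p)
    total = eig.sum()
    cumvar = float(eig[:k].sum() / total) if total > 0 else 1.0
    components = Vt[:k]
    scores = Z @ components.T
    return PCAReduction(mean, scale, components, eig, k, cumvar, scores)
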