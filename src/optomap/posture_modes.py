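"""Low-dimensional postural time series via Radon transform and PCA.

Aligned frames are Radon-transformed at two-degree angular spacing; the
Radon-space pixels carrying the most variance (default: the smallest set
capturing 95% of the total) are kept, and PCA over those pixels yields the
postural modes (default 50). Projecting each frame onto the retained
eigenvectors gives the mode time series consumed by the wavelet stage.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)


def radon_frame(image: np.ndarray, angle_spacing: float = 2.0) -> np.ndarray:
    """Sinogram of one aligned frame: projections over {0, 2, ..., 178} degrees.

    Implemented as forward splatting: each pixel's value is split linearly
    between the two offset bins its center projects onto, so every
    projection sums exactly to the total image mass (backward-warp Radon
    implementations leak a few tenths of a percent at object edges, which
    would contaminate the variance-based pixel selection).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("radon_frame expects a square aligned image")
    size = img.shape[0]
    thetas = np.deg2rad(np.arange(0.0, 180.0, angle_spacing))
    n_offsets = int(np.ceil(np.sqrt(2) * size)) + 3
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    x = (xx - c).ravel()
    y = (yy - c).ravel()
    v = img.ravel()
    out = np.zeros((len(thetas), n_offsets))
    for a, th in enumerate(thetas):
        s = x * np.cos(th) + y * np.sin(th) + (n_offsets - 1) / 2.0
        i0 = np.floor(s).astype(int)
        frac = s - i0
        out[a] = (np.bincount(i0, weights=v * (1 - frac), minlength=n_offsets)
                  + np.bincount(i0 + 1, weights=v * frac, minlength=n_offsets))[:n_offsets]
    return out


def radon_stack(frames: np.ndarray, angle_spacing: float = 2.0) -> np.ndarray:
    """Sinograms for a frame stack, shape (T, angles, offsets)."""
    return np.stack([radon_frame(f, angle_spacing) for f in frames])


@dataclass
class PixelSelection:
    """Retained high-variance Radon-space pixels."""

    indices: np.ndarray            # sorted unique flat indices into the sinogram
    variance_fraction: float       # fraction of total variance captured
    sinogram_shape: tuple

    @property
    def n_pixels(self) -> int:
        return len(self.indices)


def select_pixels(stack: np.ndarray, target_variance: float = 0.95) -> PixelSelection:
    """Smallest set of highest-variance Radon pixels capturing the target fraction.

    The printed pixel count of any one dataset is not transferable, so the
    selection is parameterized by variance fraction and the resulting count
    is recorded.
    """
    X = np.asarray(stack, dtype=float)
    if X.ndim != 3 or X.shape[0] < 2:
        raise ValueError("need a (T, angles, offsets) stack with at least 2 frames")
    flat = X.reshape(X.shape[0], -1)
    var = flat.var(axis=0)
    total = var.sum()
    if total <= 0:
        raise ValueError("zero total variance: frames are identical")
    order = np.argsort(var)[::-1]
    csum = np.cumsum(var[order])
    n_keep = int(np.searchsorted(csum, target_variance * total) + 1)
    n_keep = min(n_keep, (var > 0).sum())
    idx = np.sort(order[:n_keep])
    return PixelSelection(indices=idx, variance_fraction=float(csum[n_keep - 1] / total),
                          sinogram_shape=X.shape[1:])


@dataclass
class PCABasis:
    """Orthonormal postural eigenmodes over the selected Radon pixels."""

    mean: np.ndarray               # (n_pixels,)
    components: np.ndarray         # (n_modes, n_pixels), orthonormal rows
    eigenvalues: np.ndarray        # (n_modes,), non-increasing
    total_variance: float
    geometry_hash: str             # guards against projecting mismatched geometry

    @property
    def n_modes(self) -> int:
        return self.components.shape[0]

    @property
    def variance_fraction(self) -> float:
        return float(self.eigenvalues.sum() / self.total_variance)


def _geometry_hash(selection: PixelSelection) -> str:
    h = hashlib.sha1()
    h.update(np.asarray(selection.sinogram_shape).tobytes())
    h.update(selection.indices.tobytes())
    return h.hexdigest()


def fit_postural_pca(selected_matrix: np.ndarray, n_modes: int = 50,
                     selection: PixelSelection | None = None,
                     seed: int = 0) -> PCABasis:
    """Top-``n_modes`` eigendecomposition of the selected Radon pixels.

    Exact SVD when the pixel count is moderate (<= 20,000), randomized
    solver with a fixed seed beyond that. ``n_modes`` beyond the data rank
    is truncated with a warning.
    """
    X = np.asarray(selected_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("selected_matrix must be (frames, pixels)")
    if X.shape[0] < n_modes:
        raise ValueError("need at least as many frames as requested modes")
    rank = min(X.shape[0] - 1, X.shape[1])
    k = min(n_modes, rank)
    if k < n_modes:
        log.warning("requested %d modes but rank allows only %d; truncating",
                    n_modes, k)
    solver = "full" if X.shape[1] <= 20000 else "randomized"
    pca = PCA(n_components=k, svd_solver=solver, random_state=seed)
    pca.fit(X)
    total = X.var(axis=0, ddof=1).sum()  # same ddof as the eigenvalues
    ghash = _geometry_hash(selection) if selection is not None else ""
    return PCABasis(mean=pca.mean_, components=pca.components_,
                    eigenvalues=pca.explained_variance_,
                    total_variance=float(total), geometry_hash=ghash)


@dataclass
class PosturalModes:
    """Per-frame projections onto the postural eigenmodes."""

    series: np.ndarray    # (T, n_modes)
    valid: np.ndarray     # (T,) bool
    fps: float


def project_frames(stack: np.ndarray, selection: PixelSelection,
                   basis: PCABasis, valid: np.ndarray | None = None,
                   fps: float = 100.0) -> PosturalModes:
    """Centered projections of each frame's selected Radon pixels.

    Refuses geometry mismatches (sinogram shape or pixel selection differing
    from what the basis was fitted on); invalid frames yield masked rows.
    """
    X = np.asarray(stack, dtype=float)
    if X.shape[1:] != tuple(selection.sinogram_shape):
        raise ValueError("sinogram geometry does not match the pixel selection")
    if basis.geometry_hash and basis.geometry_hash != _geometry_hash(selection):
        raise ValueError("pixel selection does not match the basis geometry")
    flat = X.reshape(X.shape[0], -1)[:, selection.indices]
    series = (flat - basis.mean) @ basis.components.T
    if valid is None:
        valid = np.ones(len(series), dtype=bool)
    series = np.where(valid[:, None], series, 0.0)
    return PosturalModes(series=series, valid=np.asarray(valid, dtype=bool), fps=fps)
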