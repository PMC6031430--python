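"""Segmentation, size normalization and rigid alignment of fly-centered frames.

The fly is outlined by Canny edge detection plus morphological dilation and
filled to a single mask; a per-fly rescaling factor equalizes body-pixel
counts against a reference (body pixels split from legs/wings by a
two-component Gaussian mixture over foreground intensities); rotational
alignment maximizes the angular cross-correlation of polar Fourier-transform
magnitudes against a common reference, and translational alignment maximizes
the spatial cross-correlation. Frames that cannot be segmented (blank, or
fly touching the border) are flagged invalid and excluded downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.transform import rescale as _sk_rescale
from skimage.transform import rotate as _sk_rotate
from skimage.transform import warp_polar
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)

#: polar-grid resolution of the rotational alignment (degrees per bin)
ANGULAR_BIN_DEG = 1.0


@dataclass
class FrameStack:
    """Time-ordered fly-centered grayscale frames with validity flags."""

    frames: np.ndarray        # (T, H, W) float
    valid: np.ndarray         # (T,) bool
    fps: float
    scale_factor: float = 1.0


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_fly(frame: np.ndarray, canny_sigma: float = 1.5,
                low_quantile: float = 0.1, high_quantile: float = 0.3,
                dilation_radius: int = 3, border_invalid: bool = True):
    """Mask of the fly: filled interior of the dilated Canny edge map.

    Returns ``(mask, valid)``. Thresholds are set per frame from gradient
    quantiles. Frames with no closed contour, or where the fly touches the
    image border (partially out of frame), are flagged invalid with an
    empty mask. Multiple similar-size components keep the largest (warned).
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_fly expects a single grayscale frame")
    if np.ptp(img) < 1e-12:
        return np.zeros_like(img, dtype=bool), False
    gmax = ndimage.sobel(img, 0) ** 2 + ndimage.sobel(img, 1) ** 2
    gmax = np.sqrt(gmax).max()
    edges = canny(img, sigma=canny_sigma, low_threshold=low_quantile * gmax,
                  high_threshold=high_quantile * gmax)
    closed = ndimage.binary_dilation(edges, structure=disk(dilation_radius))
    filled = ndimage.binary_fill_holes(closed)
    labels, n = ndimage.label(filled)
    if n == 0:
        return np.zeros_like(img, dtype=bool), False
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    if n > 1 and np.sort(sizes)[-2] > 0.5 * sizes.max():
        log.warning("multiple similar-size components; keeping the largest")
    mask = labels == (1 + int(np.argmax(sizes)))
    # erode back so the mask hugs the outline the dilation closed; one size
    # smaller than the dilation so thin appendages survive
    if dilation_radius > 1:
        mask = ndimage.binary_erosion(mask, structure=disk(dilation_radius - 1))
    if border_invalid:
        # the edge detector is blind in a border strip as wide as the
        # dilation, so "touching" means reaching into that strip
        b = 2 * dilation_radius
        touches = (mask[:b].any() or mask[-b:].any() or
                   mask[:, :b].any() or mask[:, -b:].any())
        if touches:
            return np.zeros_like(mask), False
    return mask, True


# ---------------------------------------------------------------------------
# size normalization
# ---------------------------------------------------------------------------

def estimate_body_area(frames: np.ndarray, masks: np.ndarray,
                       min_frames: int = 100, seed: int = 0,
                       mean_separation: float = 10.0) -> float:
    """Mean body-pixel count over a sample of segmented frames.

    Foreground intensities of each frame are split by a two-component
    Gaussian mixture; the brighter component is the body (head, thorax,
    abdomen), the dimmer one legs and wings. If the mixture degenerates
    (components indistinguishable) the frame falls back to an Otsu split,
    and to the full foreground area when even that fails.
    """
    frames = np.asarray(frames)
    masks = np.asarray(masks, dtype=bool)
    if len(frames) < min_frames:
        raise ValueError(f"need at least {min_frames} segmented frames "
                         f"(got {len(frames)})")
    areas = []
    for img, mask in zip(frames, masks):
        vals = np.asarray(img, dtype=float)[mask]
        if vals.size == 0:
            continue
        gm = GaussianMixture(n_components=2, random_state=seed, n_init=1)
        gm.fit(vals.reshape(-1, 1))
        means = gm.means_.ravel()
        if abs(means[0] - means[1]) < mean_separation:
            log.warning("degenerate intensity mixture; falling back to Otsu split")
            try:
                thr = threshold_otsu(vals)
                body = (vals > thr).sum()
                if body == 0 or np.ptp(vals) < 1e-9:
                    body = vals.size
            except ValueError:
                body = vals.size
            areas.append(body)
            continue
        body_comp = int(np.argmax(means))
        areas.append(int((gm.predict(vals.reshape(-1, 1)) == body_comp).sum()))
    if not areas:
        raise ValueError("no usable frames for body-area estimation")
    return float(np.mean(areas))


def rescale_frame(frame: np.ndarray, body_area: float,
                  reference_area: float) -> tuple[np.ndarray, float]:
    """Uniformly rescale so the fly's body-pixel count matches the reference.

    The linear factor is sqrt(reference_area / body_area); output is
    center-cropped or zero-padded back to the input shape.
    """
    if body_area <= 0 or reference_area <= 0:
        raise ValueError("areas must be positive")
    factor = float(np.sqrt(reference_area / body_area))
    if abs(factor - 1.0) < 1e-12:
        return np.asarray(frame, dtype=float), 1.0
    out = _sk_rescale(np.asarray(frame, dtype=float), factor, order=1,
                      preserve_range=True, anti_aliasing=factor < 1)
    H, W = frame.shape
    h, w = out.shape
    canvas = np.zeros((H, W), dtype=float)
    # center-align the rescaled image on the original canvas
    r0, c0 = (h - H) // 2, (w - W) // 2
    rr = slice(max(r0, 0), max(r0, 0) + min(h, H))
    cc = slice(max(c0, 0), max(c0, 0) + min(w, W))
    tr = slice((H - min(h, H)) // 2, (H - min(h, H)) // 2 + min(h, H))
    tc = slice((W - min(w, W)) // 2, (W - min(w, W)) // 2 + min(w, W))
    canvas[tr, tc] = out[rr, cc]
    return canvas, factor


# ---------------------------------------------------------------------------
# rotational and translational alignment
# ---------------------------------------------------------------------------

def _polar_spectrum(frame: np.ndarray, n_angles: int) -> np.ndarray:
    """Angular x radial log-magnitude of the centered 2D Fourier transform.

    Log compression keeps high-frequency structure from being swamped by
    the DC-adjacent peak, which sharpens the angular correlation by an
    order of magnitude.
    """
    F = np.log1p(np.fft.fftshift(np.abs(np.fft.fft2(frame))))
    radius = min(frame.shape) // 2
    return warp_polar(F, radius=radius, output_shape=(n_angles, radius))


def align_rotation(frame: np.ndarray, reference: np.ndarray,
                   n_angles: int = 360, resolve_head_up: bool = True):
    """Rotation angle (degrees) aligning ``frame`` to the common reference.

    The angle maximizes the angular cross-correlation of the polar Fourier
    magnitudes. Because the magnitude spectrum is 180-degree symmetric the
    peak is ambiguous up to a half turn; of the two candidates the one
    placing more mask mass in the image's top half is chosen (synthetic
    flies are rendered head-up). Returns ``(angle, rotated_frame, valid)``.
    """
    f = np.asarray(frame, dtype=float)
    r = np.asarray(reference, dtype=float)
    if f.shape != r.shape:
        raise ValueError("frame and reference must share a shape")
    if np.ptp(f) < 1e-12:
        return 0.0, f, False
    pf = _polar_spectrum(f, n_angles)
    pr = _polar_spectrum(r, n_angles)
    # circular cross-correlation along the angular axis, summed over radius
    X = np.fft.fft(pf - pf.mean(axis=0), axis=0)
    Y = np.fft.fft(pr - pr.mean(axis=0), axis=0)
    corr = np.real(np.fft.ifft(np.conj(X) * Y, axis=0)).sum(axis=1)
    shift_bins = int(np.argmax(corr))
    # quadratic interpolation of the correlation peak for sub-bin precision
    c0 = corr[(shift_bins - 1) % n_angles]
    c1 = corr[shift_bins]
    c2 = corr[(shift_bins + 1) % n_angles]
    denom = c0 - 2 * c1 + c2
    frac = 0.5 * (c0 - c2) / denom if abs(denom) > 1e-12 else 0.0
    angle = (shift_bins + np.clip(frac, -0.5, 0.5)) * (360.0 / n_angles)
    candidates = [angle % 360.0, (angle + 180.0) % 360.0]
    best = candidates[0]
    if resolve_head_up:
        masses = []
        for a in candidates:
            rot = _sk_rotate(f, -a, preserve_range=True)
            H = rot.shape[0]
            masses.append(rot[: H // 2].sum())
        best = candidates[int(np.argmax(masses))]
    rotated = _sk_rotate(f, -best, preserve_range=True)
    return best, rotated, True


def align_translation(frame: np.ndarray, reference: np.ndarray):
    """Integer-pixel shift maximizing the spatial cross-correlation.

    Returns ``(dx, dy, shifted_frame)`` with (dx, dy) the displacement of
    the frame relative to the reference (row, column convention).
    """
    f = np.asarray(frame, dtype=float)
    r = np.asarray(reference, dtype=float)
    if f.shape != r.shape:
        raise ValueError("frame and reference must share a shape")
    F = np.fft.fft2(f - f.mean())
    R = np.fft.fft2(r - r.mean())
    corr = np.real(np.fft.ifft2(F * np.conj(R)))
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    shifts = []
    for p, n in zip(peak, f.shape):
        shifts.append(p - n if p > n // 2 else p)
    dx, dy = int(shifts[0]), int(shifts[1])
    shifted = np.roll(f, (-dx, -dy), axis=(0, 1))
    return dx, dy, shifted


# ---------------------------------------------------------------------------
# whole-stack preparation
# ---------------------------------------------------------------------------

def prepare_stack(frames: np.ndarray, fps: float,
                  reference: np.ndarray | None = None,
                  reference_area: float | None = None,
                  sample_size: int = 100, seed: int = 0) -> FrameStack:
    """Segment, rescale and align a raw stack into canonical form.

    The reference frame defaults to the first segmentable frame; masked
    (background-suppressed) frames are aligned rotationally then
    translationally against it. Invalid frames propagate as gaps.
    """
    frames = np.asarray(frames, dtype=float)
    T = len(frames)
    masks = np.zeros(frames.shape, dtype=bool)
    valid = np.zeros(T, dtype=bool)
    for t in range(T):
        masks[t], valid[t] = segment_fly(frames[t])
    if not valid.any():
        return FrameStack(frames=np.zeros_like(frames), valid=valid, fps=fps)

    rng = np.random.default_rng(seed)
    vi = np.flatnonzero(valid)
    sample = rng.choice(vi, size=min(sample_size, len(vi)), replace=len(vi) < sample_size)
    body_area = estimate_body_area(frames[sample], masks[sample],
                                   min_frames=min(sample_size, len(sample)), seed=seed)
    scale = 1.0
    masked = np.where(masks, frames, 0.0)
    if reference_area is not None:
        rescaled = np.zeros_like(masked)
        for t in vi:
            rescaled[t], scale = rescale_frame(masked[t], body_area, reference_area)
        masked = rescaled

    ref = masked[vi[0]] if reference is None else np.asarray(reference, dtype=float)
    out = np.zeros_like(masked)
    for t in vi:
        angle, rot, ok = align_rotation(masked[t], ref)
        if not ok:
            valid[t] = False
            continue
        _, _, out[t] = align_translation(rot, ref)
    return FrameStack(frames=out, valid=valid, fps=fps, scale_factor=scale)
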