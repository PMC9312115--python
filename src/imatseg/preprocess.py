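"""Preprocessing: receive-bias correction, anatomy cropping, normalization.

The receive coil's spatial sensitivity (B1-) multiplies every echo image by
a smooth field.  ``correct_receiver_bias`` estimates that field from the
echo-summed image with a robust log-domain polynomial fit and divides it
out -- a self-contained stand-in for external N4-style tools, with the same
contract (smooth multiplicative field, mean 1 over the foreground, applied
per slice).  ``crop_and_resize`` finds the anatomy with a Canny edge
detector and crops/resizes to the network input size; ``normalize_input``
clips at a high percentile and z-scores, exactly as maps are fed to the
networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import feature, filters, measure, morphology, transform

from .acquisition import EchoSeries


@dataclass
class PreprocessReport:
    """Record of what was actually applied, for reproducibility."""

    crop_bbox: tuple | None = None          # (row0, col0, row1, col1), half-open
    clip_value: float | None = None
    normalization: tuple | None = None      # (mean, std)
    bias_degree: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _poly_design(h: int, w: int, degree: int) -> np.ndarray:
    y, x = np.mgrid[0:h, 0:w]
    u = 2.0 * x / max(w - 1, 1) - 1.0
    v = 2.0 * y / max(h - 1, 1) - 1.0
    cols = []
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            cols.append((u ** i) * (v ** j))
    return np.stack(cols, axis=-1)  # (h, w, n_terms)


def _kmeans_1d(values: np.ndarray, k: int, n_iter: int = 15) -> np.ndarray:
    """Deterministic 1-D k-means (quantile init); returns labels."""
    centers = np.percentile(values, np.linspace(10, 90, k))
    for _ in range(n_iter):
        lab = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        for j in range(k):
            if (lab == j).any():
                centers[j] = values[lab == j].mean()
    return np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)


def estimate_bias_field(
    image: np.ndarray,
    foreground: np.ndarray | None = None,
    degree: int = 3,
    n_iter: int = 20,
    n_classes: int = 3,
) -> np.ndarray:
    """Smooth multiplicative field under ``image``, mean 1 over foreground.

    Log-domain model: ``log I = poly(x, y) + offset(class) + noise``.  The
    shared low-order polynomial is the gain field; per-pixel tissue classes
    (``n_classes`` levels, 1-D k-means on the field-compensated
    log-intensity) absorb tissue contrast, so the bright subcutaneous-fat
    ring does not masquerade as a radial gain pattern.  Class assignment and
    a Tukey-reweighted least-squares fit alternate for ``n_iter`` rounds.
    """
    img = np.asarray(image, dtype=np.float64)
    if foreground is None:
        pos = img[img > 0]
        if pos.size == 0:
            thr = 0.0
        elif np.ptp(pos) == 0:
            thr = pos[0]          # constant foreground: Otsu undefined
        else:
            thr = filters.threshold_otsu(pos)
        foreground = img > 0.1 * thr
    fg = foreground & (img > 0)
    if fg.sum() < 32:
        raise ValueError("too few foreground pixels to estimate a bias field")

    design = _poly_design(*img.shape, degree)
    A = design[fg]                                   # (n, terms)
    b = np.log(img[fg])
    n, nt = A.shape
    field_log = np.zeros(n)
    wts = np.ones(n)
    coef = np.zeros(nt)
    for _ in range(n_iter):
        classes = _kmeans_1d(b - field_log, n_classes)
        # one-hot offsets for classes 1..k-1 (class 0 folds into the
        # polynomial's constant term)
        X = np.concatenate(
            [A] + [(classes == j).astype(float)[:, None]
                   for j in range(1, n_classes)], axis=1,
        )
        Xw = X * wts[:, None]
        beta, *_ = np.linalg.lstsq(Xw, b * wts, rcond=None)
        r = b - X @ beta
        s = 1.4826 * np.median(np.abs(r - np.median(r))) + 1e-12
        t = r / (4.685 * s)
        wts = np.where(np.abs(t) < 1, (1 - t ** 2) ** 2, 0.0)
        coef = beta[:nt]
        field_log = A @ coef
    field = np.exp(design @ coef)
    field = field / field[fg].mean()
    return field


def correct_receiver_bias(
    series: EchoSeries,
    degree: int = 3,
    n_iter: int = 20,
    field: np.ndarray | None = None,
) -> tuple[EchoSeries, np.ndarray]:
    """Divide a smooth receive-field estimate out of every echo.

    The field is estimated from the echo-summed image (see
    ``estimate_bias_field``) and normalized to mean 1 over the foreground so
    the global intensity scale is preserved.  ``field`` substitutes an
    externally computed field (e.g. from an N4 implementation) while keeping
    the same normalization and division contract.
    """
    data = series.data
    if np.any(data < 0):
        raise ValueError("magnitude inputs must be non-negative")
    summed = data.sum(axis=2)
    if not np.any(summed > 0):
        raise ValueError("all-zero input series")
    if field is None:
        field = estimate_bias_field(summed, degree=degree, n_iter=n_iter)
    else:
        pos = summed[summed > 0]
        thr = pos[0] if np.ptp(pos) == 0 else filters.threshold_otsu(pos)
        fg = summed > 0.1 * thr
        field = np.asarray(field, dtype=np.float64)
        field = field / field[fg].mean()
    corrected = data / field[..., None]
    return EchoSeries(corrected, series.protocol), field


def find_anatomy_mask(image: np.ndarray, closing_size: int = 5) -> np.ndarray:
    """Foreground anatomy via Canny edges, closing, hole fill, largest CC."""
    img = np.asarray(image, dtype=np.float64)
    rng = img.max() - img.min()
    if rng == 0:
        raise ValueError("no foreground found (constant image)")
    norm = (img - img.min()) / rng
    edges = feature.canny(norm, sigma=2.0)
    closed = morphology.closing(
        edges, morphology.footprint_rectangle((closing_size, closing_size))
    )
    filled = ndimage.binary_fill_holes(closed)
    lab = measure.label(filled)
    if lab.max() == 0:
        raise ValueError("no foreground found")
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (1 + np.argmax(sizes))


def crop_and_resize(
    stack: np.ndarray,
    out_size: int = 128,
    margin: int = 2,
    nearest_channels: tuple = (),
) -> tuple[np.ndarray, tuple]:
    """Crop the anatomy bounding box (+margin) and resize to out_size^2.

    ``stack`` is (H, W) or (H, W, C); edge detection runs on the first
    channel.  Channels listed in ``nearest_channels`` (e.g. masks) are
    resized with nearest-neighbor, all others bilinearly.  Returns the
    resized stack and the half-open crop bbox (row0, col0, row1, col1).
    """
    arr = np.asarray(stack, dtype=np.float64)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[..., None]
    mask = find_anatomy_mask(arr[..., 0])
    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    r0 = max(0, rows[0] - margin)
    r1 = min(arr.shape[0], rows[-1] + 1 + margin)
    c0 = max(0, cols[0] - margin)
    c1 = min(arr.shape[1], cols[-1] + 1 + margin)
    bbox = (int(r0), int(c0), int(r1), int(c1))

    out = np.empty((out_size, out_size, arr.shape[2]))
    for ch in range(arr.shape[2]):
        order = 0 if ch in nearest_channels else 1
        out[..., ch] = transform.resize(
            arr[r0:r1, c0:c1, ch], (out_size, out_size), order=order,
            mode="edge", anti_aliasing=False, preserve_range=True,
        )
    return (out[..., 0] if squeeze else out), bbox


def normalize_input(
    image: np.ndarray, clip_percentile: float = 98.0
) -> tuple[np.ndarray, float, float, float]:
    """Clip above the given percentile, then z-score.

    Returns (normalized image, clip_value, mean, std); the constants are the
    ones actually applied.  The percentile is computed over the whole image
    including background.  A zero-variance image is rejected.
    """
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    clip_value = float(np.percentile(img, clip_percentile))
    clipped = np.minimum(img, clip_value)
    mean = float(clipped.mean())
    std = float(clipped.std())
    if std == 0:
        raise ValueError("zero variance after clipping; cannot normalize")
    return (clipped - mean) / std, clip_value, mean, std
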