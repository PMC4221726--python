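"""Cell-center extraction: thresholded non-maximum suppression and baselines.

A detected center is a pixel that exceeds a response threshold and is at
least as large as every pixel in its (2*half+1)^2 neighborhood; plateau
ties are resolved by keeping only the lexicographically smallest (row, col)
of each tied group, which makes the output deterministic and guarantees a
minimum Chebyshev separation of ``window_half_width + 1`` between centers.

Two classical baselines are provided for comparison with the sliding-band
detector: Laplacian-of-Gaussian blob detection and dark-object intensity
thresholding with connected-component centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .filters import FilterParams, ResponseMap, filter_image, normalize_image

__all__ = [
    "NMSParams",
    "DetectionResult",
    "non_max_suppression",
    "detect_cells",
    "detect_cells_log_baseline",
    "detect_cells_threshold_baseline",
]

THRESHOLD_MODES = ("absolute", "mean_plus_k_std", "fraction_of_max")


@dataclass(frozen=True)
class NMSParams:
    """Non-maximum-suppression window and response threshold.

    ``window_half_width=None`` defers to the detector, which uses the
    minimum cell radius ``r_min`` (window side ``2*r_min + 1``): two maxima
    closer than one minimum cell radius cannot be distinct cells.  The
    default threshold is ``mean + 2*std`` of the response map, which
    suppresses background maxima on noise.
    """

    window_half_width: int | None = None
    response_threshold_mode: str = "mean_plus_k_std"
    threshold_value: float = 2.0

    def __post_init__(self) -> None:
        if self.window_half_width is not None and self.window_half_width < 1:
            raise ValueError("window_half_width must be >= 1")
        if self.response_threshold_mode not in THRESHOLD_MODES:
            raise ValueError(f"threshold mode must be one of {THRESHOLD_MODES}")

    def resolve_threshold(self, values: np.ndarray) -> float:
        if self.response_threshold_mode == "absolute":
            return float(self.threshold_value)
        if self.response_threshold_mode == "mean_plus_k_std":
            return float(values.mean() + self.threshold_value * values.std())
        return float(self.threshold_value * values.max())


@dataclass(frozen=True)
class DetectionResult:
    """Detected centers (0-based integer (row, col)), sorted by score.

    ``border_flags`` marks detections whose support region was clipped at
    the image boundary.  ``count`` is the detected cell count.
    """

    centers: np.ndarray
    scores: np.ndarray
    border_flags: np.ndarray

    @property
    def count(self) -> int:
        return len(self.centers)

    def __len__(self) -> int:
        return len(self.centers)


def _result(centers: list[tuple[int, int]], scores: list[float],
            border: np.ndarray | None) -> DetectionResult:
    c = np.asarray(centers, dtype=int).reshape(-1, 2)
    s = np.asarray(scores, dtype=float)
    order = np.lexsort((c[:, 1], c[:, 0], -s)) if len(c) else np.array([], int)
    c, s = c[order], s[order]
    if border is None:
        flags = np.zeros(len(c), dtype=bool)
    else:
        flags = border[c[:, 0], c[:, 1]] if len(c) else np.zeros(0, bool)
    return DetectionResult(centers=c, scores=s, border_flags=flags)


def non_max_suppression(response: ResponseMap | np.ndarray,
                        params: NMSParams = NMSParams()) -> DetectionResult:
    """Extract local maxima of a response map above threshold.

    A pixel is kept iff its value is strictly above the resolved threshold,
    is >= every value in its window, and no equal-valued pixel with a
    lexicographically smaller (row, col) lies in its window.
    """
    if isinstance(response, ResponseMap):
        values = response.values
        border = response.border_mask()
    else:
        values = np.asarray(response, dtype=float)
        border = None
    if not np.all(np.isfinite(values)):
        raise ValueError("response map contains non-finite values")
    half = params.window_half_width
    if half is None:
        raise ValueError("window_half_width unresolved; set it or use detect_cells")
    thr = params.resolve_threshold(values)
    side = 2 * half + 1
    maxf = ndi.maximum_filter(values, size=side, mode="constant", cval=-np.inf)
    cand = np.argwhere((values >= maxf) & (values > thr))  # row-major = lex order
    H, W = values.shape
    centers, scores = [], []
    for r, c in cand:
        v = values[r, c]
        win = values[max(0, r - half): r + half + 1, max(0, c - half): c + half + 1]
        eq = np.argwhere(win == v)
        eq[:, 0] += max(0, r - half)
        eq[:, 1] += max(0, c - half)
        smaller = (eq[:, 0] < r) | ((eq[:, 0] == r) & (eq[:, 1] < c))
        if not smaller.any():
            centers.append((int(r), int(c)))
            scores.append(float(v))
    return _result(centers, scores, border)


def _resolve_nms(nms: NMSParams, r_min: int) -> NMSParams:
    if nms.window_half_width is None:
        return replace(nms, window_half_width=int(r_min))
    return nms


def detect_cells(image: np.ndarray,
                 filter_params: FilterParams = FilterParams(),
                 nms_params: NMSParams = NMSParams(),
                 smoothing_sigma: float = 1.0) -> DetectionResult:
    """Full sliding-band pipeline: TSBF enhancement then non-max suppression."""
    resp = filter_image(image, filter_params, kind="TSBF",
                        smoothing_sigma=smoothing_sigma)
    return non_max_suppression(resp, _resolve_nms(nms_params, filter_params.r_min))


def detect_cells_log_baseline(image: np.ndarray, sigma: float,
                              nms_params: NMSParams = NMSParams(),
                              window_half_width: int = 8) -> DetectionResult:
    """Laplacian-of-Gaussian blob baseline passed through the same NMS.

    The sign is chosen so that the (relatively bright) cell interior of the
    bright-field ring model — and a bright dark-field blob — produce maxima
    at the cell center.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    img = normalize_image(image)
    resp = -ndi.gaussian_laplace(img, sigma, mode="nearest")
    return non_max_suppression(resp, _resolve_nms(nms_params, window_half_width))


def detect_cells_threshold_baseline(image: np.ndarray,
                                    threshold: float) -> DetectionResult:
    """Intensity-threshold baseline: dark-object binarization + centroids.

    Pixels below ``threshold`` (dark membrane convention for bright field)
    are grouped into 8-connected components; each component's centroid,
    rounded to the nearest pixel, is reported as a center with the
    component size as its score.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    img = normalize_image(image)
    mask = img < threshold
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return _result([], [], None)
    coms = ndi.center_of_mass(mask, labels, index=np.arange(1, n + 1))
    sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    centers = [(int(round(r)), int(round(c))) for r, c in np.atleast_2d(coms)]
    return _result(centers, [float(s) for s in sizes], None)
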