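"""Convergence-index filter family: CI, SBF and TSBF responses.

The convergence index (CI) at a candidate center is the mean, over a
support region, of ``cos(alpha)`` where ``alpha`` is the angle between the
image gradient at a support pixel and the direction from that pixel toward
the center.  The sliding band filter (SBF) restricts the support to a band
of fixed radial width that slides along each of ``n_lines`` radial rays to
maximize the per-ray band-average convergence.  The transformed SBF (TSBF)
replaces the signed cosine with ``omega * |cos| * |grad|`` so that both the
convergent inner edge and the divergent outer edge of a bright-field cell
membrane reinforce the response at the cell center; its output is
consequently non-negative and scales linearly with image contrast.

All rays are sampled at integer radii with nearest-pixel rounding (no
interpolation); band samples falling outside the image, or at radius < 1,
are dropped and the band mean renormalized over the remaining samples.  A
band with no valid sample is skipped; a ray with no valid band contributes
0 to the outer mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "FilterParams",
    "GradientField",
    "ResponseMap",
    "compute_gradient",
    "convergence_index",
    "sbf_response",
    "tsbf_response",
    "filter_image",
    "ray_offsets",
    "normalize_image",
]

FILTER_KINDS = ("CI", "SBF", "TSBF")


@dataclass(frozen=True)
class FilterParams:
    """Geometry and weighting of the sliding-band support region.

    Parameters
    ----------
    r_min, r_max : int
        Minimum / maximum radius (pixels) of the band-center position along
        each ray; chosen so the support covers the smallest and largest
        expected cell radius.
    n_lines : int
        Number of radial support rays, evenly spaced over 2*pi.
    band_width : int
        Radial width of the sliding band, in samples (the width of the cell
        edge in pixels).
    omega : float
        Global gradient-magnitude weight of the TSBF score (unitless).
    """

    r_min: int = 8
    r_max: int = 30
    n_lines: int = 32
    band_width: int = 6
    omega: float = 1.0

    def __post_init__(self) -> None:
        if int(self.r_min) != self.r_min or self.r_min < 1:
            raise ValueError("r_min must be an integer >= 1")
        if int(self.r_max) != self.r_max or self.r_max <= self.r_min:
            raise ValueError("r_max must be an integer > r_min")
        if int(self.n_lines) != self.n_lines or self.n_lines < 4:
            raise ValueError("n_lines must be an integer >= 4")
        if int(self.band_width) != self.band_width or self.band_width < 1:
            raise ValueError("band_width must be an integer >= 1")
        if self.band_width > self.r_max - self.r_min + 1:
            raise ValueError("band_width must be <= r_max - r_min + 1")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")

    @property
    def band_before(self) -> int:
        """Samples of the band strictly before its center radius."""
        return self.band_width // 2

    @property
    def band_after(self) -> int:
        """Samples of the band at/after its center radius (center included)."""
        return self.band_width - self.band_width // 2

    @property
    def support_radius(self) -> int:
        """Largest sampled radius: r_max + ceil(band_width/2) - 1."""
        return self.r_max + self.band_after - 1

    @property
    def border_margin(self) -> int:
        """Pixels closer than this to an edge use a clipped support region."""
        return self.r_max + (self.band_width + 1) // 2


@dataclass(frozen=True)
class GradientField:
    """Per-pixel image gradient: column/row components, magnitude, angle.

    ``angle`` is ``atan2(gy, gx)``; by convention it is 0 (and every
    cosine term involving it contributes 0) wherever the magnitude is 0.
    """

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    angle: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.gx.shape


@dataclass(frozen=True)
class ResponseMap:
    """Filter response aligned pixel-for-pixel with the source image.

    ``border_margin`` marks the frame of pixels whose support region was
    clipped at the image boundary (``border_mask`` returns it as a boolean
    image).  CI and SBF values lie in [-1, 1]; TSBF values are >= 0.
    """

    values: np.ndarray
    filter_kind: str
    params: FilterParams
    border_margin: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def border_mask(self) -> np.ndarray:
        m = self.border_margin
        mask = np.zeros(self.values.shape, dtype=bool)
        if m > 0:
            mask[:m, :] = True
            mask[-m:, :] = True
            mask[:, :m] = True
            mask[:, -m:] = True
        return mask


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Rescale an intensity image to float64 in [0, 1].

    Integer dtypes are divided by their dtype range; float inputs are
    min-max scaled (a constant float image maps to all zeros).
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel 2D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return (arr.astype(np.float64) - info.min) / (info.max - info.min)
    arr = arr.astype(np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    lo, hi = arr.min(), arr.max()
    if 0.0 <= lo and hi <= 1.0:
        return arr
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def compute_gradient(image: np.ndarray, smoothing_sigma: float = 1.0) -> GradientField:
    """Central-difference gradient of an optionally Gaussian-smoothed image.

    Borders are handled by edge replication.  ``gx`` is the column
    derivative, ``gy`` the row derivative, in intensity units per pixel.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be 2D and at least 3x3")
    if smoothing_sigma < 0:
        raise ValueError("smoothing_sigma must be >= 0")
    if smoothing_sigma > 0:
        img = ndi.gaussian_filter(img, smoothing_sigma, mode="nearest")
    p = np.pad(img, 1, mode="edge")
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    mag = np.hypot(gx, gy)
    ang = np.where(mag > 0, np.arctan2(gy, gx), 0.0)
    return GradientField(gx=gx, gy=gy, magnitude=mag, angle=ang)


def _cos_toward(grad: GradientField, rows: np.ndarray, cols: np.ndarray,
                center: tuple[float, float]) -> np.ndarray:
    """cos(angle between gradient at (rows, cols) and direction toward center).

    Zero wherever the gradient magnitude is zero or the sample coincides
    with the center.
    """
    vr = center[0] - rows
    vc = center[1] - cols
    vnorm = np.hypot(vr, vc)
    g = grad.magnitude[rows, cols]
    dot = grad.gx[rows, cols] * vc + grad.gy[rows, cols] * vr
    denom = g * vnorm
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 0, dot / denom, 0.0)
    return cos


def convergence_index(grad: GradientField,
                      center: tuple[int, int],
                      support: Iterable[tuple[int, int]]) -> float:
    """Mean gradient convergence over an arbitrary support region.

    Returns ``(1/|support|) * sum cos(alpha_p)`` with ``alpha_p`` the angle
    between the gradient at support pixel ``p`` and the direction from
    ``p`` toward ``center``; result lies in [-1, 1].
    """
    pts = np.atleast_2d(np.asarray(list(support), dtype=int))
    if pts.size == 0:
        raise ValueError("support region must be non-empty")
    rows, cols = pts[:, 0], pts[:, 1]
    H, W = grad.shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= H or cols.max() >= W:
        raise ValueError("support pixels must lie inside the image")
    return float(np.mean(_cos_toward(grad, rows, cols, center)))


def ray_offsets(params: FilterParams) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                               np.ndarray, np.ndarray]:
    """Integer pixel offsets of every (ray, radius) support sample.

    Returns ``(radii, dr, dc, ur, uc)``: ``radii`` the sampled radii
    (those >= 1 in ``[r_min - band_width//2, r_max + ceil(band_width/2) - 1]``),
    ``dr``/``dc`` of shape (n_lines, n_radii) the rounded row/column offsets
    from the filter center, and ``ur``/``uc`` the unit vector components
    pointing from each sample back toward the center.  Ray ``i`` points at
    angle ``2*pi*i/n_lines``.  The same table is shared by the point
    evaluators and the full-image filter so they agree bit-for-bit.
    """
    rad_lo = max(1, params.r_min - params.band_before)
    radii = np.arange(rad_lo, params.support_radius + 1)
    ang = 2.0 * np.pi * np.arange(params.n_lines) / params.n_lines
    dr = np.round(radii[None, :] * np.sin(ang)[:, None]).astype(int)
    dc = np.round(radii[None, :] * np.cos(ang)[:, None]).astype(int)
    norm = np.hypot(dr, dc)
    ur = -dr / norm
    uc = -dc / norm
    return radii, dr, dc, ur, uc


def _band_slices(params: FilterParams, radii: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs into ``radii`` for each band-center radius."""
    out = []
    for r in range(params.r_min, params.r_max + 1):
        lo = max(int(radii[0]), r - params.band_before)
        hi = r + params.band_after - 1
        out.append((lo - int(radii[0]), hi - int(radii[0]) + 1))
    return out


def _point_sample_scores(grad: GradientField, center: tuple[int, int],
                         params: FilterParams, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-(ray, radius) sample scores and validity at one candidate center."""
    radii, dr, dc, ur, uc = ray_offsets(params)
    H, W = grad.shape
    r0, c0 = int(center[0]), int(center[1])
    rr = r0 + dr
    cc = c0 + dc
    valid = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
    rs = np.clip(rr, 0, H - 1)
    cs = np.clip(cc, 0, W - 1)
    gxs = grad.gx[rs, cs]
    gys = grad.gy[rs, cs]
    mag = grad.magnitude[rs, cs]
    dot = gxs * uc + gys * ur
    if kind == "TSBF":
        score = params.omega * np.abs(dot)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(mag > 0, dot / mag, 0.0)
    return np.where(valid, score, np.nan), valid


def _band_line_means(scores: np.ndarray, params: FilterParams,
                     radii: np.ndarray) -> np.ndarray:
    """Per-ray maximum over band positions of the clipped-band mean."""
    n_lines = scores.shape[0]
    line_best = np.full(n_lines, -np.inf)
    for lo, hi in _band_slices(params, radii):
        band = scores[:, lo:hi]
        cnt = np.sum(~np.isnan(band), axis=1)
        s = np.nansum(band, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(cnt > 0, s / np.maximum(cnt, 1), -np.inf)
        line_best = np.maximum(line_best, mean)
    return np.where(np.isfinite(line_best), line_best, 0.0)


def sbf_response(grad: GradientField, center: tuple[int, int],
                 params: FilterParams) -> float:
    """Sliding-band-filter response at one candidate center, in [-1, 1].

    For each ray, a band of ``band_width`` consecutive radial samples slides
    with its center radius in ``[r_min, r_max]``; the band score is the mean
    convergence cosine over its (in-image) samples and each ray contributes
    its best band.  The response is the mean over rays.
    """
    scores, _ = _point_sample_scores(grad, center, params, "SBF")
    radii = ray_offsets(params)[0]
    return float(np.mean(_band_line_means(scores, params, radii)))


def tsbf_response(grad: GradientField, center: tuple[int, int],
                  params: FilterParams) -> float:
    """Transformed-SBF response at one candidate center (>= 0 for omega >= 0).

    Same band geometry as :func:`sbf_response`, but each sample scores
    ``omega * |cos(alpha)| * |grad|`` so membrane convergence and divergence
    both reinforce the cell-center response.
    """
    scores, _ = _point_sample_scores(grad, center, params, "TSBF")
    radii = ray_offsets(params)[0]
    return float(np.mean(_band_line_means(scores, params, radii)))


def filter_image(image: np.ndarray, params: FilterParams = FilterParams(),
                 kind: str = "TSBF", smoothing_sigma: float = 1.0) -> ResponseMap:
    """Apply CI (annular support), SBF or TSBF at every pixel of an image.

    ``kind='CI'`` uses the full annulus ``r_min <= r <= r_max`` as support;
    ``'SBF'``/``'TSBF'`` use the sliding band.  Pixels within
    ``params.border_margin`` of an edge are computed on the clipped support
    and flagged via the returned map's ``border_mask``.  Deterministic, and
    bit-identical to the per-pixel point evaluators.
    """
    arr = np.asarray(image)
    if np.issubdtype(arr.dtype, np.integer):
        img = normalize_image(arr)
    else:
        img = arr.astype(np.float64)
        if img.ndim != 2 or not np.all(np.isfinite(img)):
            raise ValueError("image must be a finite 2D array")
    if kind not in FILTER_KINDS:
        raise ValueError(f"kind must be one of {FILTER_KINDS}")
    H, W = img.shape
    need = 2 * (params.r_max + params.band_width)
    if H < need or W < need:
        raise ValueError(
            f"image {H}x{W} too small for support region (need >= {need} per side)")
    grad = compute_gradient(img, smoothing_sigma)
    radii, dr, dc, ur, uc = ray_offsets(params)
    m = int(radii[-1])
    pgx = np.pad(grad.gx, m, mode="constant", constant_values=np.nan)
    pgy = np.pad(grad.gy, m, mode="constant", constant_values=np.nan)

    n_rad = len(radii)
    bands = _band_slices(params, radii)
    ann_lo = int(np.searchsorted(radii, params.r_min))
    ann_hi = int(np.searchsorted(radii, params.r_max, side="right"))

    acc = np.zeros((H, W))
    ci_cnt = np.zeros((H, W)) if kind == "CI" else None
    S = np.empty((n_rad, H, W))
    valid = np.empty((n_rad, H, W), dtype=bool)
    for i in range(params.n_lines):
        for k in range(n_rad):
            gxs = pgx[m + dr[i, k]: m + dr[i, k] + H, m + dc[i, k]: m + dc[i, k] + W]
            gys = pgy[m + dr[i, k]: m + dr[i, k] + H, m + dc[i, k]: m + dc[i, k] + W]
            valid[k] = ~np.isnan(gxs)
            dot = gxs * uc[i, k] + gys * ur[i, k]
            if kind == "TSBF":
                S[k] = params.omega * np.abs(dot)
            else:
                mag = np.hypot(gxs, gys)
                with np.errstate(invalid="ignore", divide="ignore"):
                    S[k] = np.where(mag > 0, dot / mag, 0.0)
        sz = np.where(valid, S, 0.0)
        if kind == "CI":
            acc += sz[ann_lo:ann_hi].sum(axis=0)
            ci_cnt += valid[ann_lo:ann_hi].sum(axis=0)
        else:
            csum = np.concatenate([np.zeros((1, H, W)), np.cumsum(sz, axis=0)])
            ccnt = np.concatenate([np.zeros((1, H, W)),
                                   np.cumsum(valid, axis=0)])
            line_best = np.full((H, W), -np.inf)
            for lo, hi in bands:
                cnt = ccnt[hi] - ccnt[lo]
                s = csum[hi] - csum[lo]
                with np.errstate(invalid="ignore", divide="ignore"):
                    mean = np.where(cnt > 0, s / np.maximum(cnt, 1), -np.inf)
                line_best = np.maximum(line_best, mean)
            acc += np.where(np.isfinite(line_best), line_best, 0.0)
    if kind == "CI":
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(ci_cnt > 0, acc / np.maximum(ci_cnt, 1), 0.0)
    else:
        values = acc / params.n_lines
    return ResponseMap(values=values, filter_kind=kind, params=params,
                       border_margin=min(params.border_margin, H // 2, W // 2))
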