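"""Spatio-temporal cross-cumulant (SOFI) images of orders 2-4.

A blinking emitter produces correlated intensity fluctuations in all camera
pixels covered by its PSF.  The joint zero-time-lag cumulant of *n* pixel
traces is assigned to the centroid of the contributing pixels, which yields a
virtual grid *n* times finer than the camera grid and a PSF sharpened by
sqrt(n).  Combinations of distinct pixels are preferred because the joint
cumulant of distinct pixels is free of shot-noise bias; the amplitude lost to
pixel separation is undone by the Gaussian distance factor
``exp(-sum_i |r_i - c|^2 / (2 sigma^2))``.

Photobleaching is mitigated by splitting the sequence into short blocks
(default 500 frames), mean-subtracting each pixel trace per block, and
averaging the per-block cumulant images.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .stack_io import ImageSequence

__all__ = [
    "CumulantSet",
    "BsofiImage",
    "split_blocks",
    "joint_cumulant",
    "cross_cumulant_image",
    "aggregate_blocks",
    "compute_cumulants",
    "linearize",
]

UPSAMPLING = 4  # common output grid is the 4th-order virtual grid


@dataclass
class CumulantSet:
    """2nd/3rd/4th-order cumulant rasters resampled onto the 4x grid.

    ``pitch_nm`` is the virtual-grid pitch, i.e. camera pitch / 4.
    """

    g2: np.ndarray
    g3: np.ndarray
    g4: np.ndarray
    pitch_nm: float
    n_blocks: int
    block_len: int

    def __post_init__(self) -> None:
        if not (self.g2.shape == self.g3.shape == self.g4.shape):
            raise ValueError("g2, g3, g4 must share a common grid")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")


@dataclass
class BsofiImage:
    """Linearized cumulant image used as a background transparency mask."""

    values: np.ndarray
    order_used: int


def split_blocks(seq: ImageSequence, block_len: int = 500) -> list[ImageSequence]:
    """Split a sequence into consecutive non-overlapping blocks.

    Blocks are kept short so that photobleaching is roughly stationary
    within each; the trailing remainder of ``T mod block_len`` frames is
    discarded.
    """
    if block_len < 2:
        raise ValueError("block_len must be >= 2")
    T = seq.n_frames
    if T < block_len:
        raise ValueError(f"sequence of {T} frames is shorter than one "
                         f"block of {block_len}")
    n = T // block_len
    return [
        ImageSequence(seq.frames[i * block_len:(i + 1) * block_len],
                      pixel_pitch_nm=seq.pixel_pitch_nm,
                      frame_time_s=seq.frame_time_s)
        for i in range(n)
    ]


def joint_cumulant(traces: np.ndarray, order: int) -> float:
    """Joint zero-time-lag cumulant of ``order`` scalar time traces.

    ``traces`` has shape (order, T).  Traces are mean-subtracted; for
    mean-free variables the joint cumulants are

    * order 2: ``E[X1 X2]``
    * order 3: ``E[X1 X2 X3]``
    * order 4: ``E[X1X2X3X4] - E[X1X2]E[X3X4] - E[X1X3]E[X2X4]
      - E[X1X4]E[X2X3]``
    """
    X = np.asarray(traces, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != order:
        raise ValueError(f"expected ({order}, T) traces, got {X.shape}")
    X = X - X.mean(axis=1, keepdims=True)
    if order == 2:
        return float(np.mean(X[0] * X[1]))
    if order == 3:
        return float(np.mean(X[0] * X[1] * X[2]))
    if order == 4:
        m = lambda i, j: np.mean(X[i] * X[j])
        return float(np.mean(X[0] * X[1] * X[2] * X[3])
                     - m(0, 1) * m(2, 3) - m(0, 2) * m(1, 3)
                     - m(0, 3) * m(1, 2))
    raise ValueError("order must be in {2, 3, 4}")


# ---------------------------------------------------------------------------
# pixel-combination selection


@lru_cache(maxsize=32)
def _phase_combinations(order: int, sigma_px: float, n_combos: int = 4):
    """For each sub-pixel phase, the pixel-offset combinations to use.

    The virtual node of phase ``(a, b)`` sits at camera coordinate
    ``(y0 + a/n, x0 + b/n)``; a valid combination is ``n`` integer offsets
    summing to ``(a, b)`` (so their centroid is the node).  Among candidates
    with every pixel within ``2 sigma`` of the node, all-distinct
    combinations are preferred (shot-noise-free), then minimal spread, with
    a lexicographic tie-break for determinism.  Up to ``n_combos``
    equivalent combinations are kept per node and their distance-corrected
    cumulants averaged, which reduces estimator variance without changing
    the expectation.

    Returns a dict ``(a, b) -> list of (offsets (n, 2) int array, weight,
    distinct)`` where ``weight`` is the Gaussian distance factor the raw
    cumulant must be divided by.
    """
    n = order
    window = [(dy, dx) for dy in range(-1, 3) for dx in range(-1, 3)]
    out = {}
    for a in range(n):
        for b in range(n):
            node = np.array([a / n, b / n])
            candidates = []  # (not-distinct, spread, combo)
            fallback = []
            for combo in itertools.combinations_with_replacement(window, n):
                arr = np.asarray(combo, dtype=np.float64)
                if arr[:, 0].sum() != a or arr[:, 1].sum() != b:
                    continue
                d2 = ((arr - node) ** 2).sum(axis=1)
                distinct = len(set(combo)) == n
                key = (not distinct, float(d2.sum()), combo)
                fallback.append(key)
                if np.sqrt(d2.max()) > 2.0 * sigma_px:
                    continue
                candidates.append(key)
            if not candidates:
                # PSF too narrow for any off-node combination: fall back to
                # minimal spread regardless of the 2-sigma restriction
                candidates = sorted(fallback)[:1]
            else:
                candidates = sorted(candidates)[:n_combos]
                # never mix repeated-pixel combos in with distinct ones:
                # their shot-noise bias would contaminate the average
                if not candidates[0][0]:
                    candidates = [c for c in candidates if not c[0]]
            entries = []
            for not_distinct, spread, combo in candidates:
                weight = float(np.exp(-spread / (2.0 * sigma_px ** 2)))
                entries.append((np.asarray(combo, dtype=np.int64), weight,
                                not not_distinct))
            out[(a, b)] = entries
    return out


def cross_cumulant_image(block: ImageSequence, order: int,
                         psf_sigma_nm: float) -> np.ndarray:
    """Order-``n`` cross-cumulant image of one block on the n-fold grid.

    Per-pixel traces are mean-subtracted over the block before cumulant
    evaluation.  The returned raster has shape ``(n*H, n*W)``; a border of
    camera pixels (where the pixel combinations would leave the field) is
    zero.
    """
    if order not in (2, 3, 4):
        raise ValueError("order must be in {2, 3, 4}")
    if psf_sigma_nm <= 0:
        raise ValueError("psf_sigma_nm must be positive")
    if block.n_frames < 2:
        raise ValueError("block must contain at least 2 frames")
    sigma_px = psf_sigma_nm / block.pixel_pitch_nm
    combos = _phase_combinations(order, round(sigma_px, 9))

    X = block.frames - block.frames.mean(axis=0)
    T, H, W = X.shape
    all_offsets = np.concatenate([offs for entries in combos.values()
                                  for offs, _, _ in entries])
    lo = int(max(0, -all_offsets.min()))
    hi = int(max(0, all_offsets.max()))
    if H - lo - hi <= 0 or W - lo - hi <= 0:
        raise ValueError("field too small for the cumulant pixel combinations")

    out = np.zeros((order * H, order * W))
    for (a, b), entries in combos.items():
        acc = 0.0
        wsum = 0.0
        for offsets, weight, _ in entries:
            tr = [X[:, lo + oy:H - hi + oy, lo + ox:W - hi + ox]
                  for oy, ox in offsets]
            if order == 2:
                cum = np.mean(tr[0] * tr[1], axis=0)
            elif order == 3:
                cum = np.mean(tr[0] * tr[1] * tr[2], axis=0)
            else:
                m01 = np.mean(tr[0] * tr[1], axis=0)
                m23 = np.mean(tr[2] * tr[3], axis=0)
                m02 = np.mean(tr[0] * tr[2], axis=0)
                m13 = np.mean(tr[1] * tr[3], axis=0)
                m03 = np.mean(tr[0] * tr[3], axis=0)
                m12 = np.mean(tr[1] * tr[2], axis=0)
                cum = (np.mean(tr[0] * tr[1] * tr[2] * tr[3], axis=0)
                       - m01 * m23 - m02 * m13 - m03 * m12)
            # inverse-variance average: the corrected estimate cum/weight has
            # noise amplified by 1/weight, so each term enters with weight^2
            acc = acc + weight * cum
            wsum += weight ** 2
        out[order * lo + a:order * (H - hi) + a:order,
            order * lo + b:order * (W - hi) + b:order] = acc / wsum
    return out


def _resample_to_common(raster: np.ndarray, order: int) -> np.ndarray:
    """Bilinearly resample an order-n raster onto the 4x virtual grid.

    Both grids share the camera origin: order-n index ``k`` sits at camera
    coordinate ``k/n``, so the 4x node ``j`` maps to source index ``j*n/4``.
    """
    if order == UPSAMPLING:
        return raster
    h, w = raster.shape
    H, W = h * UPSAMPLING // order, w * UPSAMPLING // order
    jj, ii = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    coords = np.stack([jj * order / UPSAMPLING, ii * order / UPSAMPLING])
    return ndimage.map_coordinates(raster, coords, order=1, mode="nearest")


def aggregate_blocks(per_block: dict[int, list[np.ndarray]],
                     pixel_pitch_nm: float, block_len: int) -> CumulantSet:
    """Average per-block cumulant images and assemble a :class:`CumulantSet`.

    Each order is averaged arithmetically across blocks, then the native
    2x/3x rasters are resampled onto the common 4x grid.  Negative values in
    the aggregated g2 are pure estimation noise and are clamped at zero;
    g3 and g4 keep their signs for the density inversion.
    """
    means = {}
    n_blocks = None
    for order in (2, 3, 4):
        rasters = per_block.get(order)
        if not rasters:
            raise ValueError(f"no blocks supplied for order {order}")
        shapes = {r.shape for r in rasters}
        if len(shapes) != 1:
            raise ValueError(f"order {order}: inconsistent raster shapes {shapes}")
        if n_blocks is None:
            n_blocks = len(rasters)
        mean = np.mean(rasters, axis=0)
        means[order] = _resample_to_common(mean, order)
    g2 = np.clip(means[2], 0.0, None)
    return CumulantSet(g2=g2, g3=means[3], g4=means[4],
                       pitch_nm=pixel_pitch_nm / UPSAMPLING,
                       n_blocks=n_blocks, block_len=block_len)


def compute_cumulants(seq: ImageSequence, psf_sigma_nm: float,
                      block_len: int = 500) -> CumulantSet:
    """Convenience wrapper: block, cumulate orders 2-4, aggregate."""
    blocks = split_blocks(seq, block_len)
    per_block = {order: [cross_cumulant_image(b, order, psf_sigma_nm)
                         for b in blocks]
                 for order in (2, 3, 4)}
    return aggregate_blocks(per_block, seq.pixel_pitch_nm, block_len)


def linearize(cumulant: np.ndarray, order: int) -> BsofiImage:
    """Magnitude linearization ``|c|^(1/n)`` of a cumulant raster.

    The n-th root makes the image amplitude proportional to emitter
    brightness rather than brightness^n, which evens out the dynamic range
    so the image can serve as a transparency mask.
    """
    if order not in (2, 3, 4):
        raise ValueError("order must be in {2, 3, 4}")
    return BsofiImage(values=np.abs(cumulant) ** (1.0 / order),
                      order_used=order)
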