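"""Threshold-free quantification of high-density regions (HDRs).

Rather than segmenting at a single user-chosen density cut-off, the map is
segmented at every threshold on a grid spanning the full range of densities
present (thresholds are expressed as multiples of the ROI mean density
delta_avg).  Per-threshold region statistics form curves whose shape
characterizes the clustering behaviour; the working threshold is then picked
automatically as the point where a Gaussian fitted to the number-of-regions
curve — the signature of randomly scattered molecules — drops below one
expected region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage import measure

from .density import DensityMap

__all__ = [
    "HDRRegion",
    "ThresholdSweep",
    "segment_hdrs",
    "sweep_thresholds",
    "select_optimal_threshold",
    "summarize",
]


@dataclass(frozen=True)
class HDRRegion:
    """One connected high-density region at a given threshold."""

    label: int
    area_px: int
    area_um2: float
    equivalent_diameter_nm: float  # diameter of the circle of equal area
    centroid_nm: tuple[float, float]  # (x, y)
    mean_density: float  # relative to delta_avg


@dataclass
class ThresholdSweep:
    """Per-threshold HDR statistics over the full density range."""

    thresholds: np.ndarray          # multiples of delta_avg
    n_regions: np.ndarray
    mean_area_px: np.ndarray        # NaN where no region
    mean_diameter_nm: np.ndarray    # NaN where no region
    relative_area: np.ndarray       # fraction of masked ROI covered
    regions_at: list[list[HDRRegion]]
    pitch_nm: float
    roi_area_px: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "n_regions": self.n_regions,
            "mean_area_px2": self.mean_area_px,
            "mean_equivalent_diameter_nm": self.mean_diameter_nm,
            "relative_area": self.relative_area,
        })

    def nearest_index(self, threshold: float) -> int:
        return int(np.argmin(np.abs(self.thresholds - threshold)))


# Regions smaller than the Nyquist-resolvable area are not reported as HDRs
# by the sweep: on the 4x grid the minimum detectable diameter is 2 px, i.e.
# an equivalent-diameter threshold of pi px^2 ~ 4 px.
NYQUIST_MIN_AREA_PX = 4


def segment_hdrs(dmap: DensityMap, threshold: float,
                 min_area_px: int = 1) -> list[HDRRegion]:
    """Connected components of masked pixels with N/delta_avg >= threshold.

    8-connectivity; with the default ``min_area_px = 1`` every component is
    reported.  The sweep passes the Nyquist limit instead so that
    sub-resolution specks do not count as detected HDRs.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    rel = dmap.relative
    sel = dmap.mask & (rel >= threshold)
    labels = measure.label(sel, connectivity=2)
    pitch = dmap.pitch_nm
    px_area_um2 = (pitch * 1e-3) ** 2
    regions = []
    for rp in measure.regionprops(labels, intensity_image=rel):
        area_px = int(rp.area)
        if area_px < min_area_px:
            continue
        eq_d_nm = 2.0 * np.sqrt(area_px / np.pi) * pitch
        cy, cx = rp.centroid
        regions.append(HDRRegion(
            label=int(rp.label),
            area_px=area_px,
            area_um2=area_px * px_area_um2,
            equivalent_diameter_nm=eq_d_nm,
            centroid_nm=(cx * pitch, cy * pitch),
            mean_density=float(rp.intensity_mean),
        ))
    return regions


def sweep_thresholds(dmap: DensityMap, t_max: float | None = None,
                     step: float = 0.1,
                     min_area_px: int = NYQUIST_MIN_AREA_PX) -> ThresholdSweep:
    """Segment at every threshold in {0, step, 2 step, ..., t_max}."""
    if step <= 0:
        raise ValueError("step must be positive")
    if t_max is None:
        t_max = float(dmap.N[dmap.mask].max() / dmap.delta_avg)
    thresholds = np.arange(0.0, t_max + step / 2.0, step)
    roi_area = int(dmap.mask.sum())
    n_regions = np.zeros(len(thresholds), dtype=int)
    mean_area = np.full(len(thresholds), np.nan)
    mean_diam = np.full(len(thresholds), np.nan)
    rel_area = np.zeros(len(thresholds))
    regions_at: list[list[HDRRegion]] = []
    for i, t in enumerate(thresholds):
        regions = segment_hdrs(dmap, float(t), min_area_px=min_area_px)
        regions_at.append(regions)
        n_regions[i] = len(regions)
        if regions:
            areas = np.array([r.area_px for r in regions], dtype=float)
            mean_area[i] = areas.mean()
            mean_diam[i] = np.mean([r.equivalent_diameter_nm for r in regions])
            rel_area[i] = areas.sum() / roi_area
    return ThresholdSweep(thresholds=thresholds, n_regions=n_regions,
                          mean_area_px=mean_area, mean_diameter_nm=mean_diam,
                          relative_area=rel_area, regions_at=regions_at,
                          pitch_nm=dmap.pitch_nm, roi_area_px=roi_area)


def _gaussian_plus_floor(t, A, m, s, c):
    return A * np.exp(-(t - m) ** 2 / (2.0 * s ** 2)) + c


def fit_region_count_gaussian(thresholds: np.ndarray, n_regions: np.ndarray
                              ) -> tuple[float, float, float, float]:
    """Fit A exp(-(t-m)^2/2s^2) + c to a number-of-regions curve.

    The Gaussian bump models the contribution of randomly scattered
    molecules; the non-negative floor ``c`` absorbs any plateau of
    persistent genuine clusters so the plateau cannot inflate the fitted
    width.  Only the peak and its descending flank are fitted: below the
    peak the count is suppressed by percolation (regions merge into the
    near-full-field component), so the ascending flank does not reflect
    the random height distribution the Gaussian models.  Residuals are
    minimized on a log scale, which keeps the fit faithful to the tail the
    threshold rule extrapolates into.

    Returns ``(A, m, s, c)``.
    """
    t = np.asarray(thresholds, dtype=float)
    y = np.asarray(n_regions, dtype=float)
    if len(t) < 4 or y.max() <= 0:
        raise ValueError("region-count curve is degenerate; cannot fit a "
                         "Gaussian (all-zero or too few thresholds)")
    step = t[1] - t[0]
    i0 = int(np.argmax(y))
    A0, m0 = y[i0], t[i0]
    if len(y) - i0 < 5:
        raise ValueError("region-count curve has no interior maximum; "
                         "cannot locate the random-distribution bump")
    # thresholds beyond the last one with >= 1 region carry no count
    # information ("falls below 1" happens at that boundary) and would only
    # destabilize the floor estimate
    nz = np.nonzero(y >= 1.0)[0]
    i1 = max(int(nz[-1]) + 1, i0 + 5) if len(nz) else len(y)
    t, y = t[:i1], y[:i1]
    c0 = float(np.median(y))
    # width seed from the right half-maximum crossing of the bump above c0
    half = c0 + (A0 - c0) / 2.0
    right = np.nonzero((t > m0) & (y <= half))[0]
    s0 = (t[right[0]] - m0) / 1.177 if len(right) else 2 * step
    s0 = max(s0, step)

    def model(tt, A, m, s, c):
        return np.log1p(_gaussian_plus_floor(tt, A, m, s, c))

    try:
        popt, _ = curve_fit(
            model, t[i0:], np.log1p(y[i0:]),
            p0=(max(A0 - c0, 1e-3), m0, s0, c0),
            bounds=([1e-6, max(t.min(), m0 - 2 * step), step / 2.0, 0.0],
                    [2.0 * A0 + 1.0, m0 + s0, 3.0 * s0, A0 + 1.0]),
            maxfev=40000)
    except RuntimeError as exc:
        raise ValueError(
            f"Gaussian fit to the region-count curve failed: {exc}")
    A, m, s, c = (float(v) for v in popt)
    return A, m, s, c


def select_threshold_from_curve(thresholds: np.ndarray,
                                n_regions: np.ndarray) -> float:
    """Threshold where the fitted random-distribution Gaussian falls below 1.

    The continuous crossing is ``m + s sqrt(2 ln A)``; the returned value
    is the smallest threshold on the sweep grid at which the fitted
    Gaussian is strictly below one region.  If the fitted amplitude never
    exceeds one region, the centre m itself is returned.
    """
    A, m, s, _ = fit_region_count_gaussian(thresholds, n_regions)
    if A <= 1.0:
        return float(m)
    t = np.asarray(thresholds, dtype=float)
    step = t[1] - t[0]
    t_cross = m + s * np.sqrt(2.0 * np.log(A))
    # snap up: first grid threshold with G(t) < 1
    return float(np.ceil(t_cross / step) * step)


def select_optimal_threshold(sweep: ThresholdSweep) -> float:
    """Automatic threshold separating random scatter from genuine HDRs."""
    return select_threshold_from_curve(sweep.thresholds, sweep.n_regions)


def summarize(sweeps: dict[str, list[ThresholdSweep]],
              at: float) -> pd.DataFrame:
    """Box-plot statistics per group at the threshold nearest to ``at``.

    For each group: median, IQR bounds, min and max of the per-sample
    number of regions, mean HDR area, mean equivalent diameter and relative
    occupied area.
    """
    rows = []
    for group, group_sweeps in sweeps.items():
        if not group_sweeps:
            raise ValueError(f"group {group!r} is empty")
        metrics: dict[str, list[float]] = {
            "n_regions": [], "mean_area_px2": [],
            "equivalent_diameter_nm": [], "relative_area": [],
        }
        for sw in group_sweeps:
            i = sw.nearest_index(at)
            metrics["n_regions"].append(float(sw.n_regions[i]))
            metrics["mean_area_px2"].append(float(sw.mean_area_px[i]))
            metrics["equivalent_diameter_nm"].append(float(sw.mean_diameter_nm[i]))
            metrics["relative_area"].append(float(sw.relative_area[i]))
        for metric, values in metrics.items():
            v = np.asarray(values, dtype=float)
            rows.append({
                "group": group,
                "metric": metric,
                "threshold": at,
                "n_samples": len(v),
                "median": float(np.nanmedian(v)),
                "q1": float(np.nanpercentile(v, 25)),
                "q3": float(np.nanpercentile(v, 75)),
                "min": float(np.nanmin(v)),
                "max": float(np.nanmax(v)),
            })
    return pd.DataFrame(rows)
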