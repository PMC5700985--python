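"""Fiducial-based lateral drift correction.

Gold beads deposited on the coverslip are persistently bright, unlike the
blinking fluorophores, so candidate fiducials are pixels that stay above a
brightness threshold in nearly every frame.  Their sub-pixel positions are
tracked frame by frame, averaged into a single drift trace, and the trace is
removed by translating every frame with bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage.feature import peak_local_max

from .stack_io import ImageSequence

__all__ = [
    "FiducialTrack",
    "DriftTrace",
    "track_fiducials",
    "estimate_drift",
    "apply_correction",
]

# fraction of frames a fiducial must be bright in (beads do not blink)
PERSISTENCE = 0.95
_WINDOW = 7  # centroid refinement window (px), odd


@dataclass
class FiducialTrack:
    """Per-frame sub-pixel (x, y) positions and peak intensity of one bead."""

    positions: np.ndarray  # (T, 2) as (x, y) in px
    intensity: np.ndarray  # (T,) peak counts

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (T, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class DriftTrace:
    """Per-frame (dx, dy) displacement in px relative to frame 0."""

    displacements: np.ndarray  # (T, 2) as (dx, dy)

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.displacements.ndim != 2 or self.displacements.shape[1] != 2:
            raise ValueError("displacements must be (T, 2)")
        if not np.allclose(self.displacements[0], 0.0, atol=1e-9):
            raise ValueError("displacement of frame 0 must be (0, 0)")

    def __len__(self) -> int:
        return self.displacements.shape[0]


def _centroid(frame: np.ndarray, y: float, x: float) -> tuple[float, float, float]:
    """Background-subtracted centroid in a window centred on the local peak."""
    H, W = frame.shape
    h = _WINDOW // 2
    yi = int(round(y))
    xi = int(round(x))
    yi = min(max(yi, h), H - h - 1)
    xi = min(max(xi, h), W - h - 1)
    win = frame[yi - h:yi + h + 1, xi - h:xi + h + 1]
    # subtract the window minimum so diffuse background does not pull the
    # centroid toward the window centre
    w = win - win.min()
    total = w.sum()
    if total <= 0:
        return float(x), float(y), float(win.max())
    ys, xs = np.mgrid[-h:h + 1, -h:h + 1]
    cy = yi + float((w * ys).sum() / total)
    cx = xi + float((w * xs).sum() / total)
    return cx, cy, float(win.max())


def track_fiducials(seq: ImageSequence, min_brightness: float) -> list[FiducialTrack]:
    """Detect and track immobile bright beads through the whole sequence.

    Candidates are local maxima of an early-frame average (before drift has
    accumulated).  Each candidate is followed frame by frame with a 7x7
    centroid window, and only tracks whose peak stays above
    ``min_brightness`` in at least 95% of frames are kept — blinking
    fluorophores fail this persistence test, gold beads do not.
    """
    frames = seq.frames
    T = frames.shape[0]
    ref = frames[:min(T, 20)].mean(axis=0)
    peaks = peak_local_max(ref, min_distance=_WINDOW,
                           threshold_abs=min_brightness,
                           exclude_border=_WINDOW // 2)
    tracks = []
    for py, px in peaks:
        pos = np.empty((T, 2))
        inten = np.empty(T)
        y, x = float(py), float(px)
        for t in range(T):
            x, y, peak = _centroid(frames[t], y, x)
            pos[t] = (x, y)
            inten[t] = peak
        if (inten > min_brightness).mean() >= PERSISTENCE:
            tracks.append(FiducialTrack(pos, inten))
    if not tracks:
        raise ValueError(
            "no persistent fiducial found; skip drift correction for this "
            "sequence or lower min_brightness")
    return tracks


def estimate_drift(tracks: list[FiducialTrack], smooth_window: int = 51) -> DriftTrace:
    """Average the per-bead displacements into one smoothed drift trace.

    The per-frame displacement is the mean over tracks of ``position_t -
    position_0``, smoothed by a moving average to suppress localization
    jitter without distorting slow mechanical drift.  Mirror boundary
    handling keeps linear drift unbiased at the sequence ends.
    """
    if not tracks:
        raise ValueError("at least one fiducial track is required")
    T = len(tracks[0])
    if any(len(t) != T for t in tracks):
        raise ValueError("all tracks must cover the same number of frames")
    disp = np.mean([t.positions - t.positions[0] for t in tracks], axis=0)
    if smooth_window > 1:
        window = min(smooth_window, len(disp))
        # polyorder-1 Savitzky-Golay is a moving average in the interior but
        # fits a line in the edge windows, so linear drift stays unbiased at
        # the sequence ends
        disp = signal.savgol_filter(disp, window_length=window, polyorder=1,
                                    axis=0, mode="interp")
    disp = disp - disp[0]
    return DriftTrace(disp)


def apply_correction(seq: ImageSequence, drift: DriftTrace) -> ImageSequence:
    """Translate each frame by minus its drift via bilinear interpolation.

    Pixels shifted in from outside the field are set to 0.  A zero trace
    returns a bit-identical copy; integer shifts are lossless away from the
    borders.
    """
    if len(drift) != seq.n_frames:
        raise ValueError(
            f"drift trace length {len(drift)} != sequence length {seq.n_frames}")
    out = np.empty_like(seq.frames)
    for t in range(seq.n_frames):
        dx, dy = drift.displacements[t]
        if dx == 0.0 and dy == 0.0:
            out[t] = seq.frames[t]
        else:
            # ndimage.shift displaces content by +shift along each axis
            out[t] = ndimage.shift(seq.frames[t], shift=(-dy, -dx), order=1,
                                   mode="constant", cval=0.0, prefilter=False)
    np.clip(out, 0.0, None, out=out)
    return ImageSequence(out, pixel_pitch_nm=seq.pixel_pitch_nm,
                         frame_time_s=seq.frame_time_s)
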