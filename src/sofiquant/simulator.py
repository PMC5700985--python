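"""Synthetic TIRF sequences of blinking fluorophores with known ground truth.

The generator emulates a PALM-style acquisition of a fixed membrane: a
ground-truth object of circular high-density regions (HDRs) on a sparse
random background, photoactivatable emitters with Markovian on/off blinking
and irreversible bleaching, Gaussian-PSF rendering onto an EMCCD camera with
Poisson photoelectron conversion, linear EM gain, offset and Gaussian read
noise.

Default study conditions: 10 HDRs on a 3 × 3 µm field, HDR diameters in
60–180 nm, in-HDR densities 500–3000 molecules/µm², HDR-to-background
contrast in {20, 50, 100}, sequences of 5000 frames; a layout with no HDRs
serves as the random control.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

from .stack_io import AcquisitionConfig, ImageSequence

__all__ = [
    "GroundTruth",
    "PhotokineticsModel",
    "make_ground_truth",
    "simulate_traces",
    "render_sequence",
    "simulate_sequence",
    "run_scenarios",
]

FIELD_UM = 3.0
# camera pixels of margin around the ground-truth field, so that PSF tails
# and cumulant border effects do not clip molecules near the field edge
PAD_PX = 3


@dataclass(frozen=True)
class PhotokineticsModel:
    """Markov photoswitching model of a photoactivatable emitter.

    Each molecule is dark until a geometric activation step, then cycles
    between an emitting on-state (geometric dwell, mean ``mean_on_frames``)
    and a dark off-state (mean ``mean_off_frames``), and bleaches
    irreversibly from the on-state.  Photon emission per on-frame is
    Poissonian with mean ``brightness_photons_per_frame``.

    Defaults emulate sparse mEos2-like traces at 32 ms exposure.
    """

    mean_on_frames: float = 2.0
    mean_off_frames: float = 20.0
    activation_rate_per_frame: float = 0.0005
    bleach_prob_per_on_frame: float = 0.05
    brightness_photons_per_frame: float = 300.0
    detection_efficiency: float = 0.9

    @property
    def rho_on(self) -> float:
        """Stationary on-time ratio of the on/off cycle (ignoring bleaching)."""
        return self.mean_on_frames / (self.mean_on_frames + self.mean_off_frames)

    def __post_init__(self) -> None:
        if self.mean_on_frames < 1 or self.mean_off_frames < 1:
            raise ValueError("mean dwell times must be >= 1 frame")
        for name in ("activation_rate_per_frame", "bleach_prob_per_on_frame",
                     "detection_efficiency"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.brightness_photons_per_frame < 0:
            raise ValueError("brightness must be non-negative")


@dataclass
class GroundTruth:
    """Molecule positions and the HDR layout they were drawn from."""

    molecule_xy_nm: np.ndarray        # (M, 2) positions, nm
    hdr_specs: list[tuple[tuple[float, float], float, float]]
    # [(center_xy_nm, diameter_nm, density_per_um2), ...]
    background_density_per_um2: float
    field_um: float
    seed: int
    molecule_hdr_id: np.ndarray = field(default=None)  # -1 = background

    @property
    def n_molecules(self) -> int:
        return self.molecule_xy_nm.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_nm": self.molecule_xy_nm[:, 0],
            "y_nm": self.molecule_xy_nm[:, 1],
            "hdr_id": self.molecule_hdr_id,
        })


def make_ground_truth(n_hdrs: int = 10,
                      diameter_nm: float | tuple[float, float] = (60.0, 180.0),
                      hdr_density_per_um2: float | tuple[float, float] = (500.0, 3000.0),
                      contrast: float = 100.0,
                      seed: int = 0,
                      field_um: float = FIELD_UM,
                      background_density_per_um2: float | None = None,
                      max_retries: int = 10000) -> GroundTruth:
    """Draw an HDR layout and populate it with molecules.

    HDR centres are uniform over the field with a margin of one radius so
    no disk crosses the border; overlapping draws are rejected and redrawn.
    Molecule counts are Poisson (density × disk area) per HDR; background
    molecules are Poisson with density ``hdr_density / contrast`` placed
    uniformly between the HDRs.  ``n_hdrs = 0`` gives the random control;
    ``background_density_per_um2`` overrides the contrast-derived background
    density, e.g. to build a control matched in total molecule count to a
    clustered scenario.
    """
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    rng = np.random.default_rng(seed)
    field_nm = field_um * 1000.0

    def draw(value, name):
        if np.isscalar(value):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
            return float(value)
        lo, hi = value
        return float(rng.uniform(lo, hi))

    # place non-overlapping disks
    specs: list[tuple[tuple[float, float], float, float]] = []
    placed: list[tuple[float, float, float]] = []  # (x, y, r)
    for _ in range(n_hdrs):
        d = draw(diameter_nm, "diameter_nm")
        dens = draw(hdr_density_per_um2, "hdr_density_per_um2")
        r = d / 2.0
        if 2 * r >= field_nm:
            raise ValueError("HDR diameter exceeds the field")
        for attempt in range(max_retries):
            x = rng.uniform(r, field_nm - r)
            y = rng.uniform(r, field_nm - r)
            if all((x - px) ** 2 + (y - py) ** 2 >= (r + pr) ** 2
                   for px, py, pr in placed):
                placed.append((x, y, r))
                specs.append(((x, y), d, dens))
                break
        else:
            raise RuntimeError(f"could not place {n_hdrs} non-overlapping "
                               f"HDRs after {max_retries} retries")

    xs, ys, ids = [], [], []
    mean_hdr_density = None
    for i, ((cx, cy), d, dens) in enumerate(specs):
        r_um = d / 2000.0
        n = rng.poisson(dens * np.pi * r_um ** 2)
        # uniform in the disk
        phi = rng.uniform(0, 2 * np.pi, n)
        rad = (d / 2.0) * np.sqrt(rng.uniform(0, 1, n))
        xs.append(cx + rad * np.cos(phi))
        ys.append(cy + rad * np.sin(phi))
        ids.append(np.full(n, i))
    if specs:
        mean_hdr_density = float(np.mean([s[2] for s in specs]))
    else:
        mean_hdr_density = draw(hdr_density_per_um2, "hdr_density_per_um2")

    bg_density = (background_density_per_um2 if background_density_per_um2
                  is not None else mean_hdr_density / contrast)
    hdr_area_um2 = sum(np.pi * (d / 2000.0) ** 2 for _, d, _ in specs)
    outside_area = field_um ** 2 - hdr_area_um2
    n_bg = rng.poisson(bg_density * outside_area)
    bx, by = [], []
    while len(bx) < n_bg:
        x = rng.uniform(0, field_nm)
        y = rng.uniform(0, field_nm)
        if all((x - px) ** 2 + (y - py) ** 2 >= pr ** 2
               for px, py, pr in placed):
            bx.append(x)
            by.append(y)
    xs.append(np.asarray(bx))
    ys.append(np.asarray(by))
    ids.append(np.full(len(bx), -1))

    xy = np.column_stack([np.concatenate(xs), np.concatenate(ys)])
    return GroundTruth(molecule_xy_nm=xy, hdr_specs=specs,
                       background_density_per_um2=bg_density,
                       field_um=field_um, seed=seed,
                       molecule_hdr_id=np.concatenate(ids).astype(int))


def simulate_traces(n_molecules: int, T: int, model: PhotokineticsModel,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Photon time traces, shape (n_molecules, T).

    Each molecule stays inactive for a geometric number of frames, switches
    on, then alternates geometric on/off dwells; every on-frame it bleaches
    with fixed probability (irreversibly) and emits a Poisson number of
    photons.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    photons = np.zeros((n_molecules, T))
    p_on_end = 1.0 / model.mean_on_frames
    p_off_end = 1.0 / model.mean_off_frames
    act = model.activation_rate_per_frame
    bleach = model.bleach_prob_per_on_frame
    for i in range(n_molecules):
        t = int(rng.geometric(act)) - 1 if act > 0 else 0
        on = True
        while t < T:
            if on:
                dwell = int(rng.geometric(p_on_end))
                if bleach > 0:
                    to_bleach = int(rng.geometric(bleach))
                    bleaches = to_bleach <= dwell
                    dwell = min(dwell, to_bleach)
                else:
                    bleaches = False
                end = min(t + dwell, T)
                if model.brightness_photons_per_frame > 0 and end > t:
                    photons[i, t:end] = rng.poisson(
                        model.brightness_photons_per_frame, end - t)
                if bleaches:
                    break
                t = end
                on = False
            else:
                t += int(rng.geometric(p_off_end))
                on = True
    return photons


def _pixel_gaussian(centers_px: np.ndarray, sigma_px: float,
                    shape: tuple[int, int]) -> list[tuple[slice, slice, np.ndarray]]:
    """Pixel-integrated Gaussian footprint of each molecule.

    Returns per molecule a (row-slice, col-slice, weights) triple; weights
    integrate the PSF over each pixel via error functions and sum to ~1
    inside a ±4σ window.
    """
    H, W = shape
    half = int(np.ceil(4.0 * sigma_px))
    s2 = sigma_px * np.sqrt(2.0)
    out = []
    for cx, cy in centers_px:
        x0 = int(np.floor(cx)) - half
        y0 = int(np.floor(cy)) - half
        x1 = x0 + 2 * half + 1
        y1 = y0 + 2 * half + 1
        x0c, y0c = max(x0, 0), max(y0, 0)
        x1c, y1c = min(x1, W), min(y1, H)
        if x0c >= x1c or y0c >= y1c:
            out.append((slice(0, 0), slice(0, 0), np.zeros((0, 0))))
            continue
        ex = np.arange(x0c, x1c + 1) - 0.5  # pixel edges (centres at integers)
        ey = np.arange(y0c, y1c + 1) - 0.5
        fx = 0.5 * (erf((ex[1:] - cx) / s2) - erf((ex[:-1] - cx) / s2))
        fy = 0.5 * (erf((ey[1:] - cy) / s2) - erf((ey[:-1] - cy) / s2))
        out.append((slice(y0c, y1c), slice(x0c, x1c), np.outer(fy, fx)))
    return out


def render_sequence(gt: GroundTruth, traces: np.ndarray,
                    optics: AcquisitionConfig,
                    seed: int | np.random.Generator = 0,
                    detection_efficiency: float = 1.0,
                    pad_px: int = PAD_PX) -> ImageSequence:
    """Render photon traces through the camera model into an image sequence.

    Per frame: photon rates are splatted through a pixel-integrated
    Gaussian PSF onto the camera grid (which extends ``pad_px`` pixels
    beyond the ground-truth field on every side); photoelectrons are
    Poisson(rate × detection efficiency); raw counts are
    ``counts_per_pe × pe + offset + N(0, read_noise)``, rounded and
    clipped to 16 bits.  The returned sequence holds the photoelectron
    counts recovered by the linear camera inversion, as
    :func:`sofiquant.stack_io.read_stack` would produce.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if traces.shape[0] != gt.n_molecules:
        raise ValueError("traces must cover all molecules")
    pitch = optics.pixel_pitch_nm
    field_nm = gt.field_um * 1000.0
    n_field = int(np.ceil(field_nm / pitch))
    H = W = n_field + 2 * pad_px
    sigma_px = optics.psf_sigma_nm / pitch
    centers_px = (gt.molecule_xy_nm + pad_px * pitch) / pitch
    footprints = _pixel_gaussian(centers_px, sigma_px, (H, W))

    T = traces.shape[1]
    frames = np.empty((T, H, W))
    for t in range(T):
        rate = np.zeros((H, W))
        for i in np.nonzero(traces[:, t])[0]:
            ys, xs, w = footprints[i]
            rate[ys, xs] += traces[i, t] * w
        frames[t] = rng.poisson(rate * detection_efficiency)
    raw = frames * optics.counts_per_pe + optics.offset_counts
    raw += rng.normal(0.0, optics.read_noise_counts, raw.shape)
    raw = np.clip(np.rint(raw), 0, 65535)
    pe_counts = np.clip((raw - optics.offset_counts) / optics.counts_per_pe,
                        0, None)
    return ImageSequence(pe_counts, pixel_pitch_nm=pitch,
                         frame_time_s=optics.frame_time_s)


def simulate_sequence(gt: GroundTruth, T: int, model: PhotokineticsModel,
                      optics: AcquisitionConfig, seed: int = 0,
                      pad_px: int = PAD_PX) -> ImageSequence:
    """Ground truth → traces → rendered sequence with one master seed."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB11F)))
    traces = simulate_traces(gt.n_molecules, T, model, rng)
    return render_sequence(gt, traces, optics, rng,
                           detection_efficiency=model.detection_efficiency,
                           pad_px=pad_px)


def run_scenarios(out_dir: str | Path,
                  diameters_nm: list[float],
                  densities_per_um2: list[float],
                  contrasts: list[float],
                  layouts: list[int] | None = None,
                  replicates: int = 1,
                  T: int = 5000,
                  model: PhotokineticsModel | None = None,
                  optics: AcquisitionConfig | None = None,
                  seed: int = 0) -> pd.DataFrame:
    """Generate the Cartesian product of scenario parameters to disk.

    ``layouts`` is a list of HDR counts (e.g. ``[10, 0]`` for clustered +
    random control).  Every scenario gets a deterministic seed derived from
    the master seed, a ``stack.tif``, a ``truth.csv`` and a manifest row.
    """
    from . import stack_io  # local import to avoid a cycle at module load

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = model or PhotokineticsModel()
    optics = optics or AcquisitionConfig()
    layouts = [10] if layouts is None else layouts
    rows = []
    combos = list(itertools.product(diameters_nm, densities_per_um2,
                                    contrasts, layouts, range(replicates)))
    for idx, (d, dens, c, n_hdrs, rep) in enumerate(combos):
        scen_seed = int(np.random.SeedSequence((seed, idx)).generate_state(1)[0]
                        % (2 ** 31))
        gt = make_ground_truth(n_hdrs=n_hdrs, diameter_nm=d,
                               hdr_density_per_um2=dens, contrast=c,
                               seed=scen_seed)
        seq = simulate_sequence(gt, T, model, optics, seed=scen_seed)
        stem = f"scenario_{idx:04d}"
        stack_io.write_stack(out_dir / f"{stem}_stack.tif", seq, optics)
        gt.to_frame().to_csv(out_dir / f"{stem}_truth.csv", index=False)
        rows.append({
            "scenario": stem, "diameter_nm": d, "density_per_um2": dens,
            "contrast": c, "n_hdrs": n_hdrs, "replicate": rep,
            "seed": scen_seed, "n_frames": T,
            "stack": f"{stem}_stack.tif", "truth": f"{stem}_truth.csv",
        })
    manifest = pd.DataFrame(rows, columns=[
        "scenario", "diameter_nm", "density_per_um2", "contrast", "n_hdrs",
        "replicate", "seed", "n_frames", "stack", "truth"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
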