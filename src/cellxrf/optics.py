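"""Holographic multi-trap generation and optical-stability tracking.

Gerchberg-Saxton phase retrieval alternates between the SLM plane (unit
amplitude, free phase) and the focal plane (target amplitude at the trap
sites, free phase), connected by a discrete Fourier transform.  The
returned phase is wrapped to [0, 2pi); efficiency (fraction of focal
power inside 3x3 windows at the targets) and uniformity (min/max trap
power) are recorded per iteration.

Stability tracking follows the four-points-of-interest scheme: templates
are cut from frame 0 around each point (two on the organism, one on the
capillary wall, one on the laser spot), located in every later frame by
normalized cross-correlation with quadratic sub-pixel peak interpolation,
and summarised as mean absolute deviation and sd per axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from skimage.feature import match_template

logger = logging.getLogger(__name__)

__all__ = [
    "TrapTargets",
    "PhaseHologram",
    "ROISpec",
    "TrackResult",
    "gerchberg_saxton",
    "propagate",
    "add_fresnel_lens",
    "track_stability",
]


@dataclass(frozen=True)
class TrapTargets:
    """Desired trap positions in the focal plane.

    Offsets are given in um and converted to focal-plane pixels through
    the hologram geometry: one focal pixel spans lambda * f / (N * pitch).
    Defaults describe a 1070 nm trapping laser, 2 mm effective focal
    length and a 20 um SLM pixel pitch.
    """

    offsets_um: Tuple[Tuple[float, float], ...]
    slm_shape: Tuple[int, int] = (256, 256)
    wavelength_nm: float = 1070.0
    focal_length_mm: float = 2.0
    pixel_pitch_um: float = 20.0
    weights: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if len(self.offsets_um) < 1:
            raise ValueError("need at least one trap target")
        if self.weights is not None and len(self.weights) != len(self.offsets_um):
            raise ValueError("one weight per target required")

    @property
    def focal_pixel_um(self) -> float:
        n = self.slm_shape[0]
        return (self.wavelength_nm * 1e-3 * self.focal_length_mm * 1e3
                / (n * self.pixel_pitch_um))

    def target_pixels(self) -> np.ndarray:
        """Integer (row, col) focal-plane pixels relative to the DC pixel."""
        scale = self.focal_pixel_um
        px = np.rint(np.asarray(self.offsets_um, dtype=float) / scale).astype(int)
        n_r, n_c = self.slm_shape
        if np.any(np.abs(px[:, 0]) >= n_r // 2) or np.any(np.abs(px[:, 1]) >= n_c // 2):
            raise ValueError("trap target outside the Nyquist field of view")
        return px


@dataclass
class PhaseHologram:
    """SLM phase mask in [0, 2pi) plus convergence metrics."""

    phase: np.ndarray
    n_iter: int
    efficiency: float
    uniformity: float
    efficiency_history: List[float] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phase.ndim != 2:
            raise ValueError("phase must be 2-D")
        if np.any(self.phase < 0) or np.any(self.phase >= 2 * np.pi):
            raise ValueError("phase must be wrapped to [0, 2pi)")


def propagate(phase: np.ndarray) -> np.ndarray:
    """Focal intensity |DFT(exp(i*phase))|^2 with the DC term centred.

    Uses the orthonormal DFT so total focal power equals total pupil
    power (Parseval).
    """
    field_slm = np.exp(1j * np.asarray(phase, dtype=float))
    focal = np.fft.fftshift(np.fft.fft2(field_slm, norm="ortho"))
    return np.abs(focal) ** 2


def _trap_powers(intensity: np.ndarray, targets_px: np.ndarray) -> np.ndarray:
    """Power inside a 3x3 window at each target (DC-centred intensity)."""
    n_r, n_c = intensity.shape
    c_r, c_c = n_r // 2, n_c // 2
    powers = np.empty(len(targets_px))
    for i, (dr, dc) in enumerate(targets_px):
        r, c = c_r + dr, c_c + dc
        powers[i] = intensity[r - 1:r + 2, c - 1:c + 2].sum()
    return powers


def gerchberg_saxton(targets: TrapTargets, n_iter: int = 30,
                     seed: int = 0) -> PhaseHologram:
    """Iterative Fourier-transform phase retrieval for a trap array.

    Starts from a random phase drawn from ``seed`` (except for a single
    on-axis target, whose known optimum is the flat phase) and alternates
    amplitude constraints between pupil and focal plane for ``n_iter``
    rounds.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n_r, n_c = targets.slm_shape
    px = targets.target_pixels()
    weights = (np.asarray(targets.weights, dtype=float)
               if targets.weights is not None else np.ones(len(px)))
    amp = np.sqrt(weights / weights.sum())
    target_amp = np.zeros((n_r, n_c))
    rows = (px[:, 0] + n_r // 2) % n_r
    cols = (px[:, 1] + n_c // 2) % n_c
    target_amp[rows, cols] = amp

    rng = np.random.default_rng(seed)
    single_on_axis = len(px) == 1 and np.all(px == 0)
    if single_on_axis:
        phase = np.zeros((n_r, n_c))
    else:
        phase = rng.uniform(0.0, 2 * np.pi, size=(n_r, n_c))

    history: List[float] = []
    total_power = float(n_r * n_c) / (n_r * n_c)  # ortho norm: pupil power = 1
    for _ in range(n_iter):
        pupil = np.exp(1j * phase)
        focal = np.fft.fftshift(np.fft.fft2(pupil, norm="ortho"))
        intensity = np.abs(focal) ** 2
        history.append(float(_trap_powers(intensity, px).sum()
                             / intensity.sum()))
        constrained = target_amp * np.exp(1j * np.angle(focal))
        back = np.fft.ifft2(np.fft.ifftshift(constrained), norm="ortho")
        phase = np.angle(back)
    phase = np.mod(phase, 2 * np.pi)

    intensity = propagate(phase)
    powers = _trap_powers(intensity, px)
    efficiency = float(powers.sum() / intensity.sum())
    uniformity = float(powers.min() / powers.max())
    history.append(efficiency)
    return PhaseHologram(phase, n_iter, efficiency, uniformity, history,
                         meta={"seed": seed, "targets_px": px.tolist(),
                               "total_power": total_power,
                               "weights": weights.tolist()})


def add_fresnel_lens(hologram: PhaseHologram, defocus_rad: float
                     ) -> PhaseHologram:
    """Axial trap displacement: add a quadratic (Fresnel lens) phase.

    ``defocus_rad`` is the peak-to-centre quadratic phase at the pupil
    edge; positive values push the trap downstream.
    """
    n_r, n_c = hologram.phase.shape
    r = (np.arange(n_r) - n_r / 2) / (n_r / 2)
    c = (np.arange(n_c) - n_c / 2) / (n_c / 2)
    quad = defocus_rad * (r[:, None] ** 2 + c[None, :] ** 2)
    phase = np.mod(hologram.phase + quad, 2 * np.pi)
    return PhaseHologram(phase, hologram.n_iter, hologram.efficiency,
                         hologram.uniformity,
                         list(hologram.efficiency_history),
                         meta={**hologram.meta, "defocus_rad": defocus_rad})


# ---------------------------------------------------------------------------
# stability tracking

@dataclass(frozen=True)
class ROISpec:
    """Template region around one point of interest in frame 0."""

    name: str
    center_px: Tuple[float, float]      # (row, col)
    half_size_px: int = 8
    search_half_px: int = 12


@dataclass
class TrackResult:
    """Per-frame POI positions (um) and deviation statistics."""

    positions_um: Dict[str, np.ndarray]      # name -> (n_frames, 2) (z, y)
    mad_um: Dict[str, Tuple[float, float]]   # mean absolute deviation (z, y)
    sd_um: Dict[str, Tuple[float, float]]
    relative_to_wall_sd_um: Dict[str, Tuple[float, float]]
    lost_frames: Dict[str, List[int]]
    um_per_px: float
    meta: dict = field(default_factory=dict)


def _quadratic_peak(corr: np.ndarray, r: int, c: int) -> Tuple[float, float]:
    """Sub-pixel refinement: 3-point parabola through the NCC peak."""
    def refine(fm1, f0, fp1):
        denom = fm1 - 2.0 * f0 + fp1
        if denom >= 0 or abs(denom) < 1e-12:
            return 0.0
        return float(np.clip(0.5 * (fm1 - fp1) / denom, -0.5, 0.5))

    dr = dc = 0.0
    if 0 < r < corr.shape[0] - 1:
        dr = refine(corr[r - 1, c], corr[r, c], corr[r + 1, c])
    if 0 < c < corr.shape[1] - 1:
        dc = refine(corr[r, c - 1], corr[r, c], corr[r, c + 1])
    return dr, dc


def track_stability(frames: np.ndarray, roi_specs: Sequence[ROISpec],
                    um_per_px: float, min_correlation: float = 0.5,
                    wall_name: str = "wall") -> TrackResult:
    """Track each POI through the series by normalized cross-correlation.

    Templates come from frame 0 and are never updated, so slow drifts do
    not accumulate into the reference.  Frames whose correlation peak
    falls below ``min_correlation`` are flagged as lost and the previous
    position is carried forward.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (n_frames, H, W) series with >= 2 frames")
    n_frames, h, w = frames.shape
    positions: Dict[str, np.ndarray] = {}
    lost: Dict[str, List[int]] = {}
    for spec in roi_specs:
        r0, c0 = spec.center_px
        hs = spec.half_size_px
        if not (hs <= r0 <= h - hs - 1 and hs <= c0 <= w - hs - 1):
            raise ValueError(f"ROI {spec.name!r} outside the frame")
        template = frames[0,
                          int(round(r0)) - hs:int(round(r0)) + hs + 1,
                          int(round(c0)) - hs:int(round(c0)) + hs + 1]
        pos = np.empty((n_frames, 2))
        lost_list: List[int] = []
        prev = np.array([float(r0), float(c0)])
        for i in range(n_frames):
            sh = spec.search_half_px + hs
            rmin = max(0, int(round(prev[0])) - sh)
            rmax = min(h, int(round(prev[0])) + sh + 1)
            cmin = max(0, int(round(prev[1])) - sh)
            cmax = min(w, int(round(prev[1])) + sh + 1)
            window = frames[i, rmin:rmax, cmin:cmax]
            corr = match_template(window, template, pad_input=False)
            peak = np.unravel_index(np.argmax(corr), corr.shape)
            if corr[peak] < min_correlation:
                lost_list.append(i)
                pos[i] = prev
                continue
            dr, dc = _quadratic_peak(corr, *peak)
            pos[i] = (rmin + peak[0] + dr + hs, cmin + peak[1] + dc + hs)
            prev = pos[i]
        positions[spec.name] = pos
        lost[spec.name] = lost_list
        if lost_list:
            logger.warning("POI %s lost in %d frames", spec.name,
                           len(lost_list))

    mad: Dict[str, Tuple[float, float]] = {}
    sd: Dict[str, Tuple[float, float]] = {}
    for name, pos in positions.items():
        dev = (pos - pos.mean(axis=0)) * um_per_px
        mad[name] = tuple(float(x) for x in np.abs(dev).mean(axis=0))
        sd[name] = tuple(float(x) for x in dev.std(axis=0, ddof=1))
    rel: Dict[str, Tuple[float, float]] = {}
    if wall_name in positions:
        wall = positions[wall_name]
        for name, pos in positions.items():
            if name == wall_name:
                continue
            dev = ((pos - wall) - (pos - wall).mean(axis=0)) * um_per_px
            rel[name] = tuple(float(x) for x in dev.std(axis=0, ddof=1))
    pos_um = {n: p * um_per_px for n, p in positions.items()}
    return TrackResult(pos_um, mad, sd, rel, lost, um_per_px,
                       meta={"min_correlation": min_correlation,
                             "template_frame": 0})
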