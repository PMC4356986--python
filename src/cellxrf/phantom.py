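"""Synthetic raster-scan phantoms with known ground truth.

The generator emulates a single ~30 um dinoflagellate levitated in a
100 um-ID quartz capillary and raster-scanned through a 13 keV micro-beam:
per-pixel energy-dispersive spectra with Gaussian Kalpha lines on a scatter
background (Poisson statistics), a co-registered integrated-SAXS contrast
map that is elevated over the cell body, an external-standard reference
spectrum, and microscope image series for optical-stability studies.

Scan defaults follow the mixture-toxicity study conditions: 2 um steps,
0.5 s live time per point, 2e10 photons/s.  Element signal loss across
consecutive scan passes (up to 40% for the most radiation-sensitive
elements; negative values model beam-induced concentration) is available
through :func:`apply_radiation_damage`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import erf

from .segmentation import SAXSMap
from .spectral import (KALPHA_KEV, DetectorModel, LineDefinition, Spectrum,
                       SpectrumStack, gaussian_line_profile)

__all__ = [
    "CellGeometry",
    "Hotspot",
    "PhantomConfig",
    "PhantomTruth",
    "ImageSeries",
    "DEFAULT_SENSITIVITY",
    "SRM_LIKE_CERTIFIED_UG_G",
    "generate_phantom",
    "generate_standard_spectrum",
    "generate_image_series",
    "apply_radiation_damage",
    "expected_line_maps",
]

#: true instrument sensitivities used by the generator,
#: net Kalpha counts per (fg/um2) per second of live time.  Values rise
#: with Z towards the 13 keV excitation as fluorescence yield increases.
DEFAULT_SENSITIVITY: Dict[str, float] = {
    "Si": 200.0,
    "K": 500.0,
    "Ca": 600.0,
    "Mn": 1300.0,
    "Fe": 1500.0,
    "Ni": 1800.0,
    "Cu": 2000.0,
    "Zn": 2200.0,
}

#: certified concentrations (ug/g) of a bovine-liver-like reference pellet
SRM_LIKE_CERTIFIED_UG_G: Dict[str, float] = {
    "K": 29700.0,
    "Ca": 131.0,
    "Mn": 10.46,
    "Fe": 197.94,
    "Cu": 275.2,
    "Zn": 181.1,
}


@dataclass(frozen=True)
class CellGeometry:
    """Quasi-spherical cell as an elliptical footprint with an
    ellipsoid-chord thickness profile t = t_max * sqrt(1 - (dy/a)^2 - (dz/b)^2)."""

    center_px: Tuple[float, float] = (24.5, 24.5)  # (row=Z, col=Y)
    semi_axis_y_um: float = 15.0
    semi_axis_z_um: float = 15.0
    thickness_max_um: float = 30.0


@dataclass(frozen=True)
class Hotspot:
    """Local enrichment: density multiplied inside a circle."""

    element: str
    center_px: Tuple[float, float]
    radius_um: float
    multiplier: float = 2.0


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of one simulated scan.

    Densities are areal concentrations in fg/um2 over the cell footprint;
    ``background_rates`` are uniform line rates (counts/s) from the sample
    environment (capillary Si, medium K/Ca).
    """

    # 50 x 50 px at 2 um steps spans the 100 um capillary bore
    grid_shape: Tuple[int, int] = (50, 50)
    step_y_um: float = 2.0
    step_z_um: float = 2.0
    cell: CellGeometry = field(default_factory=CellGeometry)
    true_areal_density: Mapping[str, float] = field(
        default_factory=lambda: {"Cu": 0.20})
    hotspots: Sequence[Hotspot] = ()
    background_rates: Mapping[str, float] = field(
        default_factory=lambda: {"Si": 40.0, "K": 20.0, "Ca": 10.0})
    dwell_s: float = 0.5
    flux_ph_s: float = 2.0e10
    damage: Mapping[str, float] = field(default_factory=dict)
    sensitivity_true: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SENSITIVITY))
    n_channels: int = 1024
    ev_per_channel: float = 20.0
    detector: DetectorModel = field(default_factory=DetectorModel)
    continuum_rate: float = 40.0         # counts/s/keV at E=0
    continuum_tau_keV: float = 6.0
    apply_absorption: bool = True        # attenuate cell-borne lines by
                                         # capillary wall + self-absorption
    scatter_rate: float = 60.0           # counts/s in Compton+Rayleigh pair
    saxs_baseline: float = 100.0
    saxs_contrast: float = 50.0
    saxs_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows < 2 or cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.dwell_s <= 0:
            raise ValueError("dwell_s must be positive")
        if self.step_y_um <= 0 or self.step_z_um <= 0:
            raise ValueError("step sizes must be positive")
        if any(v < 0 for v in self.true_areal_density.values()):
            raise ValueError("areal densities must be >= 0")
        for h in self.hotspots:
            if h.multiplier < 1:
                raise ValueError("hotspot multiplier must be >= 1")
        for el, d in self.damage.items():
            if not (-1.0 <= d <= 0.4):
                raise ValueError(
                    f"damage fraction for {el} outside [-1, 0.4]: {d}")
        if self.cell.semi_axis_y_um <= 0 or self.cell.semi_axis_z_um <= 0:
            raise ValueError("cell has zero area")
        if (self.cell.semi_axis_y_um > cols * self.step_y_um / 2
                or self.cell.semi_axis_z_um > rows * self.step_z_um / 2):
            raise ValueError("grid smaller than the cell footprint")

    @property
    def energy_keV(self) -> np.ndarray:
        # channel centres; channel 0 centred at half a channel width
        return (np.arange(self.n_channels) + 0.5) * self.ev_per_channel * 1e-3


@dataclass
class PhantomTruth:
    """Ground truth the analysis chain must recover."""

    density_maps: Dict[str, np.ndarray]   # element -> fg/um2
    mask_true: np.ndarray                 # bool
    pixel_area_um2: float
    thickness_um: np.ndarray
    config: PhantomConfig

    def total_mass_fg(self, element: str) -> float:
        return float(self.density_maps[element].sum() * self.pixel_area_um2)

    def mean_in_mask(self, element: str) -> float:
        m = self.mask_true
        return float(self.density_maps[element][m].mean()) if m.any() else 0.0


@dataclass
class ImageSeries:
    """Microscope frame series with the injected ground-truth trajectories."""

    frames: np.ndarray                    # (n_frames, H, W) float32
    dt_s: float
    um_per_px: float
    truth_px: Dict[str, np.ndarray]       # POI name -> (n_frames, 2) (row, col)
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry and expectations

def _grid_um(config: PhantomConfig):
    rows, cols = config.grid_shape
    cz, cy = config.cell.center_px
    dz = (np.arange(rows) - cz)[:, None] * config.step_z_um
    dy = (np.arange(cols) - cy)[None, :] * config.step_y_um
    return dz, dy


def thickness_profile(config: PhantomConfig) -> np.ndarray:
    """Chord length (um) through the cell at each pixel centre."""
    dz, dy = _grid_um(config)
    u = 1.0 - (dy / config.cell.semi_axis_y_um) ** 2 \
            - (dz / config.cell.semi_axis_z_um) ** 2
    return config.cell.thickness_max_um * np.sqrt(np.clip(u, 0.0, None))


def build_truth(config: PhantomConfig) -> PhantomTruth:
    t = thickness_profile(config)
    mask = t > 0
    if not mask.any():
        raise ValueError("cell footprint does not cover any pixel centre")
    density = {}
    dz, dy = _grid_um(config)
    for el, rho in config.true_areal_density.items():
        m = np.where(mask, float(rho), 0.0)
        for h in config.hotspots:
            if h.element != el:
                continue
            hz = (np.arange(config.grid_shape[0]) - h.center_px[0])[:, None] \
                * config.step_z_um
            hy = (np.arange(config.grid_shape[1]) - h.center_px[1])[None, :] \
                * config.step_y_um
            inside = (hz ** 2 + hy ** 2) <= h.radius_um ** 2
            m = np.where(inside & mask, m * h.multiplier, m)
        density[el] = m
    return PhantomTruth(density, mask, config.step_y_um * config.step_z_um,
                        t, config)


def expected_line_maps(config: PhantomConfig,
                       truth: Optional[PhantomTruth] = None
                       ) -> Dict[str, np.ndarray]:
    """Expected net Kalpha counts per pixel for every element with either a
    cell-borne density or a uniform environment rate."""
    truth = truth if truth is not None else build_truth(config)
    rows, cols = config.grid_shape
    lam: Dict[str, np.ndarray] = {}
    elements = set(config.true_areal_density) | set(config.background_rates)
    for el in sorted(elements):
        m = np.zeros((rows, cols))
        if el in truth.density_maps:
            signal = truth.density_maps[el] \
                * config.sensitivity_true[el] * config.dwell_s
            if config.apply_absorption:
                signal = signal / _cell_absorption_factor(config, el)
            m = m + signal
        rate = config.background_rates.get(el, 0.0)
        m = m + rate * config.dwell_s
        lam[el] = m
    return lam


def _cell_absorption_factor(config: PhantomConfig, element: str) -> float:
    """Attenuation the in-capillary cell measurement suffers relative to
    the ambient-air standard: quartz wall plus mean self-absorption."""
    from .quantify import CorrectionGeometry, absorption_correction
    geom = CorrectionGeometry(
        cell_diameter_um=config.cell.thickness_max_um)
    return absorption_correction(KALPHA_KEV[element], geom)


# channel-binned unit-area Gaussian shared with the spectral fitter
_line_profile = gaussian_line_profile


def _background_expectation(config: PhantomConfig, live_time_s: float
                            ) -> np.ndarray:
    """Continuum + Compton/Rayleigh scatter pair near the 13 keV excitation."""
    e = config.energy_keV
    de = config.ev_per_channel * 1e-3
    cont = config.continuum_rate * np.exp(-e / config.continuum_tau_keV) * de
    compton = 0.7 * config.scatter_rate * _line_profile(e, 12.60, 0.25)
    rayleigh = 0.3 * config.scatter_rate * _line_profile(
        e, 13.0, config.detector.sigma_keV(13.0))
    return (cont + compton + rayleigh) * live_time_s


def expected_stack(config: PhantomConfig,
                   truth: Optional[PhantomTruth] = None,
                   include_background: bool = True) -> SpectrumStack:
    """Pre-sampling expectation stack (float counts)."""
    truth = truth if truth is not None else build_truth(config)
    lam = expected_line_maps(config, truth)
    rows, cols = config.grid_shape
    e = config.energy_keV
    exp_counts = np.zeros((rows, cols, config.n_channels))
    for el, amp in lam.items():
        line_e = KALPHA_KEV[el]
        prof = _line_profile(e, line_e, config.detector.sigma_keV(line_e))
        exp_counts += amp[:, :, None] * prof[None, None, :]
    if include_background:
        exp_counts += _background_expectation(config, config.dwell_s)
    return SpectrumStack(exp_counts, e, config.dwell_s,
                         step_y_um=config.step_y_um,
                         step_z_um=config.step_z_um,
                         meta={"seed": config.seed, "expectation": True})


def generate_phantom(config: PhantomConfig, pass_index: int = 0
                     ) -> Tuple[PhantomTruth, SpectrumStack, SAXSMap]:
    """Generate ground truth, a Poisson-sampled spectrum stack, and the
    co-registered integrated-SAXS contrast map.

    ``pass_index`` > 0 applies the configured per-pass element damage to
    the line expectations before sampling (scan pass 0 is undamaged).
    """
    rng = np.random.default_rng(config.seed)
    truth = build_truth(config)
    exp_stack = expected_stack(config, truth)
    if pass_index and config.damage:
        exp_stack = apply_radiation_damage(exp_stack, config.damage,
                                           pass_index)
    counts = rng.poisson(exp_stack.counts).astype(np.uint32)
    stack = SpectrumStack(counts, exp_stack.energy_keV, config.dwell_s,
                          step_y_um=config.step_y_um,
                          step_z_um=config.step_z_um,
                          meta={"seed": config.seed,
                                "pass_index": pass_index,
                                "generator": "cellxrf.phantom"})
    profile = truth.thickness_um / config.cell.thickness_max_um
    saxs_values = (config.saxs_baseline
                   + config.saxs_contrast * profile
                   + rng.normal(0.0, config.saxs_noise_sd,
                                size=config.grid_shape))
    saxs = SAXSMap(saxs_values, step_y_um=config.step_y_um,
                   step_z_um=config.step_z_um,
                   meta={"seed": config.seed})
    return truth, stack, saxs


def generate_standard_spectrum(certified_ug_g: Mapping[str, float],
                               live_time_s: float = 250.0,
                               pellet_areal_mass_mg_cm2: float = 50.0,
                               sensitivity_true: Optional[Mapping[str, float]] = None,
                               config: Optional[PhantomConfig] = None,
                               seed: int = 0) -> Spectrum:
    """Reference-standard spectrum (pressed pellet, confocal geometry).

    Certified mass fractions (ug/g) are converted to areal densities via
    the pellet areal mass: rho_e [fg/um2] = c_e [ug/g] * M [mg/cm2] * 0.01.
    Expected line area = rho_e * S_e * live_time, Poisson sampled.
    """
    if any(v <= 0 for v in certified_ug_g.values()):
        raise ValueError("certified concentrations must be > 0")
    if live_time_s < 0:
        raise ValueError("live time must be >= 0")
    cfg = config if config is not None else PhantomConfig()
    sens = sensitivity_true if sensitivity_true is not None else cfg.sensitivity_true
    missing = [el for el in certified_ug_g if el not in sens]
    if missing:
        raise KeyError(f"no true sensitivity for element(s) {missing}")
    rng = np.random.default_rng(seed)
    e = cfg.energy_keV
    expected = np.zeros_like(e)
    for el, c in certified_ug_g.items():
        areal_fg_um2 = c * pellet_areal_mass_mg_cm2 * 0.01
        amp = areal_fg_um2 * sens[el] * live_time_s
        prof = _line_profile(e, KALPHA_KEV[el],
                             cfg.detector.sigma_keV(KALPHA_KEV[el]))
        expected += amp * prof
    expected += _background_expectation(cfg, live_time_s)
    counts = rng.poisson(expected).astype(np.uint32)
    return Spectrum(counts, e, live_time_s=live_time_s,
                    meta={"seed": seed,
                          "pellet_areal_mass_mg_cm2": pellet_areal_mass_mg_cm2,
                          "certified_ug_g": dict(certified_ug_g)})


def apply_radiation_damage(stack: SpectrumStack,
                           damage: Mapping[str, float],
                           pass_index: int,
                           lines: Optional[Mapping[str, LineDefinition]] = None
                           ) -> SpectrumStack:
    """Scale element line expectations by (1 - damage)^pass_index.

    Intended for pre-sampling expectation stacks: each element's Kalpha
    window (+-4 sigma) is scaled, which is exact while lines do not
    overlap.  Negative damage models beam-induced concentration (factor
    > 1), e.g. Cu; positive damage models preferential escape, e.g. Mn,
    with at most 40% loss per pass.
    """
    if pass_index < 0:
        raise ValueError("pass_index must be >= 0")
    for el, d in damage.items():
        if not (-1.0 <= d <= 0.4):
            raise ValueError(f"damage fraction for {el} outside [-1, 0.4]")
    counts = np.array(stack.counts, dtype=float, copy=True)
    e = stack.energy_keV
    det = DetectorModel()
    for el, d in damage.items():
        factor = (1.0 - d) ** pass_index
        if lines is not None and el in lines:
            center, sig = lines[el].energy_keV, lines[el].sigma_keV
        else:
            center = KALPHA_KEV[el]
            sig = det.sigma_keV(center)
        sel = (e >= center - 4 * sig) & (e <= center + 4 * sig)
        counts[:, :, sel] *= factor
    return SpectrumStack(counts, e, stack.dwell_s,
                         step_y_um=stack.step_y_um, step_z_um=stack.step_z_um,
                         meta={**stack.meta, "damage": dict(damage),
                               "pass_index": pass_index})


# ---------------------------------------------------------------------------
# microscope image series (optical stability)

def _render_frame(shape, cell_rc, laser_rc, wall_row, um_per_px):
    """Analytic smooth rendering: dark cell disc, dark capillary wall below
    a horizontal edge, bright laser spot; sub-pixel positions exact."""
    h, w = shape
    rr = np.arange(h)[:, None].astype(float)
    cc = np.arange(w)[None, :].astype(float)
    edge_sigma = 1.2  # px, microscope PSF softening
    img = np.full(shape, 0.70)
    # capillary wall: darker band below wall_row, with a small surface
    # defect that makes the wall POI localizable along the axis too
    step = 0.5 * (1 + erf((rr - wall_row) / (np.sqrt(2) * edge_sigma)))
    img *= (0.45 + 0.55 * (1 - step))
    d2w = (rr - (wall_row + 3.0)) ** 2 + (cc - 0.31 * w) ** 2
    img *= 1.0 - 0.5 * np.exp(-0.5 * d2w / 1.5 ** 2)
    # cell: dark disc of radius 9 px
    d = np.hypot(rr - cell_rc[0], cc - cell_rc[1])
    disc = 0.5 * (1 + erf((d - 9.0) / (np.sqrt(2) * edge_sigma)))
    img *= (0.25 + 0.75 * disc)
    # laser spot: bright Gaussian
    d2 = (rr - laser_rc[0]) ** 2 + (cc - laser_rc[1]) ** 2
    img += 0.6 * np.exp(-0.5 * d2 / 2.0 ** 2)
    return img.astype(np.float32)


def generate_image_series(n_frames: int = 9000,
                          drift_model: str = "static",
                          jitter_sd_um: Tuple[float, float] = (0.23, 0.84),
                          seed: int = 0,
                          um_per_px: float = 0.4,
                          dt_s: float = 0.1,
                          shape: Tuple[int, int] = (64, 96),
                          drift_px_per_frame: Tuple[float, float] = (0.0, 0.0),
                          ) -> ImageSeries:
    """Microscope frames of an optically lifted cell in a capillary.

    ``jitter_sd_um`` is (horizontal Y, vertical Z) Gaussian positional
    jitter of the cell around the trap; the defaults are the deviations a
    15-minute stability run at 0.1 s/frame is expected to show.  The
    laser spot and capillary wall stay fixed (the wall may drift if a
    linear ``drift_model`` is chosen, emulating stage drift).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if any(s < 0 for s in jitter_sd_um):
        raise ValueError("jitter sd must be >= 0")
    if drift_model not in ("static", "linear"):
        raise ValueError(f"unknown drift model {drift_model!r}")
    rng = np.random.default_rng(seed)
    h, w = shape
    cell0 = np.array([h * 0.42, w * 0.38])
    laser0 = np.array([h * 0.42, w * 0.70])
    wall_row0 = h * 0.80
    sd_px = np.array([jitter_sd_um[1], jitter_sd_um[0]]) / um_per_px  # (row=Z, col=Y)
    jitter = rng.normal(0.0, 1.0, size=(n_frames, 2)) * sd_px[None, :]
    drift = np.zeros((n_frames, 2))
    if drift_model == "linear":
        k = np.arange(n_frames)[:, None].astype(float)
        drift = k * np.asarray(drift_px_per_frame, dtype=float)[None, :]
    cell_traj = cell0[None, :] + jitter + drift
    laser_traj = np.tile(laser0, (n_frames, 1))
    wall_traj = np.column_stack([np.full(n_frames, wall_row0 + 3.0),
                                 np.full(n_frames, 0.31 * w)])
    frames = np.empty((n_frames, h, w), dtype=np.float32)
    for i in range(n_frames):
        frames[i] = _render_frame(shape, cell_traj[i], laser_traj[i],
                                  wall_traj[i, 0], um_per_px)
    truth = {
        "cell": cell_traj,
        "cell_edge": cell_traj + np.array([0.0, -9.0]),
        "wall": wall_traj,
        "laser": laser_traj,
    }
    return ImageSeries(frames, dt_s, um_per_px, truth,
                       meta={"seed": seed, "drift_model": drift_model,
                             "jitter_sd_um": tuple(jitter_sd_um)})
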