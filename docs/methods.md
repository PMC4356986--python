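# Methods

This note documents the models, defaults and numerical choices behind
`cellxrf`, and what the synthetic-data validation does and does not show
about real measurements.

## The measurement being modelled

A quasi-spherical microalga (~30 µm) is optically levitated in a quartz
capillary (100 µm inner diameter, 10 µm wall) and raster-scanned through
a 13 keV micro-beam. Per pixel, an energy-dispersive detector in confocal
geometry (take-off 45°) records a fluorescence spectrum, and a downstream
camera records the integrated small-angle scattering. Scan defaults are
the mixture-toxicity operating point: 2 µm steps, 0.5 s live time,
2×10¹⁰ photons/s in a 2×3 µm² focus. The default field of view is
50×50 px = 100×100 µm, spanning the capillary bore.

## Synthetic-data generator

**Spectra.** Expected net Kα counts per pixel are
`density(fg/µm²) × S_true,e × dwell`, with true sensitivities fixed at
Si 200, K 500, Ca 600, Mn 1300, Fe 1500, Ni 1800, Cu 2000, Zn 2200
counts/(fg/µm²)/s — realistic synchrotron confocal values, rising with Z
towards the 13 keV excitation, and sized so the weakest study condition
(0.10 fg/µm² over a ~150 px mask) still accumulates ≥10⁴ in-mask counts,
the statistics regime the recovery guarantees are stated for. Line
amplitudes are spread over channels with an exact (erf-binned) Gaussian
at the detector resolution `FWHM(E) = sqrt(noise² + 2.355²·F·ε·E)`
(noise 72 eV, Fano 0.114, ε 3.85 eV → 140 eV at Mn Kα; the resolution
model is a package choice, configurable). The background is an
exponential continuum (40 counts/s/keV at E=0, τ=6 keV) plus a
Compton/Rayleigh pair near 13 keV, reflecting the substantial scatter
contribution such spectra carry. Counts are Poisson-sampled from one
seeded generator per call; identical seeds give bitwise-identical
output.

**Absorption realism.** Cell-borne line expectations are divided by the
same wall + self-absorption factor the quantifier later corrects for
(the phantom cell sits in the capillary; the standard is measured in
air). This makes the recovery test exercise the correction path;
the correction model itself is validated separately against numerical
ray integration through the cylindrical wall (agreement within 5 %).

**Geometry.** Row = Z (vertical), column = Y (horizontal), 0-based pixel
centres, geometry in µm. The cell is an elliptical footprint with an
ellipsoid-chord thickness profile `t = t_max·sqrt(1−(dy/a)²−(dz/b)²)`.
Hotspots multiply the density inside a circle (≥1), emulating
accumulation centres. The SAXS observable is one scalar per pixel:
`baseline 100 + contrast 50 × (t/t_max) + N(0, 5)` — SNR 10.

**Damage.** `apply_radiation_damage` scales each element's Kα window
(±4σ) of a pre-sampling expectation stack by `(1−d)^pass`, d ∈ [−1, 0.4]
(0.4 = the maximum per-pass loss modelled; negative values model
beam-induced concentration, e.g. Cu). Exact while lines do not overlap,
which holds for the Kα-only phantom; it is not meant for already-sampled
integer stacks.

**Image series.** Frames contain a dark cell disc, the capillary wall
(horizontal edge with a small surface defect so the wall POI is
localisable along both axes) and a bright laser spot, rendered
analytically at sub-pixel positions with a ~1.2 px PSF softening. The
cell jitters around the trap with Gaussian sd 0.23 µm (Y) / 0.84 µm (Z)
by default at 0.1 s/frame; optional linear drift models stage creep.
True trajectories are returned for round-trip tests.

## Spectral evaluation

Net Kα areas per pixel come from either a background-subtracted window
sum (`roi`) or a linear least-squares fit of a fixed-shape Gaussian plus
linear baseline (`gaussian_fit`, the default; the line position and
width come from the calibrated detector model, so the fit is linear and
vectorises over all pixels). Evaluation windows are ±1.5 FWHM with two
1-FWHM flanking background bands, and every window is narrowed to the
midpoint towards any neighbouring Kα line — without this, the Fe tail
biases Mn by −4 % and K makes Ca unusable in the standard. The ROI sum
is corrected for the Gaussian tail fractions outside the window and
inside the background bands. Negative net areas are clamped to zero and
counted in the map metadata. Kβ lines are ignored (folded into the
calibration); the phantom correspondingly emits Kα only.

## Segmentation

The SAXS map is smoothed (Gaussian, σ = 1 px default), thresholded at
µ + k·σ (k = 1) with µ, σ the mean and population sd over **all** pixels
of the smoothed map; the largest 8-connected component is kept, interior
holes are filled, and the pixel count is recorded with full provenance.
Because the statistics are global, the mask is **not** invariant to
padding the field with background, and for objects occupying only a few
percent of a large field the threshold drops towards the smoothing skirt
and the mask dilates. Both are inherent to the µ+σ rule: a
median/MAD-based `exclude_background_tail` variant is provided for the
padding case, and scans are assumed framed around the cell (object at
5–15 % of the field), where the rule cuts near the footprint rim
(IoU ≈ 0.97 at SNR 10). Size invariance of the per-pixel mean holds in
that framing regime.

## Quantification

`c_e = N̄_e · A_e / (S_e · t)`. Sensitivities come from a
bovine-liver-like certified pellet (250 s live time) via
`S_e = net counts / (areal density × live time)`, with µg/g converted to
fg/µm² through a configurable pellet areal mass (default 50 mg/cm²; the
absolute scale of recovered concentrations is only as good as this
number, which is why the method is semi-quantitative). Calibration uses
the clean 5.9–8.6 keV lines (Mn, Fe, Cu, Zn); K and Ca Kα are strongly
air-absorbed in an ambient-air pellet measurement and K's tail overlaps
Ca, so elements missing from the standard (e.g. Ni) get sensitivities
log-linearly interpolated against atomic number between calibrated
neighbours — standard external-calibration practice.

The absorption correction is
`A_e = exp(µ_SiO₂(E_line)·ρ·t_wall/sin 45°) × x/(1−e^(−x))` with
`x = (µ_w(13 keV) + µ_w(E_line)/sin 45°)·ρ_w·t̄` and `t̄ = 2r/3`, the mean
chord of a sphere, applied to incident and emergent paths (emergent
weighted by the 45° exit). The slab wall model is appropriate because
the confocal exit ray runs in the plane of the capillary axis, where the
wall crossing is slab-like; the numerical cylinder-shell integration in
the test suite confirms ≤5 % deviation across the cell width. The cell
matrix is water (H₂O mass fractions) at 1 g/cm³.

LOD = 3·√B·A_e/(S_e·t), with B the mean gross counts under the line in
the **off-cell** pixels — what a cell-free pixel contributes under the
peak. Replicates aggregate as mean ± sample sd (n−1); a single cell
reports no sd. Accumulation ranking orders elements by (mean at the
highest exposure − control), using only conditions where no other
studied metal was added; ties break alphabetically with a warning.

## X-ray physics

Mass attenuation and mass energy-absorption coefficients for H, O and Si
are bundled as CSV tables (2–100 keV grid; the range starts above the Si
K edge at 1.839 keV so log-log linear interpolation is valid everywhere
on the grid). Compounds (water, silica, or arbitrary mass-fraction maps)
are always mixture-rule sums of the element tables. The absorbed dose at
one scan point is `N·E·(1−e^(−(µ_en/ρ)·ρ·t)) / (A_beam·t·ρ)` — energy is
scored where photons interact (photoelectron escape ignored), the
convention for quoting single-point doses in micro-beam scanning.
Defaults (13 keV, 2×10¹⁰ ph/s, 0.5 s, 2×3 µm², 30 µm of water) give
7.5×10⁵ Gy.

## Optics

Plain Gerchberg–Saxton (no per-trap weighting updates): unit pupil
amplitude with free phase ↔ focal amplitude fixed at the trap pixels,
via the orthonormal FFT; fixed iteration count (default 30) keeps runs
reproducible; the random initial phase comes from the seed, except for a
single on-axis target where the flat phase is the known optimum.
Efficiency = fraction of focal power in 3×3 windows at the targets;
uniformity = weakest/strongest trap power; both are recorded per
iteration. Trap offsets in µm map to focal pixels via λf/(N·pitch)
(1070 nm, f = 2 mm, 20 µm pitch defaults) and must lie inside the
Nyquist field. Axial displacement is a quadratic Fresnel-lens phase
added after convergence.

Tracking cuts a template around each POI from frame 0 (never updated, so
reference drift cannot accumulate), locates it per frame by normalized
cross-correlation inside a search window around the previous position,
refines to sub-pixel by a 3-point parabola through the correlation peak,
and reports mean absolute deviation and sd per axis plus cell-relative-
to-wall deviations. Correlation peaks below 0.5 flag the frame as lost
and carry the previous position forward.

## Problem sizes and determinism

The bundled study is 12 conditions × 3 replicate cells at 50×50 px ×
1024 channels; it runs in a few seconds. Stability validation uses
3000-frame series in the test suite and the full 9000-frame (15 min)
series in the acceptance script. All randomness flows through
`numpy.random.default_rng` seeded per call; derived seeds come from
`SeedSequence` so condition/replicate streams are independent. Repeated
runs with the same configuration produce byte-identical CSV outputs.

## What the validation does and does not show

Parameter recovery on phantoms demonstrates that the chain is
self-consistent and unbiased at the stated counting statistics — it
cannot certify accuracy on real cells, where the pellet areal mass, the
true matrix composition, detector artefacts (pile-up, escape peaks,
L-lines), non-uniform self-absorption through an inhomogeneous cell, and
the ~30 % optical elongation introduced by the cylindrical capillary all
enter. The phantom also omits biological concentration variability
between replicates (only size varies), so replicate sds on synthetic
data are counting-statistics-small. SAXS is modelled as a scalar
contrast proportional to projected thickness, not as a scattering
pattern; segmentation results transfer to real data only insofar as the
cell outline dominates the integrated-SAXS contrast.
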