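"""Absorbed dose at a single scan point of a micro-beam raster scan.

A 13 keV beam of 2e10 photons/s focused to 2 x 3 um2 dwells 0.5 s on a
water-density cell traversed over ~30 um.
"""

from cellxrf.xray import DoseParameters, absorbed_dose

result = absorbed_dose(DoseParameters())
print(f"photons delivered:   {result.n_photons:.3g}")
print(f"mu_en/rho (water):   {result.muen_rho_cm2_g:.3f} cm2/g at 13 keV")
print(f"absorbed fraction:   {result.absorbed_fraction:.3%}")
print(f"irradiated mass:     {result.mass_kg:.3g} kg")
print(f"absorbed dose:       {result.dose_Gy:.3g} Gy")
# Of order 1e6 Gy per point: radiation damage cannot be neglected, which
# is why element-dependent signal loss (up to 40%/pass) is modelled and
# multi-pass techniques such as XRF tomography are impractical on cells.
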