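"""Element-dependent signal change across consecutive scan passes.

Mn preferentially escapes the irradiated cell (up to 40% loss per pass
for the most sensitive elements) while Cu tends to concentrate; the
damage model scales each element's line expectation by (1-d)^pass.
"""

from cellxrf.phantom import (PhantomConfig, apply_radiation_damage,
                             expected_stack)
from cellxrf.spectral import KALPHA_KEV

cfg = PhantomConfig(true_areal_density={"Mn": 1.0, "Cu": 1.0},
                    background_rates={}, continuum_rate=0.0,
                    scatter_rate=0.0, apply_absorption=False)
fresh = expected_stack(cfg, include_background=False)
damage = {"Mn": 0.4, "Cu": -0.05}

print(f"{'pass':>4s} {'Mn signal':>10s} {'Cu signal':>10s}")
for n_pass in range(4):
    stack = apply_radiation_damage(fresh, damage, pass_index=n_pass)
    row = [f"{n_pass:4d}"]
    for el in ("Mn", "Cu"):
        e = stack.energy_keV
        win = (e > KALPHA_KEV[el] - 0.2) & (e < KALPHA_KEV[el] + 0.2)
        rel = stack.counts[..., win].sum() / fresh.counts[..., win].sum()
        row.append(f"{rel:10.3f}")
    print(" ".join(row))
# After three passes Mn retains only 0.6^3 = 22% of its signal while Cu
# grows by 5%/pass: multi-pass scanning distorts elemental ratios, so
# quantification uses single-pass scans.
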