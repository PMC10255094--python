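"""Particle-to-molecule density calibration on the liposome leaflet model.

Computes the theoretical molecule density of a 5 mol% lipid species, the
labeling efficiency implied by an observed gold density of 850 particles/µm²,
and converts two observed cell-membrane particle densities into molecule
densities using regime-appropriate efficiencies.
"""

from replipat import (
    efficiency_curve,
    labeling_efficiency,
    molecule_density,
    percent_reduction,
    theoretical_density,
)

theo = theoretical_density(5.0)
eff = labeling_efficiency(850.0, 5.0, subtract_background=False)
print(f"5 mol% leaflet -> {theo:,.0f} molecules/um^2 (theoretical)")
print(f"850 particles/um^2 observed -> labeling efficiency {100 * eff:.1f}%")

# converting observed particle densities with regime-appropriate efficiencies:
# near saturation the probe labels ~5% of molecules, at sparse densities ~17%
control = molecule_density(203.8, 0.05)
depleted = molecule_density(58.3, 0.17)
print(f"control membrane: 203.8 particles/um^2 at 5% -> {control:.0f} molecules/um^2")
print(f"depleted membrane: 58.3 particles/um^2 at 17% -> {depleted:.0f} molecules/um^2")
print(f"depletion removed ~{percent_reduction(control, depleted):.0f}% of the target lipid")

# a concentration series with background subtraction, plus the CSR-expected
# mean nearest-neighbor distance at each theoretical density
points = [(0.01, 32.0), (0.1, 150.0), (1.0, 500.0), (5.0, 870.0)]
print()
print(efficiency_curve(points).to_string(index=False))
print("falling efficiency above ~0.5 mol% reflects probe-binding saturation")
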