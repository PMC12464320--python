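"""Poisson single-cell encapsulation: why ~90% of droplets stay empty.

Stochastic confinement dilutes the inoculum so that droplet occupancy is
Poisson with lambda = CFU/mL x droplet volume.  At the standard loading of
1e5 CFU/mL into 1 nL droplets, almost every occupied droplet holds exactly
one cell — the condition that turns droplet growth readout into a
single-cell MIC measurement.
"""

from dropast import poisson_occupancy

for cfu in (5e4, 1e5, 2e5, 1e6):
    occ = poisson_occupancy(cfu, droplet_volume_nl=1.0)
    print(
        f"{cfu:>8.0e} CFU/mL  lambda={occ['lambda']:.2f}  "
        f"empty={occ['P0']:.1%}  single={occ['P1']:.1%}  multi={occ['P2plus']:.2%}"
    )

# At 1e5 CFU/mL: ~90% empty, ~9% single-cell, <0.5% multi-cell droplets.
# Raising the inoculum 10x makes multi-occupancy (26%) rival single cells,
# breaking the single-cell interpretation of positive droplets.
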