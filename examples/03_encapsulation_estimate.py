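"""From measured radii of gyration to an encapsulated protein concentration.

Sweeps the water-pool contrast of the canonical vesicle, tabulates the
relation between encapsulated concentration (% w/v in the pool) and the
relative Rg decrement, and inverts it for Guinier radii of 587 Å (empty)
and 501-509 Å (filled) — with a sensitivity band over the protein
scattering density (11.7-12.0e10 cm^-2) and partial specific volume
(0.70-0.75 cm^3/g).
"""

import numpy as np

from liposaxs import (
    build_efficiency_relation,
    canonical_fixture,
    efficiency_sensitivity_band,
    estimate_encapsulated_concentration,
)

fixture = canonical_fixture()
relation = build_efficiency_relation(fixture.profile, fixture.distribution)

print("concentration -> Rg decrement (first rows):")
for c, d in list(zip(relation.concentration, relation.decrement))[:6]:
    print(f"  {c:6.2f} % w/v : {d:.4f}")

rg_empty = 587.0
for rg_filled in (501.0, 506.0, 509.0):
    est = estimate_encapsulated_concentration(rg_empty, rg_filled, relation)
    print(f"Rg {rg_empty:.0f} -> {rg_filled:.0f} A : {est:5.2f} % w/v encapsulated")

band = efficiency_sensitivity_band(fixture.profile, fixture.distribution, rg_empty, 505.33)
print(f"\ncentral estimate {band['estimate']:.2f} % w/v "
      f"(sensitivity band {band['low']:.2f} - {band['high']:.2f})")
print("A ~14 % Rg drop corresponds to a pool concentration of a few % w/v;")
print("the steep low-concentration slope makes Rg a sensitive occlusion probe.")
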