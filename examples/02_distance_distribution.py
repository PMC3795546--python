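"""Distance distribution of empty vs protein-filled vesicles.

Computes p(r) for the canonical vesicle with an empty water pool and with
the pool at relative contrast 2.6 (fully occupied by protein).  Filling the
pool moves the broad p(r) maximum to smaller distances and smears out the
short-distance oscillation that the bilayer's alternating contrast produces.
"""

import numpy as np

from liposaxs import ScatteringCurve, canonical_fixture, distance_distribution, intensity_polydisperse

q = np.linspace(3e-3, 0.3, 1500)
r = np.linspace(0.0, 2000.0, 2001)

for contrast, label in [(0.0, "empty"), (2.6, "filled (contrast 2.6)")]:
    fixture = canonical_fixture(core_contrast=contrast)
    intensity = intensity_polydisperse(fixture.profile, fixture.distribution, q)
    dd = distance_distribution(ScatteringCurve(q=q, intensity=intensity), r_grid=r)
    print(f"{label:>22}: p(r) peak = {dd.peak_position:6.1f} A, "
          f"ripple extent = {dd.ripple_extent:4.1f} A")

print()
print("The peak shift (about 700 -> 480 A) tracks the scattering mass moving")
print("from a hollow shell toward a filled sphere; the vanishing sub-55 A")
print("ripple shows the wall oscillation being buried by the bright core.")
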