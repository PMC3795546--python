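"""Shell-model fit of a noisy synthetic vesicle curve.

Generates a synthetic empty-vesicle curve with 1 % counting-statistics
noise, perturbs the wall contrasts of the generating model by 20 %, and
refines them back by bounded log-residual least squares.  The reliability
factor R = sum|I_obs - I_model| / sum I_obs scores the fit on q <= 0.2 1/A.
"""

import numpy as np

from liposaxs import NoiseModel, canonical_fixture, fit_shell_model, synth_curve

fixture = canonical_fixture()
profile, dist = fixture.profile, fixture.distribution

q = np.linspace(3e-3, 0.3, 400)
curve = synth_curve(profile, dist, NoiseModel(floor=0.01, seed=42), q_grid=q, n_radius=151)

start = profile.with_contrasts(profile.contrasts * 1.2)
result = fit_shell_model(curve, start, dist, free=("scale", "contrasts"), n_radius=151)

fitted = result.profile.contrasts[1:]
# relative-intensity data fix contrasts only up to one global factor (the
# free scale absorbs its square), so compare shapes normalized to the core
normalized = fitted * (profile.contrasts[3] / result.profile.contrasts[3])

print("true wall contrasts:        ", np.round(profile.contrasts[1:], 3))
print("starting guess (x1.2):      ", np.round(start.contrasts[1:], 3))
print("fitted, raw:                ", np.round(fitted, 3))
print("fitted, core-normalized:    ", np.round(normalized, 3))
print(f"reliability factor R = {result.reliability_r:.4f} on q <= 0.2 1/A")
print()
print("With a free intensity scale the contrast profile is determined up to")
print("one global factor; the core-normalized shape matches the generator.")
print("R of a few hundredths means the model tracks the data at the noise")
print("level across ~4 intensity decades.")
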