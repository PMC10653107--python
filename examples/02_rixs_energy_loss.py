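"""2p3d RIXS on an energy-loss axis, at the incident energy of the L3 maximum.

Uses the reduced three-valence-orbital model (small enough that the dense
sum-over-states route can cross-check every point).
"""

import numpy as np

from cvxray import (
    FrequencyGrid,
    ground_state,
    rixs_spectrum,
    select_omega_ex,
    xas_spectrum,
)
from cvxray.fixtures import fixture

ints, space = fixture("rixs_small").build()
gs = ground_state(ints, space)

xgrid = FrequencyGrid.linspace(700.0, 722.0, 0.05, eta=0.3)
xas = xas_spectrum(ints, gs, xgrid)
omega_ex = select_omega_ex(xas, l3_window=(700.0, 714.0))
print(f"incident energy at the L3 maximum: omega_ex = {omega_ex:.2f} eV")

loss = FrequencyGrid.linspace(0.0, 6.0, 0.02, eta=0.3, eta_prime=0.1)
spec = rixs_spectrum(ints, gs, omega_ex, loss)
t = spec.total / spec.total.max()
bands = [
    (loss.values[i], t[i])
    for i in range(1, len(t) - 1)
    if t[i] >= t[i - 1] and t[i] > t[i + 1] and t[i] > 0.02
]
print("energy-loss features (eV, relative intensity):")
for e, h in [(0.0, t[0])] + bands:
    print(f"  {e:6.2f}  {h:6.3f}")
spec.write_tsv("rixs_small.tsv")
print("wrote rixs_small.tsv")
# The peak at zero loss is elastic scattering; the features at finite loss
# are d-d excitations of the valence shell reached through the 2p core hole,
# each broadened by eta' = 0.1 eV.
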