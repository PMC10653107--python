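"""Active-space construction from (synthetic) mean-field output.

A mean-field engine would supply natural-orbital coefficients, occupation
numbers and full-basis integrals; here a small synthetic set stands in.
Orbitals with fractional occupation inside the window are selected,
localized, and the integrals are transformed into the active basis.
"""

import numpy as np

from cvxray.adapter import SelectionRule, from_adapter
from cvxray.integrals import symmetrize_eri

rng = np.random.default_rng(3)
nb = 6
a = rng.normal(size=(nb, nb))
mo, _ = np.linalg.qr(a)
occupations = np.array([2.0, 1.99, 1.2, 0.8, 0.01, 0.0])
h1 = rng.normal(size=(nb, nb)); h1 = 0.5 * (h1 + h1.T)
source = {
    "mo_coeffs": mo,
    "occupations": occupations,
    "h1": h1,
    "eri": symmetrize_eri(0.1 * rng.normal(size=(nb,) * 4)),
    "dip": np.stack([0.5 * (m + m.T) for m in rng.normal(size=(3, nb, nb))]),
    "e_core": 1.25,
}

rule = SelectionRule(window=(0.02, 1.98), n_orb=2,
                     labels=("act_a", "act_b"))
ints = from_adapter(source, rule, localize=False)
print(f"occupations: {occupations}")
print(f"selected {ints.n_orb} orbitals inside window {rule.window}: "
      f"{', '.join(ints.space.labels)}")
print(f"active h1 (Hartree):\n{np.round(ints.h1, 4)}")
# The selection window picks the fractionally occupied (strongly correlated)
# natural orbitals; doubly occupied and empty orbitals stay outside the
# active space.
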