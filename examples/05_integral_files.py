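"""Write and read the extended integral file format.

The text dialect is a standard FCIDUMP (one-/two-electron integrals and the
core energy) extended with &SOC x/y/z sections for the imaginary
antisymmetric Breit-Pauli matrices and &DIP x/y/z sections for the dipole
matrices; orbital labels, RAS partition and shell tags live in a YAML
sidecar next to the file.
"""

from cvxray import build_model, read_integrals, write_integrals
from cvxray.fixtures import fixture

fx = fixture("p_shell")
ints = build_model(fx.params)
write_integrals(ints, "p_shell.fcidump")
print("wrote p_shell.fcidump and p_shell.fcidump.orbitals.yaml")

back = read_integrals("p_shell.fcidump")
assert (back.h1 == ints.h1).all() and (back.h_soc == ints.h_soc).all()
print(f"round trip exact; {back.n_orb} orbitals: {', '.join(back.space.labels)}")
print(f"partitions: {', '.join(back.space.partition)}")
with open("p_shell.fcidump") as fh:
    for line in list(fh)[:6]:
        print("  " + line.rstrip())
# Stored entries are the symmetry-unique ones; permutation partners (8-fold
# for the two-electron integrals, antisymmetry for SOC) are completed on read.
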