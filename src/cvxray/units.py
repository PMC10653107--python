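"""Unit conversions.  Internal energies are Hartree; user-facing I/O is eV."""

HARTREE_EV = 27.211386245988


def ev_to_ha(x):
    return x / HARTREE_EV


def ha_to_ev(x):
    return x * HARTREE_EV
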