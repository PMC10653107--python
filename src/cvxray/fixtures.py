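"""Named model fixtures: the desk-scale study conditions.

Each fixture is a ligand-field stand-in for a tetrahedral Fe L-edge problem:
a 2p core shell (zeta = 8 eV, the Fe 2p spin-orbit scale), a 3d valence
shell with a small tetrahedral splitting (10Dq = 0.65 eV, e below t2),
Kanamori-style valence interactions (U = 4 eV, Hund J = 0.8 eV — a high-spin
ground state and multiplet structure), a core-valence Coulomb term
(Q = 5 eV) binding the core-excited electron, and the standard broadenings
eta = 0.3 eV, eta' = 0.1 eV.  The 2p level sits at -710 eV so the L3 edge
falls near 710 eV.

Fixtures:
  p_shell    one-electron 2p^6 -> 2p^5 v^1 model (no two-electron terms);
             the XAS splits into two bands separated by 3 zeta / 2.
  d6 / d5    2p^6 3d^6 (ferrous-like) and 2p^6 3d^5 (ferric-like) models.
  d6_nosoc   the d6 model with zeta = 0 (spin-free reference).
  sigma      d6 plus one filled sigma-donor orbital hybridized with the
             valence shell (RAS1' partition, at most one hole).
  rixs_small reduced three-valence-orbital model small enough for dense
             double-resolvent cross-checks of RIXS.
"""

from __future__ import annotations

from dataclasses import dataclass

from .integrals import IntegralSet
from .model import ModelParams, build_model
from .ras import DeterminantSpace, RASSpec, enumerate_space

__all__ = ["FIXTURES", "Fixture", "fixture", "fixture_names"]

ETA_EV = 0.3
ETA_PRIME_EV = 0.1


@dataclass(frozen=True)
class Fixture:
    name: str
    params: ModelParams
    n_elec: int

    def build(self) -> tuple[IntegralSet, DeterminantSpace]:
        ints = build_model(self.params)
        spec = RASSpec.from_space(ints.space, self.n_elec)
        return ints, enumerate_space(spec)


_TD_CF = (0.0, 0.0, 0.65, 0.65, 0.65)  # (z2, x2y2) e set below (xy, xz, yz) t2

FIXTURES: dict[str, Fixture] = {
    f.name: f
    for f in [
        Fixture(
            "p_shell",
            ModelParams(core_orbitals=3, valence_orbitals=1, zeta_core=8.0,
                        crystal_field=(0.0,), dipole_strengths=1.0),
            n_elec=6,
        ),
        Fixture(
            "d6",
            ModelParams(crystal_field=_TD_CF, zeta_core=8.0, u_direct=4.0,
                        j_exchange=0.8, core_valence_attraction=5.0),
            n_elec=12,
        ),
        Fixture(
            "d5",
            ModelParams(crystal_field=_TD_CF, zeta_core=8.0, u_direct=4.0,
                        j_exchange=0.8, core_valence_attraction=5.0),
            n_elec=11,
        ),
        Fixture(
            "d6_nosoc",
            ModelParams(crystal_field=_TD_CF, zeta_core=0.0, u_direct=4.0,
                        j_exchange=0.8, core_valence_attraction=5.0),
            n_elec=12,
        ),
        Fixture(
            "sigma",
            ModelParams(crystal_field=_TD_CF, zeta_core=8.0, u_direct=4.0,
                        j_exchange=0.8, core_valence_attraction=5.0,
                        ligand_orbitals=1, ligand_energies=(-3.0,),
                        ligand_hopping=0.5),
            n_elec=14,
        ),
        Fixture(
            "rixs_small",
            ModelParams(core_orbitals=3, valence_orbitals=3,
                        crystal_field=(0.0, 0.5, 1.0), zeta_core=8.0,
                        u_direct=4.0, j_exchange=0.8,
                        core_valence_attraction=5.0),
            n_elec=8,
        ),
    ]
}


def fixture(name: str) -> Fixture:
    try:
        return FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}") from None


def fixture_names() -> tuple[str, ...]:
    return tuple(FIXTURES)
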