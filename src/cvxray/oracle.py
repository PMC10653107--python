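"""Sum-over-states reference spectra by dense diagonalization.

The correction vectors admit the formal expansions

    A_l(w_ex)  = sum_I |Psi_I> <Psi_I| mu_l |Psi0> / (E0 + w_ex - E_I + i eta)
    B_rl       = sum_F |Psi_F> [sum_I <Psi_F|mu_r|Psi_I><Psi_I|mu_l|Psi0>
                   / (E0 + w_ex - E_I + i eta)] / (E0 + w_ex - w_em - E_F + i eta')

so the spectral quantities become explicit sums over eigenstates — the
resonant Kramers-Heisenberg form for RIXS.  This module evaluates those sums
from a full diagonalization and serves as the independent oracle for the
iterative correction-vector pipeline; it is capped at desk-scale dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .integrals import IntegralSet
from .operators import GroundState, StateVector, dipole_matrix, get_hamiltonian
from .ras import DeterminantSpace
from .response import FrequencyGrid, Spectrum
from .units import HARTREE_EV, ev_to_ha

__all__ = [
    "EigenDecomposition",
    "diagonalize",
    "sos_xas",
    "sos_rixs",
    "normalize_spectrum",
    "DimensionError",
]

DENSE_CAP = 2000


class DimensionError(ValueError):
    """Space dimension exceeds the dense-diagonalization cap."""


@dataclass
class EigenDecomposition:
    space: DeterminantSpace
    energies: np.ndarray  # Hartree, ascending
    vectors: np.ndarray  # columns are eigenvectors

    def ground_manifold(self, degeneracy_tol: float = 1e-6) -> GroundState:
        e0 = float(self.energies[0])
        sel = np.nonzero(self.energies <= e0 + degeneracy_tol)[0]
        states = [StateVector(self.space, self.vectors[:, i]) for i in sel]
        return GroundState(e0, states, degeneracy_tol)


def diagonalize(
    ints: IntegralSet, space: DeterminantSpace, cap: int = DENSE_CAP
) -> EigenDecomposition:
    if space.dim > cap:
        raise DimensionError(f"dimension {space.dim} exceeds dense cap {cap}")
    h = get_hamiltonian(ints, space).to_dense()
    evals, evecs = scipy.linalg.eigh(h)
    return EigenDecomposition(space, evals, evecs)


def sos_xas(
    ints: IntegralSet,
    eig: EigenDecomposition,
    gs: GroundState,
    grid: FrequencyGrid,
) -> Spectrum:
    """S(w) = (1/pi) sum_{I,l} |<Psi_I|mu_l|Psi0>|^2 eta/((E0+w-E_I)^2+eta^2),
    manifold-averaged, on the eV axis."""
    space = eig.space
    de_ev = (eig.energies - gs.energy) * HARTREE_EV
    eta = grid.eta
    total = np.zeros(len(grid.values))
    for g in gs.states:
        for c in range(3):
            mu_g = dipole_matrix(ints, c, space) @ g.amp
            mom2 = np.abs(eig.vectors.conj().T @ mu_g) ** 2
            total += (eta / np.pi) * np.sum(
                mom2[:, None] / ((grid.values[None, :] - de_ev[:, None]) ** 2 + eta**2),
                axis=0,
            )
    total /= gs.n_states
    return Spectrum(grid, total, meta={"kind": "xas_sos", "n_ground": gs.n_states})


def sos_rixs(
    ints: IntegralSet,
    eig: EigenDecomposition,
    gs: GroundState,
    omega_ex: float,
    loss_grid: FrequencyGrid,
) -> Spectrum:
    """Resonant Kramers-Heisenberg double sum on the energy-loss axis."""
    if loss_grid.eta_prime is None:
        raise ValueError("RIXS needs eta_prime on the loss grid")
    space = eig.space
    de_ev = (eig.energies - gs.energy) * HARTREE_EV  # eigenstate energies above E0
    eta = loss_grid.eta
    etap = loss_grid.eta_prime
    total = np.zeros(len(loss_grid.values))
    denom1 = omega_ex - de_ev + 1j * eta  # (E0 + w_ex - E_I) + i eta, in eV
    for g in gs.states:
        weight_f = np.zeros(len(de_ev))
        for lam in range(3):
            mu_g = dipole_matrix(ints, lam, space) @ g.amp
            # a_coef = <I|mu_l|0> / (z1 - E_I), denominators in Hartree
            a_coef = (eig.vectors.conj().T @ mu_g) / ev_to_ha(denom1)
            a_vec = eig.vectors @ a_coef
            for rho in range(3):
                mu_a = dipole_matrix(ints, rho, space) @ a_vec
                t_f = eig.vectors.conj().T @ mu_a
                weight_f += np.abs(t_f) ** 2
        lor = (ev_to_ha(etap) / np.pi) / (
            (ev_to_ha(loss_grid.values[None, :] - de_ev[:, None])) ** 2 + ev_to_ha(etap) ** 2
        )
        total += np.sum(weight_f[:, None] * lor, axis=0)
    total /= gs.n_states * HARTREE_EV
    return Spectrum(
        loss_grid,
        total,
        meta={"kind": "rixs_sos", "omega_ex_eV": omega_ex, "n_ground": gs.n_states},
    )


def normalize_spectrum(
    spec: Spectrum,
    target: float = 1.0,
    window: tuple[float, float] | None = None,
) -> Spectrum:
    """Scale so the maximum total intensity inside ``window`` equals ``target``.

    Component columns are scaled by the same factor, preserving sum rules;
    the factor is recorded in the metadata.
    """
    vals = spec.grid.values
    mask = np.ones_like(vals, dtype=bool) if window is None else (vals >= window[0]) & (vals <= window[1])
    if not mask.any():
        raise ValueError("window does not intersect the grid")
    peak = float(np.max(spec.total[mask]))
    if peak <= 0:
        raise ValueError("cannot normalize an identically zero spectrum")
    scale = target / peak
    return Spectrum(
        spec.grid,
        spec.total * scale,
        components={k: np.asarray(v) * scale for k, v in spec.components.items()},
        meta={**spec.meta, "normalization_scale": scale, "normalization_target": target},
    )
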