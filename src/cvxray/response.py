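"""Correction-vector response: shifted linear solves and XAS/RIXS spectra.

The correction vector (CV) for a frequency z with Im z = eta > 0 is
C = (z - H)^(-1) X, obtained by solving (z - H) C = X rather than by summing
over eigenstates.  The XAS spectral function and the (resonant,
orientation-averaged) RIXS cross section follow from the CV norms:

    (z1 - H) A_l(w_ex) = mu_l |Psi0>,     z1 = E0 + w_ex + i eta
    S(w_ex) = (eta/pi) sum_l <A_l|A_l>

    (z2 - H) B_rl(w_ex, w_em) = mu_r A_l(w_ex),
    z2 = E0 + w_ex - w_em + i eta'
    sigma(w_ex, w_em) = (eta'/pi) sum_rl <B_rl|B_rl>

(both identical to -(1/pi) Im of the corresponding resolvent matrix element
for Hermitian H).  Spectra are averaged uniformly over a degenerate ground
manifold and reported on an eV axis; RIXS uses the energy-loss axis
w_ex - w_em by default.

The shifted systems for all frequencies share a Krylov space of H, so they
are solved together by the Lanczos process with full reorthogonalization;
the per-shift residual is available in closed form and every solve is
verified against the requested tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.linalg as spla

from .integrals import IntegralSet
from .operators import GroundState, StateVector, dipole_matrix, get_hamiltonian
from .units import HARTREE_EV, ev_to_ha

__all__ = [
    "FrequencyGrid",
    "Spectrum",
    "SolverError",
    "resolvent_apply",
    "shifted_solve",
    "xas_spectrum",
    "select_omega_ex",
    "rixs_spectrum",
]


class SolverError(RuntimeError):
    """Linear solver failed to reach the requested residual."""

    def __init__(self, msg, achieved=None):
        super().__init__(msg)
        self.achieved = achieved


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered energy grid (eV) with Lorentzian broadenings (eV)."""

    values: np.ndarray
    eta: float
    eta_prime: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or len(v) == 0 or np.any(np.diff(v) <= 0):
            raise ValueError("grid values must be strictly increasing")
        if self.eta <= 0 or (self.eta_prime is not None and self.eta_prime <= 0):
            raise ValueError("broadenings must be positive")

    @classmethod
    def linspace(cls, emin, emax, step, eta, eta_prime=None) -> "FrequencyGrid":
        npts = int(round((emax - emin) / step)) + 1
        return cls(np.linspace(emin, emax, npts), eta, eta_prime)


@dataclass
class Spectrum:
    """Frequency grid plus total and component-resolved intensities."""

    grid: FrequencyGrid
    total: np.ndarray
    components: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def component_sum(self) -> np.ndarray:
        return np.sum([np.asarray(v) for v in self.components.values()], axis=0)

    def integrate(self, values: np.ndarray | None = None) -> float:
        y = self.total if values is None else values
        return float(np.trapezoid(y, self.grid.values))

    def write_tsv(self, path: str) -> None:
        keys = list(self.components)
        with open(path, "w") as fh:
            for k, v in sorted(self.meta.items()):
                fh.write(f"# {k} = {v}\n")
            fh.write(f"# eta_eV = {self.grid.eta}\n")
            if self.grid.eta_prime is not None:
                fh.write(f"# eta_prime_eV = {self.grid.eta_prime}\n")
            fh.write("energy_eV\ttotal" + "".join("\t" + str(k) for k in keys) + "\n")
            for i, e in enumerate(self.grid.values):
                row = [f"{e:.10g}", f"{self.total[i]:.12e}"]
                row += [f"{np.asarray(self.components[k])[i]:.12e}" for k in keys]
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Shifted Lanczos resolvent solver


def _tridiag_solve(alphas, betas, z, beta0):
    """Solve (z I - T_m) y = beta0 e1 for symmetric tridiagonal T."""
    m = len(alphas)
    ab = np.zeros((3, m), dtype=complex)
    ab[1] = z - np.asarray(alphas)
    if m > 1:
        ab[0, 1:] = -np.asarray(betas[: m - 1])
        ab[2, : m - 1] = -np.asarray(betas[: m - 1])
    rhs = np.zeros(m, dtype=complex)
    rhs[0] = beta0
    return scipy.linalg.solve_banded((1, 1), ab, rhs)


def resolvent_apply(
    hmat,
    rhs: np.ndarray,
    zs: np.ndarray,
    tol: float = 1e-10,
    max_krylov: int | None = None,
    check_every: int = 20,
):
    """Compute (z - H)^(-1) rhs for every z at once via shifted Lanczos.

    Returns an array of shape (dim, len(zs)).  The relative residual
    ||(z-H)C - rhs|| / ||rhs|| is bounded by ``tol`` for every shift
    (exact residuals from the Lanczos recurrence); raises
    :class:`SolverError` when the Krylov cap is reached first.
    """
    zs = np.atleast_1d(np.asarray(zs, dtype=complex))
    if np.any(zs.imag == 0):
        raise ValueError("shifts must have a nonzero imaginary part")
    dim = rhs.shape[0]
    beta0 = np.linalg.norm(rhs)
    if beta0 == 0:
        return np.zeros((dim, len(zs)), dtype=complex)
    cap = dim if max_krylov is None else min(max_krylov, dim)
    v_list = np.empty((cap + 1, dim), dtype=complex)
    v_list[0] = rhs / beta0
    alphas: list[float] = []
    betas: list[float] = []
    m = 0
    exhausted = False
    while True:
        w = hmat @ v_list[m]
        alpha = float(np.vdot(v_list[m], w).real)
        w = w - alpha * v_list[m]
        if m > 0:
            w = w - betas[m - 1] * v_list[m - 1]
        # full reorthogonalization keeps the Krylov basis numerically exact
        w = w - v_list[: m + 1].T @ (v_list[: m + 1].conj() @ w)
        beta = float(np.linalg.norm(w))
        alphas.append(alpha)
        betas.append(beta)
        m += 1
        invariant = beta < 1e-13 * max(1.0, abs(alpha))
        if invariant or m == cap or m % check_every == 0:
            ys = [_tridiag_solve(alphas, betas, z, beta0) for z in zs]
            resid = np.array([betas[m - 1] * abs(y[-1]) / beta0 for y in ys])
            if invariant:
                resid[:] = 0.0
            if np.all(resid <= tol):
                ymat = np.stack(ys, axis=1)
                return v_list[:m].T @ ymat
            if invariant or m == cap:
                exhausted = True
                break
        v_list[m] = w / beta
    raise SolverError(
        f"shifted Lanczos stagnated at Krylov dimension {m} "
        f"(worst relative residual {float(np.max(resid)):.3e})",
        achieved=float(np.max(resid)),
    )


def shifted_solve(
    ints: IntegralSet,
    space,
    z: complex,
    rhs: StateVector,
    tol: float = 1e-6,
    method: str = "lanczos",
    max_krylov: int | None = None,
) -> StateVector:
    """Solve (z - H) C = rhs to relative residual ``tol`` (one shift).

    ``method`` is "lanczos" (shared-Krylov solver), "gmres" (diagonally
    preconditioned) or "dense" (LU).  The residual is verified explicitly.
    """
    if np.imag(z) == 0:
        raise ValueError("z must have a nonzero imaginary part (eta > 0)")
    h = get_hamiltonian(ints, space)
    b = rhs.amp
    nb = np.linalg.norm(b)
    if nb == 0:
        return StateVector(space, np.zeros(space.dim, dtype=complex))
    if method == "lanczos":
        x = resolvent_apply(h.matrix, b, [z], tol=tol, max_krylov=max_krylov)[:, 0]
    elif method == "dense":
        a = z * np.eye(space.dim, dtype=complex) - h.to_dense()
        x = np.linalg.solve(a, b)
    elif method == "gmres":
        a = spla.LinearOperator(
            (space.dim, space.dim), matvec=lambda v: z * v - h.matvec(v), dtype=complex
        )
        dinv = 1.0 / (z - h.diagonal())
        prec = spla.LinearOperator((space.dim, space.dim), matvec=lambda v: dinv * v, dtype=complex)
        x, info = spla.gmres(a, b, rtol=tol * 0.1, atol=0.0, M=prec, maxiter=space.dim, restart=200)
        if info != 0:
            achieved = np.linalg.norm(z * x - h.matvec(x) - b) / nb
            raise SolverError(f"GMRES stagnated (info={info})", achieved=achieved)
    else:
        raise ValueError(f"unknown method {method!r}")
    achieved = float(np.linalg.norm(z * x - h.matvec(x) - b) / nb)
    if achieved > tol * 1.01:
        raise SolverError(
            f"solver met its own criterion but residual {achieved:.3e} > tol {tol:.1e}",
            achieved=achieved,
        )
    return StateVector(space, x)


# ---------------------------------------------------------------------------
# Spectra


def xas_spectrum(
    ints: IntegralSet,
    gs: GroundState,
    grid: FrequencyGrid,
    tol: float = 1e-10,
    max_krylov: int | None = None,
) -> Spectrum:
    """XAS spectral function from correction vectors, ground-manifold averaged.

    Intensities are per eV: an isolated transition of moment m at energy D
    appears as (m^2/pi) * eta / ((w - D)^2 + eta^2) on the eV axis.
    """
    space = gs.states[0].space
    h = get_hamiltonian(ints, space)
    eta_ha = ev_to_ha(grid.eta)
    zs = gs.energy + ev_to_ha(grid.values) + 1j * eta_ha
    total = np.zeros(len(grid.values))
    for g in gs.states:
        for c in range(3):
            b = dipole_matrix(ints, c, space) @ g.amp
            if np.linalg.norm(b) == 0:
                continue
            cv = resolvent_apply(h.matrix, b, zs, tol=tol, max_krylov=max_krylov)
            total += (eta_ha / np.pi) * np.sum(np.abs(cv) ** 2, axis=0)
    total /= gs.n_states * HARTREE_EV
    return Spectrum(grid, total, meta={"kind": "xas", "n_ground": gs.n_states})


def select_omega_ex(spec: Spectrum, l3_window: tuple[float, float]) -> float:
    """Grid energy of maximum total intensity inside the window (ties: lower)."""
    lo, hi = l3_window
    mask = (spec.grid.values >= lo) & (spec.grid.values <= hi)
    if not mask.any():
        raise ValueError("window does not intersect the grid")
    vals = np.where(mask, spec.total, -np.inf)
    return float(spec.grid.values[int(np.argmax(vals))])


def rixs_spectrum(
    ints: IntegralSet,
    gs: GroundState,
    omega_ex: float,
    loss_grid: FrequencyGrid,
    tol: float = 1e-10,
    max_krylov: int | None = None,
) -> Spectrum:
    """Resonant RIXS cross section at fixed incident energy, on a loss axis.

    ``loss_grid.eta`` broadens the intermediate (core-excited) resolvent and
    ``loss_grid.eta_prime`` the final-state resolvent.  Intensities are
    relative (overall prefactors normalized away).
    """
    if loss_grid.eta_prime is None:
        raise ValueError("RIXS needs eta_prime on the loss grid")
    space = gs.states[0].space
    h = get_hamiltonian(ints, space)
    eta_ha = ev_to_ha(loss_grid.eta)
    etap_ha = ev_to_ha(loss_grid.eta_prime)
    z1 = gs.energy + ev_to_ha(omega_ex) + 1j * eta_ha
    zs2 = gs.energy + ev_to_ha(loss_grid.values) + 1j * etap_ha
    total = np.zeros(len(loss_grid.values))
    for g in gs.states:
        for lam in range(3):
            b1 = dipole_matrix(ints, lam, space) @ g.amp
            if np.linalg.norm(b1) == 0:
                continue
            a_cv = resolvent_apply(h.matrix, b1, [z1], tol=tol, max_krylov=max_krylov)[:, 0]
            for rho in range(3):
                b2 = dipole_matrix(ints, rho, space) @ a_cv
                if np.linalg.norm(b2) == 0:
                    continue
                bb = resolvent_apply(h.matrix, b2, zs2, tol=tol, max_krylov=max_krylov)
                total += (etap_ha / np.pi) * np.sum(np.abs(bb) ** 2, axis=0)
    total /= gs.n_states * HARTREE_EV
    return Spectrum(
        loss_grid,
        total,
        meta={"kind": "rixs", "omega_ex_eV": omega_ex, "n_ground": gs.n_states},
    )
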