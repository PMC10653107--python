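"""Deconvolution of XAS/RIXS spectra into particle-hole and spin channels.

Particle-hole channels.  The dipole operator is a sum of one-body excitation
terms, mu_l = sum_pq d^l_pq E_pq, so the correction-vector right-hand side
splits exactly into orbital-pair contributions d^l_pq E_pq |Psi0>.  Solving
the shifted equation for each piece gives component correction vectors whose
sum is the total CV, and the cross-term spectra

    S_ia(w) = (eta/pi) sum_l Re <A^(ph)_l,ia | A_l>

sum to the total spectrum pointwise by construction.  On resonance
S_ia measures the amplitude of the i -> a excitation in the final state.
For RIXS the net transition is valence -> valence: the absorption solve is
decomposed by the created (particle) orbital and the emission solve by the
annihilated valence (hole) orbital; pieces that do not correspond to a
core-mediated valence-to-valence path are aggregated into a flagged channel
so that the sum rule remains exact.

Spin channels.  Lowdin's projector P_S = prod_{S' != S} (S^2 - S'(S'+1)) /
(S(S+1) - S'(S'+1)) resolves the identity over the attainable total spins of
the space, so S_S = (eta/pi) sum_l ||P_S A_l||^2 sums to the total exactly.

Deconvolution labels live in the orbital basis used for the solve; passing a
basis rotation (e.g. natural orbitals of the ground-state wave function)
re-expresses the integrals and recomputes the ground state in that basis
(totals are invariant under active-space rotations).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .integrals import IntegralSet
from .operators import (
    GroundState,
    StateVector,
    get_hamiltonian,
    ground_state,
    one_body_matrix,
    s2_matrix,
)
from .response import FrequencyGrid, Spectrum, resolvent_apply
from .units import HARTREE_EV, ev_to_ha

__all__ = [
    "PHKey",
    "OrbitalSetPair",
    "SpinChannel",
    "natural_orbital_basis",
    "ph_decompose_xas",
    "ph_decompose_rixs",
    "valence_sums",
    "average_ph",
    "attainable_spins",
    "spin_project",
    "spin_decompose_xas",
    "spin_decompose_rixs",
    "sumrule_check",
]


@dataclass(frozen=True)
class PHKey:
    """Hole/particle orbital pair labelling one deconvolution channel.

    ``hole == particle`` marks the elastic channel; ``hole == particle == -1``
    is the aggregated channel of contributions outside the requested
    particle-hole classification (kept so sum rules stay exact).
    """

    hole: int
    particle: int
    hole_label: str = ""
    particle_label: str = ""
    valence_to_valence: bool = False

    @property
    def elastic(self) -> bool:
        return self.hole == self.particle and self.hole >= 0

    @property
    def aggregated(self) -> bool:
        return self.hole < 0

    def __str__(self) -> str:
        if self.aggregated:
            return "ph:other"
        return f"ph:{self.hole_label or self.hole}->{self.particle_label or self.particle}"


@dataclass(frozen=True)
class OrbitalSetPair:
    """Hole-set/particle-set pair for averaged particle-hole contributions."""

    holes: tuple[int, ...]
    particles: tuple[int, ...]
    label: str = ""

    def __post_init__(self):
        if not self.holes or not self.particles:
            raise ValueError("hole and particle sets must be nonempty")


@dataclass(frozen=True)
class SpinChannel:
    """Total spin S and the excluded spins S' entering the Lowdin product."""

    s: float
    excluded: tuple[float, ...]


def attainable_spins(space) -> tuple[float, ...]:
    """All total spins attainable with n_elec electrons in n_orb orbitals."""
    n_elec = space.spec.n_elec
    n_orb = space.spec.n_orb
    s_max = min(n_elec, 2 * n_orb - n_elec) / 2.0
    s_min = (n_elec % 2) / 2.0
    out = []
    s = s_min
    while s <= s_max + 1e-9:
        out.append(s)
        s += 1.0
    return tuple(out)


# ---------------------------------------------------------------------------
# Natural orbitals


def _rdm1_spin_summed(gs: GroundState) -> np.ndarray:
    """Spin-summed one-particle RDM averaged over the ground manifold."""
    space = gs.states[0].space
    n = space.spec.n_orb
    dm = np.zeros((n, n), dtype=complex)
    from .ras import excitation_apply

    for g in gs.states:
        amp = g.amp
        for col, det in enumerate(space.dets):
            det = int(det)
            if amp[col] == 0:
                continue
            for s in range(2):
                for q in range(n):
                    if not det >> (q + s * n) & 1:
                        continue
                    for p in range(n):
                        res = excitation_apply(det, p + s * n, q + s * n)
                        if res is None:
                            continue
                        tgt, sign = res
                        pos = space.index.get(tgt)
                        if pos is not None:
                            dm[p, q] += sign * np.conj(amp[pos]) * amp[col]
    dm /= gs.n_states
    return dm


def natural_orbital_basis(ints: IntegralSet, gs: GroundState) -> np.ndarray:
    """Real orthogonal rotation to natural orbitals, blocked by shell.

    Diagonalizes the (manifold-averaged, symmetrized real part of the)
    spin-summed 1-RDM within each shell block separately so partition and
    shell tags keep their meaning; columns are sorted by descending
    occupation and signed so the largest-magnitude coefficient is positive.
    """
    dm = _rdm1_spin_summed(gs)
    d = 0.5 * (dm.real + dm.real.T)
    n = d.shape[0]
    shells = ints.space.shell
    u = np.eye(n)
    for tag in sorted(set(shells)):
        idx = [i for i in range(n) if shells[i] == tag]
        sub = d[np.ix_(idx, idx)]
        occ, vec = np.linalg.eigh(sub)
        order = np.argsort(-occ)
        vec = vec[:, order]
        for c in range(vec.shape[1]):
            k = int(np.argmax(np.abs(vec[:, c])))
            if vec[k, c] < 0:
                vec[:, c] = -vec[:, c]
        u[np.ix_(idx, idx)] = vec
    return u


# ---------------------------------------------------------------------------
# Shared helpers


def _prepare(ints: IntegralSet, gs: GroundState, basis: np.ndarray | None):
    """Optionally rotate the integrals and recompute the ground state."""
    if basis is None:
        return ints, gs
    basis = np.asarray(basis, dtype=float)
    n = ints.n_orb
    if basis.shape != (n, n) or not np.allclose(basis.T @ basis, np.eye(n), atol=1e-10):
        raise ValueError("basis must be a real orthogonal active-space rotation")
    rotated = ints.rotate(basis)
    space = gs.states[0].space
    gs2 = ground_state(rotated, space, degeneracy_tol=gs.degeneracy_tol)
    return rotated, gs2


def _pair_rhs_terms(ints: IntegralSet, comp: int, space, amp: np.ndarray):
    """Split mu_comp |amp> into ordered-orbital-pair pieces d_pq E_pq |amp>.

    Returns [((p, q), vector), ...]; pieces of numerically vanishing norm
    (relative to the largest piece) are dropped.  The sum of the returned
    vectors equals mu_comp |amp> to machine precision.
    """
    n = ints.n_orb
    d = ints.dip[comp]
    pieces = []
    for p in range(n):
        for q in range(n):
            if d[p, q] == 0.0:
                continue
            w = np.zeros((2 * n, 2 * n), dtype=complex)
            w[p, q] = d[p, q]
            w[n + p, n + q] = d[p, q]
            vec = one_body_matrix(space, w) @ amp
            nrm = np.linalg.norm(vec)
            if nrm > 0:
                pieces.append(((p, q), vec, nrm))
    if not pieces:
        return []
    cut = 1e-12 * max(nrm for _, _, nrm in pieces)
    return [(pq, vec) for pq, vec, nrm in pieces if nrm > cut]


def _labels(ints: IntegralSet):
    return ints.space.labels


# ---------------------------------------------------------------------------
# Particle-hole deconvolution


def ph_decompose_xas(
    ints: IntegralSet,
    gs: GroundState,
    grid: FrequencyGrid,
    basis: np.ndarray | None = None,
    tol: float = 1e-10,
) -> Spectrum:
    """XAS spectrum with components keyed by (hole, particle) orbital pairs."""
    ints, gs = _prepare(ints, gs, basis)
    space = gs.states[0].space
    h = get_hamiltonian(ints, space)
    labels = _labels(ints)
    shell = ints.space.shell
    eta_ha = ev_to_ha(grid.eta)
    zs = gs.energy + ev_to_ha(grid.values) + 1j * eta_ha
    total = np.zeros(len(grid.values))
    comps: dict[PHKey, np.ndarray] = {}
    for g in gs.states:
        for lam in range(3):
            pieces = list(_pair_rhs_terms(ints, lam, space, g.amp))
            if not pieces:
                continue
            solved = [
                ((p, q), resolvent_apply(h.matrix, vec, zs, tol=tol))
                for (p, q), vec in pieces
            ]
            cv_total = np.sum([cv for _, cv in solved], axis=0)
            total += (eta_ha / np.pi) * np.sum(np.abs(cv_total) ** 2, axis=0)
            for (p, q), cv in solved:
                key = PHKey(
                    hole=q,
                    particle=p,
                    hole_label=labels[q],
                    particle_label=labels[p],
                    valence_to_valence=(shell[p] == "valence" and shell[q] == "valence"),
                )
                contrib = (eta_ha / np.pi) * np.sum(np.real(np.conj(cv) * cv_total), axis=0)
                comps[key] = comps.get(key, 0.0) + contrib
    scale = gs.n_states * HARTREE_EV
    total /= scale
    comps = {k: np.asarray(v) / scale for k, v in comps.items()}
    return Spectrum(
        grid, total, components=comps, meta={"kind": "xas_ph", "n_ground": gs.n_states}
    )


def ph_decompose_rixs(
    ints: IntegralSet,
    gs: GroundState,
    omega_ex: float,
    loss_grid: FrequencyGrid,
    basis: np.ndarray | None = None,
    tol: float = 1e-10,
) -> Spectrum:
    """RIXS spectrum with valence -> valence particle-hole components.

    The absorption CV is split by the orbital the electron is created in and
    the emission right-hand side by the valence orbital the emitted electron
    leaves from; a channel (hole=v, particle=a) then tracks the net
    valence v -> valence a transition of the final state.  Everything not of
    that core-mediated form is collected in the aggregated "other" channel.
    The integrated valence-to-valence fraction is reported in the metadata.
    """
    if loss_grid.eta_prime is None:
        raise ValueError("RIXS needs eta_prime on the loss grid")
    ints, gs = _prepare(ints, gs, basis)
    space = gs.states[0].space
    h = get_hamiltonian(ints, space)
    labels = _labels(ints)
    shell = ints.space.shell
    eta_ha = ev_to_ha(loss_grid.eta)
    etap_ha = ev_to_ha(loss_grid.eta_prime)
    z1 = gs.energy + ev_to_ha(omega_ex) + 1j * eta_ha
    zs2 = gs.energy + ev_to_ha(loss_grid.values) + 1j * etap_ha
    npts = len(loss_grid.values)
    total = np.zeros(npts)
    comps: dict[PHKey, np.ndarray] = {}
    other_key = PHKey(hole=-1, particle=-1)
    for g in gs.states:
        for lam in range(3):
            # absorption channels keyed by the created (particle) orbital
            abs_chan: dict[object, np.ndarray] = {}
            for (p, q), vec in _pair_rhs_terms(ints, lam, space, g.amp):
                tag = p if (shell[q] == "core" and shell[p] == "valence") else "other"
                abs_chan[tag] = abs_chan.get(tag, 0.0) + vec
            if not abs_chan:
                continue
            a_cv = {
                tag: resolvent_apply(h.matrix, vec, [z1], tol=tol)[:, 0]
                for tag, vec in abs_chan.items()
            }
            for rho in range(3):
                b_solved: list[tuple[object, np.ndarray]] = []
                for a_tag, avec in a_cv.items():
                    em_chan: dict[object, np.ndarray] = {}
                    for (p2, q2), vec in _pair_rhs_terms(ints, rho, space, avec):
                        tag = (
                            q2
                            if (shell[p2] == "core" and shell[q2] == "valence")
                            else "other"
                        )
                        em_chan[tag] = em_chan.get(tag, 0.0) + vec
                    for v_tag, vec in em_chan.items():
                        bb = resolvent_apply(h.matrix, vec, zs2, tol=tol)
                        b_solved.append(((a_tag, v_tag), bb))
                if not b_solved:
                    continue
                b_total = np.sum([bb for _, bb in b_solved], axis=0)
                total += (etap_ha / np.pi) * np.sum(np.abs(b_total) ** 2, axis=0)
                for (a_tag, v_tag), bb in b_solved:
                    if a_tag == "other" or v_tag == "other":
                        key = other_key
                    else:
                        key = PHKey(
                            hole=v_tag,
                            particle=a_tag,
                            hole_label=labels[v_tag],
                            particle_label=labels[a_tag],
                            valence_to_valence=True,
                        )
                    contrib = (etap_ha / np.pi) * np.sum(
                        np.real(np.conj(bb) * b_total), axis=0
                    )
                    comps[key] = comps.get(key, 0.0) + contrib
    scale = gs.n_states * HARTREE_EV
    total /= scale
    comps = {k: np.asarray(v) / scale for k, v in comps.items()}
    vv = np.zeros(npts)
    for k, v in comps.items():
        if isinstance(k, PHKey) and k.valence_to_valence:
            vv += v
    denom = float(np.trapezoid(total, loss_grid.values))
    frac = float(np.trapezoid(vv, loss_grid.values)) / denom if denom > 0 else np.nan
    return Spectrum(
        loss_grid,
        total,
        components=comps,
        meta={
            "kind": "rixs_ph",
            "omega_ex_eV": omega_ex,
            "n_ground": gs.n_states,
            "valence_to_valence_fraction": frac,
        },
    )


def valence_sums(spec: Spectrum) -> dict:
    """Particle (valence) contributions: sum components over the hole index."""
    out: dict[str, np.ndarray] = {}
    for k, v in spec.components.items():
        if isinstance(k, PHKey) and not k.aggregated:
            key = k.particle_label or str(k.particle)
            out[key] = out.get(key, 0.0) + np.asarray(v)
    return out


def average_ph(components: dict, pair: OrbitalSetPair) -> np.ndarray:
    """Average particle-hole contribution over a hole set H and particle set P:
    (1/(N_H N_P)) sum_{i in H, a in P} sigma_ia."""
    by_pair = {
        (k.hole, k.particle): np.asarray(v)
        for k, v in components.items()
        if isinstance(k, PHKey) and not k.aggregated
    }
    acc = None
    for i in pair.holes:
        for a in pair.particles:
            if (i, a) not in by_pair:
                raise KeyError(f"missing particle-hole component ({i}, {a})")
            acc = by_pair[(i, a)] if acc is None else acc + by_pair[(i, a)]
    return acc / (len(pair.holes) * len(pair.particles))


# ---------------------------------------------------------------------------
# Spin deconvolution


def _project_columns(space, mat: np.ndarray, s: float, spins) -> np.ndarray:
    """Apply the Lowdin projector P_S to every column of ``mat``."""
    s2 = s2_matrix(space)
    out = np.array(mat, dtype=complex, copy=True)
    c = s * (s + 1)
    for sp in sorted((x for x in spins if x != s), reverse=True):
        cp = sp * (sp + 1)
        out = (s2 @ out - cp * out) / (c - cp)
    return out


def spin_project(channel: SpinChannel | float, v: StateVector, spins=None) -> StateVector:
    """Lowdin projection of a state onto total spin S.

    Idempotent; annihilates pure-S' components for S' != S.  ``spins`` (or
    the channel's ``excluded`` list plus S) defaults to every spin attainable
    in the space.
    """
    space = v.space
    if isinstance(channel, SpinChannel):
        s = channel.s
        spins = (channel.s, *channel.excluded)
    else:
        s = float(channel)
        if spins is None:
            spins = attainable_spins(space)
    if s not in spins:
        raise ValueError(f"spin {s} not attainable in this space")
    out = _project_columns(space, v.amp[:, None], s, spins)[:, 0]
    return StateVector(space, out)


def spin_decompose_xas(
    ints: IntegralSet,
    gs: GroundState,
    grid: FrequencyGrid,
    channels=None,
    tol: float = 1e-10,
) -> Spectrum:
    """XAS spectrum resolved into total-spin channels of the final states."""
    space = gs.states[0].space
    spins = tuple(channels) if channels is not None else attainable_spins(space)
    h = get_hamiltonian(ints, space)
    eta_ha = ev_to_ha(grid.eta)
    zs = gs.energy + ev_to_ha(grid.values) + 1j * eta_ha
    total = np.zeros(len(grid.values))
    comps = {s: np.zeros(len(grid.values)) for s in spins}
    from .operators import dipole_matrix

    for g in gs.states:
        for lam in range(3):
            b = dipole_matrix(ints, lam, space) @ g.amp
            if np.linalg.norm(b) == 0:
                continue
            cv = resolvent_apply(h.matrix, b, zs, tol=tol)
            total += (eta_ha / np.pi) * np.sum(np.abs(cv) ** 2, axis=0)
            for s in spins:
                proj = _project_columns(space, cv, s, spins)
                comps[s] += (eta_ha / np.pi) * np.sum(np.abs(proj) ** 2, axis=0)
    scale = gs.n_states * HARTREE_EV
    total /= scale
    comps = {s: v / scale for s, v in comps.items()}
    spec = Spectrum(
        grid, total, components=comps, meta={"kind": "xas_spin", "n_ground": gs.n_states}
    )
    spec.meta["channel_percent"] = _channel_percentages(spec)
    _check_spin_sum(spec)
    return spec


def spin_decompose_rixs(
    ints: IntegralSet,
    gs: GroundState,
    omega_ex: float,
    loss_grid: FrequencyGrid,
    channels=None,
    tol: float = 1e-10,
) -> Spectrum:
    """RIXS spectrum resolved into total-spin channels of the final states."""
    if loss_grid.eta_prime is None:
        raise ValueError("RIXS needs eta_prime on the loss grid")
    space = gs.states[0].space
    spins = tuple(channels) if channels is not None else attainable_spins(space)
    h = get_hamiltonian(ints, space)
    eta_ha = ev_to_ha(loss_grid.eta)
    etap_ha = ev_to_ha(loss_grid.eta_prime)
    z1 = gs.energy + ev_to_ha(omega_ex) + 1j * eta_ha
    zs2 = gs.energy + ev_to_ha(loss_grid.values) + 1j * etap_ha
    total = np.zeros(len(loss_grid.values))
    comps = {s: np.zeros(len(loss_grid.values)) for s in spins}
    from .operators import dipole_matrix

    for g in gs.states:
        for lam in range(3):
            b1 = dipole_matrix(ints, lam, space) @ g.amp
            if np.linalg.norm(b1) == 0:
                continue
            a_cv = resolvent_apply(h.matrix, b1, [z1], tol=tol)[:, 0]
            for rho in range(3):
                b2 = dipole_matrix(ints, rho, space) @ a_cv
                if np.linalg.norm(b2) == 0:
                    continue
                bb = resolvent_apply(h.matrix, b2, zs2, tol=tol)
                total += (etap_ha / np.pi) * np.sum(np.abs(bb) ** 2, axis=0)
                for s in spins:
                    proj = _project_columns(space, bb, s, spins)
                    comps[s] += (etap_ha / np.pi) * np.sum(np.abs(proj) ** 2, axis=0)
    scale = gs.n_states * HARTREE_EV
    total /= scale
    comps = {s: v / scale for s, v in comps.items()}
    spec = Spectrum(
        loss_grid,
        total,
        components=comps,
        meta={"kind": "rixs_spin", "omega_ex_eV": omega_ex, "n_ground": gs.n_states},
    )
    spec.meta["channel_percent"] = _channel_percentages(spec)
    _check_spin_sum(spec)
    return spec


def _channel_percentages(spec: Spectrum) -> dict:
    """Integrated share of each channel over the full grid, in percent."""
    x = spec.grid.values
    denom = float(np.trapezoid(spec.total, x))
    if denom <= 0:
        return {k: np.nan for k in spec.components}
    return {
        k: 100.0 * float(np.trapezoid(np.asarray(v), x)) / denom
        for k, v in spec.components.items()
    }


def _check_spin_sum(spec: Spectrum, threshold: float = 1e-6) -> None:
    dev = sumrule_check(spec, spec.components)
    if dev > threshold:
        raise ValueError(
            f"spin channels do not resolve the identity (deviation {dev:.2e}); "
            "the channel list is probably incomplete"
        )


def sumrule_check(total: Spectrum | np.ndarray, components: dict) -> float:
    """Max pointwise |sum(components) - total| / max(total)."""
    tot = total.total if isinstance(total, Spectrum) else np.asarray(total)
    if not components:
        raise ValueError("no components given")
    acc = np.sum([np.asarray(v) for v in components.values()], axis=0)
    if acc.shape != tot.shape:
        raise ValueError("component grids do not match the total")
    scale = float(np.max(np.abs(tot)))
    if scale == 0:
        return float(np.max(np.abs(acc)))
    return float(np.max(np.abs(acc - tot)) / scale)
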