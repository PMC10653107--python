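"""Ligand-field model generator.

Builds an :class:`~cvxray.integrals.IntegralSet` for a crystal-field model of
a 2p -> 3d absorbing centre: a core p shell carrying spin-orbit coupling
``zeta * l.s``, a valence d shell with crystal-field energies and either a
simplified direct/exchange (Hund) two-electron structure or full Slater-Condon
multiplet integrals, a core-valence Coulomb term whose loss on core-hole
creation binds the excited electron, optional filled ligand sigma orbitals
hybridizing with the valence shell, and dipole matrices coupling core to
valence orbitals with the proper p-d angular factors.

All user parameters are in eV (dipoles in a.u.); the generated integrals are
in Hartree.  The fixture stands in for ab initio integrals so the method can
be built and verified without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .integrals import IntegralSet, OrbitalSpace, symmetrize_eri
from .units import ev_to_ha

__all__ = [
    "ModelParams",
    "build_model",
    "angular_momentum_real",
    "real_harmonic_transform",
    "shell_eri_block",
    "d_shell_eri",
]


# ---------------------------------------------------------------------------
# Real spherical harmonics and angular momentum

# Orbital order conventions used throughout the package:
#   p shell: (p_x, p_y, p_z)
#   d shell: (d_z2, d_x2y2, d_xy, d_xz, d_yz)
# i.e. for d: m-character (0, +2c, -2s, +1c, -1s) with c/s = cos/sin type.

_REAL_ORDER = {
    1: [(1, +1), (1, -1), (0, 0)],  # p_x, p_y, p_z as (|m|, cos/sin sign)
    2: [(0, 0), (2, +1), (2, -1), (1, +1), (1, -1)],  # z2, x2y2, xy, xz, yz
}


def real_harmonic_transform(l: int) -> np.ndarray:
    """Unitary U with columns = real harmonics expanded in |l,m>, m=-l..l.

    Real combination for |m|>0 with Condon-Shortley phases:
      cos type: ((-1)^m Y_{l,m} + Y_{l,-m}) / sqrt(2)
      sin type: ((-1)^m Y_{l,m} - Y_{l,-m}) / (i sqrt(2))
    """
    dim = 2 * l + 1
    u = np.zeros((dim, dim), dtype=complex)

    def row(m):
        return m + l

    for col, (am, kind) in enumerate(_REAL_ORDER[l]):
        if am == 0:
            u[row(0), col] = 1.0
        elif kind > 0:
            u[row(am), col] = (-1) ** am / np.sqrt(2)
            u[row(-am), col] = 1 / np.sqrt(2)
        else:
            u[row(am), col] = (-1) ** am / (1j * np.sqrt(2))
            u[row(-am), col] = -1 / (1j * np.sqrt(2))
    return u


def angular_momentum_real(l: int) -> np.ndarray:
    """Cartesian angular momentum matrices (3, 2l+1, 2l+1) over real harmonics.

    Each component is purely imaginary and antisymmetric (hbar = 1).
    """
    dim = 2 * l + 1
    m = np.arange(-l, l + 1)
    lz = np.diag(m).astype(complex)
    lp = np.zeros((dim, dim), dtype=complex)
    for mm in range(-l, l):
        lp[mm + 1 + l, mm + l] = np.sqrt(l * (l + 1) - mm * (mm + 1))
    lm = lp.conj().T
    lx = 0.5 * (lp + lm)
    ly = -0.5j * (lp - lm)
    u = real_harmonic_transform(l)
    return np.stack([u.conj().T @ c @ u for c in (lx, ly, lz)])


@lru_cache(maxsize=None)
def _gaunt(l1, l2, l3, m1, m2, m3) -> float:
    from sympy.physics.wigner import gaunt

    return float(gaunt(l1, l2, l3, m1, m2, m3))


@lru_cache(maxsize=None)
def _complex_eri_block(l1: int, l2: int, l3: int, l4: int, k: int) -> np.ndarray:
    """Angular factor of (12|34) for one multipole rank k, complex harmonics.

    (ij|kl) = sum_k R^k * B_k[m_i, m_j, m_k, m_l] with, from the multipole
    expansion of 1/r12,

      B_k = (4pi/(2k+1)) (-1)^(m_i + m_k + q)
            G(l1,k,l2; -m_i,-q,m_j) G(l3,k,l4; -m_k,q,m_l),  q = m_k - m_l.
    """
    d1, d2, d3, d4 = (2 * l + 1 for l in (l1, l2, l3, l4))
    out = np.zeros((d1, d2, d3, d4))
    pref = 4 * np.pi / (2 * k + 1)
    for i, mi in enumerate(range(-l1, l1 + 1)):
        for j, mj in enumerate(range(-l2, l2 + 1)):
            for a, mk in enumerate(range(-l3, l3 + 1)):
                for b, ml in enumerate(range(-l4, l4 + 1)):
                    q = mk - ml
                    if mj - mi != q:
                        continue
                    g1 = _gaunt(l1, k, l2, -mi, -q, mj)
                    g2 = _gaunt(l3, k, l4, -mk, q, ml)
                    out[i, j, a, b] = pref * (-1) ** (mi + mk + q) * g1 * g2
    return out


def shell_eri_block(l1: int, l2: int, l3: int, l4: int, radial: Mapping[int, float]) -> np.ndarray:
    """Real-harmonic eri block (12|34) from Slater radial integrals R^k.

    ``radial`` maps multipole rank k to R^k (F^k for within-shell charge
    distributions, G^k for cross-shell distributions).  Ranks violating the
    triangle conditions contribute nothing.
    """
    d1, d2, d3, d4 = (2 * l + 1 for l in (l1, l2, l3, l4))
    block = np.zeros((d1, d2, d3, d4), dtype=complex)
    for k, rk in radial.items():
        if rk == 0.0:
            continue
        block += rk * _complex_eri_block(l1, l2, l3, l4, k)
    us = [real_harmonic_transform(l) for l in (l1, l2, l3, l4)]
    # charge distributions are phi_i^* phi_j -> conjugate on axes 0 and 2
    real = np.einsum(
        "pi,qj,rk,sl,pqrs->ijkl",
        us[0].conj(), us[1], us[2].conj(), us[3], block, optimize=True,
    )
    if not np.allclose(real.imag, 0.0, atol=1e-12):
        raise AssertionError("real-harmonic eri block has spurious imaginary part")
    return real.real


def d_shell_eri(f0: float, f2: float, f4: float) -> np.ndarray:
    """(5,5,5,5) Coulomb tensor of a d shell from Slater parameters F0, F2, F4."""
    return shell_eri_block(2, 2, 2, 2, {0: f0, 2: f2, 4: f4})


@lru_cache(maxsize=None)
def _pd_dipole_angular() -> np.ndarray:
    """T[c, i, a] = <p_i | r_c / r | d_a> over real harmonics.

    r_c/r = sqrt(4pi/3) * (real l=1 harmonic c), c in (x, y, z) matching the
    package p order.
    """
    up = real_harmonic_transform(1)
    ud = real_harmonic_transform(2)
    t = np.zeros((3, 3, 5), dtype=complex)
    pref = np.sqrt(4 * np.pi / 3)
    for i in range(3):
        for c in range(3):
            for a in range(5):
                val = 0.0
                for mi_idx, mi in enumerate(range(-1, 2)):
                    for mc_idx, mc in enumerate(range(-1, 2)):
                        for ma_idx, ma in enumerate(range(-2, 3)):
                            coef = (
                                np.conj(up[mi_idx, i]) * up[mc_idx, c] * ud[ma_idx, a]
                            )
                            if coef == 0:
                                continue
                            # int Y*_{1mi} Y_{1mc} Y_{2ma}
                            g = (-1) ** mi * _gaunt(1, 1, 2, -mi, mc, ma)
                            val += coef * g
                t[c, i, a] = pref * val
    if not np.allclose(t.imag, 0.0, atol=1e-12):
        raise AssertionError("p-d dipole angular factors should be real")
    return t.real


# ---------------------------------------------------------------------------
# Model parameters and builder


@dataclass
class ModelParams:
    """Crystal-field model parameters (energies in eV, dipoles in a.u.)."""

    core_orbitals: int = 3
    valence_orbitals: int = 5
    crystal_field: Sequence[float] | None = None
    zeta_core: float = 0.0
    valence_soc: float = 0.0
    u_direct: float = 0.0
    j_exchange: float = 0.0
    core_valence_attraction: float = 0.0
    dipole_strengths: float = 1.0
    core_level_energy: float = -710.0
    ligand_orbitals: int = 0
    ligand_energies: Sequence[float] | None = None
    ligand_hopping: float | Sequence[Sequence[float]] = 0.0
    slater_condon: Mapping[str, float] | None = None
    n_elec: int | None = None  # bookkeeping convenience for fixtures

    def validate(self) -> None:
        if self.core_orbitals < 0 or self.valence_orbitals < 0 or self.ligand_orbitals < 0:
            raise ValueError("orbital counts must be nonnegative")
        if self.crystal_field is not None and len(self.crystal_field) != self.valence_orbitals:
            raise ValueError("crystal_field length must match valence_orbitals")
        if self.ligand_energies is not None and len(self.ligand_energies) != self.ligand_orbitals:
            raise ValueError("ligand_energies length must match ligand_orbitals")
        if self.slater_condon is not None:
            allowed = {"f0_dd", "f2_dd", "f4_dd", "f0_pd", "f2_pd", "g1_pd", "g3_pd"}
            bad = set(self.slater_condon) - allowed
            if bad:
                raise ValueError(f"unknown Slater-Condon parameters {sorted(bad)}")
            if self.valence_orbitals != 5 or (self.core_orbitals not in (0, 3)):
                raise ValueError("Slater-Condon input requires p core (3) and d valence (5)")
        for name in ("zeta_core", "valence_soc", "u_direct", "j_exchange",
                     "core_valence_attraction", "core_level_energy"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.zeta_core != 0.0 and self.core_orbitals != 3:
            raise ValueError("core SOC is defined for a p shell (core_orbitals = 3)")
        if self.valence_soc != 0.0 and self.valence_orbitals != 5:
            raise ValueError("valence SOC is defined for a d shell (valence_orbitals = 5)")


_P_LABELS = ("2p_x", "2p_y", "2p_z")
_D_LABELS = ("3d_z2", "3d_x2y2", "3d_xy", "3d_xz", "3d_yz")


def build_model(params: ModelParams) -> IntegralSet:
    """Assemble the IntegralSet of the crystal-field model (Hartree)."""
    params.validate()
    nc, nv, nl = params.core_orbitals, params.valence_orbitals, params.ligand_orbitals
    if nc == 3:
        core_labels = list(_P_LABELS)
    else:
        core_labels = [f"core_{i + 1}" for i in range(nc)]
    if nv == 5:
        val_labels = list(_D_LABELS)
    else:
        val_labels = [f"val_{i + 1}" for i in range(nv)]
    lig_labels = [f"sigma_{i + 1}" for i in range(nl)]
    space = OrbitalSpace(
        labels=tuple(core_labels + lig_labels + val_labels),
        partition=("RAS1",) * nc + ("RAS1P",) * nl + ("RAS2",) * nv,
        shell=("core",) * nc + ("ligand",) * nl + ("valence",) * nv,
    )
    ints = IntegralSet.zeros(space)
    core = space.indices(shell="core")
    lig = space.indices(shell="ligand")
    val = space.indices(shell="valence")

    # --- one-electron ---
    h1 = np.zeros((space.n_orb, space.n_orb))
    for i in core:
        h1[i, i] = ev_to_ha(params.core_level_energy)
    cf = params.crystal_field if params.crystal_field is not None else [0.0] * nv
    for a, e in zip(val, cf):
        h1[a, a] = ev_to_ha(e)
    le = params.ligand_energies if params.ligand_energies is not None else [0.0] * nl
    for p, e in zip(lig, le):
        h1[p, p] = ev_to_ha(e)
    hop = params.ligand_hopping
    if nl:
        hop_mat = np.full((nl, nv), float(hop)) if np.isscalar(hop) else np.asarray(hop, float)
        if hop_mat.shape != (nl, nv):
            raise ValueError("ligand_hopping must be scalar or (n_ligand, n_valence)")
        for li, p in enumerate(lig):
            for ai, a in enumerate(val):
                h1[p, a] = h1[a, p] = ev_to_ha(hop_mat[li, ai])
    ints.h1 = h1

    # --- spin-orbit: zeta * l.s on each shell (electron convention) ---
    h_soc = np.zeros((3, space.n_orb, space.n_orb), dtype=complex)
    if params.zeta_core != 0.0:
        lmat = angular_momentum_real(1)
        idx = np.ix_(range(3), core, core)
        h_soc[idx] = ev_to_ha(params.zeta_core) * lmat
    if params.valence_soc != 0.0:
        lmat = angular_momentum_real(2)
        idx = np.ix_(range(3), val, val)
        h_soc[idx] = h_soc[idx] + ev_to_ha(params.valence_soc) * lmat
    # enforce exact imaginary antisymmetry and chop rounding noise
    h_soc = 1j * 0.5 * (h_soc.imag - h_soc.imag.transpose(0, 2, 1))
    scale = np.max(np.abs(h_soc)) if np.any(h_soc) else 0.0
    if scale:
        h_soc[np.abs(h_soc) < 1e-14 * scale] = 0.0
    ints.h_soc = h_soc

    # --- two-electron ---
    n = space.n_orb
    eri = np.zeros((n, n, n, n))
    sc = params.slater_condon
    if sc is not None:
        dd = d_shell_eri(
            ev_to_ha(sc.get("f0_dd", 0.0)),
            ev_to_ha(sc.get("f2_dd", 0.0)),
            ev_to_ha(sc.get("f4_dd", 0.0)),
        )
        eri[np.ix_(val, val, val, val)] = dd
        if nc == 3:
            direct = shell_eri_block(
                1, 1, 2, 2, {0: ev_to_ha(sc.get("f0_pd", 0.0)), 2: ev_to_ha(sc.get("f2_pd", 0.0))}
            )
            eri[np.ix_(core, core, val, val)] = direct
            eri[np.ix_(val, val, core, core)] = direct.transpose(2, 3, 0, 1)
            exch = shell_eri_block(
                1, 2, 2, 1, {1: ev_to_ha(sc.get("g1_pd", 0.0)), 3: ev_to_ha(sc.get("g3_pd", 0.0))}
            )
            eri[np.ix_(core, val, val, core)] = exch
            eri[np.ix_(val, core, core, val)] = exch.transpose(3, 2, 1, 0)
            # (pd|pd)-type pair distributions share the same G^k radials
            cross = shell_eri_block(
                1, 2, 1, 2, {1: ev_to_ha(sc.get("g1_pd", 0.0)), 3: ev_to_ha(sc.get("g3_pd", 0.0))}
            )
            eri[np.ix_(core, val, core, val)] = cross
            eri[np.ix_(val, core, val, core)] = cross.transpose(1, 0, 3, 2)
    else:
        u = ev_to_ha(params.u_direct)
        j = ev_to_ha(params.j_exchange)
        for a in val:
            for b in val:
                if a == b:
                    eri[a, a, a, a] = u
                else:
                    eri[a, a, b, b] = u - 2 * j
                    eri[a, b, b, a] = j
                    eri[a, b, a, b] = j
    q = ev_to_ha(params.core_valence_attraction)
    if q != 0.0:
        for i in core:
            for a in val:
                eri[i, i, a, a] = q
                eri[a, a, i, i] = q
    ints.eri = symmetrize_eri(eri)

    # --- dipole: couples core <-> valence only ---
    dip = np.zeros((3, n, n))
    t = float(params.dipole_strengths)
    if t != 0.0 and nc and nv:
        if nc == 3 and nv == 5:
            ang = _pd_dipole_angular()  # (comp, p, d)
            for c in range(3):
                for ii, i in enumerate(core):
                    for aa, a in enumerate(val):
                        dip[c, i, a] = dip[c, a, i] = t * ang[c, ii, aa]
        else:
            for c in range(3):
                for i in core:
                    for a in val:
                        dip[c, i, a] = dip[c, a, i] = t
    scale = np.max(np.abs(dip)) if np.any(dip) else 0.0
    if scale:
        dip[np.abs(dip) < 1e-14 * scale] = 0.0
    ints.dip = dip
    ints.validate(atol=1e-10)
    return ints
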