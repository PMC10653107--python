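"""Second-quantized operators over a RAS determinant space.

The Hamiltonian is

    H = sum_ij h_ij E_ij + 1/2 sum_ijkl (ij|kl) (E_ij E_kl - d_jk E_il)
        + sum_ij sum_c h^BP,c_ij T^c_ij + e_core,

with E_ij the spin-summed excitation operator and T^c the Cartesian triplet
(spin-tensor) operators

    T^x_ij = (a+_ia a_jb + a+_ib a_ja) / 2,
    T^y_ij = (a+_ia a_jb - a+_ib a_ja) / (2i),
    T^z_ij = (a+_ia a_ja - a+_ib a_jb) / 2.

Because the one-body part (spin-free + SOC) is a general one-body operator in
spin-orbital space, H is assembled by Slater-Condon rules with a complex
one-body spin-orbital matrix W = h1 (x) 1 + sum_c h^c (x) s_c and the
spin-free two-electron integrals.  Matrices are cached per
(IntegralSet, DeterminantSpace) pair.
"""

from __future__ import annotations

import weakref
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .integrals import IntegralSet
from .ras import DeterminantSpace, connections, excitation_apply

__all__ = [
    "StateVector",
    "GroundState",
    "Hamiltonian",
    "spinorb_one_body",
    "one_body_matrix",
    "s2_matrix",
    "apply_h",
    "apply_s2",
    "apply_dipole",
    "apply_triplet",
    "ground_state",
    "ConvergenceError",
]

# Pauli/2 spin matrices in the (alpha, beta) basis
_SPIN = np.array(
    [
        [[0.0, 0.5], [0.5, 0.0]],
        [[0.0, -0.5j], [0.5j, 0.0]],
        [[0.5, 0.0], [0.0, -0.5]],
    ],
    dtype=complex,
)


class ConvergenceError(RuntimeError):
    pass


@dataclass
class StateVector:
    """Complex amplitudes over a determinant space."""

    space: DeterminantSpace
    amp: np.ndarray

    def __post_init__(self):
        self.amp = np.asarray(self.amp, dtype=complex)
        if self.amp.shape != (self.space.dim,):
            raise ValueError("amplitude length must equal space dimension")

    def norm(self) -> float:
        return float(np.linalg.norm(self.amp))

    def dot(self, other: "StateVector") -> complex:
        return complex(np.vdot(self.amp, other.amp))


@dataclass
class GroundState:
    """Lowest eigenvalue and an orthonormal basis of its degenerate manifold."""

    energy: float
    states: list
    degeneracy_tol: float

    @property
    def n_states(self) -> int:
        return len(self.states)


def spinorb_one_body(ints: IntegralSet) -> np.ndarray:
    """Complex one-body matrix over spin orbitals (alpha block then beta)."""
    n = ints.n_orb
    w = np.zeros((2 * n, 2 * n), dtype=complex)
    for s in range(2):
        w[s * n:(s + 1) * n, s * n:(s + 1) * n] = ints.h1
    for c in range(3):
        for s1 in range(2):
            for s2 in range(2):
                coef = _SPIN[c, s1, s2]
                if coef != 0:
                    w[s1 * n:(s1 + 1) * n, s2 * n:(s2 + 1) * n] += coef * ints.h_soc[c]
    return w


def one_body_matrix(space: DeterminantSpace, w: np.ndarray) -> sp.csr_matrix:
    """Sparse matrix of sum_pq w[p,q] a+_p a_q over the determinant space."""
    nso = space.n_spinorb
    w = np.asarray(w, dtype=complex)
    if w.shape != (nso, nso):
        raise ValueError("one-body matrix must be (2 n_orb, 2 n_orb)")
    rows, cols, vals = [], [], []
    diag_w = np.real_if_close(np.diag(w))
    cols_of = [np.nonzero(w[:, q])[0] for q in range(nso)]
    for col, det in enumerate(space.dets):
        det = int(det)
        occ = [k for k in range(nso) if det >> k & 1]
        dval = sum(diag_w[k] for k in occ)
        if dval != 0:
            rows.append(col)
            cols.append(col)
            vals.append(dval)
        for q in occ:
            for p in cols_of[q]:
                if p == q:
                    continue
                res = excitation_apply(det, int(p), q)
                if res is None:
                    continue
                tgt, sign = res
                pos = space.index.get(tgt)
                if pos is None:
                    continue
                rows.append(pos)
                cols.append(col)
                vals.append(sign * w[p, q])
    return sp.coo_matrix((vals, (rows, cols)), shape=(space.dim, space.dim), dtype=complex).tocsr()


def _antisymmetrized_so_eri(ints: IntegralSet) -> np.ndarray:
    """Physicist <pq||rs> over spin orbitals from the spatial chemist eri."""
    n = ints.n_orb
    nso = 2 * n
    # chemist spin-orbital (pq|rs) = (PQ|RS) d(sp,sq) d(sr,ss)
    g = np.zeros((nso, nso, nso, nso))
    for s1 in range(2):
        for s2 in range(2):
            g[
                s1 * n:(s1 + 1) * n, s1 * n:(s1 + 1) * n,
                s2 * n:(s2 + 1) * n, s2 * n:(s2 + 1) * n,
            ] = ints.eri
    phys = g.transpose(0, 2, 1, 3)  # <pq|rs> = (pr|qs)
    return phys - phys.transpose(0, 1, 3, 2)


class Hamiltonian:
    """Sparse Hamiltonian (including e_core) over a determinant space."""

    def __init__(self, ints: IntegralSet, space: DeterminantSpace):
        self.ints = ints
        self.space = space
        self.e_core = ints.e_core
        self.matrix = self._build()

    def _build(self) -> sp.csr_matrix:
        ints, space = self.ints, self.space
        nso = space.n_spinorb
        w = spinorb_one_body(ints)
        aso = _antisymmetrized_so_eri(ints)
        dim = space.dim
        rows, cols, vals = [], [], []
        for col, det in enumerate(space.dets):
            det = int(det)
            occ = np.array([k for k in range(nso) if det >> k & 1], dtype=int)
            # diagonal
            dval = w[occ, occ].sum()
            if len(occ) > 1:
                oc, or_ = occ[:, None], occ[None, :]
                dval += 0.5 * aso[oc, or_, oc, or_].sum()
            rows.append(col)
            cols.append(col)
            vals.append(dval + self.e_core)
            for pos, (create, annihilate), sign in connections(det, space):
                if len(create) == 1:
                    p, q = create[0], annihilate[0]
                    val = w[p, q] + aso[p, occ, q, occ].sum()
                else:
                    p1, p2 = create
                    q1, q2 = annihilate
                    val = aso[p1, p2, q1, q2]
                if val != 0:
                    rows.append(pos)
                    cols.append(col)
                    vals.append(sign * val)
        return sp.coo_matrix((vals, (rows, cols)), shape=(dim, dim), dtype=complex).tocsr()

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return self.matrix @ v

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def diagonal(self) -> np.ndarray:
        return self.matrix.diagonal()


_ham_cache: dict = {}
_s2_cache: dict = {}
_dip_cache: dict = {}


def _cached(cache: dict, key_objs: tuple, build):
    key = tuple(id(o) for o in key_objs)
    hit = cache.get(key)
    if hit is not None:
        refs, value = hit
        if all(r() is o for r, o in zip(refs, key_objs)):
            return value
    value = build()
    cache[key] = (tuple(weakref.ref(o) for o in key_objs), value)
    return value


def get_hamiltonian(ints: IntegralSet, space: DeterminantSpace) -> Hamiltonian:
    return _cached(_ham_cache, (ints, space), lambda: Hamiltonian(ints, space))


def apply_h(ints: IntegralSet, v: StateVector) -> StateVector:
    """H v, including the e_core shift."""
    h = get_hamiltonian(ints, v.space)
    return StateVector(v.space, h.matvec(v.amp))


def dipole_matrix(ints: IntegralSet, component: int | str, space: DeterminantSpace) -> sp.csr_matrix:
    c = "xyz".index(component) if isinstance(component, str) else int(component)
    store = _cached(_dip_cache, (ints, space), lambda: [None, None, None])
    if store[c] is None:
        n = ints.n_orb
        w = np.zeros((2 * n, 2 * n), dtype=complex)
        w[:n, :n] = ints.dip[c]
        w[n:, n:] = ints.dip[c]
        store[c] = one_body_matrix(space, w)
    return store[c]


def apply_dipole(ints: IntegralSet, component: int | str, v: StateVector) -> StateVector:
    """Apply the spin-free one-body dipole operator (one Cartesian component)."""
    return StateVector(v.space, dipole_matrix(ints, component, v.space) @ v.amp)


def triplet_matrix(space: DeterminantSpace, component: int | str, i: int, j: int) -> sp.csr_matrix:
    c = "xyz".index(component) if isinstance(component, str) else int(component)
    n = space.spec.n_orb
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError("orbital index out of range")
    w = np.zeros((2 * n, 2 * n), dtype=complex)
    for s1 in range(2):
        for s2 in range(2):
            coef = _SPIN[c, s1, s2]
            if coef != 0:
                w[s1 * n + i, s2 * n + j] = coef
    return one_body_matrix(space, w)


def apply_triplet(component: int | str, i: int, j: int, v: StateVector) -> StateVector:
    """Apply the Cartesian triplet operator T^c_ij."""
    return StateVector(v.space, triplet_matrix(v.space, component, i, j) @ v.amp)


def s2_matrix(space: DeterminantSpace) -> sp.csr_matrix:
    """Sparse total-spin operator S^2 = S- S+ + Sz (Sz + 1)."""

    def build():
        n = space.spec.n_orb
        w = np.zeros((2 * n, 2 * n), dtype=complex)
        for i in range(n):
            w[i, n + i] = 1.0  # S+ = sum_i a+_ia a_ib
        splus = one_body_matrix(space, w)
        na = np.zeros(space.dim)
        nb = np.zeros(space.dim)
        for k in range(n):
            na += space.occupations(k)
            nb += space.occupations(n + k)
        sz = 0.5 * (na - nb)
        return (splus.conj().T @ splus + sp.diags(sz * (sz + 1))).tocsr()

    return _cached(_s2_cache, (space,), build)


def apply_s2(v: StateVector) -> StateVector:
    """S^2 v; Hermitian with eigenvalues S(S+1)."""
    return StateVector(v.space, s2_matrix(v.space) @ v.amp)


def space_hash(space: DeterminantSpace) -> str:
    """Stable hash of the determinant list (guards state-file compatibility)."""
    import hashlib

    return hashlib.sha256(space.dets.tobytes()).hexdigest()[:16]


def save_state(v: StateVector, path: str, meta: dict | None = None) -> None:
    """Write a state vector to an HDF5 container (/amp, /space_hash, /meta)."""
    import h5py

    with h5py.File(path, "w") as f:
        f["amp"] = v.amp
        f["space_hash"] = space_hash(v.space)
        g = f.create_group("meta")
        for k, val in (meta or {}).items():
            g.attrs[k] = val


def load_state(path: str, space: DeterminantSpace) -> tuple[StateVector, dict]:
    import h5py

    with h5py.File(path, "r") as f:
        stored = f["space_hash"][()].decode()
        if stored != space_hash(space):
            raise ValueError("state file belongs to a different determinant space")
        amp = f["amp"][()]
        meta = dict(f["meta"].attrs)
    return StateVector(space, amp), meta


def ground_state(
    ints: IntegralSet,
    space: DeterminantSpace,
    degeneracy_tol: float = 1e-6,
    tol: float = 1e-8,
    dense_threshold: int = 2500,
) -> GroundState:
    """Lowest eigenvalue of H and all eigenvectors within ``degeneracy_tol``.

    Deterministic: dense diagonalization below ``dense_threshold`` (a single
    Lanczos run cannot resolve the multiplicity of a degenerate level, and
    degenerate ground manifolds are the norm here), otherwise ARPACK started
    from a unit vector on the lowest-diagonal determinant, which then bounds
    the manifold only by the requested window.
    """
    h = get_hamiltonian(ints, space)
    dim = space.dim
    if dim == 1:
        e0 = float(h.matrix[0, 0].real)
        return GroundState(e0, [StateVector(space, np.ones(1, dtype=complex))], degeneracy_tol)
    if dim <= dense_threshold:
        evals, evecs = scipy.linalg.eigh(h.to_dense())
        e0 = float(evals[0])
        sel = np.nonzero(evals <= e0 + degeneracy_tol)[0]
        states = [StateVector(space, evecs[:, i]) for i in sel]
        return GroundState(e0, states, degeneracy_tol)

    diag = h.diagonal().real
    v0 = np.zeros(dim, dtype=complex)
    v0[int(np.argmin(diag))] = 1.0
    k = min(dim - 2, 10)
    while True:
        try:
            evals, evecs = spla.eigsh(h.matrix, k=k, which="SA", v0=v0, tol=1e-12, maxiter=5000)
        except spla.ArpackNoConvergence as exc:
            raise ConvergenceError(f"ground-state solver did not converge: {exc}") from exc
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
        e0 = float(evals[0])
        in_manifold = evals <= e0 + degeneracy_tol
        if not in_manifold.all() or k >= dim - 2:
            break
        k = min(dim - 2, 2 * k)  # manifold may extend past the window
    sel = np.nonzero(in_manifold)[0]
    states_raw = evecs[:, sel]
    # re-orthonormalize (ARPACK vectors are orthonormal to solver precision)
    q, _ = np.linalg.qr(states_raw)
    states = [StateVector(space, q[:, i]) for i in range(q.shape[1])]
    for s in states:
        resid = np.linalg.norm(h.matvec(s.amp) - e0 * s.amp)
        if resid > max(1e-6, 100 * tol):
            raise ConvergenceError(f"ground-state residual {resid:.2e} exceeds tolerance")
    return GroundState(e0, states, degeneracy_tol)
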