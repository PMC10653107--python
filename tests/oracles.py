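"""Independent brute-force oracles used by the tests.

Everything here is built on the full 4^n_orb Fock space via Jordan-Wigner
matrix representations of the elementary fermion operators — deliberately
naive and independent of the package's Slater-Condon / bitstring machinery.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np

_SPIN = np.array(
    [
        [[0.0, 0.5], [0.5, 0.0]],
        [[0.0, -0.5j], [0.5j, 0.0]],
        [[0.5, 0.0], [0.0, -0.5]],
    ]
)


@lru_cache(maxsize=None)
def creation_ops(nso: int) -> tuple:
    """Jordan-Wigner creation matrices on the 2**nso Fock space."""
    eye = np.eye(2)
    z = np.diag([1.0, -1.0])
    raise_op = np.array([[0.0, 0.0], [1.0, 0.0]])  # |1><0|
    ops = []
    for k in range(nso):
        m = np.array([[1.0]])
        for j in range(nso):
            m = np.kron(m, z if j < k else (raise_op if j == k else eye))
        ops.append(m)
    return tuple(ops)


def fock_index(det: int, nso: int) -> int:
    """Map the package's bitmask convention onto the kron ordering above."""
    idx = 0
    for k in range(nso):
        if det >> k & 1:
            idx |= 1 << (nso - 1 - k)
    return idx


def project(mat: np.ndarray, dets, nso: int) -> np.ndarray:
    sub = [fock_index(int(d), nso) for d in dets]
    return mat[np.ix_(sub, sub)]


def spin_summed_e(p: int, q: int, n_orb: int) -> np.ndarray:
    c = creation_ops(2 * n_orb)
    a = [m.conj().T for m in c]
    return c[p] @ a[q] + c[n_orb + p] @ a[n_orb + q]


def dense_hamiltonian(ints) -> np.ndarray:
    """H on the full Fock space from the definition, term by term."""
    n = ints.n_orb
    nso = 2 * n
    c = creation_ops(nso)
    a = [m.conj().T for m in c]
    dim = 2**nso
    h = ints.e_core * np.eye(dim, dtype=complex)
    e_cache = {}

    def e_op(p, q):
        if (p, q) not in e_cache:
            e_cache[(p, q)] = spin_summed_e(p, q, n)
        return e_cache[(p, q)]

    for i in range(n):
        for j in range(n):
            if ints.h1[i, j] != 0:
                h += ints.h1[i, j] * e_op(i, j)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                for l in range(n):
                    g = ints.eri[i, j, k, l]
                    if g == 0:
                        continue
                    ee = e_op(i, j) @ e_op(k, l)
                    if j == k:
                        ee = ee - e_op(i, l)
                    h += 0.5 * g * ee
    for comp in range(3):
        for i in range(n):
            for j in range(n):
                if ints.h_soc[comp, i, j] == 0:
                    continue
                t = sum(
                    _SPIN[comp, s1, s2] * (c[s1 * n + i] @ a[s2 * n + j])
                    for s1 in range(2)
                    for s2 in range(2)
                )
                h += ints.h_soc[comp, i, j] * t
    return h


def dense_triplet(comp: int, i: int, j: int, n_orb: int) -> np.ndarray:
    c = creation_ops(2 * n_orb)
    a = [m.conj().T for m in c]
    return sum(
        _SPIN[comp, s1, s2] * (c[s1 * n_orb + i] @ a[s2 * n_orb + j])
        for s1 in range(2)
        for s2 in range(2)
    )


def dense_s2(n_orb: int) -> np.ndarray:
    sp = sum(spin_raise(i, n_orb) for i in range(n_orb))
    sz = sum(0.5 * (number_op(i, n_orb) - number_op(n_orb + i, n_orb)) for i in range(n_orb))
    return sp.conj().T @ sp + sz @ sz + sz


def spin_raise(i: int, n_orb: int) -> np.ndarray:
    c = creation_ops(2 * n_orb)
    return c[i] @ c[n_orb + i].conj().T


def number_op(k: int, n_orb: int) -> np.ndarray:
    c = creation_ops(2 * n_orb)
    return c[k] @ c[k].conj().T


def brute_force_ras(n_orb: int, partitions, n_elec: int) -> list[int]:
    """All bitmasks satisfying the RAS constraints, by filtering every
    n_elec-subset of the 2*n_orb spin orbitals."""
    nso = 2 * n_orb
    out = []
    for occ in combinations(range(nso), n_elec):
        mask = 0
        for k in occ:
            mask |= 1 << k
        ok = True
        for orbs, max_holes in partitions:
            if max_holes is None:
                continue
            filled = sum(
                1 for i in orbs for k in (i, i + n_orb) if mask >> k & 1
            )
            if 2 * len(orbs) - filled > max_holes:
                ok = False
                break
        if ok:
            out.append(mask)
    return out
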