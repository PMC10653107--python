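"""Restricted-active-space determinant basis.

Determinants are occupation bitstrings over 2*n_orb spin orbitals.  Spin
orbital ``k`` for k < n_orb is the alpha spin orbital of spatial orbital k;
``k = n_orb + i`` is the beta spin orbital of orbital i (blocked by spin).
A determinant is stored as a Python int whose bit ``k`` is the occupation of
spin orbital ``k``; a (alpha_mask, beta_mask) view is used for ordering.

The canonical order of a DeterminantSpace is ascending (alpha_mask,
beta_mask) as integers — the alpha block is most significant — which is a
total, hash-free, reproducible order.

The second-quantized phase convention: ``a_q`` applied to a determinant
picks up (-1)**(number of occupied spin orbitals with index < q), i.e. the
creation-operator string is ordered by ascending spin-orbital index.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "RASSpec",
    "DeterminantSpace",
    "enumerate_space",
    "excitation_apply",
    "connections",
    "popcount",
]


class EmptySpaceError(ValueError):
    """No determinant satisfies the electron count and hole limits."""


def popcount(x: int) -> int:
    return int(x).bit_count()


@dataclass(frozen=True)
class RASSpec:
    """Partitioned active space with per-partition limits on hole counts.

    ``partitions`` is an ordered sequence of (spatial orbital indices,
    max_holes) pairs; ``max_holes=None`` means unrestricted.  Hole counts
    are relative to the fully occupied partition (2 electrons per spatial
    orbital, i.e. holes are counted in spin orbitals).
    """

    n_orb: int
    partitions: tuple[tuple[tuple[int, ...], int | None], ...]
    n_elec: int

    def __init__(self, n_orb: int, partitions: Sequence, n_elec: int):
        parts = tuple((tuple(p[0]), p[1]) for p in partitions)
        seen: set[int] = set()
        for orbs, max_holes in parts:
            if seen & set(orbs):
                raise ValueError("partitions must be disjoint")
            seen |= set(orbs)
            if max_holes is not None and not 0 <= max_holes <= 2 * len(orbs):
                raise ValueError("max_holes must lie in [0, 2*|partition|]")
        if seen != set(range(n_orb)):
            raise ValueError("partitions must cover all orbitals exactly once")
        if not 0 <= n_elec <= 2 * n_orb:
            raise ValueError("n_elec out of range")
        object.__setattr__(self, "n_orb", n_orb)
        object.__setattr__(self, "partitions", parts)
        object.__setattr__(self, "n_elec", int(n_elec))

    @classmethod
    def from_space(cls, space, n_elec: int, *, restrict: dict | None = None) -> "RASSpec":
        """Build from an OrbitalSpace using its partition tags.

        ``restrict`` maps partition tag to max_holes; the default is the
        standard setup: RAS1 and RAS1P at most one hole, RAS2 unrestricted.
        """
        restrict = {"RAS1": 1, "RAS1P": 1, "RAS2": None} | (restrict or {})
        parts = []
        for tag in ("RAS1", "RAS1P", "RAS2"):
            orbs = space.indices(partition=tag)
            if orbs:
                parts.append((orbs, restrict[tag]))
        return cls(space.n_orb, parts, n_elec)


@dataclass(frozen=True)
class DeterminantSpace:
    """Canonically ordered list of determinants plus an index lookup."""

    spec: RASSpec
    dets: np.ndarray  # int64 bitmasks, canonical order
    index: dict  # int bitmask -> position

    @property
    def dim(self) -> int:
        return len(self.dets)

    @property
    def n_spinorb(self) -> int:
        return 2 * self.spec.n_orb

    def occupations(self, k: int) -> np.ndarray:
        """Occupation (0/1) of spin orbital k across all determinants."""
        return (self.dets >> np.int64(k)) & np.int64(1)


def _masks_with_electrons(spin_orbs: Sequence[int], count: int) -> list[int]:
    out = []
    for occ in combinations(spin_orbs, count):
        m = 0
        for k in occ:
            m |= 1 << k
        out.append(m)
    return out


def enumerate_space(spec: RASSpec, ms2: int | None = None) -> DeterminantSpace:
    """Enumerate every determinant obeying the electron count and hole limits.

    ``ms2`` optionally restricts to a single S_z sector (2*M_s); the default
    keeps all sectors because the spin-orbit triplet operators couple them.
    """
    n = spec.n_orb
    per_part: list[list[list[int]]] = []  # per partition: masks grouped by count
    ranges = []
    for orbs, max_holes in spec.partitions:
        cap = 2 * len(orbs)
        lo = 0 if max_holes is None else max(0, cap - max_holes)
        spin_orbs = [i for i in orbs] + [i + n for i in orbs]
        ranges.append((lo, cap))
        per_part.append([_masks_with_electrons(spin_orbs, c) for c in range(cap + 1)])

    dets: list[int] = []

    def recurse(p: int, remaining: int, mask: int):
        if p == len(per_part):
            if remaining == 0:
                dets.append(mask)
            return
        lo, cap = ranges[p]
        for c in range(lo, cap + 1):
            if c > remaining:
                break
            for m in per_part[p][c]:
                recurse(p + 1, remaining - c, mask | m)

    recurse(0, spec.n_elec, 0)
    if ms2 is not None:
        beta_shift = np.int64(n)
        alpha_mask_all = (1 << n) - 1
        dets = [
            d for d in dets
            if popcount(d & alpha_mask_all) - popcount(d >> n) == ms2
        ]
    if not dets:
        raise EmptySpaceError("no determinant satisfies the RAS constraints")
    amask = (1 << n) - 1
    dets.sort(key=lambda d: ((d & amask), d >> n))
    arr = np.array(dets, dtype=np.int64)
    return DeterminantSpace(spec=spec, dets=arr, index={int(d): i for i, d in enumerate(dets)})


def _phase(det: int, k: int) -> int:
    """Parity of occupied spin orbitals below k."""
    return -1 if popcount(det & ((1 << k) - 1)) & 1 else 1


def excitation_apply(det: int, create: int, annihilate: int):
    """Apply a+_create a_annihilate; return (determinant, sign) or None."""
    det = int(det)
    if create < 0 or annihilate < 0:
        raise IndexError("spin-orbital index out of range")
    if not det >> annihilate & 1:
        return None
    sign = _phase(det, annihilate)
    d1 = det & ~(1 << annihilate)
    if d1 >> create & 1:
        return None
    sign *= _phase(d1, create)
    return d1 | (1 << create), sign


def connections(det: int, space: DeterminantSpace) -> Iterator[tuple[int, tuple, int]]:
    """Singles and doubles from ``det`` that stay inside the space.

    Yields (target index, ((create,...), (annihilate,...)), sign), without
    duplicates.  Double descriptors use p1 < p2 creations and q1 < q2
    annihilations; the sign corresponds to a+_p1 a+_p2 a_q2 a_q1.
    """
    det = int(det)
    nso = space.n_spinorb
    occ = [k for k in range(nso) if det >> k & 1]
    vir = [k for k in range(nso) if not det >> k & 1]
    idx = space.index
    for q in occ:
        for p in vir:
            res = excitation_apply(det, p, q)
            if res is None:
                continue
            tgt, sign = res
            pos = idx.get(tgt)
            if pos is not None:
                yield pos, ((p,), (q,)), sign
    for a in range(len(occ)):
        for b in range(a + 1, len(occ)):
            q1, q2 = occ[a], occ[b]
            d1 = det & ~(1 << q1) & ~(1 << q2)
            for c in range(len(vir)):
                for d_ in range(c + 1, len(vir)):
                    p1, p2 = vir[c], vir[d_]
                    tgt = d1 | (1 << p1) | (1 << p2)
                    pos = idx.get(tgt)
                    if pos is None:
                        continue
                    # sign of a+_p1 a+_p2 a_q2 a_q1 on det
                    s = _phase(det, q1)
                    dd = det & ~(1 << q1)
                    s *= _phase(dd, q2)
                    dd &= ~(1 << q2)
                    s *= _phase(dd, p2)
                    dd |= 1 << p2
                    s *= _phase(dd, p1)
                    yield pos, ((p1, p2), (q1, q2)), s


def write_space(space: DeterminantSpace, path: str) -> None:
    """Dump the determinant list, one bitstring per line, canonical order."""
    n = space.spec.n_orb
    with open(path, "w") as fh:
        parts = ";".join(
            f"{orbs}:{'inf' if mh is None else mh}" for orbs, mh in space.spec.partitions
        )
        fh.write(f"# n_orb={n} n_elec={space.spec.n_elec} partitions={parts}\n")
        for d in space.dets:
            bits = "".join(str(int(d) >> k & 1) for k in range(2 * n))
            fh.write(bits + "\n")
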