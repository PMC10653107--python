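"""Operator data in the active orbital basis.

An :class:`IntegralSet` carries everything that defines the Hamiltonian and
the dipole operator over a set of active spatial orbitals:

* ``h1`` — real symmetric spin-free one-electron integrals h_ij (Hartree),
* ``eri`` — two-electron integrals (ij|kl) in chemist notation with the full
  8-fold permutational symmetry of real orbitals (Hartree),
* ``h_soc`` — three Cartesian mean-field Breit-Pauli spin-orbit matrices,
  each purely imaginary and antisymmetric in a real orbital basis (Hartree),
* ``dip`` — three real symmetric Cartesian dipole matrices (atomic units),
* ``e_core`` — scalar core/frozen energy (Hartree).

On-disk formats: an extended FCIDUMP text dialect (with ``&SOC`` and ``&DIP``
sections and a YAML sidecar for orbital labels/partitions) and an HDF5
container holding the same arrays.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

PARTITIONS = ("RAS1", "RAS1P", "RAS2")
SHELLS = ("core", "valence", "ligand")


class IntegralFileError(ValueError):
    """Malformed integral file; message carries the offending line number."""


@dataclass(frozen=True)
class OrbitalSpace:
    """Active spatial orbitals with labels, RAS partition and shell tags."""

    labels: tuple[str, ...]
    partition: tuple[str, ...]
    shell: tuple[str, ...]

    def __post_init__(self):
        n = len(self.labels)
        if n < 1:
            raise ValueError("OrbitalSpace needs at least one orbital")
        if len(set(self.labels)) != n:
            raise ValueError("orbital labels must be unique")
        if len(self.partition) != n or len(self.shell) != n:
            raise ValueError("labels/partition/shell lengths differ")
        for p in self.partition:
            if p not in PARTITIONS:
                raise ValueError(f"unknown partition tag {p!r}")
        for s in self.shell:
            if s not in SHELLS:
                raise ValueError(f"unknown shell tag {s!r}")

    @property
    def n_orb(self) -> int:
        return len(self.labels)

    def indices(self, *, partition: str | None = None, shell: str | None = None) -> tuple[int, ...]:
        """Orbital indices matching the given partition and/or shell tag."""
        out = []
        for i in range(self.n_orb):
            if partition is not None and self.partition[i] != partition:
                continue
            if shell is not None and self.shell[i] != shell:
                continue
            out.append(i)
        return tuple(out)

    @classmethod
    def default(cls, n_orb: int) -> "OrbitalSpace":
        return cls(
            labels=tuple(f"orb{i + 1}" for i in range(n_orb)),
            partition=("RAS2",) * n_orb,
            shell=("valence",) * n_orb,
        )


def symmetrize_eri(eri: np.ndarray) -> np.ndarray:
    """Average an eri tensor over the 8-fold real-orbital permutation orbit."""
    e = np.asarray(eri, dtype=float)
    e = 0.5 * (e + e.transpose(1, 0, 2, 3))
    e = 0.5 * (e + e.transpose(0, 1, 3, 2))
    e = 0.5 * (e + e.transpose(2, 3, 0, 1))
    return e


@dataclass
class IntegralSet:
    """All operator matrix elements defining H and the dipole operator."""

    space: OrbitalSpace
    e_core: float
    h1: np.ndarray
    eri: np.ndarray
    h_soc: np.ndarray  # shape (3, n, n), complex (purely imaginary entries)
    dip: np.ndarray  # shape (3, n, n), real symmetric

    @classmethod
    def zeros(cls, space: OrbitalSpace, e_core: float = 0.0) -> "IntegralSet":
        n = space.n_orb
        return cls(
            space=space,
            e_core=float(e_core),
            h1=np.zeros((n, n)),
            eri=np.zeros((n, n, n, n)),
            h_soc=np.zeros((3, n, n), dtype=complex),
            dip=np.zeros((3, n, n)),
        )

    @property
    def n_orb(self) -> int:
        return self.space.n_orb

    def validate(self, atol: float = 1e-12) -> None:
        n = self.n_orb
        if self.h1.shape != (n, n) or self.eri.shape != (n, n, n, n):
            raise ValueError("integral array shapes inconsistent with orbital space")
        if self.h_soc.shape != (3, n, n) or self.dip.shape != (3, n, n):
            raise ValueError("SOC/dipole array shapes inconsistent with orbital space")
        if not np.allclose(self.h1, self.h1.T, atol=atol):
            raise ValueError("h1 must be symmetric")
        e = self.eri
        for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
            if not np.allclose(e, e.transpose(*perm), atol=atol):
                raise ValueError("eri must have 8-fold permutational symmetry")
        for c in range(3):
            m = self.h_soc[c]
            if not np.allclose(m.real, 0.0, atol=atol):
                raise ValueError("h_soc components must be purely imaginary")
            if not np.allclose(m, -m.T, atol=atol):
                raise ValueError("h_soc components must be antisymmetric")
            if not np.allclose(self.dip[c], self.dip[c].T, atol=atol):
                raise ValueError("dip components must be symmetric")

    def rotate(self, u: np.ndarray) -> "IntegralSet":
        """Transform all integrals by a real orthogonal active-space rotation.

        Column ``a`` of ``u`` expresses new orbital ``a`` in the old basis.
        Labels are kept; totals of downstream spectra are invariant.
        """
        u = np.asarray(u, dtype=float)
        n = self.n_orb
        if u.shape != (n, n) or not np.allclose(u.T @ u, np.eye(n), atol=1e-10):
            raise ValueError("rotation must be a real orthogonal n_orb x n_orb matrix")
        h1 = u.T @ self.h1 @ u
        eri = np.einsum("pi,qj,rk,sl,pqrs->ijkl", u, u, u, u, self.eri, optimize=True)
        h_soc = np.stack([u.T @ self.h_soc[c] @ u for c in range(3)])
        dip = np.stack([u.T @ self.dip[c] @ u for c in range(3)])
        return IntegralSet(self.space, self.e_core, h1, symmetrize_eri(eri), h_soc, dip)


def _unique_eri_entries(eri: np.ndarray, tol: float = 0.0):
    """Yield (value, i, j, k, l) over canonical representatives of nonzero
    8-fold orbits, 0-based indices, deterministic order."""
    n = eri.shape[0]
    for i in range(n):
        for j in range(i + 1):
            ij = i * (i + 1) // 2 + j
            for k in range(i + 1):
                for l in range(k + 1):
                    kl = k * (k + 1) // 2 + l
                    if kl > ij:
                        continue
                    v = eri[i, j, k, l]
                    if abs(v) > tol:
                        yield v, i, j, k, l


_FMT = "%23.16e"


def write_integrals(ints: IntegralSet, path: str) -> None:
    """Write the extended FCIDUMP dialect plus the orbital-metadata sidecar.

    Output is deterministic (fixed entry order and float format) and
    round-trips bit-exactly through :func:`read_integrals`.
    """
    ints.validate(atol=1e-8)
    n = ints.n_orb
    lines = []
    orbsym = ",".join(["1"] * n)
    lines.append(f"&FCI NORB={n},NELEC=0,MS2=0,")
    lines.append(f" ORBSYM={orbsym},")
    lines.append(" ISYM=1,")
    lines.append("&END")
    for v, i, j, k, l in _unique_eri_entries(ints.eri):
        lines.append(f"{_FMT % v} {i + 1:4d} {j + 1:4d} {k + 1:4d} {l + 1:4d}")
    for i in range(n):
        for j in range(i + 1):
            v = ints.h1[i, j]
            if v != 0.0:
                lines.append(f"{_FMT % v} {i + 1:4d} {j + 1:4d}    0    0")
    lines.append(f"{_FMT % ints.e_core}    0    0    0    0")
    for c, name in enumerate("XYZ"):
        block = [
            f"{_FMT % ints.h_soc[c, i, j].imag} {i + 1:4d} {j + 1:4d}"
            for i in range(n)
            for j in range(i)
            if ints.h_soc[c, i, j] != 0.0
        ]
        if block:
            lines.append(f"&SOC {name}")
            lines.extend(block)
    for c, name in enumerate("XYZ"):
        block = [
            f"{_FMT % ints.dip[c, i, j]} {i + 1:4d} {j + 1:4d}"
            for i in range(n)
            for j in range(i + 1)
            if ints.dip[c, i, j] != 0.0
        ]
        if block:
            lines.append(f"&DIP {name}")
            lines.extend(block)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    _write_sidecar(ints.space, _sidecar_path(path))


def _sidecar_path(path: str) -> str:
    return str(path) + ".orbitals.yaml"


def _write_sidecar(space: OrbitalSpace, path: str) -> None:
    data = {
        "orbitals": {
            i + 1: {
                "label": space.labels[i],
                "partition": space.partition[i],
                "shell": space.shell[i],
            }
            for i in range(space.n_orb)
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def _read_sidecar(path: str, n: int) -> OrbitalSpace:
    if not os.path.exists(path):
        return OrbitalSpace.default(n)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    orbs = data["orbitals"]
    if set(orbs) != set(range(1, n + 1)):
        raise IntegralFileError(f"{path}: sidecar must describe orbitals 1..{n}")
    return OrbitalSpace(
        labels=tuple(orbs[i + 1]["label"] for i in range(n)),
        partition=tuple(orbs[i + 1]["partition"] for i in range(n)),
        shell=tuple(orbs[i + 1]["shell"] for i in range(n)),
    )


def read_integrals(path: str) -> IntegralSet:
    """Parse the extended FCIDUMP dialect; symmetry partners are completed."""
    with open(path) as fh:
        raw = fh.readlines()
    # --- header ---
    header = []
    body_start = None
    for ln, line in enumerate(raw):
        header.append(line)
        if "&END" in line.upper() or "/" == line.strip():
            body_start = ln + 1
            break
    if body_start is None:
        raise IntegralFileError(f"{path}:1: missing &END terminating the header")
    head = " ".join(header).upper().replace(",", " ")
    norb = None
    for tok in head.split():
        if tok.startswith("NORB="):
            try:
                norb = int(tok[5:])
            except ValueError:
                raise IntegralFileError(f"{path}:1: malformed NORB field {tok!r}")
    if norb is None or norb < 1:
        raise IntegralFileError(f"{path}:1: header must define NORB >= 1")

    ints = IntegralSet.zeros(_read_sidecar(_sidecar_path(path), norb))
    seen_eri: dict[tuple, float] = {}
    seen_h1: dict[tuple, float] = {}
    section = "main"  # or ("soc", c) / ("dip", c)
    for ln in range(body_start, len(raw)):
        line = raw[ln].strip()
        lineno = ln + 1
        if not line or line.startswith("#"):
            continue
        up = line.upper().split()
        if up[0] in ("&SOC", "&DIP"):
            if len(up) != 2 or up[1] not in ("X", "Y", "Z"):
                raise IntegralFileError(f"{path}:{lineno}: malformed section sentinel {line!r}")
            section = ("soc" if up[0] == "&SOC" else "dip", "XYZ".index(up[1]))
            continue
        toks = line.split()
        try:
            val = float(toks[0])
            idx = [int(t) for t in toks[1:]]
        except (ValueError, IndexError):
            raise IntegralFileError(f"{path}:{lineno}: cannot parse record {line!r}")
        if section == "main":
            if len(idx) != 4:
                raise IntegralFileError(f"{path}:{lineno}: main-section records need 4 indices")
            i, j, k, l = idx
            if any(t < 0 or t > norb for t in idx):
                raise IntegralFileError(f"{path}:{lineno}: orbital index out of range 0..{norb}")
            if i == j == k == l == 0:
                ints.e_core = val
            elif k == 0 and l == 0:
                if i == 0 or j == 0:
                    raise IntegralFileError(f"{path}:{lineno}: malformed one-electron record")
                key = (max(i, j), min(i, j))
                if key in seen_h1 and seen_h1[key] != val:
                    raise IntegralFileError(
                        f"{path}:{lineno}: conflicting duplicate h1 entry {key}")
                seen_h1[key] = val
                ints.h1[i - 1, j - 1] = val
                ints.h1[j - 1, i - 1] = val
            elif 0 in idx:
                raise IntegralFileError(f"{path}:{lineno}: mixed zero/nonzero indices")
            else:
                a, b, c, d = i - 1, j - 1, k - 1, l - 1
                key = _eri_canonical(a, b, c, d)
                if key in seen_eri and seen_eri[key] != val:
                    raise IntegralFileError(
                        f"{path}:{lineno}: conflicting duplicate eri entry {key}")
                seen_eri[key] = val
                for p, q, r, s in _eri_orbit(a, b, c, d):
                    ints.eri[p, q, r, s] = val
        else:
            kind, comp = section
            if len(idx) != 2:
                raise IntegralFileError(f"{path}:{lineno}: {kind} records need 2 indices")
            i, j = idx
            if not (1 <= i <= norb and 1 <= j <= norb):
                raise IntegralFileError(f"{path}:{lineno}: orbital index out of range 1..{norb}")
            a, b = i - 1, j - 1
            if kind == "soc":
                if a == b:
                    if val != 0.0:
                        raise IntegralFileError(
                            f"{path}:{lineno}: diagonal SOC entry must vanish (antisymmetry)")
                    continue
                prev = ints.h_soc[comp, a, b]
                if prev != 0 and prev.imag != val:
                    raise IntegralFileError(
                        f"{path}:{lineno}: conflicting duplicate SOC entry ({i},{j})")
                ints.h_soc[comp, a, b] = 1j * val
                ints.h_soc[comp, b, a] = -1j * val
            else:
                prev = ints.dip[comp, a, b]
                if ints.dip[comp, a, b] != 0 and prev != val:
                    raise IntegralFileError(
                        f"{path}:{lineno}: conflicting duplicate DIP entry ({i},{j})")
                ints.dip[comp, a, b] = val
                ints.dip[comp, b, a] = val
    ints.validate(atol=1e-10)
    return ints


def _eri_orbit(i, j, k, l):
    return {
        (i, j, k, l), (j, i, k, l), (i, j, l, k), (j, i, l, k),
        (k, l, i, j), (l, k, i, j), (k, l, j, i), (l, k, j, i),
    }


def _eri_canonical(i, j, k, l):
    return min(_eri_orbit(i, j, k, l))


# ---------------------------------------------------------------------------
# HDF5 container (same arrays, binary alternative to the text dialect)

_H5_SOC = ("soc_x", "soc_y", "soc_z")
_H5_DIP = ("dip_x", "dip_y", "dip_z")


def write_integrals_h5(ints: IntegralSet, path: str) -> None:
    import h5py

    ints.validate(atol=1e-8)
    with h5py.File(path, "w") as f:
        f["h1"] = ints.h1
        f["eri"] = ints.eri
        f["e_core"] = ints.e_core
        for c in range(3):
            f[_H5_SOC[c]] = ints.h_soc[c]
            f[_H5_DIP[c]] = ints.dip[c]
        f["labels"] = np.array(ints.space.labels, dtype="S")
        f["partition"] = np.array(ints.space.partition, dtype="S")
        f["shell"] = np.array(ints.space.shell, dtype="S")


def read_integrals_h5(path: str) -> IntegralSet:
    import h5py

    with h5py.File(path, "r") as f:
        space = OrbitalSpace(
            labels=tuple(s.decode() for s in f["labels"][()]),
            partition=tuple(s.decode() for s in f["partition"][()]),
            shell=tuple(s.decode() for s in f["shell"][()]),
        )
        ints = IntegralSet(
            space=space,
            e_core=float(f["e_core"][()]),
            h1=f["h1"][()],
            eri=f["eri"][()],
            h_soc=np.stack([f[k][()] for k in _H5_SOC]).astype(complex),
            dip=np.stack([f[k][()] for k in _H5_DIP]),
        )
    ints.validate(atol=1e-10)
    return ints
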