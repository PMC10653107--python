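"""Active-space construction from external mean-field output.

The file contract: a mean-field engine provides natural-orbital coefficients
over its full orbital basis, the corresponding occupation numbers, and
full-basis integrals (one-electron, two-electron, dipole and optionally SOC
matrices).  This module selects active orbitals whose occupations fall in a
configurable window (fractionally occupied orbitals are the correlated ones),
optionally localizes them by a Pipek-style population criterion within the
active space, transforms the integrals into that basis and attaches RAS
partition tags from shell labels.

Everything is array-based (or an ``.npz`` file of the same arrays); no
electronic-structure engine is imported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrals import IntegralSet, OrbitalSpace, symmetrize_eri

__all__ = ["SelectionRule", "AdapterError", "from_adapter", "pipek_localize"]


class AdapterError(ValueError):
    pass


@dataclass
class SelectionRule:
    """Occupation window plus requested orbital count and tags.

    ``window`` is the open interval of natural occupation numbers accepted
    for the correlated (RAS2-type) selection; ``extra`` lists orbital indices
    included regardless of occupation (e.g. the core 2p set).  ``labels``,
    ``partition`` and ``shell`` tag the selected orbitals in their final
    order (extra first, then window-selected by ascending index).
    """

    window: tuple[float, float] = (0.02, 1.98)
    n_orb: int | None = None
    extra: tuple[int, ...] = ()
    labels: tuple[str, ...] | None = None
    partition: tuple[str, ...] | None = None
    shell: tuple[str, ...] | None = None


def select_orbitals(occupations: np.ndarray, rule: SelectionRule) -> list[int]:
    occ = np.asarray(occupations, dtype=float)
    lo, hi = rule.window
    cand = [i for i in range(len(occ)) if lo < occ[i] < hi and i not in rule.extra]
    if rule.n_orb is not None and len(cand) != rule.n_orb:
        listing = ", ".join(f"{i}:{occ[i]:.4f}" for i in cand) or "(none)"
        raise AdapterError(
            f"occupation window {rule.window} selected {len(cand)} orbitals, "
            f"requested {rule.n_orb}; candidates {listing}"
        )
    return list(rule.extra) + cand


def pipek_localize(
    coeffs: np.ndarray,
    populations: np.ndarray | None,
    groups: list[list[int]] | None = None,
    max_sweeps: int = 100,
    tol: float = 1e-10,
) -> np.ndarray:
    """Pipek-style localization of active orbitals by Jacobi rotations.

    ``populations`` has shape (n_centers, nbasis, nbasis): one population
    operator per atomic center.  Rotations are confined to each ``groups``
    block (default: one block over all columns); the rotation maximizing
    sum_A sum_i <i|P_A|i>^2 is returned (identity when no populations are
    given — spectra totals are invariant to the choice).
    """
    nact = coeffs.shape[1]
    u = np.eye(nact)
    if populations is None:
        return u
    populations = np.asarray(populations, dtype=float)
    if groups is None:
        groups = [list(range(nact))]
    c = coeffs @ u

    def pair_locality(cs_pair):
        val = 0.0
        for pa in populations:
            val += (cs_pair[:, 0] @ pa @ cs_pair[:, 0]) ** 2
            val += (cs_pair[:, 1] @ pa @ cs_pair[:, 1]) ** 2
        return val

    for _ in range(max_sweeps):
        gain = 0.0
        for block in groups:
            for ii in range(len(block)):
                for jj in range(ii + 1, len(block)):
                    s, t = block[ii], block[jj]
                    base = pair_locality(c[:, [s, t]])
                    # the pair functional is a sinusoid in 4*gamma: sampling
                    # finely then polishing locates the exact maximizer
                    gammas = np.linspace(-np.pi / 4, np.pi / 4, 181)
                    best, best_val = 0.0, base
                    for g in gammas:
                        cg, sg = np.cos(g), np.sin(g)
                        rot = np.array([[cg, sg], [-sg, cg]])
                        val = pair_locality(c[:, [s, t]] @ rot)
                        if val > best_val + 1e-15:
                            best, best_val = g, val
                    from scipy.optimize import minimize_scalar

                    if best_val > base + tol:
                        res = minimize_scalar(
                            lambda g: -pair_locality(
                                c[:, [s, t]] @ np.array(
                                    [[np.cos(g), np.sin(g)], [-np.sin(g), np.cos(g)]]
                                )
                            ),
                            bracket=(best - 0.02, best, best + 0.02),
                        )
                        g = float(res.x)
                        cg, sg = np.cos(g), np.sin(g)
                        rot = np.array([[cg, sg], [-sg, cg]])
                        c[:, [s, t]] = c[:, [s, t]] @ rot
                        u[:, [s, t]] = u[:, [s, t]] @ rot
                        gain += -res.fun - base
        if gain < tol:
            break
    return u


def from_adapter(
    source,
    rule: SelectionRule,
    localize: bool = True,
    populations: np.ndarray | None = None,
) -> IntegralSet:
    """Build an IntegralSet from mean-field output and a selection rule.

    ``source`` is a dict (or ``.npz`` path) with keys ``mo_coeffs``
    (nbasis x nmo natural-orbital coefficients), ``occupations`` (nmo),
    ``h1``, ``eri``, ``dip`` (3,nb,nb) and optionally ``soc`` (3,nb,nb,
    imaginary antisymmetric), ``e_core`` and ``populations``
    (ncenters,nb,nb) — all over the full basis, in Hartree/a.u.
    """
    if isinstance(source, (str, bytes)):
        with np.load(source) as f:
            source = {k: f[k] for k in f.files}
    mo = np.asarray(source["mo_coeffs"], dtype=float)
    occ = np.asarray(source["occupations"], dtype=float)
    sel = select_orbitals(occ, rule)
    cact = mo[:, sel]
    if populations is None:
        populations = source.get("populations")
    if localize:
        shells = rule.shell or ("valence",) * len(sel)
        groups = [
            [i for i in range(len(sel)) if shells[i] == tag] for tag in dict.fromkeys(shells)
        ]
        u = pipek_localize(cact, populations, groups=groups)
        cact = cact @ u
    n = len(sel)
    space = OrbitalSpace(
        labels=rule.labels or tuple(f"act_{i + 1}" for i in range(n)),
        partition=rule.partition or ("RAS2",) * n,
        shell=rule.shell or ("valence",) * n,
    )
    h1 = cact.T @ np.asarray(source["h1"]) @ cact
    eri = np.einsum(
        "pi,qj,rk,sl,pqrs->ijkl", cact, cact, cact, cact,
        np.asarray(source["eri"]), optimize=True,
    )
    dip = np.stack([cact.T @ m @ cact for m in np.asarray(source["dip"])])
    if "soc" in source:
        soc = np.stack([cact.T @ m @ cact for m in np.asarray(source["soc"], dtype=complex)])
    else:
        soc = np.zeros((3, n, n), dtype=complex)
    ints = IntegralSet(
        space=space,
        e_core=float(source.get("e_core", 0.0)),
        h1=0.5 * (h1 + h1.T),
        eri=symmetrize_eri(eri),
        h_soc=soc,
        dip=np.stack([0.5 * (m + m.T) for m in dip]),
    )
    ints.validate(atol=1e-8)
    return ints
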