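"""Particle-hole and spin deconvolutions: sum rules, projector algebra, labels."""

import numpy as np
import pytest

from cvxray.integrals import IntegralSet, OrbitalSpace
from cvxray.deconvolution import (
    OrbitalSetPair,
    PHKey,
    SpinChannel,
    attainable_spins,
    average_ph,
    natural_orbital_basis,
    ph_decompose_rixs,
    ph_decompose_xas,
    spin_decompose_rixs,
    spin_decompose_xas,
    spin_project,
    sumrule_check,
    valence_sums,
)
from cvxray.fixtures import fixture
from cvxray.model import ModelParams, build_model
from cvxray.operators import StateVector, ground_state, s2_matrix
from cvxray.ras import RASSpec, enumerate_space
from cvxray.response import FrequencyGrid, rixs_spectrum, select_omega_ex, xas_spectrum
from cvxray.units import ev_to_ha

from conftest import random_integrals


# ---------------------------------------------------------------------------
# Lowdin projector algebra


@pytest.fixture(scope="module")
def spin_space():
    ints = random_integrals(3, seed=31)
    space = enumerate_space(RASSpec(3, [((0, 1, 2), None)], 4))
    return ints, space


def test_projector_idempotent_orthogonal_complete(spin_space, rng):
    _, space = spin_space
    spins = attainable_spins(space)
    v = StateVector(space, rng.normal(size=space.dim) + 1j * rng.normal(size=space.dim))
    parts = {s: spin_project(s, v) for s in spins}
    # resolution of identity
    acc = np.sum([p.amp for p in parts.values()], axis=0)
    np.testing.assert_allclose(acc, v.amp, atol=1e-8 * v.norm())
    for s, p in parts.items():
        again = spin_project(s, p)
        np.testing.assert_allclose(again.amp, p.amp, atol=1e-8 * max(p.norm(), 1e-30))
        for s2 in spins:
            if s2 != s:
                cross = spin_project(s2, p)
                assert cross.norm() < 1e-8 * v.norm()


def test_projection_against_dense_s2_eigendecomposition(spin_space, rng):
    """P_S v equals the exact S^2-eigenspace projection of v (dense oracle)."""
    _, space = spin_space
    s2 = s2_matrix(space).toarray()
    evals, evecs = np.linalg.eigh(s2)
    v = rng.normal(size=space.dim) + 1j * rng.normal(size=space.dim)
    for s in attainable_spins(space):
        sel = np.abs(evals - s * (s + 1)) < 1e-8
        ref = evecs[:, sel] @ (evecs[:, sel].conj().T @ v)
        ours = spin_project(s, StateVector(space, v)).amp
        np.testing.assert_allclose(ours, ref, atol=1e-8 * np.linalg.norm(v))


def test_projection_of_pure_spin_states(spin_space):
    _, space = spin_space
    s2 = s2_matrix(space).toarray()
    evals, evecs = np.linalg.eigh(s2)
    # a pure S=1 eigenvector survives its own channel and dies in others
    idx = int(np.argmin(np.abs(evals - 2.0)))
    v = StateVector(space, evecs[:, idx])
    kept = spin_project(1.0, v)
    np.testing.assert_allclose(kept.amp, v.amp, atol=1e-10)
    killed = spin_project(0.0, v)
    assert killed.norm() < 1e-10


def test_spin_channel_validation(spin_space):
    _, space = spin_space
    v = StateVector(space, np.ones(space.dim))
    with pytest.raises(ValueError, match="not attainable"):
        spin_project(7.5, v)
    ch = SpinChannel(s=2.0, excluded=(0.0, 1.0))
    out = spin_project(ch, v)
    assert out.amp.shape == v.amp.shape


# ---------------------------------------------------------------------------
# Particle-hole deconvolution


def test_single_coupled_pair_takes_all_weight():
    """Dipole coupling exactly one core-valence pair localizes the spectrum."""
    space_o = OrbitalSpace(
        labels=("c1", "c2", "v1", "v2"),
        partition=("RAS1", "RAS1", "RAS2", "RAS2"),
        shell=("core", "core", "valence", "valence"),
    )
    ints = IntegralSet.zeros(space_o)
    ints.h1 = np.diag([ev_to_ha(-700.0), ev_to_ha(-705.0), 0.0, ev_to_ha(1.0)])
    ints.dip[0, 0, 2] = ints.dip[0, 2, 0] = 1.0  # only c1 <-> v1
    space = enumerate_space(RASSpec(4, [((0, 1), 1), ((2, 3), None)], 4))
    gs = ground_state(ints, space)
    grid = FrequencyGrid.linspace(695.0, 710.0, 0.1, 0.3)
    spec = ph_decompose_xas(ints, gs, grid)
    main = PHKey(hole=0, particle=2, hole_label="c1", particle_label="v1")
    assert main in spec.components
    others = sum(
        np.max(np.abs(np.asarray(v))) for k, v in spec.components.items() if k != main
    )
    assert others <= 1e-10 * np.max(spec.total)
    assert sumrule_check(spec, spec.components) < 1e-10


def test_ph_sum_rule_and_total_agreement():
    ints, space = fixture("rixs_small").build()
    gs = ground_state(ints, space)
    grid = FrequencyGrid.linspace(702.0, 718.0, 0.2, 0.3)
    spec = ph_decompose_xas(ints, gs, grid)
    assert sumrule_check(spec, spec.components) < 1e-8
    ref = xas_spectrum(ints, gs, grid)
    assert np.max(np.abs(spec.total - ref.total)) < 1e-8 * np.max(ref.total)


def test_valence_component_peaks_split_by_10dq():
    """One-electron crystal-field model: valence-summed components 10Dq apart."""
    ten_dq = 2.0
    p = ModelParams(crystal_field=(0.0, 0.0, ten_dq, ten_dq, ten_dq),
                    zeta_core=0.0, dipole_strengths=1.0)
    ints = build_model(p)
    space = enumerate_space(RASSpec.from_space(ints.space, 6))
    gs = ground_state(ints, space)
    grid = FrequencyGrid.linspace(705.0, 716.0, 0.02, 0.3)
    spec = ph_decompose_xas(ints, gs, grid)
    sums = valence_sums(spec)
    lower = sums["3d_z2"]  # e set
    upper = sums["3d_xy"]  # t2 set
    p_lo = grid.values[int(np.argmax(lower))]
    p_hi = grid.values[int(np.argmax(upper))]
    assert p_hi - p_lo == pytest.approx(ten_dq, abs=0.04)


def test_ph_basis_rotation_leaves_total_invariant():
    ints, space = fixture("rixs_small").build()
    gs = ground_state(ints, space)
    grid = FrequencyGrid.linspace(702.0, 718.0, 0.4, 0.3)
    plain = ph_decompose_xas(ints, gs, grid)
    u = natural_orbital_basis(ints, gs)
    rotated = ph_decompose_xas(ints, gs, grid, basis=u)
    np.testing.assert_allclose(rotated.total, plain.total, rtol=1e-7, atol=1e-12)
    assert sumrule_check(rotated, rotated.components) < 1e-8


def test_ph_rejects_non_unitary_basis():
    ints, space = fixture("rixs_small").build()
    gs = ground_state(ints, space)
    grid = FrequencyGrid.linspace(702.0, 718.0, 1.0, 0.3)
    with pytest.raises(ValueError, match="orthogonal"):
        ph_decompose_xas(ints, gs, grid, basis=np.ones((ints.n_orb, ints.n_orb)))


def test_rixs_ph_sum_rule_and_vv_fraction():
    ints, space = fixture("rixs_small").build()
    gs = ground_state(ints, space)
    xgrid = FrequencyGrid.linspace(700.0, 722.0, 0.1, 0.3)
    omega = select_omega_ex(xas_spectrum(ints, gs, xgrid), (700.0, 714.0))
    loss = FrequencyGrid.linspace(0.0, 6.0, 0.25, 0.3, 0.1)
    spec = ph_decompose_rixs(ints, gs, omega, loss)
    assert sumrule_check(spec, spec.components) < 1e-8
    ref = rixs_spectrum(ints, gs, omega, loss)
    assert np.max(np.abs(spec.total - ref.total)) < 1e-8 * np.max(ref.total)
    assert spec.meta["valence_to_valence_fraction"] > 0.99


def test_three_level_rixs_attributed_to_designed_pair():
    """The single loss peak belongs to the designed valence (g -> v) channel.

    Core c is doubly occupied, one electron sits in valence g; absorption
    c -> v and emission g -> c leave the net valence excitation g -> v at
    loss E(v) - E(g).
    """
    ev_v = 1.2
    space_o = OrbitalSpace(
        labels=("c", "g", "v"), partition=("RAS1", "RAS2", "RAS2"),
        shell=("core", "valence", "valence"),
    )
    ints = IntegralSet.zeros(space_o)
    ints.h1 = np.diag([ev_to_ha(-710.0), 0.0, ev_to_ha(ev_v)])
    ints.dip[0, 0, 2] = ints.dip[0, 2, 0] = 1.0  # c <-> v
    ints.dip[1, 0, 1] = ints.dip[1, 1, 0] = 0.6  # c <-> g
    space = enumerate_space(RASSpec(3, [((0,), 1), ((1, 2), None)], 3))
    gs = ground_state(ints, space)
    loss = FrequencyGrid.linspace(0.0, 3.0, 0.02, 0.3, 0.1)
    spec = ph_decompose_rixs(ints, gs, 710.0 + ev_v, loss)
    inelastic = PHKey(hole=1, particle=2, hole_label="g", particle_label="v",
                      valence_to_valence=True)
    assert inelastic in spec.components
    i_peak = int(np.argmin(np.abs(loss.values - ev_v)))
    comp = np.asarray(spec.components[inelastic])
    # dominates the inelastic peak (the rest is the elastic line's tail)
    assert comp[i_peak] > 0.9 * spec.total[i_peak]
    assert loss.values[int(np.argmax(comp))] == pytest.approx(ev_v, abs=0.02)
    elastic = np.asarray(spec.components[PHKey(2, 2, "v", "v", True)])
    residual = spec.total - comp - elastic
    assert np.max(residual[loss.values > 0.5]) < 0.01 * spec.total[i_peak]


def test_average_ph_rules():
    grid = np.linspace(0, 1, 5)
    c = lambda x: np.full(5, x)
    comps = {
        PHKey(0, 1): c(1.0),
        PHKey(0, 2): c(2.0),
        PHKey(0, 3): c(3.0),
    }
    single = average_ph(comps, OrbitalSetPair((0,), (1,)))
    np.testing.assert_allclose(single, 1.0)
    # {z2} -> 3-fold t2 set: one third of the component sum
    avg = average_ph(comps, OrbitalSetPair((0,), (1, 2, 3), label="z2->t2"))
    np.testing.assert_allclose(avg, (1.0 + 2.0 + 3.0) / 3)
    uniform = average_ph({PHKey(0, 1): c(4.0), PHKey(0, 2): c(4.0)},
                         OrbitalSetPair((0,), (1, 2)))
    np.testing.assert_allclose(uniform, 4.0)
    with pytest.raises(KeyError, match="missing"):
        average_ph(comps, OrbitalSetPair((0,), (4,)))


# ---------------------------------------------------------------------------
# Spin deconvolution


def test_spin_free_selection_rule_and_sum_rule():
    """With h_soc = 0 only the ground-spin channel absorbs (dipole is spin-free)."""
    p = ModelParams(core_orbitals=3, valence_orbitals=3,
                    crystal_field=(0.0, 0.5, 1.0), zeta_core=0.0,
                    u_direct=4.0, j_exchange=0.8, core_valence_attraction=5.0)
    ints = build_model(p)
    space = enumerate_space(RASSpec.from_space(ints.space, 8))
    gs = ground_state(ints, space)
    grid = FrequencyGrid.linspace(702.0, 716.0, 0.2, 0.3)
    spec = spin_decompose_xas(ints, gs, grid)
    assert sumrule_check(spec, spec.components) < 1e-8
    pct = spec.meta["channel_percent"]
    ground_s = 1.0  # two unpaired valence electrons, Hund triplet
    assert pct[ground_s] == pytest.approx(100.0, abs=1e-8)
    for s, val in pct.items():
        if s != ground_s:
            assert val <= 1e-8


def test_soc_transfers_weight_to_spin_flip_monotonically():
    fractions = []
    for zeta in (0.0, 0.05, 0.1):
        p = ModelParams(core_orbitals=3, valence_orbitals=3,
                        crystal_field=(0.0, 0.5, 1.0), zeta_core=zeta,
                        u_direct=4.0, j_exchange=0.8, core_valence_attraction=5.0)
        ints = build_model(p)
        space = enumerate_space(RASSpec.from_space(ints.space, 8))
        gs = ground_state(ints, space)
        grid = FrequencyGrid.linspace(702.0, 716.0, 0.5, 0.3)
        pct = spin_decompose_xas(ints, gs, grid).meta["channel_percent"]
        fractions.append(pct[0.0] + pct[2.0])  # Delta-S = 1 relative to S0 = 1
    assert fractions[0] <= 1e-10
    assert fractions[0] < fractions[1] < fractions[2]


def test_rixs_spin_channels_sum_to_total():
    ints, space = fixture("rixs_small").build()
    gs = ground_state(ints, space)
    xgrid = FrequencyGrid.linspace(700.0, 722.0, 0.1, 0.3)
    omega = select_omega_ex(xas_spectrum(ints, gs, xgrid), (700.0, 714.0))
    loss = FrequencyGrid.linspace(0.0, 6.0, 0.5, 0.3, 0.1)
    spec = spin_decompose_rixs(ints, gs, omega, loss)
    assert sumrule_check(spec, spec.components) < 1e-8
    ref = rixs_spectrum(ints, gs, omega, loss)
    np.testing.assert_allclose(spec.total, ref.total, rtol=1e-8)


def test_sumrule_check_detects_missing_component():
    grid = FrequencyGrid(np.linspace(0, 1, 4), 0.3)
    from cvxray.response import Spectrum

    total = np.array([1.0, 2.0, 4.0, 2.0])
    comps = {"a": 0.25 * total, "b": 0.75 * total}
    spec = Spectrum(grid, total, components=comps)
    assert sumrule_check(spec, comps) == 0.0
    assert sumrule_check(spec, {"a": comps["a"]}) == pytest.approx(0.75)


def test_natural_orbitals_sorted_and_orthogonal():
    ints, space = fixture("rixs_small").build()
    gs = ground_state(ints, space)
    u = natural_orbital_basis(ints, gs)
    np.testing.assert_allclose(u.T @ u, np.eye(ints.n_orb), atol=1e-10)
    # occupations descending within the valence block
    from cvxray.deconvolution import _rdm1_spin_summed

    dm = 0.5 * (_rdm1_spin_summed(gs).real + _rdm1_spin_summed(gs).real.T)
    val = list(ints.space.indices(shell="valence"))
    occ = np.diag(u.T @ dm @ u)[val]
    assert np.all(np.diff(occ) <= 1e-10)
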