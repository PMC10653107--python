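"""Correction-vector solves and XAS/RIXS spectra against closed forms and SOS."""

import numpy as np
import pytest

from cvxray.integrals import IntegralSet, OrbitalSpace
from cvxray.fixtures import fixture
from cvxray.operators import StateVector, ground_state, get_hamiltonian
from cvxray.oracle import diagonalize, sos_rixs, sos_xas
from cvxray.ras import RASSpec, enumerate_space
from cvxray.response import (
    FrequencyGrid,
    SolverError,
    resolvent_apply,
    rixs_spectrum,
    select_omega_ex,
    shifted_solve,
    xas_spectrum,
)
from cvxray.units import HARTREE_EV, ev_to_ha

from conftest import random_integrals


def two_level_model(delta_ev: float, moment: float):
    """One electron, two orbitals: a single dipole transition (delta, m)."""
    space_o = OrbitalSpace.default(2)
    ints = IntegralSet.zeros(space_o)
    ints.h1[1, 1] = ev_to_ha(delta_ev)
    ints.dip[0, 0, 1] = ints.dip[0, 1, 0] = moment
    space = enumerate_space(RASSpec(2, [((0, 1), None)], 1))
    return ints, space


def test_shifted_solve_diagonal_closed_form(rng):
    ints = random_integrals(2, seed=4, with_soc=False)
    ints.eri[:] = 0.0
    ints.h1 = np.diag(np.diag(ints.h1))  # diagonal H: C_k = rhs_k / (z - H_kk)
    space = enumerate_space(RASSpec(2, [((0, 1), None)], 1))
    h = get_hamiltonian(ints, space)
    rhs = StateVector(space, rng.normal(size=space.dim) + 1j * rng.normal(size=space.dim))
    z = 0.3 + 0.05j
    out = shifted_solve(ints, space, z, rhs, tol=1e-12)
    np.testing.assert_allclose(out.amp, rhs.amp / (z - h.diagonal()), atol=1e-10)


@pytest.mark.parametrize("method", ["lanczos", "gmres", "dense"])
def test_shifted_solve_matches_dense(method, rng):
    ints = random_integrals(3, seed=15)
    space = enumerate_space(RASSpec(3, [((0, 1, 2), None)], 3))
    h = get_hamiltonian(ints, space).to_dense()
    rhs = StateVector(space, rng.normal(size=space.dim) + 1j * rng.normal(size=space.dim))
    z = 0.2 + 0.02j
    ref = np.linalg.solve(z * np.eye(space.dim) - h, rhs.amp)
    out = shifted_solve(ints, space, z, rhs.amp * 1.0 if False else rhs, tol=1e-10, method=method)
    np.testing.assert_allclose(out.amp, ref, atol=1e-8)


def test_shifted_solve_zero_rhs_and_errors():
    ints = random_integrals(2, seed=3)
    space = enumerate_space(RASSpec(2, [((0, 1), None)], 2))
    zero = StateVector(space, np.zeros(space.dim))
    assert np.all(shifted_solve(ints, space, 1j, zero).amp == 0)
    with pytest.raises(ValueError, match="imaginary"):
        shifted_solve(ints, space, 1.0, zero)


def test_solver_stagnation_reports_residual(rng):
    ints = random_integrals(3, seed=16)
    space = enumerate_space(RASSpec(3, [((0, 1, 2), None)], 3))
    h = get_hamiltonian(ints, space)
    rhs = rng.normal(size=space.dim) + 0j
    with pytest.raises(SolverError) as err:
        resolvent_apply(h.matrix, rhs, [0.1 + 1e-6j], tol=1e-14, max_krylov=3)
    assert err.value.achieved is not None and err.value.achieved > 1e-14


@pytest.mark.parametrize("eta", [0.1, 0.3])
def test_single_transition_lorentzian_peak(eta):
    """Isolated transition (delta, m): peak height m^2 / (pi eta) on the eV axis."""
    delta, m = 5.0, 0.7
    ints, space = two_level_model(delta, m)
    gs = ground_state(ints, space)
    grid = FrequencyGrid.linspace(delta - 2.0, delta + 2.0, eta / 20, eta)
    spec = xas_spectrum(ints, gs, grid)
    peak = spec.total.max()
    expected = m**2 / (np.pi * eta)
    assert peak == pytest.approx(expected, rel=1e-3)
    closed = (m**2 / np.pi) * eta / ((grid.values - delta) ** 2 + eta**2)
    np.testing.assert_allclose(spec.total, closed, rtol=5e-4, atol=1e-12)


def test_peak_height_decreases_with_eta():
    ints, space = two_level_model(5.0, 1.0)
    gs = ground_state(ints, space)
    peaks = []
    for eta in (0.1, 0.3, 0.6):
        grid = FrequencyGrid.linspace(4.9, 5.1, 0.005, eta)
        peaks.append(xas_spectrum(ints, gs, grid).total.max())
    assert peaks[0] > peaks[1] > peaks[2]


def test_integrated_xas_approximates_total_moment():
    """Wide-grid integral of S(w) ~ sum_l <0|mu_l^2|0> minus the elastic part."""
    ints, space = two_level_model(5.0, 0.8)
    gs = ground_state(ints, space)
    grid = FrequencyGrid.linspace(-30.0, 40.0, 0.05, 0.1)
    spec = xas_spectrum(ints, gs, grid)
    total = 0.0
    from cvxray.operators import dipole_matrix

    for g in gs.states:
        for c in range(3):
            mu_g = dipole_matrix(ints, c, space) @ g.amp
            total += np.vdot(mu_g, mu_g).real - abs(np.vdot(g.amp, mu_g)) ** 2
    total /= gs.n_states
    assert spec.integrate() == pytest.approx(total, rel=0.01)


def test_xas_nonnegative_and_matches_sos_on_fixtures():
    for name in ("p_shell", "rixs_small"):
        ints, space = fixture(name).build()
        gs = ground_state(ints, space)
        grid = FrequencyGrid.linspace(698.0, 726.0, 0.25, 0.3)
        cv = xas_spectrum(ints, gs, grid)
        assert np.all(cv.total >= -1e-12)
        sos = sos_xas(ints, diagonalize(ints, space), gs, grid)
        assert np.max(np.abs(cv.total - sos.total)) <= 1e-8 * np.max(sos.total)


def test_p_shell_xas_shows_two_bands_split_by_soc():
    zeta = 8.0
    ints, space = fixture("p_shell").build()
    gs = ground_state(ints, space)
    grid = FrequencyGrid.linspace(700.0, 724.0, 0.02, 0.3)
    spec = xas_spectrum(ints, gs, grid)
    t = spec.total
    peaks = [
        grid.values[i]
        for i in range(1, len(t) - 1)
        if t[i] > t[i - 1] and t[i] > t[i + 1] and t[i] > 0.01 * t.max()
    ]
    assert len(peaks) == 2
    assert peaks[1] - peaks[0] == pytest.approx(1.5 * zeta, abs=2 * 0.02)
    # L3 (j=3/2 core hole) carries roughly twice the L2 weight and lies lower
    i3 = np.argmin(np.abs(grid.values - peaks[0]))
    i2 = np.argmin(np.abs(grid.values - peaks[1]))
    assert t[i3] > t[i2]


def test_select_omega_ex_rules():
    grid = FrequencyGrid(np.array([1.0, 2.0, 3.0, 4.0]), 0.3)
    from cvxray.response import Spectrum

    spec = Spectrum(grid, np.array([0.1, 0.9, 0.2, 0.9]))
    assert select_omega_ex(spec, (0.5, 4.5)) == 2.0  # tie broken toward lower energy
    flat = Spectrum(grid, np.ones(4))
    assert select_omega_ex(flat, (1.5, 4.5)) == 2.0
    with pytest.raises(ValueError):
        select_omega_ex(spec, (10.0, 11.0))


def three_level_model(ev_v=1.2, ec=710.0, t1=0.9, t2=0.5):
    """|0>, valence |v> and core-excited |c| levels; x couples 0-c, y couples v-c."""
    space_o = OrbitalSpace(
        labels=("g", "v", "c"), partition=("RAS2", "RAS2", "RAS1"),
        shell=("valence", "valence", "core"),
    )
    ints = IntegralSet.zeros(space_o)
    # single electron: levels 0 (ground), ev_v (valence final), ec (core-excited)
    ints.h1[1, 1] = ev_to_ha(ev_v)
    ints.h1[2, 2] = ev_to_ha(ec)
    ints.dip[0, 0, 2] = ints.dip[0, 2, 0] = t1
    ints.dip[1, 1, 2] = ints.dip[1, 2, 1] = t2
    space = enumerate_space(RASSpec(3, [((0, 1, 2), None)], 1))
    return ints, space


def test_three_level_rixs_closed_form():
    """Single-intermediate, single-final Kramers-Heisenberg line shape."""
    ev_v, ec, t1, t2 = 1.2, 710.0, 0.9, 0.5
    ints, space = three_level_model(ev_v, ec, t1, t2)
    gs = ground_state(ints, space)
    omega_ex = ec + 0.1
    loss = FrequencyGrid.linspace(0.0, 3.0, 0.01, 0.3, 0.1)
    spec = rixs_spectrum(ints, gs, omega_ex, loss)
    # closed form (Hartree denominators, eV axis)
    eta, etap = ev_to_ha(0.3), ev_to_ha(0.1)
    amp_c = 1.0 / (ev_to_ha(omega_ex - ec) + 1j * eta)
    w_el = abs(t1 * t1 * amp_c) ** 2
    w_v = abs(t2 * t1 * amp_c) ** 2
    closed = np.zeros_like(loss.values)
    for w, de in ((w_el, 0.0), (w_v, ev_v)):
        closed += (etap / np.pi) * w / (ev_to_ha(loss.values - de) ** 2 + etap**2)
    closed /= HARTREE_EV
    np.testing.assert_allclose(spec.total, closed, rtol=1e-8, atol=1e-14)
    # the inelastic peak sits at the final-state energy with width eta'
    inel = np.where(loss.values > 0.5, spec.total, 0.0)
    assert loss.values[np.argmax(inel)] == pytest.approx(ev_v, abs=0.01)


def test_rixs_matches_sos_oracle_and_zero_dipole():
    ints, space = fixture("rixs_small").build()
    gs = ground_state(ints, space)
    grid = FrequencyGrid.linspace(700.0, 722.0, 0.1, 0.3)
    omega = select_omega_ex(xas_spectrum(ints, gs, grid), (700.0, 714.0))
    loss = FrequencyGrid.linspace(0.0, 6.0, 0.1, 0.3, 0.1)
    cv = rixs_spectrum(ints, gs, omega, loss)
    sos = sos_rixs(ints, diagonalize(ints, space), gs, omega, loss)
    assert np.max(np.abs(cv.total - sos.total)) <= 1e-8 * np.max(sos.total)
    # elastic line present at zero loss (ground state reachable back)
    assert cv.total[0] > 0.1 * cv.total.max()
    # zero dipole -> identically zero
    dead = IntegralSet.zeros(ints.space, e_core=ints.e_core)
    dead.h1, dead.eri, dead.h_soc = ints.h1, ints.eri, ints.h_soc
    z = rixs_spectrum(dead, gs, omega, loss)
    assert np.all(z.total == 0)


def test_spectrum_tsv_round_trip(tmp_path):
    ints, space = two_level_model(5.0, 1.0)
    gs = ground_state(ints, space)
    grid = FrequencyGrid.linspace(3.0, 7.0, 0.1, 0.3)
    spec = xas_spectrum(ints, gs, grid)
    spec.components = {"a": spec.total * 0.4, "b": spec.total * 0.6}
    p = tmp_path / "spec.tsv"
    spec.write_tsv(str(p))
    rows = [l for l in p.read_text().splitlines() if not l.startswith("#")]
    header = rows[0].split("\t")
    assert header == ["energy_eV", "total", "a", "b"]
    data = np.array([[float(x) for x in r.split("\t")] for r in rows[1:]])
    np.testing.assert_allclose(data[:, 0], grid.values)
    np.testing.assert_allclose(data[:, 1], spec.total, rtol=1e-10)
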