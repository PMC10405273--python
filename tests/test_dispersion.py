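"""Dispersion assembly over the frequency grid and static induction."""

import numpy as np
import pytest

from mrdisp.backend import OrbitalPartition
from mrdisp.dispersion import (MonomerResponseInput, convergence_scan,
                               dispersion_energy, induction_static)
from mrdisp.erpa import ERPAHessians, build_pair_index, split_alpha
from mrdisp.pipeline import dispersion_eq1, induction_both_ways
from mrdisp.response import make_frequency_grid


def _single_mode_monomer(a_plus, a_minus, d):
    """One occupied-virtual pair with metric 2 and coupling strength d."""
    pm = build_pair_index(OrbitalPartition([0], [], [1]),
                          np.array([1.0, 0.0]))
    h = ERPAHessians(np.array([[a_plus]]), np.array([[a_minus]]),
                     np.array([2.0]), pm)
    split_alpha(h)
    return MonomerResponseInput(h, np.array([1.0, 0.0]),
                                np.array([[d]]))


def test_two_single_mode_monomers_analytic():
    """One-term Casimir-Polder value, fully in closed form.

    For a single pair with metric 2, coupling d and Hessians a±, the
    response kernel is m(w) = a+/(2(wX^2+w^2)) with wX^2 = a+ a-/4, and

        E = -4 dA^2 dB^2 (a+_A/2)(a+_B/2) / (wA wB (wA + wB)).
    """
    ap_a, am_a, d_a = 1.2, 2.0, 0.7
    ap_b, am_b, d_b = 1.6, 2.6, 0.4
    ma = _single_mode_monomer(ap_a, am_a, d_a)
    mb = _single_mode_monomer(ap_b, am_b, d_b)
    wa = np.sqrt(ap_a * am_a) / 2.0
    wb = np.sqrt(ap_b * am_b) / 2.0
    expected = -(4.0 * d_a ** 2 * d_b ** 2 * (ap_a / 2) * (ap_b / 2)
                 / (wa * wb * (wa + wb)))
    res = dispersion_energy(ma, mb, make_frequency_grid(8), order=None)
    assert res.e_coupled == pytest.approx(expected, rel=1e-6)
    assert res.e_coupled < 0


def test_eq1_equals_eq11_on_fixture(h2_dimer_work):
    """Cross-path equivalence at tight threshold and high order."""
    e1, sa, sb = dispersion_eq1(h2_dimer_work)
    ra = h2_dimer_work.A.response_input()
    rb = h2_dimer_work.B.response_input()
    res = dispersion_energy(ra, rb, make_frequency_grid(8), order=30)
    assert abs(res.e_coupled - e1) < 1e-6
    assert res.e_coupled < 0


def test_monomer_swap_symmetry(h2_dimer_work):
    ra = h2_dimer_work.A.response_input()
    rb = h2_dimer_work.B.response_input()
    grid = make_frequency_grid(8)
    ab = dispersion_energy(ra, rb, grid, order=6)
    ba = dispersion_energy(rb, ra, grid, order=6)
    assert ab.e_coupled == pytest.approx(ba.e_coupled, rel=1e-12)


def test_per_order_last_equals_coupled(h2_dimer_work):
    ra = h2_dimer_work.A.response_input()
    rb = h2_dimer_work.B.response_input()
    res = dispersion_energy(ra, rb, make_frequency_grid(8), order=5)
    assert res.per_order[-1] == res.e_coupled
    assert res.per_order[0] == pytest.approx(res.e_uncoupled)


def test_quadrature_consistency(h2_dimer_work):
    ra = h2_dimer_work.A.response_input()
    rb = h2_dimer_work.B.response_input()
    e16 = dispersion_energy(ra, rb, make_frequency_grid(16), order=None)
    e32 = dispersion_energy(ra, rb, make_frequency_grid(32), order=None)
    assert abs(e32.e_coupled - e16.e_coupled) < 1e-6 * abs(e32.e_coupled)


def test_convergence_scan_reports(h2_dimer_work):
    ra = h2_dimer_work.A.response_input()
    rb = h2_dimer_work.B.response_input()
    scan = convergence_scan(ra, rb, n_max=8)
    assert scan["order_converged"] is not None
    assert scan["abs_error"][8] <= scan["abs_error"][2]
    assert not scan["diverging"]
    with pytest.raises(ValueError):
        convergence_scan(ra, rb, n_max=0)


def test_grid_mismatch_rejected(h2_dimer_work):
    ra = h2_dimer_work.A.response_input()
    bad = MonomerResponseInput(h2_dimer_work.B.hessians,
                               h2_dimer_work.B.state.occupations,
                               h2_dimer_work.B.D[:, :3])
    with pytest.raises(ValueError):
        dispersion_energy(ra, bad)


# ---------------------------------------------------------------------------
# Static induction
# ---------------------------------------------------------------------------

def test_zero_potential_zero_induction(h2_cas_monomer):
    h = h2_cas_monomer["hess"]
    e = induction_static(np.zeros(h.pairs.dim), h)
    assert e == 0.0


def test_single_mode_induction_closed_form():
    """1x1 static response: E = -v^2 * metric^2 / A- = -4 v^2 / A-."""
    mono = _single_mode_monomer(1.2, 2.0, 0.0)
    v = 0.3
    got = induction_static(np.array([v]), mono.hessians)
    assert got == pytest.approx(-4.0 * v * v / 2.0, rel=1e-12)
    assert got < 0


def test_static_route_equals_spectral_route(h2_cas_monomer):
    from mrdisp.erpa import pair_scale_factors, solve_erpa
    h = h2_cas_monomer["hess"]
    occ = h2_cas_monomer["state"].occupations
    rng = np.random.default_rng(0)
    v = 0.05 * rng.normal(size=h.pairs.dim)
    sol = solve_erpa(h, occ)
    w = pair_scale_factors(h.pairs, occ)
    d = sol.Y * w[:, None]
    e_spec = -sum((v @ d[:, k]) ** 2 / sol.omegas[k]
                  for k in range(len(sol.omegas)))
    e_resp = induction_static(v, h)
    assert e_resp == pytest.approx(e_spec, abs=1e-8)
    assert e_resp < 0


def test_induction_both_directions_negative(h2_dimer_work):
    out = induction_both_ways(h2_dimer_work)
    assert out["A<-B"] < 0 and out["B<-A"] < 0
    assert out["total"] == pytest.approx(out["A<-B"] + out["B<-A"])
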