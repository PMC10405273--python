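"""Frequency grid, direct response and the recursive alpha-expansion."""

import numpy as np
import pytest

from mrdisp.erpa import pair_scale_factors, solve_erpa
from mrdisp.fixtures import (generate_synthetic_instance,
                             projected_response_oracle)
from mrdisp.response import (RecursionState, make_frequency_grid,
                             project_response, recursive_projected_response,
                             response_direct)


# ---------------------------------------------------------------------------
# Casimir-Polder quadrature
# ---------------------------------------------------------------------------

def test_casimir_polder_identity_equal_widths():
    grid = make_frequency_grid(8)
    assert grid.casimir_polder(1.0, 1.0) == pytest.approx(0.5, rel=1e-6)


@pytest.mark.parametrize("a,b", [(2.0, 3.0), (0.5, 1.5), (0.3, 4.0)])
def test_casimir_polder_identity_general(a, b):
    grid = make_frequency_grid(8)
    assert grid.casimir_polder(a, b) == pytest.approx(1.0 / (a + b), rel=1e-6)


def test_nodes_positive_and_increasing():
    for grid in (make_frequency_grid(8), make_frequency_grid(12, 0.7)):
        assert np.all(grid.nodes > 0)
        assert np.all(np.diff(grid.nodes) > 0)
        assert np.all(grid.weights > 0)


def test_refined_grid_no_worse():
    cases = [(a, b) for a in (0.2, 1.0, 5.0) for b in (0.2, 1.0, 5.0)]
    e8 = max(abs(make_frequency_grid(8).casimir_polder(a, b) - 1 / (a + b))
             * (a + b) for a, b in cases)
    e16 = max(abs(make_frequency_grid(16).casimir_polder(a, b) - 1 / (a + b))
              * (a + b) for a, b in cases)
    assert e16 <= e8


def test_grid_input_validation():
    with pytest.raises(ValueError):
        make_frequency_grid(0)
    with pytest.raises(ValueError):
        make_frequency_grid(12, omega0=-1.0)
    with pytest.raises(ValueError):
        make_frequency_grid(12, kind="cp")


# ---------------------------------------------------------------------------
# Direct response
# ---------------------------------------------------------------------------

def test_response_matches_spectral_form(h2_cas_monomer):
    h = h2_cas_monomer["hess"]
    occ = h2_cas_monomer["state"].occupations
    sol = solve_erpa(h, occ)
    Ap, Am = h.tilde()
    s = np.sqrt(h.metric)
    w = pair_scale_factors(h.pairs, occ)
    d = sol.Y * w[:, None]
    for om in (0.0, 0.3, 2.0):
        M_spec = sum(np.outer(d[:, k] / s, d[:, k] / s)
                     * sol.omegas[k] / (sol.omegas[k] ** 2 + om ** 2)
                     for k in range(len(sol.omegas)))
        M = response_direct(Ap, Am, om)
        assert np.max(np.abs(M - M_spec)) < 1e-9


def test_high_frequency_decay(h2_cas_monomer):
    Ap, Am = h2_cas_monomer["hess"].tilde()
    M = response_direct(Ap, Am, 1e6)
    assert np.max(np.abs(M)) < 1e-6


def test_negative_frequency_rejected(h2_cas_monomer):
    Ap, Am = h2_cas_monomer["hess"].tilde()
    with pytest.raises(ValueError):
        response_direct(Ap, Am, -0.1)


def test_project_response_contracts():
    rng = np.random.default_rng(11)
    C = rng.normal(size=(6, 6))
    C = 0.5 * (C + C.T)
    D = rng.normal(size=(6, 4))
    assert np.allclose(project_response(C, D), C @ D)
    e = np.zeros((6, 1))
    e[2, 0] = 1.0
    assert np.allclose(project_response(C, e)[:, 0], C[:, 2])
    assert np.all(project_response(C, np.zeros((6, 2))) == 0.0)
    with pytest.raises(ValueError):
        project_response(C, rng.normal(size=(5, 2)))


def test_projected_response_triple_loop_oracle():
    inst = generate_synthetic_instance(5, pair_dim=7, n_chol=3,
                                       coupling_strength=0.05)
    Ap, Am = inst.A_plus, inst.A_minus
    M = response_direct(Ap, Am, 0.4)
    ref = projected_response_oracle(Ap, Am, inst.D, 0.4)
    assert np.allclose(project_response(M, inst.D), ref, atol=1e-10)


# ---------------------------------------------------------------------------
# Recursion
# ---------------------------------------------------------------------------

def test_uncoupled_reference_terminates_recursion():
    inst = generate_synthetic_instance(1, pair_dim=9, n_chol=4,
                                       coupling_strength=0.0)
    pr = recursive_projected_response(inst.A0_plus, inst.A0_minus,
                                      inst.A1_plus, inst.A1_minus,
                                      inst.blocks, inst.D, 0.3, n=10)
    assert pr.order == 0
    direct = response_direct(inst.A_plus, inst.A_minus, 0.3) @ inst.D
    assert np.allclose(pr.total(), direct, atol=1e-10)


def test_same_seed_reproducible():
    a = generate_synthetic_instance(42, 8, 3, 0.1)
    b = generate_synthetic_instance(42, 8, 3, 0.1)
    assert np.array_equal(a.A0_plus, b.A0_plus)
    assert np.array_equal(a.A1_minus, b.A1_minus)
    assert np.array_equal(a.D, b.D)


def test_recursion_converges_to_direct_solve():
    inst = generate_synthetic_instance(7, pair_dim=12, n_chol=4,
                                       coupling_strength=0.1)
    for om in (0.1, 1.0):
        direct = response_direct(inst.A_plus, inst.A_minus, om) @ inst.D
        pr = recursive_projected_response(inst.A0_plus, inst.A0_minus,
                                          inst.A1_plus, inst.A1_minus,
                                          inst.blocks, inst.D, om, n=30)
        assert not pr.diverging
        err = np.linalg.norm(pr.total() - direct) / np.linalg.norm(direct)
        assert err < 1e-8


def test_increment_norms_decay_geometrically():
    inst = generate_synthetic_instance(3, pair_dim=12, n_chol=4,
                                       coupling_strength=0.05)
    pr = recursive_projected_response(inst.A0_plus, inst.A0_minus,
                                      inst.A1_plus, inst.A1_minus,
                                      inst.blocks, inst.D, 0.5, n=10)
    norms = [np.linalg.norm(z) for z in pr.increments]
    assert norms[6] < norms[2]
    assert norms[10] < 1e-3 * norms[0]


def test_error_decreases_with_order():
    inst = generate_synthetic_instance(9, pair_dim=10, n_chol=3,
                                       coupling_strength=0.15)
    om = 0.4
    direct = response_direct(inst.A_plus, inst.A_minus, om) @ inst.D
    pr = recursive_projected_response(inst.A0_plus, inst.A0_minus,
                                      inst.A1_plus, inst.A1_minus,
                                      inst.blocks, inst.D, om, n=12)
    errs = [np.linalg.norm(pr.total(k) - direct) for k in (2, 6, 12)]
    assert errs[2] < errs[1] < errs[0]


def test_block_resolvent_applies_blockwise_only():
    """Lam(omega) solves agree with the dense block-diagonal system and the
    state never stores a full-dimension factorization."""
    inst = generate_synthetic_instance(13, pair_dim=11, n_chol=2,
                                       coupling_strength=0.1, block_size=4)
    om = 0.6
    rs = RecursionState(inst.A0_plus, inst.A0_minus, inst.blocks, om)
    assert max(len(b) for b in rs.blocks) == 4
    assert all(lu[0].shape[0] == len(b)
               for lu, b in zip(rs._lu, rs.blocks))
    rhs = np.arange(11.0).reshape(-1, 1)
    lam_dense = inst.A0_plus @ inst.A0_minus + om ** 2 * np.eye(11)
    assert np.allclose(rs.solve(rhs), np.linalg.solve(lam_dense, rhs),
                       atol=1e-10)


def test_incomplete_block_cover_rejected():
    inst = generate_synthetic_instance(2, pair_dim=6, n_chol=2)
    with pytest.raises(ValueError):
        RecursionState(inst.A0_plus, inst.A0_minus, [np.array([0, 1])], 0.5)
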