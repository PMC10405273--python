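"""ERPA pair space, Hessians, eigensolution and the sum-over-states oracle."""

import itertools

import numpy as np
import pytest

from mrdisp.backend import OrbitalPartition
from mrdisp.erpa import (_double_commutator_tensor, build_hessians,
                         build_pair_index, dispersion_sum_over_states,
                         solve_erpa, split_alpha)
from mrdisp.fixtures import rpa_oracle_dense
from mrdisp.response import response_direct
from mrdisp.scf import _FCISpace


# ---------------------------------------------------------------------------
# Pair index
# ---------------------------------------------------------------------------

def test_single_pair_space():
    part = OrbitalPartition([0], [], [1])
    pm = build_pair_index(part, np.array([1.0, 0.0]))
    assert pm.pairs == [(1, 0)]
    assert pm.metric[0] == pytest.approx(2.0)


def test_pair_enumeration_matches_brute_force():
    """|s1|=2, |s2|=2, |s3|=3 with nondegenerate occupations -> 17 pairs."""
    part = OrbitalPartition([0, 1], [2, 3], [4, 5, 6])
    occ = np.array([1.0, 1.0, 0.8, 0.3, 0.0, 0.0, 0.0])
    pm = build_pair_index(part, occ, metric_tol=1e-12)
    s1, s2, s3 = set(part.s1), set(part.s2), set(part.s3)
    brute = [(p, q) for p, q in itertools.permutations(range(7), 2)
             if p > q
             and not (p in s1 and q in s1) and not (p in s3 and q in s3)]
    assert pm.dim == len(brute) == 17
    assert sorted(pm.pairs) == sorted(brute)
    # group sizes are basis-order independent quantities
    sizes = {g: sl.stop - sl.start for g, sl in pm.groups.items()}
    assert sizes == {"s2s1": 4, "s3s1": 6, "s2s2": 1, "s3s2": 6}


def test_block_layout_sizes_bounded_by_active_dimension():
    part = OrbitalPartition([0, 1], [2, 3, 4], [5, 6, 7, 8])
    occ = np.array([1, 1, 0.9, 0.5, 0.1, 0, 0, 0, 0], dtype=float)
    pm = build_pair_index(part, occ, metric_tol=1e-12)
    M = 3
    max_block = max(len(b) for b in pm.blocks)
    assert max_block <= max(M * (M - 1) // 2, M)
    covered = sorted(np.concatenate(pm.blocks).tolist())
    assert covered == list(range(pm.dim))


def test_empty_spaces_rejected():
    with pytest.raises(ValueError):
        build_pair_index(OrbitalPartition([], [], [0, 1]), np.zeros(2))
    with pytest.raises(ValueError):
        build_pair_index(OrbitalPartition([0, 1], [], []), np.ones(2))


# ---------------------------------------------------------------------------
# Hessians
# ---------------------------------------------------------------------------

def test_double_commutator_tensor_vs_exact_operator_algebra():
    """The RDM contraction equals <[E_qp,[H,E_rs]]> evaluated exactly."""
    rng = np.random.default_rng(7)
    n, nel = 3, 2
    h1 = rng.normal(size=(n, n))
    h1 = 0.5 * (h1 + h1.T)
    eri = 0.1 * rng.normal(size=(n, n, n, n))
    eri = eri + eri.transpose(1, 0, 2, 3)
    eri = eri + eri.transpose(0, 1, 3, 2)
    eri = eri + eri.transpose(2, 3, 0, 1)
    sp = _FCISpace(n, nel // 2, nel // 2)
    H = sp.hamiltonian(h1, eri)
    _, vecs = np.linalg.eigh(H)
    psi = vecs[:, 0]
    dim = sp.dim
    I = np.eye(dim)
    E = {(p, q): np.array([sp.apply_epq(I[:, k], p, q)
                           for k in range(dim)]).T
         for p in range(n) for q in range(n)}
    gamma = np.array([[psi @ E[(p, q)] @ psi for q in range(n)]
                      for p in range(n)])
    d = np.zeros((n, n, n, n))
    for p, q, r, s in itertools.product(range(n), repeat=4):
        d[p, q, r, s] = psi @ E[(p, q)] @ E[(r, s)] @ psi \
            - (q == r) * gamma[p, s]
    T = _double_commutator_tensor(h1, eri, gamma, d)
    for p, q, r, s in itertools.product(range(n), repeat=4):
        HE = H @ E[(r, s)] - E[(r, s)] @ H
        comm = E[(q, p)] @ HE - HE @ E[(q, p)]
        assert psi @ comm @ psi == pytest.approx(T[p, q, r, s], abs=1e-12)


def test_hessian_symmetry(h2_cas_monomer):
    h = h2_cas_monomer["hess"]
    assert np.max(np.abs(h.A_plus - h.A_plus.T)) < 1e-10
    assert np.max(np.abs(h.A_minus - h.A_minus.T)) < 1e-10


def test_alpha_split_exact_and_block_diagonal(h2_cas_monomer):
    h = h2_cas_monomer["hess"]
    (A0p, A0m), (A1p, A1m) = split_alpha(h)
    assert np.allclose(A0p + A1p, h.A_plus, atol=0)
    assert np.allclose(A0m + A1m, h.A_minus, atol=0)
    mask = np.zeros_like(A0p, dtype=bool)
    for b in h.pairs.blocks:
        mask[np.ix_(b, b)] = True
    assert np.all(A0p[~mask] == 0.0)
    assert np.all(A0m[~mask] == 0.0)
    # a Hessian already block diagonal has zero first-order part
    import copy
    h2 = copy.deepcopy(h)
    h2.A_plus = A0p
    h2.A_minus = A0m
    (_, _), (B1p, B1m) = split_alpha(h2)
    assert np.all(B1p == 0.0) and np.all(B1m == 0.0)


def test_single_pair_closed_form_rpa(h2_monomer):
    """1x1 reduction: omega = sqrt((A+B)(A-B)) with textbook integrals.

    For one occupied-virtual pair (i, a): A = de + 2(ia|ia) - (ii|aa) and
    B = (ia|ia); the package's A± restricted to that pair must equal
    2(A-B) and 2(A+B) (metric 2), elementwise.
    """
    st = h2_monomer["state"]
    eri_no = h2_monomer["eri_no"]
    part = st.partition
    i, a = part.s1[0], part.s3[0]
    h_no = st.metadata["hcore_no"]
    occ = part.s1
    F = h_no + 2 * np.einsum("pqii->pq", eri_no[:, :, occ][:, :, :, occ]) \
        - np.einsum("piiq->pq", eri_no[:, occ][:, :, occ])
    de = F[a, a] - F[i, i]
    A = de + 2 * eri_no[i, a, i, a] - eri_no[i, i, a, a]
    B = eri_no[i, a, i, a]
    h = h2_monomer["hess"]
    k = h2_monomer["pairs"].pairs.index((a, i))
    assert h.metric[k] == pytest.approx(2.0, abs=1e-12)
    assert h.A_plus[k, k] == pytest.approx(2.0 * (A - B), rel=1e-10)
    assert h.A_minus[k, k] == pytest.approx(2.0 * (A + B), rel=1e-10)


def test_mean_field_limit_equals_dense_rpa_oracle(h2_monomer):
    """Empty active space: ERPA roots match an independent RPA routine."""
    st = h2_monomer["state"]
    eri_no = h2_monomer["eri_no"]
    h_no = st.metadata["hcore_no"]
    occ = st.partition.s1
    F = h_no + 2 * np.einsum("pqii->pq", eri_no[:, :, occ][:, :, :, occ]) \
        - np.einsum("piiq->pq", eri_no[:, occ][:, :, occ])
    om_ref, _, _ = rpa_oracle_dense(np.diag(F), eri_no, st.partition.s1,
                                    st.partition.s3)
    sol = solve_erpa(h2_monomer["hess"], st.occupations)
    assert np.allclose(np.sort(sol.omegas), om_ref, atol=1e-8)
    assert sol.n_discarded_negative == 0


def test_solver_contracts(h2_cas_monomer):
    sol = solve_erpa(h2_cas_monomer["hess"],
                     h2_cas_monomer["state"].occupations)
    assert np.all(sol.omegas > 0)
    assert len(sol.omegas) <= h2_cas_monomer["pairs"].dim
    assert "normalization" in sol.metadata


def test_no_roots_removed_when_product_positive_definite(h2_monomer):
    h = h2_monomer["hess"]
    Ap, Am = h.tilde()
    assert np.min(np.linalg.eigvalsh(0.5 * (Ap + Ap.T))) > 0
    assert np.min(np.linalg.eigvalsh(0.5 * (Am + Am.T))) > 0
    sol = solve_erpa(h, h2_monomer["state"].occupations)
    assert sol.n_discarded_negative == 0


def test_static_polarizability_matches_finite_field(h2_monomer):
    """Coupled static response == finite-field SCF polarizability (CPHF)."""
    from mrdisp import integrals as ig
    from mrdisp.scf import run_rhf
    st = h2_monomer["state"]
    basis = h2_monomer["basis"]
    geom = h2_monomer["geom"]
    dip = ig.dipole(basis)
    C = st.no_coefficients
    z_no = C.T @ dip[2] @ C
    pairs = h2_monomer["pairs"]
    zbar = np.array([z_no[p, q] for p, q in pairs.pairs])
    Ap, Am = h2_monomer["hess"].tilde()
    M0 = response_direct(Ap, Am, 0.0)
    s = np.sqrt(h2_monomer["hess"].metric)
    alpha = 2.0 * (s * zbar) @ M0 @ (s * zbar)
    S = ig.overlap(basis)
    h0 = ig.kinetic(basis) + ig.nuclear_attraction(basis, geom.charges())
    eri_ao = h2_monomer["eri_ao"]
    enuc = ig.nuclear_repulsion(geom.charges())

    def e_at(F):
        return run_rhf(h0, S, eri_ao, 2, enuc, field=-F * dip[2],
                       conv=1e-12).energy

    f = 1e-3
    alpha_ff = -(e_at(f) - 2 * e_at(0.0) + e_at(-f)) / f ** 2
    assert alpha == pytest.approx(alpha_ff, rel=1e-5)


# ---------------------------------------------------------------------------
# Sum-over-states dispersion
# ---------------------------------------------------------------------------

def test_one_term_sum_is_negative_casimir_polder():
    from mrdisp.erpa import EigenSolution
    sa = EigenSolution(np.array([0.7]), np.array([[1.3]]), 0)
    sb = EigenSolution(np.array([0.9]), np.array([[0.4]]), 0)
    t = 1.3 * 0.4 * 0.25
    e = dispersion_sum_over_states(sa, sb, np.array([[0.25]]))
    assert e == pytest.approx(-t * t / (0.7 + 0.9), rel=1e-14)
    assert e < 0


def test_doubling_couplings_quadruples_energy():
    rng = np.random.default_rng(3)
    from mrdisp.erpa import EigenSolution
    sa = EigenSolution(np.array([0.5, 1.1]), rng.normal(size=(4, 2)), 0)
    sb = EigenSolution(np.array([0.8, 1.7]), rng.normal(size=(3, 2)), 0)
    g = rng.normal(size=(4, 3)) * 0.01
    e1 = dispersion_sum_over_states(sa, sb, g)
    e2 = dispersion_sum_over_states(sa, sb, 2.0 * g)
    assert e2 == pytest.approx(4.0 * e1, rel=1e-12)


def test_empty_spectrum_rejected():
    from mrdisp.erpa import EigenSolution
    sa = EigenSolution(np.array([]), np.zeros((0, 0)), 0)
    sb = EigenSolution(np.array([0.5]), np.ones((1, 1)), 0)
    with pytest.raises(ValueError):
        dispersion_sum_over_states(sa, sb, np.zeros((0, 1)))
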