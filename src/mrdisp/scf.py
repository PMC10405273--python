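"""Restricted Hartree-Fock and small-active-space CASCI solvers.

These provide the monomer wave functions (orbitals, occupation numbers and
spin-free reduced density matrices) consumed by the extended-RPA machinery.
The CASCI step performs a full CI in the active orbital window on top of RHF
orbitals; the resulting one-electron density is diagonalized in the active
block to yield natural orbitals with fractional occupations, while inactive
(doubly occupied) and virtual orbitals keep occupations one and zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

__all__ = ["RHFResult", "run_rhf", "CASCIResult", "run_casci",
           "fci_states", "spinfree_rdms"]


@dataclass
class RHFResult:
    energy: float           # total electronic + nuclear energy (hartree)
    mo_coeff: np.ndarray    # AO -> MO
    mo_energy: np.ndarray
    n_occ: int              # doubly occupied orbital count
    converged: bool


def run_rhf(hcore: np.ndarray, S: np.ndarray, eri: np.ndarray, n_electrons: int,
            e_nuc: float = 0.0, max_cycles: int = 200, conv: float = 1e-10,
            field: np.ndarray | None = None) -> RHFResult:
    """Closed-shell SCF with DIIS.  `eri` is the full (pq|rs) AO tensor.

    `field` optionally adds a one-electron operator (e.g. -F.r for a finite
    electric field) to the core Hamiltonian.
    """
    if n_electrons % 2:
        raise ValueError("run_rhf requires an even electron count")
    h = hcore if field is None else hcore + field
    n_occ = n_electrons // 2
    s_val, s_vec = eigh(S)
    if s_val.min() < 1e-10:
        raise np.linalg.LinAlgError("AO overlap is numerically singular")
    X = s_vec @ np.diag(s_val ** -0.5) @ s_vec.T

    e_mo, C = eigh(X.T @ h @ X)
    C = X @ C
    dm = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
    diis_F, diis_err = [], []
    energy = 0.0
    converged = False
    for _ in range(max_cycles):
        J = np.einsum("pqrs,rs->pq", eri, dm)
        K = np.einsum("prqs,rs->pq", eri, dm)
        F = h + J - 0.5 * K
        err = F @ dm @ S - S @ dm @ F
        diis_F.append(F)
        diis_err.append(err)
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_err.pop(0)
        if len(diis_F) > 1:
            m = len(diis_F)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = np.vdot(diis_err[i], diis_err[j])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                c = np.linalg.solve(B, rhs)[:m]
                F = sum(ci * Fi for ci, Fi in zip(c, diis_F))
            except np.linalg.LinAlgError:
                pass
        e_mo, Cp = eigh(X.T @ F @ X)
        C = X @ Cp
        dm_new = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
        e_new = 0.5 * np.einsum("pq,pq->", dm_new, h + F) + e_nuc
        if abs(e_new - energy) < conv and np.max(np.abs(dm_new - dm)) < 1e-7:
            converged = True
            dm, energy = dm_new, e_new
            break
        dm, energy = dm_new, e_new
    return RHFResult(energy, C, e_mo, n_occ, converged)


# ---------------------------------------------------------------------------
# Determinant full CI in an active window
# ---------------------------------------------------------------------------

def _bits(occ_tuple: tuple[int, ...]) -> int:
    b = 0
    for o in occ_tuple:
        b |= 1 << o
    return b


def _popcount_below(mask: int, orb: int) -> int:
    return bin(mask & ((1 << orb) - 1)).count("1")


def _excite(mask: int, i: int, a: int):
    """Move one electron from orbital i to orbital a; returns (new_mask, sign)."""
    if not (mask >> i) & 1:
        return None, 0
    if i == a:
        return mask, 1
    if (mask >> a) & 1:
        return None, 0
    sign = 1
    m1 = mask & ~(1 << i)
    if _popcount_below(mask, i) % 2:
        sign = -sign
    if _popcount_below(m1, a) % 2:
        sign = -sign
    return m1 | (1 << a), sign


class _FCISpace:
    """Enumerated determinant space for (n_alpha, n_beta) electrons in M orbitals."""

    def __init__(self, n_orb: int, n_alpha: int, n_beta: int):
        self.n_orb = n_orb
        self.alpha = [_bits(c) for c in
                      itertools.combinations(range(n_orb), n_alpha)]
        self.beta = [_bits(c) for c in
                     itertools.combinations(range(n_orb), n_beta)]
        self.a_index = {m: i for i, m in enumerate(self.alpha)}
        self.b_index = {m: i for i, m in enumerate(self.beta)}
        self.dim = len(self.alpha) * len(self.beta)

    def apply_epq(self, vec: np.ndarray, p: int, q: int) -> np.ndarray:
        """Spin-summed excitation E_pq = sum_s a+_ps a_qs applied to a CI vector."""
        na, nb = len(self.alpha), len(self.beta)
        v = vec.reshape(na, nb)
        out = np.zeros_like(v)
        for ia, ma in enumerate(self.alpha):
            new, sgn = _excite(ma, q, p)
            if new is not None:
                out[self.a_index[new], :] += sgn * v[ia, :]
        for ib, mb in enumerate(self.beta):
            new, sgn = _excite(mb, q, p)
            if new is not None:
                out[:, self.b_index[new]] += sgn * v[:, ib]
        return out.ravel()

    def hamiltonian(self, h1: np.ndarray, eri: np.ndarray) -> np.ndarray:
        """Dense Hamiltonian via H = sum h1 E_pq + 1/2 sum (pq|rs) (E_pq E_rs - d_qr E_ps)."""
        n = self.n_orb
        dim = self.dim
        H = np.zeros((dim, dim))
        # effective one-electron part absorbing the -1/2 d_qr E_ps term
        h_eff = h1 - 0.5 * np.einsum("prrs->ps", eri)
        basis = np.eye(dim)
        # apply E_rs to all basis vectors once: store E_rs acting on identity
        E_cols = {}
        for r in range(n):
            for s in range(n):
                E_cols[(r, s)] = np.array(
                    [self.apply_epq(basis[:, k], r, s) for k in range(dim)]).T
        for p in range(n):
            for q in range(n):
                H += h_eff[p, q] * E_cols[(p, q)]
        for p in range(n):
            for q in range(n):
                Epq = E_cols[(p, q)]
                for r in range(n):
                    for s in range(n):
                        g = eri[p, q, r, s]
                        if abs(g) > 1e-14:
                            H += 0.5 * g * (Epq @ E_cols[(r, s)])
        return H


def fci_states(h1: np.ndarray, eri: np.ndarray, n_electrons: int,
               n_roots: int = 1, spin_penalty: float = 0.0):
    """Lowest singlet-sector eigenstates of the active-space Hamiltonian.

    Returns (energies, vectors, space).  With equal alpha/beta counts the
    spectrum contains both singlets and triplets; states are returned in
    energy order, tagged by total-spin expectation stored alongside.
    """
    if n_electrons % 2:
        raise ValueError("only spin-compensated active spaces are supported")
    n_orb = h1.shape[0]
    space = _FCISpace(n_orb, n_electrons // 2, n_electrons // 2)
    H = space.hamiltonian(h1, eri)
    evals, evecs = eigh(H)
    return evals[:n_roots], evecs[:, :n_roots], space


def spinfree_rdms(space: _FCISpace, vec: np.ndarray):
    """Spin-free 1- and 2-RDMs of a CI vector.

    gamma_pq = <E_pq>;  d_pqrs = <E_pq E_rs> - delta_qr <E_ps>
    (chemists' pairing: d couples charge distributions (pq) and (rs)).
    """
    n = space.n_orb
    t = {}
    for r in range(n):
        for s in range(n):
            t[(r, s)] = space.apply_epq(vec, r, s)
    gamma = np.zeros((n, n))
    for p in range(n):
        for q in range(n):
            gamma[p, q] = vec @ t[(p, q)]
    d = np.zeros((n, n, n, n))
    for p in range(n):
        for q in range(n):
            tq = t[(q, p)]  # <v|E_pq = (E_qp |v>)^T
            for r in range(n):
                for s in range(n):
                    d[p, q, r, s] = tq @ t[(r, s)]
    d -= np.einsum("qr,ps->pqrs", np.eye(n), gamma)
    return gamma, d


def _sa_casci_rdms(h_act, eri_act, n_el_act, weights):
    """State-averaged CASCI: energies, per-root and averaged RDMs."""
    n_roots = len(weights)
    evals, evecs, space = fci_states(h_act, eri_act, n_el_act, n_roots=n_roots)
    gammas, d2s = [], []
    for r in range(n_roots):
        g, d = spinfree_rdms(space, evecs[:, r])
        gammas.append(g)
        d2s.append(d)
    g_avg = sum(w * g for w, g in zip(weights, gammas))
    d_avg = sum(w * d for w, d in zip(weights, d2s))
    return evals, gammas, d2s, g_avg, d_avg


def run_casscf(hcore: np.ndarray, S: np.ndarray, eri_ao: np.ndarray,
               n_electrons: int, e_nuc: float, n_active_electrons: int,
               n_active_orbitals: int, weights=(1.0,), root: int = 0,
               mo_guess: np.ndarray | None = None, gtol: float = 1e-7,
               max_iter: int = 400):
    """(State-averaged) CASSCF: full CI in the active window with orbital
    optimization over the nonredundant rotations.

    The orbitals are parametrized as C = C0 exp(K) with K antisymmetric over
    inactive-active, inactive-virtual and active-virtual pairs; the averaged
    energy is minimized quasi-Newton (L-BFGS) with the analytic gradient
    from the generalized Fock matrix.  Returns a CASCIResult for ``root``
    evaluated at the optimal orbitals (state-averaged natural orbitals are
    *not* formed here; callers diagonalize the root's own density).
    """
    from scipy.linalg import expm
    from scipy.optimize import minimize

    if mo_guess is None:
        rhf = run_rhf(hcore, S, eri_ao, n_electrons, e_nuc)
        if not rhf.converged:
            raise RuntimeError("RHF preconverger failed")
        C0 = rhf.mo_coeff
    else:
        C0 = mo_guess
    n_orb = C0.shape[1]
    n_inactive = n_electrons // 2 - n_active_electrons // 2
    if n_inactive < 0 or n_inactive + n_active_orbitals > n_orb:
        raise ValueError("active space does not fit the orbital window")
    inact = list(range(n_inactive))
    act = list(range(n_inactive, n_inactive + n_active_orbitals))
    virt = list(range(n_inactive + n_active_orbitals, n_orb))
    rot_pairs = ([(a, i) for i in inact for a in act]
                 + [(a, i) for i in inact for a in virt]
                 + [(a, t) for t in act for a in virt])
    weights = np.asarray(weights, dtype=float)

    def orbitals(x):
        K = np.zeros((n_orb, n_orb))
        for val, (a, i) in zip(x, rot_pairs):
            K[a, i] = val
            K[i, a] = -val
        return C0 @ expm(K)

    def casci_at(C):
        h_mo = C.T @ hcore @ C
        eri_mo = np.einsum("pqrs,pi,qj,rk,sl->ijkl", eri_ao, C, C, C, C,
                           optimize=True)
        e_core = e_nuc
        h_eff = h_mo
        if inact:
            ii = np.ix_(inact, inact)
            e_core += 2.0 * np.trace(h_mo[ii])
            Jc = 2.0 * np.einsum("pqii->pq",
                                 eri_mo[:, :, inact][:, :, :, inact])
            Kc = np.einsum("piiq->pq", eri_mo[:, inact][:, :, inact])
            e_core += sum(2.0 * eri_mo[i, i, j, j] - eri_mo[i, j, j, i]
                          for i in inact for j in inact)
            h_eff = h_mo + Jc - Kc
        aa = np.ix_(act, act)
        evals, gammas, d2s, g_avg, d_avg = _sa_casci_rdms(
            h_eff[aa], eri_mo[np.ix_(act, act, act, act)],
            n_active_electrons, weights)
        return h_mo, eri_mo, e_core, evals, gammas, d2s, g_avg, d_avg

    def energy_grad(x):
        C = orbitals(x)
        h_mo, eri_mo, e_core, evals, gammas, d2s, g_avg, d_avg = casci_at(C)
        e_sa = float(np.dot(weights, evals) + e_core)
        # full-space averaged RDMs for the gradient
        gamma = np.zeros((n_orb, n_orb))
        for i in inact:
            gamma[i, i] = 2.0
        gamma[np.ix_(act, act)] += g_avg
        d = _full_rdm2(gamma, g_avg, d_avg, inact, act, n_orb)
        G = 2.0 * (h_mo @ gamma + np.einsum("mqrs,pqrs->mp", eri_mo, d,
                                            optimize=True))
        grad = np.array([G[a, i] - G[i, a] for (a, i) in rot_pairs])
        return e_sa, grad

    # L-BFGS with periodic re-expansion of exp(K) around the current point
    # (resets the parametrization when rotations grow large, which the
    # near-redundant inactive/active directions otherwise make very slow)
    converged = False
    for _ in range(8):
        res = minimize(lambda x: energy_grad(x), np.zeros(len(rot_pairs)),
                       jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter, "gtol": gtol,
                                "ftol": 1e-14})
        C0 = orbitals(res.x)
        if np.max(np.abs(energy_grad(np.zeros(len(rot_pairs)))[1])) < 1e-4:
            converged = True
            break
    C = C0
    h_mo, eri_mo, e_core, evals, gammas, d2s, g_avg, d_avg = casci_at(C)
    tot = np.asarray(evals) + e_core
    out = CASCIResult(float(tot[root]), tot, C, inact, act,
                      gammas[root], d2s[root], root)
    out.converged = converged
    out.e_state_average = float(np.dot(weights, evals) + e_core)
    return out


def _full_rdm2(gamma, g_act, d_act, inact, act, n_orb):
    """Full-space spin-free 2-RDM from core + active parts (chemists')."""
    gc = np.zeros((n_orb, n_orb))
    for i in inact:
        gc[i, i] = 2.0
    d = (np.einsum("pq,rs->pqrs", gc, gamma)
         + np.einsum("pq,rs->pqrs", gamma, gc)
         - np.einsum("pq,rs->pqrs", gc, gc))
    d -= 0.5 * (np.einsum("ps,rq->pqrs", gc, gamma)
                + np.einsum("ps,rq->pqrs", gamma, gc)
                - np.einsum("ps,rq->pqrs", gc, gc))
    if act:
        d[np.ix_(act, act, act, act)] += d_act
    return d


@dataclass
class CASCIResult:
    energy: float              # total energy of the target state
    energies: np.ndarray       # all requested roots (total energies)
    mo_coeff: np.ndarray       # AO -> MO (RHF orbitals, active window intact)
    inactive: list[int]
    active: list[int]
    gamma_active: np.ndarray   # spin-free 1-RDM in the active MO window
    rdm2_active: np.ndarray    # spin-free 2-RDM, chemists' pairing
    root: int


def run_casci(rhf: RHFResult, hcore: np.ndarray, eri_ao: np.ndarray,
              e_nuc: float, n_active_electrons: int, n_active_orbitals: int,
              n_roots: int = 1, root: int = 0) -> CASCIResult:
    """Full CI in an active window centred on the Fermi level of an RHF state."""
    C = rhf.mo_coeff
    n_orb = C.shape[1]
    n_inactive = rhf.n_occ - n_active_electrons // 2
    if n_inactive < 0 or n_inactive + n_active_orbitals > n_orb:
        raise ValueError("active space does not fit the orbital window")
    inactive = list(range(n_inactive))
    active = list(range(n_inactive, n_inactive + n_active_orbitals))

    h_mo = C.T @ hcore @ C
    eri_mo = np.einsum("pqrs,pi,qj,rk,sl->ijkl", eri_ao, C, C, C, C,
                       optimize=True)
    # inactive Fock embedding
    e_core = e_nuc
    h_eff = h_mo.copy()
    if inactive:
        ii = np.ix_(inactive, inactive)
        e_core += 2.0 * h_mo[ii][np.diag_indices(len(inactive))].sum()
        Jc = 2.0 * np.einsum("pqii->pq", eri_mo[:, :, inactive][:, :, :, inactive])
        Kc = np.einsum("piiq->pq", eri_mo[:, inactive][:, :, inactive])
        e_core += sum(
            2.0 * eri_mo[i, i, j, j] - eri_mo[i, j, j, i]
            for i in inactive for j in inactive)
        h_eff = h_mo + Jc - Kc
    h_act = h_eff[np.ix_(active, active)]
    eri_act = eri_mo[np.ix_(active, active, active, active)]
    evals, evecs, space = fci_states(h_act, eri_act, n_active_electrons,
                                     n_roots=max(n_roots, root + 1))
    gamma, d2 = spinfree_rdms(space, evecs[:, root])
    tot = evals + e_core
    return CASCIResult(tot[root], tot, C, inactive, active, gamma, d2, root)
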