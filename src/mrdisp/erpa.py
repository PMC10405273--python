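"""Extended random-phase approximation (ERPA) over natural-orbital pairs.

The ERPA eigenproblem for a monomer described by spin-free 1- and 2-RDMs is
built from double-commutator expectation values (equations-of-motion form).
With spin-summed excitation operators E_pq = sum_s a+_ps a_qs, a real wave
function |0>, and the symmetric / antisymmetric one-body combinations
S_pq = E_pq + E_qp and R_pq = E_pq - E_qp over orbital pairs (p > q), the
working Hessians are

    A+_(pq),(rs) = 1/2 <0| [S_pq, [H, S_rs]] |0>     ("non-unitary" modes)
    A-_(pq),(rs) = 1/2 <0| [R_pq, [H, R_rs]] |0>     (orbital rotations)
    N_(pq),(rs)  = delta * (gamma_q - gamma_p)       (diagonal metric)

which close over the 1- and 2-RDM because the double commutator of one-body
operators with a two-body Hamiltonian is again (at most) two-body.  For a
single determinant A+ and A- are exactly the singlet TDHF stability
matrices 2(A-B) and 2(A+B).  With amplitude vectors F and G the
eigenproblem reads

    A+ F = omega N G,     A- G = omega N F,

and the (real) transition-density vector of root nu is d_nu = N G_nu; the
static limit reproduces coupled-perturbed (finite-field) response exactly
in the mean-field case.  In the metric-orthonormal representation
(S = N^(1/2), A~± = S^-1 A± S^-1) the squared transition energies are the
eigenvalues of A~+ A~- and the G-carriers are its right eigenvectors.

The pair index runs over the subranges (active x inactive), (virtual x
inactive), (active x active, p > q), (virtual x active); inactive-inactive
and virtual-virtual pairs are excluded.  Pairs with a (numerically) zero
occupation-difference metric support no excitation and are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eig, solve

from .backend import MonomerState, OrbitalPartition, full_space_rdms

__all__ = ["PairIndexMap", "ERPAHessians", "EigenSolution", "build_pair_index",
           "build_hessians", "split_alpha", "solve_erpa",
           "dispersion_sum_over_states", "pair_scale_factors"]

GROUP_ORDER = ("s2s1", "s3s1", "s2s2", "s3s2")


@dataclass
class PairIndexMap:
    """Ordered orbital pairs (p, q), p > q, with group offsets and block layout."""

    pairs: list[tuple[int, int]]
    groups: dict[str, slice]
    metric: np.ndarray                      # N_pq = gamma_q - gamma_p = 2(n_q - n_p)
    blocks: list[np.ndarray]                # alpha = 0 block layout (pair indices)
    dropped: list[tuple[int, int]] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return len(self.pairs)

    def index(self, p: int, q: int) -> int:
        return self.pairs.index((p, q))


def build_pair_index(partition: OrbitalPartition,
                     occupations: np.ndarray,
                     metric_tol: float = 0.02) -> PairIndexMap:
    """Enumerate excitation pairs by subrange and attach the ERPA metric.

    Pairs whose occupation difference n_q - n_p falls below half of
    ``metric_tol`` (default: 0.01 electron pair) are excluded: their ERPA
    metric is near-singular, they carry O((n_q-n_p)^2) transition strength,
    and they couple pathologically in the coupling-constant expansion.  Pass
    ``metric_tol=0`` (or tiny) to keep every pair of the formal subranges.

    The alpha = 0 block layout (group-product-function reference) couples:
    all active-active pairs in one block; the active pairs sharing one
    inactive (or one virtual) partner in one block each; virtual-inactive
    pairs are 1 x 1 blocks.  With an empty active set this reduces to a
    diagonal zeroth order (Moller-Plesset-like).
    """
    s1, s2, s3 = partition.s1, partition.s2, partition.s3
    occ = np.asarray(occupations, dtype=float)
    if not (s1 or s2):
        raise ValueError("no occupied orbitals: no excitations exist")
    if not (s2 or s3):
        raise ValueError("no secondary orbitals: no excitations exist")
    raw: dict[str, list[tuple[int, int]]] = {g: [] for g in GROUP_ORDER}
    for q in s1:
        for p in s2:
            raw["s2s1"].append((p, q))
    for q in s1:
        for p in s3:
            raw["s3s1"].append((p, q))
    for i, q in enumerate(s2):
        for p in s2[i + 1:]:
            raw["s2s2"].append((p, q))
    for q in s2:
        for p in s3:
            raw["s3s2"].append((p, q))

    pairs, dropped, metric = [], [], []
    groups = {}
    pos = 0
    kept_by_group = {}
    for gname in GROUP_ORDER:
        kept = []
        for (p, q) in raw[gname]:
            m = 2.0 * (occ[q] - occ[p])
            if m > metric_tol:
                kept.append((p, q))
                metric.append(m)
            else:
                dropped.append((p, q))
        groups[gname] = slice(pos, pos + len(kept))
        kept_by_group[gname] = kept
        pairs.extend(kept)
        pos += len(kept)

    blocks = []
    # active-active pairs: one block
    sl = groups["s2s2"]
    if sl.stop > sl.start:
        blocks.append(np.arange(sl.start, sl.stop))
    # inactive -> active: one block per inactive partner
    for gname, shared_pos in (("s2s1", 1), ("s3s2", 0)):
        sl = groups[gname]
        kept = kept_by_group[gname]
        by_partner: dict[int, list[int]] = {}
        for k, pq in enumerate(kept):
            by_partner.setdefault(pq[shared_pos], []).append(sl.start + k)
        for key in sorted(by_partner):
            blocks.append(np.array(by_partner[key]))
    # inactive -> virtual: diagonal
    sl = groups["s3s1"]
    for k in range(sl.start, sl.stop):
        blocks.append(np.array([k]))
    blocks.sort(key=lambda b: b[0])
    return PairIndexMap(pairs, groups, np.array(metric), blocks, dropped)


def pair_scale_factors(pairs: PairIndexMap, occupations: np.ndarray) -> np.ndarray:
    """w_pq = n_p^(1/2) + n_q^(1/2): occupation scaling of the integrals g."""
    occ = np.asarray(occupations, dtype=float)
    return np.array([np.sqrt(max(occ[p], 0.0)) + np.sqrt(max(occ[q], 0.0))
                     for p, q in pairs.pairs])


# ---------------------------------------------------------------------------
# Hessians
# ---------------------------------------------------------------------------

@dataclass
class ERPAHessians:
    A_plus: np.ndarray
    A_minus: np.ndarray
    metric: np.ndarray               # diagonal of N over the pair index
    pairs: PairIndexMap
    A0_plus: np.ndarray | None = None
    A0_minus: np.ndarray | None = None
    A1_plus: np.ndarray | None = None
    A1_minus: np.ndarray | None = None

    @property
    def block_layout(self):
        return self.pairs.blocks

    def tilde(self):
        """Metric-orthonormal Hessians (S^-1 A± S^-1 with S = N^(1/2))."""
        s = 1.0 / np.sqrt(self.metric)
        return (self.A_plus * np.outer(s, s), self.A_minus * np.outer(s, s))

    def tilde_split(self):
        s = 1.0 / np.sqrt(self.metric)
        ss = np.outer(s, s)
        return (self.A0_plus * ss, self.A0_minus * ss,
                self.A1_plus * ss, self.A1_minus * ss)


def _double_commutator_tensor(h: np.ndarray, eri: np.ndarray,
                              gamma: np.ndarray, d: np.ndarray) -> np.ndarray:
    """T[p,q,r,s] = <[E_qp, [H, E_rs]]> from spin-free RDMs.

    Derivation sketch: [H, E_rs] = sum_a h_ar E_as - h_sa E_ra
        + sum_tuv (tu|vr) e_tuvs - (tu|sv) e_turv,
    then a second commutator with E_qp is taken and contracted with
    gamma_pq = <E_pq> and d_pqrs = <e_pqrs> (chemists' pairing).
    """
    n = h.shape[0]
    I = np.eye(n)
    gh = gamma @ h
    T = np.einsum("pr,qs->pqrs", h, gamma)
    T -= np.einsum("qs,pr->pqrs", I, gh)
    T -= np.einsum("pr,sq->pqrs", I, h @ gamma)
    T += np.einsum("sq,rp->pqrs", h, gamma)
    opt = True
    T += np.einsum("puvr,quvs->pqrs", eri, d, optimize=opt)
    T += np.einsum("tupr,tuqs->pqrs", eri, d, optimize=opt)
    T -= np.einsum("tqvr,tpvs->pqrs", eri, d, optimize=opt)
    m1 = np.einsum("tuvr,tuvp->rp", eri, d, optimize=opt)
    T -= np.einsum("qs,rp->pqrs", I, m1)
    T -= np.einsum("pusv,qurv->pqrs", eri, d, optimize=opt)
    m2 = np.einsum("tusv,tuqv->sq", eri, d, optimize=opt)
    T -= np.einsum("pr,sq->pqrs", I, m2)
    T += np.einsum("tqsv,tprv->pqrs", eri, d, optimize=opt)
    T += np.einsum("tusq,turp->pqrs", eri, d, optimize=opt)
    return T


def build_hessians(state: MonomerState, eri_no: np.ndarray,
                   pairs: PairIndexMap, symmetry_tol: float = 1e-6) -> ERPAHessians:
    """ERPA Hessian matrices A± over the pair index of one monomer.

    ``eri_no`` is the full (pq|rs) tensor in the monomer's NO basis.  The
    matrices are symmetrized (exact for an eigenstate; for a CASCI state the
    asymmetry is of the order of the active-space truncation and is folded in
    symmetrically).
    """
    gamma, d = full_space_rdms(state)
    if abs(np.trace(gamma) - state.n_electrons) > 1e-8:
        raise ValueError("1-RDM trace inconsistent with electron count")
    h_core = state.metadata.get("hcore_no")
    if h_core is None:
        raise ValueError("state.metadata['hcore_no'] (NO-basis core Hamiltonian)"
                         " is required to build Hessians")
    T = _double_commutator_tensor(h_core, eri_no, gamma, d)
    idx = np.array(pairs.pairs)
    P, Q = idx[:, 0], idx[:, 1]
    # Hessians of the symmetric (E_pq + E_qp) and antisymmetric (E_pq - E_qp)
    # operator combinations: for a single determinant these are exactly the
    # singlet RPA/TDHF stability matrices 2(A+B) and 2(A-B).
    Tpqrs = T[P[:, None], Q[:, None], P[None, :], Q[None, :]]
    Tpqsr = T[P[:, None], Q[:, None], Q[None, :], P[None, :]]
    Tqprs = T[Q[:, None], P[:, None], P[None, :], Q[None, :]]
    Tqpsr = T[Q[:, None], P[:, None], Q[None, :], P[None, :]]
    Aplus = 0.5 * (Tpqrs + Tpqsr + Tqprs + Tqpsr)
    Aminus = 0.5 * (Tpqrs - Tpqsr - Tqprs + Tqpsr)
    Aplus = 0.5 * (Aplus + Aplus.T)
    Aminus = 0.5 * (Aminus + Aminus.T)
    hess = ERPAHessians(Aplus, Aminus, pairs.metric.copy(), pairs)
    split_alpha(hess)
    return hess


def split_alpha(h: ERPAHessians) -> tuple:
    """Exact split A(alpha) = A0 + alpha A1 with block-diagonal A0.

    A0 is the restriction of the full Hessian to the declared block layout
    (the group-product-function zeroth order); A1 is the complement, so the
    alpha = 1 sum reproduces the input to machine precision.
    """
    mask = np.zeros_like(h.A_plus, dtype=bool)
    for b in h.pairs.blocks:
        mask[np.ix_(b, b)] = True
    h.A0_plus = np.where(mask, h.A_plus, 0.0)
    h.A0_minus = np.where(mask, h.A_minus, 0.0)
    h.A1_plus = h.A_plus - h.A0_plus
    h.A1_minus = h.A_minus - h.A0_minus
    return (h.A0_plus, h.A0_minus), (h.A1_plus, h.A1_minus)


# ---------------------------------------------------------------------------
# Eigensolution and the sum-over-states dispersion oracle
# ---------------------------------------------------------------------------

@dataclass
class EigenSolution:
    omegas: np.ndarray       # retained transition energies (hartree), > 0
    Y: np.ndarray            # reduced transition amplitudes, pairs x n_roots:
                             # d_nu(pq) = w_pq Y[:, nu], w = sqrt(n_p)+sqrt(n_q)
    n_discarded_negative: int
    spurious: list = field(default_factory=list)
                             # (lambda, v_tilde, v^T A-~ v) of discarded real
                             # modes, for deflating them from the response
    metadata: dict = field(default_factory=dict)


def solve_erpa(h: ERPAHessians, occupations: np.ndarray,
               imag_tol: float = 1e-8) -> EigenSolution:
    """Solve the ERPA eigenproblem; discard non-positive (spurious) roots.

    Roots with omega^2 <= 0 (or complex / non-normalizable within the
    symplectic metric) are counted in ``n_discarded_negative`` and excluded,
    mirroring the practice of removing negative ERPA transitions from the
    dispersion sum.
    """
    if not np.all(np.isfinite(h.A_plus)) or not np.all(np.isfinite(h.A_minus)):
        raise ValueError("non-finite Hessian")
    Ap, Am = h.tilde()
    # right eigenvectors of A+ A- are the (tilde) transition-density carriers
    K = Ap @ Am
    lam, V = eig(K)
    keep, spurious = [], []
    discard = 0
    for i in range(len(lam)):
        li = lam[i]
        g = V[:, i].real
        if abs(li.imag) > imag_tol * max(1.0, abs(li)):
            discard += 1
            continue
        norm = g @ Am @ g
        if li.real <= imag_tol or norm <= 0:
            discard += 1
            spurious.append((li.real, g, norm))
            continue
        keep.append((np.sqrt(li.real), g, norm))
    keep.sort(key=lambda t: t[0])
    if not keep:
        raise ValueError("ERPA produced no positive excitations")
    omegas = np.array([k[0] for k in keep])
    s = np.sqrt(h.metric)
    w = pair_scale_factors(h.pairs, occupations)
    Y = np.zeros((h.pairs.dim, len(keep)))
    for j, (om, g, norm) in enumerate(keep):
        gt = g * np.sqrt(om / norm)      # F^T N G = 1 normalization
        Y[:, j] = s * gt / w             # d_nu / w
    return EigenSolution(omegas, Y, discard, spurious,
                         {"normalization": "F^T N G = 1 (symplectic)",
                          "metric": "N_pq = 2(n_q - n_p)"})


def dispersion_sum_over_states(sol_a: EigenSolution, sol_b: EigenSolution,
                               g_cross: np.ndarray) -> float:
    """Second-order dispersion energy from the two monomer ERPA spectra.

    E = - sum_{nu, mu} |sum_{pq, rs} g_pqrs Y^nu_pq Y^mu_rs|^2
                       / (omega_nu + omega_mu)

    ``g_cross`` couples A-pairs to B-pairs: g[(pq), (rs)] =
    (sqrt n_p + sqrt n_q)(sqrt n_r + sqrt n_s) <pr|qs> over the monomers'
    NO bases.  Scales as the sixth power of system size; this is the oracle
    the reduced-scaling path is validated against.
    """
    if sol_a.omegas.size == 0 or sol_b.omegas.size == 0:
        raise ValueError("empty excitation spectrum")
    T = sol_a.Y.T @ g_cross @ sol_b.Y
    denom = sol_a.omegas[:, None] + sol_b.omegas[None, :]
    return float(-np.sum(T * T / denom))
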