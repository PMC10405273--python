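"""Second-order dispersion (and static induction) from projected responses.

The coupled dispersion energy in the Cholesky representation is

    E_disp = -(2/pi) int_0^inf d omega  Tr[ W^A(omega) W^B(omega) ],
    W^X(omega) = D_X^T C_X(omega) D_X        (N_Chol x N_Chol)

evaluated on an imaginary-frequency quadrature.  Internally the monomer
response is handled in the metric-orthonormal pair basis: with the dressing
D~_pq,L = sqrt(N_pq) / w_pq * D_pq,L (N the ERPA metric, w the occupation
scale factors), W^X = D~^T M(omega) D~ where M is the tilde-space response
kernel of :mod:`mrdisp.response`.  The projected kernel M D~ comes either
from the direct linear solve (m^6-ish dense reference) or from the
alpha-recursion truncated at order n (the m^5 path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .erpa import ERPAHessians, pair_scale_factors, solve_erpa
from .response import (FrequencyGrid, ProjectedResponse, RecursionState,
                       make_frequency_grid, response_direct,
                       recursive_projected_response)

__all__ = ["DispersionResult", "MonomerResponseInput", "dispersion_energy",
           "convergence_scan", "induction_static", "KCAL_PER_HARTREE"]

KCAL_PER_HARTREE = 627.5095


@dataclass
class MonomerResponseInput:
    """Bundle of one monomer's ERPA Hessians and projected Cholesky factors.

    ``deflate`` optionally carries spurious (negative/zero) ERPA modes as
    (lambda, v_tilde, v^T A-~ v) triples; their exact rank-one contribution
    is removed from the projected response at every frequency so that the
    response route and the (filtered) sum-over-states route describe the
    same positive-excitation spectrum.
    """

    hessians: ERPAHessians
    occupations: np.ndarray
    D: np.ndarray                  # spec-level factors, pair x N_Chol
    deflate: list = field(default_factory=list)

    def dressed(self) -> np.ndarray:
        w = pair_scale_factors(self.hessians.pairs, self.occupations)
        return (np.sqrt(self.hessians.metric) / w)[:, None] * self.D


@dataclass
class DispersionResult:
    e_coupled: float               # hartree
    e_uncoupled: float             # hartree
    per_order: np.ndarray          # cumulative energy at orders 0..n
    n_chol: int
    grid: FrequencyGrid
    order: int | None              # truncation order (None = direct solve)
    diverging: bool = False
    discarded_negative_roots: dict = field(default_factory=dict)
    pair_energies: dict = field(default_factory=dict)  # per-monomer e_pq shares

    @property
    def e_coupled_kcal(self) -> float:
        return self.e_coupled * KCAL_PER_HARTREE


def _monomer_Z(mono: MonomerResponseInput, omega: float,
               order: int | None):
    """Projected response Z = M(omega) D~; list of cumulative orders."""
    Ap, Am = mono.hessians.tilde()
    Dt = mono.dressed()
    if order is None:
        M = response_direct(Ap, Am, omega)
        return [_deflated(M @ Dt, mono, omega, Dt)], False
    A0p, A0m, A1p, A1m = mono.hessians.tilde_split()
    pr = recursive_projected_response(A0p, A0m, A1p, A1m,
                                      mono.hessians.block_layout, Dt,
                                      omega, order)
    cum = [_deflated(z, mono, omega, Dt) for z in np.cumsum(pr.increments,
                                                            axis=0)]
    return cum, pr.diverging


def _deflated(Z: np.ndarray, mono: MonomerResponseInput, omega: float,
              Dt: np.ndarray) -> np.ndarray:
    for lam, v, norm in mono.deflate:
        Z = Z - (lam / ((lam + omega * omega) * norm)) * np.outer(v, v @ Dt)
    return Z


def dispersion_energy(mono_a: MonomerResponseInput,
                      mono_b: MonomerResponseInput,
                      grid: FrequencyGrid | None = None,
                      order: int | None = 8,
                      pair_contributions: bool = False) -> DispersionResult:
    """E_disp^(2) from the frequency integral of monomer response kernels.

    ``order=None`` uses the direct (fully coupled) solve at every node;
    integer ``order`` truncates the alpha-recursion at that order.  The
    order-0 term is the uncoupled approximation and is always reported.
    """
    if grid is None:
        grid = make_frequency_grid(8)
    if mono_a.D.shape[1] != mono_b.D.shape[1]:
        raise ValueError("monomers carry different Cholesky dimensions")
    n_orders = 1 if order is None else order + 1
    acc = np.zeros(n_orders)
    e_unc = 0.0
    diverging = False
    pair_a = np.zeros(mono_a.hessians.pairs.dim)
    pair_b = np.zeros(mono_b.hessians.pairs.dim)
    Dta = mono_a.dressed()
    Dtb = mono_b.dressed()
    for wj, om in zip(grid.weights, grid.nodes):
        Za, diva = _monomer_Z(mono_a, om, order)
        Zb, divb = _monomer_Z(mono_b, om, order)
        diverging = diverging or diva or divb
        Wa = [Dta.T @ z for z in Za]
        Wb = [Dtb.T @ z for z in Zb]
        pref = -(2.0 / np.pi) * wj
        for k in range(n_orders):
            acc[k] += pref * np.sum(Wa[min(k, len(Wa) - 1)]
                                    * Wb[min(k, len(Wb) - 1)])
        if order is not None:
            e_unc += pref * np.sum(Wa[0] * Wb[0])
        else:
            Za0, _ = _monomer_Z(mono_a, om, 0)
            Zb0, _ = _monomer_Z(mono_b, om, 0)
            e_unc += pref * np.sum((Dta.T @ Za0[0]) * (Dtb.T @ Zb0[0]))
        if pair_contributions:
            Wa_f, Wb_f = Wa[-1], Wb[-1]
            Za_f, Zb_f = Za[-1], Zb[-1]
            pair_a += pref * np.einsum("pL,LK,pK->p", Dta, Wb_f, Za_f,
                                       optimize=True)
            pair_b += pref * np.einsum("pL,LK,pK->p", Dtb, Wa_f, Zb_f,
                                       optimize=True)
    res = DispersionResult(
        e_coupled=float(acc[-1]),
        e_uncoupled=float(e_unc),
        per_order=acc,
        n_chol=mono_a.D.shape[1],
        grid=grid,
        order=order,
        diverging=diverging)
    if pair_contributions:
        res.pair_energies = {"A": pair_a, "B": pair_b}
    return res


def convergence_scan(mono_a: MonomerResponseInput,
                     mono_b: MonomerResponseInput,
                     n_max: int = 10,
                     grid: FrequencyGrid | None = None,
                     tol: float = 1e-6) -> dict:
    """Per-order energies against the direct coupled result.

    Reports cumulative E(n), absolute and percentage deviations from the
    direct solve, and the first order meeting ``tol`` (default 1 uE_h).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if grid is None:
        grid = make_frequency_grid(8)
    direct = dispersion_energy(mono_a, mono_b, grid, order=None)
    trunc = dispersion_energy(mono_a, mono_b, grid, order=n_max)
    per_order = trunc.per_order
    abs_err = np.abs(per_order - direct.e_coupled)
    pct_err = 100.0 * abs_err / abs(direct.e_coupled)
    hit = np.nonzero(abs_err < tol)[0]
    return {
        "e_direct": direct.e_coupled,
        "per_order": per_order,
        "abs_error": abs_err,
        "pct_error": pct_err,
        "order_converged": int(hit[0]) if hit.size else None,
        "diverging": trunc.diverging,
    }


def write_node_diagnostics(path, mono_a: MonomerResponseInput,
                           mono_b: MonomerResponseInput,
                           grid: FrequencyGrid, n_max: int = 8) -> None:
    """Per-node / per-order CSV diagnostics of the alpha-expansion.

    Columns: omega, order, increment norm of monomer A's projected response,
    and the partial (cumulative) energy contribution of that node.
    """
    import csv

    Dta, Dtb = mono_a.dressed(), mono_b.dressed()
    rows = []
    for wj, om in zip(grid.weights, grid.nodes):
        Za, _ = _monomer_Z(mono_a, om, n_max)
        Zb, _ = _monomer_Z(mono_b, om, n_max)
        incs = [Za[0]] + [Za[k] - Za[k - 1] for k in range(1, len(Za))]
        for k in range(len(Za)):
            e_node = -(2.0 / np.pi) * wj * np.sum(
                (Dta.T @ Za[min(k, len(Za) - 1)])
                * (Dtb.T @ Zb[min(k, len(Zb) - 1)]))
            rows.append((om, k, np.linalg.norm(incs[min(k, len(incs) - 1)]),
                         e_node))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["omega", "order", "increment_norm_a", "partial_energy"])
        w.writerows(rows)


def induction_static(potential_pair: np.ndarray,
                     hessians: ERPAHessians,
                     min_eig_tol: float = 1e-10) -> float:
    """Second-order induction of one monomer in a frozen partner potential.

    E_ind(X <- partner) = - v^T C_X(0) v, with v the partner's electrostatic
    potential over X's excitation pairs (p > q elements of the NO-basis
    potential matrix) and C_X(0) the static pair-space response.  The total
    induction is the sum over both directions, which the caller assembles.
    """
    v = np.asarray(potential_pair, dtype=float)
    if v.shape[0] != hessians.pairs.dim:
        raise ValueError("potential vector does not match the pair space")
    Ap, Am = hessians.tilde()
    K = Am @ Ap
    ev = np.linalg.eigvals(K)
    if np.min(ev.real) < min_eig_tol:
        raise np.linalg.LinAlgError(
            f"near-singular static response: smallest eigenvalue of A-A+ is "
            f"{np.min(ev.real):.3e}")
    M0 = response_direct(Ap, Am, 0.0)
    s = np.sqrt(hessians.metric)
    vt = s * v
    return float(-(vt @ M0 @ vt))
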