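"""End-to-end orchestration: geometries -> monomer states -> dispersion.

Ties the backend, Cholesky, ERPA and response layers together for a dimer
calculation in the dimer-centered basis.  The heavy objects (AO integrals,
NO-basis transforms, Hessians) are built once per dimer and reused across
the direct, truncated and sum-over-states routes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import integrals as ig
from .backend import (ActiveSpaceSpec, CoulombAccessor, Geometry,
                      MonomerState, electrostatic_potential_matrix,
                      prepare_monomer_state)
from .cholesky import CholeskyFactor, pivoted_cholesky, transform_and_scale
from .dispersion import (DispersionResult, MonomerResponseInput,
                         dispersion_energy, induction_static)
from .erpa import (ERPAHessians, PairIndexMap, build_hessians,
                   build_pair_index, dispersion_sum_over_states,
                   pair_scale_factors, solve_erpa)
from .response import FrequencyGrid, make_frequency_grid

__all__ = ["DimerWork", "setup_dimer", "cross_coupling", "dispersion_eq1",
           "induction_both_ways"]


@dataclass
class MonomerWork:
    state: MonomerState
    pairs: PairIndexMap
    hessians: ERPAHessians
    eri_no: np.ndarray
    D: np.ndarray

    def response_input(self, deflate_spurious: bool = True
                       ) -> MonomerResponseInput:
        deflate = []
        if deflate_spurious:
            sol = solve_erpa(self.hessians, self.state.occupations)
            deflate = sol.spurious
        return MonomerResponseInput(self.hessians, self.state.occupations,
                                    self.D, deflate)


@dataclass
class DimerWork:
    geometry_a: Geometry
    geometry_b: Geometry
    basis: ig.BasisSet
    basis_label: str
    eri_ao: np.ndarray
    cholesky: CholeskyFactor
    A: MonomerWork
    B: MonomerWork


def _monomer_work(state: MonomerState, eri_ao: np.ndarray,
                  factor: CholeskyFactor) -> MonomerWork:
    C = state.no_coefficients
    eri_no = np.einsum("pqrs,pi,qj,rk,sl->ijkl", eri_ao, C, C, C, C,
                       optimize=True)
    pairs = build_pair_index(state.partition, state.occupations)
    hess = build_hessians(state, eri_no, pairs)
    D = transform_and_scale(factor, state, pairs)
    return MonomerWork(state, pairs, hess, eri_no, D)


def setup_dimer(geom_a: Geometry, geom_b: Geometry, basis_label: str,
                active_a: ActiveSpaceSpec, active_b: ActiveSpaceSpec,
                cholesky_threshold: float = 1e-2) -> DimerWork:
    """Prepare both monomers in the dimer-centered basis plus shared factors."""
    # one shared AO ordering (A atoms first) for both monomer calculations
    ga = geom_a.with_ghosts(geom_b)
    gb = Geometry(geom_a.atoms + geom_b.atoms,
                  [True] * len(geom_a.atoms) + list(geom_b.ghost_flags))
    state_a = prepare_monomer_state(ga, basis_label, active_a, label="A")
    state_b = prepare_monomer_state(gb, basis_label, active_b, label="B")
    basis = ig.build_basis(ga.atoms_bohr(), basis_label)
    eri_ao = ig.eri_tensor(basis)
    accessor = CoulombAccessor(dense=eri_ao)
    factor = pivoted_cholesky(accessor, cholesky_threshold)
    return DimerWork(geom_a, geom_b, basis, basis_label, eri_ao, factor,
                     _monomer_work(state_a, eri_ao, factor),
                     _monomer_work(state_b, eri_ao, factor))


def cross_coupling(work: DimerWork) -> np.ndarray:
    """Dense occupation-scaled coupling g[(pq) in A, (rs) in B].

    g_pqrs = (sqrt n_p + sqrt n_q)(sqrt n_r + sqrt n_s) <pr|qs> with (pq)
    over A's NO pairs and (rs) over B's.  Used by the sum-over-states route;
    the Cholesky route never forms it.
    """
    Ca = work.A.state.no_coefficients
    Cb = work.B.state.no_coefficients
    eri_cross = np.einsum("mnls,mp,nq,lr,st->pqrt", work.eri_ao,
                          Ca, Ca, Cb, Cb, optimize=True)
    ia = np.array(work.A.pairs.pairs)
    ib = np.array(work.B.pairs.pairs)
    g = eri_cross[ia[:, 0][:, None], ia[:, 1][:, None],
                  ib[:, 0][None, :], ib[:, 1][None, :]]
    wa = pair_scale_factors(work.A.pairs, work.A.state.occupations)
    wb = pair_scale_factors(work.B.pairs, work.B.state.occupations)
    return wa[:, None] * g * wb[None, :]


def dispersion_eq1(work: DimerWork):
    """Sum-over-states dispersion (the sixth-power-scaling reference route)."""
    sol_a = solve_erpa(work.A.hessians, work.A.state.occupations)
    sol_b = solve_erpa(work.B.hessians, work.B.state.occupations)
    g = cross_coupling(work)
    e = dispersion_sum_over_states(sol_a, sol_b, g)
    return e, sol_a, sol_b


def induction_both_ways(work: DimerWork) -> dict:
    """Static-response second-order induction, both directions, in hartree."""
    out = {}
    for lbl, mono, other, geom_other in (
            ("A<-B", work.A, work.B, work.geometry_b),
            ("B<-A", work.B, work.A, work.geometry_a)):
        v_no = electrostatic_potential_matrix(other.state, mono.state,
                                              geom_other, work.basis,
                                              work.eri_ao)
        v_pair = np.array([v_no[p, q] for p, q in mono.pairs.pairs])
        out[lbl] = induction_static(v_pair, mono.hessians)
    out["total"] = out["A<-B"] + out["B<-A"]
    return out
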