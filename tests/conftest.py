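import numpy as np
import pytest

from mrdisp import integrals as ig
from mrdisp.backend import ActiveSpaceSpec, Geometry, prepare_monomer_state
from mrdisp.erpa import build_hessians, build_pair_index
from mrdisp.fixtures import fixture_suite
from mrdisp.pipeline import setup_dimer


@pytest.fixture(scope="session")
def h2_monomer():
    """H2 monomer at the equilibrium bond length, split-valence basis, HF."""
    geom = Geometry([("H", [0.0, 0.0, 0.0]), ("H", [0.0, 0.0, 0.7414])])
    state = prepare_monomer_state(geom, "dz", ActiveSpaceSpec(0, 0))
    basis = ig.build_basis(geom.atoms_bohr(), "dz")
    eri_ao = ig.eri_tensor(basis)
    C = state.no_coefficients
    eri_no = np.einsum("pqrs,pi,qj,rk,sl->ijkl", eri_ao, C, C, C, C,
                       optimize=True)
    pairs = build_pair_index(state.partition, state.occupations)
    hess = build_hessians(state, eri_no, pairs)
    return {"geom": geom, "state": state, "basis": basis, "eri_ao": eri_ao,
            "eri_no": eri_no, "pairs": pairs, "hess": hess}


@pytest.fixture(scope="session")
def h2_cas_monomer():
    geom = Geometry([("H", [0.0, 0.0, 0.0]), ("H", [0.0, 0.0, 0.7414])])
    state = prepare_monomer_state(geom, "dz", ActiveSpaceSpec(2, 2))
    basis = ig.build_basis(geom.atoms_bohr(), "dz")
    eri_ao = ig.eri_tensor(basis)
    C = state.no_coefficients
    eri_no = np.einsum("pqrs,pi,qj,rk,sl->ijkl", eri_ao, C, C, C, C,
                       optimize=True)
    pairs = build_pair_index(state.partition, state.occupations)
    hess = build_hessians(state, eri_no, pairs)
    return {"geom": geom, "state": state, "basis": basis, "eri_ao": eri_ao,
            "eri_no": eri_no, "pairs": pairs, "hess": hess}


@pytest.fixture(scope="session")
def h2_dimer_work():
    """H2-H2 dimer with CAS(2,2) monomers, tight Cholesky threshold."""
    fx = fixture_suite(["h2-h2"])[0]
    return setup_dimer(fx.geom_a, fx.geom_b, fx.basis_label, fx.active_a,
                       fx.active_b, cholesky_threshold=1e-8)


@pytest.fixture(scope="session")
def suite_works():
    """Every shipped fixture dimer, fully prepared (tight threshold).

    Session-scoped: the water CASSCF dominates the cost, so all acceptance
    checks share one preparation.
    """
    out = {}
    for fx in fixture_suite():
        out[fx.name] = (fx, setup_dimer(fx.geom_a, fx.geom_b, fx.basis_label,
                                        fx.active_a, fx.active_b,
                                        cholesky_threshold=1e-8))
    return out
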