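"""Backend adapter: monomer electronic structure behind a neutral contract.

This module produces the quantities the dispersion machinery consumes —
natural orbitals, occupation numbers, spin-free 1-/2-RDMs, Coulomb-integral
access and counterpoise-corrected supermolecular energies — using the
built-in RHF/CASSCF solver.  Everything downstream (Cholesky factors, ERPA,
response recursion) only ever sees the `MonomerState` contract and a Coulomb
accessor, so it can equally run from an interchange file produced elsewhere.

Monomer states for interaction-energy work are computed in the dimer-centered
basis: the partner's atoms are included as ghost centers carrying basis
functions but neither charge nor electrons, consistent with counterpoise-
corrected supermolecular energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import integrals as ig
from .scf import run_casscf, run_rhf

__all__ = [
    "Geometry", "ActiveSpaceSpec", "OrbitalPartition", "MonomerState",
    "CoulombAccessor", "prepare_monomer_state", "coulomb_diagonal_and_columns",
    "supermolecular_energy", "read_xyz", "write_interchange",
    "read_interchange", "full_space_rdms", "electrostatic_potential_matrix",
]

GHOST_PREFIX = "X-"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Geometry:
    """Atoms in Å; ghost atoms carry basis functions but no nucleus/electrons."""

    atoms: list[tuple[str, np.ndarray]]
    ghost_flags: list[bool] = None
    fragments: list[int] | None = None  # optional 0/1 monomer labels

    def __post_init__(self):
        if self.ghost_flags is None:
            self.ghost_flags = [False] * len(self.atoms)
        self.atoms = [(el, np.asarray(x, dtype=float)) for el, x in self.atoms]
        if len(self.ghost_flags) != len(self.atoms):
            raise ValueError("ghost_flags length mismatch")
        if all(self.ghost_flags):
            raise ValueError("geometry must contain at least one real atom")
        for _, x in self.atoms:
            if not np.all(np.isfinite(x)):
                raise ValueError("non-finite coordinates")

    def atoms_bohr(self):
        return [(el, x * ig.ANGSTROM_TO_BOHR) for el, x in self.atoms]

    def charges(self):
        """(Z, xyz_bohr) for real atoms only."""
        return [(float(ig.ATOMIC_NUMBERS[el]), x * ig.ANGSTROM_TO_BOHR)
                for (el, x), g in zip(self.atoms, self.ghost_flags) if not g]

    @property
    def n_electrons(self) -> int:
        return int(sum(z for z, _ in self.charges()))

    def with_ghosts(self, other: "Geometry") -> "Geometry":
        """This geometry plus the other's atoms as ghost centers."""
        atoms = self.atoms + other.atoms
        ghosts = list(self.ghost_flags) + [True] * len(other.atoms)
        return Geometry(atoms, ghosts)


@dataclass
class ActiveSpaceSpec:
    n_active_electrons: int
    n_active_orbitals: int
    n_states: int = 1
    target_state: int = 0
    weights: list[float] | None = None

    def __post_init__(self):
        if not 0 <= self.n_active_electrons <= 2 * self.n_active_orbitals:
            raise ValueError("electron count incompatible with active orbitals")
        if self.target_state >= self.n_states:
            raise ValueError("target state outside the averaged set")
        if self.weights is None:
            self.weights = [1.0 / self.n_states] * self.n_states
        w = np.asarray(self.weights, dtype=float)
        if len(w) != self.n_states or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("weights must be nonnegative and sum to one")


@dataclass
class OrbitalPartition:
    """Inactive (s1), active (s2) and virtual (s3) orbital index sets."""

    s1: list[int]
    s2: list[int]
    s3: list[int]

    def __post_init__(self):
        all_idx = self.s1 + self.s2 + self.s3
        if sorted(all_idx) != list(range(len(all_idx))):
            raise ValueError("partition sets must be disjoint and contiguous")
        if self.s1 and self.s2 and max(self.s1) > min(self.s2):
            raise ValueError("inactive orbitals must precede active ones")
        if (self.s2 and self.s3 and max(self.s2) > min(self.s3)) or \
           (self.s1 and self.s3 and not self.s2 and max(self.s1) > min(self.s3)):
            raise ValueError("active orbitals must precede virtual ones")

    @property
    def n_orb(self):
        return len(self.s1) + len(self.s2) + len(self.s3)


@dataclass
class MonomerState:
    """One monomer in one electronic state, in its natural-orbital basis."""

    label: str                      # "A" or "B"
    no_coefficients: np.ndarray     # AO -> NO
    occupations: np.ndarray         # n_p in [0, 1]; 2 sum n_p = N
    partition: OrbitalPartition
    rdm1: np.ndarray                # NO basis, trace N/2 (equals diag(occupations))
    rdm2_active: np.ndarray         # spin-free 2-RDM over active NOs (chemists')
    n_electrons: int
    electronic_state: str = "GS"    # "GS" or "ES"
    energy: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.occupations
        if abs(2.0 * n.sum() - self.n_electrons) > 1e-10:
            raise ValueError("occupation sum violates 2*sum(n) = N")
        for i in self.partition.s1:
            if abs(n[i] - 1.0) > 1e-8:
                raise ValueError("inactive orbital with occupation != 1")
        for i in self.partition.s3:
            if abs(n[i]) > 1e-8:
                raise ValueError("virtual orbital with occupation != 0")


# ---------------------------------------------------------------------------
# Monomer preparation
# ---------------------------------------------------------------------------

def _integrals_for(geometry: Geometry, basis_label: str):
    basis = ig.build_basis(geometry.atoms_bohr(), basis_label)
    charges = geometry.charges()
    h = ig.kinetic(basis) + ig.nuclear_attraction(basis, charges)
    S = ig.overlap(basis)
    eri = ig.eri_tensor(basis)
    e_nuc = ig.nuclear_repulsion(charges)
    return basis, S, h, eri, e_nuc


def prepare_monomer_state(geometry: Geometry, basis_label: str,
                          active: ActiveSpaceSpec, label: str = "A",
                          electronic_state: str | None = None) -> MonomerState:
    """RHF (+ state-averaged CASSCF when an active space is requested).

    With ``n_active_orbitals = 0`` the state is the RHF determinant with
    occupations exactly 0/1 and an empty active set.  Otherwise a CASSCF
    (full CI in the active window, orbitals optimized) is performed and the
    requested root (``target_state``) defines the state; its one-density is
    diagonalized to natural orbitals and the inactive/virtual blocks are
    semicanonicalized.
    """
    n_el = geometry.n_electrons
    if n_el % 2:
        raise ValueError("only spin-compensated monomers are supported")
    basis, S, h, eri, e_nuc = _integrals_for(geometry, basis_label)
    rhf = run_rhf(h, S, eri, n_el, e_nuc)
    if not rhf.converged:
        raise RuntimeError(
            f"SCF failed to converge for monomer {label} "
            f"(basis {basis_label}, {n_el} electrons)")
    n_orb = rhf.mo_coeff.shape[1]
    if electronic_state is None:
        electronic_state = "ES" if active.target_state > 0 else "GS"

    if active.n_active_orbitals == 0:
        if active.target_state != 0:
            raise ValueError("excited states require an active space")
        occ = np.zeros(n_orb)
        occ[: rhf.n_occ] = 1.0
        part = OrbitalPartition(list(range(rhf.n_occ)), [],
                                list(range(rhf.n_occ, n_orb)))
        C = rhf.mo_coeff
        return MonomerState(label, C, occ, part,
                            np.diag(occ), np.zeros((0, 0, 0, 0)), n_el,
                            electronic_state, rhf.energy,
                            {"method": "RHF", "basis": basis_label,
                             "hcore_no": C.T @ h @ C})

    if active.n_active_orbitals + (n_el - active.n_active_electrons) // 2 > n_orb:
        raise ValueError("active space does not fit the orbital count")
    cas = run_casscf(h, S, eri, n_el, e_nuc, active.n_active_electrons,
                     active.n_active_orbitals, weights=active.weights,
                     root=active.target_state, mo_guess=rhf.mo_coeff)
    if not cas.converged:
        raise RuntimeError(f"CASSCF orbital optimization did not converge "
                           f"for monomer {label}")
    n_inact = len(cas.inactive)
    M = active.n_active_orbitals
    # natural orbitals of the active block, ordered by decreasing occupation
    occ_act, U = np.linalg.eigh(cas.gamma_active)
    order = np.argsort(occ_act)[::-1]
    occ_act = occ_act[order] / 2.0
    U = U[:, order]
    C = cas.mo_coeff.copy()
    C[:, cas.active] = C[:, cas.active] @ U
    # rotate the active 2-RDM into the NO basis
    d2 = np.einsum("pqrs,pi,qj,rk,sl->ijkl", cas.rdm2_active, U, U, U, U,
                   optimize=True)
    occ = np.zeros(n_orb)
    occ[:n_inact] = 1.0
    occ[n_inact:n_inact + M] = np.clip(occ_act, 0.0, 1.0)
    part = OrbitalPartition(list(range(n_inact)),
                            list(range(n_inact, n_inact + M)),
                            list(range(n_inact + M, n_orb)))
    # semicanonicalize the inactive and virtual blocks (occupations there are
    # pinned at 1/0, so these rotations leave the state invariant while
    # diagonalizing the one-body part of the zeroth-order Hamiltonian)
    C = _semicanonicalize(C, h, eri, occ, part)
    return MonomerState(label, C, occ, part, np.diag(occ), d2, n_el,
                        electronic_state, cas.energy,
                        {"method": f"CASCI({active.n_active_electrons},{M})",
                         "basis": basis_label, "root": active.target_state,
                         "weights": list(active.weights),
                         "hcore_no": C.T @ h @ C})


def _semicanonicalize(C: np.ndarray, h_ao: np.ndarray, eri_ao: np.ndarray,
                      occ: np.ndarray, part: OrbitalPartition) -> np.ndarray:
    """Rotate inactive and virtual orbitals to diagonalize the generalized
    Fock matrix F = h + J[gamma] - K[gamma]/2 within those blocks."""
    dm_ao = C @ np.diag(2.0 * occ) @ C.T
    J = np.einsum("pqrs,rs->pq", eri_ao, dm_ao)
    K = np.einsum("prqs,rs->pq", eri_ao, dm_ao)
    F_ao = h_ao + J - 0.5 * K
    F = C.T @ F_ao @ C
    Cnew = C.copy()
    for block in (part.s1, part.s3):
        if len(block) > 1:
            ix = np.ix_(block, block)
            _, U = np.linalg.eigh(F[ix])
            Cnew[:, block] = Cnew[:, block] @ U
    return Cnew


def full_space_rdms(state: MonomerState):
    """Spin-free 1- and 2-RDM over the full NO space.

    gamma = diag(2 n_p).  The 2-RDM combines the active-space CI density with
    the closed-shell inactive contribution:

        d = d_active (embedded)
            + gamma_c x gamma + gamma x gamma_c - gamma_c x gamma_c   (Coulomb)
            - 1/2 [same with exchange index pairing]

    where gamma_c is the inactive part of gamma.  Elements with any virtual
    index vanish.
    """
    n = len(state.occupations)
    gamma = np.diag(2.0 * state.occupations)
    gc = np.zeros((n, n))
    for i in state.partition.s1:
        gc[i, i] = 2.0
    d = (np.einsum("pq,rs->pqrs", gc, gamma)
         + np.einsum("pq,rs->pqrs", gamma, gc)
         - np.einsum("pq,rs->pqrs", gc, gc))
    d -= 0.5 * (np.einsum("ps,rq->pqrs", gc, gamma)
                + np.einsum("ps,rq->pqrs", gamma, gc)
                - np.einsum("ps,rq->pqrs", gc, gc))
    act = state.partition.s2
    if act:
        d[np.ix_(act, act, act, act)] += state.rdm2_active
    return gamma, d


# ---------------------------------------------------------------------------
# Coulomb-integral access
# ---------------------------------------------------------------------------

class CoulombAccessor:
    """Diagonal and on-demand columns of the AO Coulomb matrix (pq|rs).

    The matrix is indexed by packed AO pairs p >= q; columns are produced
    without materializing the fourth-order tensor.
    """

    def __init__(self, basis: ig.BasisSet = None, dense: np.ndarray = None):
        if (basis is None) == (dense is None):
            raise ValueError("provide exactly one of basis / dense tensor")
        self._basis = basis
        self._dense = dense
        self.n_ao = basis.n_ao if basis is not None else dense.shape[0]
        self.pairs = [(p, q) for p in range(self.n_ao) for q in range(p + 1)]
        self.n_pairs = len(self.pairs)

    def diagonal(self) -> np.ndarray:
        if self._dense is not None:
            diag = np.einsum("pqpq->pq", self._dense)
        else:
            diag = ig.eri_diagonal(self._basis)
        if diag[np.diag_indices(self.n_ao)].min() < -1e-12:
            raise ValueError("negative Coulomb diagonal: input not PSD")
        return np.array([diag[p, q] for p, q in self.pairs])

    def column(self, k: int) -> np.ndarray:
        r, s = self.pairs[k]
        if self._dense is not None:
            block = self._dense[:, :, r, s]
        else:
            block = ig.eri_block(self._basis, r, s)
        return np.array([block[p, q] for p, q in self.pairs])


def coulomb_diagonal_and_columns(geometry: Geometry,
                                 basis_label: str) -> CoulombAccessor:
    basis = ig.build_basis(geometry.atoms_bohr(), basis_label)
    return CoulombAccessor(basis=basis)


def electrostatic_potential_matrix(source: MonomerState,
                                   target: MonomerState,
                                   geometry_source: Geometry,
                                   basis: ig.BasisSet,
                                   eri_ao: np.ndarray) -> np.ndarray:
    """Electrostatic potential of `source` in the NO basis of `target`.

    v_pq = sum_{rs in source} gamma_rs (pq|rs)  -  sum_I Z_I <p|1/|r-R_I||q>,
    both expressed over the shared (dimer-centered) AO basis.
    """
    dm_ao = source.no_coefficients @ np.diag(2.0 * source.occupations) \
        @ source.no_coefficients.T
    J = np.einsum("pqrs,rs->pq", eri_ao, dm_ao)
    Vn = ig.nuclear_attraction(basis, geometry_source.charges())
    v_ao = J + Vn
    C = target.no_coefficients
    return C.T @ v_ao @ C


# ---------------------------------------------------------------------------
# Supermolecular energies
# ---------------------------------------------------------------------------

def supermolecular_energy(dimer: Geometry, method: str = "hf",
                          active_a: ActiveSpaceSpec | None = None,
                          active_b: ActiveSpaceSpec | None = None,
                          active_dimer: ActiveSpaceSpec | None = None,
                          basis_label: str = "sto-3g",
                          target_state: int = 0) -> dict:
    """Counterpoise-corrected interaction energy.

    E_int = E(dimer) - E(A with ghost B) - E(B with ghost A), all three in the
    full dimer basis.  ``method`` is "hf" or "cas" (CASCI on RHF orbitals; the
    dimer active space defaults to the union of the monomer ones).
    """
    if dimer.fragments is None or set(dimer.fragments) != {0, 1}:
        raise ValueError("dimer.fragments must label atoms with 0 and 1")
    idx_a = [i for i, f in enumerate(dimer.fragments) if f == 0]
    idx_b = [i for i, f in enumerate(dimer.fragments) if f == 1]
    mono_a = Geometry([dimer.atoms[i] for i in idx_a],
                      [dimer.ghost_flags[i] for i in idx_a])
    mono_b = Geometry([dimer.atoms[i] for i in idx_b],
                      [dimer.ghost_flags[i] for i in idx_b])

    def total(geom: Geometry, active: ActiveSpaceSpec | None, state: int):
        basis, S, h, eri, e_nuc = _integrals_for(geom, basis_label)
        rhf = run_rhf(h, S, eri, geom.n_electrons, e_nuc)
        if not rhf.converged:
            raise RuntimeError("SCF did not converge in supermolecular run")
        if method.lower() == "hf" or active is None or active.n_active_orbitals == 0:
            return rhf.energy
        nst = max(active.n_states, state + 1)
        cas = run_casscf(h, S, eri, geom.n_electrons, e_nuc,
                         active.n_active_electrons, active.n_active_orbitals,
                         weights=[1.0 / nst] * nst, root=state,
                         mo_guess=rhf.mo_coeff)
        return cas.energy

    if method.lower() == "cas" and active_dimer is None and active_a is not None:
        nae = active_a.n_active_electrons + (active_b.n_active_electrons if active_b else 0)
        nao = active_a.n_active_orbitals + (active_b.n_active_orbitals if active_b else 0)
        active_dimer = ActiveSpaceSpec(nae, nao, n_states=target_state + 1,
                                       target_state=target_state)
    e_dimer = total(dimer, active_dimer, target_state)
    e_a = total(mono_a.with_ghosts(mono_b), active_a,
                target_state if (active_a and active_a.target_state) else 0)
    e_b = total(mono_b.with_ghosts(mono_a), active_b, 0)
    return {"e_int": e_dimer - e_a - e_b, "e_dimer": e_dimer,
            "e_monomer_a": e_a, "e_monomer_b": e_b}


# ---------------------------------------------------------------------------
# I/O: XYZ and the interchange container
# ---------------------------------------------------------------------------

def read_xyz(path, ghost_prefix: str = GHOST_PREFIX) -> Geometry:
    """Standard XYZ in Å; ghost atoms marked with a prefix (default "X-")."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    n = int(lines[0].split()[0])
    body = lines[2:2 + n] if len(lines) >= n + 2 else lines[1:1 + n]
    atoms, ghosts = [], []
    for ln in body:
        parts = ln.split()
        el = parts[0]
        ghost = el.startswith(ghost_prefix)
        if ghost:
            el = el[len(ghost_prefix):]
        atoms.append((el, np.array([float(x) for x in parts[1:4]])))
        ghosts.append(ghost)
    return Geometry(atoms, ghosts)


def write_interchange(path, states: dict[str, MonomerState],
                      nuclei: Geometry | None = None,
                      cholesky: dict | None = None) -> None:
    """Persist monomer states (and optionally Cholesky factors) to HDF5.

    Layout per monomer label X (group /monomer_X): /no_coeff, /occupations,
    /partition (sizes of s1/s2/s3), /rdm1, /rdm2_active plus scalar attrs.
    Top-level /nuclei holds element numbers, coordinates (Å) and ghost flags.
    """
    import h5py

    with h5py.File(path, "w") as f:
        for lbl, st in states.items():
            g = f.create_group(f"monomer_{lbl}")
            g.create_dataset("no_coeff", data=st.no_coefficients)
            g.create_dataset("occupations", data=st.occupations)
            g.create_dataset("partition", data=np.array(
                [len(st.partition.s1), len(st.partition.s2),
                 len(st.partition.s3)]))
            g.create_dataset("rdm1", data=st.rdm1)
            g.create_dataset("rdm2_active", data=st.rdm2_active)
            g.attrs["n_electrons"] = st.n_electrons
            g.attrs["electronic_state"] = st.electronic_state
            g.attrs["label"] = st.label
            if st.energy is not None:
                g.attrs["energy"] = st.energy
            if "hcore_no" in st.metadata:
                g.create_dataset("hcore_no", data=st.metadata["hcore_no"])
        if nuclei is not None:
            g = f.create_group("nuclei")
            g.create_dataset("z", data=np.array(
                [ig.ATOMIC_NUMBERS[el] for el, _ in nuclei.atoms]))
            g.create_dataset("xyz", data=np.array([x for _, x in nuclei.atoms]))
            g.create_dataset("ghost", data=np.array(nuclei.ghost_flags,
                                                    dtype=bool))
        if cholesky:
            g = f.create_group("cholesky")
            for k, v in cholesky.items():
                g.create_dataset(k, data=v)


def read_interchange(path):
    """Load monomer states (and Cholesky factors if present) from HDF5."""
    import h5py

    states, cholesky = {}, {}
    with h5py.File(path, "r") as f:
        for key in f:
            if key.startswith("monomer_"):
                g = f[key]
                n1, n2, n3 = (int(x) for x in g["partition"][...])
                part = OrbitalPartition(list(range(n1)),
                                        list(range(n1, n1 + n2)),
                                        list(range(n1 + n2, n1 + n2 + n3)))
                st = MonomerState(
                    label=str(g.attrs["label"]),
                    no_coefficients=g["no_coeff"][...],
                    occupations=g["occupations"][...],
                    partition=part,
                    rdm1=g["rdm1"][...],
                    rdm2_active=g["rdm2_active"][...],
                    n_electrons=int(g.attrs["n_electrons"]),
                    electronic_state=str(g.attrs["electronic_state"]),
                    energy=float(g.attrs["energy"]) if "energy" in g.attrs else None)
                if "hcore_no" in g:
                    st.metadata["hcore_no"] = g["hcore_no"][...]
                states[st.label] = st
        if "cholesky" in f:
            for k in f["cholesky"]:
                cholesky[k] = f["cholesky"][k][...]
    return states, cholesky
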