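"""Fixture dimers, synthetic response instances and brute-force oracles.

Everything here is test scaffolding that the production code paths are
checked against:

* ``fixture_suite`` loads small dimers (XYZ + YAML shipped with the package)
  whose full sum-over-states dispersion is affordable in seconds;
* ``generate_synthetic_instance`` builds seeded random block-structured
  response problems so the alpha-recursion can be exercised without any
  electronic structure at all;
* the oracle functions re-derive quantities (occupation-scaled integral
  tensors, RPA excitation energies, projected responses) with independent,
  deliberately naive algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .backend import ActiveSpaceSpec, Geometry, MonomerState, read_xyz

__all__ = ["FixtureDimer", "fixture_suite", "SyntheticERPAInstance",
           "generate_synthetic_instance", "oracle_g_tensor",
           "rpa_oracle_dense", "projected_response_oracle"]


@dataclass
class FixtureDimer:
    name: str
    geom_a: Geometry
    geom_b: Geometry
    basis_label: str
    active_a: ActiveSpaceSpec
    active_b: ActiveSpaceSpec
    tags: list[str] = field(default_factory=list)


def _active_from(d: dict) -> ActiveSpaceSpec:
    return ActiveSpaceSpec(
        n_active_electrons=d.get("active_electrons", 0),
        n_active_orbitals=d.get("active_orbitals", 0),
        n_states=d.get("n_states", max(1, d.get("target_state", 0) + 1)),
        target_state=d.get("target_state", 0))


def fixture_suite(names: list[str] | None = None) -> list[FixtureDimer]:
    """Load the shipped fixture dimers (optionally a named subset)."""
    root = resources.files("mrdisp") / "data" / "fixtures"
    out = []
    for entry in sorted(p.name for p in root.iterdir()
                        if p.name.endswith(".yaml")):
        spec = yaml.safe_load((root / entry).read_text())
        if names is not None and spec["name"] not in names:
            continue
        xyz_name = spec.get("geometry", entry.replace(".yaml", ".xyz"))
        import tempfile, os
        text = (root / xyz_name).read_text()
        with tempfile.NamedTemporaryFile("w", suffix=".xyz",
                                         delete=False) as fh:
            fh.write(text)
            tmp = fh.name
        try:
            geom = read_xyz(tmp)
        finally:
            os.unlink(tmp)
        frag = spec["fragments"]
        atoms_a = [geom.atoms[i] for i, f in enumerate(frag) if f == 0]
        atoms_b = [geom.atoms[i] for i, f in enumerate(frag) if f == 1]
        out.append(FixtureDimer(
            spec["name"], Geometry(atoms_a), Geometry(atoms_b),
            spec["basis"], _active_from(spec["monomer_a"]),
            _active_from(spec["monomer_b"]), spec.get("tags", [])))
    return out


# ---------------------------------------------------------------------------
# Synthetic response instances
# ---------------------------------------------------------------------------

@dataclass
class SyntheticERPAInstance:
    """Seeded random block-structured A± (tilde representation) plus D."""

    seed: int
    A0_plus: np.ndarray
    A0_minus: np.ndarray
    A1_plus: np.ndarray
    A1_minus: np.ndarray
    blocks: list[np.ndarray]
    D: np.ndarray
    coupling_strength: float

    @property
    def A_plus(self):
        return self.A0_plus + self.A1_plus

    @property
    def A_minus(self):
        return self.A0_minus + self.A1_minus

    @property
    def pair_dim(self):
        return self.A0_plus.shape[0]


def generate_synthetic_instance(seed: int, pair_dim: int, n_chol: int,
                                coupling_strength: float = 0.1,
                                block_size: int = 3) -> SyntheticERPAInstance:
    """Deterministic random instance with controllable off-block coupling.

    A0± are SPD and block-diagonal; A1± are symmetric with support only off
    the blocks, scaled so that ||A1|| ~ coupling_strength * ||A0||.  For the
    tested alpha range the sum stays positive definite when the coupling is
    moderate, so recursion-vs-direct comparisons are well posed.
    """
    if pair_dim < 1:
        raise ValueError("pair_dim must be >= 1")
    rng = np.random.default_rng(seed)
    edges = list(range(0, pair_dim, block_size)) + [pair_dim]
    blocks = [np.arange(a, b) for a, b in zip(edges[:-1], edges[1:])
              if b > a]
    mask = np.zeros((pair_dim, pair_dim), dtype=bool)
    for b in blocks:
        mask[np.ix_(b, b)] = True

    def spd():
        X = rng.normal(size=(pair_dim, pair_dim))
        M = X @ X.T / pair_dim + np.diag(1.0 + rng.random(pair_dim))
        return M

    def sym_offblock():
        X = rng.normal(size=(pair_dim, pair_dim))
        X = 0.5 * (X + X.T)
        X[mask] = 0.0
        return X

    A0p = np.where(mask, spd(), 0.0)
    A0m = np.where(mask, spd(), 0.0)
    scale = coupling_strength * min(np.abs(np.diag(A0p)).min(),
                                    np.abs(np.diag(A0m)).min())
    A1p = scale * sym_offblock()
    A1m = scale * sym_offblock()
    D = rng.normal(size=(pair_dim, n_chol))
    return SyntheticERPAInstance(seed, A0p, A0m, A1p, A1m, blocks, D,
                                 coupling_strength)


# ---------------------------------------------------------------------------
# Brute-force oracles (kept independent of the production kernels)
# ---------------------------------------------------------------------------

def oracle_g_tensor(state: MonomerState, eri_no: np.ndarray,
                    max_orbitals: int = 24) -> np.ndarray:
    """Dense occupation-scaled integral tensor, assembled element by element.

    g_pqrs = (sqrt n_p + sqrt n_q)(sqrt n_r + sqrt n_s) <pr|qs> over the full
    NO range of one monomer.  Quadruple loop on purpose: this is the oracle
    the Cholesky reconstruction is compared against.
    """
    n = len(state.occupations)
    if n > max_orbitals:
        raise ValueError("oracle_g_tensor is guarded to small systems")
    sq = np.sqrt(np.clip(state.occupations, 0.0, None))
    g = np.empty((n, n, n, n))
    for p in range(n):
        for q in range(n):
            for r in range(n):
                for s in range(n):
                    g[p, q, r, s] = ((sq[p] + sq[q]) * (sq[r] + sq[s])
                                     * eri_no[p, q, r, s])
    return g


def rpa_oracle_dense(eps: np.ndarray, eri_no: np.ndarray, occ: list[int],
                     virt: list[int]):
    """Textbook singlet RPA excitation energies from orbital energies and
    MO integrals (chemists' notation); independent of the ERPA code path.

    A_ia,jb = d_ij d_ab (eps_a - eps_i) + 2 (ia|jb) - (ij|ab)
    B_ia,jb = 2 (ia|jb) - (ib|ja);   omega from (A-B)(A+B) eigenvalues.
    """
    pairs = [(i, a) for i in occ for a in virt]
    n = len(pairs)
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    for I, (i, a) in enumerate(pairs):
        for J, (j, b) in enumerate(pairs):
            A[I, J] = 2.0 * eri_no[i, a, j, b] - eri_no[i, j, a, b]
            if i == j and a == b:
                A[I, J] += eps[a] - eps[i]
            B[I, J] = 2.0 * eri_no[i, a, j, b] - eri_no[i, b, j, a]
    w2 = np.linalg.eigvals((A - B) @ (A + B))
    return np.sort(np.sqrt(w2.real)), A, B


def projected_response_oracle(A_plus_t: np.ndarray, A_minus_t: np.ndarray,
                              D_t: np.ndarray, omega: float) -> np.ndarray:
    """Triple-loop contraction of the dense response with D (no BLAS path).

    Solves the response system densely, then contracts elementwise; used to
    check ``project_response`` and the recursion limit.
    """
    n = A_plus_t.shape[0]
    K = A_plus_t @ A_minus_t + omega * omega * np.eye(n)
    M = np.linalg.solve(K, A_plus_t)
    M = 0.5 * (M + M.T)
    out = np.zeros((n, D_t.shape[1]))
    for p in range(n):
        for L in range(D_t.shape[1]):
            acc = 0.0
            for q in range(n):
                acc += M[p, q] * D_t[q, L]
            out[p, L] = acc
    return out
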