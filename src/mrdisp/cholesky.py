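"""Pivoted Cholesky decomposition of the AO Coulomb matrix.

The two-electron Coulomb matrix over packed AO pairs (p >= q) is positive
semidefinite, so it admits an incomplete Cholesky factorization

    (pq|rs) ~ sum_L R_pq,L R_rs,L

terminated when the *summed* residual diagonal sum_{p>=q} [(pp|qq)_pair -
sum_L R_pq,L^2] drops below a threshold (default 1e-2; a tight 1e-8 mode
serves the oracle tests).  Transformation to each monomer's natural-orbital
basis and scaling by (sqrt n_p + sqrt n_q) yields the factors D of the
occupation-modified integrals g_pqrs = sum_L D_pq,L D_rs,L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backend import CoulombAccessor, MonomerState
from .erpa import PairIndexMap, pair_scale_factors

__all__ = ["CholeskyFactor", "pivoted_cholesky", "transform_and_scale"]


@dataclass
class CholeskyFactor:
    R: np.ndarray                   # packed AO-pair x N_Chol
    threshold: float
    ao_pairs: list[tuple[int, int]]  # packed (p, q), p >= q
    n_ao: int
    residual: float                 # summed residual diagonal at termination
    D: dict[str, np.ndarray] = field(default_factory=dict)  # per monomer label

    @property
    def n_chol(self) -> int:
        return self.R.shape[1]

    def unpacked(self) -> np.ndarray:
        """R as a full (n_ao, n_ao, N_Chol) symmetric array."""
        out = np.zeros((self.n_ao, self.n_ao, self.n_chol))
        for k, (p, q) in enumerate(self.ao_pairs):
            out[p, q, :] = self.R[k]
            out[q, p, :] = self.R[k]
        return out


def pivoted_cholesky(accessor: CoulombAccessor, threshold: float = 1e-2,
                     max_vectors: int | None = None) -> CholeskyFactor:
    """Diagonal-pivoted incomplete Cholesky of the packed Coulomb matrix.

    Pivots on the largest remaining diagonal (ties broken by lowest index);
    terminates when the summed residual diagonal falls below ``threshold``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    diag = accessor.diagonal().astype(float).copy()
    n_pairs = accessor.n_pairs
    if max_vectors is None:
        max_vectors = n_pairs
    cols: list[np.ndarray] = []
    noise = 1e-10 * max(1.0, diag.max(initial=0.0))
    if diag.min(initial=0.0) < -noise:
        raise np.linalg.LinAlgError(
            f"negative diagonal {diag.min():.3e}: Coulomb matrix not PSD")
    while diag.sum() >= threshold and len(cols) < max_vectors:
        k = int(np.argmax(diag))  # np.argmax returns the lowest index on ties
        dk = diag[k]
        if dk <= noise:
            break
        col = accessor.column(k).astype(float)
        for r in cols:
            col -= r * r[k]
        r_new = col / np.sqrt(dk)
        cols.append(r_new)
        diag -= r_new * r_new
        if diag.min() < -noise:
            raise np.linalg.LinAlgError(
                f"negative residual pivot {diag.min():.3e}: input not PSD")
        np.clip(diag, 0.0, None, out=diag)
    R = np.array(cols).T if cols else np.zeros((n_pairs, 0))
    return CholeskyFactor(R, threshold, list(accessor.pairs), accessor.n_ao,
                          float(diag.sum()))


def transform_and_scale(factor: CholeskyFactor, state: MonomerState,
                        pairs: PairIndexMap) -> np.ndarray:
    """Occupation-scaled NO-basis Cholesky factors for one monomer.

    D_pq,L = (n_p^(1/2) + n_q^(1/2)) * sum_{mu nu} C_mu,p C_nu,q R_munu,L
    restricted to the monomer's excitation pairs.  Stored on the factor under
    the monomer's label and returned.
    """
    C = state.no_coefficients
    if C.shape[0] != factor.n_ao:
        raise ValueError("AO dimension of NO coefficients does not match "
                         "the Cholesky factor")
    Rfull = factor.unpacked()
    Rno = np.einsum("mp,nq,mnL->pqL", C, C, Rfull, optimize=True)
    w = pair_scale_factors(pairs, state.occupations)
    idx = np.array(pairs.pairs)
    D = Rno[idx[:, 0], idx[:, 1], :] * w[:, None]
    factor.D[state.label] = D
    return D
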