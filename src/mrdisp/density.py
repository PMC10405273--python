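"""Spatial dispersion-density maps Q^A, Q^B, Q^AB and cube export.

Each monomer's dispersion energy is attributed to its generalized-occupied
natural orbitals: every excitation pair (p, q) contributes its share of the
frequency-integrated trace to the occupied member q, and the spatial map is

    Q^X(r) = sum_q  s_q  |phi_q(r)|^2

with s_q the accumulated share (so integral Q^X = E_disp).  The combined map
Q^AB = (Q^A + Q^B) / 2 integrates to the dispersion energy as well; on a
finite grid it is rescaled so the discrete normalization holds exactly.
Units on export are kcal mol^-1 A^-3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import integrals as ig
from .dispersion import KCAL_PER_HARTREE

__all__ = ["DensityGrid", "build_dispersion_density", "isosurface_fractions",
           "write_cube", "orbital_shares"]

BOHR_PER_ANG = ig.ANGSTROM_TO_BOHR


@dataclass
class DensityGrid:
    """Regular 3-D grid (Å units) carrying the dispersion-density fields."""

    origin: np.ndarray          # Å
    spacing: np.ndarray         # Å per step along each axis
    shape: tuple[int, int, int]
    q_a: np.ndarray             # kcal mol^-1 A^-3
    q_b: np.ndarray
    q_ab: np.ndarray
    normalization_error: float  # relative, before rescaling

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def integral(self, field: str = "q_ab") -> float:
        return float(getattr(self, field).sum() * self.voxel_volume)

    def points(self) -> np.ndarray:
        ii = np.indices(self.shape).reshape(3, -1).T
        return self.origin[None, :] + ii * self.spacing[None, :]


def orbital_shares(pair_energies: np.ndarray, pairs) -> dict[int, float]:
    """Fold per-pair dispersion contributions onto the occupied pair member.

    The occupied member of pair (p, q), p > q, is q (the more occupied
    orbital).  Returns orbital index -> energy share (hartree).
    """
    shares: dict[int, float] = {}
    for e, (p, q) in zip(pair_energies, pairs.pairs):
        shares[q] = shares.get(q, 0.0) + float(e)
    return shares


def build_dispersion_density(work, result, spacing: float = 0.25,
                             padding: float = 3.0,
                             warn_tol: float = 0.05) -> DensityGrid:
    """Q maps on a regular grid from a dispersion run with pair bookkeeping.

    ``work`` is the DimerWork of the calculation and ``result`` a
    DispersionResult computed with ``pair_contributions=True``.  The grid
    covers all atoms with ``padding`` Å margin at ``spacing`` Å resolution.
    Both Q^X fields are rescaled so their grid integrals match E_disp
    exactly; the pre-rescaling error is recorded and a warning is attached
    when it exceeds ``warn_tol``.
    """
    if not result.pair_energies:
        raise ValueError("dispersion result lacks per-pair contributions; "
                         "rerun with pair_contributions=True")
    coords = np.array([x for _, x in work.geometry_a.atoms]
                      + [x for _, x in work.geometry_b.atoms])
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1
                  for k in range(3))
    grid = DensityGrid(lo, np.full(3, spacing), shape,
                       np.zeros(shape), np.zeros(shape), np.zeros(shape), 0.0)
    pts_bohr = grid.points() * BOHR_PER_ANG
    ao = ig.evaluate_aos(work.basis, pts_bohr)          # (npt, nao)
    e_disp_kcal = result.e_coupled * KCAL_PER_HARTREE

    fields = {}
    for lbl, mono in (("A", work.A), ("B", work.B)):
        shares = orbital_shares(result.pair_energies[lbl], mono.pairs)
        C = mono.state.no_coefficients
        dens = np.zeros(pts_bohr.shape[0])
        for q, share in shares.items():
            phi = ao @ C[:, q]
            # |phi|^2 integrates to 1 in bohr^-3; convert to A^-3
            dens += (share * KCAL_PER_HARTREE) * phi * phi * BOHR_PER_ANG ** 3
        fields[lbl] = dens.reshape(shape)

    grid.q_a = fields["A"]
    grid.q_b = fields["B"]
    raw = 0.5 * (grid.q_a + grid.q_b)
    raw_int = raw.sum() * grid.voxel_volume
    grid.normalization_error = abs(raw_int - e_disp_kcal) / abs(e_disp_kcal)
    if grid.normalization_error > warn_tol:
        import warnings
        warnings.warn(
            f"dispersion-density grid integral off by "
            f"{100 * grid.normalization_error:.1f}%; refine the grid "
            f"(smaller spacing and/or larger padding)")
    grid.q_ab = raw * (e_disp_kcal / raw_int)
    return grid


def isosurface_fractions(grid: DensityGrid, fractions,
                         field: str = "q_ab") -> list[float]:
    """Iso-values whose super-level sets of |density| hold given percentages.

    For each fraction f (percent), returns the value v such that grid cells
    with |density| >= v contain f% of the integrated |density|.
    """
    vals = np.abs(getattr(grid, field)).ravel()
    if vals.size == 0:
        raise ValueError("empty grid")
    order = np.argsort(vals)[::-1]
    sorted_vals = vals[order]
    cum = np.cumsum(sorted_vals)
    total = cum[-1]
    out = []
    for f in fractions:
        if not 0.0 < f <= 100.0:
            raise ValueError("fractions must lie in (0, 100]")
        if f == 100.0:
            out.append(0.0)
            continue
        k = int(np.searchsorted(cum, f / 100.0 * total))
        k = min(k, len(sorted_vals) - 1)
        out.append(float(sorted_vals[k]))
    return out


def write_cube(path, grid: DensityGrid, work, field: str = "q_ab",
               comment: str = "dispersion energy density") -> None:
    """Gaussian cube file (values in kcal mol^-1 A^-3, axes in bohr)."""
    atoms = ([(el, x, False) for (el, x), g in
              zip(work.geometry_a.atoms, work.geometry_a.ghost_flags)]
             + [(el, x, False) for (el, x), g in
                zip(work.geometry_b.atoms, work.geometry_b.ghost_flags)])
    data = getattr(grid, field)
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        fh.write(f"{comment}\n{field}\n")
        org = grid.origin * BOHR_PER_ANG
        fh.write(f"{len(atoms):5d} {org[0]:12.6f} {org[1]:12.6f} "
                 f"{org[2]:12.6f}\n")
        for n, k in ((nx, 0), (ny, 1), (nz, 2)):
            step = np.zeros(3)
            step[k] = grid.spacing[k] * BOHR_PER_ANG
            fh.write(f"{n:5d} {step[0]:12.6f} {step[1]:12.6f} "
                     f"{step[2]:12.6f}\n")
        for el, x, _ in atoms:
            z = ig.ATOMIC_NUMBERS[el]
            xb = np.asarray(x) * BOHR_PER_ANG
            fh.write(f"{z:5d} {float(z):12.6f} {xb[0]:12.6f} {xb[1]:12.6f} "
                     f"{xb[2]:12.6f}\n")
        flat = data.reshape(nx * ny, nz)
        for row in flat:
            for k in range(0, nz, 6):
                fh.write("".join(f"{v:13.5e}" for v in row[k:k + 6]) + "\n")
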