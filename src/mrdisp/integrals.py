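"""Minimal Gaussian-orbital integral engine (McMurchie–Davidson scheme).

Provides overlap, kinetic, nuclear-attraction, dipole and two-electron Coulomb
integrals over contracted Cartesian Gaussians, plus evaluation of basis
functions on real-space grids.  The engine exists so that the dispersion
algorithms in this package can be exercised end-to-end on small molecules
without an external electronic-structure code; it is deliberately restricted
to low angular momentum (s and p shells are what the built-in basis sets use,
the recursions themselves are general).

Conventions: atomic units throughout; two-electron integrals are returned in
chemists' notation (pq|rs) = <pr|qs>, i.e. charge distributions (pq) and (rs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, gamma

__all__ = [
    "Shell",
    "BasisSet",
    "BASIS_LIBRARY",
    "build_basis",
    "overlap",
    "kinetic",
    "nuclear_attraction",
    "dipole",
    "eri_tensor",
    "eri_block",
    "eri_diagonal",
    "evaluate_aos",
    "nuclear_repulsion",
    "ATOMIC_NUMBERS",
    "ANGSTROM_TO_BOHR",
]

ANGSTROM_TO_BOHR = 1.8897261246257702

ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10,
}

# ---------------------------------------------------------------------------
# Basis-set library (exponents / contraction coefficients, standard values).
# "sto-3g" is the usual minimal set; "dz" is a small split-valence set
# (6-31G for H/He, STO-3G core + split valence would be overkill for the
# fixture systems, so heavier atoms fall back to sto-3g in "dz").
# ---------------------------------------------------------------------------

_STO3G_S = [0.15432897, 0.53532814, 0.44463454]
_STO3G_SP_S = [-0.09996723, 0.39951283, 0.70011547]
_STO3G_SP_P = [0.15591627, 0.60768372, 0.39195739]

BASIS_LIBRARY: dict[str, dict[str, list[tuple[int, list[float], list[float]]]]] = {
    "sto-3g": {
        "H": [(0, [3.42525091, 0.62391373, 0.16885540], _STO3G_S)],
        "He": [(0, [6.36242139, 1.15892300, 0.31364979], _STO3G_S)],
        "O": [
            (0, [130.7093200, 23.8088610, 6.4436083], _STO3G_S),
            (0, [5.0331513, 1.1695961, 0.3803890], _STO3G_SP_S),
            (1, [5.0331513, 1.1695961, 0.3803890], _STO3G_SP_P),
        ],
        "C": [
            (0, [71.6168370, 13.0450960, 3.5305122], _STO3G_S),
            (0, [2.9412494, 0.6834831, 0.2222899], _STO3G_SP_S),
            (1, [2.9412494, 0.6834831, 0.2222899], _STO3G_SP_P),
        ],
        "N": [
            (0, [99.1061690, 18.0523120, 4.8856602], _STO3G_S),
            (0, [3.7804559, 0.8784966, 0.2857144], _STO3G_SP_S),
            (1, [3.7804559, 0.8784966, 0.2857144], _STO3G_SP_P),
        ],
    },
    "dz": {
        # 6-31G hydrogen / helium: contracted inner s + free outer s.
        "H": [
            (0, [18.7311370, 2.8253937, 0.6401217],
                [0.03349460, 0.23472695, 0.81375733]),
            (0, [0.1612778], [1.0]),
        ],
        "He": [
            (0, [38.4216340, 5.7780300, 1.2417740],
                [0.04013973, 0.26124606, 0.79326230]),
            (0, [0.2979640], [1.0]),
        ],
    },
}
# heavier atoms in "dz" reuse the minimal description
for _el in ("O", "C", "N"):
    BASIS_LIBRARY["dz"][_el] = BASIS_LIBRARY["sto-3g"][_el]

_CART_COMPONENTS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)],
}


@dataclass
class Shell:
    """A contracted Cartesian Gaussian shell on one center."""

    l: int
    exponents: np.ndarray
    coefficients: np.ndarray  # includes primitive norms after build_basis
    center: np.ndarray
    atom_index: int

    @property
    def n_functions(self) -> int:
        return len(_CART_COMPONENTS[self.l])


@dataclass
class BasisSet:
    shells: list[Shell]
    label: str = ""
    # per-AO metadata, filled in build_basis
    ao_shell: list[int] = field(default_factory=list)
    ao_component: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def n_ao(self) -> int:
        return len(self.ao_shell)


def _primitive_norm(l: int, m: int, n: int, alpha: float) -> float:
    """Norm of x^l y^m z^n exp(-alpha r^2)."""
    num = (2.0 * alpha / math.pi) ** 0.75 * (4.0 * alpha) ** ((l + m + n) / 2.0)
    den = math.sqrt(_df(2 * l - 1) * _df(2 * m - 1) * _df(2 * n - 1))
    return num / den


def _df(n: int) -> float:
    if n <= 0:
        return 1.0
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def build_basis(atoms, basis_label: str) -> BasisSet:
    """Construct a BasisSet for atoms = [(element, xyz_bohr), ...].

    Ghost atoms are passed like regular ones (the caller simply includes their
    centers); only basis functions, no charge, are attached to them there.
    """
    lib = BASIS_LIBRARY[basis_label.lower()]
    shells: list[Shell] = []
    for ia, (el, xyz) in enumerate(atoms):
        if el not in lib:
            raise ValueError(f"element {el} not available in basis {basis_label}")
        for l, exps, coefs in lib[el]:
            exps = np.asarray(exps, dtype=float)
            coefs = np.asarray(coefs, dtype=float)
            # attach primitive norms (use the (l,0,0) norm; per-component
            # corrections handled in the integral routines via _df factors
            # — for l<=1 all components share the same norm)
            norms = np.array([_primitive_norm(l, 0, 0, a) for a in exps])
            cc = coefs * norms
            shell = Shell(l, exps, cc, np.asarray(xyz, dtype=float), ia)
            # normalize the contracted function to unity
            shells.append(shell)
    basis = BasisSet(shells, basis_label)
    for isf, sh in enumerate(shells):
        for comp in _CART_COMPONENTS[sh.l]:
            basis.ao_shell.append(isf)
            basis.ao_component.append(comp)
    # contracted normalization: scale coefficients so diagonal overlap is 1
    S = overlap(basis)
    scale = 1.0 / np.sqrt(np.diag(S))
    ao = 0
    for sh in shells:
        sh.coefficients = sh.coefficients * scale[ao]
        ao += sh.n_functions
    return basis


# ---------------------------------------------------------------------------
# Hermite expansion coefficients and auxiliary integrals
# ---------------------------------------------------------------------------

def _hermite_E(i_max: int, j_max: int, a: float, b: float, AB: float) -> np.ndarray:
    """E[t, i, j] coefficients for the 1-D Gaussian product (McMurchie–Davidson)."""
    p = a + b
    mu = a * b / p
    E = np.zeros((i_max + j_max + 2, i_max + 1, j_max + 1))
    E[0, 0, 0] = math.exp(-mu * AB * AB)
    XPA = -b * AB / p  # P - A with AB = A - B
    XPB = a * AB / p   # P - B
    for i in range(1, i_max + 1):
        for t in range(i + 1):
            lower = E[t - 1, i - 1, 0] / (2 * p) if t >= 1 else 0.0
            E[t, i, 0] = lower + XPA * E[t, i - 1, 0] + (t + 1) * E[t + 1, i - 1, 0]
    for j in range(1, j_max + 1):
        for i in range(i_max + 1):
            for t in range(i + j + 1):
                lower = E[t - 1, i, j - 1] / (2 * p) if t >= 1 else 0.0
                E[t, i, j] = lower + XPB * E[t, i, j - 1] + (t + 1) * E[t + 1, i, j - 1]
    return E[: i_max + j_max + 1]


def _boys(n_max: int, x: np.ndarray) -> np.ndarray:
    """Boys functions F_0..F_n for an array of arguments."""
    x = np.asarray(x, dtype=float)
    out = np.empty((n_max + 1,) + x.shape)
    small = x < 1e-12
    xs = np.where(small, 1.0, x)
    n = n_max + 0.5
    # downward recursion from F_{n_max} for stability
    top = gamma(n) * gammainc(n, xs) / (2.0 * xs ** n)
    out[n_max] = np.where(small, 1.0 / (2 * n_max + 1), top)
    ex = np.exp(-x)
    for m in range(n_max - 1, -1, -1):
        out[m] = np.where(small, 1.0 / (2 * m + 1),
                          (2.0 * x * out[m + 1] + ex) / (2 * m + 1))
    return out


def _hermite_R(t_max: int, u_max: int, v_max: int, p,
               PC: np.ndarray) -> np.ndarray:
    """Hermite Coulomb integrals R^0_{tuv} for a batch of centers PC (n,3).

    `p` may be a scalar or an array of length n (one exponent per center).
    """
    PC = np.atleast_2d(PC)
    n = PC.shape[0]
    p = np.broadcast_to(np.asarray(p, dtype=float), (n,))
    L = t_max + u_max + v_max
    r2 = np.einsum("ij,ij->i", PC, PC)
    F = _boys(L, p * r2)
    base = np.empty((L + 1, n))
    fac = np.ones(n)
    for m in range(L + 1):
        base[m] = fac * F[m]
        fac = fac * (-2.0 * p)
    R = np.zeros((L + 1, t_max + 1, u_max + 1, v_max + 1, n))
    R[:, 0, 0, 0, :] = base
    for t in range(1, t_max + 1):
        for m in range(L - t + 1):
            val = PC[:, 0] * R[m + 1, t - 1, 0, 0]
            if t > 1:
                val = val + (t - 1) * R[m + 1, t - 2, 0, 0]
            R[m, t, 0, 0] = val
    for u in range(1, u_max + 1):
        for t in range(t_max + 1):
            for m in range(L - t - u + 1):
                val = PC[:, 1] * R[m + 1, t, u - 1, 0]
                if u > 1:
                    val = val + (u - 1) * R[m + 1, t, u - 2, 0]
                R[m, t, u, 0] = val
    for v in range(1, v_max + 1):
        for t in range(t_max + 1):
            for u in range(u_max + 1):
                for m in range(L - t - u - v + 1):
                    val = PC[:, 2] * R[m + 1, t, u, v - 1]
                    if v > 1:
                        val = val + (v - 1) * R[m + 1, t, u, v - 2]
                    R[m, t, u, v] = val
    return R[0]


# ---------------------------------------------------------------------------
# Shell-pair data
# ---------------------------------------------------------------------------

class _ShellPair:
    __slots__ = ("la", "lb", "coef", "p", "P", "Ex", "Ey", "Ez", "na", "nb")

    def __init__(self, sa: Shell, sb: Shell):
        self.la, self.lb = sa.l, sb.l
        AB = sa.center - sb.center
        coefs, ps, Ps, Exs, Eys, Ezs = [], [], [], [], [], []
        for ca, aa in zip(sa.coefficients, sa.exponents):
            for cb, ab in zip(sb.coefficients, sb.exponents):
                p = aa + ab
                P = (aa * sa.center + ab * sb.center) / p
                coefs.append(ca * cb)
                ps.append(p)
                Ps.append(P)
                Exs.append(_hermite_E(sa.l, sb.l, aa, ab, AB[0]))
                Eys.append(_hermite_E(sa.l, sb.l, aa, ab, AB[1]))
                Ezs.append(_hermite_E(sa.l, sb.l, aa, ab, AB[2]))
        self.coef = np.array(coefs)
        self.p = np.array(ps)
        self.P = np.array(Ps)
        self.Ex = np.array(Exs)  # (nprim, t, i, j)
        self.Ey = np.array(Eys)
        self.Ez = np.array(Ezs)
        self.na = len(_CART_COMPONENTS[sa.l])
        self.nb = len(_CART_COMPONENTS[sb.l])

    def hermite_coeffs(self):
        """Combined E^{ab}_{tuv} for each Cartesian component pair.

        Returns array (nprim, na, nb, t, u, v)."""
        la, lb = self.la, self.lb
        comps_a = _CART_COMPONENTS[la]
        comps_b = _CART_COMPONENTS[lb]
        npr = len(self.coef)
        L = la + lb
        out = np.zeros((npr, self.na, self.nb, L + 1, L + 1, L + 1))
        for ia, (ax, ay, az) in enumerate(comps_a):
            for ib, (bx, by, bz) in enumerate(comps_b):
                ex = self.Ex[:, : ax + bx + 1, ax, bx]
                ey = self.Ey[:, : ay + by + 1, ay, by]
                ez = self.Ez[:, : az + bz + 1, az, bz]
                out[:, ia, ib, : ax + bx + 1, : ay + by + 1, : az + bz + 1] = (
                    ex[:, :, None, None] * ey[:, None, :, None] * ez[:, None, None, :]
                )
        return out


def _shell_pairs(basis: BasisSet):
    shells = basis.shells
    pairs = {}
    for i in range(len(shells)):
        for j in range(len(shells)):
            if j <= i:
                pairs[(i, j)] = _ShellPair(shells[i], shells[j])
    def get(i, j):
        if (i, j) in pairs:
            return pairs[(i, j)], False
        return pairs[(j, i)], True
    return get


# ---------------------------------------------------------------------------
# One-electron integrals
# ---------------------------------------------------------------------------

def _s1d(E: np.ndarray, p: np.ndarray, i: int, j: int) -> np.ndarray:
    return E[:, 0, i, j] * np.sqrt(np.pi / p)


def overlap(basis: BasisSet) -> np.ndarray:
    n = basis.n_ao
    S = np.zeros((n, n))
    offs = _shell_offsets(basis)
    for isa, sa in enumerate(basis.shells):
        for isb, sb in enumerate(basis.shells):
            if isb > isa:
                continue
            sp = _ShellPair(sa, sb)
            blk = np.zeros((sp.na, sp.nb))
            for ia, (ax, ay, az) in enumerate(_CART_COMPONENTS[sa.l]):
                for ib, (bx, by, bz) in enumerate(_CART_COMPONENTS[sb.l]):
                    val = (sp.coef
                           * _s1d(sp.Ex, sp.p, ax, bx)
                           * _s1d(sp.Ey, sp.p, ay, by)
                           * _s1d(sp.Ez, sp.p, az, bz)).sum()
                    blk[ia, ib] = val
            S[offs[isa]:offs[isa] + sp.na, offs[isb]:offs[isb] + sp.nb] = blk
            S[offs[isb]:offs[isb] + sp.nb, offs[isa]:offs[isa] + sp.na] = blk.T
    return S


def kinetic(basis: BasisSet) -> np.ndarray:
    n = basis.n_ao
    T = np.zeros((n, n))
    offs = _shell_offsets(basis)
    for isa, sa in enumerate(basis.shells):
        for isb, sb in enumerate(basis.shells):
            if isb > isa:
                continue
            blk = _kinetic_block(sa, sb)
            T[offs[isa]:offs[isa] + blk.shape[0], offs[isb]:offs[isb] + blk.shape[1]] = blk
            T[offs[isb]:offs[isb] + blk.shape[1], offs[isa]:offs[isa] + blk.shape[0]] = blk.T
    return T


def _kinetic_block(sa: Shell, sb: Shell) -> np.ndarray:
    AB = sa.center - sb.center
    na = len(_CART_COMPONENTS[sa.l])
    nb = len(_CART_COMPONENTS[sb.l])
    blk = np.zeros((na, nb))
    for ca, aa in zip(sa.coefficients, sa.exponents):
        for cb, ab in zip(sb.coefficients, sb.exponents):
            p = aa + ab
            # E tables padded by 2 in j for the +2 terms
            Ex = _hermite_E(sa.l, sb.l + 2, aa, ab, AB[0])
            Ey = _hermite_E(sa.l, sb.l + 2, aa, ab, AB[1])
            Ez = _hermite_E(sa.l, sb.l + 2, aa, ab, AB[2])
            sqp = math.sqrt(math.pi / p)

            def s(E, i, j):
                if j < 0:
                    return 0.0
                return E[0, i, j] * sqp

            def t1d(E, i, j):
                out = -2.0 * ab * ab * s(E, i, j + 2)
                out += ab * (2 * j + 1) * s(E, i, j)
                if j >= 2:
                    out -= 0.5 * j * (j - 1) * s(E, i, j - 2)
                return out

            for ia, (ax, ay, az) in enumerate(_CART_COMPONENTS[sa.l]):
                for ib, (bx, by, bz) in enumerate(_CART_COMPONENTS[sb.l]):
                    val = (t1d(Ex, ax, bx) * s(Ey, ay, by) * s(Ez, az, bz)
                           + s(Ex, ax, bx) * t1d(Ey, ay, by) * s(Ez, az, bz)
                           + s(Ex, ax, bx) * s(Ey, ay, by) * t1d(Ez, az, bz))
                    blk[ia, ib] += ca * cb * val
    return blk


def nuclear_attraction(basis: BasisSet, charges) -> np.ndarray:
    """V_ab = -sum_I Z_I <a| 1/|r-R_I| |b>; charges = [(Z, xyz_bohr), ...]."""
    n = basis.n_ao
    V = np.zeros((n, n))
    offs = _shell_offsets(basis)
    if not charges:
        return V
    Zs = np.array([z for z, _ in charges])
    Cs = np.array([c for _, c in charges])
    for isa, sa in enumerate(basis.shells):
        for isb, sb in enumerate(basis.shells):
            if isb > isa:
                continue
            sp = _ShellPair(sa, sb)
            Eab = sp.hermite_coeffs()
            L = sa.l + sb.l
            blk = np.zeros((sp.na, sp.nb))
            for k in range(len(sp.coef)):
                PC = sp.P[k][None, :] - Cs
                R = _hermite_R(L, L, L, sp.p[k], PC)  # (t,u,v,ncharge)
                pref = 2.0 * np.pi / sp.p[k] * sp.coef[k]
                contrib = np.einsum("abtuv,tuvc,c->ab",
                                    Eab[k], R, Zs, optimize=True)
                blk -= pref * contrib
            V[offs[isa]:offs[isa] + sp.na, offs[isb]:offs[isb] + sp.nb] = blk
            V[offs[isb]:offs[isb] + sp.nb, offs[isa]:offs[isa] + sp.na] = blk.T
    return V


def dipole(basis: BasisSet, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Electronic dipole integrals <a| r_k |b>, returned as (3, n, n)."""
    n = basis.n_ao
    out = np.zeros((3, n, n))
    offs = _shell_offsets(basis)
    origin = np.asarray(origin, dtype=float)
    for isa, sa in enumerate(basis.shells):
        for isb, sb in enumerate(basis.shells):
            if isb > isa:
                continue
            sp = _ShellPair(sa, sb)
            sqp = np.sqrt(np.pi / sp.p)
            for ia, (ax, ay, az) in enumerate(_CART_COMPONENTS[sa.l]):
                for ib, (bx, by, bz) in enumerate(_CART_COMPONENTS[sb.l]):
                    s = [
                        sp.Ex[:, 0, ax, bx] * sqp,
                        sp.Ey[:, 0, ay, by] * sqp,
                        sp.Ez[:, 0, az, bz] * sqp,
                    ]
                    # <x> = E_1 + (P_x - origin) E_0 (Hermite first moment)
                    E1 = [
                        (sp.Ex[:, 1, ax, bx] if ax + bx >= 1 else 0.0),
                        (sp.Ey[:, 1, ay, by] if ay + by >= 1 else 0.0),
                        (sp.Ez[:, 1, az, bz] if az + bz >= 1 else 0.0),
                    ]
                    for k in range(3):
                        mom = (E1[k] + (sp.P[:, k] - origin[k]) *
                               [sp.Ex[:, 0, ax, bx], sp.Ey[:, 0, ay, by],
                                sp.Ez[:, 0, az, bz]][k]) * sqp
                        comps = [s[0], s[1], s[2]]
                        comps[k] = mom
                        val = (sp.coef * comps[0] * comps[1] * comps[2]).sum()
                        out[k, offs[isa] + ia, offs[isb] + ib] = val
                        out[k, offs[isb] + ib, offs[isa] + ia] = val
    return out


def _shell_offsets(basis: BasisSet) -> list[int]:
    offs, n = [], 0
    for sh in basis.shells:
        offs.append(n)
        n += sh.n_functions
    return offs


# ---------------------------------------------------------------------------
# Two-electron integrals
# ---------------------------------------------------------------------------


def _pair_cached(basis: BasisSet, i: int, j: int) -> "_ShellPair":
    cache = getattr(basis, "_paircache", None)
    if cache is None:
        cache = {}
        basis._paircache = cache
    key = (i, j)
    if key not in cache:
        cache[key] = _ShellPair(basis.shells[i], basis.shells[j])
    return cache[key]


def _eri_shell_quartet(spa: _ShellPair, spb: _ShellPair) -> np.ndarray:
    """(ab|cd) block over Cartesian components, shape (na, nb, nc, nd)."""
    Eab = spa.hermite_coeffs()  # (np1, na, nb, t, u, v)
    Ecd = spb.hermite_coeffs()  # (np2, nc, nd, t, u, v)
    La = spa.la + spa.lb
    Lb = spb.la + spb.lb
    np1 = len(spa.coef)
    np2 = len(spb.coef)
    # phase (-1)^{t+u+v} on the ket side
    phase = np.fromfunction(
        lambda t, u, v: (-1.0) ** (t + u + v), (Lb + 1, Lb + 1, Lb + 1))
    Ecd_ph = Ecd * phase[None, None, None]
    # all primitive combinations in one batch
    p = spa.p[:, None]                       # (np1, 1)
    q = spb.p[None, :]                       # (1, np2)
    alpha = (p * q / (p + q)).ravel()
    PQ = (spa.P[:, None, :] - spb.P[None, :, :]).reshape(-1, 3)
    pref = (2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
            * spa.coef[:, None] * spb.coef[None, :])  # (np1, np2)
    L = La + Lb
    Rfull = _hermite_R(L, L, L, alpha, PQ)   # (t, u, v, np1*np2)
    Rfull = Rfull.reshape(L + 1, L + 1, L + 1, np1, np2)
    out = np.zeros((spa.na, spa.nb, spb.na, spb.nb))
    # contract: sum_{tuv,TUV} Eab[t,u,v] Ecd[T,U,V] R[t+T,u+U,v+V]
    for t in range(La + 1):
        for u in range(La + 1 - t):
            for v in range(La + 1 - t - u):
                Rsub = Rfull[t:t + Lb + 1, u:u + Lb + 1, v:v + Lb + 1]
                ket = np.einsum("kcdTUV,TUVmk,mk->mcd",
                                Ecd_ph, Rsub, pref, optimize=True)
                out += np.einsum("mab,mcd->abcd",
                                 Eab[:, :, :, t, u, v], ket, optimize=True)
    return out


def eri_tensor(basis: BasisSet) -> np.ndarray:
    """Full (pq|rs) tensor.  Only for small systems (guarded)."""
    n = basis.n_ao
    if n > 48:
        raise ValueError("dense ERI tensor guarded to <=48 basis functions")
    offs = _shell_offsets(basis)
    nsh = len(basis.shells)
    plist = [(i, j) for i in range(nsh) for j in range(i + 1)]
    eri = np.zeros((n, n, n, n))
    for ij, (i, j) in enumerate(plist):
        for kl, (k, l) in enumerate(plist):
            if kl > ij:
                continue
            blk = _eri_shell_quartet(_pair_cached(basis, i, j),
                                     _pair_cached(basis, k, l))
            _scatter(eri, blk, offs, i, j, k, l)
    return eri


def _scatter(eri, blk, offs, i, j, k, l):
    si, sj, sk, sl = offs[i], offs[j], offs[k], offs[l]
    na, nb, nc, nd = blk.shape
    eri[si:si + na, sj:sj + nb, sk:sk + nc, sl:sl + nd] = blk
    eri[sj:sj + nb, si:si + na, sk:sk + nc, sl:sl + nd] = blk.transpose(1, 0, 2, 3)
    eri[si:si + na, sj:sj + nb, sl:sl + nd, sk:sk + nc] = blk.transpose(0, 1, 3, 2)
    eri[sj:sj + nb, si:si + na, sl:sl + nd, sk:sk + nc] = blk.transpose(1, 0, 3, 2)
    eri[sk:sk + nc, sl:sl + nd, si:si + na, sj:sj + nb] = blk.transpose(2, 3, 0, 1)
    eri[sl:sl + nd, sk:sk + nc, si:si + na, sj:sj + nb] = blk.transpose(3, 2, 0, 1)
    eri[sk:sk + nc, sl:sl + nd, sj:sj + nb, si:si + na] = blk.transpose(2, 3, 1, 0)
    eri[sl:sl + nd, sk:sk + nc, sj:sj + nb, si:si + na] = blk.transpose(3, 2, 1, 0)


def eri_block(basis: BasisSet, r: int, s: int) -> np.ndarray:
    """One column (pq|rs) of the Coulomb matrix for fixed AOs r, s.

    Returns the n x n matrix over (p, q) without building the full tensor.
    """
    offs = _shell_offsets(basis)
    shr = basis.ao_shell[r]
    shs = basis.ao_shell[s]
    cr = r - offs[shr]
    cs = s - offs[shs]
    if shs <= shr:
        spb = _pair_cached(basis, shr, shs)
        pick = (cr, cs)
    else:
        spb = _pair_cached(basis, shs, shr)
        pick = (cs, cr)
    n = basis.n_ao
    out = np.zeros((n, n))
    nsh = len(basis.shells)
    for i in range(nsh):
        for j in range(i + 1):
            spa = _pair_cached(basis, i, j)
            blk = _eri_shell_quartet(spa, spb)[:, :, pick[0], pick[1]]
            si, sj = offs[i], offs[j]
            out[si:si + blk.shape[0], sj:sj + blk.shape[1]] = blk
            out[sj:sj + blk.shape[1], si:si + blk.shape[0]] = blk.T
    return out


def eri_diagonal(basis: BasisSet) -> np.ndarray:
    """Diagonal (pq|pq) of the AO Coulomb matrix over packed pairs p >= q.

    Returned as an n x n symmetric matrix d[p, q] = (pq|pq).
    """
    n = basis.n_ao
    offs = _shell_offsets(basis)
    out = np.zeros((n, n))
    nsh = len(basis.shells)
    for i in range(nsh):
        for j in range(i + 1):
            sp = _pair_cached(basis, i, j)
            blk = _eri_shell_quartet(sp, sp)
            na, nb = blk.shape[:2]
            for a in range(na):
                for b in range(nb):
                    out[offs[i] + a, offs[j] + b] = blk[a, b, a, b]
                    out[offs[j] + b, offs[i] + a] = blk[a, b, a, b]
    return out


# ---------------------------------------------------------------------------
# Misc
# ---------------------------------------------------------------------------

def nuclear_repulsion(charges) -> float:
    e = 0.0
    for i, (zi, ci) in enumerate(charges):
        for j, (zj, cj) in enumerate(charges):
            if j < i:
                e += zi * zj / np.linalg.norm(np.asarray(ci) - np.asarray(cj))
    return e


def evaluate_aos(basis: BasisSet, points: np.ndarray) -> np.ndarray:
    """Values of all AOs at Cartesian points (npt, 3) in bohr -> (npt, n_ao)."""
    pts = np.atleast_2d(points)
    out = np.zeros((pts.shape[0], basis.n_ao))
    ao = 0
    for sh in basis.shells:
        d = pts - sh.center[None, :]
        r2 = np.einsum("ij,ij->i", d, d)
        rad = np.zeros(pts.shape[0])
        for c, a in zip(sh.coefficients, sh.exponents):
            rad += c * np.exp(-a * r2)
        for (lx, ly, lz) in _CART_COMPONENTS[sh.l]:
            ang = d[:, 0] ** lx * d[:, 1] ** ly * d[:, 2] ** lz
            out[:, ao] = ang * rad
            ao += 1
    return out
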