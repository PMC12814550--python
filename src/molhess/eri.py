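"""Electron-repulsion integrals over contracted spherical Gaussian shells.

The shell-quartet engine follows the nine-step Obara-Saika evaluation
scheme: auxiliary integrals from pairwise overlaps and the Boys function,
vertical recurrence relations raising angular momentum on the ket (D) and
bra (B) centers of the primitive Cartesian integrals, early contraction,
a horizontal recurrence moving angular momentum from D to C, an early
transformation of the ket side to the spherical representation, the
mixed-representation horizontal recurrence moving angular momentum from
B to A, the final bra transformation, and distribution into the Fock
matrix.

Shell quartet (ij|kl) notation: i sits on center A, j on B, k on C and
l on D; the vertical recurrences accumulate angular momentum on B and D,
the horizontal ones transfer it to A and C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .basis import AOBasis, GaussianShell
from .boys import boys_array
from .spherical import cart_components, cart_to_spherical_raw, n_cart


@lru_cache(maxsize=None)
def _comp_index(l: int) -> dict:
    return {c: i for i, c in enumerate(cart_components(l))}


@lru_cache(maxsize=None)
def _lower_map(l: int):
    """Per component of shell l: (reduction direction i, index of c-1_i in
    shell l-1, index of c-2_i in shell l-2 or -1)."""
    out = []
    for c in cart_components(l):
        i = next(d for d in range(3) if c[d] > 0)
        low = list(c)
        low[i] -= 1
        lo1 = _comp_index(l - 1)[tuple(low)]
        lo2 = -1
        if low[i] > 0:
            low2 = list(low)
            low2[i] -= 1
            lo2 = _comp_index(l - 2)[tuple(low2)]
        out.append((i, lo1, lo2))
    return tuple(out)


@lru_cache(maxsize=None)
def _raise_index(l: int, direction: int) -> tuple:
    """Component c of shell l -> index of c+1_direction in shell l+1."""
    idx_up = _comp_index(l + 1)
    out = []
    for c in cart_components(l):
        up = list(c)
        up[direction] += 1
        out.append(idx_up[tuple(up)])
    return tuple(out)


@dataclass
class QuartetIntermediates:
    """Composite Obara-Saika quantities for all primitive quartets of one
    shell quartet, vectorized over the primitive axis."""

    zeta: np.ndarray
    eta: np.ndarray
    rho: np.ndarray
    T: np.ndarray
    S_AB: np.ndarray
    S_CD: np.ndarray
    weights: np.ndarray
    exp_b: np.ndarray
    exp_d: np.ndarray
    PB: np.ndarray  # (n,3) P - B
    WP: np.ndarray
    QD: np.ndarray  # (n,3) Q - D
    WQ: np.ndarray
    BA: np.ndarray  # (3,) B - A
    DC: np.ndarray  # (3,) D - C

    @classmethod
    def build(cls, sha, shb, shc, shd):
        A, B, C, D = sha.center, shb.center, shc.center, shd.center
        a = sha.exponents[:, None, None, None]
        b = shb.exponents[None, :, None, None]
        c = shc.exponents[None, None, :, None]
        d = shd.exponents[None, None, None, :]
        w4 = (sha.coefficients[:, None, None, None]
              * shb.coefficients[None, :, None, None]
              * shc.coefficients[None, None, :, None]
              * shd.coefficients[None, None, None, :])
        shape = w4.shape
        a4 = np.broadcast_to(a, shape).ravel()
        b4 = np.broadcast_to(b, shape).ravel()
        c4 = np.broadcast_to(c, shape).ravel()
        d4 = np.broadcast_to(d, shape).ravel()
        w = w4.ravel()
        zeta = a4 + b4
        eta = c4 + d4
        rho = zeta * eta / (zeta + eta)
        P = (a4[:, None] * A + b4[:, None] * B) / zeta[:, None]
        Q = (c4[:, None] * C + d4[:, None] * D) / eta[:, None]
        W = (zeta[:, None] * P + eta[:, None] * Q) / (zeta + eta)[:, None]
        AB2 = float(np.dot(A - B, A - B))
        CD2 = float(np.dot(C - D, C - D))
        S_AB = (math.pi / zeta) ** 1.5 * np.exp(-a4 * b4 / zeta * AB2)
        S_CD = (math.pi / eta) ** 1.5 * np.exp(-c4 * d4 / eta * CD2)
        T = rho * ((P - Q) ** 2).sum(axis=1)
        return cls(zeta, eta, rho, T, S_AB, S_CD, w, b4, d4,
                   P - B, W - P, Q - D, W - Q, B - A, D - C)


def primitive_blocks(sha, shb, shc, shd, b_max: int, d_max: int):
    """Steps 1-3: primitive Cartesian [0b|0d]^(0) for all b <= b_max and
    d <= d_max, plus the intermediates (for derivative weighting).

    Returns (prim, blocks) with blocks[(b, d)] of shape
    (n_prim_quartets, ncart(b), ncart(d)).
    """
    prim = QuartetIntermediates.build(sha, shb, shc, shd)
    m_tot = b_max + d_max
    aux = _auxiliary(prim, m_tot)  # (n, m_tot+1)
    n = aux.shape[0]

    # ket VRR: kblk[d] = (n, ncart_d, m) valid for m <= m_tot - d
    kblk = {0: aux[:, None, :]}
    for d in range(1, d_max + 1):
        nm = m_tot - d + 1
        out = np.zeros((n, n_cart(d), nm))
        prev = kblk[d - 1]
        prev2 = kblk.get(d - 2)
        for ti, (i, lo1, lo2) in enumerate(_lower_map(d)):
            v = (prim.QD[:, i, None] * prev[:, lo1, :nm]
                 + prim.WQ[:, i, None] * prev[:, lo1, 1:nm + 1])
            if lo2 >= 0:
                Ni = cart_components(d)[ti][i] - 1
                v += Ni / (2 * prim.eta[:, None]) * (
                    prev2[:, lo2, :nm]
                    - (prim.rho / prim.eta)[:, None] * prev2[:, lo2, 1:nm + 1])
            out[:, ti, :] = v
        kblk[d] = out

    # bra VRR: blocks[(b,d)] = (n, ncart_b, ncart_d, m)
    blocks = {(0, d): kblk[d][:, None, :, :] for d in range(d_max + 1)}
    for b in range(1, b_max + 1):
        for d in range(0, d_max + 1):
            nm = m_tot - b - d + 1
            out = np.zeros((n, n_cart(b), n_cart(d), nm))
            prev = blocks[(b - 1, d)]
            prev2 = blocks.get((b - 2, d))
            prevd = blocks.get((b - 1, d - 1))
            comps_d = cart_components(d)
            for ti, (i, lo1, lo2) in enumerate(_lower_map(b)):
                v = (prim.PB[:, i, None, None] * prev[:, lo1, :, :nm]
                     + prim.WP[:, i, None, None] * prev[:, lo1, :, 1:nm + 1])
                if lo2 >= 0:
                    Ni = cart_components(b)[ti][i] - 1
                    v += Ni / (2 * prim.zeta[:, None, None]) * (
                        prev2[:, lo2, :, :nm]
                        - (prim.rho / prim.zeta)[:, None, None]
                        * prev2[:, lo2, :, 1:nm + 1])
                if prevd is not None:
                    # transfer term lowering the ket: N_i(d)/(2(zeta+eta))
                    coef = 1.0 / (2 * (prim.zeta + prim.eta))
                    for di, dc in enumerate(comps_d):
                        if dc[i] > 0:
                            low_d = list(dc)
                            low_d[i] -= 1
                            src = _comp_index(d - 1)[tuple(low_d)]
                            v[:, di, :] += (dc[i] * coef)[:, None] \
                                * prevd[:, lo1, src, 1:nm + 1]
                out[:, ti, :, :] = v
            blocks[(b, d)] = out

    final = {key: arr[..., 0] for key, arr in blocks.items()}
    return prim, final


def _auxiliary(prim: QuartetIntermediates, m_max: int) -> np.ndarray:
    F = boys_array(m_max, prim.T)
    pref = 2.0 * np.sqrt(prim.rho / math.pi) * prim.S_AB * prim.S_CD
    return pref[:, None] * F


def contract(prim: QuartetIntermediates, blocks: dict,
             weights: np.ndarray | None = None) -> dict:
    """Step 4: early contraction over the primitive axis."""
    w = prim.weights if weights is None else weights
    return {key: np.tensordot(w, arr, axes=(0, 0)) for key, arr in blocks.items()}


def hrr_ket(cont: dict[int, np.ndarray], DC: np.ndarray, lk: int, ll: int,
            deriv_blocks: dict | None = None):
    """Step 5: horizontal recurrence transferring angular momentum from D
    to C on contracted blocks.

    cont maps d -> array (..., ncart_d) holding (0b|0d).  When
    deriv_blocks carries lower-derivative blocks for differentiated ket
    centers, the differentiated recurrence adds the Kronecker-delta terms
    (see :mod:`molhess.eri_deriv`).  Returns array (..., ncart_k, ncart_l).
    """
    # table[c][d] = (..., ncart_c, ncart_d)
    table = {0: {d: arr[..., None, :] for d, arr in cont.items()}}
    for c in range(1, lk + 1):
        table[c] = {}
        for d in range(ll, lk + ll - c + 1):
            prev = table[c - 1]
            shape = prev[d].shape[:-2] + (n_cart(c), n_cart(d))
            out = np.zeros(shape)
            for ti, (i, lo1, _lo2) in enumerate(_lower_map(c)):
                up = list(_raise_index(d, i))
                out[..., ti, :] = (DC[i] * prev[d][..., lo1, :]
                                   + prev[d + 1][..., lo1, up])
            table[c][d] = out
    return table[lk][ll]


def hrr_bra(blocks: dict[int, np.ndarray], BA: np.ndarray, li: int, lj: int):
    """Step 7: mixed-representation horizontal recurrence from B to A.

    blocks maps b -> (ncart_b, nk, nl) arrays (ket already spherical).
    Returns (ncart_a=li, ncart_b=lj, nk, nl).
    """
    table = {0: {b: arr[None, ...] for b, arr in blocks.items()}}
    for a in range(1, li + 1):
        table[a] = {}
        for b in range(lj, li + lj - a + 1):
            prev = table[a - 1]
            shape = (n_cart(a), n_cart(b)) + prev[b].shape[2:]
            out = np.zeros(shape)
            for ti, (i, lo1, _lo2) in enumerate(_lower_map(a)):
                up = list(_raise_index(b, i))
                out[ti] = BA[i] * prev[b][lo1] + prev[b + 1][lo1][up]
            table[a][b] = out
    return table[li][lj]


def eri_quartet(sha: GaussianShell, shb: GaussianShell,
                shc: GaussianShell, shd: GaussianShell) -> np.ndarray:
    """Contracted spherical ERI block (ij|kl), shape (ni, nj, nk, nl)."""
    li, lj, lk, ll = sha.l, shb.l, shc.l, shd.l
    prim, pblocks = primitive_blocks(sha, shb, shc, shd, li + lj, lk + ll)
    cont = contract(prim, pblocks)
    tk = cart_to_spherical_raw(lk)
    tl = cart_to_spherical_raw(ll)
    mixed = {}
    for b in range(lj, li + lj + 1):
        kets = {d: cont[(b, d)] for d in range(lk + ll + 1)}
        cd = hrr_ket(kets, prim.DC, lk, ll)  # (ncart_b, nck, ncl)
        mixed[b] = np.einsum("pc,bcd,qd->bpq", tk, cd, tl)
    ab = hrr_bra(mixed, prim.BA, li, lj)
    ta = cart_to_spherical_raw(li)
    tb = cart_to_spherical_raw(lj)
    return np.einsum("pa,abkl,qb->pqkl", ta, ab, tb)


# ------------------------------------------------------------ Schwarz screen

@dataclass
class SchwarzScreen:
    """Cauchy-Schwarz shell-pair bounds Q_ij = sqrt(max |(ij|ij)|)."""

    Q_pair: np.ndarray
    threshold: float = 1e-12

    def keep(self, i: int, j: int, k: int, l: int) -> bool:
        return self.Q_pair[i, j] * self.Q_pair[k, l] >= self.threshold


class NumericalIntegrityError(RuntimeError):
    pass


def schwarz_bounds(basis: AOBasis, threshold: float = 1e-12) -> SchwarzScreen:
    ns = basis.n_shells
    Q = np.zeros((ns, ns))
    for i in range(ns):
        for j in range(i + 1):
            blk = eri_quartet(basis.shells[i], basis.shells[j],
                              basis.shells[i], basis.shells[j])
            ni, nj = blk.shape[:2]
            diag = np.array([[blk[p, q, p, q] for q in range(nj)]
                             for p in range(ni)])
            if diag.min() < -1e-14:
                raise NumericalIntegrityError(
                    f"negative Schwarz diagonal {diag.min():.3e} for pair "
                    f"({i},{j})")
            Q[i, j] = Q[j, i] = math.sqrt(max(diag.max(), 0.0))
    return SchwarzScreen(Q, threshold)


# ----------------------------------------------------------------- Fock build

def canonical_quartets(n_shells: int):
    """Canonical shell quartet loop: i>=j, k>=l, (ij)>=(kl)."""
    for i in range(n_shells):
        for j in range(i + 1):
            for k in range(i + 1):
                lmax = j if k == i else k
                for l in range(lmax + 1):
                    yield i, j, k, l


class ERICache:
    """Caches contracted spherical quartet blocks of a basis, and (for
    small systems) the fully distributed dense tensor used to amortize
    repeated Fock-type contractions across SCF/CPHF iterations."""

    DENSE_LIMIT = 48  # n_ao above which the dense tensor is not kept

    def __init__(self, basis: AOBasis):
        self.basis = basis
        self._store: dict[tuple[int, int, int, int], np.ndarray] = {}
        self._dense: dict[float, np.ndarray] = {}

    def block(self, i, j, k, l) -> np.ndarray:
        key = (i, j, k, l)
        if key not in self._store:
            sh = self.basis.shells
            self._store[key] = eri_quartet(sh[i], sh[j], sh[k], sh[l])
        return self._store[key]

    def dense_tensor(self, screen: "SchwarzScreen | None" = None
                     ) -> np.ndarray | None:
        """(mn|ts) with every canonical quartet distributed to its eight
        index permutations; None when the system is too large."""
        n = self.basis.n_ao
        if n > self.DENSE_LIMIT:
            return None
        key = -1.0 if screen is None else screen.threshold
        if key not in self._dense:
            T = np.zeros((n, n, n, n))
            offs = self.basis.ao_offsets
            sh = self.basis.shells
            for i, j, k, l in canonical_quartets(self.basis.n_shells):
                if screen is not None and not screen.keep(i, j, k, l):
                    continue
                blk = self.block(i, j, k, l)
                for (p, q, r, s), perm in _distinct_permutations(i, j, k, l):
                    T[offs[p]:offs[p] + sh[p].n_sph,
                      offs[q]:offs[q] + sh[q].n_sph,
                      offs[r]:offs[r] + sh[r].n_sph,
                      offs[s]:offs[s] + sh[s].n_sph] = \
                        np.transpose(blk, perm)
            self._dense[key] = T
        return self._dense[key]


def _distinct_permutations(i, j, k, l):
    seen = set()
    for (p, q, r, s), (ti, tj, tk, tl) in (
        ((i, j, k, l), (0, 1, 2, 3)),
        ((j, i, k, l), (1, 0, 2, 3)),
        ((i, j, l, k), (0, 1, 3, 2)),
        ((j, i, l, k), (1, 0, 3, 2)),
        ((k, l, i, j), (2, 3, 0, 1)),
        ((l, k, i, j), (3, 2, 0, 1)),
        ((k, l, j, i), (2, 3, 1, 0)),
        ((l, k, j, i), (3, 2, 1, 0)),
    ):
        if (p, q, r, s) not in seen:
            seen.add((p, q, r, s))
            yield (p, q, r, s), (ti, tj, tk, tl)


def contract_density(basis: AOBasis, D: np.ndarray, c_x: float,
                     screen: SchwarzScreen | None = None,
                     cache: ERICache | None = None) -> np.ndarray:
    """Step 9 work-horse: F_mn = sum_ts D_ts [2(mn|ts) - c_x (ms|tn)].

    D may be non-symmetric (response densities); the quartet loop visits
    canonical quartets and distributes every distinct index permutation.
    """
    n = basis.n_ao
    if D.shape != (n, n):
        raise ValueError(f"density shape {D.shape} != ({n},{n})")
    F = np.zeros((n, n))
    offs = basis.ao_offsets
    sh = basis.shells
    cache = cache or ERICache(basis)
    for i, j, k, l in canonical_quartets(basis.n_shells):
        if screen is not None and not screen.keep(i, j, k, l):
            continue
        blk = cache.block(i, j, k, l)
        for (p, q, r, s), perm in _distinct_permutations(i, j, k, l):
            g = np.transpose(blk, perm)
            sp = slice(offs[p], offs[p] + sh[p].n_sph)
            sq = slice(offs[q], offs[q] + sh[q].n_sph)
            sr = slice(offs[r], offs[r] + sh[r].n_sph)
            ss = slice(offs[s], offs[s] + sh[s].n_sph)
            # Coulomb: F_pq += 2 (pq|rs) D_rs
            F[sp, sq] += 2.0 * np.einsum("pqrs,rs->pq", g, D[sr, ss])
            # Exchange: with (mu,phi,theta,nu) = (p,q,r,s),
            # F_ps -= c_x (pq|rs) D_rq
            if c_x != 0.0:
                F[sp, ss] -= c_x * np.einsum("pqrs,rq->ps", g, D[sr, sq])
    return F


def build_fock_2e(basis: AOBasis, D: np.ndarray, c_x: float = 1.0,
                  screen: SchwarzScreen | None = None,
                  cache: ERICache | None = None,
                  method: str = "auto") -> np.ndarray:
    """Closed-shell two-electron Fock matrix G_mn = sum_ts D_ts
    [2(mn|ts) - c_x (ms|tn)].

    method 'quartets' distributes quartet blocks one by one; 'auto' uses
    the cached dense distributed tensor when the system is small enough
    (identical result, amortized over repeated builds)."""
    if method == "auto" and cache is not None:
        T = cache.dense_tensor(screen)
        if T is not None:
            n = basis.n_ao
            if D.shape != (n, n):
                raise ValueError(f"density shape {D.shape} != ({n},{n})")
            G = 2.0 * np.einsum("mnts,ts->mn", T, D)
            if c_x != 0.0:
                G -= c_x * np.einsum("mstn,ts->mn", T, D)
            return G
    return contract_density(basis, D, c_x, screen, cache)


def full_eri_tensor(basis: AOBasis) -> np.ndarray:
    """Dense (mn|ts) tensor via the quartet engine (small systems only):
    canonical quartets evaluated once, distributed to all permutations."""
    limit, ERICache.DENSE_LIMIT = ERICache.DENSE_LIMIT, basis.n_ao
    try:
        return ERICache(basis).dense_tensor()
    finally:
        ERICache.DENSE_LIMIT = limit
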