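"""One-electron integrals and their geometric derivatives.

Overlap, kinetic-energy, nuclear-attraction and electric-dipole matrices
over contracted spherical Gaussians, plus first and second derivatives
with respect to nuclear displacements.

Base integrals use Hermite (McMurchie-Davidson) expansions; geometric
derivatives are produced by the angular-momentum shift relation on
primitives -- d/dA_i raises the target component with 2*alpha and lowers
it with the Cartesian quantum number -- the same differentiation rule the
two-electron derivative recursions use.  Operator-center derivatives of
the nuclear attraction follow from translational invariance of each
single-nucleus term.

All per-primitive tables of a shell pair are built once (1D product
tables for the multiplicative operators, dense Hermite-contracted
Coulomb tensors per nucleus); every derivative block is then an array
transformation of those tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .basis import AOBasis, GaussianShell
from .boys import boys
from .molecule import Molecule
from .spherical import cart_components, cart_to_spherical_raw


class LinearDependenceError(ValueError):
    pass


class UnsupportedOrderError(ValueError):
    pass


@dataclass
class OneElectronSet:
    S: np.ndarray
    T_kin: np.ndarray
    V_nuc: np.ndarray
    D_dip: np.ndarray  # (3, n_ao, n_ao), origin-fixed, e*bohr
    dipole_origin: np.ndarray


@dataclass
class DerivativeOneElectronSet:
    """First (and optionally second) geometric derivatives.

    dS, dT, dV: (n_atoms, 3, n_ao, n_ao); dDip: (n_atoms, 3, 3, n_ao, n_ao)
    with the dipole component as the third axis.  Second derivatives d2S,
    d2T, d2V: (n_atoms, 3, n_atoms, 3, n_ao, n_ao).
    """

    order: int
    dS: np.ndarray
    dT: np.ndarray
    dV: np.ndarray
    dDip: np.ndarray
    d2S: np.ndarray | None = None
    d2T: np.ndarray | None = None
    d2V: np.ndarray | None = None


# -------------------------------------------------------- primitive tables

def _overlap_1d(a, b, A, B, imax, jmax):
    """1D overlap tables S[d][i, j], one per Cartesian direction."""
    p = a + b
    mu = a * b / p
    out = []
    for d in range(3):
        S = np.zeros((imax + 1, jmax + 1))
        S[0, 0] = math.sqrt(math.pi / p) * math.exp(-mu * (A[d] - B[d]) ** 2)
        XPA = (a * A[d] + b * B[d]) / p - A[d]
        XPB = (a * A[d] + b * B[d]) / p - B[d]
        for i in range(imax + 1):
            for j in range(jmax + 1):
                if i == 0 and j == 0:
                    continue
                if j == 0:
                    v = XPA * S[i - 1, 0]
                    if i >= 2:
                        v += (i - 1) * S[i - 2, 0] / (2 * p)
                else:
                    v = XPB * S[i, j - 1]
                    if j >= 2:
                        v += (j - 1) * S[i, j - 2] / (2 * p)
                    if i >= 1:
                        v += i * S[i - 1, j - 1] / (2 * p)
                S[i, j] = v
        out.append(S)
    return out


def _hermite_e(a, b, A, B, imax, jmax):
    p = a + b
    mu = a * b / p
    out = []
    for d in range(3):
        E = np.zeros((imax + 1, jmax + 1, imax + jmax + 2))
        E[0, 0, 0] = math.exp(-mu * (A[d] - B[d]) ** 2)
        XPA = (a * A[d] + b * B[d]) / p - A[d]
        XPB = (a * A[d] + b * B[d]) / p - B[d]
        for i in range(imax + 1):
            for j in range(jmax + 1):
                if i == 0 and j == 0:
                    continue
                src = E[i - 1, 0] if j == 0 else E[i, j - 1]
                X = XPA if j == 0 else XPB
                for t in range(i + j + 1):
                    v = X * src[t] + (t + 1) * src[t + 1]
                    if t >= 1:
                        v += src[t - 1] / (2 * p)
                    E[i, j, t] = v
        out.append(E)
    return out


def _hermite_r(p, PC, tmax):
    T = p * float(PC @ PC)
    F = boys(tmax, T)
    base = (-2.0 * p) ** np.arange(tmax + 1) * F
    R = np.zeros((tmax + 2, tmax + 1, tmax + 1, tmax + 1))
    R[: tmax + 1, 0, 0, 0] = base
    for n in range(tmax - 1, -1, -1):
        for t in range(tmax - n + 1):
            for u in range(tmax - n - t + 1):
                for v in range(tmax - n - t - u + 1):
                    if t + u + v == 0:
                        continue
                    if t > 0:
                        val = PC[0] * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * R[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = PC[1] * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * R[n + 1, t, u - 2, v]
                    else:
                        val = PC[2] * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * R[n + 1, t, u, v - 2]
                    R[n, t, u, v] = val
    return R[0]


# --------------------------------------------------- shift-relation operators

def _shift_nd(V: np.ndarray, exp, axis: int) -> np.ndarray:
    """Shift-relation derivative along one axis of a dense tensor; ``exp``
    may be a scalar or an array broadcastable against V."""
    out = np.zeros_like(V)
    n = V.shape[axis]
    sl_lo = [slice(None)] * V.ndim
    sl_hi = [slice(None)] * V.ndim
    sl_lo[axis] = slice(0, n - 1)
    sl_hi[axis] = slice(1, n)
    out[tuple(sl_lo)] = 2.0 * exp * V[tuple(sl_hi)]
    shape = [1] * V.ndim
    shape[axis] = n - 1
    i = np.arange(1, n).reshape(shape)
    out[tuple(sl_hi)] -= i * V[tuple(sl_lo)]
    return out


class _PairEngine:
    """All one-electron integral blocks of one shell pair.

    Primitive tables are sized for derivative orders up to ``max_da`` /
    ``max_db`` on centers A and B and stacked over the primitive-pair
    axis (and, for the Coulomb tensors, over the nuclei); block() then
    evaluates any requested kind and derivative spec as a handful of
    array transformations.
    """

    def __init__(self, sha: GaussianShell, shb: GaussianShell,
                 max_da: int = 0, max_db: int = 0, nuclei=None, origin=None):
        self.sha, self.shb = sha, shb
        self.nuclei = nuclei or []
        self.origin = origin
        la, lb = sha.l, shb.l
        imax = la + max_da
        jmax = lb + max_db
        self.comps_a = cart_components(la)
        self.comps_b = cart_components(lb)
        self.ia = np.array(self.comps_a)          # (ncart_a, 3)
        self.jb = np.array(self.comps_b)
        exps_a, exps_b, weights, S1s, Vs = [], [], [], [], []
        for pa in range(sha.n_prim):
            for pb in range(shb.n_prim):
                a, b = float(sha.exponents[pa]), float(shb.exponents[pb])
                exps_a.append(a)
                exps_b.append(b)
                weights.append(float(sha.coefficients[pa]
                                     * shb.coefficients[pb]))
                S1s.append(_overlap_1d(a, b, sha.center, shb.center,
                                       imax + 1, jmax + 3))
                if self.nuclei:
                    p = a + b
                    P = (a * sha.center + b * shb.center) / p
                    E = _hermite_e(a, b, sha.center, shb.center, imax, jmax)
                    nt = imax + jmax + 1
                    Vk = []
                    for _Z, C in self.nuclei:
                        R = _hermite_r(p, P - np.asarray(C), imax + jmax)
                        Vk.append(2.0 * math.pi / p * np.einsum(
                            "adt,beu,cfv,tuv->abcdef",
                            E[0][:, :, :nt], E[1][:, :, :nt],
                            E[2][:, :, :nt], R, optimize=True))
                    Vs.append(Vk)
        self.a = np.array(exps_a)                 # (np,)
        self.b = np.array(exps_b)
        self.w = np.array(weights)
        # S1[d]: (np, imax+2, jmax+4)
        self.S1 = [np.stack([s[d] for s in S1s]) for d in range(3)]
        if self.nuclei:
            # V: (np, n_nuc, ia, iya, iza, jxb, jyb, jzb)
            self.V = np.stack([np.stack(v) for v in Vs])
        self.Z = np.array([z for z, _c in self.nuclei])

    # -- stacked 1D tables -------------------------------------------------
    def _kin_tables(self):
        b = self.b[:, None, None]
        out = []
        for S in self.S1:
            j = np.arange(S.shape[2])
            K = -2.0 * b * (2 * j + 1)[None, None, :] * S
            K[:, :, :-2] += 4.0 * b * b * S[:, :, 2:]
            K[:, :, 2:] += (j[2:] * (j[2:] - 1))[None, None, :] * S[:, :, :-2]
            out.append(-0.5 * K)
        return out

    def _dip_tables(self, comp):
        b_to_o = self.shb.center[comp] - self.origin[comp]
        S = self.S1[comp]
        D = np.zeros_like(S)
        D[:, :, :-1] = S[:, :, 1:]
        D += b_to_o * S
        out = list(self.S1)
        out[comp] = D
        return out

    def _apply_ops(self, tables, da, db):
        a = self.a[:, None, None]
        b = self.b[:, None, None]
        tables = list(tables)
        for d in da:
            T = tables[d]
            out = np.zeros_like(T)
            out[:, :-1] = 2.0 * a * T[:, 1:]
            out[:, 1:] -= np.arange(1, T.shape[1])[None, :, None] * T[:, :-1]
            tables[d] = out
        for d in db:
            T = tables[d]
            out = np.zeros_like(T)
            out[:, :, :-1] = 2.0 * b * T[:, :, 1:]
            out[:, :, 1:] -= np.arange(1, T.shape[2])[None, None, :] \
                * T[:, :, :-1]
            tables[d] = out
        return tables

    def _gather(self, tables):
        """Weight-contract per-dimension stacked tables into the
        (ncart_a, ncart_b) block."""
        blk = tables[0][:, self.ia[:, 0]][:, :, self.jb[:, 0]]
        for d in (1, 2):
            blk = blk * tables[d][:, self.ia[:, d]][:, :, self.jb[:, d]]
        return np.tensordot(self.w, blk, axes=(0, 0))

    # -- public block evaluation ------------------------------------------
    def block(self, kind: str, da=(), db=(), nucleus: int | None = None
              ) -> np.ndarray:
        """Contracted raw-Cartesian block; kind in {'S','T','D','Vk'}.

        'D' returns (3, ncart_a, ncart_b); 'Vk' is the positive
        single-nucleus Coulomb integral block for ``nucleus``.
        """
        if kind == "S":
            return self._gather(self._apply_ops(self.S1, da, db))
        if kind == "T":
            K = self._kin_tables()
            out = 0.0
            for dim in range(3):
                mixed = [K[d] if d == dim else self.S1[d] for d in range(3)]
                out = out + self._gather(self._apply_ops(mixed, da, db))
            return out
        if kind == "D":
            return np.stack([
                self._gather(self._apply_ops(self._dip_tables(c), da, db))
                for c in range(3)])
        if kind == "Vk":
            V = self._v_deriv(da, db)[:, nucleus]
            blk = V[:, self.ia[:, 0], self.ia[:, 1], self.ia[:, 2]][
                :, :, self.jb[:, 0], self.jb[:, 1], self.jb[:, 2]]
            return np.tensordot(self.w, blk, axes=(0, 0))
        raise ValueError(kind)

    def _v_deriv(self, da, db):
        V = self.V
        exp_a = self.a.reshape(-1, 1, 1, 1, 1, 1, 1, 1)
        exp_b = self.b.reshape(-1, 1, 1, 1, 1, 1, 1, 1)
        for d in da:
            V = _shift_nd(V, exp_a, 2 + d)
        for d in db:
            V = _shift_nd(V, exp_b, 5 + d)
        return V

    def v_blocks_all_nuclei(self, da=(), db=()) -> np.ndarray:
        """Positive Coulomb blocks for every nucleus at once:
        (n_nuclei, ncart_a, ncart_b)."""
        V = self._v_deriv(da, db)
        blk = V[:, :, self.ia[:, 0], self.ia[:, 1], self.ia[:, 2]][
            :, :, :, self.jb[:, 0], self.jb[:, 1], self.jb[:, 2]]
        return np.tensordot(self.w, blk, axes=(0, 0))

    def v_total(self, da=(), db=()) -> np.ndarray:
        """-sum_k Z_k <a|1/|r-C_k||b> with the requested derivatives."""
        blocks = self.v_blocks_all_nuclei(da, db)
        return -np.tensordot(self.Z, blocks, axes=(0, 0))


# ------------------------------------------------------------- shell drivers

def _sph(sha, shb, block):
    ta = cart_to_spherical_raw(sha.l)
    tb = cart_to_spherical_raw(shb.l)
    return np.einsum("pc,...cd,qd->...pq", ta, block, tb)


def _pairs(basis: AOBasis):
    for i, sha in enumerate(basis.shells):
        for j, shb in enumerate(basis.shells):
            if j <= i:
                yield i, j, sha, shb


def default_dipole_origin(molecule: Molecule) -> np.ndarray:
    return molecule.center_of_nuclear_charge()


def one_electron_matrices(molecule: Molecule, basis: AOBasis,
                          origin: np.ndarray | None = None,
                          strict: bool = False) -> OneElectronSet:
    """Overlap, kinetic, nuclear-attraction and dipole matrices."""
    n = basis.n_ao
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    D = np.zeros((3, n, n))
    if origin is None:
        origin = default_dipole_origin(molecule)
    nuclei = [(z, c) for z, c in zip(molecule.charges, molecule.coords)]
    for i, j, sha, shb in _pairs(basis):
        eng = _PairEngine(sha, shb, nuclei=nuclei, origin=origin)
        oa = slice(basis.ao_offsets[i], basis.ao_offsets[i] + sha.n_sph)
        ob = slice(basis.ao_offsets[j], basis.ao_offsets[j] + shb.n_sph)
        bS = _sph(sha, shb, eng.block("S"))
        bT = _sph(sha, shb, eng.block("T"))
        bV = _sph(sha, shb, eng.v_total())
        bD = _sph(sha, shb, eng.block("D"))
        S[oa, ob] = bS
        T[oa, ob] = bT
        V[oa, ob] = bV
        D[:, oa, ob] = bD
        if i != j:
            S[ob, oa] = bS.T
            T[ob, oa] = bT.T
            V[ob, oa] = bV.T
            D[:, ob, oa] = np.transpose(bD, (0, 2, 1))
    smallest = np.linalg.eigvalsh(S)[0]
    if smallest < 1e-10:
        msg = (f"overlap matrix near-singular "
               f"(smallest eigenvalue {smallest:.3e})")
        if strict:
            raise LinearDependenceError(msg)
        import warnings

        warnings.warn(msg)
    return OneElectronSet(S, T, V, D, np.asarray(origin, float))


def one_electron_derivatives(molecule: Molecule, basis: AOBasis,
                             order: int = 1,
                             origin: np.ndarray | None = None
                             ) -> DerivativeOneElectronSet:
    """First (order=1) or first+second (order=2) geometric derivatives."""
    if order not in (1, 2):
        raise UnsupportedOrderError(f"derivative order {order} not supported")
    n = basis.n_ao
    na = molecule.n_atoms
    if origin is None:
        origin = default_dipole_origin(molecule)
    nuclei = [(z, c) for z, c in zip(molecule.charges, molecule.coords)]
    dS = np.zeros((na, 3, n, n))
    dT = np.zeros((na, 3, n, n))
    dV = np.zeros((na, 3, n, n))
    dD = np.zeros((na, 3, 3, n, n))
    d2S = d2T = d2V = None
    if order == 2:
        d2S = np.zeros((na, 3, na, 3, n, n))
        d2T = np.zeros((na, 3, na, 3, n, n))
        d2V = np.zeros((na, 3, na, 3, n, n))

    Zv = np.array([z for z, _c in nuclei])
    for i, j, sha, shb in _pairs(basis):
        eng = _PairEngine(sha, shb, max_da=order, max_db=order,
                          nuclei=nuclei, origin=origin)
        oa = slice(basis.ao_offsets[i], basis.ao_offsets[i] + sha.n_sph)
        ob = slice(basis.ao_offsets[j], basis.ao_offsets[j] + shb.n_sph)
        atA, atB = sha.center_index, shb.center_index
        nca, ncb = sha.n_cart, shb.n_cart

        def scatter(target, cart):
            """Spherical-transform a (..., nca, ncb) stack and accumulate
            into the matching (..., n_ao, n_ao) target."""
            s = _sph(sha, shb, cart)
            target[..., oa, ob] += s
            if i != j:
                target[..., ob, oa] += np.swapaxes(s, -1, -2)

        # ---- first derivatives
        cS = np.zeros((na, 3, nca, ncb))
        cT = np.zeros((na, 3, nca, ncb))
        cD = np.zeros((na, 3, 3, nca, ncb))
        cV = np.zeros((na, 3, nca, ncb))
        for d in range(3):
            cS[atA, d] += eng.block("S", da=(d,))
            cS[atB, d] += eng.block("S", db=(d,))
            cT[atA, d] += eng.block("T", da=(d,))
            cT[atB, d] += eng.block("T", db=(d,))
            cD[atA, d] += eng.block("D", da=(d,))
            cD[atB, d] += eng.block("D", db=(d,))
            vA = eng.v_blocks_all_nuclei(da=(d,))   # (n_nuc, nca, ncb)
            vB = eng.v_blocks_all_nuclei(db=(d,))
            cV[atA, d] -= np.tensordot(Zv, vA, axes=(0, 0))
            cV[atB, d] -= np.tensordot(Zv, vB, axes=(0, 0))
            cV[:, d] += Zv[:, None, None] * (vA + vB)
        scatter(dS, cS)
        scatter(dT, cT)
        scatter(dD, cD)
        scatter(dV, cV)

        if order != 2:
            continue

        # ---- second derivatives, S and T: role pairs (A,A), (A,B), (B,B)
        for kind, tgt in (("S", d2S), ("T", d2T)):
            AA = {(p, q): eng.block(kind, da=(p, q))
                  for p in range(3) for q in range(p, 3)}
            AB = {(p, q): eng.block(kind, da=(p,), db=(q,))
                  for p in range(3) for q in range(3)}
            BB = {(p, q): eng.block(kind, db=(p, q))
                  for p in range(3) for q in range(p, 3)}

            def r2(rp, p, rq, q):
                if rp == "A" and rq == "A":
                    return AA[(p, q) if p <= q else (q, p)]
                if rp == "B" and rq == "B":
                    return BB[(p, q) if p <= q else (q, p)]
                if rp == "A":
                    return AB[(p, q)]
                return AB[(q, p)]

            cart = np.zeros((na, 3, na, 3, nca, ncb))
            for p in range(3):
                for q in range(3):
                    for rp, atX in (("A", atA), ("B", atB)):
                        for rq, atY in (("A", atA), ("B", atB)):
                            cart[atX, p, atY, q] += r2(rp, p, rq, q)
            scatter(tgt, cart)

        # ---- second derivatives, V with operator-center roles
        AA = {(p, q): eng.v_blocks_all_nuclei(da=(p, q))
              for p in range(3) for q in range(p, 3)}
        AB = {(p, q): eng.v_blocks_all_nuclei(da=(p,), db=(q,))
              for p in range(3) for q in range(3)}
        BB = {(p, q): eng.v_blocks_all_nuclei(db=(p, q))
              for p in range(3) for q in range(p, 3)}

        def r2v(rp, p, rq, q):
            if rp == "C" and rq == "C":
                return (r2v("A", p, "A", q) + r2v("A", p, "B", q)
                        + r2v("B", p, "A", q) + r2v("B", p, "B", q))
            if rp == "C":
                return -(r2v("A", p, rq, q) + r2v("B", p, rq, q))
            if rq == "C":
                return -(r2v(rp, p, "A", q) + r2v(rp, p, "B", q))
            if rp == "A" and rq == "A":
                return AA[(p, q) if p <= q else (q, p)]
            if rp == "B" and rq == "B":
                return BB[(p, q) if p <= q else (q, p)]
            if rp == "A":
                return AB[(p, q)]
            return AB[(q, p)]

        cart = np.zeros((na, 3, na, 3, nca, ncb))
        for p in range(3):
            for q in range(3):
                for rp in ("A", "B", "C"):
                    for rq in ("A", "B", "C"):
                        blk = r2v(rp, p, rq, q)   # (n_nuc, nca, ncb)
                        wblk = -Zv[:, None, None] * blk
                        if rp == "C" and rq == "C":
                            cart[:, p, :, q][np.arange(na), np.arange(na)] \
                                += wblk
                        elif rp == "C":
                            atY = atA if rq == "A" else atB
                            cart[:, p, atY, q] += wblk
                        elif rq == "C":
                            atX = atA if rp == "A" else atB
                            cart[atX, p, :, q] += wblk
                        else:
                            atX = atA if rp == "A" else atB
                            atY = atA if rq == "A" else atB
                            cart[atX, p, atY, q] += np.tensordot(
                                -Zv, blk, axes=(0, 0))
        scatter(d2V, cart)

    return DerivativeOneElectronSet(order, dS, dT, dV, dD, d2S, d2T, d2V)
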