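"""Greedy Orthogonal Matching Pursuit (OMP) sparse coding.

OMP is Step 1 of the alternating dictionary-learning scheme: with the
dictionary fixed, each signal column is approximated by at most k atoms,
greedily selecting at every iteration the atom most correlated with the
current residual and re-solving the least-squares problem on the selected
support.

Two entry points are provided:

``omp_encode``
    single-signal reference form, solving the active-set least squares by
    QR/SVD factorization (never normal equations);

``sparse_code_batch``
    a vectorized batch form that runs all L columns in lockstep using the
    precomputed Gram matrix and progressive Cholesky updates, mathematically
    equivalent to the column-by-column form.

The sparsifier is a named strategy (``SparsifierSpec``) so that other
sparse decomposition methods could be plugged in later; only OMP ships.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .signal_model import Dictionary, SignalSet, SparseCodeMatrix

__all__ = ["SparsifierSpec", "omp_encode", "sparse_code_batch"]

# guard against selecting atoms from a numerically-zero residual; relative
# to the signal norm so the rule is scale invariant
_REL_RESIDUAL_FLOOR = 1e-12
# the batch engines track ||r||^2 by subtraction, which carries cancellation
# noise of order eps * ||y||^2; stop once the tracked value sinks below this
# relative floor (residual ~1e-7 of the signal: numerically exact fit)
_REL_RES2_FLOOR = 1e-14


@dataclass(frozen=True)
class SparsifierSpec:
    """Configuration of the per-column sparse decomposition.

    Parameters
    ----------
    k : int
        Per-column budget of nonzero coefficients (runs exactly k greedy
        iterations unless the residual hits ``residual_tolerance`` early).
    residual_tolerance : float
        Early-stop threshold on the l2 residual norm; the default 0
        reproduces fixed-k behavior.
    name : str
        Sparsifier identifier; only ``"omp"`` is implemented.
    """

    k: int
    residual_tolerance: float = 0.0
    name: str = "omp"

    def __post_init__(self):
        if self.name != "omp":
            raise ValueError(f"unknown sparsifier {self.name!r}; only 'omp' ships")
        if self.k < 1:
            raise ValueError("sparsity k must be >= 1")
        if self.residual_tolerance < 0:
            raise ValueError("residual_tolerance must be nonnegative")


def _dict_matrix(D) -> np.ndarray:
    if isinstance(D, Dictionary):
        return D.D
    return np.asarray(D, dtype=float)


def omp_encode(y, D, spec: SparsifierSpec) -> np.ndarray:
    """Encode a single signal, returning a dense length-m coefficient vector.

    Ties in |correlation| break toward the lowest atom index; on the selected
    support the coefficients are the least-squares solution and the residual
    is orthogonal to the span of the selected atoms.
    """
    Dd = _dict_matrix(D)
    y = np.asarray(y, dtype=float).ravel()
    n, m = Dd.shape
    if y.shape[0] != n:
        raise ValueError(f"signal length {y.shape[0]} != dictionary rows {n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("signal contains non-finite entries")
    if spec.k > n:
        raise ValueError(f"sparsity k={spec.k} exceeds signal dimension n={n}")

    tol = max(spec.residual_tolerance, _REL_RESIDUAL_FLOOR * np.linalg.norm(y))
    x = np.zeros(m)
    support: list[int] = []
    residual = y.copy()
    coef = np.empty(0)
    for _ in range(spec.k):
        if np.linalg.norm(residual) <= tol:
            break
        corr = np.abs(Dd.T @ residual)
        corr[support] = -1.0  # never reselect an atom
        j = int(np.argmax(corr))  # argmax takes the first maximum: lowest index
        support.append(j)
        sub = Dd[:, support]
        coef, *_ = np.linalg.lstsq(sub, y, rcond=None)
        residual = y - sub @ coef
    x[support] = coef
    return x


def sparse_code_batch(Y, D, spec: SparsifierSpec,
                      engine: str = "auto") -> SparseCodeMatrix:
    """Encode every column of Y; column i equals ``omp_encode(Y[:, i], D, spec)``.

    Uses the Gram-matrix/progressive-Cholesky formulation of OMP.  Two
    interchangeable engines implement it: a compiled per-column kernel
    (``"numba"``, used by default when numba is importable) and a pure-NumPy
    lockstep form (``"numpy"``) that vectorizes the per-iteration argmax,
    triangular solves and correlation updates across signals.  Columns are
    independent, so both match the single-signal loop.
    """
    Dd = _dict_matrix(D)
    Yd = Y.Y if isinstance(Y, SignalSet) else np.asarray(Y, dtype=float)
    n, m = Dd.shape
    if Yd.ndim != 2 or Yd.shape[0] != n:
        raise ValueError(f"Y must be {n} x L, got {Yd.shape}")
    if not np.all(np.isfinite(Yd)):
        bad = int(np.flatnonzero(~np.all(np.isfinite(Yd), axis=0))[0])
        raise ValueError(f"non-finite entries in signal column {bad}")
    if spec.k > n:
        raise ValueError(f"sparsity k={spec.k} exceeds signal dimension n={n}")

    L = Yd.shape[1]
    k = spec.k
    G = Dd.T @ Dd

    if engine not in ("auto", "numba", "numpy"):
        raise ValueError(f"unknown engine {engine!r}")
    use_numba = engine == "numba" or (engine == "auto" and _numba_kernel() is not None)

    cols_idx = np.empty((L, k), dtype=np.int64)
    cols_val = np.empty((L, k), dtype=float)
    cols_len = np.zeros(L, dtype=np.int64)

    if use_numba:
        kernel = _numba_kernel()
        if kernel is None:
            raise RuntimeError("numba requested but not importable")
        A0 = Yd.T @ Dd  # (L, m) C-contiguous, one correlation row per signal
        ynorm2 = np.einsum("ij,ij->j", Yd, Yd)
        tol = np.maximum(spec.residual_tolerance,
                         _REL_RESIDUAL_FLOOR * np.sqrt(ynorm2))
        kernel(np.ascontiguousarray(G), A0, ynorm2, k, tol,
               cols_idx, cols_val, cols_len)
    else:
        # chunk columns so the (m, B, k) gathered-Gram workspace stays ~tens of MB
        B = max(64, min(L, int(4e6 / max(m * k, 1))))
        for start in range(0, L, B):
            Yc = Yd[:, start : start + B]
            bsz = Yc.shape[1]
            _omp_chunk(
                Yc, Dd, G, k, spec.residual_tolerance,
                cols_idx[start : start + bsz],
                cols_val[start : start + bsz],
                cols_len[start : start + bsz],
            )

    indptr = np.zeros(L + 1, dtype=np.int64)
    np.cumsum(cols_len, out=indptr[1:])
    keep = np.arange(k)[None, :] < cols_len[:, None]  # ragged-row mask
    X = sp.csc_array((cols_val[keep], cols_idx[keep], indptr), shape=(m, L))
    return SparseCodeMatrix(X=X, k=k)


def _omp_chunk(Yc, Dd, G, k, tol, out_idx, out_val, out_len):
    """Lockstep OMP over one chunk of columns (results written in place)."""
    m = G.shape[0]
    bsz = Yc.shape[1]
    A0 = Dd.T @ Yc  # (m, B) initial correlations
    alpha = A0.copy()
    ynorm2 = np.einsum("ij,ij->j", Yc, Yc)
    eff_tol2 = np.maximum(
        np.maximum(tol, _REL_RESIDUAL_FLOOR * np.sqrt(ynorm2)) ** 2,
        _REL_RES2_FLOOR * ynorm2,
    )
    res2 = ynorm2.copy()

    sel = np.zeros((bsz, k), dtype=np.int64)
    Lch = np.zeros((bsz, k, k))  # progressive Cholesky of G on the support
    z = np.zeros((bsz, k))  # z = L^{-1} A0_S  (so ||r||^2 = ||y||^2 - z.z)
    x = np.zeros((bsz, k))
    Gsel = np.empty((m, bsz, k))  # Gram columns of selected atoms
    a0sel = np.zeros((bsz, k))
    taken = np.zeros((bsz, m), dtype=bool)
    nsel = np.zeros(bsz, dtype=np.int64)

    active = res2 > eff_tol2
    for t in range(k):
        if not active.any():
            break
        absa = np.abs(alpha)
        absa[taken.T] = -1.0
        j = np.argmax(absa, axis=0)  # first maximum: lowest index on ties

        act = np.flatnonzero(active)
        ja = j[act]
        # Cholesky update: solve L[:t,:t] w = G[sel[:t], j] per active column
        g_new = G[sel[act, :t], ja[:, None]] if t > 0 else np.empty((act.size, 0))
        w = np.empty((act.size, t))
        for i in range(t):
            w[:, i] = g_new[:, i] - np.einsum(
                "bj,bj->b", Lch[act, i, :i], w[:, :i]
            )
            w[:, i] /= Lch[act, i, i]
        d2 = 1.0 - np.einsum("bj,bj->b", w, w)
        # an atom (numerically) inside the selected span cannot extend the
        # support; freeze those columns
        ok = d2 > 1e-12
        if not ok.all():
            active[act[~ok]] = False
            act = act[ok]
            ja = ja[ok]
            w = w[ok]
            d2 = d2[ok]
            if act.size == 0:
                continue

        Lch[act, t, :t] = w
        Lch[act, t, t] = np.sqrt(d2)
        sel[act, t] = ja
        taken[act, ja] = True
        a0sel[act, t] = A0[ja, act]
        Gsel[:, act, t] = G[:, ja]  # Gram columns of the newly selected atoms
        nsel[act] = t + 1

        # z update: one new forward-substitution row
        z[act, t] = (
            a0sel[act, t]
            - np.einsum("bj,bj->b", Lch[act, t, :t], z[act, :t])
        ) / Lch[act, t, t]
        res2[act] = ynorm2[act] - np.einsum("bj,bj->b", z[act, : t + 1], z[act, : t + 1])

        # back-substitution L^T x = z for the current support size
        tt = t + 1
        xa = np.empty((act.size, tt))
        for i in range(tt - 1, -1, -1):
            xa[:, i] = z[act, i] - np.einsum(
                "bj,bj->b", Lch[act, i + 1 : tt, i], xa[:, i + 1 : tt]
            )
            xa[:, i] /= Lch[act, i, i]
        x[act, :tt] = xa

        if tt < k:
            # refresh correlations: alpha = A0 - G_S x_S  (active columns only)
            alpha[:, act] = A0[:, act] - np.einsum(
                "mbt,bt->mb", Gsel[:, act, :tt], xa
            )
        active[act] = res2[act] > eff_tol2[act]

    out_len[:] = nsel
    out_idx[:, :] = sel
    out_val[:, :] = x


_NUMBA_KERNEL = None
_NUMBA_TRIED = False


def _numba_kernel():
    """Compile (once) and return the per-column OMP kernel, or None if
    numba is unavailable."""
    global _NUMBA_KERNEL, _NUMBA_TRIED
    if _NUMBA_TRIED:
        return _NUMBA_KERNEL
    _NUMBA_TRIED = True
    try:
        import numba
    except ImportError:
        return None

    @numba.njit(cache=False, fastmath=False)
    def kernel(G, A0, ynorm2, k, tol, out_idx, out_val, out_len):
        m = G.shape[0]
        L = A0.shape[0]
        alpha = np.empty(m)
        taken = np.zeros(m, numba.boolean)
        sel = np.empty(k, np.int64)
        Lch = np.empty((k, k))
        w = np.empty(k)
        z = np.empty(k)
        x = np.empty(k)
        for i in range(L):
            a0 = A0[i]
            for j in range(m):
                alpha[j] = a0[j]
                taken[j] = False
            res2 = ynorm2[i]
            tol2 = max(tol[i] * tol[i], 1e-14 * ynorm2[i])
            t = 0
            while t < k and res2 > tol2:
                # first maximum of |alpha| over unselected atoms (lowest index wins)
                best = -1
                bv = -1.0
                for j in range(m):
                    if taken[j]:
                        continue
                    a = abs(alpha[j])
                    if a > bv:
                        bv = a
                        best = j
                # progressive Cholesky of the support Gram matrix
                for r in range(t):
                    acc = G[sel[r], best]
                    for c in range(r):
                        acc -= Lch[r, c] * w[c]
                    w[r] = acc / Lch[r, r]
                d2 = 1.0
                for r in range(t):
                    d2 -= w[r] * w[r]
                if d2 <= 1e-12:
                    break  # atom numerically inside the selected span
                for r in range(t):
                    Lch[t, r] = w[r]
                Lch[t, t] = np.sqrt(d2)
                sel[t] = best
                taken[best] = True
                acc = a0[best]
                for r in range(t):
                    acc -= Lch[t, r] * z[r]
                z[t] = acc / Lch[t, t]
                res2 -= z[t] * z[t]
                t += 1
                # back substitution L^T x = z on the current support
                for r in range(t - 1, -1, -1):
                    acc = z[r]
                    for c in range(r + 1, t):
                        acc -= Lch[c, r] * x[c]
                    x[r] = acc / Lch[r, r]
                if t < k and res2 > tol2:
                    # refresh correlations: alpha = a0 - G_S x_S
                    for j in range(m):
                        alpha[j] = a0[j]
                    for r in range(t):
                        xr = x[r]
                        grow = G[sel[r]]
                        for j in range(m):
                            alpha[j] -= xr * grow[j]
            out_len[i] = t
            for r in range(t):
                out_idx[i, r] = sel[r]
                out_val[i, r] = x[r]

    _NUMBA_KERNEL = kernel
    return kernel
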