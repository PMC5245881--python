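"""Alternating dictionary learners: rotation-based group updates (R-SVD),
K-SVD, and ILS-DLA.

All three learners share the alternating scheme

    repeat T times:
        Step 1  sparse coding       X <- argmin ||Y - D X||  s.t. k-sparse columns
        Step 2  dictionary update   D <- (algorithm specific), X fixed or re-encoded

and differ only in Step 2:

* ``rsvd_learn``   partitions the atoms into groups of size s by ascending
  popularity and rotates each group by its optimal orthogonal Procrustes
  transformation (cross-products assembled from a per-sweep cache);
* ``ksvd_learn``   updates one atom at a time as the leading singular pair
  of its residual submatrix, re-encoding the nonzero coefficients;
* ``ilsdla_learn`` replaces the whole dictionary by the batch least-squares
  optimum Y X^T (X X^T)^{-1} followed by column renormalization.

Atoms that no training signal uses are replaced by the worst-represented
signal (largest column residual), normalized — the standard rescue that
keeps the dictionary from carrying dead atoms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .procrustes_update import (
    GroupIndex,
    ProductCache,
    build_cache,
    cross_product,
    _polar_rotation,
)
from .signal_model import Dictionary, SignalSet, SparseCodeMatrix, objective
from .sparse_coding import SparsifierSpec, sparse_code_batch

__all__ = [
    "LearnConfig",
    "LearnResult",
    "init_dictionary",
    "popularity_partition",
    "rsvd_learn",
    "ksvd_learn",
    "ilsdla_learn",
    "learn",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("rsvd", "ksvd", "ilsdla")


@dataclass(frozen=True)
class LearnConfig:
    """Hyper-parameters shared by all learners.

    Defaults mirror the study conditions: T=200 update iterations and group
    size s=10 (the value at which the rotation update behaves best in the
    group-size sweep).
    """

    m: int
    k: int
    s: int = 10
    T: int = 200
    seed: int = 0
    algorithm: str = "rsvd"
    sparsifier: SparsifierSpec | None = None
    use_truncated_svd: bool = True

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.k < 1 or self.m < 2 or self.T < 1:
            raise ValueError("need k >= 1, m >= 2, T >= 1")
        if self.s < 1:
            raise ValueError("group size s must be >= 1")
        # s larger than m degenerates to a single all-atom group

    @property
    def spec(self) -> SparsifierSpec:
        return self.sparsifier or SparsifierSpec(k=self.k)


@dataclass(frozen=True)
class LearnResult:
    D: Dictionary
    X: SparseCodeMatrix
    error_trace: np.ndarray  # E_SNR(Y, D X) after each iteration, dB
    objective_trace: np.ndarray  # ||Y - D X||_F^2 after each iteration
    config: LearnConfig


def init_dictionary(Y, m: int, seed: int) -> Dictionary:
    """Initialize the dictionary from m distinct training columns, normalized.

    Deterministic given the seed; zero columns are resampled (bounded
    retries) before giving up.
    """
    Yd = Y.Y if isinstance(Y, SignalSet) else np.asarray(Y, dtype=float)
    n, L = Yd.shape
    if L < m:
        raise ValueError(f"need at least m={m} training columns, got L={L}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(L, size=m, replace=False)
    norms = np.linalg.norm(Yd[:, chosen], axis=0)
    for _ in range(50):
        bad = norms <= 1e-12
        if not bad.any():
            break
        pool = np.setdiff1d(np.arange(L), chosen)
        if pool.size < bad.sum():
            raise ValueError("not enough nonzero training columns to initialize")
        chosen[bad] = rng.choice(pool, size=int(bad.sum()), replace=False)
        norms = np.linalg.norm(Yd[:, chosen], axis=0)
    else:
        raise ValueError("could not draw m nonzero training columns")
    D = Yd[:, chosen] / norms
    return Dictionary(D=D)


def popularity_partition(X, s: int) -> list[GroupIndex]:
    """Partition atom indices into G = ceil(m/s) consecutive groups after
    sorting by ascending popularity (row l0-count, ties by index).

    The last group holds the remainder m - (G-1) s indices.
    """
    if s < 1:
        raise ValueError("group size s must be >= 1")
    if isinstance(X, SparseCodeMatrix):
        usage = X.row_usage()
        m = X.m
    else:
        Xd = np.asarray(X.todense() if sp.issparse(X) else X)
        usage = np.count_nonzero(Xd, axis=1)
        m = Xd.shape[0]
    order = np.lexsort((np.arange(m), usage))  # usage primary, index tie-break
    return [GroupIndex(indices=order[i : i + s], m=m) for i in range(0, m, s)]


def _replace_unused_atoms(Yd, Dd, X: SparseCodeMatrix) -> np.ndarray:
    """Replace zero-popularity (or zero-norm) atoms by the worst-represented
    training signals, normalized.  Returns the (possibly modified) matrix."""
    usage = X.row_usage()
    dead = (usage == 0) | (np.linalg.norm(Dd, axis=0) <= 1e-12)
    n_dead = int(dead.sum())
    if n_dead == 0:
        return Dd
    resid = Yd - Dd @ X.X  # column residuals
    col_norms = np.linalg.norm(np.asarray(resid), axis=0)
    worst = np.argsort(col_norms)[::-1]
    Dd = Dd.copy()
    filled = 0
    for j in np.flatnonzero(dead):
        while filled < worst.size:
            cand = Yd[:, worst[filled]]
            filled += 1
            nrm = np.linalg.norm(cand)
            if nrm > 1e-12:
                Dd[:, j] = cand / nrm
                break
        else:
            raise ValueError("no nonzero training column available for atom rescue")
    logger.debug("replaced %d unused atom(s)", n_dead)
    return Dd


def _rank1_factors(E: np.ndarray):
    """Leading singular triple (u, sigma, v) of E via the smaller Gram matrix."""
    n, c = E.shape
    if n <= c:
        w, V = np.linalg.eigh(E @ E.T)
        u = V[:, -1]
        sigma = float(np.sqrt(max(w[-1], 0.0)))
        v = (E.T @ u) / sigma if sigma > 0 else np.zeros(c)
    else:
        w, V = np.linalg.eigh(E.T @ E)
        v = V[:, -1]
        sigma = float(np.sqrt(max(w[-1], 0.0)))
        u = (E @ v) / sigma if sigma > 0 else np.zeros(n)
    return u, sigma, v


def _update_rsvd(Yd, Dd, X: SparseCodeMatrix, cfg: LearnConfig):
    cache = build_cache(Yd, X)
    groups = popularity_partition(X, cfg.s)
    for I in groups:
        HEt = cross_product(Dd, cache, I)
        R = _polar_rotation(HEt.T, I.s if cfg.use_truncated_svd else None)
        Dd[:, I.indices] = R @ Dd[:, I.indices]
    return Dd, X


def _update_ksvd(Yd, Dd, X: SparseCodeMatrix, cfg: LearnConfig):
    kernel = _ksvd_kernel()
    if kernel is not None:
        Xr = sp.csr_array(X.X)
        Xr.sort_indices()
        resid = np.ascontiguousarray(Yd - Dd @ Xr)
        Dc = np.ascontiguousarray(Dd)  # kernel mutates Dc and Xr.data in place
        kernel(Dc, resid,
               Xr.indptr.astype(np.int64), Xr.indices.astype(np.int64),
               Xr.data)
        return Dc, SparseCodeMatrix(X=sp.csc_array(Xr), k=X.k)
    return _update_ksvd_numpy(Yd, Dd, X, cfg)


def _update_ksvd_numpy(Yd, Dd, X: SparseCodeMatrix, cfg: LearnConfig):
    Xd = X.toarray()
    resid = Yd - Dd @ Xd  # maintained incrementally across atoms
    for j in range(Dd.shape[1]):
        omega = np.flatnonzero(Xd[j])
        if omega.size == 0:
            continue  # rescued afterwards
        Ej = resid[:, omega] + np.outer(Dd[:, j], Xd[j, omega])
        u, sigma, v = _rank1_factors(Ej)
        if sigma <= 0:
            continue
        Dd[:, j] = u
        Xd[j, omega] = sigma * v
        resid[:, omega] = Ej - np.outer(u, sigma * v)
    return Dd, SparseCodeMatrix(X=sp.csc_array(Xd), k=X.k)


_KSVD_KERNEL = None
_KSVD_TRIED = False


def _ksvd_kernel():
    """Compile (once) the sequential atom-sweep kernel, or None without numba."""
    global _KSVD_KERNEL, _KSVD_TRIED
    if _KSVD_TRIED:
        return _KSVD_KERNEL
    _KSVD_TRIED = True
    try:
        import numba
    except ImportError:
        return None

    @numba.njit(cache=False)
    def kernel(Dd, resid, indptr, indices, data):
        n, m = Dd.shape
        for j in range(m):
            a, b = indptr[j], indptr[j + 1]
            c = b - a
            if c == 0:
                continue  # dead atom; rescued by the caller
            # residual submatrix with atom j's own contribution restored
            Ej = np.empty((n, c))
            for ci in range(c):
                col = indices[a + ci]
                v = data[a + ci]
                for r in range(n):
                    Ej[r, ci] = resid[r, col] + Dd[r, j] * v
            # leading singular pair via the smaller Gram matrix
            if n <= c:
                w, V = np.linalg.eigh(Ej @ Ej.T)
                lam = w[n - 1]
                if lam <= 0.0:
                    continue
                sigma = np.sqrt(lam)
                u = V[:, n - 1].copy()
                vvec = (Ej.T @ u) / sigma
            else:
                w, V = np.linalg.eigh(Ej.T @ Ej)
                lam = w[c - 1]
                if lam <= 0.0:
                    continue
                sigma = np.sqrt(lam)
                vvec = V[:, c - 1].copy()
                u = (Ej @ vvec) / sigma
            for r in range(n):
                Dd[r, j] = u[r]
            for ci in range(c):
                sv = sigma * vvec[ci]
                data[a + ci] = sv
                col = indices[a + ci]
                for r in range(n):
                    resid[r, col] = Ej[r, ci] - u[r] * sv

    _KSVD_KERNEL = kernel
    return kernel


def _update_ilsdla(Yd, Dd, X: SparseCodeMatrix, cfg: LearnConfig):
    Xs = X.X
    XXt = (Xs @ Xs.T).toarray()
    XYt = np.asarray(Xs @ Yd.T)
    try:
        c, low = scipy.linalg.cho_factor(XXt)
        Dnew = scipy.linalg.cho_solve((c, low), XYt).T
    except np.linalg.LinAlgError:
        warnings.warn("X X^T is rank deficient; using pseudo-inverse update")
        Dnew = (np.linalg.pinv(XXt) @ XYt).T
    norms = np.linalg.norm(Dnew, axis=0)
    ok = norms > 1e-12
    Dnew[:, ok] /= norms[ok]
    Dnew[:, ~ok] = Dd[:, ~ok]  # keep old atoms where the update degenerated
    # compensate the coefficient rows so D X equals the least-squares
    # optimum product (renormalization must not change the model)
    scale = np.where(ok, norms, 1.0)
    Xc = sp.csr_array(Xs)
    row_sizes = np.diff(Xc.indptr)
    Xc.data *= np.repeat(scale, row_sizes)
    return Dnew, SparseCodeMatrix(X=sp.csc_array(Xc), k=X.k)


_UPDATES = {"rsvd": _update_rsvd, "ksvd": _update_ksvd, "ilsdla": _update_ilsdla}


def learn(Y, cfg: LearnConfig) -> LearnResult:
    """Run the configured learner for cfg.T alternating iterations.

    Fully deterministic given (Y, cfg): the only randomness is the seeded
    initialization (and the fixed-seed randomized SVD range finder).
    """
    Yd = Y.Y if isinstance(Y, SignalSet) else np.asarray(Y, dtype=float)
    n, L = Yd.shape
    if not n < cfg.m:
        raise ValueError(f"dictionary must be overcomplete: n={n} >= m={cfg.m}")
    if cfg.k > n:
        raise ValueError(f"sparsity k={cfg.k} exceeds signal dimension n={n}")
    update = _UPDATES[cfg.algorithm]
    spec = cfg.spec

    Dd = init_dictionary(Yd, cfg.m, cfg.seed).D.copy()
    err_trace = np.empty(cfg.T)
    obj_trace = np.empty(cfg.T)
    sig_norm = float(np.linalg.norm(Yd))
    X = None
    for t in range(cfg.T):
        X = sparse_code_batch(Yd, Dd, spec)
        Dd, X = update(Yd, Dd, X, cfg)
        # rescue dead atoms; their X rows are zero so D X is unchanged
        Dd = _replace_unused_atoms(Yd, Dd, X)
        resid2 = float(np.sum((Yd - Dd @ X.X) ** 2))
        obj_trace[t] = resid2
        err_trace[t] = (
            np.inf if resid2 == 0.0
            else 20.0 * np.log10(sig_norm / np.sqrt(resid2))
        )
    return LearnResult(
        D=Dictionary(D=Dd),
        X=X,
        error_trace=err_trace,
        objective_trace=obj_trace,
        config=cfg,
    )


def rsvd_learn(Y, cfg: LearnConfig) -> LearnResult:
    """Rotation-based group-update learner (Procrustes dictionary update)."""
    if cfg.algorithm != "rsvd":
        raise ValueError("cfg.algorithm must be 'rsvd'")
    return learn(Y, cfg)


def ksvd_learn(Y, cfg: LearnConfig) -> LearnResult:
    """K-SVD baseline: per-atom rank-1 SVD update with coefficient re-encoding."""
    if cfg.algorithm != "ksvd":
        raise ValueError("cfg.algorithm must be 'ksvd'")
    return learn(Y, cfg)


def ilsdla_learn(Y, cfg: LearnConfig) -> LearnResult:
    """ILS-DLA baseline: batch least-squares dictionary update + renormalization."""
    if cfg.algorithm != "ilsdla":
        raise ValueError("cfg.algorithm must be 'ilsdla'")
    return learn(Y, cfg)
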