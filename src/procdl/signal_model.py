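"""Core data contracts and global reconstruction-quality metrics.

The sparse linear representation model writes each signal column y of a
training set Y (n x L) as y ~ D x, where D is an overcomplete dictionary
(n x m, n < m) with unit-norm columns ("atoms") and x is a k-sparse
coefficient vector.  Everything else in the package — the learners, the
synthetic benchmark, the ECG pipeline — is phrased in terms of the three
containers and two metrics defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SignalSet",
    "Dictionary",
    "SparseCodeMatrix",
    "objective",
    "esnr",
    "UNIT_NORM_TOL",
]

#: tolerance for the unit-norm atom invariant
UNIT_NORM_TOL = 1e-8


def _as_dense(obj) -> np.ndarray:
    """Coerce a container, sparse matrix or array-like to a dense float ndarray."""
    for attr in ("Y", "D", "X"):
        inner = getattr(obj, attr, None)
        if inner is not None:
            obj = inner
            break
    if sp.issparse(obj):
        return np.asarray(obj.todense(), dtype=float)
    return np.asarray(obj, dtype=float)


@dataclass(frozen=True)
class SignalSet:
    """A set of L training/test signals as the columns of an n x L matrix."""

    Y: np.ndarray

    def __post_init__(self):
        Y = np.asarray(self.Y, dtype=float)
        if Y.ndim != 2 or Y.shape[0] < 1 or Y.shape[1] < 1:
            raise ValueError(f"signal set must be a 2-D matrix, got shape {Y.shape}")
        if not np.all(np.isfinite(Y)):
            raise ValueError("signal set contains non-finite entries")
        object.__setattr__(self, "Y", Y)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def L(self) -> int:
        return self.Y.shape[1]


@dataclass(frozen=True)
class Dictionary:
    """An overcomplete dictionary: n x m matrix, n < m, unit-l2 columns."""

    D: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2:
            raise ValueError("dictionary must be a 2-D matrix")
        n, m = D.shape
        if not n < m:
            raise ValueError(f"dictionary must be overcomplete (n < m), got {n} x {m}")
        if not np.all(np.isfinite(D)):
            raise ValueError("dictionary contains non-finite entries")
        norms = np.linalg.norm(D, axis=0)
        if np.any(np.abs(norms - 1.0) > UNIT_NORM_TOL):
            worst = float(np.max(np.abs(norms - 1.0)))
            raise ValueError(
                f"dictionary atoms must be unit l2-norm (max deviation {worst:.2e})"
            )
        object.__setattr__(self, "D", D)

    @property
    def n(self) -> int:
        return self.D.shape[0]

    @property
    def m(self) -> int:
        """Number of atoms."""
        return self.D.shape[1]


@dataclass(frozen=True)
class SparseCodeMatrix:
    """An m x L coefficient matrix whose columns are at most k-sparse.

    The matrix is stored in CSC form; dense input is accepted and converted.
    """

    X: sp.csc_array
    k: int

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("sparsity bound k must be a positive integer")
        X = self.X
        if not sp.issparse(X):
            X = sp.csc_array(np.asarray(X, dtype=float))
        else:
            X = sp.csc_array(X)
        if not np.all(np.isfinite(X.data)):
            raise ValueError("code matrix contains non-finite entries")
        col_nnz = np.diff(X.indptr)
        if np.any(col_nnz > self.k):
            raise ValueError(
                f"column sparsity exceeds bound k={self.k} "
                f"(max column support {int(col_nnz.max())})"
            )
        object.__setattr__(self, "X", X)

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def L(self) -> int:
        return self.X.shape[1]

    def toarray(self) -> np.ndarray:
        return self.X.toarray()

    def row_usage(self) -> np.ndarray:
        """Popularity of each atom: l0-norm of each row of X."""
        return np.diff(sp.csr_array(self.X).indptr)


def objective(Y, D, X) -> float:
    """Squared-Frobenius reconstruction error ||Y - D X||_F^2.

    This is the quantity both alternating stages (sparse coding and
    dictionary update) monotonically decrease.
    """
    Yd = _as_dense(Y)
    Dd = _as_dense(D)
    Xobj = X.X if isinstance(X, SparseCodeMatrix) else X
    n, L = Yd.shape
    if Dd.shape[0] != n:
        raise ValueError(f"row mismatch: Y has n={n}, D has n={Dd.shape[0]}")
    if Xobj.shape != (Dd.shape[1], L):
        raise ValueError(
            f"code matrix must be {Dd.shape[1]} x {L}, got {Xobj.shape}"
        )
    if sp.issparse(Xobj):
        R = Yd - Dd @ Xobj  # sparse matmul keeps cost ~ nnz
    else:
        R = Yd - Dd @ np.asarray(Xobj, dtype=float)
    return float(np.sum(np.asarray(R) ** 2))


def esnr(Y, Yhat) -> float:
    """Reconstruction quality in dB: 20 log10(||Y||_F / ||Y - Yhat||_F).

    Returns ``math.inf`` when the residual is exactly zero (noiseless
    exact recovery), so experiment tables can hold that cell without
    special-casing exceptions.
    """
    Yd = _as_dense(Y)
    Yh = _as_dense(Yhat)
    if Yd.shape != Yh.shape:
        raise ValueError(f"shape mismatch: {Yd.shape} vs {Yh.shape}")
    sig = float(np.linalg.norm(Yd))
    if sig == 0.0:
        raise ValueError("reference signal is all-zero; E_SNR undefined")
    res = float(np.linalg.norm(Yd - Yh))
    if res == 0.0:
        return math.inf
    return 20.0 * math.log10(sig / res)
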