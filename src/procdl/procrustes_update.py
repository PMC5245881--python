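"""Group-wise orthogonal Procrustes dictionary update.

The dictionary-update stage rotates a whole group of atoms at once.  With a
group I of s atoms, write the reconstruction as

    Y - D X = (Y - D_{I^c} X_{I^c}) - D_I X_I = E - H,

where E is the residual excluding the group and H the group's current
contribution.  The best orthogonal transformation of the group solves the
Orthogonal Procrustes problem

    min_{R in O(n)} ||E - R H||_F^2,

whose solution is the orthogonal polar factor of E H^T: if E H^T = U S V^T
then R = U V^T (proper or improper rotation — both admissible).  Applying
R to the group, D_I <- R D_I, leaves atom norms untouched (no
renormalization needed) and never increases ||Y - D X||_F^2 with X fixed.

Forming E and H densely costs O(n L) per group; instead the cross-product
H E^T is assembled from cached products X Y^T and X X^T in
O(s n (n + m - s)) flops, and its SVD may be truncated at rank s because
rank(H E^T) <= rank(H) <= s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd

from .signal_model import Dictionary, SignalSet, SparseCodeMatrix

__all__ = [
    "GroupIndex",
    "ProductCache",
    "RotationResult",
    "build_cache",
    "cross_product",
    "optimal_rotation",
    "update_group",
]


@dataclass(frozen=True)
class GroupIndex:
    """An ordered set of distinct atom indices within [0, m)."""

    indices: np.ndarray
    m: int

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1 or idx.size < 1:
            raise ValueError("group must hold at least one index")
        if idx.size > self.m:
            raise ValueError("group larger than the dictionary")
        if np.unique(idx).size != idx.size:
            raise ValueError("group indices must be distinct")
        if idx.min() < 0 or idx.max() >= self.m:
            raise ValueError(f"group indices out of range [0, {self.m})")
        object.__setattr__(self, "indices", idx)

    @property
    def s(self) -> int:
        return self.indices.size

    def complement(self) -> np.ndarray:
        mask = np.ones(self.m, dtype=bool)
        mask[self.indices] = False
        return np.flatnonzero(mask)


@dataclass(frozen=True)
class ProductCache:
    """Precomputed X Y^T (m x n) and X X^T (m x m) for one update sweep."""

    XYt: np.ndarray
    XXt: np.ndarray

    def __post_init__(self):
        XYt = np.asarray(self.XYt, dtype=float)
        XXt = np.asarray(self.XXt, dtype=float)
        if XXt.shape[0] != XXt.shape[1] or XXt.shape[0] != XYt.shape[0]:
            raise ValueError("inconsistent cache shapes")
        if np.max(np.abs(XXt - XXt.T), initial=0.0) > 1e-10:
            raise ValueError("X X^T cache is not symmetric")
        object.__setattr__(self, "XYt", XYt)
        object.__setattr__(self, "XXt", XXt)


@dataclass(frozen=True)
class RotationResult:
    R: np.ndarray
    objective_before: float
    objective_after: float


def build_cache(Y, X) -> ProductCache:
    """Assemble the X Y^T and X X^T products, exploiting the sparsity of X.

    Cost is proportional to the number of nonzeros of X, not to m*L.
    """
    Yd = Y.Y if isinstance(Y, SignalSet) else np.asarray(Y, dtype=float)
    Xs = X.X if isinstance(X, SparseCodeMatrix) else X
    if not sp.issparse(Xs):
        Xs = sp.csr_array(np.asarray(Xs, dtype=float))
    else:
        Xs = sp.csr_array(Xs)
    if Xs.shape[1] != Yd.shape[1]:
        raise ValueError(
            f"X has L={Xs.shape[1]} columns but Y has L={Yd.shape[1]}"
        )
    XYt = Xs @ Yd.T
    XXt = (Xs @ Xs.T).toarray()
    # symmetrize to guard against sparse round-off
    XXt = 0.5 * (XXt + XXt.T)
    return ProductCache(XYt=np.asarray(XYt), XXt=XXt)


def cross_product(D, cache: ProductCache, I: GroupIndex) -> np.ndarray:
    """The n x n cross-product H E^T assembled from the cache.

    Equals D_I [ X_I Y^T - X_I X_{I^c}^T D_{I^c}^T ], which expands to
    (D_I X_I)(Y - D_{I^c} X_{I^c})^T = H E^T without ever forming the
    n x L matrices E and H.
    """
    Dd = D.D if isinstance(D, Dictionary) else np.asarray(D, dtype=float)
    m = Dd.shape[1]
    if I.m != m:
        raise ValueError(f"group defined over m={I.m}, dictionary has m={m}")
    idx = I.indices
    comp = I.complement()
    bracket = cache.XYt[idx] - cache.XXt[np.ix_(idx, comp)] @ Dd[:, comp].T
    return Dd[:, idx] @ bracket  # (n, n)


def _orthogonal_completion(B: np.ndarray) -> np.ndarray:
    """Extend an n x s matrix with orthonormal columns to a full n x n
    orthogonal matrix (any completion of the orthogonal complement)."""
    n, s = B.shape
    if s >= n:
        return B[:, :n]
    Q, _ = np.linalg.qr(B, mode="complete")
    # col(Q[:, :s]) = col(B), so Q[:, s:] is an orthonormal basis of the
    # orthogonal complement; keep B itself in the leading block
    Q = Q.copy()
    Q[:, :s] = B
    return Q


def _polar_rotation(M: np.ndarray, rank_hint: int | None = None) -> np.ndarray:
    """Orthogonal R maximizing tr(R^T M): R = U V^T for SVD M = U S V^T.

    When ``rank_hint`` s is given and small (< n/2), a seeded randomized
    rank-s SVD (oversampling 10) is used and the singular bases are
    completed to full orthogonal matrices so that R itself stays orthogonal
    even when M is rank deficient; otherwise LAPACK's full SVD is used.
    """
    n = M.shape[0]
    if rank_hint is not None and 0 < rank_hint < n / 2:
        U, _, Vt = randomized_svd(
            M, n_components=rank_hint, n_oversamples=10, random_state=0
        )
        Uf = _orthogonal_completion(U)
        Vf = _orthogonal_completion(Vt.T)
        return Uf @ Vf.T
    U, _, Vt = np.linalg.svd(M)
    return U @ Vt


def optimal_rotation(E, H, rank_hint: int | None = None) -> RotationResult:
    """Solve min_{R in O(n)} ||E - R H||_F^2 for dense E, H of equal shape."""
    E = np.asarray(E, dtype=float)
    H = np.asarray(H, dtype=float)
    if E.shape != H.shape:
        raise ValueError(f"shape mismatch: E {E.shape} vs H {H.shape}")
    if not (np.all(np.isfinite(E)) and np.all(np.isfinite(H))):
        raise ValueError("non-finite input")
    R = _polar_rotation(E @ H.T, rank_hint)
    before = float(np.sum((E - H) ** 2))
    after = float(np.sum((E - R @ H) ** 2))
    return RotationResult(R=R, objective_before=before, objective_after=after)


def update_group(D, X, I: GroupIndex, cache: ProductCache,
                 use_truncated: bool = True) -> Dictionary:
    """Rotate the atoms of group I by the optimal Procrustes transformation.

    Returns a dictionary equal to D outside I and R D_I on I.  Rotation
    preserves atom norms, so no renormalization is applied, and the
    reconstruction objective never increases with X fixed.
    """
    Dd = (D.D if isinstance(D, Dictionary) else np.asarray(D, dtype=float)).copy()
    HEt = cross_product(Dd, cache, I)
    # H E^T = V S U^T when E H^T = U S V^T; transpose to reuse the
    # "maximize tr(R^T (E H^T))" polar form
    rank_hint = I.s if use_truncated else None
    R = _polar_rotation(HEt.T, rank_hint)
    Dd[:, I.indices] = R @ Dd[:, I.indices]
    return Dictionary(D=Dd)
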