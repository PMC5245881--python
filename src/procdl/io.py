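"""Readers and writers for the matrix and result formats used by the CLI.

Dense matrices travel as CSV (17 significant digits) or NumPy ``.npy``
binary; sparse coefficient matrices as MatrixMarket coordinate files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .signal_model import Dictionary, SparseCodeMatrix

__all__ = ["read_matrix", "write_matrix", "write_json", "FORMATS"]

FORMATS = ("csv", "matrixmarket", "binary")

_SUFFIX = {"csv": ".csv", "matrixmarket": ".mtx", "binary": ".npy"}


class MatrixParseError(ValueError):
    """Raised when a matrix file cannot be parsed; message names the file
    and, where available, the offending line."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in FORMATS:
            raise ValueError(f"format must be one of {FORMATS}, got {fmt!r}")
        return fmt
    for name, suffix in _SUFFIX.items():
        if path.suffix == suffix:
            return name
    raise ValueError(f"cannot infer matrix format from suffix {path.suffix!r}")


def read_matrix(path, fmt: str | None = None):
    """Read a dense (CSV/binary) or sparse (MatrixMarket) matrix."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "csv":
            M = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
        elif fmt == "matrixmarket":
            M = scipy.io.mmread(path)
            if sp.issparse(M):
                M = sp.csc_array(M)
        else:
            M = np.load(path, allow_pickle=False)
    except Exception as exc:  # normalize parse failures across backends
        raise MatrixParseError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if M.size == 0:
        raise MatrixParseError(f"{path} holds an empty matrix")
    return M


def write_matrix(matrix, path, fmt: str | None = None,
                 force: bool = False) -> None:
    """Write a matrix; refuses to overwrite unless ``force`` is set.

    Writing a :class:`Dictionary` records its shape and the unit-norm
    invariant in a header comment; full float precision is preserved in
    binary, 17 significant digits in text formats.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")

    header = ""
    if isinstance(matrix, Dictionary):
        header = (f"dictionary {matrix.n} x {matrix.m}; "
                  "columns unit l2-norm")
        matrix = matrix.D
    elif isinstance(matrix, SparseCodeMatrix):
        matrix = matrix.X

    if sp.issparse(matrix):
        if matrix.size == 0 or 0 in matrix.shape:
            raise ValueError("refusing to write an empty matrix")
        if fmt != "matrixmarket":
            matrix = matrix.toarray()
    if not sp.issparse(matrix):
        matrix = np.asarray(matrix)
        if matrix.size == 0:
            raise ValueError("refusing to write an empty matrix")

    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        np.savetxt(path, np.atleast_2d(matrix), delimiter=",",
                   fmt="%.17g", header=header)
    elif fmt == "matrixmarket":
        scipy.io.mmwrite(path, sp.coo_matrix(matrix), comment=header)
    else:
        np.save(path, np.asarray(matrix), allow_pickle=False)


def write_json(obj, path, force: bool = False) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
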