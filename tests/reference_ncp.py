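"""Independent reference solver for non-negative CP on fully observed tensors.

Alternating non-negative least squares: each factor update solves an
exact NNLS problem per row (scipy.optimize.nnls) against the Khatri–Rao
design of the other two factors.  Shares no code with the package's
multiplicative-update solver; used only as a cross-check oracle.
"""

import numpy as np
from scipy.optimize import nnls


def khatri_rao(b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product, (J*K) x R with K varying fastest."""
    r = b.shape[1]
    return np.stack([np.kron(b[:, i], c[:, i]) for i in range(r)], axis=1)


def unfold(x: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def als_nnls_ncp(
    x: np.ndarray, factors: list[np.ndarray], n_iter: int
) -> tuple[list[np.ndarray], float]:
    """Run ALS-NNLS from the given starting factors; return factors and the
    final sum-of-squares objective."""
    a, b, c = (f.copy() for f in factors)
    for _ in range(n_iter):
        design = khatri_rao(b, c)
        tgt = unfold(x, 0)
        a = np.stack([nnls(design, row)[0] for row in tgt])
        design = khatri_rao(a, c)
        tgt = unfold(x, 1)
        b = np.stack([nnls(design, row)[0] for row in tgt])
        design = khatri_rao(a, b)
        tgt = unfold(x, 2)
        c = np.stack([nnls(design, row)[0] for row in tgt])
    xhat = np.einsum("ir,jr,kr->ijk", a, b, c)
    return [a, b, c], float(np.sum((x - xhat) ** 2))
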