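"""Central-difference Hessians for observed-information standard errors."""

from __future__ import annotations

from typing import Callable

import numpy as np


def numeric_hessian(
    f: Callable[[np.ndarray], float], x: np.ndarray, rel_step: float = 1e-4
) -> np.ndarray:
    """Symmetric central-difference Hessian of scalar ``f`` at ``x``."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    # diagonal terms
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
    # off-diagonal terms
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)


def hessian_from_grad(
    grad: Callable[[np.ndarray], np.ndarray], x: np.ndarray, rel_step: float = 1e-5
) -> np.ndarray:
    """Hessian via central differences of an analytic gradient (2p calls)."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i] = (grad(x + ei) - grad(x - ei)) / (2.0 * h[i])
    return 0.5 * (H + H.T)


def safe_inverse(H: np.ndarray) -> tuple[np.ndarray, bool]:
    """Inverse of an observed-information matrix.

    Returns (V, is_pd).  When H is not positive definite the
    Moore-Penrose pseudo-inverse is returned with ``is_pd=False`` so the
    caller can flag the standard errors.
    """
    try:
        L = np.linalg.cholesky(H)
        Linv = np.linalg.inv(L)
        return Linv.T @ Linv, True
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H), False
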