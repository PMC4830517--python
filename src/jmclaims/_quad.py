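"""Quadrature helpers: Gauss-Legendre and Gauss-Hermite node caches.

All fitting and simulation code funnels its numerical integration through
these small utilities so that every module uses the same, reproducible
rules (default: 15-point Legendre for single integrals, 7-point outer
rule for cumulative hazards, 9 Hermite nodes per random-effect dimension).
"""

from __future__ import annotations

import functools
import itertools

import numpy as np


@functools.lru_cache(maxsize=32)
def gauss_legendre(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for the n-point Gauss-Legendre rule on [-1, 1]."""
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def legendre_01(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Rule mapped to [0, 1]: integral f ~ sum(w * f(x))."""
    x, w = gauss_legendre(n)
    return 0.5 * (x + 1.0), 0.5 * w


def composite_legendre_nodes(
    times: np.ndarray,
    breakpoints: np.ndarray,
    n_points: int = 7,
    halve: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss-Legendre nodes on [0, t] split at breakpoints.

    For each t in ``times`` the interval [0, t] is partitioned at the
    breakpoints lying inside it (plus one halving of every panel when
    ``halve``), and an ``n_points`` rule is laid on each panel.  Panels
    are padded across times with zero-width/zero-weight entries so the
    result is rectangular: returns (S, W) of shape
    (len(times), max_panels * n_points) with  integral f ~ sum(W * f(S)).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    x, w = legendre_01(n_points)
    rows_s, rows_w = [], []
    max_len = 0
    for t in times:
        edges = np.concatenate(
            [[0.0], np.asarray(breakpoints, dtype=float)[
                (np.asarray(breakpoints) > 0) & (np.asarray(breakpoints) < t)
            ], [max(t, 0.0)]]
        )
        edges = np.unique(edges)
        if halve and edges.size > 1:
            mids = 0.5 * (edges[:-1] + edges[1:])
            edges = np.unique(np.concatenate([edges, mids]))
        widths = np.diff(edges)
        s = (edges[:-1, None] + widths[:, None] * x).ravel()
        wt = (widths[:, None] * w).ravel()
        rows_s.append(s)
        rows_w.append(wt)
        max_len = max(max_len, s.size)
    S = np.zeros((times.size, max_len))
    W = np.zeros((times.size, max_len))
    for i, (s, wt) in enumerate(zip(rows_s, rows_w)):
        S[i, : s.size] = s
        W[i, : wt.size] = wt
    return S, W


@functools.lru_cache(maxsize=32)
def gauss_hermite(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Physicists' Gauss-Hermite rule (weight exp(-z^2))."""
    z, w = np.polynomial.hermite.hermgauss(n)
    return z, w


@functools.lru_cache(maxsize=32)
def hermite_grid(n: int, dim: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product Hermite grid in `dim` dimensions.

    Returns (Z, log_w) where Z has shape (n**dim, dim) and
    log_w[q] = sum_d log w[q_d] + |z_q|^2, the log-weight adjusted for
    the Gaussian kernel so that  integral g(z) dz ~ sum exp(log_w) g(z).
    """
    z, w = gauss_hermite(n)
    idx = np.array(list(itertools.product(range(n), repeat=dim)))
    logw = np.log(w)[idx].sum(axis=1)
    nodes = z[idx]
    logw = logw + (nodes**2).sum(axis=1)
    return nodes, logw
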