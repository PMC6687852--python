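"""Canonical correlation between conductance factors and pro-arrhythmia.

With a one-dimensional second view (the binary event vector z), the
canonical pair maximizing corr(X w_x, z w_z) reduces to the least-squares
direction of z on column-centered X; the canonical correlation is the
multiple correlation coefficient.  The weight vector's overall sign is
fixed so that corr(X w_x, z) >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CCAResult:
    w_x: np.ndarray          # canonical weights, unit norm
    w_z: float
    correlation: float       # in [0, 1]
    signs: np.ndarray        # per-feature interpretation signs
    ridge_eps: float = 0.0


def fit_cca(x, z, ridge: float | None = None) -> CCAResult:
    """Single-pair CCA of features X (N x D) against a binary outcome z.

    Collinear feature blocks are ridge-stabilized with a logged epsilon.
    Raises for a constant z (degenerate problem).
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.ndim != 2 or z.shape != (x.shape[0],):
        raise ValueError("X must be N x D and z length N")
    n, d = x.shape
    if n <= d:
        raise ValueError("need more samples than features")
    if np.all(z == z[0]):
        raise ValueError("z is constant: canonical correlation undefined")
    xc = x - x.mean(axis=0)
    zc = z - z.mean()
    sxx = xc.T @ xc / n
    sxz = xc.T @ zc / n
    eps = 0.0
    if ridge is not None:
        eps = ridge
    else:
        cond = np.linalg.cond(sxx)
        if cond > 1e10:
            eps = 1e-8 * np.trace(sxx) / d
    w = np.linalg.solve(sxx + eps * np.eye(d), sxz)
    proj = xc @ w
    denom = np.linalg.norm(proj) * np.linalg.norm(zc)
    corr = float(proj @ zc / denom) if denom > 0 else 0.0
    if corr < 0:
        w = -w
        corr = -corr
    w = w / np.linalg.norm(w)
    return CCAResult(w_x=w, w_z=1.0, correlation=corr,
                     signs=np.sign(w).astype(int), ridge_eps=eps)
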