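"""Hot inner loops of the 3D convolution: column gather / scatter-add.

Jitted with numba when available (it is in the supported environment); a
pure-numpy fallback keeps the package importable without it.  Both paths are
exercised by the same gradient checks.
"""

from __future__ import annotations

import itertools

import numpy as np

_OFFSETS3 = list(itertools.product(range(3), repeat=3))

try:
    from numba import njit

    @njit(fastmath=True, cache=True)
    def _gather27_jit(xp, cols, Do, Ho, Wo, s):  # pragma: no cover - jitted
        B = xp.shape[0]
        C = xp.shape[4]
        for b in range(B):
            k = 0
            for dz in range(3):
                for dy in range(3):
                    for dx in range(3):
                        for i in range(Do):
                            zi = dz + i * s
                            for j in range(Ho):
                                yi = dy + j * s
                                for l in range(Wo):
                                    xi = dx + l * s
                                    for c in range(C):
                                        cols[b, i, j, l, k, c] = xp[b, zi, yi, xi, c]
                        k += 1

    @njit(fastmath=True, cache=True)
    def _scatter27_jit(dxp, dcols, Do, Ho, Wo, s):  # pragma: no cover - jitted
        B = dxp.shape[0]
        C = dxp.shape[4]
        for b in range(B):
            k = 0
            for dz in range(3):
                for dy in range(3):
                    for dx in range(3):
                        for i in range(Do):
                            zi = dz + i * s
                            for j in range(Ho):
                                yi = dy + j * s
                                for l in range(Wo):
                                    xi = dx + l * s
                                    for c in range(C):
                                        dxp[b, zi, yi, xi, c] += dcols[b, i, j, l, k, c]
                        k += 1

    @njit(fastmath=True, cache=True)
    def _adam_jit(p, g, m, v, b1, b2, alpha, eps):  # pragma: no cover - jitted
        for i in range(p.size):
            gi = g[i]
            m[i] = b1 * m[i] + (1.0 - b1) * gi
            v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
            p[i] -= alpha * m[i] / (np.sqrt(v[i]) + eps)

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False
    _adam_jit = None


def adam_update(p, g, m, v, b1, b2, alpha, eps, scratch=None) -> None:
    """One Adam step on flat float32 views (fused single pass when jitted)."""
    if HAVE_NUMBA:
        _adam_jit(p, g, m, v, b1, b2, alpha, eps)
        return
    m *= b1
    np.multiply(g, 1 - b1, out=scratch)
    m += scratch
    v *= b2
    np.multiply(g, g, out=scratch)
    scratch *= 1 - b2
    v += scratch
    np.sqrt(v, out=scratch)
    scratch += eps
    np.divide(m, scratch, out=scratch)
    scratch *= alpha
    p -= scratch


def _slab(k, Do, Ho, Wo, s):
    dz, dy, dx = _OFFSETS3[k]
    return (slice(None),
            slice(dz, dz + (Do - 1) * s + 1, s),
            slice(dy, dy + (Ho - 1) * s + 1, s),
            slice(dx, dx + (Wo - 1) * s + 1, s),
            slice(None))


def gather27(xp: np.ndarray, out_shape, stride: int) -> np.ndarray:
    """Collect the 27 shifted slabs of a padded volume into a column buffer
    of shape (B, Do, Ho, Wo, 27, C)."""
    B, Do, Ho, Wo, _, C = out_shape
    cols = np.empty(out_shape, dtype=xp.dtype)
    if HAVE_NUMBA:
        _gather27_jit(xp, cols, Do, Ho, Wo, stride)
    else:
        for k in range(27):
            cols[..., k, :] = xp[_slab(k, Do, Ho, Wo, stride)]
    return cols


def scatter27(dxp: np.ndarray, dcols: np.ndarray, stride: int) -> None:
    """Adjoint of :func:`gather27`: scatter-add columns back into the padded
    gradient buffer (in place)."""
    B, Do, Ho, Wo, _, C = dcols.shape
    if HAVE_NUMBA:
        _scatter27_jit(dxp, dcols, Do, Ho, Wo, stride)
    else:
        for k in range(27):
            dxp[_slab(k, Do, Ho, Wo, stride)] += dcols[..., k, :]
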