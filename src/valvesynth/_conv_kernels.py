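"""Numba JIT kernels for the 2D/3D convolution layers.

Direct convolution (kernel 3, stride 1) over zero-padded channels-last
float arrays.  Per output position the accumulator lives in a small local
buffer so the inner output-channel loop vectorizes, and zero input values
are skipped — thresholded volumes and ReLU activation/gradient maps are
mostly zero.  The input-gradient pass is itself a convolution with the
spatially flipped, transposed kernel, so it reuses the forward kernel; the
weight gradient has its own fused pass.  All kernels are single-threaded
and bit-deterministic for fixed inputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_JIT = dict(cache=True, fastmath=True, nogil=True)


@njit(**_JIT)
def conv2d_forward(xp, w, bias, out):
    # xp: (B, R+2, C+2, ci); w: (3, 3, ci, co); out: (B, R, C, co)
    B, R, C, co = out.shape
    ci = xp.shape[-1]
    acc = np.empty(co, dtype=out.dtype)
    for b in range(B):
        for r in range(R):
            for c in range(C):
                for o in range(co):
                    acc[o] = bias[o]
                for dr in range(3):
                    xrow = xp[b, r + dr]
                    for dc in range(3):
                        for i in range(ci):
                            xv = xrow[c + dc, i]
                            if xv != 0.0:
                                for o in range(co):
                                    acc[o] += xv * w[dr, dc, i, o]
                for o in range(co):
                    out[b, r, c, o] = acc[o]


@njit(**_JIT)
def conv2d_wgrad(xp, gout, gw, gb):
    # gw: (3, 3, ci, co) accumulated; gb: (co,) accumulated
    B, R, C, co = gout.shape
    ci = xp.shape[-1]
    g = np.empty(co, dtype=gout.dtype)
    for b in range(B):
        for r in range(R):
            for c in range(C):
                for o in range(co):
                    g[o] = gout[b, r, c, o]
                    gb[o] += g[o]
                for dr in range(3):
                    xrow = xp[b, r + dr]
                    for dc in range(3):
                        for i in range(ci):
                            xv = xrow[c + dc, i]
                            if xv != 0.0:
                                for o in range(co):
                                    gw[dr, dc, i, o] += xv * g[o]


@njit(**_JIT)
def conv3d_forward(xp, w, bias, out):
    # xp: (B, Z+2, R+2, C+2, ci); w: (3, 3, 3, ci, co); out: (B, Z, R, C, co)
    B, Z, R, C, co = out.shape
    ci = xp.shape[-1]
    if co == 1:
        # single output channel: vectorize over the input channels instead
        for b in range(B):
            for z in range(Z):
                for r in range(R):
                    for c in range(C):
                        s = bias[0]
                        for dz in range(3):
                            for dr in range(3):
                                xrow = xp[b, z + dz, r + dr]
                                for dc in range(3):
                                    for i in range(ci):
                                        s += xrow[c + dc, i] * w[dz, dr, dc, i, 0]
                        out[b, z, r, c, 0] = s
        return
    acc = np.empty(co, dtype=out.dtype)
    for b in range(B):
        for z in range(Z):
            for r in range(R):
                for c in range(C):
                    for o in range(co):
                        acc[o] = bias[o]
                    for dz in range(3):
                        for dr in range(3):
                            xrow = xp[b, z + dz, r + dr]
                            for dc in range(3):
                                for i in range(ci):
                                    xv = xrow[c + dc, i]
                                    if xv != 0.0:
                                        for o in range(co):
                                            acc[o] += xv * w[dz, dr, dc, i, o]
                    for o in range(co):
                        out[b, z, r, c, o] = acc[o]


@njit(**_JIT)
def conv3d_wgrad(xp, gout, gw, gb):
    B, Z, R, C, co = gout.shape
    ci = xp.shape[-1]
    if co == 1:
        for b in range(B):
            for z in range(Z):
                for r in range(R):
                    for c in range(C):
                        g0 = gout[b, z, r, c, 0]
                        if g0 != 0.0:
                            gb[0] += g0
                            for dz in range(3):
                                for dr in range(3):
                                    xrow = xp[b, z + dz, r + dr]
                                    for dc in range(3):
                                        for i in range(ci):
                                            gw[dz, dr, dc, i, 0] += xrow[c + dc, i] * g0
        return
    g = np.empty(co, dtype=gout.dtype)
    for b in range(B):
        for z in range(Z):
            for r in range(R):
                for c in range(C):
                    for o in range(co):
                        g[o] = gout[b, z, r, c, o]
                        gb[o] += g[o]
                    for dz in range(3):
                        for dr in range(3):
                            xrow = xp[b, z + dz, r + dr]
                            for dc in range(3):
                                for i in range(ci):
                                    xv = xrow[c + dc, i]
                                    if xv != 0.0:
                                        for o in range(co):
                                            gw[dz, dr, dc, i, o] += xv * g[o]
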