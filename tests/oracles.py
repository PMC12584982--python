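"""Independent oracles used to cross-check the implementation.

Everything here is built directly from first principles (the basis
multiplication table, the Rodrigues formula, explicit double/triple-loop
sums) and deliberately shares no code path with the package beyond the
plain coefficient containers.
"""

from __future__ import annotations

import numpy as np

# Structure constants of the quaternion basis: BASIS_TABLE[m][n] is the
# coefficient 4-vector of e_m * e_n for e in (1, i, j, k).
_ONE = (1, 0, 0, 0)
_I = (0, 1, 0, 0)
_J = (0, 0, 1, 0)
_K = (0, 0, 0, 1)


def _neg(t):
    return tuple(-x for x in t)


BASIS_TABLE = [
    [_ONE, _I, _J, _K],
    [_I, _neg(_ONE), _K, _neg(_J)],
    [_J, _neg(_K), _neg(_ONE), _I],
    [_K, _J, _neg(_I), _neg(_ONE)],
]


def table_product(p, q):
    """Quaternion product expanded term-by-term over the basis table."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    out = np.zeros(4)
    for m in range(4):
        for n in range(4):
            out += p[m] * q[n] * np.asarray(BASIS_TABLE[m][n], dtype=float)
    return out


def left_matrix(p):
    """4x4 real matrix L(p) with L(p) @ q == p * q, columns from the table."""
    cols = [table_product(p, np.eye(4)[n]) for n in range(4)]
    return np.column_stack(cols)


def rodrigues(axis, angle):
    """3x3 rotation matrix from the Rodrigues formula."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def qdft2_slow(planes):
    """Brute-force left-sided 2-D quaternion DFT with transform axis i.

    ``planes`` is a (4, R, C) array of coefficients; returns the same shape.
    O((RC)^2) double sum; the exponential multiplies on the left.
    """
    planes = np.asarray(planes, dtype=float)
    _, R, C = planes.shape
    out = np.zeros_like(planes)
    for u in range(R):
        for v in range(C):
            acc = np.zeros(4)
            for m in range(R):
                for n in range(C):
                    th = 2 * np.pi * (u * m / R + v * n / C)
                    e = np.array([np.cos(th), -np.sin(th), 0.0, 0.0])
                    acc += table_product(e, planes[:, m, n])
            out[:, u, v] = acc
    return out


def spatial_convolve_real(planes, kernel):
    """Circular spatial convolution of quaternion planes with a real kernel
    centred on each cell (kernel entry at offset d multiplies the value at
    s - d)."""
    planes = np.asarray(planes, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    _, R, C = planes.shape
    kr, kc = kernel.shape
    cr, cc = kr // 2, kc // 2
    out = np.zeros_like(planes)
    for sr in range(R):
        for sc in range(C):
            acc = np.zeros(4)
            for r in range(kr):
                for c in range(kc):
                    dr, dc = r - cr, c - cc
                    acc += kernel[r, c] * planes[:, (sr - dr) % R, (sc - dc) % C]
            out[:, sr, sc] = acc
    return out


def spatial_biconvolve(kl_planes, planes, kr_planes):
    """Triple-loop spatial biconvolution KL * X * KR over kernel offsets.

    Kernel arguments are (4, k, k) coefficient arrays (centred); X is
    (4, R, C).  Products are taken in the exact left/right order using the
    basis-table product.
    """
    planes = np.asarray(planes, dtype=float)
    kl = np.asarray(kl_planes, dtype=float)
    kr = np.asarray(kr_planes, dtype=float)
    _, R, C = planes.shape
    _, krr, krc = kl.shape
    clr, clc = krr // 2, krc // 2
    _, krr2, krc2 = kr.shape
    crr, crc = krr2 // 2, krc2 // 2
    out = np.zeros_like(planes)
    for sr in range(R):
        for sc in range(C):
            acc = np.zeros(4)
            for lr in range(krr):
                for lc in range(krc):
                    ml = kl[:, lr, lc]
                    if not ml.any():
                        continue
                    dlr, dlc = lr - clr, lc - clc
                    for rr in range(krr2):
                        for rc in range(krc2):
                            mr = kr[:, rr, rc]
                            if not mr.any():
                                continue
                            drr, drc = rr - crr, rc - crc
                            x = planes[:, (sr - dlr - drr) % R, (sc - dlc - drc) % C]
                            acc += table_product(table_product(ml, x), mr)
            out[:, sr, sc] = acc
    return out
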