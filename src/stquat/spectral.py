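"""Spectral filtering and FFT-based (bi)convolution of quaternion grids.

Convolution is circular (FFT-native) throughout.  Small kernels are embedded
into grid-sized mask matrices wrap-around-centred at the origin so the output
stays spatially aligned with the input.

Real-valued kernels commute with quaternions, so convolution with a real
mask is applied plane-wise and is exact with a single FFT per plane.  The
built-in real kernels are the usual sharpening and edge-detection stencils::

    Ksharp = [[ 0, -1,  0],      Kedge = [[-1, -1, -1],
              [-1,  5, -1],               [-1,  8, -1],
              [ 0, -1,  0]]               [-1, -1, -1]]

Quaternion-valued masks do not commute, so a left and a right mask are used
(biconvolution ``ML * X * MR``), mirroring the sandwich form ``r q r^-1`` of
quaternion rotation.  The rotation kernel pair for a unit quaternion r is

    KL = [[r, 0, r^-1]] x 3 rows,    KR = [[r^-1, 0, r]] x 3 rows,

which responds to spatial changes of the vector field: changes parallel to
the rotation axis produce output parallel to the axis, while changes
orthogonal to the axis produce output in the orthogonal plane, so measuring
the off-axis output magnitude yields an edge detector that ignores
transitions along the axis direction.
"""

from __future__ import annotations

import numpy as np

from .algebra import QuaternionArray, RotationQuaternion
from .qft import Spectrum, iqfft2, qfft2
from .st_io import QuaternionGrid

__all__ = [
    "KSHARP",
    "KEDGE",
    "spectral_filter",
    "embed_kernel",
    "convolve_real",
    "biconvolve",
    "rotation_kernels",
    "read_kernel_csv",
    "write_kernel_csv",
]

KSHARP = np.array([[0.0, -1.0, 0.0], [-1.0, 5.0, -1.0], [0.0, -1.0, 0.0]])
KEDGE = np.array([[-1.0, -1.0, -1.0], [-1.0, 8.0, -1.0], [-1.0, -1.0, -1.0]])

# Radial frequencies are grouped into bands after rounding to this many
# decimals, keeping conjugate-symmetric cells in one band.
BAND_DECIMALS = 12


def _as_qarray(Q) -> QuaternionArray:
    if isinstance(Q, QuaternionGrid):
        return Q.quaternions
    if isinstance(Q, Spectrum):
        return Q.F
    return Q


def _radial_frequency(rows: int, cols: int) -> np.ndarray:
    fu = np.fft.fftfreq(rows)
    fv = np.fft.fftfreq(cols)
    return np.sqrt(fu[:, None] ** 2 + fv[None, :] ** 2)


def spectral_filter(Q, mode: str, n_components: int) -> QuaternionArray:
    """Zero out radial-frequency bands of a quaternion grid.

    Cells of the spectrum are ranked by their centred radial frequency
    rho(u, v) = sqrt((u'/R)^2 + (v'/C)^2).  ``mode="lowpass"`` removes the
    ``n_components`` distinct highest-rho bands, ``mode="highpass"`` the
    distinct lowest (DC is the lowest band).
    """
    if mode not in ("lowpass", "highpass"):
        raise ValueError("mode must be 'lowpass' or 'highpass'")
    if n_components < 0:
        raise ValueError("n_components must be >= 0")
    Q = _as_qarray(Q)
    rows, cols = Q.shape
    rho = np.round(_radial_frequency(rows, cols), BAND_DECIMALS)
    bands = np.unique(rho)
    if n_components > len(bands):
        raise ValueError(
            f"n_components={n_components} exceeds the {len(bands)} available bands"
        )
    if n_components == 0:
        selected = np.zeros((rows, cols), dtype=bool)
    elif mode == "lowpass":
        cut = bands[len(bands) - n_components]
        selected = rho >= cut
    else:
        cut = bands[n_components - 1]
        selected = rho <= cut
    F = qfft2(Q).F
    keep = ~selected
    return iqfft2(
        Spectrum(F=QuaternionArray(F.a * keep, F.b * keep, F.c * keep, F.d * keep))
    )


def _as_kernel(kernel) -> QuaternionArray:
    if isinstance(kernel, QuaternionArray):
        k = kernel
    else:
        kernel = np.asarray(kernel, dtype=float)
        k = QuaternionArray.from_scalar(kernel)
    if k.ndim != 2:
        raise ValueError("kernel must be 2-D")
    return k


def embed_kernel(kernel, rows: int, cols: int) -> QuaternionArray:
    """Embed a small kernel in a grid-sized mask, wrap-around-centred so FFT
    convolution equals circular convolution with the kernel centred on each
    cell."""
    k = _as_kernel(kernel)
    kr, kc = k.shape
    if kr > rows or kc > cols:
        raise ValueError(f"kernel {k.shape} larger than grid ({rows}, {cols})")
    mask = QuaternionArray.zeros((rows, cols))
    cr, cc = kr // 2, kc // 2
    for r in range(kr):
        for c in range(kc):
            rr = (r - cr) % rows
            cc2 = (c - cc) % cols
            mask.a[rr, cc2] = k.a[r, c]
            mask.b[rr, cc2] = k.b[r, c]
            mask.c[rr, cc2] = k.c[r, c]
            mask.d[rr, cc2] = k.d[r, c]
    return mask


def _cconv(f: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Complex circular convolution via the FFT."""
    return np.fft.ifft2(np.fft.fft2(f) * np.fft.fft2(g))


def convolve_real(Q, kernel, vector_only: bool = True) -> QuaternionArray:
    """Circular convolution of a quaternion grid with a real kernel.

    Real masks commute with quaternion values, so a plane-wise FFT
    convolution is exact.  With ``vector_only`` (the model's default) the
    real plane passes through unchanged and only the vector planes are
    convolved.
    """
    Q = _as_qarray(Q)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 2:
        raise ValueError("real kernel must be a 2-D real matrix")
    for plane in (Q.a, Q.b, Q.c, Q.d):
        if not np.all(np.isfinite(plane)):
            raise ValueError("input contains non-finite values")
    mask = embed_kernel(kernel, *Q.shape).a
    fmask = np.fft.fft2(mask)
    out = [
        np.fft.ifft2(np.fft.fft2(plane) * fmask).real
        for plane in (Q.a, Q.b, Q.c, Q.d)
    ]
    if vector_only:
        out[0] = Q.a.copy()
    return QuaternionArray(*out)


def biconvolve(ML, Q, MR, vector_only: bool = True) -> QuaternionArray:
    """Biconvolution ``ML * X * MR`` with quaternion-valued mask matrices.

    ``*`` is circular convolution with the quaternion products taken in the
    stated left/right order.  Each mask is split in Cayley-Dickson form
    ``M = C1 + C2 j`` and the products are expanded over the complex planes:

        (C1 + C2 j)(A + B j) = (C1 A - C2 conj(B)) + (C1 B + C2 conj(A)) j
        (A + B j)(C1 + C2 j) = (A C1 - B conj(C2)) + (A C2 + B conj(C1)) j

    so each term is an ordinary complex FFT convolution.  With
    ``vector_only`` the convolution acts on the pure-vector field (input real
    plane zeroed) and the input real plane passes through to the output.
    """
    ML = _as_kernel(_as_qarray(ML))
    MR = _as_kernel(_as_qarray(MR))
    Q = _as_qarray(Q)
    if ML.shape != Q.shape or MR.shape != Q.shape:
        raise ValueError(
            f"mask shapes {ML.shape}, {MR.shape} must match grid shape {Q.shape}"
        )
    a_in = Q.a.copy()
    A = (0.0 * Q.a if vector_only else Q.a) + 1j * Q.b
    B = Q.c + 1j * Q.d
    # Left convolution ML * X.
    C1, C2 = ML.a + 1j * ML.b, ML.c + 1j * ML.d
    A1 = _cconv(C1, A) - _cconv(C2, np.conj(B))
    B1 = _cconv(C1, B) + _cconv(C2, np.conj(A))
    # Right convolution (ML * X) * MR.
    D1, D2 = MR.a + 1j * MR.b, MR.c + 1j * MR.d
    A2 = _cconv(A1, D1) - _cconv(B1, np.conj(D2))
    B2 = _cconv(A1, D2) + _cconv(B1, np.conj(D1))
    out = QuaternionArray(A2.real, A2.imag, B2.real, B2.imag)
    if vector_only:
        out.a = a_in
    return out


def rotation_kernels(r: RotationQuaternion) -> tuple[QuaternionArray, QuaternionArray]:
    """The 3x3 left/right rotation kernel pair for a unit quaternion ``r``:
    rows of KL are ``(r, 0, r^-1)`` and rows of KR are ``(r^-1, 0, r)``."""
    if not isinstance(r, QuaternionArray) or r.ndim != 0:
        raise ValueError("r must be a single quaternion")
    if abs(float(r.norm()) - 1.0) > 1e-8:
        raise ValueError("r must have unit norm")
    rinv = r.inverse()
    KL = QuaternionArray.zeros((3, 3))
    KR = QuaternionArray.zeros((3, 3))
    for row in range(3):
        for mask, left, right in ((KL, r, rinv), (KR, rinv, r)):
            for col, val in ((0, left), (2, right)):
                mask.a[row, col] = float(val.a)
                mask.b[row, col] = float(val.b)
                mask.c[row, col] = float(val.c)
                mask.d[row, col] = float(val.d)
    return KL, KR


def write_kernel_csv(kernel: QuaternionArray, path) -> None:
    """Write a quaternion kernel as CSV rows ``row,col,a,b,c,d``."""
    k = _as_kernel(kernel)
    with open(path, "w") as fh:
        fh.write("row,col,a,b,c,d\n")
        for r in range(k.shape[0]):
            for c in range(k.shape[1]):
                fh.write(
                    f"{r},{c},{k.a[r, c]:.17g},{k.b[r, c]:.17g},"
                    f"{k.c[r, c]:.17g},{k.d[r, c]:.17g}\n"
                )


def read_kernel_csv(path) -> QuaternionArray:
    import pandas as pd

    df = pd.read_csv(path)
    rows = int(df["row"].max()) + 1
    cols = int(df["col"].max()) + 1
    k = QuaternionArray.zeros((rows, cols))
    for _, rec in df.iterrows():
        r, c = int(rec["row"]), int(rec["col"])
        k.a[r, c] = rec["a"]
        k.b[r, c] = rec["b"]
        k.c[r, c] = rec["c"]
        k.d[r, c] = rec["d"]
    return k
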