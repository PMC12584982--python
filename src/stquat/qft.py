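"""Two-dimensional quaternion-domain DFT via Cayley-Dickson decomposition.

A quaternion matrix Q = A + Bi + Cj + Dk is rewritten in Cayley-Dickson form
as Q = Calpha + Cbeta * j with complex planes Calpha = A + Bi and
Cbeta = C + Di.  Because ``exp(-i t) (alpha + beta j) = exp(-i t) alpha +
(exp(-i t) beta) j``, taking the ordinary complex 2-D FFT of each plane and
reassembling F = Falpha + Fbeta * j yields exactly the *left-sided*
quaternion DFT with transform axis i:

    F(u, v) = sum_{m,n} exp(-i 2 pi (u m / R + v n / C)) Q(m, n)

with the exponential multiplied on the left.  The forward transform is
unnormalized; the inverse carries the 1/(RC) factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .algebra import QuaternionArray
from .st_io import QuaternionGrid

__all__ = ["CayleyDicksonPair", "Spectrum", "cd_split", "cd_join", "qfft2", "iqfft2"]


@dataclass
class CayleyDicksonPair:
    """Complex planes alpha = a + b*i and beta = c + d*i of a quaternion array."""

    alpha: np.ndarray
    beta: np.ndarray


@dataclass
class Spectrum:
    """Quaternion-valued frequency-domain matrix (DC at index (0, 0))."""

    F: QuaternionArray

    @property
    def shape(self):
        return self.F.shape


def cd_split(q: QuaternionArray) -> CayleyDicksonPair:
    return CayleyDicksonPair(alpha=q.a + 1j * q.b, beta=q.c + 1j * q.d)


def cd_join(pair: CayleyDicksonPair) -> QuaternionArray:
    return QuaternionArray(
        pair.alpha.real, pair.alpha.imag, pair.beta.real, pair.beta.imag
    )


def _as_qarray(Q) -> QuaternionArray:
    if isinstance(Q, QuaternionGrid):
        Q = Q.quaternions
    if not isinstance(Q, QuaternionArray):
        raise TypeError("expected a QuaternionArray or QuaternionGrid")
    if Q.ndim != 2:
        raise ValueError(f"transform input must be 2-D, got shape {Q.shape}")
    for plane in (Q.a, Q.b, Q.c, Q.d):
        if not np.all(np.isfinite(plane)):
            raise ValueError("transform input contains non-finite values")
    return Q


def qfft2(Q) -> Spectrum:
    """Forward 2-D quaternion DFT of a quaternion matrix (or grid)."""
    Q = _as_qarray(Q)
    pair = cd_split(Q)
    return Spectrum(
        F=cd_join(
            CayleyDicksonPair(
                alpha=np.fft.fft2(pair.alpha), beta=np.fft.fft2(pair.beta)
            )
        )
    )


def iqfft2(F) -> QuaternionArray:
    """Inverse 2-D quaternion DFT; ``iqfft2(qfft2(Q)) == Q`` to rounding."""
    if isinstance(F, Spectrum):
        F = F.F
    F = _as_qarray(F)
    pair = cd_split(F)
    return cd_join(
        CayleyDicksonPair(
            alpha=np.fft.ifft2(pair.alpha), beta=np.fft.ifft2(pair.beta)
        )
    )
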