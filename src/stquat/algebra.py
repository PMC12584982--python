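"""Hamilton quaternion arithmetic on scalars and arrays.

A quaternion ``q = a + b*i + c*j + d*k`` is a four-dimensional hypercomplex
number whose imaginary basis obeys Hamilton's rules::

    i^2 = j^2 = k^2 = i*j*k = -1
    i*j =  k,   j*i = -k
    j*k =  i,   k*j = -i
    k*i =  j,   i*k = -j

Quaternions form a normed division algebra: the product is associative and
distributive but *not* commutative, and ``|q1 q2| = |q1| |q2|``.

Unit quaternions encode rotations of R^3.  A rotation by angle ``theta``
about the unit axis ``u`` is represented by

    r = cos(theta/2) + sin(theta/2) * (ux*i + uy*j + uz*k)

and applied to a pure (vector) quaternion ``qv`` as the sandwich product
``r * qv * r^-1``.  For a unit ``r`` the inverse equals the conjugate, which
is what this module uses (it avoids the division by the squared norm).

The array carrier :class:`QuaternionArray` stores the four real coefficient
planes separately (structure of arrays), so the complex planes needed by the
Cayley-Dickson Fourier transform can be formed without repacking.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Quaternion",
    "QuaternionArray",
    "RotationQuaternion",
    "qmul",
    "conjugate",
    "norm",
    "inverse",
    "qconj_norm_inv",
    "make_rotation",
    "rotate",
    "rotation_between",
]

# Module-level tolerance configuration.  UNIT_ATOL guards unit-norm
# preconditions; STRICT_ATOL is the accuracy promised by post-conditions.
UNIT_ATOL = 1e-8
STRICT_ATOL = 1e-12


class QuaternionArray:
    """Array of quaternions held as four parallel real coefficient planes.

    Parameters
    ----------
    a, b, c, d
        Real coefficient arrays (broadcast to a common shape): the scalar
        part ``a`` and the i, j, k components ``b, c, d``.
    """

    __slots__ = ("a", "b", "c", "d")

    def __init__(self, a, b, c, d):
        a, b, c, d = np.broadcast_arrays(
            np.asarray(a, dtype=float),
            np.asarray(b, dtype=float),
            np.asarray(c, dtype=float),
            np.asarray(d, dtype=float),
        )
        self.a = np.array(a, dtype=float)
        self.b = np.array(b, dtype=float)
        self.c = np.array(c, dtype=float)
        self.d = np.array(d, dtype=float)

    # -- constructors -----------------------------------------------------

    @classmethod
    def zeros(cls, shape) -> "QuaternionArray":
        z = np.zeros(shape)
        return cls(z, z, z, z)

    @classmethod
    def from_scalar(cls, a) -> "QuaternionArray":
        a = np.asarray(a, dtype=float)
        z = np.zeros_like(a)
        return cls(a, z, z, z)

    @classmethod
    def pure(cls, vec) -> "QuaternionArray":
        """Pure (vector) quaternions from an ``(..., 3)`` array."""
        vec = np.asarray(vec, dtype=float)
        if vec.shape[-1] != 3:
            raise ValueError(f"expected trailing dimension 3, got {vec.shape}")
        z = np.zeros(vec.shape[:-1])
        return cls(z, vec[..., 0], vec[..., 1], vec[..., 2])

    @classmethod
    def from_vector(cls, real, vec) -> "QuaternionArray":
        """Quaternions from a real part and an ``(..., 3)`` vector part."""
        vec = np.asarray(vec, dtype=float)
        return cls(real, vec[..., 0], vec[..., 1], vec[..., 2])

    # -- basic structure --------------------------------------------------

    @property
    def shape(self):
        return self.a.shape

    @property
    def ndim(self):
        return self.a.ndim

    def __len__(self):
        return len(self.a)

    def __getitem__(self, idx) -> "QuaternionArray":
        return QuaternionArray(self.a[idx], self.b[idx], self.c[idx], self.d[idx])

    def copy(self) -> "QuaternionArray":
        return QuaternionArray(self.a, self.b, self.c, self.d)

    def coeffs(self) -> np.ndarray:
        """Stack the four planes into an ``(..., 4)`` real array."""
        return np.stack([self.a, self.b, self.c, self.d], axis=-1)

    def vector(self) -> np.ndarray:
        """The (b, c, d) vector part as an ``(..., 3)`` real array."""
        return np.stack([self.b, self.c, self.d], axis=-1)

    # -- algebra ----------------------------------------------------------

    def __add__(self, other: "QuaternionArray") -> "QuaternionArray":
        return QuaternionArray(
            self.a + other.a, self.b + other.b, self.c + other.c, self.d + other.d
        )

    def __sub__(self, other: "QuaternionArray") -> "QuaternionArray":
        return QuaternionArray(
            self.a - other.a, self.b - other.b, self.c - other.c, self.d - other.d
        )

    def __neg__(self) -> "QuaternionArray":
        return QuaternionArray(-self.a, -self.b, -self.c, -self.d)

    def __mul__(self, other):
        if isinstance(other, QuaternionArray):
            return qmul(self, other)
        return QuaternionArray(
            self.a * other, self.b * other, self.c * other, self.d * other
        )

    def __rmul__(self, other):
        # Real scalars commute with every quaternion.
        return QuaternionArray(
            other * self.a, other * self.b, other * self.c, other * self.d
        )

    def conj(self) -> "QuaternionArray":
        return QuaternionArray(self.a, -self.b, -self.c, -self.d)

    def norm(self) -> np.ndarray:
        return np.sqrt(self.a**2 + self.b**2 + self.c**2 + self.d**2)

    def norm_sq(self) -> np.ndarray:
        return self.a**2 + self.b**2 + self.c**2 + self.d**2

    def vector_norm(self) -> np.ndarray:
        return np.sqrt(self.b**2 + self.c**2 + self.d**2)

    def inverse(self) -> "QuaternionArray":
        """Multiplicative inverse ``q* / |q|^2``; undefined at zero."""
        n2 = self.norm_sq()
        if np.any(n2 == 0.0):
            raise ZeroDivisionError("zero quaternion has no inverse")
        return QuaternionArray(self.a / n2, -self.b / n2, -self.c / n2, -self.d / n2)

    def allclose(self, other: "QuaternionArray", atol: float = STRICT_ATOL) -> bool:
        return bool(
            np.allclose(self.a, other.a, atol=atol)
            and np.allclose(self.b, other.b, atol=atol)
            and np.allclose(self.c, other.c, atol=atol)
            and np.allclose(self.d, other.d, atol=atol)
        )

    def __repr__(self):
        if self.ndim == 0:
            return (
                f"Quaternion({float(self.a):.6g}, {float(self.b):.6g}, "
                f"{float(self.c):.6g}, {float(self.d):.6g})"
            )
        return f"QuaternionArray(shape={self.shape})"


def Quaternion(a, b=0.0, c=0.0, d=0.0) -> QuaternionArray:
    """A single quaternion ``a + b*i + c*j + d*k`` (0-d :class:`QuaternionArray`)."""
    q = QuaternionArray(float(a), float(b), float(c), float(d))
    if q.ndim != 0:
        raise ValueError("Quaternion takes scalar coefficients")
    return q


def qmul(q1: QuaternionArray, q2: QuaternionArray) -> QuaternionArray:
    """Hamilton product of two quaternion arrays (element-wise, broadcast).

    In scalar/vector notation ``(r1, v1)(r2, v2) =
    (r1 r2 - v1.v2,  r1 v2 + r2 v1 + v1 x v2)``; the cross product makes the
    product non-commutative.
    """
    try:
        np.broadcast_shapes(q1.shape, q2.shape)
    except ValueError as exc:
        raise ValueError(
            f"quaternion shapes {q1.shape} and {q2.shape} are not broadcastable"
        ) from exc
    a1, b1, c1, d1 = q1.a, q1.b, q1.c, q1.d
    a2, b2, c2, d2 = q2.a, q2.b, q2.c, q2.d
    return QuaternionArray(
        a1 * a2 - b1 * b2 - c1 * c2 - d1 * d2,
        a1 * b2 + b1 * a2 + c1 * d2 - d1 * c2,
        a1 * c2 - b1 * d2 + c1 * a2 + d1 * b2,
        a1 * d2 + b1 * c2 - c1 * b2 + d1 * a2,
    )


def conjugate(q: QuaternionArray) -> QuaternionArray:
    return q.conj()


def norm(q: QuaternionArray) -> np.ndarray:
    return q.norm()


def inverse(q: QuaternionArray) -> QuaternionArray:
    return q.inverse()


def qconj_norm_inv(q: QuaternionArray):
    """Conjugate, norm and inverse of ``q`` in one call."""
    return q.conj(), q.norm(), q.inverse()


class RotationQuaternion(QuaternionArray):
    """Unit quaternion encoding a rotation of R^3.

    ``r`` and ``-r`` encode the same rotation (double cover of SO(3)); the
    stored representative is canonicalized to a non-negative real part so
    serialized rotations are reproducible.
    """

    def __init__(self, a, b, c, d):
        super().__init__(a, b, c, d)
        if self.ndim != 0:
            raise ValueError("RotationQuaternion must be a single quaternion")
        n = float(self.norm())
        if abs(n - 1.0) > UNIT_ATOL:
            raise ValueError(f"rotation quaternion must have unit norm, got {n!r}")
        # Renormalize exactly and resolve the double cover.
        sign = -1.0 if float(self.a) < 0.0 else 1.0
        self.a = np.asarray(sign * float(self.a) / n)
        self.b = np.asarray(sign * float(self.b) / n)
        self.c = np.asarray(sign * float(self.c) / n)
        self.d = np.asarray(sign * float(self.d) / n)

    @property
    def angle(self) -> float:
        """Rotation angle in radians, in [0, pi] after canonicalization."""
        va = float(self.vector_norm())
        return 2.0 * np.arctan2(va, float(self.a))

    @property
    def axis(self) -> np.ndarray:
        """Unit rotation axis; (1, 0, 0) by convention for the identity."""
        v = self.vector().astype(float)
        n = np.linalg.norm(v)
        if n == 0.0:
            return np.array([1.0, 0.0, 0.0])
        return v / n

    def __repr__(self):
        ax = self.axis
        return (
            f"RotationQuaternion(angle={np.degrees(self.angle):.4g} deg, "
            f"axis=({ax[0]:.4g}, {ax[1]:.4g}, {ax[2]:.4g}))"
        )


def make_rotation(axis, angle: float) -> RotationQuaternion:
    """Rotation quaternion ``cos(theta/2) + sin(theta/2) * u`` for angle
    ``theta`` (radians) about ``axis`` (any non-zero 3-vector, normalized
    internally)."""
    axis = np.asarray(axis, dtype=float)
    if axis.shape != (3,):
        raise ValueError(f"axis must be a 3-vector, got shape {axis.shape}")
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("rotation axis must be non-zero")
    u = axis / n
    h = 0.5 * float(angle)
    s = np.sin(h)
    return RotationQuaternion(np.cos(h), s * u[0], s * u[1], s * u[2])


def _check_unit_rotation(r: QuaternionArray) -> None:
    n = float(np.asarray(r.norm()))
    if abs(n - 1.0) > UNIT_ATOL:
        raise ValueError(f"rotation quaternion must be unit norm, got {n!r}")


def rotate(r: QuaternionArray, q: QuaternionArray) -> QuaternionArray:
    """Rotate the vector part of ``q`` by the unit quaternion ``r``.

    Applies the sandwich product ``r q r^-1``; for unit ``r`` the inverse is
    the conjugate, which is used here.  The real part of ``q`` and the length
    of its vector part are preserved.
    """
    _check_unit_rotation(r)
    return qmul(qmul(r, q), r.conj())


def rotation_between(u1, u2) -> RotationQuaternion:
    """The minimal rotation carrying unit vector ``u1`` onto unit vector ``u2``.

    The rotation angle is ``arccos(u1.u2)`` and the axis is parallel to
    ``u1 x u2``.  Antiparallel inputs rotate by pi about a deterministic
    axis orthogonal to ``u1`` (the normalized cross of ``u1`` with the
    standard basis vector along which ``u1`` has the smallest magnitude).
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    for name, u in (("u1", u1), ("u2", u2)):
        if u.shape != (3,):
            raise ValueError(f"{name} must be a 3-vector")
        if abs(np.linalg.norm(u) - 1.0) > UNIT_ATOL:
            raise ValueError(f"{name} must be unit length, got norm {np.linalg.norm(u)!r}")
    dot = float(np.clip(np.dot(u1, u2), -1.0, 1.0))
    cross = np.cross(u1, u2)
    cn = np.linalg.norm(cross)
    if cn <= STRICT_ATOL and dot > 0.0:
        return RotationQuaternion(1.0, 0.0, 0.0, 0.0)
    if cn <= STRICT_ATOL and dot < 0.0:
        # Antiparallel: any axis orthogonal to u1 works; pick deterministically.
        e = np.zeros(3)
        e[int(np.argmin(np.abs(u1)))] = 1.0
        axis = np.cross(u1, e)
        axis /= np.linalg.norm(axis)
        return make_rotation(axis, np.pi)
    angle = np.arccos(dot)
    return make_rotation(cross / cn, angle)
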