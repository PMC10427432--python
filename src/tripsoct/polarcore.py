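"""Stokes/Jones/Mueller algebra for polarization-sensitive OCT.

Conventions used throughout the package
---------------------------------------
* Stokes vectors are ordered ``(I, Q, U, V)``.
* The Pauli basis is ``sigma_1 = diag(1,-1)`` (Q), ``sigma_2 = [[0,1],[1,0]]``
  (U) and ``sigma_3 = [[0,-i],[i,0]]`` (V), so an in-plane optic axis at
  physical angle ``theta`` maps to the Poincare direction
  ``(cos 2theta, sin 2theta, 0)``.
* A retarder of retardance ``delta`` about Poincare axis ``a`` has Jones
  matrix ``exp(-i delta/2 (a . sigma))``; its Mueller matrix rotates the
  (Q,U,V) block right-handedly by ``delta`` about ``a``.
* Matrix square roots and logarithms are principal: the retardance of the
  result stays below 180 deg (360 deg on the argument), branch continuity
  across an image is the caller's job (see ``recon.estimate_cornea``).

All operations are vectorised over arbitrary leading axes; a "matrix" is any
array whose trailing axes are ``(4, 4)`` (Mueller) or ``(2, 2)`` (Jones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "PAULI",
    "PolarimetryError",
    "InvalidAxisError",
    "NullTransmissionError",
    "DegenerateMatrixError",
    "PurityError",
    "BranchAmbiguityError",
    "StokesVector",
    "MuellerMatrix",
    "DiattenuationParams",
    "ProbingStates",
    "stokes_dop",
    "jones_retarder",
    "retarder_mueller",
    "jones_diattenuator",
    "diattenuator_mueller",
    "jones_to_mueller",
    "jones_from_mueller",
    "is_pure",
    "purity_residual",
    "depolarization_index",
    "jones_exp",
    "jones_log",
    "jones_sqrt",
    "mueller_sqrt",
    "rotation_block",
    "retardance_axis_of",
    "axis_azimuth_deg",
    "design_probing_states",
    "orthogonality_defect",
    "jones_mueller_jacobian_rank",
]

# ---------------------------------------------------------------------------
# errors

class PolarimetryError(ValueError):
    """Base class for polarimetric algebra errors."""


class InvalidAxisError(PolarimetryError):
    pass


class NullTransmissionError(PolarimetryError):
    pass


class DegenerateMatrixError(PolarimetryError):
    pass


class PurityError(PolarimetryError):
    pass


class BranchAmbiguityError(PolarimetryError):
    pass


# ---------------------------------------------------------------------------
# basis

PAULI = np.stack([
    np.eye(2, dtype=complex),
    np.array([[1, 0], [0, -1]], dtype=complex),
    np.array([[0, 1], [1, 0]], dtype=complex),
    np.array([[0, -1j], [1j, 0]], dtype=complex),
])


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class StokesVector:
    """A single Stokes vector in detector units.

    ``I`` must be positive; for physical (sub-unity DOP) vectors
    ``sqrt(Q^2+U^2+V^2) <= I`` within tolerance.
    """

    I: float
    Q: float
    U: float
    V: float

    @property
    def dop(self) -> float:
        return float(np.sqrt(self.Q**2 + self.U**2 + self.V**2) / self.I)

    def as_array(self) -> np.ndarray:
        return np.array([self.I, self.Q, self.U, self.V], dtype=float)

    def validate(self, tol: float = 1e-9) -> None:
        if self.I <= 0:
            raise DegenerateMatrixError("Stokes intensity must be positive")
        if self.dop > 1 + tol:
            raise PolarimetryError(f"unphysical DOP {self.dop:.6f} > 1")


@dataclass
class MuellerMatrix:
    """A tagged 4x4 Mueller matrix.

    ``stage_tag`` records the physical interpretation: ``general``, ``pure``
    (Jones-derivable), ``retarder``, ``diattenuator`` or ``depolarizer``.
    """

    m: np.ndarray
    stage_tag: str = "general"

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape[-2:] != (4, 4):
            raise PolarimetryError("Mueller matrix must be (...,4,4)")

    def validate(self, tol: float = 1e-6) -> None:
        m00 = self.m[..., 0, 0]
        if np.any(m00 <= 0):
            raise DegenerateMatrixError("m00 must be positive")
        if self.stage_tag == "retarder":
            r = self.m[..., 1:, 1:]
            if not np.allclose(r @ np.swapaxes(r, -1, -2),
                               np.broadcast_to(np.eye(3), r.shape), atol=tol):
                raise PolarimetryError("retarder QUV block is not orthogonal")
            if np.any(np.abs(np.linalg.det(r) - 1) > 10 * tol):
                raise PolarimetryError("retarder QUV block has det != +1")
            edge = np.concatenate([self.m[..., 0, 1:], self.m[..., 1:, 0]], axis=-1)
            if np.any(np.abs(edge) > tol):
                raise PolarimetryError("retarder must not polarize")
        if self.stage_tag == "pure":
            ok, res = is_pure(self.m, tol=tol)
            if not np.all(ok):
                raise PurityError(f"matrix not Jones-derivable (residual {np.max(res):.3g})")


@dataclass(frozen=True)
class DiattenuationParams:
    """Extreme amplitude transmissions ``p1 >= p2 >= 0`` and Poincare axis."""

    p1: float
    p2: float
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0 <= self.p2 <= self.p1):
            raise PolarimetryError("require 0 <= p2 <= p1")
        if self.p1 == 0:
            raise NullTransmissionError("p1 = p2 = 0 transmits nothing")

    @property
    def dia(self) -> float:
        """Diattenuation magnitude (p1^2 - p2^2)/(p1^2 + p2^2), in [0, 1]."""
        return (self.p1**2 - self.p2**2) / (self.p1**2 + self.p2**2)


@dataclass(frozen=True)
class ProbingStates:
    """The triple of input polarization states of the modulator.

    ``theta_pol`` is the physical angle between the linear polarizer and the
    EOM optic axis (degrees); ``eom_retardances`` the triple-step retardance
    drive (degrees); ``s`` the 4x3 probing matrix whose columns are the three
    unit-intensity Stokes states.
    """

    theta_pol: float
    eom_retardances: tuple[float, float, float]
    s: np.ndarray = field(repr=False)

    def validate(self, tol: float = 1e-9) -> None:
        quv = self.s[1:]
        if not np.allclose(np.linalg.norm(quv, axis=0), 1.0, atol=tol):
            raise PolarimetryError("probing states must be fully polarized")
        g = quv.T @ quv
        if np.max(np.abs(g - np.diag(np.diag(g)))) > tol:
            raise PolarimetryError("probing states must be mutually orthogonal")


# ---------------------------------------------------------------------------
# Stokes helpers

def stokes_dop(s: np.ndarray) -> np.ndarray:
    """Degree of polarization of Stokes vectors stored on the last axis."""
    s = np.asarray(s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(np.sum(s[..., 1:] ** 2, axis=-1)) / s[..., 0]


def _unit_axis(axis, allow_zero: bool = False) -> np.ndarray:
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a, axis=-1, keepdims=True)
    if np.any(n < 1e-300):
        if allow_zero:
            return np.zeros_like(a)
        raise InvalidAxisError("axis must have nonzero norm")
    return a / n


# ---------------------------------------------------------------------------
# constructors

def jones_retarder(delta_deg, axis) -> np.ndarray:
    """Jones matrix ``exp(-i delta/2 (a . sigma))`` of a linear/elliptical retarder."""
    d = np.deg2rad(np.asarray(delta_deg, dtype=float))
    if np.all(d == 0):
        a = np.asarray(axis, dtype=float)
    else:
        a = _unit_axis(axis)
    asig = np.einsum("...k,kij->...ij", a, PAULI[1:])
    c = np.cos(d / 2)[..., None, None]
    s = np.sin(d / 2)[..., None, None]
    return c * np.eye(2) - 1j * s * asig


def retarder_mueller(delta_deg, axis) -> np.ndarray:
    """Mueller matrix of a pure retarder: QUV rotation by ``delta_deg`` about ``axis``.

    Dual route to ``jones_to_mueller(jones_retarder(...))`` (Rodrigues form);
    the two agree to machine precision and are cross-checked in the tests.
    """
    d = np.deg2rad(np.asarray(delta_deg, dtype=float))
    if np.all(d == 0):
        a = _unit_axis(axis, allow_zero=True)
    else:
        a = _unit_axis(axis)
    d = np.broadcast_to(d, a.shape[:-1])
    zeros = np.zeros_like(a[..., 0])
    K = np.stack([
        np.stack([zeros, -a[..., 2], a[..., 1]], axis=-1),
        np.stack([a[..., 2], zeros, -a[..., 0]], axis=-1),
        np.stack([-a[..., 1], a[..., 0], zeros], axis=-1),
    ], axis=-2)
    sd = np.sin(d)[..., None, None]
    cd = (1 - np.cos(d))[..., None, None]
    r = np.eye(3) + sd * K + cd * (K @ K)
    out = np.zeros(a.shape[:-1] + (4, 4), dtype=float)
    out[..., 0, 0] = 1.0
    out[..., 1:, 1:] = r
    return out


def jones_diattenuator(p1, p2, axis) -> np.ndarray:
    a = _unit_axis(axis)
    proj = 0.5 * (np.eye(2) + np.einsum("...k,kij->...ij", a, PAULI[1:]))
    p1 = np.asarray(p1, dtype=float)[..., None, None]
    p2 = np.asarray(p2, dtype=float)[..., None, None]
    return p1 * proj + p2 * (np.eye(2) - proj)


def diattenuator_mueller(p: DiattenuationParams) -> np.ndarray:
    """Symmetric Mueller matrix of a homogeneous diattenuator.

    Unpolarized transmittance is ``(p1^2+p2^2)/2``; the diattenuation
    magnitude equals ``p.dia``.
    """
    return jones_to_mueller(jones_diattenuator(p.p1, p.p2, p.axis))


# ---------------------------------------------------------------------------
# Jones <-> Mueller

# change of basis between the coherency vector (Ex Ex*, Ex Ey*, ...) and Stokes
_A_STOKES = np.array([[1, 0, 0, 1],
                      [1, 0, 0, -1],
                      [0, 1, 1, 0],
                      [0, 1j, -1j, 0]], dtype=complex)
_A_STOKES_INV = np.linalg.inv(_A_STOKES)


def jones_to_mueller(J: np.ndarray) -> np.ndarray:
    """Mueller matrix ``M_kl = Re tr(sigma_k J sigma_l J^dagger)/2`` of a Jones matrix.

    Expanded to real arithmetic on the Jones components (no large complex
    temporaries). Invariant under a global phase of ``J``. A zero Jones
    matrix maps to the (degenerate) zero Mueller matrix.
    """
    J = np.asarray(J)
    ar, ai = J[..., 0, 0].real, J[..., 0, 0].imag
    br, bi = J[..., 0, 1].real, J[..., 0, 1].imag
    cr, ci = J[..., 1, 0].real, J[..., 1, 0].imag
    dr, di = J[..., 1, 1].real, J[..., 1, 1].imag
    A, B = 0.5 * (ar * ar + ai * ai), 0.5 * (br * br + bi * bi)
    C, D = 0.5 * (cr * cr + ci * ci), 0.5 * (dr * dr + di * di)
    ab_r, ab_i = ar * br + ai * bi, ai * br - ar * bi     # a conj(b)-like pairs
    cd_r, cd_i = cr * dr + ci * di, ci * dr - cr * di
    ac_r, ac_i = ar * cr + ai * ci, ar * ci - ai * cr
    bd_r, bd_i = br * dr + bi * di, br * di - bi * dr
    ad_r, ad_i = ar * dr + ai * di, ar * di - ai * dr
    bc_r, bc_i = br * cr + bi * ci, br * ci - bi * cr
    M = np.empty(J.shape[:-2] + (4, 4),
                 dtype=np.result_type(ar.dtype, np.float32))
    M[..., 0, 0] = A + B + C + D
    M[..., 0, 1] = A - B + C - D
    M[..., 0, 2] = ab_r + cd_r
    M[..., 0, 3] = ab_i + cd_i
    M[..., 1, 0] = A + B - C - D
    M[..., 1, 1] = A - B - C + D
    M[..., 1, 2] = ab_r - cd_r
    M[..., 1, 3] = ab_i - cd_i
    M[..., 2, 0] = ac_r + bd_r
    M[..., 2, 1] = ac_r - bd_r
    M[..., 2, 2] = ad_r + bc_r
    M[..., 2, 3] = -ad_i + bc_i
    M[..., 3, 0] = ac_i + bd_i
    M[..., 3, 1] = ac_i - bd_i
    M[..., 3, 2] = ad_i + bc_i
    M[..., 3, 3] = ad_r - bc_r
    return M


def _coherency(M: np.ndarray) -> np.ndarray:
    """Hermitian 4x4 coherency matrix; rank one iff M is Jones-derived."""
    M = np.asarray(M, dtype=float)
    kron = np.einsum("kab,lcd->klacbd", PAULI, PAULI.conj()).reshape(4, 4, 4, 4)
    return 0.25 * np.einsum("...kl,klab->...ab", M, kron, optimize=True)


def jones_from_mueller(M: np.ndarray) -> np.ndarray:
    """Principal Jones matrix of a pure Mueller matrix (phase-arbitrary).

    Takes the dominant eigenvector of the coherency matrix; exact for pure
    inputs, the closest pure factor (in Frobenius norm of the coherency)
    otherwise.
    """
    H = _coherency(M)
    w, v = np.linalg.eigh(H)
    top = v[..., :, -1] * np.sqrt(np.maximum(w[..., -1:], 0.0) * 2.0)
    return top.reshape(top.shape[:-1] + (2, 2))


def purity_residual(M: np.ndarray) -> np.ndarray:
    """Relative Frobenius distance of ``M`` to the closest Jones-derived matrix."""
    M = np.asarray(M, dtype=float)
    w = np.linalg.eigvalsh(_coherency(M))
    tail = np.sqrt(np.sum(np.clip(w[..., :-1], None, np.inf) ** 2, axis=-1)
                   + np.clip(w[..., -1], None, 0.0) ** 2)
    norm = np.linalg.norm(M, axis=(-2, -1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(norm > 0, 2.0 * tail / norm, 0.0)


def is_pure(M: np.ndarray, tol: float = 1e-6):
    """Whether ``M`` is (numerically) Jones-derivable, plus the purity residual."""
    res = purity_residual(M)
    return res <= tol, res


def depolarization_index(M: np.ndarray) -> np.ndarray:
    """Gil-Bernabeu depolarization index.

    ``DI = sqrt((sum_ij m_ij^2 - m00^2) / (3 m00^2))``: 1 for nondepolarizing
    matrices, 0 for the ideal depolarizer diag(1,0,0,0).
    """
    M = np.asarray(M, dtype=float)
    m00 = M[..., 0, 0]
    if np.any(m00 <= 0):
        raise DegenerateMatrixError("depolarization index requires m00 > 0")
    q = (np.sum(M**2, axis=(-2, -1)) - m00**2) / (3.0 * m00**2)
    return np.sqrt(np.clip(q, 0.0, None))


# ---------------------------------------------------------------------------
# closed-form 2x2 exp / log / sqrt (Pauli algebra)

def _pauli_split(A: np.ndarray):
    A = np.asarray(A, dtype=complex)
    c = 0.5 * (A[..., 0, 0] + A[..., 1, 1])
    w = np.stack([
        0.5 * (A[..., 0, 0] - A[..., 1, 1]),
        0.5 * (A[..., 0, 1] + A[..., 1, 0]),
        0.5j * (A[..., 0, 1] - A[..., 1, 0]),
    ], axis=-1)
    return c, w


def _pauli_join(c: np.ndarray, w: np.ndarray) -> np.ndarray:
    out = np.empty(np.asarray(c).shape + (2, 2),
                   dtype=np.result_type(np.asarray(c).dtype, w.dtype, np.complex64))
    out[..., 0, 0] = c + w[..., 0]
    out[..., 1, 1] = c - w[..., 0]
    out[..., 0, 1] = w[..., 1] - 1j * w[..., 2]
    out[..., 1, 0] = w[..., 1] + 1j * w[..., 2]
    return out


def _jones_exp_cw(c: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Exponential of the generator ``c I + w . sigma`` in Pauli form."""
    lam = np.sqrt(np.sum(w * w, axis=-1) + 0j)
    small = np.abs(lam) < 1e-30
    lam_safe = np.where(small, 1.0, lam)
    sinhc = np.where(small, 1.0 + lam**2 / 6.0, np.sinh(lam_safe) / lam_safe)
    return np.exp(c)[..., None, None] * _pauli_join(np.cosh(lam), sinhc[..., None] * w)


def jones_exp(K: np.ndarray) -> np.ndarray:
    """Matrix exponential of a 2x2 complex generator, closed form."""
    c, w = _pauli_split(K)
    return _jones_exp_cw(c, w)


def jones_log(J: np.ndarray) -> np.ndarray:
    """Principal matrix logarithm of an invertible 2x2 complex matrix.

    Eigenvalue logs take their principal branch, so the retardance part of
    the generator has magnitude below 360 deg.
    """
    c, w = _pauli_split(J)
    lam = np.sqrt(np.sum(w * w, axis=-1) + 0j)
    mu_p, mu_m = c + lam, c - lam
    if np.any(np.abs(mu_p) < 1e-300) or np.any(np.abs(mu_m) < 1e-300):
        raise DegenerateMatrixError("singular Jones matrix has no logarithm")
    lp, lm = np.log(mu_p), np.log(mu_m)
    small = np.abs(lam) < 1e-30
    lam_safe = np.where(small, 1.0, lam)
    coef = np.where(small, 1.0 / np.where(np.abs(c) < 1e-300, 1.0, c),
                    (lp - lm) / (2.0 * lam_safe))
    return _pauli_join(0.5 * (lp + lm), coef[..., None] * w)


def jones_sqrt(J: np.ndarray) -> np.ndarray:
    """Principal square root, ``exp(log(J)/2)``."""
    return jones_exp(0.5 * jones_log(J))


def mueller_sqrt(M: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Principal square root of a pure Mueller matrix, taken on the Jones side.

    Halves the retardance and the diattenuation generator and takes the square
    root of the gain, so that ``sqrt(M) @ sqrt(M) == M``. Raises
    ``PurityError`` for depolarizing input and ``BranchAmbiguityError`` when
    the retardance sits at the 360 deg branch point.
    """
    ok, res = is_pure(M, tol=tol)
    if not np.all(ok):
        raise PurityError(f"mueller_sqrt needs a pure matrix (residual {np.max(res):.3g})")
    J = jones_from_mueller(M)
    c, w = _pauli_split(J)
    lam = np.sqrt(np.sum(w * w, axis=-1) + 0j)
    # at the branch point the eigenvalue ratio is real negative
    mu_p, mu_m = c + lam, c - lam
    if np.any(np.abs(mu_p) < 1e-300) or np.any(np.abs(mu_m) < 1e-300):
        raise DegenerateMatrixError("singular matrix has no principal root")
    ratio = mu_p / mu_m
    if np.any((ratio.real < 0) & (np.abs(ratio.imag) <= 1e-12 * np.abs(ratio.real))):
        raise BranchAmbiguityError("retardance at the 360 deg wrapping limit")
    return jones_to_mueller(jones_sqrt(J))


# ---------------------------------------------------------------------------
# retarder analysis

def rotation_block(M: np.ndarray) -> np.ndarray:
    """The lower-right 3x3 (QUV) block."""
    return np.asarray(M, dtype=float)[..., 1:, 1:]


def retardance_axis_of(M: np.ndarray, tol: float = 1e-6):
    """Retardance (deg, in [0, 180]) and rotation axis of a pure retarder.

    Returns ``(delta_deg, axis, defined)`` where ``defined`` flags pixels
    with nonzero retardance; at ``delta = 0`` the axis is undefined and
    returned as the zero vector rather than NaN so downstream masking stays
    explicit. The axis flips sign rather than letting ``delta`` exceed 180.
    """
    M = np.asarray(M, dtype=float)
    r = rotation_block(M)
    ortho = np.abs(r @ np.swapaxes(r, -1, -2) - np.eye(3)).max(axis=(-2, -1))
    if np.any(ortho > max(tol, 1e-6) * 100):
        raise PolarimetryError("QUV block is not a proper rotation")
    shape = r.shape[:-2]
    rv = Rotation.from_matrix(r.reshape((-1, 3, 3))).as_rotvec().reshape(shape + (3,))
    delta = np.linalg.norm(rv, axis=-1)
    defined = delta > 1e-12
    axis = np.where(defined[..., None], rv / np.where(defined, delta, 1.0)[..., None], 0.0)
    return np.rad2deg(delta), axis, defined


def axis_azimuth_deg(axis: np.ndarray) -> np.ndarray:
    """In-plane optic-axis orientation (deg, mod 180) of a Poincare axis.

    Half the azimuth of the (Q,U) projection; the V component is ignored
    (circular retardance carries no in-plane orientation).
    """
    axis = np.asarray(axis, dtype=float)
    return np.rad2deg(0.5 * np.arctan2(axis[..., 1], axis[..., 0])) % 180.0


# ---------------------------------------------------------------------------
# field-level helpers

def spinor_from_stokes_dir(d: np.ndarray) -> np.ndarray:
    """Unit Jones vector (spinor) of a fully polarized Stokes direction.

    ``d`` holds (Q,U,V)/I on the last axis with unit norm. The two affine
    charts ``(1+q, u+iv)`` and ``(u-iv, 1-q)`` describe the same projective
    point; the better-conditioned one is chosen per element, so the map is
    defined everywhere on the Poincare sphere (global phase arbitrary).
    """
    d = np.asarray(d)
    q, u, v = d[..., 0], d[..., 1], d[..., 2]
    p = np.empty(q.shape + (2,), dtype=np.result_type(d.dtype, np.complex64))
    p[..., 0] = 1 + q
    p[..., 1] = u + 1j * v
    bad = q < -0.5                       # switch chart near the south pole
    if np.any(bad):
        p[bad, 0] = u[bad] - 1j * v[bad]
        p[bad, 1] = 1 - q[bad]
    n = np.sqrt(np.abs(p[..., 0]) ** 2 + np.abs(p[..., 1]) ** 2)
    return p / n[..., None]


def stokes_from_field(E: np.ndarray) -> np.ndarray:
    """Stokes vector of a Jones field vector ``E = (Ex, Ey)`` on the last axis."""
    a, b = E[..., 0], E[..., 1]
    aa, bb = np.abs(a) ** 2, np.abs(b) ** 2
    ab = np.conj(a) * b
    return np.stack([aa + bb, aa - bb, 2 * ab.real, 2 * ab.imag], axis=-1)


# ---------------------------------------------------------------------------
# probing-state design

def _triple_states(theta_pol_deg: float, eom_retardances_deg) -> np.ndarray:
    """4x3 Stokes probing matrix for a polarizer at ``theta_pol`` before an EOM.

    The EOM optic axis is horizontal, hence a retardance step ``eta`` rotates
    the polarizer state ``(1, cos 2theta, sin 2theta, 0)`` about the Q axis.
    """
    t2 = np.deg2rad(2.0 * theta_pol_deg)
    eta = np.deg2rad(np.asarray(eom_retardances_deg, dtype=float))
    q = np.full(eta.shape, np.cos(t2))
    u = np.sin(t2) * np.cos(eta)
    v = np.sin(t2) * np.sin(eta)
    return np.stack([np.ones_like(q), q, u, v], axis=0)


def orthogonality_defect(theta_pol_deg: float,
                         eom_retardances_deg=(0.0, 120.0, -120.0)) -> float:
    """Maximum pairwise |dot| of the three output (Q,U,V) directions."""
    s = _triple_states(theta_pol_deg, eom_retardances_deg)[1:]
    g = s.T @ s
    return float(np.max(np.abs(g[~np.eye(3, dtype=bool)])))


def design_probing_states() -> ProbingStates:
    """The triple-input modulation design.

    A linear polarizer at ``theta = arccos(1/sqrt(3))/2 = 27.37 deg`` from the
    EOM axis, with the symmetric triple-step drive ``(0, +120, -120) deg``,
    yields three mutually orthogonal states on the Poincare sphere: the three
    (Q,U,V) directions share Q-component ``1/sqrt(3)`` and are spread 120 deg
    apart in the U-V plane. Deterministic; no RNG involved.
    """
    theta = np.rad2deg(np.arccos(1.0 / np.sqrt(3.0))) / 2.0
    eom = (0.0, 120.0, -120.0)
    return ProbingStates(theta_pol=float(theta), eom_retardances=eom,
                         s=_triple_states(theta, eom))


# ---------------------------------------------------------------------------
# model dimensionality

def jones_mueller_jacobian_rank(n_points: int = 8, seed: int = 0,
                                rtol: float = 1e-8) -> int:
    """Numerical rank of the Jacobian of the Jones-to-Mueller map.

    A general 2x2 complex Jones matrix has 8 real parameters; the global
    phase direction lies in the null space of the map, leaving the free
    parameter count of a pure Mueller matrix. The rank is evaluated at
    ``n_points`` random Jones matrices and must agree across them.
    """
    rng = np.random.default_rng(seed)
    ranks = set()
    for _ in range(n_points):
        x = rng.normal(size=8)
        J0 = (x[:4] + 1j * x[4:]).reshape(2, 2)
        eps = 1e-6
        cols = []
        for i in range(8):
            dx = np.zeros(8)
            dx[i] = eps
            Jp = ((x + dx)[:4] + 1j * (x + dx)[4:]).reshape(2, 2)
            Jm = ((x - dx)[:4] + 1j * (x - dx)[4:]).reshape(2, 2)
            cols.append(((jones_to_mueller(Jp) - jones_to_mueller(Jm)) / (2 * eps)).ravel())
        jac = np.stack(cols, axis=1)
        sv = np.linalg.svd(jac, compute_uv=False)
        ranks.add(int(np.sum(sv > rtol * sv[0])))
    if len(ranks) != 1:
        raise PolarimetryError(f"rank not constant across sample points: {sorted(ranks)}")
    return ranks.pop()
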