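"""The TRIPS reconstruction chain: measured Stokes volumes to local birefringence.

Pipeline stages, in running order (stage tags in brackets):

1.  ``filter_stokes``      -- lateral moving-average of the Stokes volumes;
2.  ``assemble_mu``        -- stack the three filtered Stokes vectors into the
                              4x3 measurement matrix ``mu = D L s`` per pixel;
3.  ``fit_pure_mueller``   -- re-polarize the columns of ``mu`` (correcting the
                              estimated effect of the depolarizing factor D)
                              and recover the pure Mueller matrix L, closed
                              form, per spectral bin;
4.  ``enforce_reciprocity``-- project onto transpose-symmetric Jones matrices
                              (round-trip reciprocity);
5.  ``align_spectral_bins``-- retarder-parametrized similarity transform per
                              bin, minimizing adjacent-bin misfit on sampled
                              frames;
6.  ``average_bins``       -- elementwise bin average [M] and its purification
                              by polar decomposition [M_P];
7.  ``estimate_cornea`` / ``compensate_cornea``
                           -- surface matrix S(x), its principal square root
                              C(x) with 2-D generator unwrapping, and the
                              two-sided compensation [M_PC];
8.  ``remove_diattenuation``-- polar decomposition retarder factor [M_RC];
9.  ``local_recursion``    -- layer peeling along depth to the local slab
                              retarder [m];
10. ``extract_birefringence_axis`` -- retardance/dz (deg/um), in-plane optic
                              axis (deg mod 180), depolarization index and
                              SNR masking.

A dual-input baseline (``dual_input_reconstruct``) shares stages 1 and 9-10
but estimates a pure rotation from two probing states only, assuming the
measurement contains no diattenuation.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from . import polarcore as pc
from .forward_sim import StokesFrameSet

__all__ = [
    "SurfaceNotFoundError",
    "MuMeasurement",
    "CorneaField",
    "LocalBirefVolume",
    "LuChipmanFactors",
    "ReconOptions",
    "filter_stokes",
    "assemble_mu",
    "fit_pure_mueller",
    "fit_pure_jones",
    "enforce_reciprocity",
    "enforce_reciprocity_jones",
    "align_spectral_bins",
    "average_bins",
    "lu_chipman_decompose",
    "find_tissue_surface",
    "estimate_cornea",
    "compensate_cornea",
    "remove_diattenuation",
    "local_recursion",
    "extract_birefringence_axis",
    "reconstruct",
    "dual_input_reconstruct",
    "estimate_axis_offset",
    "REFRACTIVE_INDEX",
]

#: group refractive index used to convert optical path length to tissue depth
REFRACTIVE_INDEX = 1.38


class SurfaceNotFoundError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# domain types

@dataclass
class MuMeasurement:
    """Per-pixel 4x3 measurement matrices and the probing states behind them."""

    mu: np.ndarray                      # (bin, y, x, z, 4, n_states)
    states: pc.ProbingStates


@dataclass
class CorneaField:
    """Corneal round-trip surface matrix and its compensating square root."""

    S: np.ndarray                       # (y, x, 4, 4) pure round-trip at surface
    C: np.ndarray                       # principal square root of S
    C_inv: np.ndarray
    retardance_deg: np.ndarray          # single-pass linear retardance map
    dia: np.ndarray                     # single-pass diattenuation map
    generator: np.ndarray               # (y, x, 6): unwrapped round-trip
                                        # rotation vector (rad) + dia generator
    valid: np.ndarray
    n_components: int = 1               # >1 when unwrapping ran per region


@dataclass
class LocalBirefVolume:
    """Depth-resolved birefringence product of the pipeline.

    ``birefringence`` is single-pass retardance per tissue depth (deg/um);
    ``axis_deg`` the in-plane optic-axis orientation (deg, mod 180), defined
    only where ``axis_defined``; ``mask`` is True where the pixel is valid
    (intensity SNR above threshold and no wrapping flag).
    """

    birefringence: np.ndarray           # (y, x, z)
    axis_deg: np.ndarray
    axis_defined: np.ndarray
    di: np.ndarray                      # depolarization index of stage M
    snr_db: np.ndarray
    mask: np.ndarray
    dz_um: float
    pitch_um: float
    wrap_flags: np.ndarray | None = None


@dataclass
class LuChipmanFactors:
    """M = M_delta @ M_R @ M_D, with any gain carried by M_D."""

    M_delta: np.ndarray
    M_R: np.ndarray
    M_D: np.ndarray
    flags: np.ndarray                   # True where a degenerate path was taken

    def recompose(self) -> np.ndarray:
        return self.M_delta @ self.M_R @ self.M_D


# ---------------------------------------------------------------------------
# 1-2: filtering and measurement assembly

def kernel_window(kernel_um: float, pitch_um: float) -> int:
    """Moving-average window in pixels: round(kernel/pitch), forced odd."""
    w = max(int(round(kernel_um / pitch_um)), 1)
    return w if w % 2 == 1 else w + 1


def filter_stokes(frames: StokesFrameSet, kernel_um: float) -> StokesFrameSet:
    """Moving-average the Stokes volumes along both lateral scan directions.

    Averaging Stokes vectors is intensity-weighted by construction (Stokes
    vectors of independent speckles add), and can only reduce the degree of
    polarization. A kernel below one pixel is a no-op with a warning.
    """
    w = kernel_window(kernel_um, frames.pitch_um)
    if w <= 1:
        if kernel_um < frames.pitch_um:
            warnings.warn("filter kernel below one pixel; Stokes volumes "
                          "left unfiltered", stacklevel=2)
        return frames
    st = frames.stokes.astype(np.float32, copy=True)
    st = ndimage.uniform_filter1d(st, w, axis=2, mode="nearest")
    st = ndimage.uniform_filter1d(st, w, axis=3, mode="nearest")
    meta = dict(frames.metadata)
    meta["filter_window_px"] = w
    return StokesFrameSet(stokes=st, pitch_um=frames.pitch_um,
                          dz_um=frames.dz_um, states=frames.states,
                          metadata=meta)


def assemble_mu(frames: StokesFrameSet) -> MuMeasurement:
    """Stack the filtered Stokes vectors as columns of mu, per pixel per bin."""
    mu = np.transpose(frames.stokes, (0, 2, 3, 4, 5, 1))
    return MuMeasurement(mu=mu, states=frames.states)


# ---------------------------------------------------------------------------
# 3: pure Mueller fit from three probing states

def _repolarized_dirs(mu: np.ndarray, dop_min: float):
    """Unit (Q,U,V) directions of each measured column, plus a validity flag.

    Re-normalizing the polarized part to unit DOP while keeping the intensity
    removes the isotropic part of the depolarization that bin averaging and
    speckle introduce -- the correction for the estimated effect of the
    depolarizing factor D.
    """
    inten = mu[..., 0, :]
    quv = mu[..., 1:, :]
    norm = np.linalg.norm(quv, axis=-2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dop = np.where(inten > 0, norm / inten, 0.0)
    ok = (inten > 0) & (dop >= dop_min)
    dirs = quv / np.where(norm > 0, norm, 1.0)[..., None, :]
    return dirs, inten, ok.all(axis=-1)


def _mobius_basis(spinors: np.ndarray) -> np.ndarray:
    """2x2 basis matrix B with B @ e1 ~ p1, B @ e2 ~ p3, B @ (1,1) ~ p2.

    ``spinors`` holds three unit spinors on the last-but-one axis stacked
    along the last axis, shape (..., 2, 3).
    """
    p1, p2, p3 = spinors[..., 0], spinors[..., 1], spinors[..., 2]
    A = np.stack([p1, p3], axis=-1)
    ab = np.linalg.solve(A, p2[..., None])[..., 0]
    return A * ab[..., None, :]


def fit_pure_jones(mu: np.ndarray, states: pc.ProbingStates,
                   dop_min: float = 0.05, refine_iters: int = 1):
    """Closed-form pure (Jones-derived) fit to a 4x3 measurement matrix.

    A nonsingular Jones matrix is fixed, up to complex scale, by where it
    sends three distinct polarization states on the Poincare sphere -- the
    geometric reason three probing states suffice to recover retardance and
    diattenuation together. The measured columns are re-polarized to unit
    DOP, mapped to spinors, and the unique projective map through the three
    input/output pairs is solved per pixel; the remaining gain is set so the
    mean output intensity is preserved. ``refine_iters`` Gauss-Newton steps
    then minimize the Frobenius misfit to the re-polarized measurement over
    all 7 parameters, which averages the measurement redundancy into the
    estimate (the closed form interpolates the three directions exactly and
    is used as the initial point).

    Returns ``(J, ok)``: the Jones volume (with gain) and a flag that is
    False where a column had DOP below ``dop_min`` or the fit was degenerate
    (collinear measured states); such pixels carry an identity Jones matrix
    and must be masked downstream.
    """
    mu = np.ascontiguousarray(mu)
    dirs, inten, ok = _repolarized_dirs(mu, dop_min)
    # input spinors are fixed by the probing design
    s_dirs = states.s[1:] / np.linalg.norm(states.s[1:], axis=0)
    p_in = pc.spinor_from_stokes_dir(s_dirs.T)            # (3, 2)
    Bz = _mobius_basis(np.transpose(p_in)[None])[0]       # (2, 2)
    Bz_inv = np.linalg.inv(Bz)

    c_dtype = np.result_type(mu.dtype, np.complex64)
    p_in = p_in.astype(c_dtype)
    Bz_inv = Bz_inv.astype(c_dtype)
    p_out = pc.spinor_from_stokes_dir(np.moveaxis(dirs, -2, -1))  # (...,3,2)
    p1, p2, p3 = p_out[..., 0, :], p_out[..., 1, :], p_out[..., 2, :]
    # solve [p1 p3] (alpha, beta)^T = p2 by Cramer's rule (2x2 complex)
    det = p1[..., 0] * p3[..., 1] - p1[..., 1] * p3[..., 0]
    ok = ok & (np.abs(det) > 1e-12)
    det_s = np.where(ok, det, 1.0)
    alpha = (p2[..., 0] * p3[..., 1] - p2[..., 1] * p3[..., 0]) / det_s
    beta = (p1[..., 0] * p2[..., 1] - p1[..., 1] * p2[..., 0]) / det_s
    ok = ok & (np.abs(alpha) > 1e-12) & (np.abs(beta) > 1e-12)
    Bw = np.stack([alpha[..., None] * p1, beta[..., None] * p3], axis=-1)
    J = np.where(ok[..., None, None], Bw @ Bz_inv, np.eye(2, dtype=c_dtype))

    # gain: preserve the mean measured output intensity
    E = np.einsum("...ab,sb->...sa", J, p_in, optimize=True)
    i_model = np.sum(E.real**2 + E.imag**2, axis=(-2, -1))
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.sum(inten, axis=-1) / i_model
    g = np.where(ok & np.isfinite(g) & (g > 0), g, 1.0)
    J = J * np.sqrt(g)[..., None, None]
    if refine_iters > 0:
        mu_pol = np.empty(inten.shape[:-1] + (4, 3), dtype=dirs.dtype)
        mu_pol[..., 0, :] = inten
        mu_pol[..., 1:, :] = dirs * inten[..., None, :]
        J = _gn_refine(J, mu_pol, states.s, ok, refine_iters)
    bad = ~np.isfinite(J).all(axis=(-2, -1))
    if np.any(bad):
        J[bad] = np.eye(2, dtype=J.dtype)
        ok = ok & ~bad
    return J, ok


def fit_pure_mueller(mu: np.ndarray, states: pc.ProbingStates,
                     dop_min: float = 0.05, refine_iters: int = 1):
    """Pure Mueller matrix L fitted from the triple-input measurement.

    Wrapper over :func:`fit_pure_jones`; returns ``(L, ok)`` with ``L`` of
    shape ``(..., 4, 4)``.
    """
    J, ok = fit_pure_jones(mu, states, dop_min=dop_min,
                           refine_iters=refine_iters)
    return pc.jones_to_mueller(J), ok


def _mueller_differentials() -> np.ndarray:
    """d/de M(exp(e G_k)) at e=0 for the 7 gauge-fixed Jones generators.

    Generators: gain (I), linear/circular diattenuation (sigma_j), and
    retardance (i sigma_j); the global phase direction (iI) maps to zero and
    is excluded. All differentials are analytic constants.
    """
    N = np.zeros((7, 4, 4))
    N[0] = 2.0 * np.eye(4)
    for j in range(3):                      # diattenuation along axis j
        N[1 + j, 0, 1 + j] = 2.0
        N[1 + j, 1 + j, 0] = 2.0
    eps = np.zeros((3, 3, 3))
    eps[0, 1, 2] = eps[1, 2, 0] = eps[2, 0, 1] = 1
    eps[0, 2, 1] = eps[1, 0, 2] = eps[2, 1, 0] = -1
    for j in range(3):                      # retardance about axis j
        N[4 + j, 1:, 1:] = 2.0 * eps[j]     # -2 K_j with K_j[a,b] = -eps[j,a,b]
    return N


_MUELLER_DIFFS = _mueller_differentials()


def _gn_refine(J: np.ndarray, mu_pol: np.ndarray, s: np.ndarray,
               ok: np.ndarray, iters: int, chunk: int = 1 << 17) -> np.ndarray:
    """Gauss-Newton refinement of the pure-Mueller fit.

    Minimizes the Frobenius misfit ``|mu_pol - M(J) s|`` over the 7 Jones
    parameters, starting from the closed-form solution. Uses the
    multiplicative parametrization ``J <- J exp(G)`` whose Mueller
    differentials are constant, so each step is a batched 7x7 solve.
    """
    flat_J = J.reshape(-1, 2, 2)
    flat_mu = mu_pol.reshape(-1, 4, 3)
    flat_ok = ok.reshape(-1)
    f_dtype = flat_mu.dtype
    c_dtype = np.result_type(f_dtype, np.complex64)
    sT = np.ascontiguousarray(s, dtype=f_dtype)
    Ns = (_MUELLER_DIFFS @ sT).astype(f_dtype)            # (7,4,3)
    eye7 = np.eye(7, dtype=f_dtype)
    lam = 1e-9
    for start in range(0, flat_J.shape[0], chunk):
        sl = slice(start, start + chunk)
        Jc = flat_J[sl]
        muc = flat_mu[sl]
        okc = flat_ok[sl]
        for _ in range(iters):
            M = pc.jones_to_mueller(Jc)
            r = (muc - M @ sT).reshape(-1, 12)
            B = (M[:, None] @ Ns).reshape(-1, 7, 12)      # (n,7,4,3) flat
            A = B @ np.swapaxes(B, -1, -2)
            g = (B @ r[..., None])[..., 0]
            A += (lam * np.trace(A, axis1=-2, axis2=-1))[..., None, None] \
                * eye7
            try:
                d = np.linalg.solve(A, g[..., None])[..., 0]
            except np.linalg.LinAlgError:  # pragma: no cover - singular fit
                break
            d = np.where(okc[..., None], d, 0.0)
            # trust region: ill-conditioned pixels (near-collinear measured
            # states leave directions unidentifiable) must not take wild
            # steps that overflow the exponential map
            dnorm = np.sqrt(np.sum(d * d, axis=-1, keepdims=True))
            d = d * np.minimum(1.0, 0.5 / np.maximum(dnorm, 1e-30))
            d = np.where(np.isfinite(d), d, 0.0)
            c = d[..., 0].astype(c_dtype)
            w = (d[..., 1:4] + 1j * d[..., 4:7]).astype(c_dtype)
            J_new = Jc @ pc._jones_exp_cw(c, w)
            bad = ~np.isfinite(J_new).all(axis=(-2, -1))
            if np.any(bad):
                J_new[bad] = Jc[bad]
            Jc = J_new
        flat_J[sl] = Jc
    return flat_J.reshape(J.shape)


# ---------------------------------------------------------------------------
# 4: round-trip reciprocity

def enforce_reciprocity_jones(J: np.ndarray) -> np.ndarray:
    """Project onto transpose-symmetric Jones matrices.

    The round trip through reciprocal media with in-plane axes is
    ``F^T F``, a symmetric Jones matrix; symmetrization is the orthogonal
    projection onto that constraint and is idempotent.
    """
    return 0.5 * (J + np.swapaxes(J, -1, -2))


def enforce_reciprocity(L: np.ndarray) -> np.ndarray:
    """Mueller-side wrapper of :func:`enforce_reciprocity_jones`."""
    J = pc.jones_from_mueller(L)
    return pc.jones_to_mueller(enforce_reciprocity_jones(J))


# ---------------------------------------------------------------------------
# 5: spectral-bin alignment

def _sample_pixels(J_bins: np.ndarray, n_sample_frames: int, seed: int,
                   max_pixels: int = 6000):
    nbin, ny = J_bins.shape[0], J_bins.shape[1]
    rng = np.random.default_rng(seed)
    ys = rng.choice(ny, size=min(n_sample_frames, ny), replace=False)
    sub = J_bins[:, ys].reshape(nbin, -1, 2, 2)
    # keep pixels with actual signal
    power = np.sum(np.abs(sub) ** 2, axis=(-2, -1)).mean(axis=0)
    good = np.flatnonzero(power > 0.01 * np.median(power[power > 0])) \
        if np.any(power > 0) else np.arange(sub.shape[1])
    if good.size > max_pixels:
        good = rng.choice(good, size=max_pixels, replace=False)
    return sub[:, good]


def _normalized_mueller(J: np.ndarray) -> np.ndarray:
    M = pc.jones_to_mueller(J)
    m00 = M[..., 0:1, 0:1]
    return M / np.where(m00 > 1e-12, m00, 1.0)


def align_spectral_bins(J_bins: np.ndarray, n_sample_frames: int = 10,
                        seed: int = 0):
    """Align the per-bin Mueller matrices to the central bin.

    The residual inter-bin transformation of the system is modelled as a
    similarity transform ``Q_b^-1 L_b Q_b`` with ``Q_b`` a pure retarder
    (3 parameters), solved by minimizing the mean Frobenius misfit to the
    already-aligned adjacent bin over pixels sampled from ``n_sample_frames``
    random frames. Bins are processed outward from the centre. If the
    optimizer fails to reduce the misfit for a bin, that bin keeps the
    identity aligner and is flagged.

    Returns ``(J_aligned, aligners, info)`` where ``aligners`` is the list of
    4x4 retarder Muellers ``Q_b`` and ``info`` records pre/post misfits.
    """
    nbin = J_bins.shape[0]
    center = nbin // 2
    if nbin < 2:
        return J_bins, [np.eye(4)] * nbin, {"misfit_pre": [], "misfit_post": []}
    sample = _sample_pixels(J_bins, n_sample_frames, seed)
    Msam = _normalized_mueller(sample)                    # (nbin, P, 4, 4)

    aligners_rv = [np.zeros(3) for _ in range(nbin)]
    fallback = np.zeros(nbin, dtype=bool)
    pre, post = [], []

    def misfit(rv, Mb, Mref):
        Q = pc.retarder_mueller(np.rad2deg(np.linalg.norm(rv)),
                                rv / max(np.linalg.norm(rv), 1e-12))
        return float(np.mean((Q.T @ Mb @ Q - Mref) ** 2))

    order = [(b, b - 1) if b > center else (b, b + 1)
             for b in list(range(center + 1, nbin)) + list(range(center - 1, -1, -1))]
    Maligned = Msam.copy()
    for b, ref in order:
        m0 = misfit(np.zeros(3), Msam[b], Maligned[ref])
        res = optimize.minimize(misfit, np.zeros(3),
                                args=(Msam[b], Maligned[ref]),
                                method="Powell",
                                options={"xtol": 1e-5, "ftol": 1e-9,
                                         "maxfev": 200})
        if res.fun <= m0:
            aligners_rv[b] = res.x
            Maligned[b] = _apply_aligner_sample(Msam[b], res.x)
            pre.append(m0), post.append(float(res.fun))
        else:  # pragma: no cover - optimizer contract violation
            warnings.warn(f"bin alignment failed for bin {b}; identity kept",
                          stacklevel=2)
            fallback[b] = True
            Maligned[b] = Msam[b]
            pre.append(m0), post.append(m0)

    aligners = []
    J_out = J_bins.copy()
    for b in range(nbin):
        rv = aligners_rv[b]
        ang = np.linalg.norm(rv)
        axis = rv / max(ang, 1e-12)
        aligners.append(pc.retarder_mueller(np.rad2deg(ang), axis))
        if ang > 0:
            Qj = pc.jones_retarder(np.rad2deg(ang), axis).astype(J_bins.dtype)
            Qj_inv = pc.jones_retarder(-np.rad2deg(ang), axis).astype(J_bins.dtype)
            J_out[b] = Qj_inv @ J_bins[b] @ Qj
    info = {"misfit_pre": pre, "misfit_post": post, "fallback": fallback}
    return J_out, aligners, info


def _apply_aligner_sample(M: np.ndarray, rv: np.ndarray) -> np.ndarray:
    ang = np.linalg.norm(rv)
    if ang == 0:
        return M
    Q = pc.retarder_mueller(np.rad2deg(ang), rv / ang)
    return Q.T @ M @ Q


# ---------------------------------------------------------------------------
# 6: bin averaging, purification, Lu-Chipman

def masked_depolarization_index(M: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Depolarization index with degenerate (no-signal) pixels set to 0."""
    m00 = M[..., 0, 0]
    safe = np.where(m00 > eps, m00, 1.0)
    q = (np.sum(M**2, axis=(-2, -1)) - m00**2) / (3.0 * safe**2)
    return np.where(m00 > eps, np.sqrt(np.clip(q, 0.0, None)), 0.0)


def lu_chipman_decompose(M: np.ndarray) -> LuChipmanFactors:
    """Lu-Chipman polar decomposition ``M = M_delta M_R M_D``.

    The diattenuator is read off the first row of ``M`` (and carries the
    gain); the remainder is split by the 3x3 polar decomposition into a
    symmetric depolarizer (zero retardance) and a proper rotation
    (pure retarder). Recomposition is exact. A full polarizer (D -> 1)
    takes a clamped pseudo-inverse path and is flagged.
    """
    M = np.asarray(M)
    if M.dtype != np.float32:
        M = M.astype(np.float64, copy=False)
    eye3 = np.eye(3, dtype=M.dtype)
    eye4 = np.eye(4, dtype=M.dtype)
    m00 = M[..., 0, 0]
    flags = m00 <= 1e-12
    m00s = np.where(flags, 1.0, m00)
    d = M[..., 0, 1:] / m00s[..., None]
    D = np.sqrt(np.einsum("...k,...k->...", d, d))
    flags = flags | (D >= 1.0 - 1e-9)
    D = np.minimum(D, 1.0 - 1e-9)
    dhat = d / np.where(D > 1e-15, D, 1.0)[..., None]
    d = dhat * D[..., None]
    sq = np.sqrt(1.0 - D**2)
    outer = dhat[..., :, None] * dhat[..., None, :]
    mD = sq[..., None, None] * eye3 + (1 - sq)[..., None, None] * outer
    M_D = np.zeros_like(M)
    M_D[..., 0, 0] = 1.0
    M_D[..., 0, 1:] = d
    M_D[..., 1:, 0] = d
    M_D[..., 1:, 1:] = mD
    M_D *= m00s[..., None, None]

    Mn = M
    if np.any(flags):
        Mn = M.copy()
        Mn[flags] = eye4
        M_D[flags] = eye4
    # closed-form diattenuator inverse: 1 - D^2 = sq^2, eigenstructure along dhat
    M_Dinv = np.zeros_like(M)
    M_Dinv[..., 0, 0] = 1.0
    M_Dinv[..., 0, 1:] = -d
    M_Dinv[..., 1:, 0] = -d
    M_Dinv[..., 1:, 1:] = mD
    M_Dinv /= (m00s * sq**2)[..., None, None]
    if np.any(flags):
        M_Dinv[flags] = eye4
    Mp = Mn @ M_Dinv                                      # M' = M M_D^-1

    mprime = Mp[..., 1:, 1:]
    U, s, Vt = np.linalg.svd(mprime)
    detsign = np.sign(np.linalg.det(U @ Vt))
    detsign = np.where(detsign == 0, 1.0, detsign)
    corr = np.ones(s.shape)
    corr[..., 2] = detsign
    m_R = (U * corr[..., None, :]) @ Vt
    m_delta = (U * (s * corr)[..., None, :]) @ np.swapaxes(U, -1, -2)

    M_R = np.zeros_like(M)
    M_R[..., 0, 0] = 1.0
    M_R[..., 1:, 1:] = m_R
    M_delta = np.zeros_like(M)
    M_delta[..., 0, 0] = 1.0
    M_delta[..., 1:, 0] = Mp[..., 1:, 0]
    M_delta[..., 1:, 1:] = m_delta
    return LuChipmanFactors(M_delta=M_delta, M_R=M_R, M_D=M_D, flags=flags)


def average_bins(J_bins: np.ndarray):
    """Elementwise bin average M, its purification M_P, and the DI of M.

    Averaging pure per-bin matrices introduces depolarization (the bins
    disagree chromatically); the depolarizer factor is removed by polar
    decomposition, ``M_P = M_R M_D``.
    """
    nbin = J_bins.shape[0]
    M = pc.jones_to_mueller(J_bins[0])
    for b in range(1, nbin):
        M += pc.jones_to_mueller(J_bins[b])
    M /= nbin
    di = masked_depolarization_index(M)
    lc = lu_chipman_decompose(M)
    M_P = lc.M_R @ lc.M_D
    return M, M_P, di


# ---------------------------------------------------------------------------
# 7: surface, cornea estimation, compensation

def find_tissue_surface(intensity: np.ndarray, min_rel: float = 0.12,
                        lateral_smooth_px: int = 3,
                        min_contrast: float = 4.0) -> np.ndarray:
    """First axial index of significant signal per lateral position.

    Median-smooths each A-line and thresholds adaptively between the
    volume's noise floor and its bright quantile (both measured on a heavily
    axially-smoothed copy, which is insensitive to speckle tails). A volume
    whose smoothed bright/floor contrast stays below ``min_contrast`` -- the
    signature of pure noise -- raises :class:`SurfaceNotFoundError`. The
    depth map is median-smoothed laterally.
    """
    inten = np.asarray(intensity, dtype=float)
    med = ndimage.median_filter(inten, size=(1, 1, 3), mode="nearest")
    smooth = ndimage.uniform_filter1d(med, 9, axis=-1, mode="nearest")
    floor = np.quantile(smooth, 0.02)
    peak = np.quantile(smooth, 0.995)
    if peak <= min_contrast * floor + 1e-300:
        raise SurfaceNotFoundError("no intensity contrast; surface not found")
    thr = floor + min_rel * (peak - floor)
    above = med > thr
    # demand three consecutive supra-threshold voxels so isolated speckle
    # spikes cannot pose as a surface
    run = above[..., :-2] & above[..., 1:-1] & above[..., 2:]
    has = run.any(axis=-1)
    if has.mean() < 0.5:
        raise SurfaceNotFoundError("no sustained signal; surface not found")
    idx = run.argmax(axis=-1).astype(float)
    idx[~has] = np.median(idx[has])
    idx = ndimage.median_filter(idx, size=lateral_smooth_px, mode="nearest")
    return np.round(idx).astype(int)


def _purify_mueller_field(M: np.ndarray) -> np.ndarray:
    """Closest pure Jones field of a small (ny,nx,4,4) Mueller field."""
    return pc.jones_from_mueller(M)


def _unwrap_rotvec_field(rho: np.ndarray, valid: np.ndarray):
    """2-D branch unwrapping of a round-trip rotation-vector field.

    Region-growing (breadth-first) from the centre of the valid region,
    choosing per pixel the ``rho + 2 pi k rho_hat`` branch closest to the
    already-unwrapped neighbour. Disconnected valid regions are unwrapped
    independently and counted.
    """
    ny, nx = rho.shape[:2]
    out = rho.copy()
    visited = np.zeros((ny, nx), dtype=bool)
    n_comp = 0
    order = np.argsort(
        (np.mgrid[0:ny, 0:nx][0] - ny / 2) ** 2
        + (np.mgrid[0:ny, 0:nx][1] - nx / 2) ** 2, axis=None)
    branches = np.arange(-3, 4)

    for flat in order:
        sy, sx = np.unravel_index(flat, (ny, nx))
        if not valid[sy, sx] or visited[sy, sx]:
            continue
        n_comp += 1
        visited[sy, sx] = True
        queue = deque([(sy, sx)])
        while queue:
            y, x = queue.popleft()
            ref = out[y, x]
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                v, u = y + dy, x + dx
                if not (0 <= v < ny and 0 <= u < nx):
                    continue
                if visited[v, u] or not valid[v, u]:
                    continue
                r = rho[v, u]
                n = np.linalg.norm(r)
                if n > 1e-12:
                    rhat = r / n
                    cands = r[None, :] + 2 * np.pi * branches[:, None] * rhat
                    best = np.argmin(np.sum((cands - ref) ** 2, axis=1))
                    out[v, u] = cands[best]
                visited[v, u] = True
                queue.append((v, u))
    return out, n_comp


def estimate_cornea(M_P: np.ndarray, surface: np.ndarray,
                    band_px: int = 3) -> CorneaField:
    """Estimate the corneal round-trip matrix S(x) and its square root C(x).

    ``S`` is the purified, axially-averaged cumulative Mueller matrix over a
    small band below the detected tissue surface. Its Jones generator is
    unwrapped across the field (continuity of the corneal retarder in the
    x-y plane) before halving, which keeps ``C`` single-valued even when the
    round-trip corneal retardance crosses 360 deg.
    """
    ny, nx = surface.shape
    nz = M_P.shape[2]
    z_idx = np.clip(surface[..., None] + np.arange(band_px), 0, nz - 1)
    yy, xx = np.mgrid[0:ny, 0:nx]
    band = M_P[yy[..., None], xx[..., None], z_idx]       # (ny,nx,band,4,4)
    S_raw = band.mean(axis=2, dtype=np.float64)
    J_S = _purify_mueller_field(S_raw)
    valid = np.abs(np.linalg.det(J_S)) > 1e-12
    J_S = np.where(valid[..., None, None], J_S, np.eye(2))
    S = pc.jones_to_mueller(J_S)

    K = pc.jones_log(J_S)
    c, w = pc._pauli_split(K)
    rho = -2.0 * w.imag                                   # round-trip rotation vector
    dvec = 2.0 * w.real
    rho_u, n_comp = _unwrap_rotvec_field(rho, valid)
    w_u = dvec / 2.0 - 1j * rho_u / 2.0
    K_u = pc._pauli_join(c, w_u)

    C_j = pc.jones_exp(0.5 * K_u)
    Cinv_j = pc.jones_exp(-0.5 * K_u)
    C = pc.jones_to_mueller(C_j)
    C_inv = pc.jones_to_mueller(Cinv_j)
    # the generator is round-trip: halve for the single-pass maps
    ret_deg = np.rad2deg(np.linalg.norm(rho_u, axis=-1)) / 2.0
    dia = np.tanh(np.linalg.norm(dvec, axis=-1) / 2.0)
    gen = np.concatenate([rho_u, dvec], axis=-1)
    return CorneaField(S=S, C=C, C_inv=C_inv, retardance_deg=ret_deg,
                       dia=dia, generator=gen, valid=valid,
                       n_components=n_comp)


def compensate_cornea(M_P: np.ndarray, cornea: CorneaField) -> np.ndarray:
    """Two-sided corneal compensation ``M_PC = C^-1 M_P C^-1`` per A-line."""
    Cinv = cornea.C_inv.astype(M_P.dtype, copy=False)
    return np.einsum("yxab,yxzbc,yxcd->yxzad", Cinv, M_P, Cinv,
                     optimize=True)


# ---------------------------------------------------------------------------
# 8: diattenuation removal

def remove_diattenuation(M_PC: np.ndarray):
    """Retarder factor of the (pure) compensated matrix, ``M_PC = M_RC M_DC``.

    Returns ``(R, dia)``: the rotation (QUV) blocks of ``M_RC`` and the
    diattenuation magnitude map of the discarded ``M_DC``.
    """
    M_PC = np.asarray(M_PC)
    if M_PC.dtype != np.float32:
        M_PC = M_PC.astype(np.float64, copy=False)
    m00 = M_PC[..., 0, 0]
    safe = np.where(np.abs(m00) > 1e-12, m00, 1.0)
    dia = np.linalg.norm(M_PC[..., 0, 1:], axis=-1) / np.abs(safe)
    m = M_PC[..., 1:, 1:] / safe[..., None, None]
    U, s, Vt = np.linalg.svd(m)
    detsign = np.sign(np.linalg.det(U @ Vt))
    detsign = np.where(detsign == 0, 1.0, detsign)
    corr = np.ones(s.shape)
    corr[..., 2] = detsign
    R = (U * corr[..., None, :]) @ Vt
    return R, np.minimum(dia, 1.0)


def _clean_gate(valid: np.ndarray) -> np.ndarray:
    """Trim untrustworthy voxels from the deep edge of each signal run.

    Noise voxels just beyond the tissue fluctuate above the intensity-SNR
    threshold often enough to feed large spurious slabs into the peeling
    recursion and the axial averaging. They always adjoin the end of the
    signal run, so a run-length filter cannot remove them; instead a voxel
    is only trusted if the next two voxels below it also carry signal,
    which erodes the bottom edge of each run by two voxels. An opening
    additionally drops short isolated islands.
    """
    g = ndimage.binary_opening(valid, structure=np.ones((1, 1, 3), dtype=bool))
    g[..., :-1] &= g[..., 1:].copy()
    g[..., :-2] &= g[..., 2:].copy()
    return g


def _blank_above_surface(R_cum: np.ndarray, surface: np.ndarray) -> None:
    """Replace cumulative rotations above the tissue surface with identity."""
    nz = R_cum.shape[2]
    above = np.arange(nz)[None, None, :] < surface[:, :, None]
    R_cum[above] = np.eye(3, dtype=R_cum.dtype)


def _freeze_invalid(R_cum: np.ndarray, valid: np.ndarray) -> None:
    """Hold the cumulative rotation constant through invalid pixels.

    Where a pixel carries no usable signal the cumulative round trip cannot
    have changed; carrying the last valid rotation forward makes the peeled
    local slab the identity there, instead of a spurious large rotation that
    would unwind the whole stack.
    """
    nz = R_cum.shape[2]
    for z in range(1, nz):
        bad = ~valid[:, :, z]
        if np.any(bad):
            R_cum[:, :, z][bad] = R_cum[:, :, z - 1][bad]


# ---------------------------------------------------------------------------
# 9: local recursion (layer peeling)

def local_recursion(R_cum: np.ndarray, wrap_limit_deg: float = 179.0):
    """Peel the cumulative round-trip rotations into local slab retarders.

    ``m(z0) = sqrt(M_RC(z0))``; each deeper slab is the principal square
    root of the cumulative matrix conjugated by the inverses of all
    shallower slabs on both sides (the round trip to depth z traverses every
    shallower slab once on the way in and once on the way out). On rotation
    blocks the square root halves the rotation vector.

    Returns ``(rotvec_local, wrap)``: per-pixel local rotation vectors
    (radians; retardance = norm) and a flag set where the sandwiched
    round-trip rotation reached the 180 deg ambiguity, i.e. the slab
    retardance wrapped; flagged pixels are reported, not silently halved.
    """
    ny, nx, nz = R_cum.shape[:3]
    flat = R_cum.reshape(ny * nx, nz, 3, 3)
    rv_out = np.empty((ny * nx, nz, 3))
    wrap = np.zeros((ny * nx, nz), dtype=bool)
    limit = np.deg2rad(wrap_limit_deg)
    A = np.broadcast_to(np.eye(3), (ny * nx, 3, 3)).copy()
    B = A.copy()
    for z in range(nz):
        W = A @ flat[:, z] @ B
        rw = Rotation.from_matrix(W).as_rotvec()
        ang = np.linalg.norm(rw, axis=-1)
        wrap[:, z] = ang >= limit
        rv = 0.5 * rw
        rv_out[:, z] = rv
        r = Rotation.from_rotvec(rv).as_matrix()
        rT = np.swapaxes(r, -1, -2)
        A = rT @ A
        B = B @ rT
    return rv_out.reshape(ny, nx, nz, 3), wrap.reshape(ny, nx, nz)


# ---------------------------------------------------------------------------
# 10: extraction

def extract_birefringence_axis(rv_local: np.ndarray, dz_um: float,
                               snr_db: np.ndarray, di: np.ndarray,
                               pitch_um: float,
                               snr_threshold_db: float = 1.0,
                               axial_avg_um: float = 30.0,
                               wrap: np.ndarray | None = None,
                               valid_gate: np.ndarray | None = None,
                               ) -> LocalBirefVolume:
    """Birefringence (deg/um, single pass) and optic axis from local retarders.

    The local rotation vectors are averaged over a small axial window (the
    stated axial resolution of birefringence imaging) before taking the
    norm, which de-biases the positive-definite retardance of low-signal
    pixels. Pixels below the intensity-SNR threshold or flagged as wrapped
    are masked to background.
    """
    rv = np.asarray(rv_local, dtype=float)
    w = max(int(round(axial_avg_um / dz_um)), 1)
    if w % 2 == 0:
        w += 1
    good = valid_gate if valid_gate is not None \
        else snr_db >= snr_threshold_db
    if wrap is not None:
        good = good & ~wrap
    if w > 1:
        # zero out invalid slabs before the plain moving average: background
        # never smears into the tissue and boundary slabs taper rather than
        # amplify
        rv = ndimage.uniform_filter1d(rv * good[..., None], w, axis=2,
                                      mode="nearest")
    delta = np.linalg.norm(rv, axis=-1)
    biref = np.rad2deg(delta) / dz_um
    axis = rv / np.where(delta > 0, delta, 1.0)[..., None]
    axis_deg = pc.axis_azimuth_deg(axis)
    defined = delta > 1e-9
    mask = snr_db >= snr_threshold_db
    if wrap is not None:
        mask &= ~wrap
    return LocalBirefVolume(birefringence=biref, axis_deg=axis_deg,
                            axis_defined=defined & mask, di=di,
                            snr_db=snr_db, mask=mask, dz_um=dz_um,
                            pitch_um=pitch_um,
                            wrap_flags=wrap)


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class ReconOptions:
    """Tunable parameters of the reconstruction pipeline.

    Defaults follow the published processing: 30 um lateral Stokes kernel
    (small-eye imaging; use 150 um for human-scale scans), bin alignment on
    10 random frames, corneal compensation on, 1 dB intensity-SNR mask and
    30 um axial birefringence resolution.
    """

    kernel_um: float = 30.0
    refine_iters: int = 1
    align_bins: bool = True
    n_sample_frames: int = 10
    compensate_cornea: bool = True
    reciprocity: bool = True
    surface_band_px: int = 3
    snr_threshold_db: float = 1.0
    axial_avg_um: float = 30.0
    dop_min: float = 0.05
    seed: int = 0
    keep_stages: bool = False


def _fit_bins(frames: StokesFrameSet, opts: ReconOptions):
    mu = assemble_mu(frames)
    nbin = mu.mu.shape[0]
    c_dtype = np.result_type(mu.mu.dtype, np.complex64)
    J_bins = np.empty(mu.mu.shape[:-2] + (2, 2), dtype=c_dtype)
    ok = np.ones(mu.mu.shape[1:-2], dtype=bool)
    for b in range(nbin):
        J_b, ok_b = fit_pure_jones(mu.mu[b], mu.states, dop_min=opts.dop_min,
                                   refine_iters=opts.refine_iters)
        if opts.reciprocity:
            J_b = enforce_reciprocity_jones(J_b)
        J_bins[b] = J_b
        ok &= ok_b
    return J_bins, ok


def reconstruct(frames: StokesFrameSet, opts: ReconOptions | None = None):
    """Run the full TRIPS chain on a measured (or simulated) frame set.

    Returns ``(LocalBirefVolume, stages)``; ``stages`` maps stage tags to
    intermediate volumes when ``opts.keep_stages`` is set (otherwise it only
    carries the cornea field, the surface map and diagnostics).
    """
    opts = opts or ReconOptions()
    filt = filter_stokes(frames, opts.kernel_um)
    J_bins, fit_ok = _fit_bins(filt, opts)
    align_info = None
    if opts.align_bins and J_bins.shape[0] > 1:
        J_bins, aligners, align_info = align_spectral_bins(
            J_bins, n_sample_frames=opts.n_sample_frames, seed=opts.seed)
    M, M_P, di = average_bins(J_bins)
    del J_bins

    snr_db = frames.intensity_snr_db()
    intensity = frames.intensity()
    surface = find_tissue_surface(intensity)
    stages: dict = {"surface": surface, "align_info": align_info}

    cornea = None
    if opts.compensate_cornea:
        cornea = estimate_cornea(M_P, surface, band_px=opts.surface_band_px)
        M_PC = compensate_cornea(M_P, cornea)
    else:
        M_PC = M_P
    stages["cornea"] = cornea

    R_cum, dia_map = remove_diattenuation(M_PC)
    # the recursion peels tissue from the detected surface down; anything
    # above the surface is vitreous/noise and must not enter the peeling,
    # and signal-free pixels must not unwind the stack
    gate = _clean_gate(fit_ok & (snr_db >= opts.snr_threshold_db))
    _blank_above_surface(R_cum, surface)
    _freeze_invalid(R_cum, gate)
    rv_local, wrap = local_recursion(R_cum)
    vol = extract_birefringence_axis(
        rv_local, frames.dz_um, snr_db, di, frames.pitch_um,
        snr_threshold_db=opts.snr_threshold_db,
        axial_avg_um=opts.axial_avg_um, wrap=wrap, valid_gate=gate)
    vol.mask &= fit_ok
    vol.axis_defined &= fit_ok
    if opts.keep_stages:
        stages.update({"M": M, "M_P": M_P, "M_PC": M_PC, "dia": dia_map,
                       "rv_local": rv_local})
    return vol, stages


# ---------------------------------------------------------------------------
# dual-input baseline

def _dual_rotation(frames: StokesFrameSet, opts: ReconOptions) -> np.ndarray:
    """Per-pixel rotation from two probing states, averaged over bins.

    The conventional dual-input estimator: assume the measurement is a pure
    retarder, build orthonormal frames from the two measured (re-polarized)
    states and their cross product, and read the rotation off directly. Any
    diattenuation or apparent diattenuation in the data corrupts the frames
    and leaks into the rotation.
    """
    s_dirs = frames.states.s[1:, :2]
    s_dirs = s_dirs / np.linalg.norm(s_dirs, axis=0)
    t_in = np.stack([s_dirs[:, 0], s_dirs[:, 1],
                     np.cross(s_dirs[:, 0], s_dirs[:, 1])], axis=1)

    st = frames.stokes[:, :2]
    quv = np.moveaxis(st[..., 1:], 1, -1)                 # (bin,y,x,z,3,2)
    norm = np.linalg.norm(quv, axis=-2, keepdims=True)
    d = quv / np.where(norm > 0, norm, 1.0)
    d1, d2 = d[..., 0], d[..., 1]
    d2o = d2 - np.sum(d2 * d1, axis=-1, keepdims=True) * d1
    n2 = np.linalg.norm(d2o, axis=-1, keepdims=True)
    d2o = d2o / np.where(n2 > 0, n2, 1.0)
    d3 = np.cross(d1, d2o)
    t_out = np.stack([d1, d2o, d3], axis=-1)              # (bin,y,x,z,3,3)
    R = t_out @ t_in.T.astype(t_out.dtype)
    R = R.mean(axis=0)
    U, _, Vt = np.linalg.svd(R)
    detsign = np.sign(np.linalg.det(U @ Vt))
    detsign = np.where(detsign == 0, 1.0, detsign)
    corr = np.ones(U.shape[:-2] + (3,))
    corr[..., 2] = detsign
    return (U * corr[..., None, :]) @ Vt


def dual_input_reconstruct(frames: StokesFrameSet,
                           opts: ReconOptions | None = None):
    """Dual-input (pure-retardance) baseline reconstruction.

    Uses the first two probing states only, no diattenuation handling;
    corneal compensation (when enabled) uses the half-angle rotation of the
    surface. Shares the recursion and extraction stages with TRIPS.
    """
    opts = opts or ReconOptions()
    filt = filter_stokes(frames, opts.kernel_um)
    R = _dual_rotation(filt, opts)

    snr_db = frames.intensity_snr_db()
    intensity = frames.intensity()
    surface = find_tissue_surface(intensity)

    if opts.compensate_cornea:
        ny, nx, nz = R.shape[:3]
        z_idx = np.clip(surface[..., None] + np.arange(opts.surface_band_px),
                        0, nz - 1)
        yy, xx = np.mgrid[0:ny, 0:nx]
        Rs = R[yy[..., None], xx[..., None], z_idx].mean(axis=2)
        U, _, Vt = np.linalg.svd(Rs)
        detsign = np.sign(np.linalg.det(U @ Vt))
        corr = np.ones(U.shape[:-2] + (3,))
        corr[..., 2] = np.where(detsign == 0, 1.0, detsign)
        Rs = (U * corr[..., None, :]) @ Vt
        rv_s = Rotation.from_matrix(Rs.reshape(-1, 3, 3)).as_rotvec()
        C_R = Rotation.from_rotvec(0.5 * rv_s).as_matrix().reshape(ny, nx, 3, 3)
        C_T = np.swapaxes(C_R, -1, -2)
        R = np.einsum("yxab,yxzbc,yxcd->yxzad", C_T, R, C_T, optimize=True)

    gate = _clean_gate(snr_db >= opts.snr_threshold_db)
    _blank_above_surface(R, surface)
    _freeze_invalid(R, gate)
    rv_local, wrap = local_recursion(R)
    di = np.ones(R.shape[:3])
    vol = extract_birefringence_axis(
        rv_local, frames.dz_um, snr_db, di, frames.pitch_um,
        snr_threshold_db=opts.snr_threshold_db,
        axial_avg_um=opts.axial_avg_um, wrap=wrap, valid_gate=gate)
    return vol, {"surface": surface}


# ---------------------------------------------------------------------------
# axis-offset estimation against a radial pattern

def _wrap180(a: np.ndarray) -> np.ndarray:
    """Wrap an orientation difference to (-90, 90] degrees."""
    return (np.asarray(a) + 90.0) % 180.0 - 90.0


def estimate_axis_offset(axis_deg: np.ndarray, center_xy: tuple[float, float],
                         radius_px: float, valid: np.ndarray | None = None,
                         n_samples: int = 720):
    """Global axis offset against an assumed radial fibre pattern.

    Samples the measured orientation on a circle about ``center_xy``; the
    assumed orientation at polar angle phi is phi itself (radial fibres).
    The offset is the circular mean (mod 180) of the differences; returns
    ``(offset_deg, residual_after_deg, residual_before_deg)`` where the
    residuals are mean absolute circular differences.
    """
    axis_deg = np.asarray(axis_deg, dtype=float)
    ny, nx = axis_deg.shape
    phi = np.linspace(0.0, 2 * np.pi, n_samples, endpoint=False)
    xs = center_xy[0] + radius_px * np.cos(phi)
    ys = center_xy[1] + radius_px * np.sin(phi)
    xi = np.clip(np.round(xs).astype(int), 0, nx - 1)
    yi = np.clip(np.round(ys).astype(int), 0, ny - 1)
    meas = axis_deg[yi, xi]
    keep = np.ones(meas.shape, dtype=bool)
    if valid is not None:
        keep = np.asarray(valid, dtype=bool)[yi, xi]
    expected = np.rad2deg(phi) % 180.0
    diff = _wrap180(meas[keep] - expected[keep])
    z = np.exp(2j * np.deg2rad(diff))
    offset = np.rad2deg(np.angle(np.mean(z))) / 2.0
    res_before = float(np.mean(np.abs(diff)))
    res_after = float(np.mean(np.abs(_wrap180(diff - offset))))
    return float(offset), res_after, res_before
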