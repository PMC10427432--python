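"""En face projection and regional scleral-birefringence metrics.

Two quantification schemes, following the two study designs:

* small-eye (guinea pig) posterior scleral birefringence (PSB): mask by the
  depolarization index, axial line filtering, depth maximum projection,
  polar resampling about the optic nerve head, radial maximum and
  circumferential mean;
* human fundus metrics: a 200 um slab centred on the manually labelled
  choroidal-scleral interface (CSI) is averaged into an en face map; the
  outer peripapillary annulus (radii 0.3-0.7 of the ONH-fovea distance)
  yields OPSB, its 12 polar segments the segment profile, and the temporal
  segment (centred on the ONH-to-fovea direction, 0 deg) the posterior-pole
  metric PPSB.

Angles on the fundus are measured about the ONH with 0 deg pointing at the
fovea; segment labels follow that convention (-180..150 in 30 deg steps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage

from .recon import LocalBirefVolume

__all__ = [
    "QuantError",
    "InsufficientPointsError",
    "FundusGeometry",
    "CSISurface",
    "EnFaceMap",
    "FundusMetrics",
    "guineapig_psb",
    "csi_interpolate",
    "slab_enface",
    "opsb_ppsb",
    "scleral_snr",
    "SEGMENT_ANGLES_DEG",
]

#: angular labels of the 12 outer-peripapillary segments (centres, degrees)
SEGMENT_ANGLES_DEG = tuple(range(-180, 180, 30))


class QuantError(ValueError):
    pass


class InsufficientPointsError(QuantError):
    pass


@dataclass(frozen=True)
class FundusGeometry:
    """ONH and fovea positions (pixel coordinates ``(x, y)``) and pixel pitch.

    The 0 deg fundus direction is the ONH-to-fovea vector.
    """

    onh_xy: tuple[float, float]
    fovea_xy: tuple[float, float]
    pitch_um: float

    def __post_init__(self) -> None:
        if np.allclose(self.onh_xy, self.fovea_xy):
            raise QuantError("ONH and fovea must differ")

    @property
    def onh_fovea_distance_px(self) -> float:
        return float(np.hypot(self.fovea_xy[0] - self.onh_xy[0],
                              self.fovea_xy[1] - self.onh_xy[1]))

    @property
    def zero_angle_rad(self) -> float:
        return float(np.arctan2(self.fovea_xy[1] - self.onh_xy[1],
                                self.fovea_xy[0] - self.onh_xy[0]))


@dataclass
class CSISurface:
    """Choroidal-scleral interface depth per (y, x), interpolated from labels."""

    depth_um: np.ndarray                # (ny, nx)
    control_points: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.depth_um.shape


@dataclass
class EnFaceMap:
    """2-D birefringence map (deg/um) with validity mask."""

    values: np.ndarray
    valid: np.ndarray
    pitch_um: float


@dataclass
class FundusMetrics:
    """Regional birefringence summary (all in deg/um)."""

    opsb: float
    ppsb: float
    segment_means: np.ndarray           # 12 values, ordered by SEGMENT_ANGLES_DEG
    segment_angles_deg: tuple = SEGMENT_ANGLES_DEG
    segment_counts: np.ndarray | None = None
    psb: float | None = None


# ---------------------------------------------------------------------------
# guinea-pig PSB

def _masked_axial_filter(values: np.ndarray, mask: np.ndarray,
                         window_px: int) -> np.ndarray:
    """Axial moving average over valid voxels only."""
    if window_px <= 1:
        return np.where(mask, values, 0.0)
    num = ndimage.uniform_filter1d(np.where(mask, values, 0.0), window_px,
                                   axis=-1, mode="nearest")
    den = ndimage.uniform_filter1d(mask.astype(float), window_px, axis=-1,
                                   mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den > 0, out, 0.0)


def polar_resample(img: np.ndarray, valid: np.ndarray,
                   center_xy: tuple[float, float],
                   n_radii: int | None = None, n_angles: int = 360):
    """Resample an en face map to polar coordinates about ``center_xy``.

    Nearest-neighbour sampling so masked pixels stay masked rather than
    bleeding into their neighbours. Returns ``(polar_values, polar_valid)``
    with shape ``(n_radii, n_angles)``; radii extend to the image edge.
    """
    ny, nx = img.shape
    cx, cy = center_xy
    rmax = max(np.hypot(max(cx, nx - 1 - cx), max(cy, ny - 1 - cy)), 1.0)
    if n_radii is None:
        n_radii = int(np.ceil(rmax)) + 1
    rr = np.linspace(0.0, rmax, n_radii)
    tt = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    xs = cx + rr[:, None] * np.cos(tt)[None, :]
    ys = cy + rr[:, None] * np.sin(tt)[None, :]
    xi = np.round(xs).astype(int)
    yi = np.round(ys).astype(int)
    inside = (xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny)
    xi = np.clip(xi, 0, nx - 1)
    yi = np.clip(yi, 0, ny - 1)
    pv = img[yi, xi]
    pm = valid[yi, xi] & inside
    return pv, pm


def guineapig_psb(vol: LocalBirefVolume, onh_center_xy: tuple[float, float],
                  di_threshold: float = 0.9, line_kernel_um: float = 30.0):
    """Posterior scleral birefringence of a small-eye volume scan.

    Pixels whose depolarization index is at or below ``di_threshold`` are
    treated as background. Each cross-section is filtered with an axial
    (vertical-line) kernel, the volume is max-projected along depth, the en
    face map is resampled to polar coordinates about the ONH, max-projected
    along the radius and averaged along the circumference.

    Returns ``(psb, EnFaceMap)``.
    """
    good = vol.mask & (vol.di > di_threshold)
    if not np.any(good):
        raise QuantError("entire volume masked; PSB undefined")
    w = max(int(round(line_kernel_um / vol.dz_um)), 1)
    if w % 2 == 0:
        w += 1
    filt = _masked_axial_filter(vol.birefringence, good, w)
    filt = np.where(good, filt, -np.inf)
    enface = filt.max(axis=-1)
    valid = np.isfinite(enface)
    enface = np.where(valid, enface, 0.0)
    emap = EnFaceMap(values=enface, valid=valid, pitch_um=vol.pitch_um)

    pv, pm = polar_resample(enface, valid, onh_center_xy)
    pv = np.where(pm, pv, -np.inf)
    radial_max = pv.max(axis=0)                           # per angle
    ok = np.isfinite(radial_max)
    if not np.any(ok):
        raise QuantError("polar projection empty; PSB undefined")
    psb = float(np.mean(radial_max[ok]))
    return psb, emap


# ---------------------------------------------------------------------------
# human CSI slab and fundus metrics

def csi_interpolate(control_points: dict[int, np.ndarray], nx: int, ny: int,
                    min_points: int = 4) -> CSISurface:
    """Spline the labelled CSI control points into a depth surface.

    ``control_points`` maps B-scan index (y) to an ``(n, 2)`` array of
    ``(x_px, depth_um)`` labels. Depths are cubic-spline interpolated along
    each labelled B-scan (passing exactly through the labels) and linearly
    interpolated between B-scans.
    """
    if not control_points:
        raise InsufficientPointsError("no control points given")
    rows = {}
    for y, pts in sorted(control_points.items()):
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < min_points:
            raise InsufficientPointsError(
                f"B-scan {y}: need at least {min_points} (x, depth) points")
        order = np.argsort(pts[:, 0])
        if not np.array_equal(order, np.arange(len(pts))):
            warnings.warn(f"B-scan {y}: control points sorted by x",
                          stacklevel=2)
            pts = pts[order]
        if np.any(np.diff(pts[:, 0]) == 0):
            raise QuantError(f"B-scan {y}: duplicate x positions")
        spl = interpolate.CubicSpline(pts[:, 0], pts[:, 1])
        rows[y] = spl(np.arange(nx))
    ys = np.array(sorted(rows))
    stack = np.stack([rows[y] for y in ys])
    depth = np.empty((ny, nx))
    for x in range(nx):
        depth[:, x] = np.interp(np.arange(ny), ys, stack[:, x])
    return CSISurface(depth_um=depth, control_points=dict(control_points))


def slab_enface(vol: LocalBirefVolume, csi: CSISurface,
                slab_um: float = 200.0) -> EnFaceMap:
    """Mean-project the birefringence inside a slab centred on the CSI.

    The slab spans ``slab_um / 2`` above and below the interface. Only valid
    voxels contribute; a column with no valid voxel in the slab is masked.
    The mean (not the sum) makes the map independent of the slab thickness
    actually available in the volume.
    """
    ny, nx, nz = vol.birefringence.shape
    zc = csi.depth_um / vol.dz_um
    half = slab_um / 2.0 / vol.dz_um
    zz = np.arange(nz)[None, None, :]
    in_slab = (zz >= (zc[..., None] - half)) & (zz <= (zc[..., None] + half))
    sel = in_slab & vol.mask
    cnt = sel.sum(axis=-1)
    tot = np.where(sel, vol.birefringence, 0.0).sum(axis=-1)
    with np.errstate(invalid="ignore"):
        values = tot / cnt
    valid = cnt > 0
    return EnFaceMap(values=np.where(valid, values, 0.0), valid=valid,
                     pitch_um=vol.pitch_um)


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def opsb_ppsb(emap: EnFaceMap, geo: FundusGeometry,
              radii: tuple[float, float] = (0.3, 0.7),
              n_segments: int = 12) -> FundusMetrics:
    """Outer-peripapillary and posterior-pole scleral birefringence.

    The annulus spans ``radii`` (fractions of the ONH-fovea distance, inner
    radius inclusive, outer exclusive, membership by pixel centre); OPSB is
    its mean over valid pixels. The annulus divides into ``n_segments``
    equal polar segments; PPSB is the segment centred on the ONH-to-fovea
    direction (0 deg). Empty segments are reported as NaN.
    """
    ny, nx = emap.values.shape
    dist = geo.onh_fovea_distance_px
    r_in, r_out = radii[0] * dist, radii[1] * dist
    cx, cy = geo.onh_xy
    if (cx - r_out < -0.5 or cx + r_out > nx - 0.5
            or cy - r_out < -0.5 or cy + r_out > ny - 0.5):
        raise QuantError("annulus exceeds the en face map bounds")
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = np.hypot(xx - cx, yy - cy)
    ring = (rr >= r_in) & (rr < r_out)
    ang = np.rad2deg(np.arctan2(yy - cy, xx - cx) - geo.zero_angle_rad)
    ang = _wrap_deg(ang)

    sel = ring & emap.valid
    if not np.any(sel):
        raise QuantError("annulus fully masked")
    opsb = float(np.mean(emap.values[sel]))

    width = 360.0 / n_segments
    centers = tuple(sorted(_wrap_deg(np.arange(n_segments) * width).tolist()))
    pix_center = _wrap_deg(np.floor((ang + width / 2.0) / width) * width)
    means = np.full(n_segments, np.nan)
    counts = np.zeros(n_segments, dtype=int)
    for k, c in enumerate(centers):
        pix = sel & (pix_center == c)
        counts[k] = int(pix.sum())
        if counts[k]:
            means[k] = float(np.mean(emap.values[pix]))
    ppsb = means[centers.index(0.0)] if 0.0 in centers else np.nan
    return FundusMetrics(opsb=opsb, ppsb=float(ppsb),
                         segment_means=means,
                         segment_angles_deg=centers,
                         segment_counts=counts)


def scleral_snr(intensity: np.ndarray, csi: CSISurface, dz_um: float,
                noise_power: float, slab_um: float = 200.0,
                threshold_db: float = 4.6):
    """Average scleral intensity SNR (dB) inside the CSI slab.

    Returns ``(snr_db, passes)``; the quality gate passes at or above the
    threshold (ties pass).
    """
    ny, nx, nz = intensity.shape
    if noise_power <= 0:
        return float("inf"), True
    zc = csi.depth_um / dz_um
    half = slab_um / 2.0 / dz_um
    zz = np.arange(nz)[None, None, :]
    sel = (zz >= (zc[..., None] - half)) & (zz <= (zc[..., None] + half))
    if not np.any(sel):
        raise QuantError("slab outside the volume")
    mean_int = float(np.mean(intensity[sel]))
    snr_db = 10.0 * np.log10(max(mean_int, 1e-300) / noise_power)
    return snr_db, snr_db >= threshold_db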