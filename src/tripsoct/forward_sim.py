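"""Forward simulator of polarization-sensitive OCT tomograms.

Generates per-spectral-bin, per-input-state Stokes volumes from a layered
birefringent phantom seen through a corneal retarder/diattenuator, so every
stage of the reconstruction is testable without instrument data.

Physics of the measurement emulated here:

* each depth slab of a layer is a linear retarder (single-pass retardance =
  birefringence x dz, in-plane axis) combined with a weak linear
  diattenuator sharing the axis;
* the cumulative single-pass Jones matrix to depth ``z`` is the ordered slab
  product applied after the corneal Jones matrix; the round trip is
  ``F^T F`` (reciprocity: the return pass is the transpose of the forward
  product, and all media here have in-plane axes, i.e. symmetric Jones
  matrices);
* per-bin retardances are scaled by a chromatic vector, linear in inverse
  wavelength across the source sweep;
* depolarization is emulated by averaging the Stokes vectors of several
  sub-resolution realizations whose optic axes are jittered, mimicking
  speckle-scale fibre disorder;
* detection noise is additive complex Gaussian on the two tomogram channels
  before Stokes formation, with SNR defined per pixel as signal power over
  noise power.

Identical seeds produce bitwise-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import polarcore as pc

__all__ = [
    "GeometryError",
    "Layer",
    "LayeredPhantom",
    "CorneaModel",
    "AcquisitionSpec",
    "StokesFrameSet",
    "simulate_stokes_volume",
    "make_two_layer_sclera_phantom",
    "make_radial_fiber_phantom",
    "make_edge_phantom",
    "make_isotropic_phantom",
    "CENTER_WAVELENGTH_NM",
    "SWEEP_RANGE_NM",
]

CENTER_WAVELENGTH_NM = 1060.0
SWEEP_RANGE_NM = 100.0


class GeometryError(ValueError):
    pass


@dataclass
class Layer:
    """One tissue layer of a phantom.

    ``birefringence`` is the single-pass retardance rate in deg/um (scalar
    or (ny,nx) map); ``axis_deg`` the in-plane optic-axis map (scalar or
    (ny,nx), degrees);
    ``diattenuation_per_um`` the diattenuation magnitude accumulated per um
    (scalar or map, sharing the optic axis); ``axis_jitter_deg`` the s.d. of
    sub-resolution axis disorder (emulates depolarization); ``reflectivity``
    relative backscatter (scalar or map).
    """

    thickness_um: float
    birefringence: np.ndarray | float = 0.0
    axis_deg: np.ndarray | float = 0.0
    diattenuation_per_um: np.ndarray | float = 0.0
    axis_jitter_deg: float = 0.0
    reflectivity: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise GeometryError("layer thickness must be positive")
        if np.any(np.asarray(self.birefringence) < 0):
            raise GeometryError("birefringence must be nonnegative")


@dataclass
class LayeredPhantom:
    """Ground-truth layered tissue on a regular grid.

    ``z = 0`` is the shallowest pixel; layers start at ``surface_depth_um``
    and stack downwards in order. Voxels above the surface or below the last
    layer carry no signal.
    """

    nx: int
    ny: int
    nz: int
    pitch_um: float
    dz_um: float
    layers: list[Layer] = field(default_factory=list)
    surface_depth_um: float = 0.0

    def __post_init__(self) -> None:
        total = self.surface_depth_um + sum(l.thickness_um for l in self.layers)
        if total > self.nz * self.dz_um + 1e-9:
            raise GeometryError(
                f"phantom depth {total:.1f} um exceeds volume depth "
                f"{self.nz * self.dz_um:.1f} um")

    @property
    def surface_index(self) -> int:
        return int(round(self.surface_depth_um / self.dz_um))

    def layer_index_of_z(self) -> np.ndarray:
        """Layer id per axial pixel (-1 where no tissue)."""
        idx = np.full(self.nz, -1, dtype=int)
        z0 = self.surface_depth_um
        for k, layer in enumerate(self.layers):
            a = int(round(z0 / self.dz_um))
            b = int(round((z0 + layer.thickness_um) / self.dz_um))
            idx[a:min(b, self.nz)] = k
            z0 += layer.thickness_um
        return idx

    def axis_map(self, k: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.layers[k].axis_deg, dtype=float),
                               (self.ny, self.nx))

    def reflectivity_map(self, k: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.layers[k].reflectivity, dtype=float),
                               (self.ny, self.nx))


@dataclass
class CorneaModel:
    """Single-pass corneal (plus anterior segment) retarder/diattenuator.

    Maps over (ny, nx) or scalars: retardance in degrees, in-plane axis in
    degrees, diattenuation magnitude ``dia`` in [0, 1).
    """

    retardance_deg: np.ndarray | float = 0.0
    axis_deg: np.ndarray | float = 0.0
    dia: np.ndarray | float = 0.0

    def jones(self, ny: int, nx: int) -> np.ndarray:
        ret = np.broadcast_to(np.asarray(self.retardance_deg, float), (ny, nx))
        ax = np.broadcast_to(np.asarray(self.axis_deg, float), (ny, nx))
        dia = np.broadcast_to(np.asarray(self.dia, float), (ny, nx))
        if np.any(ret < 0) or np.any((dia < 0) | (dia >= 1)):
            raise GeometryError("cornea requires retardance >= 0 and 0 <= Dia < 1")
        axis3 = _inplane_axis(ax)
        J = pc.jones_retarder(ret, axis3)
        if np.any(dia > 0):
            p2 = np.sqrt((1 - dia) / (1 + dia))
            J = pc.jones_diattenuator(np.ones_like(p2), p2, axis3) @ J
        return J

    @staticmethod
    def identity() -> "CorneaModel":
        return CorneaModel()


@dataclass
class AcquisitionSpec:
    """How the volume is probed and detected.

    ``snr_db = None`` means noise-free detection. ``chromatic_scale``
    defaults to a linear-in-1/lambda retardance scaling across the source
    sweep (100 nm at 1060 nm). ``n_jitter_realizations`` sub-resolution
    realizations are Stokes-averaged when any layer has axis jitter.
    """

    n_bins: int = 9
    input_mode: str = "triple"
    snr_db: float | None = None
    seed: int = 0
    chromatic_scale: np.ndarray | None = None
    n_jitter_realizations: int = 8
    dtype: str = "float32"              # Stokes storage/compute precision

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise GeometryError("need at least one spectral bin")
        if self.input_mode not in ("triple", "dual"):
            raise GeometryError("input_mode must be 'triple' or 'dual'")
        if self.chromatic_scale is None:
            lam = CENTER_WAVELENGTH_NM + SWEEP_RANGE_NM * (
                np.linspace(-0.5, 0.5, self.n_bins) if self.n_bins > 1
                else np.zeros(1))
            self.chromatic_scale = (CENTER_WAVELENGTH_NM / lam)
        self.chromatic_scale = np.asarray(self.chromatic_scale, dtype=float)
        if self.chromatic_scale.shape != (self.n_bins,):
            raise GeometryError("chromatic_scale must have one entry per bin")


@dataclass
class StokesFrameSet:
    """Measured Stokes volumes, indexed (bin, input_state, y, x, z, IQUV)."""

    stokes: np.ndarray
    pitch_um: float
    dz_um: float
    states: pc.ProbingStates
    metadata: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.stokes.shape[0]

    @property
    def n_states(self) -> int:
        return self.stokes.shape[1]

    def intensity(self) -> np.ndarray:
        """Mean detected intensity over bins and input states, shape (y,x,z)."""
        return np.asarray(self.stokes[..., 0].mean(axis=(0, 1)))

    def intensity_snr_db(self) -> np.ndarray:
        """Per-pixel intensity SNR in dB.

        Uses the recorded detection noise power when available, otherwise
        estimates the noise floor from the dimmest decile of the volume.
        """
        inten = self.intensity()
        noise = self.metadata.get("noise_power")
        if noise is None or noise == 0:
            # noise-free acquisition: unbounded SNR wherever there is signal
            return np.where(inten > 0, np.inf, -np.inf)
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(np.maximum(inten, 1e-300) / noise)


def _inplane_axis(theta_deg: np.ndarray) -> np.ndarray:
    t2 = np.deg2rad(2.0 * np.asarray(theta_deg, dtype=float))
    return np.stack([np.cos(t2), np.sin(t2), np.zeros_like(t2)], axis=-1)


def _slab_generator(layer: Layer, axis_deg: np.ndarray, dz_um: float,
                    chroma: float):
    """Pauli generator ``(c, w)`` of one dz slab of a layer, per lateral pixel.

    The slab is the commuting product of a retarder and a co-axial
    diattenuator, i.e. ``exp(c I + w . sigma)`` with
    ``w = (atanh(dia)/2 - i delta/2) a``; consecutive slabs of a layer are
    then closed-form powers ``exp(k (cI + w.sigma))``.
    """
    axis3 = _inplane_axis(axis_deg)
    biref = np.broadcast_to(np.asarray(layer.birefringence, float),
                            axis_deg.shape)
    delta = np.deg2rad(biref * dz_um * chroma)
    dia = np.broadcast_to(np.asarray(layer.diattenuation_per_um, float),
                          axis_deg.shape)
    d = np.clip(dia * dz_um, 0.0, 0.999999)
    eta2 = np.arctanh(d) / 2.0                 # p1 = 1, p2 = exp(-2 eta2)
    coef = eta2 - 0.5j * delta
    return -eta2.astype(complex), coef[..., None] * axis3


def simulate_stokes_volume(phantom: LayeredPhantom,
                           cornea: CorneaModel | None = None,
                           acq: AcquisitionSpec | None = None,
                           states: pc.ProbingStates | None = None,
                           ) -> StokesFrameSet:
    """Simulate the measured Stokes volumes of a phantom behind a cornea.

    Returns a :class:`StokesFrameSet` with three (triple mode) or two (dual
    mode) input states. The per-pixel detection SNR is defined against the
    mean backscattered signal power of the phantom; every sub-resolution
    jitter realization receives an independent noise draw at that SNR before
    its Stokes vectors enter the incoherent average. Identical seeds give
    bitwise-identical output.
    """
    cornea = cornea or CorneaModel.identity()
    acq = acq or AcquisitionSpec()
    states = states or pc.design_probing_states()
    s_cols = states.s[:, :2] if acq.input_mode == "dual" else states.s
    n_states = s_cols.shape[1]
    e_in = pc.spinor_from_stokes_dir(s_cols[1:].T)        # (n_states, 2)

    ny, nx, nz = phantom.ny, phantom.nx, phantom.nz
    layer_of_z = phantom.layer_index_of_z()
    any_jitter = any(l.axis_jitter_deg > 0 for l in phantom.layers)
    n_real = acq.n_jitter_realizations if any_jitter else 1
    rng = np.random.default_rng(acq.seed)

    refl = np.zeros((ny, nx, nz))
    for z in range(nz):
        k = layer_of_z[z]
        if k >= 0:
            refl[:, :, z] = phantom.reflectivity_map(k)
    amp = np.sqrt(refl)
    n_signal = max(int(np.count_nonzero(refl)), 1)
    # mean backscattered power per illuminated voxel (retarders are lossless,
    # diattenuation losses are small): the SNR reference level
    sig_power = float(refl.sum()) / n_signal

    noise_power = 0.0
    sigma = 0.0
    if acq.snr_db is not None:
        noise_power = sig_power / (10.0 ** (acq.snr_db / 10.0))
        sigma = np.sqrt(noise_power / 4.0)  # per quadrature, per channel

    f_dtype = np.float32 if acq.dtype == "float32" else np.float64
    c_dtype = np.complex64 if acq.dtype == "float32" else np.complex128
    Cj = np.ascontiguousarray(cornea.jones(ny, nx), dtype=c_dtype)
    e_in = e_in.astype(c_dtype)
    amp = amp.astype(f_dtype)

    out = np.zeros((acq.n_bins, n_states, ny, nx, nz, 4), dtype=f_dtype)
    jitters = [
        [rng.normal(0.0, l.axis_jitter_deg, size=(ny, nx))
         if l.axis_jitter_deg > 0 else 0.0 for l in phantom.layers]
        for _ in range(n_real)
    ]
    # contiguous z-range per layer
    ranges = []
    z = 0
    while z < nz:
        k = layer_of_z[z]
        z1 = z
        while z1 < nz and layer_of_z[z1] == k:
            z1 += 1
        ranges.append((k, z, z1))
        z = z1

    for b in range(acq.n_bins):
        s_acc = np.zeros((n_states, ny, nx, nz, 4), dtype=np.float64)
        for r in range(n_real):
            f = np.zeros((n_states, ny, nx, nz, 2), dtype=c_dtype)
            J_start = Cj.copy()
            for k, a, bz in ranges:
                if k < 0:
                    continue
                c_g, w_g = _slab_generator(
                    phantom.layers[k],
                    phantom.axis_map(k) + jitters[r][k],
                    phantom.dz_um, acq.chromatic_scale[b])
                c_g = c_g.astype(c_dtype)
                w_g = w_g.astype(c_dtype)
                ks = np.arange(1, bz - a + 1, dtype=f_dtype)
                # cumulative Jones inside the layer: closed-form slab powers
                Jblk = pc._jones_exp_cw(c_g[..., None] * ks,
                                        w_g[..., None, :] * ks[:, None])
                Jblk = np.einsum("yxzab,yxbc->yxzac", Jblk, J_start,
                                 optimize=True)
                Jrt = np.swapaxes(Jblk, -1, -2) @ Jblk
                E = np.einsum("yxzab,sb->syxza", Jrt, e_in, optimize=True)
                E *= amp[None, :, :, a:bz, None]
                f[:, :, :, a:bz, :] = E
                J_start = np.ascontiguousarray(Jblk[..., -1, :, :])
            if sigma > 0:
                noise = rng.standard_normal(f.shape + (2,), dtype=f_dtype)
                noise *= sigma
                f += noise[..., 0]
                f += 1j * noise[..., 1]
            s_acc += pc.stokes_from_field(f)
        out[b] = (s_acc / n_real).astype(f_dtype)

    meta = {
        "seed": acq.seed, "snr_db": acq.snr_db, "mode": acq.input_mode,
        "n_bins": acq.n_bins, "noise_power": noise_power,
        "n_jitter_realizations": n_real,
        "surface_index": phantom.surface_index,
    }
    return StokesFrameSet(stokes=out, pitch_um=phantom.pitch_um,
                          dz_um=phantom.dz_um, states=states, metadata=meta)


# ---------------------------------------------------------------------------
# phantom factories


def _grid_angles(ny: int, nx: int, center: tuple[float, float]) -> np.ndarray:
    """Polar angle (deg) of each pixel about ``center = (x, y)`` in pixels."""
    cy, cx = center[1], center[0]
    yy, xx = np.mgrid[0:ny, 0:nx]
    return np.rad2deg(np.arctan2(yy - cy, xx - cx))


def make_two_layer_sclera_phantom(onh_center: tuple[float, float] | None = None,
                                  inner_birefringence: float = 0.2,
                                  outer_birefringence: float = 0.6,
                                  inner_thickness_um: float = 90.0,
                                  outer_thickness_um: float = 100.0,
                                  onh_radius_um: float = 40.0,
                                  nx: int = 64, ny: int = 64, nz: int = 256,
                                  pitch_um: float = 4.3, dz_um: float = 3.0,
                                  surface_depth_um: float = 60.0,
                                  ) -> LayeredPhantom:
    """Two-layer peripapillary sclera: inner radial, outer circumferential.

    The inner layer's optic axis points radially away from the optic nerve
    head; the outer layer's axis is rotated by 90 deg (circumferential), so
    the inter-layer axis difference is 90 deg at every pixel. Within
    ``onh_radius_um`` of the ONH the scleral canal carries no birefringent
    collagen (the fibre-orientation field is singular there in any case),
    so the birefringence maps are zero inside that disk. Default
    thicknesses keep the cumulative round-trip retardance (156 deg at the
    bottom of the stack) below the 180 deg aliasing limit of round-trip
    polarimetry, as scleral imaging itself does.
    """
    if onh_center is None:
        onh_center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    radial = _grid_angles(ny, nx, onh_center) % 180.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr_um = np.hypot(xx - onh_center[0], yy - onh_center[1]) * pitch_um
    canal = rr_um < onh_radius_um
    b_inner = np.where(canal, 0.0, inner_birefringence)
    b_outer = np.where(canal, 0.0, outer_birefringence)
    layers = [
        Layer(inner_thickness_um, b_inner, radial),
        Layer(outer_thickness_um, b_outer, (radial + 90.0) % 180.0),
    ]
    return LayeredPhantom(nx=nx, ny=ny, nz=nz, pitch_um=pitch_um, dz_um=dz_um,
                          layers=layers, surface_depth_um=surface_depth_um)


def make_radial_fiber_phantom(fovea_center: tuple[float, float] | None = None,
                              birefringence: float = 0.3,
                              thickness_um: float = 60.0,
                              retina_thickness_um: float = 30.0,
                              nx: int = 64, ny: int = 64, nz: int = 128,
                              pitch_um: float = 4.3, dz_um: float = 3.0,
                              surface_depth_um: float = 45.0,
                              ) -> LayeredPhantom:
    """A thin layer with axes radial about a fovea, like Henle's fibre layer.

    A polarization-neutral cap (the inner retina above the fibre layer)
    separates the tissue surface from the birefringent layer, so the surface
    matrix carries only the anterior-segment signature.
    """
    if fovea_center is None:
        fovea_center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    radial = _grid_angles(ny, nx, fovea_center) % 180.0
    layers = []
    if retina_thickness_um > 0:
        layers.append(Layer(retina_thickness_um, 0.0, 0.0))
    layers.append(Layer(thickness_um, birefringence, radial))
    return LayeredPhantom(nx=nx, ny=ny, nz=nz, pitch_um=pitch_um, dz_um=dz_um,
                          layers=layers, surface_depth_um=surface_depth_um)


def make_edge_phantom(reflectivity_step: float = 0.2,
                      surface_diattenuation: float = 0.3,
                      step_x: int | None = None,
                      band_halfwidth_px: int = 1,
                      nx: int = 64, ny: int = 16, nz: int = 96,
                      pitch_um: float = 4.3, dz_um: float = 3.0,
                      surface_depth_um: float = 30.0,
                      ) -> LayeredPhantom:
    """A lateral reflectivity step with an apparent-diattenuation band at it.

    Phenomenological surrogate of the polarization-dependent PSF-shift edge
    artefact: at intensity edges the measurement picks up spurious
    diattenuation, which a pure-retardance (dual-input) reconstruction
    misreads as birefringence. With a uniform reflectivity (step of 1) the
    band vanishes.
    """
    if step_x is None:
        step_x = nx // 2
    refl = np.ones((ny, nx))
    refl[:, step_x:] = reflectivity_step
    uniform = reflectivity_step == 1.0
    thin = 18.0  # um, artefact band thickness
    dia_map = np.zeros((ny, nx))
    if not uniform:
        lo = max(step_x - band_halfwidth_px, 0)
        hi = min(step_x + band_halfwidth_px + 1, nx)
        dia_map[:, lo:hi] = surface_diattenuation / thin  # per um over the band
    band = Layer(thin, 0.0, 45.0, diattenuation_per_um=dia_map,
                 reflectivity=refl)
    rest = Layer(nz * dz_um - surface_depth_um - thin, 0.05, 30.0,
                 reflectivity=refl)
    return LayeredPhantom(nx=nx, ny=ny, nz=nz, pitch_um=pitch_um, dz_um=dz_um,
                          layers=[band, rest], surface_depth_um=surface_depth_um)


def make_isotropic_phantom(nx: int = 32, ny: int = 32, nz: int = 128,
                           pitch_um: float = 4.3, dz_um: float = 3.0,
                           surface_depth_um: float = 30.0,
                           reflectivity: float = 1.0) -> LayeredPhantom:
    """Uniform, polarization-neutral scatterer (birefringence noise floor)."""
    layer = Layer(nz * dz_um - surface_depth_um, 0.0, 0.0,
                  reflectivity=reflectivity)
    return LayeredPhantom(nx=nx, ny=ny, nz=nz, pitch_um=pitch_um, dz_um=dz_um,
                          layers=[layer], surface_depth_um=surface_depth_um)
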