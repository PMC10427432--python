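# Methods

This note documents the models, estimators and numerical choices behind
`tripsoct`: a triple-input polarization-sensitive OCT (PS-OCT) simulation
and reconstruction package for depth-resolved tissue birefringence, with
posterior-scleral quantification and cluster-bootstrap statistics.

## Conventions

Stokes vectors are ordered (I, Q, U, V); the Pauli basis is
σ₁ = diag(1,−1), σ₂ = [[0,1],[1,0]], σ₃ = [[0,−i],[i,0]]. An in-plane optic
axis at physical angle θ maps to the Poincaré direction
(cos 2θ, sin 2θ, 0). A retarder of retardance δ about Poincaré axis **a**
has Jones matrix exp(−i δ/2 **a**·σ) and rotates the (Q,U,V) block
right-handedly by δ about **a**. Diattenuation is
Dia = (p₁² − p₂²)/(p₁² + p₂²) for extreme amplitude transmissions p₁ ≥ p₂.
Matrix square roots and logarithms are principal; branch continuity across
an image is handled explicitly (below). Birefringence is reported as
single-pass retardance per tissue depth, deg/µm; `recon.REFRACTIVE_INDEX =
1.38` is provided for converting optical path length to tissue depth when a
container is sampled in optical path.

## Probing-state design

A linear polarizer at angle θ before an electro-optic modulator (EOM, optic
axis horizontal) produces, under a retardance step η, the state
(1, cos 2θ, sin 2θ cos η, sin 2θ sin η). With the symmetric triple-step
drive η ∈ {0°, +120°, −120°}, the three output states are mutually
orthogonal on the Poincaré sphere iff cos²2θ = 1/3, i.e.
θ = arccos(1/√3)/2 = 27.37°. The symmetric drive (one zero-voltage state
plus two symmetric steps) is this package's choice; any drive with
pairwise 120° separation in the U–V plane works, and the instrument's exact
voltages are not public.

Three states on the Poincaré sphere fix a nonsingular Jones matrix up to a
complex scale (a projective map on CP¹ through three points), which is the
geometric reason triple-input probing recovers retardance *and*
diattenuation together, while dual-input probing must assume pure
retardance.

## Forward model

The simulator builds, per lateral pixel, the single-pass Jones matrix of a
stack of layers; each dz-slab of a layer is a linear retarder
(birefringence × dz, in-plane axis) times a co-axial linear diattenuator.
The cumulative round trip to depth z is Fᵀ F with F = (slab product) ×
(corneal Jones matrix): the return pass of a reciprocal medium is the
transpose of the forward product, and all media here have in-plane axes
(symmetric Jones matrices), which the reciprocity-symmetrization stage and
the recursion rely on. Slabs within a layer commute, so cumulative matrices
are computed as closed-form generator powers, exp(k G).

* **Spectral bins.** Per-bin retardances are scaled linearly in inverse
  wavelength across a 100 nm sweep at 1060 nm centre (scale ≈ ±4.7% over 9
  bins). Bins are otherwise abstract: no fringe-level OCT reconstruction is
  modelled.
* **Noise.** Additive complex Gaussian noise on the two detection channels
  before Stokes formation; SNR (dB) is signal power over noise power per
  pixel, referenced to the phantom's mean backscattered power.
* **Depolarization.** Sub-resolution fibre disorder: several realizations
  (default 8) with per-pixel Gaussian axis jitter are simulated and their
  Stokes vectors averaged incoherently, as speckle averaging does in real
  tomograms. Each realization receives an independent noise draw.
* **Edge artefact.** The polarization-dependent PSF-shift artefact at
  lateral intensity edges is emulated phenomenologically as an
  apparent-diattenuation band at a reflectivity step; its magnitude is a
  configuration choice, not a physical prediction.

What the simulator does **not** emulate: physical speckle statistics,
polarization-mode dispersion and PSF shifts, confocal gating, eye motion,
vessel shadows. Passing the end-to-end tests therefore demonstrates the
correctness of the estimator chain under the stated measurement model, not
robustness to every artefact of real tomograms.

## Reconstruction chain

1. **Lateral filtering.** Separable moving average of the Stokes volumes
   over both lateral axes; window = round(kernel/pitch) forced odd (30 µm
   for small-eye scans, 150 µm for human-scale scans). Stokes averaging is
   intensity-weighted by construction and can only depolarize. Noise-free
   data may be processed unfiltered; filtering exists to suppress noise.
2. **Pure-Mueller fit (per bin).** The measured 4×3 matrix is modelled as
   μ = D L s. The estimated effect of the depolarizing factor D is
   corrected by re-polarizing each measured column to unit DOP (intensity
   kept). The pure matrix L is then obtained in closed form from the
   projective three-point correspondence, its gain set to preserve the mean
   output intensity, and refined by (default one) Gauss–Newton step
   minimizing the Frobenius misfit ‖μ_pol − M(J)s‖ over the 7 Jones
   parameters. The refinement matters for noise: the closed form
   interpolates the three directions exactly, while the least-squares fit
   averages the redundancy of the 12 measured numbers and lowers the
   birefringence noise floor below the dual-input estimator. Columns with
   DOP < 0.05 or collinear measured states are flagged and masked.
3. **Reciprocity.** Projection of the Jones matrix onto its symmetric part
   (the round trip of a reciprocal medium is symmetric); idempotent.
4. **Bin alignment.** Residual bin-to-bin system transformations are
   modelled as retarder-parametrized similarity transforms Q_b⁻¹ L_b Q_b
   (3 parameters; system dispersion is retardance-like, and the restriction
   regularizes a transform the measurement leaves underdetermined).
   Each bin is aligned to its already-aligned neighbour, outward from the
   central bin, by Powell minimization over pixels sampled from 10 random
   frames; a bin whose misfit would increase keeps the identity and is
   flagged.
5. **Averaging and purification.** Bins are averaged elementwise (M); the
   depolarization index of M is recorded; the Lu–Chipman decomposition
   M = M_Δ M_R M_D removes the averaging-induced depolarizer, leaving the
   pure cumulative matrix M_P = M_R M_D. The decomposition reads the
   diattenuator off the first row and splits the remainder by the 3×3 polar
   decomposition (SVD with determinant correction); recomposition is exact,
   and a full polarizer takes a clamped path with a flag.
6. **Corneal compensation.** The surface matrix S(x) is the purified
   average of M_P over a 3-pixel band below the detected surface. Its Jones
   generator is unwrapped across the field — breadth-first region growing
   from the centre of the valid region, choosing per pixel the 2π-branch of
   the rotation part closest to the already-unwrapped neighbour — so the
   square root C = √S stays single-valued even when the round-trip corneal
   retardance crosses 360°. Compensation is two-sided:
   M_PC = C⁻¹ M_P C⁻¹. The absolute 2π branch is anchored at the seed
   pixel; single-pass circular retardance cancels on the round trip and is
   not compensated (it appears as a global axis offset; see below).
7. **Diattenuation removal.** The polar retarder factor of M_PC is kept
   (M_PC = M_RC M_DC); the diattenuation magnitude map is recorded.
8. **Depth recursion (layer peeling).** m(z₀) = √M_RC(z₀); each deeper
   local slab is the principal square root of the cumulative matrix
   conjugated by the inverses of all *shallower* slabs on both sides. On
   the rotation blocks the square root halves the rotation vector. Pixels
   whose sandwiched rotation reaches 180° (the detectable wrap limit) are
   flagged rather than silently halved. Above the detected surface the
   cumulative rotation is set to the identity, and through signal-free
   pixels it is held constant, so vitreous noise and the signal-free deep
   volume cannot unwind the stack. The signal gate trims two voxels from
   the deep edge of each valid run and drops short isolated islands: noise
   voxels just beyond the tissue fluctuate above the SNR threshold often
   enough to feed large spurious slabs into the recursion and the axial
   window, and they always adjoin the run end where no run-length filter
   can catch them.
9. **Extraction.** Local rotation vectors are averaged over a 30 µm axial
   window (the stated axial resolution of birefringence imaging; averaging
   the signed vectors before taking the norm avoids the positive bias of
   averaging retardance magnitudes), then birefringence = |rotvec|/dz and
   the in-plane axis = half the azimuth of the rotation axis, mod 180°.
   Pixels below 1 dB intensity SNR, wrap-flagged or fit-flagged are masked;
   masks only grow along the chain.

**Dual-input baseline.** Uses the first two probing states, re-polarized,
and builds the rotation directly from the two measured directions and
their cross product (Gram–Schmidt frames) — the conventional estimator,
which by construction attributes any (apparent) diattenuation to
retardance. It shares filtering, recursion and extraction with the
triple-input chain; sampling-time matching is emulated by using the same
frames (states 1 and 2 of the triple set).

**Axis offset.** The unmeasurable circular birefringence of system and
anterior segment appears as a global rotation of the axis map. It is
estimated as the circular mean (mod 180°) of the difference between the
measured orientation on a circle around the fovea and the assumed radial
fibre orientation there.

## Quantification

* **Small-eye PSB**: mask by depolarization index (> 0.9 kept), 30 µm
  axial line filter per cross-section, maximum projection along depth,
  polar resampling about the ONH (nearest-neighbour so masked pixels never
  bleed), maximum along the radius (unbounded to the image edge),
  mean along the circumference.
* **Human metrics**: the choroidal–scleral interface is cubic-spline
  interpolated through ≥4 labelled points per B-scan (exact at the labels)
  and linearly across B-scans. A 200 µm slab centred on the interface is
  *mean*-projected (the mean is thickness-invariant; the source protocol
  mentions both summing and averaging, and the average is used). OPSB is
  the mean over the annulus with radii 0.3/0.7 of the ONH–fovea distance
  (pixel-centre membership, inner radius inclusive, outer exclusive); the
  annulus splits into 12 polar segments of 30°, labelled by their centres
  with 0° pointing at the fovea; PPSB is the 0° (temporal) segment, i.e.
  the 30° sector centred on the ONH→fovea direction. Empty segments are
  NaN. The scleral-quality gate passes at mean slab SNR ≥ 4.6 dB (ties
  pass).

## Statistics

Participant-level (cluster) bootstrap with B = 5000 resamples by default:
clusters are drawn with replacement at the original cluster count, all
eyes of a drawn participant entering together. Estimates are the median of
the resample distribution, CIs its 2.5/97.5 percentiles, and the two-sided
P value is 2·min(tail fractions) of the distribution around the null value
(with a +1/(B+1) continuity correction), since the source protocol states
bootstrapped CIs and P values without the exact rule. Degenerate resamples
are redrawn, capped at 10·B attempts. Pearson P values come from the
F-test of the univariate linear fit against the constant model (identical
to the slope t-test); the rank-sum comparison uses the Mann–Whitney AUC
(U/(n₁n₂), midranks for ties) as its normalized statistic with null 1/2.

The synthetic cohort generator emulates the human study's structure: two
eyes per participant, intra-class correlation 0.5 split between
participant and eye effects, PPSB ≈ 0.68 deg/µm baseline with a
−0.03 deg/µm per dioptre link to spherical equivalent and ~0.1 deg/µm
total noise — magnitudes consistent with the reported human regression
slopes and scleral birefringence range.

## Problem sizes and defaults used in the test-bed

End-to-end recovery runs on a 64×64×256-voxel two-layer sclera phantom
(4.3 µm pitch, 3 µm axial pixel, inner 0.2 deg/µm radial / outer
0.6 deg/µm circumferential, 9 spectral bins), noise-free and at 25 dB SNR;
the noise-floor comparison on a 32×32×128 isotropic phantom at 20/25/30 dB;
corneal compensation on a 48×48×96 radial-fibre phantom behind a 40°,
Dia 0.1 cornea; bootstrap coverage on 500 Monte-Carlo cohorts of 30
clusters at B = 500. These sizes were chosen as the smallest grids on which
layer structure, annular geometry and the statistical comparisons are
well resolved.

## Known limitations

* The estimator for the depolarizing factor's effect (DOP re-normalization
  of the measured columns) is a stated stand-in for the instrument's exact
  estimator, which is not public.
* Bin alignment operates on cumulative matrices and restricts aligners to
  retarders; the original's parametrization is unspecified.
* The absolute 2π branch of the corneal generator is anchored at the
  unwrapping seed; only relative continuity is identifiable.
* On the Mueller side a 360° retarder is the identity, so the principal
  square root's genuine ambiguity sits at 180° of QUV rotation; the
  recursion flags (not halves) pixels at that limit, and round-trip slab
  retardances beyond it alias irrecoverably.
* Quantitative edge-artefact magnitudes are not reproducible from the
  phenomenological surrogate; only the qualitative triple-vs-dual contrast
  is meaningful.
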