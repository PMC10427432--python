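# tripsoct

Triple-input polarization-sensitive OCT (PS-OCT) reconstruction: from
per-spectral-bin Stokes measurements to depth-resolved tissue birefringence
and optic-axis maps, with corneal compensation, posterior-scleral
quantification and cluster-bootstrap statistics. A built-in forward
simulator of layered birefringent tissue makes every stage testable without
instrument data.

## The problem and who this is for

Collagen-rich tissues such as the sclera are birefringent: light polarized
along versus across the fibres sees slightly different refractive indices,
and the accumulated phase retardance per depth (deg/µm) reports fibre
content and alignment. Measuring this in the *posterior* eye is hard — the
probing light is weak after traversing the eye and its polarization is
scrambled by the cornea. Conventional EOM-based PS-OCT probes with two
polarization states and must assume the sample is a pure retarder, so
diattenuation (true or apparent, e.g. from polarization-dependent
point-spread-function shifts at intensity edges) corrupts the images.

Probing with **three mutually orthogonal states** on the Poincaré sphere
removes that assumption: three input/output state pairs determine a
nondepolarizing (Jones-derived) Mueller matrix — 7 free parameters,
retardance *and* diattenuation — up to gain. This package implements that
reconstruction chain and the analyses built on it, for researchers working
on polarimetric OCT methods or scleral biomarkers.

## The model in brief

Per spectral bin, the measured Stokes columns obey `μ = D L s`, with `s`
the 4×3 probing matrix, `L` the pure (Jones-derived) cumulative round-trip
Mueller matrix and `D` a depolarizing factor whose estimated effect is
removed by re-polarizing the columns of `μ`. The chain then runs:
reciprocity symmetrization → spectral-bin alignment → elementwise bin
average `M` → Lu–Chipman purification `M = M_Δ M_R M_D`, `M_P = M_R M_D` →
corneal compensation `M_PC = C⁻¹ M_P C⁻¹` with `C = √S` the principal
square root of the retinal-surface matrix (generator unwrapped in the
x–y plane) → diattenuation removal `M_PC = M_RC M_DC` → depth recursion

    m(z) = sqrt( m⁻¹(z−dz) ⋯ m⁻¹(z₀) · M_RC(z) · m⁻¹(z₀) ⋯ m⁻¹(z−dz) ),
    m(z₀) = sqrt(M_RC(z₀)),

whose local retarders give birefringence `δ(z)/dz` and the in-plane optic
axis (half the Poincaré azimuth, mod 180°). See `docs/methods.md` for
every estimator, convention and numerical choice.

## Worked example

Simulate a two-layer peripapillary sclera phantom (inner layer
0.2 deg/µm with radial fibres, outer 0.6 deg/µm circumferential, a
non-birefringent scleral canal at the ONH) at 25 dB detection SNR,
reconstruct it, and quantify the posterior scleral birefringence (PSB):

```sh
cat > demo.toml <<'TOML'
[simulate]
phantom = "two_layer_sclera"
nx = 32
ny = 32
nz = 128
n_bins = 9
snr_db = 25.0

[reconstruct]
compensate_cornea = false
TOML
tripsoct pipeline -o out -c demo.toml --seed 1
cat out/metrics.csv
```

which prints

```
phantom,seed,psb,config_hash
two_layer_sclera,1,0.5888834288353242,f271445b9c66
```

PSB is the circumferential mean of the radial maximum of the depth-max
birefringence projection (the small-eye protocol): 0.589 deg/µm here,
against the phantom's dominant outer-layer birefringence of 0.6 deg/µm —
the ~2% deficit comes from boundary tapering of the 30 µm axial window.
The same run writes the raw Stokes container (`out/volume.h5`) and the en
face map (`out/enface.tif`/`.png`). The library API exposes each stage
(`tripsoct.forward_sim.simulate_stokes_volume`,
`tripsoct.recon.reconstruct`, `tripsoct.quant.guineapig_psb`, ...) for use
from Python; a noise-free run of the same phantom recovers both layer
birefringences to 0.1% and the fibre orientations to ~1e-6 degrees.

For cohort analyses, `tripsoct.stats` provides the participant-level
bootstrap (both eyes of a drawn participant resampled together; B = 5000,
percentile CIs), Pearson correlation with the F-test against the constant
model, the rank-sum comparison and ROC/AUC, plus a synthetic two-eye
cohort generator:

```sh
tripsoct make-fixtures -o fixtures
tripsoct stats fixtures/cohort.csv -o stats.csv --seed 2
```

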