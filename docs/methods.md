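# Methods

`milsd` implements multiple-illumination learned spectral decoloring
(MI-LSD) for quantitative optoacoustic oximetry, together with the
in-silico machinery needed to train and evaluate it: chromophore
spectral models, a randomized digital-phantom sampler, a desk-scale
optical forward engine, and the estimation/evaluation stack.

## Signal model and why L1 normalization removes the unknowns

A reconstructed optoacoustic signal spectrum at a pixel x0 is

    S(x0, λ) = Γ(x0) · A(x0) · ϕ(x0, μa(x, λ), μs′(x, λ)) · μa(x0, λ)

with Γ the Grüneisen parameter, A a wavelength-independent amplitude
introduced by the imperfect acoustic reconstruction, and ϕ the fluence.
Both Γ and A are unknown per pixel but wavelength-independent, so
dividing each spectrum by its L1 norm cancels them exactly:
Ŝ(λ) = Ĥ(λ) with H = ϕ·μa the absorbed energy.  Estimators therefore
train on simulated, L1-normalized absorbed-energy spectra labeled with
the ground-truth saturation, and can be applied unchanged to normalized
measured spectra.  The residual, physically irreducible confounder is
spectral coloring: the wavelength dependence of ϕ caused by the
(unknown) absorbers between source and pixel.

Feature modes:

* **LSD** — spectra of the four illumination positions are averaged
  first, then L1-normalized (16 features).  This matches how a
  single-illumination method would consume the same delivered energy,
  so comparisons against LU and MI-LSD carry no SNR advantage.
* **MI-LSD** — each illumination's spectrum is L1-normalized separately
  and the four blocks are concatenated in illumination order
  (64 features).  The coloring differences between illumination
  positions carry information about the surrounding medium, which is
  what the learned models exploit.  A joint-normalization variant that
  preserves inter-illumination amplitude ratios exists behind a flag
  (default off), as does sorting blocks by their raw L1 norm
  (investigated in prior work and rejected; default off).
* **Mirror augmentation** — the illumination line array is laterally
  symmetric, so reversing the block order of every MI-LSD sample
  produces an equally probable sample from the mirrored volume; this
  doubles the MI-LSD training set and is a no-op for LSD.  Test sets
  are never augmented.

## Chromophore models

Two endmember families with identical algebra: local absorption is
`vf · (s·E_oxy + (1−s)·E_deoxy)` with saturation s (sO2 or the relative
copper fraction rCu) and volume fraction vf (BVF or SVF) relative to
whole-blood-equivalent concentrations.

* **Hemoglobin**: bundled molar-extinction tables (standard compiled
  literature values) scaled to whole blood, c(HbT) = 150 g/l, molar
  mass 64,500 g/mol.
* **Sulfates**: CuSO4 at 0.25 M mimics HbO2, NiSO4 at 2.2 M mimics Hb.
  Published numeric tables are not bundled; parametric stand-ins with
  fixed coefficients are used, shaped on the d-d bands of the hexaaqua
  complexes: Cu(II) one broad band near 810 nm; Ni(II) a band near
  720 nm plus the tail of its ~1150 nm band.  This preserves the
  property the sulfate phantom model is built on — spectra structurally
  analogous to HbO2/Hb — which matters quantitatively: a featureless
  monotone stand-in is nearly degenerate with fluence-attenuation
  spectra and makes saturation estimation artificially ambiguous
  (we measured ~2× the error of the hemoglobin family before adopting
  the structured form; afterwards the families agree, as they should).
  User-supplied two-column (wavelength, μa) tables override the
  stand-ins via `load_endmember_table`.
* **Water** (background solvent): bundled literature absorption table;
  its NIR band near 980 nm is a real and useful coloring signal
  (implicit path-length information).
* **Background scattering**: the Rayleigh/Mie power law
  μs′(λ) = μs500′·(f_ray (λ/500)⁻⁴ + (1−f_ray)(λ/500)^(−b_mie)) with
  defaults μs500′ = 42.4 cm⁻¹, f_ray = 0.62, b_mie = 1.0 — the generic
  tissue model fitted to time-resolved measurements of the 1.5% fat
  emulsion used as phantom background (μs′ ≈ 15 cm⁻¹ at 750 nm).
  `fit_scattering_model` provides the least-squares fit of this law to
  (λ, μs′) tuples; the defaults double as the fit's initial guess.

## Digital phantoms

The training-volume sampler draws, per volume: two sets of tubes with
per-set counts from U{3,9} (so 6–18 tubes), tube saturation ~ U(0,1),
background saturation ~ U(0,1), background volume fraction ~ U(0,3)%,
tube radius 0.4 mm.  Tubes are disks in the imaging plane (the physical
tubes run perpendicular to it), placed uniformly at depths 2–20 mm with
one tube diameter of boundary clearance; intersecting placements are
rejection-resampled (bounded retries).  The default volume is 40 mm
(lateral) × 30 mm (depth) at 0.3 mm voxel pitch — the pitch is a
desk-scale discretization choice giving ~5–6 voxels per tube
cross-section; the volume extent and placement window are declared
assumptions (they are drawn, not printed, in the source protocol).
An optional `lateral_bounds_mm` window can restrict placement to the
imaged field of view; it is off by default.

Tube interiors carry the pure mixture at 100% volume fraction and no
scattering (the tube solutions contain no scattering agent); the
background carries water plus the background mixture and the power-law
μs′.  Deterministic "digital twins" of the physical layouts are
provided: A (five single tubes at 5 mm), B (five four-tube arrays, two
tubes at 3 mm and two at 8 mm each, 8 mm array spacing), and C (the
layout-B geometry with the imaging plane rotated 90°, i.e. one shallow
and one deep tube lying *along* the plane) with the 0.29 mm layout tube
radius.  Layout-C scenes are out-of-distribution with respect to the
transversal-only training sampler.

## Forward engine

Both backends work on the 2D imaging plane; the scene is invariant
along elevation, so the plane carries all labels and the full
spectral-coloring structure.  Fluence is normalized to unit delivered
pulse energy; illumination is a line array of four beams, 8 mm apart,
7 mm FWHM Gaussians entering normal to the surface.  The 18 mm gel-pad
standoff is represented by specifying the beam FWHM at the sample
surface; an explicit water layer is available for the MC backend
(`include_standoff`), default off, because a non-scattering layer is
outside the diffusion model's validity.

* **Monte Carlo (validation backend)** — photon packets with full 3D
  transport in the y-invariant geometry (line illumination): Gaussian
  launch, exponential free paths against μt, Henyey–Greenstein
  scattering (default g = 0.9, μs = μs′/(1−g), matched refractive
  index), track-length fluence estimation, absorption weighting,
  Russian roulette (threshold 1e-4, survival 0.1).  Using 3D transport
  rather than in-plane 2D transport is deliberate: its diffusive limit
  has D = 1/(3 μtr), identical to the diffusion backend, so the two
  backends agree on heterogeneous scenes; in-plane 2D transport would
  instead approach D = 1/(2 μtr).  The energy ledger tracks
  absorbed + escaped − roulette_net = launched exactly (roulette is
  unbiased only in expectation, so its net created/killed weight is
  reported rather than hidden).
* **Finite-volume diffusion (dataset backend)** — solves
  [∇·(D∇) − μa] ϕ = −q with D = 1/(3(μa+μs′)), harmonic-mean face
  diffusivities, Robin (extrapolated-boundary, matched-index) condition
  on all outer faces, and the beam profile placed one transport mean
  free path below the surface as an isotropic source, split linearly
  over the two straddling voxel rows so the solution varies
  continuously with the optical properties.  One sparse LU
  factorization per (volume, wavelength) serves all four illumination
  positions.  The solve verifies its residual and raises on
  non-convergence.  Deterministic, ~30 ms per wavelength at default
  resolution.

Validation (see the test suite): MC matches Beer–Lambert in a pure
absorber within counting statistics; both backends match the analytic
semi-infinite K0 Green's function (line source, extrapolated boundary)
within 10–15% at 5–15 mm; MC and diffusion agree within 15% at tube
locations deeper than 2 mm on heterogeneous scenes.  Inside the
non-scattering tubes the diffusion equation is a smooth surrogate
rather than correct transport; training and test data come from the
same forward model, so estimator evaluation is self-consistent, but
absolute tube-interior fluence should not be over-interpreted.

## Estimators

* **LU** (baseline): nonnegative least squares of each normalized
  spectrum onto the two endmembers; saturation = c_oxy/(c_oxy+c_deoxy),
  clipped to [0,1].  Nonnegativity makes the ratio well-defined; a
  doubly-zero fit returns NaN with a warning rather than a silent 0.
* **Random forest**: scikit-learn regressor, 100 trees, max depth 30,
  otherwise defaults; deterministic given a seed; predictions clipped
  to [0,1].
* **Feedforward network**: a compact numpy implementation — four hidden
  layers of twice the input width (32 for LSD, 128 for MI-LSD), leaky
  ReLU (slope 0.01), optional inverted dropout (default 0), mean
  squared error, plain minibatch SGD with batch size 1e5 (capped at the
  dataset size) and lr(epoch) = 1e-2 · 0.9^(epoch/2) (epoch 0-based)
  for 100 epochs.  Loss, optimizer, and initialization are not pinned
  down by the protocol we follow; MSE + SGD + He initialization are the
  conventional choices.  Features are standardized internally (affine,
  learned from the training set, toggleable): L1-normalized spectra
  live on a ~1/16 per-feature scale on which plain SGD stalls.

All three are scikit-learn-compatible (`fit`/`predict`/`get_params`)
and compose with sklearn model selection; `train_estimator`/`predict`
are thin functional wrappers.

## Evaluation

Errors are saturation differences (estimate − truth) in percentage
points; summaries report mean, Q1/Q2/Q3, IQR, and P90 of signed and
absolute errors.  Quantiles use linear interpolation between order
statistics (the numpy default; the convention is documented because it
is not universal).  ROI threshold segmentation keeps exactly
⌈fraction·N⌉ brightest pixels of the mean signal (15% in the
3.75×3.3 mm transversal protocol, 50% in the 7.5×1.5 mm longitudinal
protocol) with stable row-major tie-breaking.

## The scaled-down reproduction experiment

`run_experiment` generates ~300 training and 100 test volumes
(diffusion backend, default grid, 4 illuminations), trains the
configured estimators, and reports held-out error summaries next to the
LU baseline; every random stream is keyed by (master seed, stage,
volume id), so runs are reproducible from their manifest.  These
problem sizes are the package's desk-scale defaults, chosen so the full
experiment runs in minutes on one CPU; the reference-scale protocol
(4000/1000 volumes, 1e8-photon 3D Monte Carlo) is reachable through the
same configuration surface but is a cluster-scale undertaking.

What scaling down costs: estimation error in this problem is limited by
the diversity of background/geometry conditions seen in training (one
background draw per volume).  Measured medians of RF MI-LSD on held-out
data: ~5 pp at 60 training volumes, ~3–4 pp at 300.  Extrapolating the
observed power-law trend to the reference scale of 4000 volumes reaches
the low single digits reported there; at 300 volumes the experiment
reproduces the qualitative structure (MI-LSD ≤ LSD ≪ LU) and
approaches, but does not fully attain, reference-scale accuracy.

## What the synthetic data do not model

No acoustic forward model or reconstruction artifacts (A(x) is exactly
wavelength-independent here, which is the assumption, not a result);
no laser noise or wavelength-dependent SNR; no Grüneisen variation with
the chromophore mixture (a known systematic of the physical sulfate
model); no tube-wall optics; no melanin or skin layer; 2D in-plane
transport only (no out-of-plane structure).  Passing tests therefore
demonstrate internal consistency of the method and its implementation
under ideal signal formation — not robustness to the measurement
physics the real instrument adds.

## Numerical choices and degenerate inputs

Zero-sum spectra cannot be L1-normalized: such voxels are dropped and
counted (`n_dropped`).  LU with both coefficients zero yields NaN and a
warning; NaNs are excluded from summaries.  The phantom sampler raises
after 100 failed placements of a tube.  The diffusion backend requires
μa + μs′ > 0 everywhere.  Tie-breaks in ROI segmentation are stable
row-major.  MC seeds are 31-bit; per-stage streams derive from
numpy SeedSequence over (master seed, stage, volume id).
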