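# Methods

This note documents the models implemented in `ratesi`, the parameter
conventions, the numerical choices made where the design was open, and
what the synthetic benchmarks do and do not demonstrate about real data.

## Head model

The volume conductor is a single compartment of homogeneous isotropic
conductivity σ = 0.33 S/m — brain tissue only, no skull or scalp, which
matches a cortical electrode system whose contacts touch the brain
surface.  Coordinates are stereotactic millimetres with bregma as origin
(+x lateral-right, +y anterior, +z dorsal).

The synthetic brain is a labeled ellipsoid of ≈ 2 cm³ (the approximate
rat brain volume; default semi-axes 7.5 × 10.5 × 6.0 mm centred at
(0, −2, −3) mm) with nested sub-regions standing in for gross anatomy: a
deep diencephalic blob, a caudal cerebellar lobe, and a ventricle that is
excluded from the source space but still conducts.  An external labeled
NIfTI volume can be ingested instead (`ratesi.io.read_labeled_volume`,
with an optional intensity threshold for mask segmentation); that path is
supported but not exercised by the test suite.

**Meshing.** Labeled voxels are split into six conforming tetrahedra each
(Kuhn subdivision along the cube diagonal).  This was chosen over
unstructured Delaunay meshing of the voxel mask because it conserves the
voxel volume exactly, cannot produce sliver elements, and keeps the
dipole grid trivially inside the conductor.  The voxel lattice is
anchored so voxel centres coincide with the integer-mm stereotactic
lattice; source-grid points therefore sit strictly inside voxels rather
than on cube faces.  For the analytic sphere validation a dedicated ball
mesh is built from concentric Fibonacci shells, each with an independent
random orientation (a shared orientation leaves a coherent layering that
acts like a numerically anisotropic conductivity and biases one moment
axis), relaxed by 20 Lloyd iterations and tetrahedralized by Delaunay,
with surface nodes exactly on the sphere.

**Electrodes.** The 12-channel montage (F3/F4, C3/C4, P3/P4, P5/P6,
T3/T4, T5/T6, plus an anterior reference) is specified by its
anterior/lateral bregma offsets; the dorsoventral position is resolved by
snapping each contact to the nearest mesh boundary node.  Snapping is
greedy over distinct nodes — on coarse meshes two channels could
otherwise land on the same node, which would short them together in the
transfer-matrix computation.  Channels snapping farther than 5 mm are
flagged, not rejected.

**Source grid.** Dipoles sit on a regular lattice (default 1 mm) at
points whose owning voxel (half-open ownership) carries an electrically
active label; adjacency is the lattice 26-neighbourhood.  Orientations
are free (three Cartesian components per position).

## Forward problem

The quasi-static potential obeys the Poisson equation with insulating
(Neumann) boundary; discretized with linear (P1) Lagrange elements this
yields a symmetric positive semi-definite stiffness matrix with the
constant vector as null space.  Dipoles enter as St. Venant loads: a
monopole distribution on the node nearest the dipole and its
edge-connected neighbourhood (widened to the 2-ring when the 1-ring has
fewer than 14 nodes), chosen as the minimum-norm solution that matches
the zeroth moment (zero) and first moment (the dipole moment) exactly, and
then, within the null space of those constraints, minimizes the
quadrupole moment.  The quadrupole correction roughly halves the sphere
validation error at no meaningful cost.

The lead field is computed with the transfer-matrix scheme: the singular
system is deflated by grounding the reference electrode's node, one
sparse solve per electrode is performed against a reused LU
factorization, and lead-field entries are inner products of transfer rows
with the load vectors.  A direct one-solve-per-dipole path exists as a
consistency oracle; the two agree to ~1e−15 relative.  The lead field is
average-referenced by default (the in-vivo pipeline re-references data to
the common average); raw reference-electrode potentials are available.

**Units.** Coordinates in mm, σ in S/m, dipole moments in A·m, potentials
in volts.  Internally the mm-based assembly is rescaled by 1e6 to SI; the
convention is pinned by the analytic-sphere comparison.

**Validation.** The analytic oracle is the spherical-harmonic series for
an eccentric dipole in an insulated homogeneous sphere,

V(e) = (4πσ)⁻¹ Σₙ (2n+1)/n · bⁿ⁻¹/Rⁿ⁺¹ · [n·m_r·Pₙ(c) + Pₙ′(c)(m·e − c·m_r)],

truncated when a term falls below 1e−10 of the running sum; it reduces to
the classic 3(m·e)/(4πσR²) for a central dipole, and its interior
expansion was verified to machine precision against the direct free-space
dipole potential.  On a radius-7 mm ball meshed at 0.75 mm edge, the FEM
solution matches the series with a mean relative difference (RDM) of
≈ 3.8% over 18 dipole/orientation combinations up to eccentricity 0.5
(acceptance threshold: mean < 5%).  This is a coarse relative resolution
(h/R ≈ 0.11, the rat-scale regime); errors shrink roughly linearly with
the edge length.

## Inverse solutions

All four solvers act on the average-referenced lead field with free
orientations; rank-deficient systems use eigendecomposition-based
pseudo-inverses with a rank warning.

* **LCMV**: w_p = (K_pᵀC⁻¹K_p)⁻¹K_pᵀC⁻¹ with diagonal loading
  C → C + γI; scalar map NAI_p = Tr[(K_pᵀC⁻¹K_p)⁻¹] / Tr[(K_pᵀK_p)⁻¹]
  (unit-matrix noise covariance).
* **DICS**: identical algebra on the complex Hermitian cross-spectral
  density at one frequency (Hann-tapered per-trial FFT cross-products at
  the nearest bin); the map is the real part of the trace quantity.
* **sLORETA**: minimum-norm operator Kᵀ(KKᵀ + γI)⁻¹, standardized by the
  3×3 diagonal blocks of the resolution matrix; scalar map is the
  standardized quadratic form summed over time.  Default γ = 5% of the
  mean data-covariance diagonal.
* **eLORETA**: fixed-point weights W_p ← [K_pᵀ(KW⁻¹Kᵀ + γI)⁺K_p]^{1/2}
  from W = I, converged when the relative Frobenius change of the whole
  weight stack drops below 1e−6 (a per-block criterion stalls on
  near-zero deep-dipole blocks), up to 100 iterations by default.
  Scalar map is Σ_t‖y_p(t)‖².  The noiseless-single-source
  zero-location-error property is exercised for every grid dipole and all
  three orientations in the acceptance suite.

**Regularization conventions.** Three eigenvalue-based loading rules are
provided because no single rule behaves well across the very different
SNR regimes this package spans:

* `mode="max"` — γ = 0.003·λ_max(C), the conventional rule; used by the
  ASSR pipeline (robust for trial-limited CSDs).
* `mode="inverse"` — γ = 0.003·λ_max(C⁻¹) = 0.003/λ_min⁺(C), an
  essentially negligible loading at realistic sensor scales; used by the
  surrogate benchmark, where it reproduces the reference behaviour of the
  beamformer (LCMV mean ED1 ≈ 1.1 mm at 25 dB) that heavy loading
  destroys (≈ 2.4 mm).
* `mode="noise"` — γ = 0.003·λ_min⁺(C), loading proportional to the
  noise-floor eigenvalue; used by the phantom pathway, where SNR is so
  high that λ_max-proportional loading flattens the NAI contrast and
  mislocalizes by ~5 mm even with a perfect forward model.

λ_min⁺ denotes the smallest eigenvalue of the non-null subspace
(average-referenced data always carry one null direction).

The eLORETA γ for the surrogate benchmark is selected by
leave-one-electrode-out cross-validation — sources estimated from 11
channels must predict the 12th through its lead-field row — evaluated on
a 12-position subsample of planted dipoles (the per-(γ, electrode) weight
fixed points dominate the cost and are shared across positions), averaged
per SNR, then frozen for the sweep.

## Surrogate benchmark

Per cell (grid position × orientation × SNR): a 100-sample white-Gaussian
moment time course at 1 kHz is projected through the lead field and
sensor noise with identical variance on every channel is added at
5/10/15/25 dB (signal power pooled over channels and samples; a
per-channel mode exists).  Metrics:

* **ED1** — distance from the planted dipole to the map's global maximum
  (ties → lowest index);
* **ED2** — Σ_l |r_l − r_true| · |Y_l/Y_max| over all local maxima
  (value strictly above all 26-neighbours; equal-valued plateaus collapse
  to their lowest-index member; the global maximum always contributes);
* **reliability** — mean over the 3P-member simulation family of
  |est/‖est‖ − sim/‖sim‖| per position, in [0, 1], 0 only for perfect
  recovery.

Summaries report mean ± population SD over all position/orientation
cells.  Randomness is counter-keyed per (SNR, position, orientation), so
any subset of the sweep reproduces exactly.

At the benchmark scale used in the acceptance suite (reduced ellipsoid,
135 positions): eLORETA mean ED1 falls 3.49 → 0.19 mm and LCMV 3.77 →
1.09 mm from 5 to 25 dB — both 25-dB values match the reference behaviour
of these solvers on a 12-electrode rat model — and LCMV ED2 falls
34.3 → 8.1.  The LCMV ED2 contraction measures ≈ 4× on the synthetic
ellipsoid (vs ≈ 11× reported for an atlas-based model); the residual
secondary-maxima weights at 25 dB are set by the T = 100 covariance
sampling error and the lead-field coherence of the dorsal-only montage,
not by any tunable parameter.

## Phantom-style mismatch benchmark

The physical-phantom experiment (agar head, platinum dipoles, 1-kHz
generator) is emulated by making the *generative* and *inverse* forward
models differ: geometry scaled by 1.8 (analysis maps positions back by
the same factor), electrode positions jittered (SD 0.3 mm) before surface
registration, conductivity perturbed by 2%, and the generative conductor
remeshed at a different edge length.  Recordings are 1-min (configurable)
sinusoidal excitations at 1 kHz sampled at 5 kHz, cut into 1-s segments;
the CSD at the excitation frequency is localized with eLORETA and DICS,
and ED1 plus signed per-axis errors are tabulated.  Six shallow
(~1–2 mm deep) and five deep (diencephalic) test dipoles are placed at
approximate positions, flagged as such.  With the default mismatch the
shallow/deep mean ED1 come out at ≈ 2.6 / 5.1 mm — the same order as a
measured phantom (1.6 / 2.6 mm), with the positive-Z (toward the
electrodes) bias clearly visible.  These numbers characterize the
emulation, not the physical device.

## Synthetic ASSR study

Each subject is a continuous 12-channel, 1-kHz recording with 120 1-s
43-Hz click-train trials at 2–4 s inter-stimulus intervals, built from
three event-locked components projected through the lead field:

* *thalamic* — a 250-Hz Gabor burst (100–400 Hz band) centred in the
  5–9 ms window, from a deep diencephalic dipole;
* *late slow wave* — a Gaussian peaking at 350 ms (σ = 60 ms) from
  frontal dipoles;
* *entrainment* — a 43-Hz sinusoid from 400 ms to train end with a 50-ms
  ramp, from bilateral temporal dipoles given independent per-trial phase
  jitter (σ = 1 rad, interhemispheric coherence ≈ 0.37; perfectly
  coherent bilateral sources are a degenerate beamformer case real data
  would not present).

Amplitudes are set so noiseless evoked deflections reach typical rat
cortical-EEG scales (≈ 180 / 50 / 30 µV at the best electrode for
late / entrainment / thalamic).  Background noise is per-channel 1/f
(slope −1, 20 µV RMS) plus white (10 µV RMS); between-subject amplitude
variability is lognormal with CV 0.3.  Broadband artifact bursts
(105–135 Hz, 20× background RMS, Hann-tapered, 2/min) can be injected
with an exact ground-truth interval mask.

The analysis chain: 110–130 Hz Hilbert-envelope z-score (threshold 4) +
peak-to-peak + manual-interval artifact flagging; 50-Hz DFT notch
(least-squares sine/cosine subtraction), 6th-order Butterworth low-pass
at 100 Hz (zero-phase by default; the forward-backward pass doubles the
attenuation at cut-off), average reference; paired 1-s
prestimulus/stimulus epochs with the early (0–150 ms), late (150–400 ms)
and entrainment (400–950 ms) windows.  Source contrasts use common
filters from the pooled prestimulus+stimulus covariance (time domain) or
CSD at 43 Hz (frequency domain); per-condition source power is
Re Tr(F C Fᴴ), and the contrast is the relative change
(stim − prestim)/prestim per dipole (difference mode available).  The
thalamic component gets a dedicated pathway: 100–400 Hz band-pass instead
of the low-pass chain, 5–9 ms epochs against the equally long baseline
ending at train onset, time-domain eLORETA.

Group inference contrasts each subject's map against their whole-brain
mean (broadcast to every dipole) with a one-sided paired t statistic per
dipole, cluster-forming threshold p < 1e−3 (1e−9 for the thalamic
window), 26-neighbourhood connected components, and a 1000-permutation
max-cluster-mass sign-flip null with +1-corrected Monte Carlo p-values at
α = 0.05.  The subject-count curve subsamples n < N subjects (100 draws),
correlating the subsample grand average with the full grand average.

**What the synthetic study shows — and does not.**  On the default
20-subject dataset the significant entrainment cluster contains the
planted auditory dipole, and the detector catches ≥ 95% of injected
artifact trials.  The group-level argmax, however, sits ≈ 3 mm
superficial to the planted source — the same toward-the-electrodes depth
bias the mismatch benchmark exposes — and deep (thalamic) localization is
blurry, with argmax errors of ≈ 4 mm at any SNR and regularization.
These are properties of a 12-channel dorsal montage, and they temper what
single-peak localization claims real recordings of this kind can support.
The generator does not emulate real inter-subject anatomical variability,
electrode impedance drift, movement artifacts beyond broadband bursts, or
non-stationary background spectra; passing tests demonstrate the
correctness and calibration of the pipeline, not field performance.

## Determinism and problem sizes

All randomness flows from explicit seeds (counter-keyed substreams for
sweeps; one generator per subject for ASSR data).  Default test-time
problem sizes: head models at 1-mm voxels (≈ 2.6 k nodes, ≈ 2 k dipoles),
a reduced ellipsoid (≈ 540 dipoles) for solver-level tests, 135 planted
positions for the benchmark sweep, 20 subjects for the group analyses,
and 100 null replicates × 1000 permutations for the FWER study; these
sizes reproduce the trends of interest while keeping the whole suite in
a few minutes.
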