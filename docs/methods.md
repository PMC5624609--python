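# Methods

## Head phantom

The phantom is a set of analytic shapes voxelised on a regular grid: an
ellipsoidal head (semi-axes ≈ 0.40/0.44/0.46 of the field of view), a skull
shell (≥4 mm), a CSF rim (≥3 mm), interior tissue, and one ellipsoidal air
cavity placed anterior–inferior on the midline as a frontal-sinus analogue.
All shapes are functions of coordinates symmetric about the grid centre, so
the label map is exactly left–right mirror symmetric — a property the
motion–field interaction tests rely on (rotations about x preserve the
symmetry of the field change; rotations about y break it). The only seeded
component is a smooth, symmetrised ±5 % PD texture inside tissue; a fixed
seed therefore reproduces the phantom bit for bit.

Volume susceptibility is two-valued: air +0.36 ppm, everything else
−9.05 ppm (standard literature values; the air–tissue contrast of 9.41 ppm is
what drives the field). Default relaxation parameters (T1/T2/T2*/PD) are
generic 3 T values per tissue class and are configurable; they give the
expected contrast behaviour (CSF bright on the long-TE structural and b=0
volumes). Diffusion tensors are isotropic in tissue (MD 0.7·10⁻³ mm²/s) and
CSF (3.0·10⁻³), with a bent-cylinder tract (an arc in an axial slab, tangent
along the arc) of eigenvalues (1.7, 0.3, 0.3)·10⁻³ mm²/s, FA ≈ 0.80, so that
principal-direction error metrics are exercised.

The diffusion signal is represented per voxel by a real, even-order
spherical-harmonic fit (order 8, 45 coefficients, fitted from 60 uniform
directions of the tensor forward model `S = S0 exp(−b gᵀDg)`). Even-only
terms enforce the antipodal symmetry of diffusion signals; negative fitted
lobes are reported, not clipped. For tensor-generated signals the order-8 fit
reproduces held-out directions to well below 1 % relative RMS.

## Off-resonance field

The field is the first-order perturbation (Fourier dipole-kernel) solution.
The grid is zero-padded by a factor of two per axis (the long-range kernel
otherwise wraps); the χ map is referenced to its exterior value before
padding so the padding continues the surrounding air; the k=0 term is zero,
making the raw field mean-free. Against the analytic uniform-sphere solution
the external field agrees to <2 % relative RMS beyond two radii and the
internal field is uniform.

Two conventions shape the field actually used by the simulator:

1. **Preparation.** The raw solution is masked to the head, eroded by one
   voxel, smoothed with a 3-D Gaussian of σ = 5 mm and smoothly extrapolated
   outside the mask — the standard preparation applied to measured fieldmaps.
   The raw interface values (~±770 Hz at the cavity at 3 T) would give
   displacement Jacobians near ±14, which no acquisition exhibits.
2. **Shim.** A constant equal to the brain-mean of the prepared field is
   subtracted, as a scanner shim would do. Under motion the shim of the
   reference volume is retained. The dipole field of the phantom's single
   large cavity otherwise carries a ~100 Hz brain-wide offset that a real
   multi-interface head (and any shimmed scan) does not have.

The resulting brain field spans roughly −75 to +180 Hz — mean distortion
≈0.6 voxels with ~11-voxel peaks at the desk bandwidth, comparable in
severity to non-accelerated high-end acquisitions.

Under rigid motion, mode `"dynamic"` resamples χ and re-solves the dipole
problem (with identical preparation and the original shim); mode `"static"`
rigidly resamples the pre-motion field — precisely the assumption of all
existing correction methods. Translations and rotations about B0 produce no
dynamic change (verified against the shifted/rotated static field); a 5°
rotation about y changes the field by up to ~40 Hz on this phantom, with the
left–right asymmetry expected from the mirror-symmetric geometry.

## EPI forward model

Distortion acts purely along the PE axis, column by column. The forward model
is a *pushforward*: each source cell's signal is deposited uniformly over the
interval its edges map to, so signal is conserved exactly (compression piles
up, stretch dilutes, fold-overs superpose); signal mapped outside the FOV is
dropped and counted. Correction uses the opposite operation, a *pullback*
(linear interpolation at `x + d(x)`) with Jacobian intensity modulation,
clamped to [0.1, 10] during correction to avoid noise blow-up near singular
points. The deliberate asymmetry (deposit forward, interpolate back) is what
lets the bench expose the information loss in compressed regions: a
distort-then-unwarp round trip is accurate to <2 % relative RMS in smooth
stretch-only regions and visibly worse at pile-up.

Acquisition is a per-slice 2-D FFT, Hamming apodization (applied before the
noise so the noise stays white), additive complex Gaussian noise, and
magnitude reconstruction — Rician noise in the image, Rayleigh in the
background. Noise is calibrated so that the whole-brain mean of the *acquired*
(apodized) b=0 volume divided by the image-domain noise σ equals the target
SNR; the calibration round-trips to within a fraction of a percent. An
optional band-limiting path (sampling a finer object at the acquisition
matrix) reproduces Gibbs ringing and its damping by apodization; the default
pipeline simulates at acquisition resolution.

Motion occurs between volumes only. Each volume's diffusion contrast is
evaluated in the head frame with the gradient rotated into it (`R⁻¹g`), then
the image is rigidly resampled into the scanner frame, distorted with the
per-volume field, and acquired. Per-volume ground-truth PE displacement
fields and transforms are stored alongside the data.

Auxiliary scans: a dual-echo spoiled GRE (TEs 4.92/7.38 ms, TR 700 ms, flip
60°) with phase 2π·f·TE, T2* decay and a sinc intra-voxel dephasing factor
driven by the local field gradient — the standard failure mechanism of
measured fieldmaps near air cavities — and an undistorted spin-echo T2
structural (TE 110 ms, TR 2200 ms) on the phantom grid (a full-scale 1 mm
structural is a resolution detail the desk bench does not need, since the
structural serves only as a registration target).

## Correction methods

All three families share the displacement conventions above and apply their
estimate by Jacobian-modulated pullback.

**FMB.** The fieldmap is `wrap(φ₂−φ₁)/(2π·ΔTE)` inside the eroded magnitude
mask, spatially unwrapped with a reliability-sorting algorithm, extrapolated
outside the mask, smoothed with σ = 1 voxel, converted to displacement per
volume polarity. The global 2π·k/ΔTE ambiguity is resolved by centring the
median in the unambiguous range ±1/(2ΔTE).

**MPB / MPB/F.** The field is estimated from the mean reversed-PE b=0 pair by
*cumulative-mass matching*: along each PE column the blip-up and blip-down
cumulative intensity profiles are the same monotone function of the
undistorted coordinate sampled at x±d, so matching equal mass fractions gives
the displacement directly — exact for noise-free conserved signal, with
unlimited capture range, and antisymmetric under swapping the pair. Two
passes (the second matches the residual after Jacobian-modulated unwarping
with the current field) with Gaussian smoothing of the field (σ = 1, then 0.5
voxels) regularise noise without accumulating bias. A coarse-to-fine
Gauss–Newton minimisation of ‖U₊(f) − U₋(f)‖² was implemented first and
found to diverge: the residual of Jacobian-modulated unwarps contains a
modulation term (−2·I·∂e/∂y) that a transport-only linearisation misattributes
wherever the intensity is flat. MPB corrects one PE set; MPB/F additionally
averages matched corrected blip-up/blip-down pairs, recovering signal in
compressed regions and averaging noise.

**RB.** The first b=0 is registered to the histogram-matched structural with
the deformation constrained along PE (SSD similarity), estimated by a damped
Gauss–Newton scheme on a smoothed voxel field over image-smoothing scales
{6, 3, 1.5} voxels, with a squared-Laplacian (bending-energy) penalty whose
printed weight 0.01 is scaled by the mean squared image intensity so it acts
as a relative weight. The estimated field is applied to every volume. As the
bending weight → ∞ the estimate collapses to zero displacement. These choices
are not equivalent to any particular external registration tool's defaults.

**Rigid registration** (6-DOF, SSD, Powell search, two-level smoothing
pyramid) recovers a 3° rotation to ~0.03° on the phantom and is used to place
corrected data in a common space when motion is present; in the no-motion
experiments the simulation already leaves corrected volumes in the
ground-truth frame, so the harness skips this step.

## Metrics and experiments

Displacement MAE is reported in voxels (and convertible to mm — published
comparisons do not always state which, so both are exposed), over the brain
mask and over a one-voxel-eroded variant. Intensity MAE is split into b=0 and
DWI volumes against the artefact-free dataset. Tensor fits are plain
log-linear least squares; V1 angular error is antipodally invariant and
restricted to voxels with ground-truth FA > 0.2. The AP–LR surrogate is the
whole-brain mean |difference| of corrected b=0 volumes from AP/PA- and
LR/RL-encoded acquisitions — by design computable without ground truth, and
documented here with the caveat that it preserves method *ordering* rather
than the contrast between methods.

The desk preset uses a 64×64×32 grid at 3 mm, 12 DWI + 2 b=0 volumes per PE
polarity, PE bandwidth 1/(1 ms · 64) ≈ 15.6 Hz/px, and 2 noise realisations
per SNR level; the full-scale preset (90×106×68 at 2 mm, 32+4 volumes,
bandwidth pinned at the quoted 9.5 Hz/px) is available but slow. The static
comparison at the desk preset runs in ~1.5 min on one CPU; the four-arm
dynamic experiment ({static, dynamic} × motion ×1/×3, noise-free, corrected
with known motion and the known static field, in one-PE and two-PE variants)
in ~30 s.

Motion traces draw 0.2° SD jitter on x/y rotations with sparse 2–5° spikes
(≈12 % of volumes), zero z-rotations and translations, scaled by the motion
factor; the first volume is the reference.

## What the phantom does and does not show

The bench reproduces: the intensity-error ordering RB > FMB > MPB > MPB/F at
every noise level; pile-up recovery by MPB/F; the surrogate ordering
RB > FMB > MPB > MPB/F; increased FA errors under a dynamic field, growing
with motion amplitude, with negatively skewed static-minus-dynamic error
histograms; and no penalty (a marginal benefit) from two-PE correction in the
dynamic case.

It does **not** reproduce the whole-brain displacement-error ranking of FMB
below MPB. On this phantom FMB's displacement estimate is *more* accurate
than MPB's (0.034 vs 0.053 voxels noise-free). Two structural reasons: the
interior field of a quasi-ellipsoidal head is nearly uniform at the brain
edge, so the edge partial-volume and extrapolation errors that dominate FMB's
whole-brain error on real cortical geometry are absent (on eroded masks,
published comparisons show the same FMB < MPB relation this bench produces);
and the simulated fieldmap scans measure the very field that distorts the
EPI, a circularity inherent to fieldmap-derived simulation inputs.
Supersampled partial-volume GRE simulation and T2*/dephasing physics were
added and do not close the gap. Conclusions about FMB-vs-MPB *geometric*
accuracy therefore do not transfer from this phantom to real heads; the
intensity, surrogate and dynamic-field conclusions do, in ordering terms.

Other limitations: no Bloch-level simulation (no eddy currents, ghosting,
chemical shift, T1 history, partial Fourier, multi-coil effects); binary
tissue labels (no partial volume in the EPI data); motion only between
volumes; a single air cavity rather than the full set of real air spaces; and
desk-scale grids, so absolute error magnitudes are smaller than published
full-scale values — orderings and qualitative behaviour are the meaningful
outputs.
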