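"""Forward simulation of distorted EPI diffusion data.

Susceptibility distortion in EPI acts along the phase-encode (PE) axis: an
off-resonance of f Hz shifts signal by f / BW_pp voxels, where BW_pp is the
PE bandwidth per pixel (1 / (echo spacing * number of PE lines)).  The forward
model deposits each source voxel's signal over the destination interval it
maps to (a signal-conserving pushforward), so compression piles signal up and
stretch dilutes it — the behaviour a pullback interpolation cannot reproduce.
k-space acquisition adds Hamming apodization and complex Gaussian noise,
giving Rician magnitude noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .phantom import (
    HeadPhantom,
    fit_spherical_harmonics,
    evaluate_sh,
    synthesize_dwi_signal,
    uniform_directions,
)
from .fieldsim import (
    FieldMap,
    RigidTransform,
    compute_susceptibility_field,
    recompute_field_after_motion,
    resample_rigid,
    smooth_and_extrapolate_field,
)


def prepare_susceptibility_field(
    phantom: HeadPhantom,
    b0: float = 3.0,
    sigma: float = 5.0,
    raw: FieldMap | None = None,
    head_mask: np.ndarray | None = None,
    shim_offset: float | None = None,
) -> FieldMap:
    """Fieldmap-style preparation of the simulation's off-resonance input.

    Mirrors the standard preparation of a measured fieldmap: mask, erode by
    one voxel, smooth with a 3-D Gaussian (sigma in mm, default 5), and
    extrapolate smoothly outside the mask.  A constant is then removed (the
    scanner shim nulls the mean field over the brain); pass ``shim_offset``
    to reuse the shim setting of a reference (pre-motion) acquisition.
    """
    if raw is None:
        raw = compute_susceptibility_field(
            phantom.chi, b0=b0, voxel_size=phantom.voxel_size
        )
    if head_mask is None:
        head_mask = phantom.head_mask()
    eroded = ndimage.binary_erosion(head_mask, structure=np.ones((3, 3, 3), bool))
    prep = smooth_and_extrapolate_field(raw, eroded, sigma=sigma)
    if shim_offset is None:
        shim_offset = float(prep.values[phantom.brain_mask()].mean())
    prep.values = prep.values - shim_offset
    prep.shim_offset = shim_offset
    return prep

logger = logging.getLogger(__name__)

#: PE-axis naming -> (grid axis, polarity).  Grid axes: x=0 (L->R), y=1 (P->A),
#: z=2 (I->S).
PE_AXES = {"AP": (1, -1), "PA": (1, +1), "LR": (0, -1), "RL": (0, +1)}


@dataclass
class Protocol:
    """EPI acquisition protocol.

    ``matrix`` is (N_PE, N_FE) in-plane; ``echo_spacing`` in ms; the PE
    bandwidth per pixel defaults to 1/(echo_spacing * N_PE) but can be pinned
    explicitly (scanners quote it directly).
    """

    matrix: tuple = (64, 64)
    n_slices: int = 32
    voxel_size: tuple = (3.0, 3.0, 3.0)
    echo_spacing: float = 1.0  # ms
    pe_axis: str = "AP"
    te: float = 109.0  # ms
    bvals: np.ndarray = dc_field(default_factory=lambda: np.zeros(1))
    bvecs: np.ndarray = dc_field(default_factory=lambda: np.array([[1.0, 0, 0]]))
    snr_target: float | None = None
    apodize: bool = True
    bandwidth_per_pixel: float | None = None  # Hz, overrides the derived value

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.pe_axis not in PE_AXES:
            raise ValueError(f"pe_axis must be one of {sorted(PE_AXES)}")

    @property
    def n_pe(self) -> int:
        return int(self.matrix[0])

    @property
    def bw_per_pixel(self) -> float:
        if self.bandwidth_per_pixel is not None:
            return float(self.bandwidth_per_pixel)
        return 1.0 / (self.echo_spacing * 1e-3 * self.n_pe)

    @property
    def pe_grid_axis(self) -> int:
        return PE_AXES[self.pe_axis][0]

    @property
    def pe_polarity(self) -> int:
        return PE_AXES[self.pe_axis][1]

    @property
    def grid_shape(self) -> tuple:
        ax, _ = PE_AXES[self.pe_axis]
        n_pe, n_fe = int(self.matrix[0]), int(self.matrix[1])
        if ax == 0:
            return (n_pe, n_fe, self.n_slices)
        return (n_fe, n_pe, self.n_slices)

    def with_pe_axis(self, pe_axis: str) -> "Protocol":
        import copy

        p = copy.copy(self)
        p.pe_axis = pe_axis
        return p

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)


def _shell_table(n_b0: int, n_dwi: int, bval: float = 1000.0):
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dwi, bval)])
    dirs = uniform_directions(n_dwi)
    bvecs = np.concatenate([np.tile([[1.0, 0.0, 0.0]], (n_b0, 1)), dirs])
    return bvals, bvecs


def desk_protocol(pe_axis: str = "AP", snr_target: float | None = None) -> Protocol:
    """Desk-scale protocol: 64x64x32 at 3 mm, 2 b=0 + 12 b=1000 volumes."""
    bvals, bvecs = _shell_table(2, 12)
    return Protocol(
        matrix=(64, 64), n_slices=32, voxel_size=(3.0, 3.0, 3.0),
        echo_spacing=1.0, pe_axis=pe_axis, te=109.0,
        bvals=bvals, bvecs=bvecs, snr_target=snr_target,
    )


def full_scale_protocol(pe_axis: str = "AP", snr_target: float | None = None) -> Protocol:
    """Full-scale preset: 106x90 matrix, 68 slices, 2 mm, 4 b=0 + 32 b=1000,
    echo spacing 1 ms, PE bandwidth per pixel pinned at 9.5 Hz."""
    bvals, bvecs = _shell_table(4, 32)
    return Protocol(
        matrix=(106, 90), n_slices=68, voxel_size=(2.0, 2.0, 2.0),
        echo_spacing=1.0, pe_axis=pe_axis, te=109.0,
        bvals=bvals, bvecs=bvecs, snr_target=snr_target,
        bandwidth_per_pixel=9.5,
    )


@dataclass
class DisplacementField:
    """Per-voxel signed shift along one grid axis, in voxels."""

    shift: np.ndarray
    axis: int
    voxel_size: tuple = (1.0, 1.0, 1.0)

    @property
    def jacobian(self) -> np.ndarray:
        """1 + d(shift)/d(PE), central differences along the PE axis."""
        return 1.0 + np.gradient(self.shift, axis=self.axis)

    def to_mm(self) -> np.ndarray:
        return self.shift * np.asarray(self.voxel_size)[self.axis]

    def scaled(self, factor: float) -> "DisplacementField":
        return DisplacementField(self.shift * factor, self.axis, self.voxel_size)


def field_to_displacement(fmap: FieldMap, protocol: Protocol) -> DisplacementField:
    """Convert off-resonance (Hz) to a PE-axis voxel shift: d = f/BW_pp * s,
    where s is the PE polarity sign."""
    shift = fmap.values / protocol.bw_per_pixel * protocol.pe_polarity
    return DisplacementField(shift=shift, axis=protocol.pe_grid_axis,
                             voxel_size=fmap.voxel_size)


# ---------------------------------------------------------------------------
# distortion (pushforward) and unwarping (pullback)
# ---------------------------------------------------------------------------

def distort_volume(volume: np.ndarray, disp: DisplacementField) -> np.ndarray:
    """Signal-conserving pushforward along the PE axis.

    Each source voxel's intensity is deposited uniformly over the destination
    interval its cell maps to (cell edges move with the interpolated shift).
    Signal mapped outside the FOV is dropped and counted, as in real EPI.
    """
    if volume.shape != disp.shift.shape:
        raise ValueError("volume and displacement shapes differ")
    axis = disp.axis
    vol = np.moveaxis(volume, axis, 0)
    d = np.moveaxis(disp.shift, axis, 0)
    n = vol.shape[0]
    cols = vol.reshape(n, -1)
    dc = d.reshape(n, -1)

    # displacement at cell edges (n+1 per column)
    d_edge = np.empty((n + 1, cols.shape[1]))
    d_edge[1:-1] = 0.5 * (dc[:-1] + dc[1:])
    d_edge[0] = dc[0]
    d_edge[-1] = dc[-1]
    edges = np.arange(n + 1)[:, None] - 0.5 + d_edge

    lo = np.minimum(edges[:-1], edges[1:])
    hi = np.maximum(edges[:-1], edges[1:])
    width = hi - lo
    eps = 1e-9
    mid = 0.5 * (lo + hi)

    out = np.zeros_like(cols)
    dropped = 0.0
    col_idx = np.broadcast_to(np.arange(cols.shape[1]), cols.shape)

    # degenerate (collapsed) cells: deposit everything at the midpoint cell
    deg = width < eps
    if np.any(deg):
        k = np.rint(mid[deg]).astype(int)
        ok = (k >= 0) & (k < n)
        np.add.at(out, (k[ok], col_idx[deg][ok]), cols[deg][ok])
        dropped += float(np.abs(cols[deg][~ok]).sum())

    nd = ~deg
    if np.any(nd):
        dens = np.zeros_like(cols)
        dens[nd] = cols[nd] / width[nd]
        k0 = np.floor(lo + 0.5).astype(int)
        kmax = np.floor(hi + 0.5).astype(int)
        max_span = int((kmax - k0)[nd].max()) if np.any(nd) else 0
        for o in range(max_span + 1):
            k = k0 + o
            active = nd & (k <= kmax)
            if not np.any(active):
                break
            ov = np.minimum(hi, k + 0.5) - np.maximum(lo, k - 0.5)
            ov = np.clip(ov, 0.0, None)
            inside = active & (k >= 0) & (k < n)
            np.add.at(
                out, (k[inside], col_idx[inside]), dens[inside] * ov[inside]
            )
            outside = active & ~((k >= 0) & (k < n))
            dropped += float(np.abs(dens[outside] * ov[outside]).sum())

    if dropped > 0:
        logger.info("distort_volume: dropped %.4g signal units outside FOV", dropped)
    out = out.reshape(vol.shape)
    return np.moveaxis(out, 0, axis)


def unwarp_volume(
    volume: np.ndarray,
    disp: DisplacementField,
    jacobian_modulate: bool = True,
    jacobian_clamp: tuple | None = (0.1, 10.0),
) -> np.ndarray:
    """Pullback correction: out(x) = vol(x + d(x)) along PE, optionally
    multiplied by the Jacobian 1 + dd/dPE.

    With ``jacobian_clamp=None`` a non-invertible field (Jacobian <= 0)
    raises; corrections pass a clamp to stay robust near pile-up.
    """
    from scipy.ndimage import map_coordinates

    if volume.shape != disp.shift.shape:
        raise ValueError("volume and displacement shapes differ")
    jac = disp.jacobian
    if jacobian_clamp is None:
        bad = jac <= 0
        if np.any(bad):
            idx = np.argwhere(bad)
            raise ValueError(
                f"displacement field not invertible: jacobian <= 0 in "
                f"{bad.sum()} voxels, e.g. around {tuple(idx[0])}"
            )
    coords = np.indices(volume.shape).astype(float)
    coords[disp.axis] += disp.shift
    out = map_coordinates(volume, coords, order=1, mode="constant", cval=0.0)
    if jacobian_modulate:
        if jacobian_clamp is not None:
            lo, hi = jacobian_clamp
            n_clamped = int(np.sum((jac < lo) | (jac > hi)))
            if n_clamped:
                logger.debug("jacobian clamped in %d voxels", n_clamped)
            jac = np.clip(jac, lo, hi)
        out = out * jac
    return out


# ---------------------------------------------------------------------------
# k-space acquisition and noise
# ---------------------------------------------------------------------------

def _hamming2d(shape):
    w0 = np.hamming(shape[0])
    w1 = np.hamming(shape[1])
    return np.fft.ifftshift(np.outer(w0, w1))


def acquire_kspace(
    volume: np.ndarray,
    protocol: Protocol,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    output_shape: tuple | None = None,
) -> np.ndarray:
    """Per-slice 2-D FFT -> Hamming apodization -> complex Gaussian noise ->
    magnitude reconstruction (Rician noise in the image domain).

    If ``output_shape`` is smaller than the input in-plane shape, only the
    central k-space region is sampled (band limiting a finer object), which
    produces Gibbs ringing at sharp edges; apodization then damps it.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    in_shape = volume.shape[:2]
    out_shape = tuple(output_shape) if output_shape is not None else in_shape
    out = np.empty(out_shape + (volume.shape[2],), dtype=float)
    win = _hamming2d(out_shape) if protocol.apodize else None
    scale = (out_shape[0] * out_shape[1]) / (in_shape[0] * in_shape[1])
    for s in range(volume.shape[2]):
        k = np.fft.fft2(volume[:, :, s])
        if out_shape != in_shape:
            kc = np.fft.fftshift(k)
            c0 = (in_shape[0] - out_shape[0]) // 2
            c1 = (in_shape[1] - out_shape[1]) // 2
            kc = kc[c0:c0 + out_shape[0], c1:c1 + out_shape[1]]
            k = np.fft.ifftshift(kc) * scale
        if win is not None:
            k = k * win
        if noise_sigma > 0:
            k = k + noise_sigma * (
                rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape)
            )
        out[:, :, s] = np.abs(np.fft.ifft2(k))
    return out


def image_noise_sigma(kspace_sigma: float, shape2d) -> float:
    """Image-domain per-channel noise std implied by k-space sigma (unnormalised
    FFT: ifft2 divides by N, so sigma_img = sigma_k / sqrt(N))."""
    n = shape2d[0] * shape2d[1]
    return kspace_sigma / np.sqrt(n)


def calibrate_noise_sigma(
    phantom: HeadPhantom, protocol: Protocol, snr_target: float
) -> float:
    """k-space noise sigma giving the requested whole-brain SNR on the b=0
    volume: SNR = mean(b=0 over brain) / sigma_image."""
    if not snr_target > 0:
        raise ValueError("snr_target must be > 0")
    if np.isinf(snr_target):
        return 0.0
    mask = phantom.brain_mask()
    if not np.any(mask):
        raise ValueError("empty brain mask")
    b0 = synthesize_dwi_signal(phantom, 0.0, (1, 0, 0), te=protocol.te)
    # the SNR is defined on the acquired volume: include acquisition
    # apodization in the reference signal level
    b0 = acquire_kspace(b0, protocol, 0.0)
    mean_signal = float(b0[mask].mean())
    sigma_img = mean_signal / snr_target
    return sigma_img * np.sqrt(phantom.grid_shape[0] * phantom.grid_shape[1])


def measure_snr(noisy_b0: np.ndarray, brain_mask: np.ndarray,
                background_mask: np.ndarray) -> float:
    """Whole-brain SNR re-measured from a magnitude image: mean brain signal
    over the noise std estimated from the Rayleigh background
    (sigma = mean(background) / sqrt(pi/2))."""
    sigma = float(noisy_b0[background_mask].mean()) / np.sqrt(np.pi / 2.0)
    return float(noisy_b0[brain_mask].mean()) / sigma


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class MotionTrace:
    """Per-volume rigid transforms (motion occurs between volumes)."""

    transforms: list
    scale: float = 1.0

    def __len__(self):
        return len(self.transforms)

    def __getitem__(self, i) -> RigidTransform:
        return self.transforms[i]


@dataclass
class GREPair:
    """Dual-echo gradient-echo field-mapping acquisition."""

    mag1: np.ndarray
    phase1: np.ndarray
    mag2: np.ndarray
    phase2: np.ndarray
    te1: float  # ms
    te2: float  # ms

    def __post_init__(self):
        if not self.te2 > self.te1:
            raise ValueError("te2 must exceed te1")

    @property
    def delta_te(self) -> float:
        return self.te2 - self.te1


@dataclass
class DWIDataset:
    """4-D stack plus acquisition metadata and per-volume ground truth."""

    volumes: np.ndarray  # (X, Y, Z, N)
    bvals: np.ndarray
    bvecs: np.ndarray
    pe_axes: list  # per-volume PE name ("AP", ...)
    protocol: Protocol
    gt_displacements: list | None = None  # per-volume DisplacementField
    motion: list | None = None  # per-volume RigidTransform
    noise_sigma: float = 0.0

    def __post_init__(self):
        n = self.volumes.shape[-1]
        if not (len(self.bvals) == len(self.bvecs) == len(self.pe_axes) == n):
            raise ValueError("metadata lengths must match volume count")

    @property
    def n_volumes(self) -> int:
        return self.volumes.shape[-1]

    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bvals == 0)

    def subset(self, idx) -> "DWIDataset":
        idx = np.asarray(idx)
        return DWIDataset(
            volumes=self.volumes[..., idx],
            bvals=self.bvals[idx],
            bvecs=self.bvecs[idx],
            pe_axes=[self.pe_axes[i] for i in idx],
            protocol=self.protocol,
            gt_displacements=None if self.gt_displacements is None
            else [self.gt_displacements[i] for i in idx],
            motion=None if self.motion is None else [self.motion[i] for i in idx],
            noise_sigma=self.noise_sigma,
        )


def ground_truth_displacement(
    static_field: FieldMap,
    transform: RigidTransform,
    protocol: Protocol,
) -> DisplacementField:
    """PE component of the total map from ground-truth space to the acquired
    volume: rigid motion followed by the susceptibility PE shift of the field
    experienced during acquisition.  Reduces to field_to_displacement for an
    identity transform."""
    base = field_to_displacement(static_field, protocol)
    if transform.is_identity():
        return base
    vs = np.asarray(static_field.voxel_size, dtype=float)
    shape = static_field.grid_shape
    # field experienced in the scanner frame (static assumption)
    moved = resample_rigid(static_field.values, transform, vs, order=1)
    d_susc = moved / protocol.bw_per_pixel * protocol.pe_polarity
    # PE component of the rigid map at each ground-truth voxel
    idx = np.indices(shape).astype(float)
    mm = idx * vs[:, None, None, None]
    tr = transform
    if not np.any(np.asarray(tr.center)):
        center = (np.asarray(shape) - 1) / 2.0 * vs
        tr = RigidTransform(tr.rotations, tr.translations, tuple(center))
    M = tr.matrix()
    ax = protocol.pe_grid_axis
    moved_pe = (
        M[ax, 0] * mm[0] + M[ax, 1] * mm[1] + M[ax, 2] * mm[2] + M[ax, 3]
    )
    rigid_pe_vox = (moved_pe - mm[ax]) / vs[ax]
    # susceptibility shift sampled at the moved position (approximated by
    # sampling the moved field at the ground-truth voxel)
    total = rigid_pe_vox + d_susc
    return DisplacementField(shift=total, axis=ax, voxel_size=tuple(vs))


def simulate_dataset(
    phantom: HeadPhantom,
    protocol: Protocol,
    motion: MotionTrace | None = None,
    field_mode: str = "static",
    seed: int = 0,
    dual_pe: bool = False,
    noise_sigma: float | None = None,
    signal_model: str = "sh",
    sh_order: int = 8,
    n_fit_directions: int = 60,
    static_field: FieldMap | None = None,
    b0_strength: float = 3.0,
    field_prep_sigma: float = 5.0,
) -> DWIDataset:
    """Simulate one DW-MR dataset volume by volume.

    Per volume: rigid motion is applied to the object, the off-resonance
    field obtained per ``field_mode`` ("static" rigidly follows the head,
    "dynamic" is re-solved from the moved susceptibility map, "none" disables
    distortion), the diffusion signal synthesized from the SH (or tensor)
    representation, distorted along PE, and passed through k-space with
    noise.  ``dual_pe`` appends a second full set with reversed PE polarity.
    The ground-truth displacement experienced by every volume is stored.
    """
    if field_mode not in ("static", "dynamic", "none"):
        raise ValueError("field_mode must be static|dynamic|none")
    if tuple(protocol.grid_shape) != tuple(phantom.grid_shape):
        raise ValueError(
            f"protocol grid {protocol.grid_shape} does not match phantom grid "
            f"{phantom.grid_shape}"
        )
    reverse = {"AP": "PA", "PA": "AP", "LR": "RL", "RL": "LR"}
    pe_list = [protocol.pe_axis] * protocol.n_volumes
    if dual_pe:
        pe_list += [reverse[protocol.pe_axis]] * protocol.n_volumes
    bvals = np.concatenate([protocol.bvals] * (2 if dual_pe else 1))
    bvecs = np.concatenate([protocol.bvecs] * (2 if dual_pe else 1))
    n_vol = len(pe_list)
    if motion is not None and len(motion) != n_vol:
        raise ValueError(
            f"motion trace length {len(motion)} != volume count {n_vol}"
        )

    if noise_sigma is None:
        if protocol.snr_target:
            noise_sigma = calibrate_noise_sigma(phantom, protocol, protocol.snr_target)
        else:
            noise_sigma = 0.0

    if field_mode != "none" and static_field is None:
        static_field = prepare_susceptibility_field(
            phantom, b0=b0_strength, sigma=field_prep_sigma
        )

    sh = None
    if signal_model == "sh":
        shell_b = float(protocol.bvals.max()) if protocol.bvals.max() > 0 else 1000.0
        fit_dirs = uniform_directions(n_fit_directions)
        sigs = [
            synthesize_dwi_signal(phantom, shell_b, g, te=protocol.te)
            for g in fit_dirs
        ]
        sh = fit_spherical_harmonics(sigs, fit_dirs, order=sh_order, bval=shell_b)
    elif signal_model != "tensor":
        raise ValueError("signal_model must be 'sh' or 'tensor'")

    ss = np.random.SeedSequence(seed)
    child_rngs = [np.random.default_rng(s) for s in ss.spawn(n_vol)]

    volumes = np.empty(phantom.grid_shape + (n_vol,), dtype=float)
    gt_disps, motions = [], []
    b0_image = synthesize_dwi_signal(phantom, 0.0, (1, 0, 0), te=protocol.te)

    for v in range(n_vol):
        tr = motion[v] if motion is not None else RigidTransform()
        prot_v = protocol.with_pe_axis(pe_list[v])
        # diffusion signal in the head frame, gradient rotated into it
        if bvals[v] == 0:
            head_sig = b0_image
        else:
            g = np.asarray(bvecs[v], dtype=float)
            R = tr.rotation_matrix()
            g_head = R.T @ g
            g_head /= np.linalg.norm(g_head)
            if sh is not None:
                head_sig = evaluate_sh(sh, g_head)
            else:
                head_sig = synthesize_dwi_signal(
                    phantom, bvals[v], g_head, te=protocol.te
                )
        if tr.is_identity():
            scanner_sig = head_sig
        else:
            scanner_sig = resample_rigid(head_sig, tr, phantom.voxel_size, order=1)

        if field_mode == "none":
            distorted = scanner_sig
            disp = DisplacementField(
                np.zeros(phantom.grid_shape), prot_v.pe_grid_axis,
                phantom.voxel_size,
            )
        else:
            if tr.is_identity():
                fmap_v = static_field
            elif field_mode == "static":
                fmap_v = recompute_field_after_motion(
                    phantom, tr, b0=b0_strength, mode="static",
                    static_field=static_field,
                )
            else:
                # physical behaviour: re-solve the dipole problem for the
                # moved head, re-prepare identically, keep the original shim
                raw = recompute_field_after_motion(
                    phantom, tr, b0=b0_strength, mode="dynamic"
                )
                head_moved = resample_rigid(
                    phantom.head_mask().astype(float), tr, phantom.voxel_size,
                    order=1,
                ) > 0.5
                fmap_v = prepare_susceptibility_field(
                    phantom, b0=b0_strength, sigma=field_prep_sigma, raw=raw,
                    head_mask=head_moved, shim_offset=static_field.shim_offset,
                )
            disp = field_to_displacement(fmap_v, prot_v)
            distorted = distort_volume(scanner_sig, disp)

        volumes[..., v] = acquire_kspace(
            distorted, prot_v, noise_sigma, child_rngs[v]
        )
        gt_disps.append(disp)
        motions.append(tr)

    return DWIDataset(
        volumes=volumes, bvals=bvals, bvecs=bvecs, pe_axes=pe_list,
        protocol=protocol, gt_displacements=gt_disps, motion=motions,
        noise_sigma=noise_sigma,
    )


# ---------------------------------------------------------------------------
# auxiliary acquisitions
# ---------------------------------------------------------------------------

def simulate_gre_pair(
    phantom: HeadPhantom,
    fmap: FieldMap,
    te1: float = 4.92,
    te2: float = 7.38,
    tr: float = 700.0,
    flip: float = 60.0,
    noise_sigma: float = 0.0,
    protocol: Protocol | None = None,
    seed: int = 0,
) -> GREPair:
    """Dual-echo spoiled-GRE field-mapping scan.

    Magnitude from the spoiled steady state PD sin(a)(1-E1)/(1-cos(a)E1)
    e^(-TE/T2*), further attenuated by intra-voxel dephasing where the
    off-resonance field has strong gradients (sinc factor per axis) — the
    mechanism that makes measured fieldmaps unreliable near air cavities.
    Phase = 2*pi*f*TE wrapped to (-pi, pi].  Complex noise is added at the
    image-domain sigma implied by the k-space sigma used for the DWI data,
    so all scans share the same thermal noise level.
    """
    rng = np.random.default_rng(seed)
    pd = phantom.param_map("pd")
    t1 = np.maximum(phantom.param_map("t1"), 1e-9)
    t2s = np.maximum(phantom.param_map("t2s"), 1e-9)
    a = np.deg2rad(flip)
    e1 = np.exp(-tr / t1)
    base = pd * np.sin(a) * (1 - e1) / (1 - np.cos(a) * e1)
    shape2d = phantom.grid_shape[:2]
    sig_img = image_noise_sigma(noise_sigma, shape2d) if noise_sigma > 0 else 0.0

    # per-voxel field change across each axis (Hz) drives intra-voxel dephasing
    grads = np.gradient(fmap.values)

    out = []
    for te in (te1, te2):
        dephase = np.ones_like(base)
        for g in grads:
            dephase *= np.abs(np.sinc(g * te * 1e-3))
        mag = base * np.exp(-te / t2s) * dephase
        phase = 2 * np.pi * fmap.values * te * 1e-3
        c = mag * np.exp(1j * phase)
        if sig_img > 0:
            c = c + sig_img * (
                rng.standard_normal(c.shape) + 1j * rng.standard_normal(c.shape)
            )
        out.append((np.abs(c), np.angle(c)))
    (m1, p1), (m2, p2) = out
    return GREPair(mag1=m1, phase1=p1, mag2=m2, phase2=p2, te1=te1, te2=te2)


def simulate_structural(
    phantom: HeadPhantom, te: float = 110.0, tr: float = 2200.0
) -> np.ndarray:
    """Undistorted T2-weighted spin-echo image (the geometric reference):
    PD (1 - exp(-TR/T1)) exp(-TE/T2) on the phantom grid."""
    pd = phantom.param_map("pd")
    t1 = np.maximum(phantom.param_map("t1"), 1e-9)
    t2 = np.maximum(phantom.param_map("t2"), 1e-9)
    return pd * (1 - np.exp(-tr / t1)) * np.exp(-te / t2)
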