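"""Synthetic head phantom and spherical-harmonic diffusion-signal representation.

The phantom is a digital stand-in for a segmented-MRI input object: a tissue
label map with per-tissue relaxation parameters, a volume-susceptibility map
(air/tissue contrast drives the B0 perturbation), and a per-voxel diffusion
tensor field containing an anisotropic "tract" so that direction-sensitive
error metrics are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.ndimage import gaussian_filter

# label codes
AIR = 0
TISSUE = 1
CSF = 2
SKULL = 3
CAVITY = 4

#: volume magnetic susceptibility (dimensionless, SI); air minus tissue ~ 9.4 ppm
CHI_AIR = 0.36e-6
CHI_TISSUE = -9.05e-6

#: default per-tissue MR parameters: T1 (ms), T2 (ms), T2* (ms), PD (arb. units)
DEFAULT_TISSUE_PARAMS = {
    TISSUE: {"t1": 1100.0, "t2": 80.0, "t2s": 45.0, "pd": 0.85},
    CSF: {"t1": 4000.0, "t2": 1500.0, "t2s": 500.0, "pd": 1.0},
    SKULL: {"t1": 350.0, "t2": 3.0, "t2s": 1.5, "pd": 0.12},
    AIR: {"t1": 1.0, "t2": 1.0, "t2s": 1.0, "pd": 0.0},
    CAVITY: {"t1": 1.0, "t2": 1.0, "t2s": 1.0, "pd": 0.0},
}

#: diffusivities (mm^2/s)
MD_TISSUE = 0.7e-3
MD_CSF = 3.0e-3
TRACT_EIGENVALUES = (1.7e-3, 0.3e-3, 0.3e-3)  # FA ~ 0.80


@dataclass
class HeadPhantom:
    """Label map, tissue parameters, susceptibility and diffusion tensors.

    All arrays share ``grid_shape``; ``chi`` is defined on every voxel
    (including air), ``tensors`` has shape ``grid_shape + (3, 3)``.
    """

    labels: np.ndarray
    chi: np.ndarray
    tensors: np.ndarray
    voxel_size: tuple[float, float, float]
    tissue_params: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_PARAMS))
    pd_map: np.ndarray | None = None

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def head_mask(self) -> np.ndarray:
        """Everything that is not air (exterior or cavity)."""
        return (self.labels != AIR) & (self.labels != CAVITY)

    def brain_mask(self) -> np.ndarray:
        """Tissue + CSF: the mask used by all whole-brain metrics."""
        return (self.labels == TISSUE) | (self.labels == CSF)

    def param_map(self, name: str) -> np.ndarray:
        out = np.zeros(self.grid_shape)
        for lab, pars in self.tissue_params.items():
            out[self.labels == lab] = pars[name]
        if name == "pd" and self.pd_map is not None:
            return self.pd_map
        return out


def _centered_coords(grid_shape, voxel_size):
    """Physical (mm) coordinates, symmetric about the grid centre.

    The x axis is symmetric under ``arr[::-1]`` so analytic shapes built from
    these coordinates produce exactly mirror-symmetric label maps.
    """
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * dv
        for n, dv in zip(grid_shape, voxel_size)
    ]
    return np.meshgrid(*axes, indexing="ij")


def make_head_phantom(
    grid_shape=(64, 64, 32),
    voxel_size=3.0,
    seed: int = 0,
    tissue_params: dict | None = None,
) -> HeadPhantom:
    """Build the synthetic head: ellipsoidal tissue, CSF rim, skull shell and
    one air cavity under the frontal lobe (a sinus analogue).

    The label map is left-right mirror symmetric by construction.  ``seed``
    fixes the only random component (a smooth, symmetrised PD texture), so
    identical calls are bit-identical.
    """
    grid_shape = tuple(int(n) for n in np.broadcast_to(grid_shape, (3,)))
    voxel_size = tuple(float(v) for v in np.broadcast_to(voxel_size, (3,)))
    if min(grid_shape) < 32:
        raise ValueError(
            f"grid {grid_shape} too small: need >= 32 voxels per axis to fit "
            "skull, CSF rim and air cavity"
        )
    x, y, z = _centered_coords(grid_shape, voxel_size)
    fov = [n * dv for n, dv in zip(grid_shape, voxel_size)]

    # head ellipsoid semi-axes (mm), leaving a margin for FOV edges
    a = 0.40 * fov[0]
    b = 0.44 * fov[1]
    c = 0.46 * fov[2]
    r2 = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2

    skull_t = max(4.0, voxel_size[0])   # mm
    csf_t = max(3.0, voxel_size[0])
    # convert shell thicknesses to fractional radius (approximate, via x axis)
    s1 = (1.0 - skull_t / a) ** 2
    s2 = (1.0 - (skull_t + csf_t) / a) ** 2

    labels = np.full(grid_shape, AIR, dtype=np.int16)
    labels[r2 <= 1.0] = SKULL
    labels[r2 <= s1] = CSF
    labels[r2 <= s2] = TISSUE

    # frontal air cavity (sinus analogue): anterior (+y), inferior (-z), midline
    cav_center = (0.0, 0.52 * b, -0.35 * c)
    cav_ax = (min(14.0, 0.25 * a), min(11.0, 0.18 * b), min(9.0, 0.28 * c))
    cav = (
        ((x - cav_center[0]) / cav_ax[0]) ** 2
        + ((y - cav_center[1]) / cav_ax[1]) ** 2
        + ((z - cav_center[2]) / cav_ax[2]) ** 2
    ) <= 1.0
    if not np.all(labels[cav] == TISSUE):
        raise ValueError(
            "grid too small: the air cavity does not fit inside tissue"
        )
    labels[cav] = CAVITY

    for lab in (AIR, TISSUE, CSF, SKULL, CAVITY):
        if not np.any(labels == lab):
            raise ValueError(f"grid too small: label {lab} absent from phantom")

    chi = np.where((labels == AIR) | (labels == CAVITY), CHI_AIR, CHI_TISSUE)

    # diffusion tensors: isotropic tissue/CSF, anisotropic bent-cylinder tract
    tensors = np.zeros(grid_shape + (3, 3))
    eye = np.eye(3)
    tensors[labels == TISSUE] = (MD_TISSUE) * eye
    tensors[labels == CSF] = (MD_CSF) * eye
    tensors[labels == SKULL] = 0.2e-3 * eye

    # tract: arc of a circle in an axial-ish slab, centred posteriorly
    arc_c = (0.0, -0.25 * b)
    arc_r = 0.45 * a
    tube_w = max(7.0, 2.0 * voxel_size[0])
    rad = np.sqrt((x - arc_c[0]) ** 2 + (y - arc_c[1]) ** 2)
    in_tube = (np.abs(rad - arc_r) < tube_w) & (np.abs(z) < tube_w)
    tract = in_tube & (labels == TISSUE)
    if np.any(tract):
        phi = np.arctan2(y[tract] - arc_c[1], x[tract] - arc_c[0])
        t = np.stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)], axis=-1)
        l1, l2, _ = TRACT_EIGENVALUES
        outer = t[:, :, None] * t[:, None, :]
        tensors[tract] = l2 * eye + (l1 - l2) * outer

    params = dict(tissue_params or DEFAULT_TISSUE_PARAMS)

    # smooth symmetric PD texture (the only seeded component)
    rng = np.random.default_rng(seed)
    tex = gaussian_filter(rng.standard_normal(grid_shape), sigma=4.0)
    tex = 0.5 * (tex + tex[::-1])  # keep left-right symmetry
    tex /= max(np.abs(tex).max(), 1e-12)
    pd = np.zeros(grid_shape)
    for lab, pars in params.items():
        pd[labels == lab] = pars["pd"]
    pd[labels == TISSUE] *= 1.0 + 0.05 * tex[labels == TISSUE]

    return HeadPhantom(
        labels=labels,
        chi=chi.astype(float),
        tensors=tensors,
        voxel_size=voxel_size,
        tissue_params=params,
        pd_map=pd,
    )


# ---------------------------------------------------------------------------
# diffusion signal forward model
# ---------------------------------------------------------------------------

def synthesize_dwi_signal(
    phantom: HeadPhantom,
    bval: float,
    direction,
    te: float = 109.0,
    tr: float | None = None,
) -> np.ndarray:
    """Tensor forward model: S = S0 * exp(-b g^T D g) per voxel.

    S0 comes from PD and T2 at the echo time ``te`` (ms); if ``tr`` is given
    a (1 - exp(-TR/T1)) saturation factor is included.  ``bval`` in s/mm^2,
    ``direction`` a unit 3-vector (ignored when b = 0).
    """
    direction = np.asarray(direction, dtype=float)
    if bval < 0:
        raise ValueError("bval must be >= 0")
    if bval > 0 and abs(np.linalg.norm(direction) - 1.0) > 1e-6:
        raise ValueError("gradient direction must be a unit vector")
    s0 = phantom.param_map("pd") * np.exp(-te / np.maximum(phantom.param_map("t2"), 1e-9))
    if tr is not None:
        s0 = s0 * (1.0 - np.exp(-tr / np.maximum(phantom.param_map("t1"), 1e-9)))
    if bval == 0:
        return s0
    quad = np.einsum("...ij,i,j->...", phantom.tensors, direction, direction)
    return s0 * np.exp(-bval * quad)


# ---------------------------------------------------------------------------
# real even-order spherical harmonics
# ---------------------------------------------------------------------------

def n_sh_coeffs(order: int) -> int:
    """Number of coefficients of the real even-only basis up to ``order``."""
    return (order + 1) * (order + 2) // 2


def real_sh_basis(order: int, directions) -> np.ndarray:
    """Design matrix of the real, even-degree spherical-harmonic basis.

    Rows are directions, columns the (l, m) pairs with even l <= order and
    -l <= m <= l, using the standard real combination of +/-m harmonics.
    """
    if order % 2 != 0 or order < 0:
        raise ValueError("SH order must be even and non-negative")
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(d, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("directions must be unit vectors")
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(d[:, 1], d[:, 0])              # azimuth
    cols = []
    for ell in range(0, order + 1, 2):
        for m in range(-ell, ell + 1):
            ylm = special.sph_harm_y(ell, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * ylm.imag)
            elif m == 0:
                cols.append(ylm.real)
            else:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * ylm.real)
    return np.stack(cols, axis=1)


@dataclass
class SHField:
    """Per-voxel real even-order SH coefficients for one b shell."""

    coeffs: np.ndarray  # (*grid, ncoef)
    order: int
    bval: float
    residual_rms: float = 0.0

    @property
    def grid_shape(self):
        return self.coeffs.shape[:-1]


def fit_spherical_harmonics(signals, directions, order: int = 8, bval: float = 1000.0) -> SHField:
    """Voxel-wise least-squares SH fit of per-direction signal images.

    ``signals``: sequence (or 4-D array, last axis = direction) of 3-D images.
    Requires at least ``(order+1)(order+2)/2`` distinct directions.  Fitted
    signals are reported as-is (negative lobes are not clipped).
    """
    sig = np.stack(list(signals), axis=-1)
    ncoef = n_sh_coeffs(order)
    ndir = sig.shape[-1]
    if ndir < ncoef:
        raise ValueError(
            f"underdetermined SH fit: order {order} needs >= {ncoef} "
            f"directions, got {ndir}"
        )
    basis = real_sh_basis(order, directions)
    if basis.shape[0] != ndir:
        raise ValueError("number of signal images must match directions")
    pinv = np.linalg.pinv(basis)
    coeffs = sig @ pinv.T
    resid = sig - coeffs @ basis.T
    rms = float(np.sqrt(np.mean(resid**2)))
    return SHField(coeffs=coeffs, order=order, bval=bval, residual_rms=rms)


def evaluate_sh(field: SHField, direction) -> np.ndarray:
    """Evaluate the fitted SH expansion at one unit direction."""
    row = real_sh_basis(field.order, np.asarray(direction)[None, :])[0]
    return field.coeffs @ row


def uniform_directions(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (Fibonacci sphere); deterministic."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
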