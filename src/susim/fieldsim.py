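"""Susceptibility-induced off-resonance field and its change under motion.

The field is computed from the volume-susceptibility map with the first-order
(Fourier dipole-kernel) perturbation solution

    f(x) = gamma_bar * B0 * IFFT[ (1/3 - kz^2/|k|^2) FFT[chi] ],

with the k=0 term set to zero (the field is defined up to a constant; constant
offsets are absorbed by the shim).  z is the B0 axis.  The grid is zero-padded
by a factor of two per axis before the FFT so the long-range dipole kernel does
not wrap around.

When the head rotates about an axis non-parallel to B0 the field in the head
frame changes ("dynamic" susceptibility artefact); existing correction methods
assume it rigidly follows the head ("static").  Both behaviours are available
from :func:`recompute_field_after_motion`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import HeadPhantom, CHI_AIR

#: gyromagnetic ratio of 1H over 2*pi, Hz/T
GAMMA_BAR = 42.5774688e6


@dataclass
class FieldMap:
    """Off-resonance field in Hz on the voxel grid."""

    values: np.ndarray
    voxel_size: tuple
    b0: float = 3.0
    gamma_bar: float = GAMMA_BAR
    mask: np.ndarray | None = None  # where the field is estimated (vs extrapolated)
    shim_offset: float = 0.0  # constant (Hz) absorbed by the scanner shim

    @property
    def grid_shape(self):
        return self.values.shape

    def copy(self) -> "FieldMap":
        return FieldMap(
            values=self.values.copy(),
            voxel_size=self.voxel_size,
            b0=self.b0,
            gamma_bar=self.gamma_bar,
            mask=None if self.mask is None else self.mask.copy(),
            shim_offset=self.shim_offset,
        )


@dataclass
class RigidTransform:
    """6-DOF rigid transform: rotations in degrees, translations in mm.

    Rotations are applied in x, y, z order about ``center`` (mm, defaults to
    the grid centre when resampling).  ``apply_point`` maps object coordinates
    to scanner coordinates.
    """

    rotations: tuple = (0.0, 0.0, 0.0)
    translations: tuple = (0.0, 0.0, 0.0)
    center: tuple = (0.0, 0.0, 0.0)

    def rotation_matrix(self) -> np.ndarray:
        rx, ry, rz = np.deg2rad(self.rotations)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix in mm coordinates."""
        R = self.rotation_matrix()
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translations, dtype=float)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c - R @ c + t
        return M

    def apply_point(self, p) -> np.ndarray:
        M = self.matrix()
        p = np.asarray(p, dtype=float)
        return M[:3, :3] @ p + M[:3, 3]

    def inverse(self) -> "RigidTransform":
        M = np.linalg.inv(self.matrix())
        # recover angles from R = Rz Ry Rx
        R = M[:3, :3]
        ry = np.arcsin(-R[2, 0])
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
        inv = RigidTransform(
            rotations=tuple(np.rad2deg([rx, ry, rz])),
            translations=(0.0, 0.0, 0.0),
            center=(0.0, 0.0, 0.0),
        )
        # fix translation so matrices agree exactly
        t = M[:3, 3] - (inv.matrix()[:3, 3])
        inv.translations = tuple(t)
        return inv

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other (apply ``other`` first)."""
        M = self.matrix() @ other.matrix()
        R = M[:3, :3]
        ry = np.arcsin(np.clip(-R[2, 0], -1, 1))
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
        out = RigidTransform(rotations=tuple(np.rad2deg([rx, ry, rz])))
        out.translations = tuple(M[:3, 3] - out.matrix()[:3, 3])
        return out

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            max(abs(r) for r in self.rotations) < tol
            and max(abs(t) for t in self.translations) < tol
        )


def _grid_center_mm(shape, voxel_size):
    return np.array(
        [(n - 1) / 2.0 * dv for n, dv in zip(shape, voxel_size)], dtype=float
    )


def resample_rigid(
    volume: np.ndarray,
    transform: RigidTransform,
    voxel_size,
    order: int = 1,
    cval: float = 0.0,
    inverse: bool = False,
) -> np.ndarray:
    """Resample ``volume`` as if the imaged object moved by ``transform``.

    out(x) = in(T^-1 x) in mm coordinates (rotation about the grid centre by
    default).  With ``inverse=True`` the opposite mapping is applied.
    """
    shape = volume.shape
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    tr = transform
    if not np.any(np.asarray(tr.center)):
        tr = RigidTransform(tr.rotations, tr.translations,
                            tuple(_grid_center_mm(shape, vs)))
    M = tr.matrix()
    if not inverse:
        M = np.linalg.inv(M)
    # voxel -> mm scaling
    S = np.diag(list(vs) + [1.0])
    Mv = np.linalg.inv(S) @ M @ S
    return ndimage.affine_transform(
        volume, Mv[:3, :3], offset=Mv[:3, 3], order=order, cval=cval,
        mode="constant",
    )


def compute_susceptibility_field(
    chi: np.ndarray,
    b0: float = 3.0,
    voxel_size=3.0,
    b0_axis: int = 2,
    pad_factor: int = 2,
    gamma_bar: float = GAMMA_BAR,
) -> FieldMap:
    """First-order dipole-kernel solution of the susceptibility field (Hz).

    ``chi`` is the dimensionless volume susceptibility on the full grid (air
    included).  The map is shifted so its exterior value is zero before
    zero-padding (the padding then continues the surrounding air), and the
    k=0 kernel value is zero so the returned field is mean-free.
    """
    chi = np.asarray(chi, dtype=float)
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    ref = chi[0, 0, 0]  # exterior medium
    work = chi - ref
    shape = chi.shape
    pshape = tuple(int(pad_factor * n) for n in shape)
    padded = np.zeros(pshape)
    padded[: shape[0], : shape[1], : shape[2]] = work

    ks = [np.fft.fftfreq(n, d=dv) for n, dv in zip(pshape, vs)]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij", sparse=True)
    k2 = kx**2 + ky**2 + kz**2
    kb = (kx, ky, kz)[b0_axis]
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = 1.0 / 3.0 - (kb**2) / k2
    kernel = np.where(k2 == 0, 0.0, kernel)

    f = np.fft.ifftn(kernel * np.fft.fftn(padded)).real
    f = f[: shape[0], : shape[1], : shape[2]]
    values = gamma_bar * b0 * f
    values -= values.mean()  # mean-free on the cropped grid
    return FieldMap(values=values, voxel_size=tuple(vs), b0=b0,
                    gamma_bar=gamma_bar, mask=np.ones(shape, bool))


def recompute_field_after_motion(
    phantom: HeadPhantom,
    transform: RigidTransform,
    b0: float = 3.0,
    mode: str = "dynamic",
    b0_axis: int = 2,
    static_field: FieldMap | None = None,
) -> FieldMap:
    """Field in the scanner frame after the head moves by ``transform``.

    mode="dynamic": resample chi under the transform and re-solve the dipole
    problem (the physical behaviour).  mode="static": rigidly resample the
    pre-motion field itself — the assumption made by every existing
    correction method, whose violation this package measures.
    """
    _check_inside(phantom, transform)
    if mode == "dynamic":
        chi_moved = resample_rigid(
            phantom.chi, transform, phantom.voxel_size, order=1, cval=CHI_AIR
        )
        return compute_susceptibility_field(
            chi_moved, b0=b0, voxel_size=phantom.voxel_size, b0_axis=b0_axis
        )
    elif mode == "static":
        if static_field is None:
            static_field = compute_susceptibility_field(
                phantom.chi, b0=b0, voxel_size=phantom.voxel_size, b0_axis=b0_axis
            )
        moved = resample_rigid(
            static_field.values, transform, phantom.voxel_size, order=1, cval=0.0
        )
        out = static_field.copy()
        out.values = moved
        return out
    raise ValueError(f"unknown field mode {mode!r}")


def _check_inside(phantom: HeadPhantom, transform: RigidTransform,
                  max_outside_frac: float = 0.002) -> None:
    """Reject transforms that move (part of) the head outside the grid."""
    shape = phantom.grid_shape
    vs = np.asarray(phantom.voxel_size, dtype=float)
    idx = np.argwhere(phantom.head_mask()).astype(float) * vs
    tr = transform
    if not np.any(np.asarray(tr.center)):
        tr = RigidTransform(tr.rotations, tr.translations,
                            tuple(_grid_center_mm(shape, vs)))
    M = tr.matrix()
    moved = idx @ M[:3, :3].T + M[:3, 3]
    fov = (np.asarray(shape) - 1) * vs
    outside = np.any(moved < -vs, axis=1) | np.any(moved > fov + vs, axis=1)
    if outside.mean() > max_outside_frac:
        raise ValueError(
            f"transform {transform} moves {100 * outside.mean():.1f}% of the "
            "head outside the grid"
        )


def smooth_and_extrapolate_field(
    fmap: FieldMap, mask: np.ndarray | None = None, sigma: float = 5.0
) -> FieldMap:
    """Gaussian-smooth the field inside ``mask`` and fill the outside smoothly.

    ``sigma`` is in mm (sigma=0 leaves interior values untouched).  Outside
    the mask, values are extended by nearest-interior lookup and then smoothed,
    which keeps the field continuous at the mask boundary; the result has no
    NaNs anywhere.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    mask = fmap.mask if mask is None else mask
    if mask is None or not np.any(mask):
        raise ValueError("mask is empty")
    vs = np.broadcast_to(np.asarray(fmap.voxel_size, dtype=float), (3,))
    values = np.asarray(fmap.values, dtype=float)

    if sigma > 0:
        sig_vox = sigma / vs
        num = ndimage.gaussian_filter(np.where(mask, values, 0.0), sig_vox)
        den = ndimage.gaussian_filter(mask.astype(float), sig_vox)
        inside = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
    else:
        inside = values

    # nearest-interior fill, then smooth only the exterior for continuity
    _, idx = ndimage.distance_transform_edt(
        ~mask, sampling=vs, return_indices=True
    )
    filled = inside[tuple(idx)]
    if sigma > 0:
        sm = ndimage.gaussian_filter(filled, sigma / vs)
        filled = np.where(mask, inside, sm)
    out = fmap.copy()
    out.values = filled
    out.mask = mask.copy()
    return out
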