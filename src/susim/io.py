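"""NIfTI / bval-bvec / JSON serialisation of phantoms, fields and datasets."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import HeadPhantom
from .fieldsim import FieldMap, RigidTransform
from .episim import DWIDataset


def _affine(voxel_size) -> np.ndarray:
    vs = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    aff = np.diag(list(vs) + [1.0])
    return aff


def save_nifti(data: np.ndarray, voxel_size, path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size))
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), tuple(img.header.get_zooms()[:3])


def save_phantom(phantom: HeadPhantom, outdir) -> None:
    """labels + chi + 6-component tensor NIfTIs, JSON sidecar of tissue params."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vs = phantom.voxel_size
    save_nifti(phantom.labels.astype(np.float32), vs, outdir / "labels.nii.gz")
    save_nifti(phantom.chi * 1e6, vs, outdir / "chi_ppm.nii.gz")
    t = phantom.tensors
    six = np.stack(
        [t[..., 0, 0], t[..., 1, 1], t[..., 2, 2],
         t[..., 0, 1], t[..., 0, 2], t[..., 1, 2]], axis=-1
    )
    save_nifti(six, vs, outdir / "tensors.nii.gz")
    if phantom.pd_map is not None:
        save_nifti(phantom.pd_map, vs, outdir / "pd.nii.gz")
    sidecar = {
        "voxel_size_mm": list(vs),
        "tissue_params": {str(k): v for k, v in phantom.tissue_params.items()},
    }
    (outdir / "phantom.json").write_text(json.dumps(sidecar, indent=2))


def save_fieldmap(fmap: FieldMap, path) -> None:
    save_nifti(fmap.values, fmap.voxel_size, path)


def write_bvals_bvecs(bvals, bvecs, bval_path, bvec_path) -> None:
    """Two-file plain-text convention: bvals on one row; bvecs one row per axis."""
    np.savetxt(bval_path, np.asarray(bvals)[None, :], fmt="%g")
    np.savetxt(bvec_path, np.asarray(bvecs).T, fmt="%.8f")


def read_bvals_bvecs(bval_path, bvec_path):
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvals, bvecs


def save_dataset(dataset: DWIDataset, outdir, stem: str = "dwi") -> None:
    """4-D NIfTI + bval/bvec + JSON sidecar (PE directions, echo spacing) +
    per-volume ground-truth PE displacement as a 4-D NIfTI (voxels)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vs = dataset.protocol.voxel_size
    save_nifti(dataset.volumes, vs, outdir / f"{stem}.nii.gz")
    write_bvals_bvecs(
        dataset.bvals, dataset.bvecs, outdir / f"{stem}.bval", outdir / f"{stem}.bvec"
    )
    sidecar = {
        "PhaseEncodingDirections": list(dataset.pe_axes),
        "EchoSpacingMs": dataset.protocol.echo_spacing,
        "EchoTimeMs": dataset.protocol.te,
        "BandwidthPerPixelPE": dataset.protocol.bw_per_pixel,
        "NoiseSigmaKspace": dataset.noise_sigma,
    }
    (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    if dataset.gt_displacements is not None:
        disp = np.stack([d.shift for d in dataset.gt_displacements], axis=-1)
        save_nifti(disp, vs, outdir / f"{stem}_gt_displacement.nii.gz")


def save_transform(transform: RigidTransform, path) -> None:
    payload = {
        "rotations_deg": list(transform.rotations),
        "translations_mm": list(transform.translations),
        "center_mm": list(transform.center),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_transform(path) -> RigidTransform:
    d = json.loads(Path(path).read_text())
    return RigidTransform(
        tuple(d["rotations_deg"]), tuple(d["translations_mm"]),
        tuple(d.get("center_mm", (0.0, 0.0, 0.0))),
    )
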