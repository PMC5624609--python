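"""Quantitative correction-quality metrics.

Displacement-field error, intensity error, diffusion-tensor metric errors
(FA, MD, principal eigenvector V1), the AP-vs-LR surrogate, and the
static-vs-dynamic FA comparison used to quantify the susceptibility-motion
interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .episim import DWIDataset, DisplacementField


@dataclass
class TensorFit:
    """Voxel-wise diffusion tensor and derived scalars."""

    tensors: np.ndarray  # (*grid, 3, 3)
    fa: np.ndarray
    md: np.ndarray  # mm^2/s
    v1: np.ndarray  # (*grid, 3), unit
    valid: np.ndarray  # voxels with a usable fit
    n_excluded: int = 0


def _design_matrix(bvals, bvecs):
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    cols = np.stack(
        [
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )
    X = np.concatenate([-b[:, None] * cols, np.ones((len(b), 1))], axis=1)
    return X


def fit_dti(
    dataset_or_volumes,
    bvals=None,
    bvecs=None,
    mask: np.ndarray | None = None,
) -> TensorFit:
    """Log-linear least-squares tensor fit per voxel.

    Accepts a DWIDataset or (volumes, bvals, bvecs).  Needs at least six
    non-collinear directions plus a b=0.  Voxels with any non-positive signal
    are excluded (reported in ``n_excluded``).
    """
    if isinstance(dataset_or_volumes, DWIDataset):
        ds = dataset_or_volumes
        volumes, bvals, bvecs = ds.volumes, ds.bvals, ds.bvecs
    else:
        volumes = dataset_or_volumes
    bvals = np.asarray(bvals, dtype=float)
    if np.sum(bvals > 0) < 6 or np.sum(bvals == 0) < 1:
        raise ValueError("tensor fit needs >= 6 DWIs and >= 1 b=0 volume")
    grid = volumes.shape[:3]
    if mask is None:
        mask = np.ones(grid, bool)
    X = _design_matrix(bvals, bvecs)
    pinv = np.linalg.pinv(X)

    sig = volumes[mask]  # (nvox, nvol)
    ok = np.all(sig > 0, axis=1)
    n_excluded = int(np.sum(~ok))
    logsig = np.log(np.where(sig > 0, sig, 1.0))
    beta = logsig @ pinv.T  # (nvox, 7)

    D = np.zeros(sig.shape[:1] + (3, 3))
    dxx, dyy, dzz, dxy, dxz, dyz = (beta[:, i] for i in range(6))
    D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = dxx, dyy, dzz
    D[:, 0, 1] = D[:, 1, 0] = dxy
    D[:, 0, 2] = D[:, 2, 0] = dxz
    D[:, 1, 2] = D[:, 2, 1] = dyz

    evals, evecs = np.linalg.eigh(D)
    md = evals.mean(axis=1)
    num = np.sum((evals - md[:, None]) ** 2, axis=1)
    den = np.sum(evals**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / np.where(den > 0, den, 1.0))
    fa = np.clip(np.where(den > 0, fa, 0.0), 0.0, 1.0)
    v1 = evecs[:, :, -1]  # eigenvector of the largest eigenvalue

    out = TensorFit(
        tensors=np.zeros(grid + (3, 3)),
        fa=np.zeros(grid),
        md=np.zeros(grid),
        v1=np.zeros(grid + (3,)),
        valid=np.zeros(grid, bool),
        n_excluded=n_excluded,
    )
    out.tensors[mask] = D
    out.fa[mask] = fa
    out.md[mask] = md
    out.v1[mask] = v1
    valid = np.zeros(grid, bool)
    valid[mask] = ok
    out.valid = valid
    return out


def displacement_error(
    est: DisplacementField,
    gt: DisplacementField,
    mask: np.ndarray,
    erode: bool = False,
) -> dict:
    """Mean absolute displacement error over the (optionally eroded) mask,
    reported in both voxels and mm."""
    if est.shift.shape != gt.shift.shape:
        raise ValueError("displacement fields on different grids")
    if erode:
        from .correct import erode_mask

        mask = erode_mask(mask, 1)
    if not np.any(mask):
        raise ValueError("empty mask")
    err = np.abs(est.shift - gt.shift)[mask]
    vox = float(err.mean())
    mm = vox * float(np.asarray(gt.voxel_size)[gt.axis])
    return {"mae_voxels": vox, "mae_mm": mm, "n_voxels": int(mask.sum())}


def intensity_error(
    corrected: DWIDataset,
    ground_truth: DWIDataset,
    mask: np.ndarray,
) -> dict:
    """Mean absolute intensity error over the brain mask, split into b=0 and
    DWI volumes.  Volumes must already be in the ground-truth space."""
    if corrected.volumes.shape[:3] != ground_truth.volumes.shape[:3]:
        raise ValueError("corrected and ground-truth grids differ")
    out = {}
    for name, sel in (("b0", corrected.bvals == 0), ("dwi", corrected.bvals > 0)):
        if not np.any(sel):
            continue
        idx = np.flatnonzero(sel)
        # match ground-truth volumes by (bval, bvec)
        errs = []
        for i in idx:
            j = _match_volume(ground_truth, corrected.bvals[i], corrected.bvecs[i])
            diff = corrected.volumes[..., i] - ground_truth.volumes[..., j]
            errs.append(np.abs(diff[mask]).mean())
        out[name] = float(np.mean(errs))
    return out


def _match_volume(ds: DWIDataset, bval, bvec) -> int:
    cand = np.flatnonzero(ds.bvals == bval)
    if len(cand) == 0:
        raise ValueError(f"no ground-truth volume with b={bval}")
    if bval == 0:
        return int(cand[0])
    dots = np.abs(ds.bvecs[cand] @ np.asarray(bvec))
    return int(cand[np.argmax(dots)])


def angular_error_v1(
    fit: TensorFit,
    gt_fit: TensorFit,
    fa_threshold: float = 0.2,
    mask: np.ndarray | None = None,
) -> dict:
    """Mean angle (degrees) between principal eigenvectors, antipodally
    invariant, over voxels with ground-truth FA above ``fa_threshold``."""
    sel = gt_fit.fa > fa_threshold
    if mask is not None:
        sel &= mask
    sel &= fit.valid & gt_fit.valid
    if not np.any(sel):
        raise ValueError(f"no voxels with ground-truth FA > {fa_threshold}")
    dots = np.abs(np.sum(fit.v1[sel] * gt_fit.v1[sel], axis=-1))
    ang = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
    return {"mean_deg": float(ang.mean()), "n_voxels": int(sel.sum())}


def dti_errors(
    fit: TensorFit, gt_fit: TensorFit, mask: np.ndarray, fa_threshold: float = 0.2
) -> dict:
    """FA / MD / V1 mean absolute errors against a ground-truth fit."""
    m = mask & fit.valid & gt_fit.valid
    fa_err = float(np.abs(fit.fa - gt_fit.fa)[m].mean())
    md_err = float(np.abs(fit.md - gt_fit.md)[m].mean())
    v1 = angular_error_v1(fit, gt_fit, fa_threshold, mask)["mean_deg"]
    return {"fa_mae": fa_err, "md_mae": md_err, "v1_mean_deg": v1}


def surrogate_ap_lr(
    corrected_ap: DWIDataset, corrected_lr: DWIDataset, mask: np.ndarray
) -> float:
    """Whole-brain mean |AP - LR| over corrected b=0 volumes: the surrogate
    quality metric usable on real data (no ground truth required).

    Note: the surrogate preserves method *ordering* but not the contrast
    between methods — intensity differences depend on where displacement
    errors fall, not only on their size.
    """
    if corrected_ap.volumes.shape[:3] != corrected_lr.volumes.shape[:3]:
        raise ValueError("datasets on different grids")
    a = corrected_ap.volumes[..., corrected_ap.b0_indices()].mean(axis=-1)
    b = corrected_lr.volumes[..., corrected_lr.b0_indices()].mean(axis=-1)
    return float(np.abs(a - b)[mask].mean())


def static_dynamic_fa_comparison(
    fa_err_static: np.ndarray,
    fa_err_dynamic: np.ndarray,
    mask: np.ndarray | None = None,
    bins: int = 81,
    hist_range: tuple = (-0.2, 0.2),
) -> dict:
    """Voxel-wise |dFA_static| - |dFA_dynamic|: a negative mean / heavy
    negative tail means the dynamic (motion-altered) field produced larger
    errors than the static control."""
    if fa_err_static.shape != fa_err_dynamic.shape:
        raise ValueError("error maps on different grids")
    diff = np.abs(fa_err_static) - np.abs(fa_err_dynamic)
    if mask is not None:
        diff = diff[mask]
    diff = np.ravel(diff)
    hist, edges = np.histogram(diff, bins=bins, range=hist_range)
    return {
        "diff": diff,
        "hist": hist,
        "bin_edges": edges,
        "mean": float(diff.mean()),
        "skew": float(stats.skew(diff)) if diff.size > 2 else 0.0,
        "frac_negative": float(np.mean(diff < 0)),
    }


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-method, per-noise-level error summary (rows of the report tables)."""

    rows: list = dc_field(default_factory=list)

    def add(self, method: str, snr, realisation: int, **metrics):
        row = {"method": method, "snr": snr, "realisation": realisation}
        row.update(metrics)
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def summary(self) -> pd.DataFrame:
        """Mean (and SD over realisations where >= 2) per method and SNR."""
        df = self.to_frame()
        vals = [c for c in df.columns if c not in ("method", "snr", "realisation")]
        g = df.groupby(["snr", "method"], dropna=False, sort=False)[vals]
        mean = g.mean()
        sd = g.std(ddof=1)
        out = mean.copy()
        for c in vals:
            out[c + "_sd"] = sd[c]
        return out.reset_index()

    def to_csv(self, path):
        self.summary().to_csv(path, index=False)

    def to_json(self, path):
        self.summary().to_json(path, orient="records", indent=2)
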