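"""End-to-end experiments: static method comparison, AP-LR surrogate, and the
susceptibility-motion interaction, at desk scale.

Every experiment is a pure function of (config, seeds): the phantom, protocol,
motion trace and noise streams are all derived deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phantom import HeadPhantom, make_head_phantom
from .fieldsim import FieldMap, RigidTransform, resample_rigid
from .episim import (
    DWIDataset,
    MotionTrace,
    Protocol,
    calibrate_noise_sigma,
    desk_protocol,
    field_to_displacement,
    full_scale_protocol,
    prepare_susceptibility_field,
    simulate_dataset,
    simulate_gre_pair,
    simulate_structural,
    unwarp_volume,
)
from .correct import (
    JACOBIAN_CLAMP,
    estimate_fieldmap_gre,
    fmb_correct,
    mpb_correct,
    mpb_estimate_field,
    rb_correct,
)
from .evaluate import (
    MetricReport,
    displacement_error,
    dti_errors,
    fit_dti,
    intensity_error,
    static_dynamic_fa_comparison,
    surrogate_ap_lr,
)

logger = logging.getLogger(__name__)

ALL_METHODS = ("RB", "FMB", "MPB", "MPB/F")


@dataclass
class ExperimentConfig:
    """Shared configuration of the three experiments."""

    phantom_seed: int = 1
    seed: int = 0
    preset: str = "desk"  # desk | full
    snr_levels: tuple = (np.inf, 40.0, 20.0)
    realisations: int = 2
    methods: tuple = ALL_METHODS
    motion_scales: tuple = (1.0, 3.0)
    b0_strength: float = 3.0
    output_dir: str | None = None

    def __post_init__(self):
        if self.realisations < 1:
            raise ValueError("realisations must be >= 1")
        bad = set(self.methods) - set(ALL_METHODS)
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")

    def protocol(self, pe_axis: str = "AP") -> Protocol:
        if self.preset == "desk":
            return desk_protocol(pe_axis)
        if self.preset == "full":
            return full_scale_protocol(pe_axis)
        raise ValueError(f"unknown preset {self.preset!r}")

    def phantom(self) -> HeadPhantom:
        prot = self.protocol()
        return make_head_phantom(
            grid_shape=prot.grid_shape, voxel_size=prot.voxel_size,
            seed=self.phantom_seed,
        )


def generate_motion_trace(n_volumes: int, scale: float = 1.0, seed: int = 0) -> MotionTrace:
    """Motion trace with small baseline jitter (0.2 deg SD on x/y rotations)
    and sparse larger spikes (2-5 deg), scaled by ``scale``.  z rotations and
    translations are zero; the first volume is the motionless reference."""
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    rng = np.random.default_rng(seed)
    rx = rng.normal(0.0, 0.2, n_volumes)
    ry = rng.normal(0.0, 0.2, n_volumes)
    spikes = rng.random(n_volumes) < 0.12
    mags = rng.uniform(2.0, 5.0, n_volumes) * rng.choice([-1.0, 1.0], n_volumes)
    which = rng.random(n_volumes) < 0.5
    rx = np.where(spikes & which, mags, rx)
    ry = np.where(spikes & ~which, mags, ry)
    rx[0] = ry[0] = 0.0
    transforms = [
        RigidTransform(rotations=(scale * rx[i], scale * ry[i], 0.0))
        for i in range(n_volumes)
    ]
    return MotionTrace(transforms=transforms, scale=scale)


# ---------------------------------------------------------------------------
# shared simulation plumbing
# ---------------------------------------------------------------------------

def _simulation_inputs(config: ExperimentConfig):
    phantom = config.phantom()
    protocol = config.protocol("AP")
    static_field = prepare_susceptibility_field(phantom, b0=config.b0_strength)
    structural = simulate_structural(phantom)
    return phantom, protocol, static_field, structural


def _correct_all_methods(
    config, phantom, protocol, static_field, structural, dual, gre, methods
):
    """Run the requested correction methods on one dual-PE dataset.

    Returns {method: (CorrectionResult-corrected AP-frame dataset, est_disp)}.
    """
    out = {}
    n_half = protocol.n_volumes
    ap = dual.subset(np.arange(n_half))
    mask = phantom.brain_mask()

    if "RB" in methods:
        out["RB"] = rb_correct(ap, structural)
    if "FMB" in methods:
        fmap = estimate_fieldmap_gre(gre, voxel_size=phantom.voxel_size)
        out["FMB"] = fmb_correct(ap, fmap)
    if "MPB" in methods or "MPB/F" in methods:
        b0_idx = dual.b0_indices()
        up_b0 = [i for i in b0_idx if i < n_half]
        down_b0 = [i for i in b0_idx if i >= n_half]
        b0_up = dual.volumes[..., up_b0].mean(axis=-1)
        b0_down = dual.volumes[..., down_b0].mean(axis=-1)
        mpb_field, diag = mpb_estimate_field(b0_up, b0_down, protocol)
        if "MPB" in methods:
            out["MPB"] = mpb_correct(ap, mpb_field, combine="none")
        if "MPB/F" in methods:
            out["MPB/F"] = mpb_correct(dual, mpb_field, combine="pair_average")
    return out


def run_static_comparison(config: ExperimentConfig) -> MetricReport:
    """No-motion comparison of RB / FMB / MPB / MPB/F.

    For each SNR level and realisation: simulate a dual-PE dataset, GRE
    field-mapping pair and structural; correct with every method; report
    displacement MAE (whole-brain and eroded), intensity MAE (b=0 / DWI) and
    FA/MD/V1 errors against the artefact-free ground truth."""
    phantom, protocol, static_field, structural = _simulation_inputs(config)
    mask = phantom.brain_mask()
    gt = simulate_dataset(
        phantom, protocol, field_mode="none", seed=config.seed,
        static_field=static_field, b0_strength=config.b0_strength,
    )
    gt_fit = fit_dti(gt, mask=mask)
    gt_disp = field_to_displacement(static_field, protocol)
    report = MetricReport()

    for i_snr, snr in enumerate(config.snr_levels):
        n_real = 1 if np.isinf(snr) else config.realisations
        sigma = (
            0.0 if np.isinf(snr) else calibrate_noise_sigma(phantom, protocol, snr)
        )
        for r in range(n_real):
            seed_r = config.seed + 1000 * (i_snr + 1) + r
            dual = simulate_dataset(
                phantom, protocol, field_mode="static", dual_pe=True,
                seed=seed_r, noise_sigma=sigma, static_field=static_field,
                b0_strength=config.b0_strength,
            )
            gre = simulate_gre_pair(
                phantom, static_field, noise_sigma=sigma, seed=seed_r + 7
            )
            # noisy ground-truth baseline (the "GT + noise" rows)
            gtn = simulate_dataset(
                phantom, protocol, field_mode="none", seed=seed_r + 13,
                noise_sigma=sigma, b0_strength=config.b0_strength,
            )
            ierr = intensity_error(gtn, gt, mask)
            derr = dti_errors(fit_dti(gtn, mask=mask), gt_fit, mask)
            report.add(
                "GT+noise", snr, r,
                disp_mae_vox=0.0, disp_mae_vox_eroded=0.0,
                b0_mae=ierr["b0"], dwi_mae=ierr["dwi"], **derr,
            )

            results = _correct_all_methods(
                config, phantom, protocol, static_field, structural,
                dual, gre, config.methods,
            )
            for method, res in results.items():
                de = displacement_error(res.displacement, gt_disp, mask)
                de_er = displacement_error(res.displacement, gt_disp, mask, erode=True)
                ierr = intensity_error(res.corrected, gt, mask)
                fit = fit_dti(res.corrected, mask=mask)
                derr = dti_errors(fit, gt_fit, mask)
                report.add(
                    method, snr, r,
                    disp_mae_vox=de["mae_voxels"],
                    disp_mae_vox_eroded=de_er["mae_voxels"],
                    b0_mae=ierr["b0"], dwi_mae=ierr["dwi"], **derr,
                )
    return report


def run_surrogate_experiment(config: ExperimentConfig) -> MetricReport:
    """AP-vs-LR surrogate: correct AP/PA and LR/RL acquisitions separately and
    report the whole-brain mean |AP - LR| of corrected b=0 volumes."""
    phantom, protocol, static_field, structural = _simulation_inputs(config)
    mask = phantom.brain_mask()
    prot_lr = config.protocol("LR")
    report = MetricReport()

    for i_snr, snr in enumerate(config.snr_levels):
        n_real = 1 if np.isinf(snr) else config.realisations
        sigma = (
            0.0 if np.isinf(snr) else calibrate_noise_sigma(phantom, protocol, snr)
        )
        for r in range(n_real):
            seed_r = config.seed + 5000 * (i_snr + 1) + r
            corrected = {}
            for prot, tag, dseed in ((protocol, "ap", seed_r), (prot_lr, "lr", seed_r + 101)):
                dual = simulate_dataset(
                    phantom, prot, field_mode="static", dual_pe=True,
                    seed=dseed, noise_sigma=sigma, static_field=static_field,
                    b0_strength=config.b0_strength,
                )
                gre = simulate_gre_pair(
                    phantom, static_field, noise_sigma=sigma, seed=dseed + 7
                )
                corrected[tag] = _correct_all_methods(
                    config, phantom, prot, static_field, structural,
                    dual, gre, config.methods,
                )
            for method in corrected["ap"]:
                val = surrogate_ap_lr(
                    corrected["ap"][method].corrected,
                    corrected["lr"][method].corrected,
                    mask,
                )
                report.add(method, snr, r, surrogate_mae=val)
    return report


# ---------------------------------------------------------------------------
# susceptibility-motion interaction
# ---------------------------------------------------------------------------

def _correct_with_ground_truth(
    dataset: DWIDataset, static_field: FieldMap, phantom: HeadPhantom
):
    """State-of-the-art correction with *known* inputs: per volume, unwarp
    with the static field rigidly moved by the known motion, then undo the
    motion.  Residual errors isolate the dynamic field (plus interpolation)."""
    corrected = np.empty_like(dataset.volumes)
    eff_bvecs = dataset.bvecs.copy()
    for v in range(dataset.n_volumes):
        tr = dataset.motion[v]
        prot_v = dataset.protocol.with_pe_axis(dataset.pe_axes[v])
        fv = static_field.values if tr.is_identity() else resample_rigid(
            static_field.values, tr, phantom.voxel_size, order=1
        )
        disp = field_to_displacement(
            FieldMap(fv, static_field.voxel_size, static_field.b0), prot_v
        )
        unwarped = unwarp_volume(
            dataset.volumes[..., v], disp, True, JACOBIAN_CLAMP
        )
        if tr.is_identity():
            corrected[..., v] = unwarped
        else:
            corrected[..., v] = resample_rigid(
                unwarped, tr, phantom.voxel_size, order=1, inverse=True
            )
        if dataset.bvals[v] > 0:
            # gradient direction as experienced by the moved head
            g = tr.rotation_matrix().T @ dataset.bvecs[v]
            eff_bvecs[v] = g / np.linalg.norm(g)
    return DWIDataset(
        volumes=corrected, bvals=dataset.bvals.copy(), bvecs=eff_bvecs,
        pe_axes=list(dataset.pe_axes), protocol=dataset.protocol,
        noise_sigma=dataset.noise_sigma,
    )


def run_dynamic_experiment(config: ExperimentConfig) -> dict:
    """Four-arm interaction experiment: {static, dynamic} fields x motion
    scales, noise-free, corrected with ground-truth static fields + motion,
    in one-PE and two-PE variants.  Returns FA-error summaries and the
    |dFA_static| - |dFA_dynamic| histograms."""
    phantom, protocol, static_field, structural = _simulation_inputs(config)
    mask = phantom.brain_mask()
    gt = simulate_dataset(
        phantom, protocol, field_mode="none", seed=config.seed,
        b0_strength=config.b0_strength,
    )
    gt_fit = fit_dti(gt, mask=mask)
    n_half = protocol.n_volumes

    out = {"arms": {}, "histograms": {}, "config": config}
    fa_err = {}
    for scale in config.motion_scales:
        motion = generate_motion_trace(2 * n_half, scale=scale, seed=config.seed + 17)
        for mode in ("static", "dynamic"):
            dual = simulate_dataset(
                phantom, protocol, motion=motion, field_mode=mode,
                dual_pe=True, seed=config.seed, noise_sigma=0.0,
                static_field=static_field, b0_strength=config.b0_strength,
            )
            corrected = _correct_with_ground_truth(dual, static_field, phantom)
            ap = corrected.subset(np.arange(n_half))
            # one-PE correction: AP volumes only
            fit1 = fit_dti(ap, mask=mask)
            # two-PE correction: average matched AP/PA pairs
            vols2 = 0.5 * (
                corrected.volumes[..., :n_half] + corrected.volumes[..., n_half:]
            )
            two = DWIDataset(
                volumes=vols2, bvals=corrected.bvals[:n_half],
                bvecs=0.5 * (corrected.bvecs[:n_half] + corrected.bvecs[n_half:]),
                pe_axes=list(corrected.pe_axes[:n_half]), protocol=protocol,
            )
            # renormalise averaged gradient directions
            norms = np.linalg.norm(two.bvecs, axis=1, keepdims=True)
            two.bvecs = two.bvecs / np.where(norms > 0, norms, 1.0)
            fit2 = fit_dti(two, mask=mask)
            for tag, fit in (("one_pe", fit1), ("two_pe", fit2)):
                err = np.abs(fit.fa - gt_fit.fa)
                key = (mode, scale, tag)
                fa_err[key] = err
                out["arms"][key] = {
                    "fa_mae": float(err[mask].mean()),
                    "md_mae": float(np.abs(fit.md - gt_fit.md)[mask].mean()),
                }
    for scale in config.motion_scales:
        for tag in ("one_pe", "two_pe"):
            comp = static_dynamic_fa_comparison(
                fa_err[("static", scale, tag)], fa_err[("dynamic", scale, tag)],
                mask=mask,
            )
            comp.pop("diff")
            out["histograms"][(scale, tag)] = comp
    return out
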