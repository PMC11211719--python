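"""End-to-end study pipeline on synthetic cohorts.

`run_subject` walks one simulated participant through every stage:
task schedule -> phantom -> BOLD run + physiological traces -> aqueduct
detection -> PAG shell -> cylindrical coordinates/ranks -> first-level
GLM -> TR-level IBI/RR and epoch change scores.  `run_study` repeats
this over a cohort (varying the phantom axis obliquity and physiological
modulation across subjects), pools the voxelwise maps in cylindrical
parameter space, and fits the group-level models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry, glm, group, masks, physio, simulate, task
from .phantom import Phantom, PhantomConfig, generate_phantom


@dataclass
class SubjectResult:
    subject: int
    schedule: task.TaskSchedule
    phantom: Phantom
    coords: geometry.PagVoxelCoordinates
    betas: dict[int, np.ndarray]  # condition -> per-voxel betas on coords
    truth: dict[int, np.ndarray]
    rank_rows: pd.DataFrame
    vif: dict[str, float]
    epoch_ibi: physio.EpochChange | None
    epoch_rr: physio.EpochChange | None
    cardiac_quality: str
    resp_quality: str
    dice_aqueduct: float


@dataclass
class StudyResult:
    subjects: list[SubjectResult]
    rank_table: pd.DataFrame
    pooled: dict[int, masks.PooledMaps]  # condition -> per-subject flat maps
    mixed_model: group.MixedModelResult | None
    condition_correlation: group.CorrelationResult
    group_z: dict[int, np.ndarray]
    physio_frame: pd.DataFrame
    ibi_beta_r: np.ndarray | None = None
    rr_beta_r: np.ndarray | None = None


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    return 2.0 * inter / max(a.sum() + b.sum(), 1)


def run_subject(
    subject: int,
    seed: int,
    order: str = "1-3-3-1",
    phantom_config: PhantomConfig | None = None,
    noise_sd: float = 1.0,
    ibi_effects: dict[str, float] | None = None,
    rr_effects: dict[str, float] | None = None,
    with_physio: bool = True,
) -> SubjectResult:
    """Simulate and analyze one participant."""
    seeds = simulate.spawn_seeds(seed, 4)
    schedule = task.generate_task_schedule(order=order, seed=seeds[0])
    phantom = generate_phantom(phantom_config)

    run, _events, motion = simulate.generate_bold_run(
        schedule, phantom, noise_sd=noise_sd, seed=seeds[1]
    )

    box = masks.central_search_box(run.data.shape[:3])
    aqueduct = masks.detect_aqueduct(run.data, search_region=box)
    shell = masks.build_pag_shell(aqueduct, phantom.gm, phantom.affine)

    csf_comps = glm.compute_acompcor(run.data, phantom.csf > 0.5)
    # the WM compartment covers most of the phantom; a strided subsample
    # stands in for the usual eroded-WM mask and keeps the PCA cheap
    wm_mask = phantom.wm > 0.5
    stride = np.zeros_like(wm_mask)
    stride[::2, ::2, ::2] = True
    wm_comps = glm.compute_acompcor(run.data, wm_mask & stride)
    design = glm.build_design_matrix(
        schedule, motion, csf_comps, wm_comps, run.tr_s, run.n_volumes
    )
    vif = glm.compute_vif(design)
    fit = glm.fit_glm(run.data, design, shell.mask)

    # PAG analyses run at 0.5 mm: smooth betas to 1 mm FWHM, resample the
    # shell mask alongside, and parameterize the fine-grid shell
    fine_shell_f, fine_affine = glm.smooth_and_resample(
        shell.mask.astype(float), phantom.affine, fwhm_mm=0.0
    )
    fine_shell = fine_shell_f > 0.5
    coords = geometry.parameterize_shell(fine_shell, fine_affine)
    idx = tuple(coords.ijk.T)
    betas = {}
    truth = {}
    for c in (1, 3):
        fine_beta, _ = glm.smooth_and_resample(
            fit.beta[f"{c}back"], phantom.affine, fwhm_mm=1.0
        )
        betas[c] = fine_beta[idx]
        fine_truth, _ = glm.smooth_and_resample(
            phantom.truth_effect[c], phantom.affine, fwhm_mm=1.0
        )
        truth[c] = fine_truth[idx]
    rank_rows = group.bin_rank_table(betas, coords, subject=subject)

    epoch_ibi = epoch_rr = None
    cq = rq = "missing"
    if with_physio:
        sim = simulate.generate_physio_traces(
            schedule, ibi_effects=ibi_effects, rr_effects=rr_effects,
            seed=seeds[2],
        )
        c_peaks = physio.detect_cardiac_peaks(sim.cardiac)
        r_peaks = physio.detect_respiratory_peaks(sim.respiratory)
        cq = physio.classify_quality(sim.cardiac)
        rq = physio.classify_quality(sim.respiratory)
        if cq == "high":
            ibi_tr = physio.series_to_tr(c_peaks, "cardiac", run.tr_s,
                                         run.n_volumes)
            epoch_ibi = physio.compute_epoch_changes(ibi_tr, schedule, run.tr_s)
        if rq == "high":
            rr_tr = physio.series_to_tr(r_peaks, "respiratory", run.tr_s,
                                        run.n_volumes)
            epoch_rr = physio.compute_epoch_changes(rr_tr, schedule, run.tr_s)

    return SubjectResult(
        subject=subject,
        schedule=schedule,
        phantom=phantom,
        coords=coords,
        betas=betas,
        truth=truth,
        rank_rows=rank_rows,
        vif=vif,
        epoch_ibi=epoch_ibi,
        epoch_rr=epoch_rr,
        cardiac_quality=cq,
        resp_quality=rq,
        dice_aqueduct=_dice(aqueduct.mask, phantom.aqueduct_mask),
    )


def run_study(
    n_subjects: int = 8,
    seed: int = 0,
    noise_sd: float = 1.0,
    obliquity_spread_deg: float = 5.0,
    ibi_coupling_s: float = 0.02,
    fit_model: bool = True,
    random_structure: str = "uncorrelated",
) -> StudyResult:
    """Simulate and analyze a cohort, then run the group models.

    Subject phantoms vary in axis obliquity; physiological modulation
    varies across subjects around the default epoch means, and the
    subject-level 3-back IBI drop co-varies with an overall gain on the
    subject's BOLD effect (a simple between-subject brain-body
    coupling), so the beta-physiology correlation map has signal.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = simulate.spawn_seeds(seed, n_subjects)
    subjects = []
    for s in range(n_subjects):
        obl = float(rng.normal(0, obliquity_spread_deg))
        gain = float(np.clip(rng.normal(1.0, 0.2), 0.5, 1.5))
        # brain-body coupling: stronger responders accelerate more at 3-back
        d3 = -0.03 - ibi_coupling_s * (gain - 1.0) + rng.normal(0, 0.005)
        ibi_effects = {"fixation": 0.90, "1back": 0.93, "3back": 0.90 + d3}
        rr_effects = {
            "fixation": 14.0,
            "1back": 15.0 + rng.normal(0, 0.3),
            "3back": 16.5 + rng.normal(0, 0.3),
        }
        cfg = PhantomConfig(axis_obliquity_deg=obl)
        cfg.condition_scale = {1: 1.0 * gain, 3: 2.0 * gain}
        order = "1-3-3-1" if s % 2 == 0 else "3-1-1-3"
        subjects.append(
            run_subject(
                s, sub_seeds[s], order=order, phantom_config=cfg,
                noise_sd=noise_sd, ibi_effects=ibi_effects,
                rr_effects=rr_effects,
            )
        )

    rank_table = pd.concat([s.rank_rows for s in subjects], ignore_index=True)
    pooled = {
        c: masks.pool_subjects(
            [s.coords for s in subjects], [s.betas[c] for s in subjects]
        )
        for c in (1, 3)
    }

    mixed = (
        group.fit_mixed_model(rank_table, random_structure=random_structure)
        if fit_model
        else None
    )

    g1 = np.nanmean(pooled[1].maps, axis=0)
    g3 = np.nanmean(pooled[3].maps, axis=0)
    corr = group.correlate_condition_maps(g1, g3, seed=seed)
    group_z = {}
    for c in (1, 3):
        z, _ = group.group_level_map(np.nan_to_num(pooled[c].maps, nan=0.0))
        group_z[c] = z

    physio_rows = []
    for s in subjects:
        physio_rows.append(
            {
                "subject": s.subject,
                "cardiac_quality": s.cardiac_quality,
                "resp_quality": s.resp_quality,
                "delta_ibi_1back": s.epoch_ibi.delta_1back if s.epoch_ibi else np.nan,
                "delta_ibi_3back": s.epoch_ibi.delta_3back if s.epoch_ibi else np.nan,
                "delta_rr_1back": s.epoch_rr.delta_1back if s.epoch_rr else np.nan,
                "delta_rr_3back": s.epoch_rr.delta_3back if s.epoch_rr else np.nan,
            }
        )
    physio_frame = pd.DataFrame(physio_rows)

    ibi_r = rr_r = None
    d_ibi = physio_frame["delta_ibi_3back"].to_numpy()
    ok = np.isfinite(d_ibi)
    if ok.sum() >= 3:
        ibi_r = group.correlate_physio_with_betas(
            pooled[3].maps[ok], d_ibi[ok]
        )
    d_rr = physio_frame["delta_rr_3back"].to_numpy()
    ok = np.isfinite(d_rr)
    if ok.sum() >= 3:
        rr_r = group.correlate_physio_with_betas(pooled[3].maps[ok], d_rr[ok])

    return StudyResult(
        subjects=subjects,
        rank_table=rank_table,
        pooled=pooled,
        mixed_model=mixed,
        condition_correlation=corr,
        group_z=group_z,
        physio_frame=physio_frame,
        ibi_beta_r=ibi_r,
        rr_beta_r=rr_r,
    )
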