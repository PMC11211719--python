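"""Subject-level GLM: design construction, nuisance regressors, fitting.

The design follows the standard brainstem-fMRI first-level recipe:
trial-wise 1 s boxcars per condition convolved with a double-gamma HRF
(summed within condition, which for closely spaced trials approximates a
block regressor), a run intercept, 6 motion parameters, 5 CSF + 5 WM
aCompCor components, a discrete cosine high-pass set with minimum period
264 s, and one-hot spike regressors for volumes with framewise
displacement above 0.5 mm.  Voxelwise betas are estimated by OLS, with
z-maps per contrast and VIF collinearity diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

FD_SPIKE_THRESHOLD_MM = 0.5
FD_EXCLUDE_FRACTION = 0.20
DCT_MIN_PERIOD_S = 264.0
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass
class HrfParams:
    """Canonical double-gamma HRF (SPM-style defaults, configurable)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    length_s: float = 32.0


def double_gamma_hrf(dt: float, params: HrfParams | None = None) -> np.ndarray:
    p = params or HrfParams()
    t = np.arange(0, p.length_s + dt, dt)
    peak = stats.gamma.pdf(t, p.peak_delay_s / p.peak_dispersion_s,
                           scale=p.peak_dispersion_s)
    under = stats.gamma.pdf(t, p.undershoot_delay_s / p.undershoot_dispersion_s,
                            scale=p.undershoot_dispersion_s)
    return peak - under / p.peak_undershoot_ratio


def hrf_convolve(
    onsets: np.ndarray,
    durations: float | np.ndarray,
    tr: float,
    n_volumes: int,
    hrf_params: HrfParams | None = None,
    dt: float = 0.1,
) -> np.ndarray:
    """HRF-convolved regressor sampled at volume acquisition times.

    Events are laid down as boxcars on a ``dt`` grid, convolved with the
    double-gamma HRF, normalized so a single isolated event of the given
    duration peaks at 1, then sampled at t = i * TR.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    run_len = n_volumes * tr
    if onsets.size and onsets.max() >= run_len:
        raise ValueError(
            f"onset {onsets.max():.2f}s beyond run end {run_len:.2f}s"
        )
    durations = np.broadcast_to(np.atleast_1d(durations), onsets.shape).astype(float)
    n_hi = int(np.ceil(run_len / dt)) + 1
    boxcar = np.zeros(n_hi)
    for o, d in zip(onsets, durations):
        boxcar[int(round(o / dt)):int(round((o + d) / dt))] = 1.0
    kernel = double_gamma_hrf(dt, hrf_params)
    # peak of one isolated event of the reference duration, for unit scaling
    ref_dur = durations[0] if durations.size else 1.0
    ref = np.convolve(
        np.ones(max(int(round(ref_dur / dt)), 1)), kernel
    ).max()
    conv = np.convolve(boxcar, kernel)[:n_hi] / ref
    sample_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[sample_idx]


@dataclass
class MotionSummary:
    fd_mm: np.ndarray
    spike_volumes: np.ndarray
    exclude_subject: bool


def compute_fd(
    motion_params: pd.DataFrame | np.ndarray,
    sphere_radius_mm: float = 50.0,
    spike_threshold_mm: float = FD_SPIKE_THRESHOLD_MM,
    exclude_fraction: float = FD_EXCLUDE_FRACTION,
) -> MotionSummary:
    """Power-style framewise displacement from 6 motion parameters.

    fd_t = sum |delta translations| + R * sum |delta rotations| with
    rotations in radians projected on an R = 50 mm sphere; fd_0 = 0.
    Volumes with fd above 0.5 mm are spikes, and a subject with spikes in
    more than 20 % of volumes is flagged for exclusion.
    """
    m = np.asarray(motion_params, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion parameters must have 6 columns")
    delta = np.abs(np.diff(m, axis=0))
    fd = np.zeros(len(m))
    fd[1:] = delta[:, :3].sum(axis=1) + sphere_radius_mm * delta[:, 3:].sum(axis=1)
    spikes = np.flatnonzero(fd > spike_threshold_mm)
    return MotionSummary(
        fd_mm=fd,
        spike_volumes=spikes,
        exclude_subject=bool(len(spikes) > exclude_fraction * len(m)),
    )


def compute_acompcor(
    bold_data: np.ndarray,
    mask: np.ndarray,
    n_components: int = 5,
) -> np.ndarray:
    """Top principal-component time courses within a noise ROI (aCompCor).

    Voxel time-series inside the mask are linearly detrended and
    variance-normalized; returns (n_volumes, n_components) unit-variance,
    mutually orthogonal component series.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("aCompCor mask is empty")
    ts = bold_data[mask].T.astype(float)  # time x voxels
    if mask.sum() < n_components:
        raise ValueError(
            f"mask has {int(mask.sum())} voxels < {n_components} components"
        )
    t = np.arange(ts.shape[0], dtype=float)
    tc = t - t.mean()
    ts = ts - ts.mean(axis=0)
    ts -= np.outer(tc, tc @ ts / (tc @ tc))
    sd = ts.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    ts /= sd
    # time-domain Gram matrix keeps the eigendecomposition at n_volumes^2
    gram = ts @ ts.T
    eigval, eigvec = np.linalg.eigh(gram)
    comps = eigvec[:, ::-1][:, :n_components]
    comps = comps / comps.std(axis=0, ddof=1)
    return comps


def dct_basis(n_volumes: int, tr: float,
              min_period_s: float = DCT_MIN_PERIOD_S) -> np.ndarray:
    """Discrete cosine high-pass set: K = floor(2 T / min_period) columns."""
    run_len = n_volumes * tr
    k_max = int(np.floor(2.0 * run_len / min_period_s))
    t = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes))
            for k in range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


def build_design_matrix(
    schedule,
    motion: pd.DataFrame | np.ndarray,
    acompcor_csf: np.ndarray,
    acompcor_wm: np.ndarray,
    tr: float,
    n_volumes: int,
    hrf_params: HrfParams | None = None,
) -> pd.DataFrame:
    """Assemble the first-level design matrix as a named DataFrame.

    Columns: task_1back, task_3back (HRF-convolved trial regressors
    summed within condition), intercept, 6 motion, 5+5 aCompCor, DCT
    high-pass set, and one-hot spike indicators from the FD summary.
    """
    cols: dict[str, np.ndarray] = {}
    for cond in (1, 3):
        onsets = schedule.condition_onsets(cond)
        reg = hrf_convolve(onsets, schedule.stim_duration_s, tr, n_volumes,
                           hrf_params)
        if not np.any(reg):
            raise ValueError(f"task_{cond}back regressor is all zero")
        cols[f"task_{cond}back"] = reg
    cols["intercept"] = np.ones(n_volumes)

    m = np.asarray(motion, dtype=float)
    if m.shape != (n_volumes, 6):
        raise ValueError("motion table must be n_volumes x 6")
    for i, name in enumerate(MOTION_COLUMNS):
        cols[name] = m[:, i]

    for prefix, comps in (("acompcor_csf", acompcor_csf),
                          ("acompcor_wm", acompcor_wm)):
        comps = np.asarray(comps, dtype=float)
        if comps.shape[0] != n_volumes:
            raise ValueError(f"{prefix} components must have n_volumes rows")
        for i in range(comps.shape[1]):
            cols[f"{prefix}_{i}"] = comps[:, i]

    dct = dct_basis(n_volumes, tr)
    for i in range(dct.shape[1]):
        cols[f"dct_{i}"] = dct[:, i]

    fd = compute_fd(m)
    for v in fd.spike_volumes:
        spike = np.zeros(n_volumes)
        spike[v] = 1.0
        cols[f"spike_{v}"] = spike

    design = pd.DataFrame(cols)
    if not np.all(np.isfinite(design.to_numpy())):
        raise ValueError("design matrix contains non-finite values")
    return design


@dataclass
class BetaMaps:
    """Voxelwise task betas, residual variance, and contrast z-maps."""

    beta: dict[str, np.ndarray]  # e.g. {"1back": 3D, "3back": 3D}
    residual_variance: np.ndarray
    z: dict[str, np.ndarray]  # contrasts: "1back", "3back", "3back_gt_1back"
    mask: np.ndarray
    df_resid: int


def _z_from_t(t: np.ndarray, df: int) -> np.ndarray:
    # symmetric conversion via the survival function keeps precision for
    # large |t|; infinities propagate (flagged upstream, never capped)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.t.sf(np.abs(t), df)
        z = stats.norm.isf(np.clip(p, 1e-300, None))
    return np.sign(t) * z


def fit_glm(
    bold_data: np.ndarray,
    design: pd.DataFrame,
    mask: np.ndarray,
) -> BetaMaps:
    """Ordinary least squares per voxel inside ``mask``.

    Raises on a rank-deficient design, naming the collinear columns.
    All-zero voxel time-series get beta = 0, z = 0 (guarded division).
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, r = np.linalg.qr(X)
        d = np.abs(np.diag(r))
        bad = design.columns[:len(d)][d < 1e-8 * d.max()]
        raise ValueError(f"rank-deficient design; collinear columns: {list(bad)}")
    mask = np.asarray(mask, dtype=bool)
    Y = bold_data[mask].T.astype(float)  # time x voxels
    pinv = np.linalg.pinv(X)
    B = pinv @ Y
    resid = Y - X @ B
    df_resid = n - p
    sigma2 = (resid**2).sum(axis=0) / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)

    shape = bold_data.shape[:3]
    task_idx = {c: design.columns.get_loc(f"task_{c}back") for c in (1, 3)}
    beta_vols: dict[str, np.ndarray] = {}
    z_vols: dict[str, np.ndarray] = {}
    contrasts = {
        "1back": np.eye(p)[task_idx[1]],
        "3back": np.eye(p)[task_idx[3]],
        "3back_gt_1back": np.eye(p)[task_idx[3]] - np.eye(p)[task_idx[1]],
    }
    for cond in (1, 3):
        vol = np.zeros(shape)
        vol[mask] = B[task_idx[cond]]
        beta_vols[f"{cond}back"] = vol
    for name, c in contrasts.items():
        est = c @ B
        var = sigma2 * (c @ xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, est / np.sqrt(np.maximum(var, 1e-300)), 0.0)
        zvol = np.zeros(shape)
        zvol[mask] = _z_from_t(t, df_resid)
        z_vols[name] = zvol
    rv = np.zeros(shape)
    rv[mask] = sigma2
    return BetaMaps(beta=beta_vols, residual_variance=rv, z=z_vols,
                    mask=mask, df_resid=df_resid)


def compute_vif(design: pd.DataFrame,
                columns: tuple[str, ...] = ("task_1back", "task_3back"),
                ) -> dict[str, float]:
    """Variance inflation factor 1 / (1 - R^2) for the named regressors.

    Perfect collinearity reports +inf rather than raising.
    """
    X = design.to_numpy(dtype=float)
    out = {}
    for name in columns:
        j = design.columns.get_loc(name)
        y = X[:, j]
        # auxiliary regression always gets an intercept so R^2 is the
        # centered coefficient of determination
        others = np.c_[np.delete(X, j, axis=1), np.ones(len(y))]
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = ((y - y.mean()) ** 2).sum()
        ss_res = (resid**2).sum()
        if ss_tot == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def smooth_and_resample(
    data: np.ndarray,
    affine: np.ndarray,
    fwhm_mm: float = 1.0,
    out_voxel_mm: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-smooth a 3D map and resample it to a finer isotropic grid.

    Smoothing uses sigma = fwhm / 2.3548 in mm; resampling is trilinear.
    The total integral (sum x voxel volume) is renormalized after
    interpolation so mass is conserved exactly, which trilinear sampling
    alone only guarantees approximately.
    """
    if out_voxel_mm <= 0:
        raise ValueError("out_voxel_mm must be positive")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    vox = float(np.abs(np.diag(affine)[:3]).mean())
    smoothed = data.astype(float)
    if fwhm_mm > 0:
        sigma_vox = fwhm_mm / 2.3548 / vox
        smoothed = ndimage.gaussian_filter(smoothed, sigma_vox, mode="constant")
    factor = vox / out_voxel_mm
    if np.isclose(factor, 1.0):
        out = smoothed
    else:
        out = ndimage.zoom(smoothed, factor, order=1, mode="grid-constant",
                           grid_mode=True)
        mass_in = smoothed.sum() * vox**3
        mass_out = out.sum() * out_voxel_mm**3
        if mass_out != 0:
            out = out * (mass_in / mass_out)
    out_affine = affine.copy()
    scale = out_voxel_mm / vox
    out_affine[:3, :3] = affine[:3, :3] * scale
    # keep the center of voxel (0,0,0) region anchored (grid_mode=True zoom)
    out_affine[:3, 3] = affine[:3, 3] - 0.5 * (vox - out_voxel_mm) * np.sign(
        np.diag(affine)[:3]
    )
    return out, out_affine


def group_zmap(subject_betas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise one-sample t across subjects converted to z.

    Returns (z, flagged) where flagged marks zero-variance voxels whose t
    is infinite/undefined; these are NaN in z, never silently capped.
    """
    b = np.asarray(subject_betas, dtype=float)
    n = b.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    mean = b.mean(axis=0)
    sd = b.std(axis=0, ddof=1)
    flagged = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    z = _z_from_t(t, n - 1)
    z[flagged] = np.nan
    return z, flagged
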