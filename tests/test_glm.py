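"""First-level GLM: HRF, nuisance regressors, fitting, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pagflat import glm
from pagflat.glm import (
    build_design_matrix,
    compute_acompcor,
    compute_fd,
    compute_vif,
    dct_basis,
    fit_glm,
    hrf_convolve,
    smooth_and_resample,
)
from pagflat.simulate import generate_bold_run
from pagflat.task import generate_task_schedule

TR = 2.34


def test_hrf_shape_single_event():
    reg = hrf_convolve(np.array([0.0]), 1.0, 0.1, 400)
    t = np.arange(400) * 0.1
    assert reg.max() == pytest.approx(1.0, abs=1e-6)
    assert 4.0 <= t[np.argmax(reg)] <= 7.0
    assert abs(reg[t > 30]).max() < 0.02


def test_hrf_linearity():
    """Two events superpose exactly (convolution is linear)."""
    a = hrf_convolve(np.array([10.0]), 1.0, TR, 100)
    b = hrf_convolve(np.array([12.34]), 1.0, TR, 100)
    ab = hrf_convolve(np.array([10.0, 12.34]), 1.0, TR, 100)
    assert np.abs(ab - (a + b)).max() < 1e-10


def test_hrf_onset_beyond_run():
    with pytest.raises(ValueError, match="beyond run end"):
        hrf_convolve(np.array([500.0]), 1.0, TR, 100)


def test_empty_onsets_give_zero_column_error(schedule):
    reg = hrf_convolve(np.array([]), 1.0, TR, 100)
    assert not reg.any()


def test_fd_zero_motion():
    fd = compute_fd(np.zeros((100, 6)))
    assert np.all(fd.fd_mm == 0)
    assert not fd.exclude_subject and len(fd.spike_volumes) == 0


def test_fd_translation_step():
    m = np.zeros((50, 6))
    m[25:, 0] = 1.0  # 1 mm x step
    fd = compute_fd(m)
    assert fd.fd_mm[25] == pytest.approx(1.0)
    assert list(fd.spike_volumes) == [25]


def test_fd_rotation_arc_length():
    m = np.zeros((50, 6))
    m[10:, 3] = 0.02  # rad
    fd = compute_fd(m)
    assert fd.fd_mm[10] == pytest.approx(0.02 * 50)  # = 1.0 mm


def test_fd_exclusion_rule():
    rng = np.random.default_rng(0)
    m = np.zeros((100, 6))
    m[::4, 0] = 1.0  # alternating jumps -> ~50 % spikes
    fd = compute_fd(m)
    assert fd.exclude_subject


@settings(max_examples=20, deadline=None, derandomize=True)
@given(offset=st.floats(-5, 5, allow_nan=False))
def test_fd_gauge_invariance(offset):
    """Adding a constant to all motion columns leaves FD unchanged."""
    rng = np.random.default_rng(1)
    m = rng.normal(0, 0.1, (60, 6))
    a = compute_fd(m).fd_mm
    b = compute_fd(m + offset).fd_mm
    assert np.allclose(a, b)


def test_fd_wrong_columns():
    with pytest.raises(ValueError):
        compute_fd(np.zeros((10, 5)))


def test_acompcor_recovers_planted_signal():
    rng = np.random.default_rng(0)
    t = np.arange(120)
    sinus = np.sin(2 * np.pi * t / 17)
    data = rng.normal(0, 0.05, (6, 6, 6, 120))
    mask = np.zeros((6, 6, 6), bool)
    mask[1:5, 1:5, 1:5] = True
    data[mask] += sinus
    comps = compute_acompcor(data, mask, n_components=3)
    assert abs(np.corrcoef(comps[:, 0], sinus)[0, 1]) > 0.99
    # mutual orthogonality
    gram = comps.T @ comps
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8


def test_acompcor_rank_bound():
    data = np.random.default_rng(0).normal(size=(3, 3, 1, 50))
    mask = np.zeros((3, 3, 1), bool)
    mask[0, :2, 0] = True  # 2 voxels
    with pytest.raises(ValueError, match="components"):
        compute_acompcor(data, mask, n_components=6)


def test_dct_count_and_orthogonality():
    # run of 615 s -> floor(2*615/264) = 4 columns
    n_vol = int(round(615 / TR))
    dct = dct_basis(n_vol, 615 / n_vol)
    assert dct.shape[1] == 4
    gram = dct.T @ dct
    assert np.abs(gram - np.diag(np.diag(gram))).max() < 1e-10


@pytest.fixture(scope="module")
def run_and_design(schedule, phantom):
    run, _, motion = generate_bold_run(schedule, phantom, noise_sd=1.0, seed=9)
    rng = np.random.default_rng(0)
    csf = rng.normal(size=(run.n_volumes, 5))
    wm = rng.normal(size=(run.n_volumes, 5))
    design = build_design_matrix(schedule, motion, csf, wm, TR, run.n_volumes)
    return run, design


def test_design_columns(run_and_design):
    run, design = run_and_design
    names = list(design.columns)
    assert "task_1back" in names and "task_3back" in names
    assert "intercept" in names
    assert sum(n.startswith("acompcor_csf") for n in names) == 5
    assert sum(n.startswith("acompcor_wm") for n in names) == 5
    k = int(np.floor(2 * run.n_volumes * TR / 264.0))
    assert sum(n.startswith("dct_") for n in names) == k
    assert len(names) == len(set(names))
    spikes = design[[c for c in names if c.startswith("spike_")]]
    assert np.all(spikes.sum(axis=0) == 1.0)  # one-hot


def test_design_vif_acceptable(run_and_design):
    _, design = run_and_design
    vif = compute_vif(design)
    assert vif["task_1back"] < 5 and vif["task_3back"] < 5


def test_vif_orthonormal_design():
    # orthonormal columns, also orthogonal to the intercept (zero mean)
    raw = np.c_[np.ones(50), np.random.default_rng(0).normal(size=(50, 5))]
    q, _ = np.linalg.qr(raw)
    design = pd.DataFrame(q[:, 1:],
                          columns=["task_1back", "task_3back", "a", "b", "c"])
    vif = compute_vif(design)
    assert vif["task_1back"] == pytest.approx(1.0, abs=1e-9)


def test_vif_duplicate_column_inf():
    x = np.random.default_rng(0).normal(size=50)
    design = pd.DataFrame({"task_1back": x, "task_3back": x})
    assert compute_vif(design)["task_1back"] == np.inf


def test_vif_known_r2():
    """Column = other + equal-variance noise -> R^2 = 0.5 -> VIF = 2."""
    vifs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=2000)
        b = a + rng.normal(size=2000)
        design = pd.DataFrame({"task_1back": b, "other": a})
        vifs.append(compute_vif(design, columns=("task_1back",))["task_1back"])
    assert np.mean(vifs) == pytest.approx(2.0, rel=0.1)


def test_noiseless_recovery_exact(schedule, phantom):
    run, _, motion = generate_bold_run(
        schedule, phantom, noise_sd=0.0, drift_amplitude=0.0, seed=0
    )
    design = build_design_matrix(
        schedule, motion, np.zeros((run.n_volumes, 0)),
        np.zeros((run.n_volumes, 0)), TR, run.n_volumes,
    )
    fit = fit_glm(run.data, design, phantom.pag_truth_mask)
    for c in (1, 3):
        err = np.abs(fit.beta[f"{c}back"] - phantom.truth_effect[c])
        assert err[phantom.pag_truth_mask].max() < 1e-4  # float32 storage


def _simple_design(schedule):
    motion = np.cumsum(
        np.random.default_rng(0).normal(0, 0.001, (259, 6)), axis=0
    )
    return build_design_matrix(
        schedule, motion, np.zeros((259, 0)), np.zeros((259, 0)), TR, 259
    )


def test_all_zero_voxel_guarded(schedule):
    data = np.zeros((2, 2, 1, 259))
    fit = fit_glm(data, _simple_design(schedule), np.ones((2, 2, 1), bool))
    assert np.all(fit.beta["1back"] == 0)
    assert np.all(fit.z["1back"] == 0)


def test_rank_deficient_design_named(schedule):
    design = _simple_design(schedule)
    design["dup"] = design["task_1back"]
    with pytest.raises(ValueError, match="collinear"):
        fit_glm(np.zeros((2, 2, 1, 259)), design, np.ones((2, 2, 1), bool))


def test_frisch_waugh_orthogonal_nuisance(schedule, phantom):
    """Adding a nuisance regressor orthogonal to all existing columns
    leaves task betas unchanged (partitioned-regression identity)."""
    run, _, motion = generate_bold_run(schedule, phantom, noise_sd=1.0, seed=4)
    base = build_design_matrix(
        schedule, motion, np.zeros((run.n_volumes, 0)),
        np.zeros((run.n_volumes, 0)), TR, run.n_volumes,
    )
    X = base.to_numpy()
    rng = np.random.default_rng(0)
    extra = rng.normal(size=run.n_volumes)
    # orthogonalize against every existing column
    extra -= X @ np.linalg.lstsq(X, extra, rcond=None)[0]
    aug = base.copy()
    aug["orth_nuisance"] = extra
    mask = phantom.pag_truth_mask
    f0 = fit_glm(run.data, base, mask)
    f1 = fit_glm(run.data, aug, mask)
    for c in ("1back", "3back"):
        assert np.abs(f0.beta[c] - f1.beta[c])[mask].max() < 1e-8


def test_smooth_resample_identity():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(10, 10, 10))
    aff = np.diag([1.1, 1.1, 1.1, 1.0])
    out, _ = smooth_and_resample(data, aff, fwhm_mm=0.0, out_voxel_mm=1.1)
    assert np.allclose(out, data)


def test_smooth_resample_delta_mass_and_location():
    data = np.zeros((15, 15, 15))
    data[7, 7, 7] = 1.0
    aff = np.diag([1.1, 1.1, 1.1, 1.0])
    aff[:3, 3] = -7.7
    out, out_aff = smooth_and_resample(data, aff, fwhm_mm=1.0, out_voxel_mm=0.5)
    mass_in = data.sum() * 1.1**3
    mass_out = out.sum() * 0.5**3
    assert mass_out == pytest.approx(mass_in, rel=0.01)
    peak = np.unravel_index(np.argmax(out), out.shape)
    world = out_aff @ np.array([*peak, 1.0])
    in_world = aff @ np.array([7, 7, 7, 1.0])
    assert np.linalg.norm(world[:3] - in_world[:3]) <= 0.5  # one fine voxel


def test_smooth_resample_constant_field():
    data = np.full((12, 12, 12), 3.0)
    aff = np.diag([1.1, 1.1, 1.1, 1.0])
    out, _ = smooth_and_resample(data, aff, fwhm_mm=1.0, out_voxel_mm=1.1)
    assert np.allclose(out[2:-2, 2:-2, 2:-2], 3.0, atol=1e-6)


def test_smooth_resample_bad_voxel():
    with pytest.raises(ValueError):
        smooth_and_resample(np.zeros((5, 5, 5)), np.eye(4), out_voxel_mm=0.0)


def test_group_zmap_null_calibration():
    """Pure-noise subject maps reject at ~5 % for |z| > 1.96."""
    rates = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        maps = rng.normal(size=(20, 400))
        z, flagged = glm.group_zmap(maps)
        rates.append(np.mean(np.abs(z[~flagged]) > 1.96))
    assert np.mean(rates) == pytest.approx(0.05, abs=0.02)


def test_group_zmap_zero_variance_flagged():
    maps = np.ones((5, 10))
    z, flagged = glm.group_zmap(maps)
    assert flagged.all() and np.isnan(z).all()
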