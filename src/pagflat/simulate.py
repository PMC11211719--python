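"""Synthetic BOLD runs and peripheral physiological traces.

The BOLD generator composes, per voxel: a constant baseline, the
HRF-convolved condition boxcars scaled by the phantom's ground-truth
effect, a low-frequency drift (linear + cosine), i.i.d. Gaussian
temporal noise, and — inside the aqueduct only — an extra high-variance
oscillation standing in for CSF pulsation, which is what makes the
aqueduct detectable by temporal variance.  Motion parameters are a slow
random walk with optional injected spike displacements.

The physiological generator lays down heartbeats from an inhomogeneous
renewal process whose mean inter-beat interval tracks the current task
epoch (fixation / 1-back / 3-back), renders each beat as a Gaussian
systolic bump (80 ms wide), and builds the respiratory belt trace as a
phase-integrated quasi-sinusoid whose instantaneous rate tracks the
epoch respiratory-rate means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import hrf_convolve
from .phantom import Phantom
from .physio import IBI_BOUNDS_S, PhysioSeries
from .task import TaskSchedule

TR_S = 2.34


@dataclass
class BoldRun:
    data: np.ndarray  # (x, y, z, time), float32 by default
    tr_s: float
    motion_params: pd.DataFrame
    affine: np.ndarray

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Expand one master seed into per-component seeds (counter-based)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def generate_bold_run(
    schedule: TaskSchedule,
    phantom: Phantom,
    noise_sd: float = 1.0,
    drift_amplitude: float = 0.5,
    spike_volumes: tuple[int, ...] = (),
    spike_mm: float = 1.0,
    tr: float = TR_S,
    n_volumes: int | None = None,
    baseline: float = 100.0,
    aqueduct_amplitude: float = 5.0,
    seed: int = 0,
    dtype=np.float32,
) -> tuple[BoldRun, pd.DataFrame, pd.DataFrame]:
    """Simulate one 4D run plus its BIDS-like event and motion tables.

    With ``noise_sd = 0`` and ``drift_amplitude = 0`` the run is exactly
    invertible by the GLM (betas equal the phantom truth), because the
    generator uses the same HRF convolution as the analysis design.
    Raises if the schedule extends past the run.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if n_volumes is None:
        n_volumes = int(np.ceil(schedule.duration_s / tr))
    if schedule.duration_s - schedule.fixation_duration_s > n_volumes * tr:
        raise ValueError("schedule is longer than the run")

    shape = phantom.shape
    data = np.full(shape + (n_volumes,), baseline, dtype=dtype)

    for cond, effect in phantom.truth_effect.items():
        reg = hrf_convolve(
            schedule.condition_onsets(cond), schedule.stim_duration_s, tr, n_volumes
        )
        sel = effect != 0
        data[sel] += np.outer(effect[sel], reg).astype(dtype)

    t = np.arange(n_volumes) * tr
    if drift_amplitude > 0:
        active = phantom.pag_truth_mask | phantom.aqueduct_mask
        n_active = int(active.sum())
        lin = rng.normal(0, drift_amplitude, n_active)
        cos_amp = rng.normal(0, drift_amplitude, n_active)
        ramp = (t - t.mean()) / t.max()
        cosine = np.cos(2 * np.pi * t / 128.0)
        data[active] += (
            np.outer(lin, ramp) + np.outer(cos_amp, cosine)
        ).astype(dtype)

    # CSF pulsation surrogate: aliased cardiac oscillation, random phase
    aq = phantom.aqueduct_mask
    n_aq = int(aq.sum())
    phase = rng.uniform(0, 2 * np.pi, n_aq)
    osc = np.sin(2 * np.pi * 0.3 * t[None, :] + phase[:, None])
    data[aq] += (aqueduct_amplitude * osc).astype(dtype)

    if noise_sd > 0:
        data += rng.normal(0, noise_sd, data.shape).astype(dtype)

    motion = np.cumsum(rng.normal(0, 0.01, (n_volumes, 6)), axis=0)
    motion[:, 3:] *= 0.002  # rotations (rad) drift far less than translations
    for v in spike_volumes:
        if not 0 <= v < n_volumes:
            raise ValueError(f"spike volume {v} outside run")
        motion[v:, 0] += spike_mm
    motion_df = pd.DataFrame(motion, columns=[
        "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"])

    run = BoldRun(data=data, tr_s=tr, motion_params=motion_df,
                  affine=phantom.affine)
    return run, schedule.to_events_frame(), motion_df


@dataclass
class SimulatedPhysio:
    cardiac: PhysioSeries
    respiratory: PhysioSeries
    beat_times_s: np.ndarray
    breath_times_s: np.ndarray
    ibi_epoch_means_s: dict[str, float]
    rr_epoch_means_bpm: dict[str, float]


def _epoch_lookup(schedule: TaskSchedule):
    blocks = schedule.block_intervals()
    starts = blocks["start_s"].to_numpy()
    ends = blocks["end_s"].to_numpy()
    conds = blocks["condition"].to_numpy()

    def epoch_of(t: float) -> str:
        i = np.searchsorted(starts, t, side="right") - 1
        if i >= 0 and t < ends[i]:
            return f"{conds[i]}back"
        return "fixation"

    return epoch_of


def generate_physio_traces(
    schedule: TaskSchedule,
    ibi_effects: dict[str, float] | None = None,
    rr_effects: dict[str, float] | None = None,
    artifact_level: float = 0.0,
    duration_s: float | None = None,
    fs: float = 1000.0,
    ibi_cv: float = 0.03,
    rr_jitter_bpm: float = 0.5,
    pulse_width_s: float = 0.08,
    seed: int = 0,
) -> SimulatedPhysio:
    """Simulate cardiac and respiratory 1 kHz traces for one run.

    ``ibi_effects`` / ``rr_effects`` give the per-epoch means (keys
    fixation / 1back / 3back); defaults reproduce the study pattern of
    cardio-deceleration under mild load, cardio-acceleration under
    moderate load, and faster breathing under both.  ``artifact_level``
    is the approximate fraction of time covered by injected
    motion-artifact bursts.
    """
    ibi_effects = ibi_effects or {"fixation": 0.90, "1back": 0.93, "3back": 0.87}
    rr_effects = rr_effects or {"fixation": 14.0, "1back": 15.0, "3back": 16.5}
    for v in ibi_effects.values():
        if not IBI_BOUNDS_S[0] <= v <= IBI_BOUNDS_S[1]:
            raise ValueError(f"IBI epoch mean {v} s outside {IBI_BOUNDS_S}")
    for v in rr_effects.values():
        if not 4.0 <= v <= 60.0:
            raise ValueError(f"respiratory rate {v} bpm not physiological")

    rng = np.random.default_rng(seed)
    duration = duration_s if duration_s is not None else schedule.duration_s
    n = int(round(duration * fs))
    epoch_of = _epoch_lookup(schedule)

    # --- cardiac: renewal process with epoch-dependent mean IBI ---
    beats = []
    t = float(rng.uniform(0, 0.5))
    while t < duration:
        beats.append(t)
        mean_ibi = ibi_effects[epoch_of(t)]
        ibi = mean_ibi * (1.0 + ibi_cv * rng.standard_normal()) if ibi_cv > 0 else mean_ibi
        t += float(np.clip(ibi, *IBI_BOUNDS_S))
    beat_times = np.array(beats)

    cardiac = rng.normal(0, 0.01, n) if ibi_cv > 0 else np.zeros(n)
    sigma = pulse_width_s / 4.0  # bump ~95% contained in the 80 ms width
    half = int(3 * sigma * fs)
    bump_t = np.arange(-half, half + 1) / fs
    bump = np.exp(-0.5 * (bump_t / sigma) ** 2)
    for bt in beat_times:
        c = int(round(bt * fs))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        cardiac[lo:hi] += bump[lo - (c - half):hi - (c - half)]

    # --- respiration: phase-integrated quasi-sinusoid ---
    dt = 1.0 / fs
    tt = np.arange(n) * dt
    # per-second epoch rate, interpolated to avoid steps in frequency
    sec = np.arange(0, duration + 1.0)
    sec_rate = np.array([rr_effects[epoch_of(s)] for s in sec])
    if rr_jitter_bpm > 0:
        sec_rate = sec_rate + rng.normal(0, rr_jitter_bpm, len(sec_rate))
    rate_hz = np.interp(tt, sec, sec_rate) / 60.0
    phase = 2 * np.pi * np.cumsum(rate_hz) * dt
    resp = np.sin(phase)
    if rr_jitter_bpm > 0:
        resp = resp + rng.normal(0, 0.01, n)
    breath_times = tt[np.flatnonzero(
        (np.mod(phase[:-1], 2 * np.pi) > np.pi * 1.5)
        & (np.mod(phase[1:], 2 * np.pi) < np.pi * 0.5)
    )]

    if artifact_level > 0:
        for samples in (cardiac, resp):
            covered = 0
            target = artifact_level * n
            while covered < target:
                burst = int(rng.uniform(0.5, 2.0) * fs)
                start = int(rng.uniform(0, n - burst))
                samples[start:start + burst] += rng.normal(
                    0, 10.0 * samples.std() + 1.0, burst
                )
                covered += burst

    return SimulatedPhysio(
        cardiac=PhysioSeries(kind="cardiac", samples=cardiac, fs_hz=fs),
        respiratory=PhysioSeries(kind="respiratory", samples=resp, fs_hz=fs),
        beat_times_s=beat_times,
        breath_times_s=breath_times,
        ibi_epoch_means_s=dict(ibi_effects),
        rr_epoch_means_bpm=dict(rr_effects),
    )
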