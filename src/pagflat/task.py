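"""N-back task schedules and behavioral scoring.

The working-memory run is a single block-design session: 12 blocks of 10
letter trials each (120 trials), alternating mild (1-back) and moderate
(3-back) load in a counterbalanced 1-3-3-1 or 3-1-1-3 order.  Each block
opens with a 3 s cue and is followed by 25 s of resting fixation; letters
are shown for 1 s with a 1 s blank response gap, so trials are spaced 2 s
apart.  Target/lure proportions are fixed exactly: 20 % of trials are
n-back targets and 12.5 % of the nontargets are lures (2-back matches in
1-back blocks; 2- or 4-back matches in 3-back blocks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LETTERS = ("Q", "W", "R", "S", "T")
BLOCK_ORDERS = {
    "1-3-3-1": (1, 3, 3, 1),
    "3-1-1-3": (3, 1, 1, 3),
}
N_BLOCKS = 12
TRIALS_PER_BLOCK = 10
TARGET_FRACTION = 0.20
LURE_FRACTION_OF_NONTARGETS = 0.125


class ScheduleGenerationError(RuntimeError):
    """Raised when constraint satisfaction fails after bounded retries."""


@dataclass(frozen=True)
class Trial:
    block_index: int
    condition: int  # 1 or 3 (n of the block's n-back rule)
    letter: str
    onset_s: float
    is_target: bool
    is_lure: bool


@dataclass
class TaskSchedule:
    trials: list[Trial]
    block_order: str
    cue_duration_s: float = 3.0
    stim_duration_s: float = 1.0
    response_window_s: float = 1.0
    fixation_duration_s: float = 25.0
    lead_in_s: float = 28.08  # 12 TRs at TR = 2.34 s

    @property
    def block_conditions(self) -> list[int]:
        base = BLOCK_ORDERS[self.block_order]
        return [base[b % len(base)] for b in range(N_BLOCKS)]

    @property
    def block_duration_s(self) -> float:
        trial_s = self.stim_duration_s + self.response_window_s
        return (
            self.cue_duration_s
            + TRIALS_PER_BLOCK * trial_s
            + self.fixation_duration_s
        )

    @property
    def duration_s(self) -> float:
        return self.lead_in_s + N_BLOCKS * self.block_duration_s

    def block_start_s(self, block: int) -> float:
        return self.lead_in_s + block * self.block_duration_s

    def condition_onsets(self, condition: int) -> np.ndarray:
        return np.array(
            [t.onset_s for t in self.trials if t.condition == condition]
        )

    def block_intervals(self) -> pd.DataFrame:
        """Cue+task interval of each block with its condition.

        The 25 s post-block fixation (and the lead-in) are the resting
        baseline; the cue is counted with its block's task epoch.
        """
        rows = []
        trial_s = self.stim_duration_s + self.response_window_s
        for b, cond in enumerate(self.block_conditions):
            start = self.block_start_s(b)
            end = start + self.cue_duration_s + TRIALS_PER_BLOCK * trial_s
            rows.append({"block": b, "condition": cond, "start_s": start, "end_s": end})
        return pd.DataFrame(rows)

    def to_events_frame(self) -> pd.DataFrame:
        """BIDS-like events table (onset, duration, trial_type, ...)."""
        return pd.DataFrame(
            {
                "onset": [t.onset_s for t in self.trials],
                "duration": self.stim_duration_s,
                "trial_type": [f"{t.condition}back" for t in self.trials],
                "letter": [t.letter for t in self.trials],
                "is_target": [int(t.is_target) for t in self.trials],
                "is_lure": [int(t.is_lure) for t in self.trials],
                "block": [t.block_index for t in self.trials],
            }
        )


def _lure_offsets(condition: int) -> tuple[int, ...]:
    return (2,) if condition == 1 else (2, 4)


def _generate_block_letters(
    condition: int,
    target_pos: set[int],
    lure_pos: dict[int, int],
    rng: np.random.Generator,
) -> list[str] | None:
    """Assign letters for one block; None if the draw is inconsistent."""
    n = condition
    seq: list[str] = []
    for i in range(TRIALS_PER_BLOCK):
        if i in target_pos:
            letter = seq[i - n]
        elif i in lure_pos:
            letter = seq[i - lure_pos[i]]
            if i >= n and letter == seq[i - n]:
                return None  # lure letter would double as a target match
        else:
            forbidden = set()
            if i >= n:
                forbidden.add(seq[i - n])
            for off in _lure_offsets(condition):
                if i >= off:
                    forbidden.add(seq[i - off])
            allowed = [c for c in LETTERS if c not in forbidden]
            letter = allowed[rng.integers(len(allowed))]
        seq.append(letter)
    return seq


def generate_task_schedule(
    order: str = "1-3-3-1",
    seed: int = 0,
    lead_in_s: float = 28.08,
    max_retries: int = 1000,
) -> TaskSchedule:
    """Generate a 12-block N-back schedule with exact target/lure counts.

    Every block carries 2 targets and 1 lure, giving 24/120 targets (20 %)
    and 12/96 lures (12.5 % of nontargets) in every schedule.  Nontarget
    letters are rejection-sampled so that no unflagged trial matches the
    block's n-back position or a lure offset; an inconsistent draw retries
    the block, and exhausting ``max_retries`` raises rather than silently
    relaxing the proportions.
    """
    if order not in BLOCK_ORDERS:
        raise ValueError(f"unknown block order {order!r}")
    rng = np.random.default_rng(seed)
    schedule = TaskSchedule(trials=[], block_order=order, lead_in_s=lead_in_s)
    conds = schedule.block_conditions
    trial_s = schedule.stim_duration_s + schedule.response_window_s

    trials: list[Trial] = []
    for b, cond in enumerate(conds):
        n = cond
        seq = None
        for _ in range(max_retries):
            # two targets at positions with enough history
            candidates = list(range(n, TRIALS_PER_BLOCK))
            t_pos = set(rng.choice(candidates, size=2, replace=False).tolist())
            # one lure with a randomly drawn offset valid at its position
            off = int(rng.choice(_lure_offsets(cond)))
            l_candidates = [
                i for i in range(off, TRIALS_PER_BLOCK) if i not in t_pos
            ]
            if not l_candidates:
                continue
            l_i = int(rng.choice(l_candidates))
            seq = _generate_block_letters(cond, t_pos, {l_i: off}, rng)
            if seq is not None:
                break
        if seq is None:
            raise ScheduleGenerationError(
                f"block {b}: no consistent letter assignment in "
                f"{max_retries} retries"
            )
        block_start = schedule.block_start_s(b)
        for i, letter in enumerate(seq):
            trials.append(
                Trial(
                    block_index=b,
                    condition=cond,
                    letter=letter,
                    onset_s=block_start + schedule.cue_duration_s + i * trial_s,
                    is_target=i in t_pos,
                    is_lure=i == l_i,
                )
            )
    schedule.trials = trials
    _validate_schedule(schedule)
    return schedule


def _validate_schedule(schedule: TaskSchedule) -> None:
    trials = schedule.trials
    if len(trials) != N_BLOCKS * TRIALS_PER_BLOCK:
        raise ScheduleGenerationError("wrong trial count")
    n_targets = sum(t.is_target for t in trials)
    n_nontargets = len(trials) - n_targets
    n_lures = sum(t.is_lure for t in trials)
    if n_targets != round(TARGET_FRACTION * len(trials)):
        raise ScheduleGenerationError("target proportion violated")
    if n_lures != round(LURE_FRACTION_OF_NONTARGETS * n_nontargets):
        raise ScheduleGenerationError("lure proportion violated")


@dataclass
class ResponseLog:
    """Per-trial button-press log; rt_s is NaN where no response occurred."""

    responded: np.ndarray
    rt_s: np.ndarray

    def __post_init__(self) -> None:
        self.responded = np.asarray(self.responded, dtype=bool)
        self.rt_s = np.asarray(self.rt_s, dtype=float)
        if self.responded.shape != self.rt_s.shape:
            raise ValueError("responded and rt_s must be aligned")
        if np.any(self.responded != np.isfinite(self.rt_s)):
            raise ValueError("rt_s must be present iff responded")
        valid = self.rt_s[self.responded]
        if valid.size and (np.any(valid <= 0) or np.any(valid > 2.0)):
            raise ValueError("rt_s must lie in (0, 2] s")


def simulate_responses(
    schedule: TaskSchedule,
    miss_prob: dict[int, float] | None = None,
    false_alarm_prob: float = 0.01,
    rt_mean: dict[int, float] | None = None,
    rt_sd: float = 0.15,
    seed: int = 0,
) -> ResponseLog:
    """Simulate a button-press log for a schedule.

    Defaults mirror near-ceiling 1-back and good-but-imperfect 3-back
    performance; reaction times are Gaussian, truncated to (0, 2] s.
    """
    miss_prob = miss_prob or {1: 0.01, 3: 0.10}
    rt_mean = rt_mean or {1: 0.76, 3: 0.99}
    rng = np.random.default_rng(seed)
    n = len(schedule.trials)
    responded = np.zeros(n, dtype=bool)
    rt = np.full(n, np.nan)
    for i, t in enumerate(schedule.trials):
        if t.is_target:
            hit = rng.random() >= miss_prob[t.condition]
        else:
            hit = rng.random() < false_alarm_prob
        if hit:
            responded[i] = True
            rt[i] = float(
                np.clip(rng.normal(rt_mean[t.condition], rt_sd), 0.05, 2.0)
            )
    return ResponseLog(responded=responded, rt_s=rt)


def score_behavior(
    schedule: TaskSchedule, responses: ResponseLog
) -> dict[int, dict[str, float]]:
    """Per-condition hit rate and mean RT for correct / incorrect responses.

    A correct response is a button press on a target; an incorrect response
    is a press on a nontarget (false alarm).  RT means are NaN when the
    relevant response set is empty.
    """
    if len(schedule.trials) != responses.responded.size:
        raise ValueError("response log does not align with schedule")
    out: dict[int, dict[str, float]] = {}
    for cond in (1, 3):
        idx = np.array([t.condition == cond for t in schedule.trials])
        is_target = np.array([t.is_target for t in schedule.trials])
        targets = idx & is_target
        hits = targets & responses.responded
        false_alarms = idx & ~is_target & responses.responded
        hit_rate = hits.sum() / targets.sum() if targets.any() else np.nan
        out[cond] = {
            "hit_rate": float(hit_rate),
            "mean_rt_correct": float(np.nanmean(responses.rt_s[hits]))
            if hits.any()
            else float("nan"),
            "mean_rt_incorrect": float(np.nanmean(responses.rt_s[false_alarms]))
            if false_alarms.any()
            else float("nan"),
        }
    return out
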