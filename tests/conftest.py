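import numpy as np
import pandas as pd
import pytest

from pagflat import pipeline
from pagflat.phantom import PhantomConfig, generate_phantom
from pagflat.task import generate_task_schedule


@pytest.fixture(scope="session")
def schedule():
    return generate_task_schedule(order="1-3-3-1", seed=7)


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom()


@pytest.fixture(scope="session")
def oblique_phantom():
    return generate_phantom(PhantomConfig(axis_obliquity_deg=12.0))


@pytest.fixture(scope="session")
def default_subject():
    """One simulated participant run through the whole pipeline."""
    return pipeline.run_subject(0, seed=42)


def nback_scan(schedule):
    """Brute-force n-back/lure scan of a schedule's letter sequence.

    Independent oracle: re-derives target and lure flags purely from the
    letter sequence and each block's rule (targets are n-back matches;
    lures are 2-back matches in 1-back blocks, 2-/4-back in 3-back
    blocks, and never targets).
    """
    from collections import defaultdict

    by_block = defaultdict(list)
    for t in schedule.trials:
        by_block[t.block_index].append(t)
    targets, lures = [], []
    for b in sorted(by_block):
        ts = by_block[b]
        n = ts[0].condition
        offsets = (2,) if n == 1 else (2, 4)
        for i, t in enumerate(ts):
            is_t = i >= n and t.letter == ts[i - n].letter
            is_l = (not is_t) and any(
                i >= o and t.letter == ts[i - o].letter for o in offsets
            )
            targets.append(is_t)
            lures.append(is_l)
    return np.array(targets), np.array(lures)


def make_null_rank_table(n_subjects, seed, re_sd=0.1, noise_sd=0.1,
                         effects=None):
    """Rank table from a known generating model (zero fixed effects by
    default), with uncorrelated by-subject random intercept + slopes."""
    effects = np.zeros(8) if effects is None else np.asarray(effects, float)
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0, re_sd, 8)
        for cond in (1, 3):
            c = 0.5 if cond == 3 else -0.5
            for rc in range(1, 5):
                rcc = rc - 2.5
                for dg in range(1, 11):
                    dgc = dg - 5.5
                    x = np.array([1, c, rcc, dgc, c * rcc, c * dgc,
                                  rcc * dgc, c * rcc * dgc])
                    rows.append({
                        "subject": s, "condition": cond, "rc_rank": rc,
                        "degree_rank": dg,
                        "mean_beta": float(x @ (u + effects)
                                           + rng.normal(0, noise_sd)),
                        "n_voxels": 10,
                    })
    return pd.DataFrame(rows)
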