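"""Group-level topography: rank table, mixed model, correlations.

Subject beta maps are averaged within 4 rostral-caudal x 10 bilateral
degree ranks (40 cells per subject per condition) and submitted to a
linear mixed-effects model::

    mean_beta ~ condition * rc * degree + (condition * rc * degree | subject)

with rc and degree entered as centered numeric rank scores (so each
fixed effect carries 1 numerator df) and condition coded -1/2, +1/2.
The model is fit by REML (statsmodels MixedLM); when the full
random-slope covariance does not converge it falls back to uncorrelated
slopes, then to a random intercept only, recording which structure was
used.  F statistics are squared t ratios with a between-subject
denominator df of n_subjects - 1.

Voxelwise condition maps are compared by Pearson correlation with a
10,000-resample bootstrap percentile CI, and per-voxel between-subject
correlations link task betas to physiological change scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

N_RC_RANKS = 4
N_DEG_RANKS = 10

FIXED_EFFECTS = [
    "condition",
    "rc",
    "degree",
    "condition:rc",
    "condition:degree",
    "rc:degree",
    "condition:rc:degree",
]


@dataclass
class MixedModelResult:
    fixed_effects: pd.DataFrame  # index: effect; estimate, se, F, df, p
    converged: bool
    random_structure: str  # "full" | "uncorrelated" | "intercept"
    df_method: str


@dataclass
class CorrelationResult:
    r: float
    ci95: tuple[float, float]
    n: int


def bin_rank_table(
    beta_maps: dict[int, np.ndarray],
    coords,
    subject: int | str = 0,
) -> pd.DataFrame:
    """Average one subject's per-voxel betas into rank cells.

    ``beta_maps`` maps condition (1, 3) to per-voxel beta arrays aligned
    with ``coords``; only retained voxels contribute.  Returns rows
    (subject, condition, rc_rank, degree_rank, mean_beta, n_voxels), at
    most 40 cells per condition.
    """
    if coords.rc_rank is None:
        raise ValueError("coords must carry rank labels (run assign_ranks)")
    ret = coords.retained
    if ret is None or not ret.any():
        raise ValueError("subject has no retained voxels")
    rows = []
    for cond, betas in beta_maps.items():
        betas = np.asarray(betas, dtype=float)
        if betas.shape[0] != len(coords):
            raise ValueError("one beta per voxel is required")
        df = pd.DataFrame(
            {
                "rc_rank": coords.rc_rank[ret],
                "degree_rank": coords.degree_rank[ret],
                "beta": betas[ret],
            }
        )
        g = df.groupby(["rc_rank", "degree_rank"])["beta"].agg(["mean", "size"])
        for (rc, deg), row in g.iterrows():
            rows.append(
                {
                    "subject": subject,
                    "condition": int(cond),
                    "rc_rank": int(rc),
                    "degree_rank": int(deg),
                    "mean_beta": float(row["mean"]),
                    "n_voxels": int(row["size"]),
                }
            )
    if not rows:
        raise ValueError("all rank cells empty for this subject")
    return pd.DataFrame(rows)


def _prepare_model_frame(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    df["condition"] = np.where(df["condition"] == 3, 0.5, -0.5)
    df["rc"] = df["rc_rank"] - df["rc_rank"].mean()
    df["degree"] = df["degree_rank"] - df["degree_rank"].mean()
    return df


_FE_FORMULA = "mean_beta ~ condition * rc * degree"
_RE_TERMS = ["condition", "rc", "degree", "condition:rc",
             "condition:degree", "rc:degree", "condition:rc:degree"]


def _fit_structure(df: pd.DataFrame, structure: str):
    kwargs = {"groups": df["subject"]}
    if structure == "full":
        kwargs["re_formula"] = "1 + " + " + ".join(_RE_TERMS)
    elif structure == "uncorrelated":
        kwargs["re_formula"] = "1"
        kwargs["vc_formula"] = {t.replace(":", "_"): f"0 + {t}" for t in _RE_TERMS}
    elif structure == "intercept":
        kwargs["re_formula"] = "1"
    else:
        raise ValueError(f"unknown random structure {structure!r}")
    model = smf.mixedlm(_FE_FORMULA, df, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, method="lbfgs", maxiter=200)
    return fit


def fit_mixed_model(
    table: pd.DataFrame,
    random_structure: str = "auto",
) -> MixedModelResult:
    """Fit the condition x rostral-caudal x degree mixed-effects model.

    Requires >= 5 subjects and both conditions.  ``random_structure``
    may be "auto" (full -> uncorrelated -> intercept fallback on
    non-convergence), or one of those names directly.
    """
    n_subjects = table["subject"].nunique()
    if n_subjects < 5:
        raise ValueError("need at least 5 subjects")
    if set(table["condition"].unique()) != {1, 3}:
        raise ValueError("both conditions (1-back, 3-back) must be present")
    df = _prepare_model_frame(table)

    order = (
        ["full", "uncorrelated", "intercept"]
        if random_structure == "auto"
        else [random_structure, "uncorrelated", "intercept"]
    )
    # drop duplicates while preserving order
    order = list(dict.fromkeys(order))
    fit = None
    used = None
    for structure in order:
        try:
            fit = _fit_structure(df, structure)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if fit.converged:
            used = structure
            break
        fit = None
    if fit is None:
        raise RuntimeError("mixed model failed to converge under any structure")

    ddf = n_subjects - 1
    rows = []
    for name in ["Intercept"] + FIXED_EFFECTS:
        est = fit.fe_params[name]
        se = fit.bse_fe[name]
        tval = est / se
        p = 2 * stats.t.sf(abs(tval), ddf)
        rows.append(
            {
                "effect": name,
                "estimate": float(est),
                "se": float(se),
                "F": float(tval**2),
                "df_num": 1,
                "df_den": int(ddf),
                "p": float(max(p, np.finfo(float).tiny)),
            }
        )
    fe = pd.DataFrame(rows).set_index("effect")
    return MixedModelResult(
        fixed_effects=fe,
        converged=bool(fit.converged),
        random_structure=used,
        df_method="between-subject (n_subjects - 1)",
    )


def correlate_condition_maps(
    map_a: np.ndarray,
    map_b: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson r between two voxel maps with a bootstrap percentile CI.

    Voxel pairs are resampled with replacement ``n_boot`` times;
    deterministic given the seed.  NaN voxels (in either map) are
    dropped first.
    """
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must have equal voxel sets")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 voxels")
    r = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(5e6 / max(n, 1))))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        xa, xb = a[idx], b[idx]
        xa = xa - xa.mean(axis=1, keepdims=True)
        xb = xb - xb.mean(axis=1, keepdims=True)
        num = (xa * xb).sum(axis=1)
        den = np.sqrt((xa**2).sum(axis=1) * (xb**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            boots[done:done + m] = np.where(den > 0, num / den, np.nan)
        done += m
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return CorrelationResult(r=r, ci95=(float(lo), float(hi)), n=int(n))


def correlate_physio_with_betas(
    beta_per_subject: np.ndarray,
    physio_delta_per_subject: np.ndarray,
) -> np.ndarray:
    """Between-subject Pearson r at each voxel/cell.

    ``beta_per_subject`` is (n_subjects, ...) and the physiological
    change scores are per subject.  Voxels where either variable has
    zero variance (or fewer than 3 finite pairs) are NaN — flagged
    missing, never zero.
    """
    b = np.asarray(beta_per_subject, dtype=float)
    d = np.asarray(physio_delta_per_subject, dtype=float)
    if b.shape[0] != d.shape[0]:
        raise ValueError("subjects must match between betas and physiology")
    if b.shape[0] < 3:
        raise ValueError("need at least 3 matched subjects")
    flat = b.reshape(b.shape[0], -1)
    out = np.full(flat.shape[1], np.nan)
    finite_d = np.isfinite(d)
    for j in range(flat.shape[1]):
        ok = np.isfinite(flat[:, j]) & finite_d
        if ok.sum() < 3:
            continue
        x, y = flat[ok, j], d[ok]
        if x.std() == 0 or y.std() == 0:
            continue
        out[j] = np.corrcoef(x, y)[0, 1]
    return out.reshape(b.shape[1:])


def group_level_map(subject_maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cellwise one-sample t across subjects converted to z.

    Returns (z, flagged); flagged cells have zero across-subject
    variance (infinite t) and are NaN in z rather than capped.
    """
    from .glm import group_zmap

    return group_zmap(subject_maps)
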