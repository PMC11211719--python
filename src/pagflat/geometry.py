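"""Cylindrical parameterization and flattening of the PAG shell.

The hollow PAG mask is reduced to per-voxel cylindrical coordinates:

* ``rc_mm`` — projection of the voxel center on the longitudinal
  (rostral-caudal) axis, estimated as the first principal component of
  the shell's world-mm coordinates, shifted so 0 sits at the caudal pole;
* ``degree_deg`` — signed angle of the radial vector around the axis,
  0 deg at the dorsomedial reference (posterior, world -y, projected
  into the plane orthogonal to the axis), right hemisphere positive,
  range (-180, 180];
* ``radius_mm`` — distance from the axis.

The ventral-most 90 deg (|degree| > 135) is excluded, rostral-caudal
position is split into 4 equal ranks and |degree| into 10 bilateral
13.5 deg ranks, and values can be gridded onto 2D (rc x degree) flat
maps per 1 mm radial bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_KEEP_ABS_DEGREE = 135.0
ROSTRAL_HINT = np.array([0.0, 1.0, 1.0]) / np.sqrt(2.0)  # anterior-superior
DORSAL_REFERENCE = np.array([0.0, -1.0, 0.0])  # posterior (world -y)


@dataclass
class PagVoxelCoordinates:
    """Per-voxel cylindrical coordinates and rank labels of a PAG shell."""

    ijk: np.ndarray  # (n, 3) voxel indices
    world: np.ndarray  # (n, 3) world mm
    rc_mm: np.ndarray
    degree_deg: np.ndarray
    radius_mm: np.ndarray
    origin: np.ndarray
    axis: np.ndarray
    retained: np.ndarray | None = None
    rc_rank: np.ndarray | None = None  # 1..n_rc on retained voxels, 0 elsewhere
    degree_rank: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.rc_mm)

    @property
    def rc_norm(self) -> np.ndarray:
        """rc scaled to [0, 1] over the observed range (caudal -> rostral)."""
        span = self.rc_mm.max() - self.rc_mm.min()
        if span == 0:
            return np.zeros_like(self.rc_mm)
        return (self.rc_mm - self.rc_mm.min()) / span

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "i": self.ijk[:, 0],
                "j": self.ijk[:, 1],
                "k": self.ijk[:, 2],
                "x_mm": self.world[:, 0],
                "y_mm": self.world[:, 1],
                "z_mm": self.world[:, 2],
                "rc_mm": self.rc_mm,
                "degree_deg": self.degree_deg,
                "radius_mm": self.radius_mm,
            }
        )
        if self.retained is not None:
            df["retained"] = self.retained.astype(int)
        if self.rc_rank is not None:
            df["rc_rank"] = self.rc_rank
            df["degree_rank"] = self.degree_rank
        return df


def signed_degree(radial_vec: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Signed angle (deg) of radial vectors around ``axis``.

    0 deg at the dorsal reference (projection of world -y into the plane
    orthogonal to the axis); right-lateral displacements positive; range
    (-180, 180].  Vectors on the axis map to 0 deg.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    dorsal = DORSAL_REFERENCE - (DORSAL_REFERENCE @ axis) * axis
    norm = np.linalg.norm(dorsal)
    if norm < 1e-12:
        raise ValueError("axis is parallel to the dorsal reference direction")
    dorsal /= norm
    lateral = np.cross(axis, dorsal)  # +90 deg lands right-lateral (+x)
    v = np.atleast_2d(radial_vec)
    deg = np.degrees(np.arctan2(v @ lateral, v @ dorsal))
    deg = np.where(deg <= -180.0, deg + 360.0, deg)
    if np.ndim(radial_vec) == 1:
        return float(deg[0])
    return deg


def fit_longitudinal_axis(
    shell_mask: np.ndarray,
    affine: np.ndarray,
    rostral_hint: np.ndarray = ROSTRAL_HINT,
) -> tuple[np.ndarray, np.ndarray]:
    """First principal component of shell voxel world coordinates.

    Returns (origin, unit axis); the origin is the centroid and the axis
    sign is flipped so it projects positively onto ``rostral_hint`` (the
    anterior-superior diagonal by default, the rostral direction for the
    midbrain aqueduct).  Raises on fewer than 10 voxels or a degenerate
    (rank < 2) coordinate covariance.
    """
    ijk = np.argwhere(shell_mask)
    if len(ijk) < 10:
        raise ValueError("shell mask has fewer than 10 voxels")
    world = (affine @ np.c_[ijk, np.ones(len(ijk))].T).T[:, :3]
    centered = world - world.mean(axis=0)
    cov = centered.T @ cov_safe(centered)
    eigval, eigvec = np.linalg.eigh(cov)
    if np.sum(eigval > 1e-9 * eigval.max()) < 2:
        raise ValueError("degenerate voxel covariance (rank < 2)")
    axis = eigvec[:, -1]
    if axis @ rostral_hint < 0:
        axis = -axis
    return world.mean(axis=0), axis


def cov_safe(centered: np.ndarray) -> np.ndarray:
    return centered / max(len(centered) - 1, 1)


def compute_cylindrical_coords(
    shell_mask: np.ndarray,
    affine: np.ndarray,
    origin: np.ndarray,
    axis: np.ndarray,
) -> PagVoxelCoordinates:
    """Cylindrical coordinates of every shell voxel.

    rc is shifted so its minimum is 0 (caudal pole).  A voxel exactly on
    the axis has undefined angle; it is assigned radius 0 / degree 0 with
    a warning.
    """
    axis = np.asarray(axis, dtype=float)
    if not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-8):
        raise ValueError("axis must be unit length")
    ijk = np.argwhere(shell_mask)
    world = (affine @ np.c_[ijk, np.ones(len(ijk))].T).T[:, :3]
    rel = world - np.asarray(origin, dtype=float)
    rc = rel @ axis
    radial_vec = rel - np.outer(rc, axis)
    radius = np.linalg.norm(radial_vec, axis=1)
    on_axis = radius < 1e-9
    if on_axis.any():
        warnings.warn(
            f"{int(on_axis.sum())} voxel(s) lie exactly on the axis; "
            "degree set to 0",
            stacklevel=2,
        )
    degree = np.zeros(len(rc))
    if (~on_axis).any():
        degree[~on_axis] = signed_degree(radial_vec[~on_axis], axis)
    return PagVoxelCoordinates(
        ijk=ijk,
        world=world,
        rc_mm=rc - rc.min(),
        degree_deg=degree,
        radius_mm=radius,
        origin=np.asarray(origin, dtype=float),
        axis=axis,
    )


def reconstruct_world(coords: PagVoxelCoordinates) -> np.ndarray:
    """Invert (rc, degree, radius) back to world mm (round-trip check)."""
    axis = coords.axis
    dorsal = DORSAL_REFERENCE - (DORSAL_REFERENCE @ axis) * axis
    dorsal /= np.linalg.norm(dorsal)
    lateral = np.cross(axis, dorsal)
    rel = coords.world - coords.origin
    rc_offset = (rel @ axis).min()  # rc_mm was shifted so min = 0
    ang = np.radians(coords.degree_deg)
    radial = coords.radius_mm[:, None] * (
        np.cos(ang)[:, None] * dorsal + np.sin(ang)[:, None] * lateral
    )
    return (
        coords.origin
        + np.outer(coords.rc_mm + rc_offset, axis)
        + radial
    )


def apply_ventral_exclusion(
    coords: PagVoxelCoordinates,
    keep_abs_degree_max: float = DEFAULT_KEEP_ABS_DEGREE,
) -> PagVoxelCoordinates:
    """Flag retained voxels: |degree| <= 135 deg (closed bound).

    The excluded ventral sector spans 90 deg and contains non-PAG
    structures (e.g., the dorsal raphe).
    """
    coords.retained = np.abs(coords.degree_deg) <= keep_abs_degree_max
    return coords


def assign_ranks(
    coords: PagVoxelCoordinates,
    n_rc: int = 4,
    n_deg: int = 10,
    keep_abs_degree_max: float = DEFAULT_KEEP_ABS_DEGREE,
) -> PagVoxelCoordinates:
    """Equal-width rostral-caudal and bilateral |degree| ranks.

    rc ranks partition the observed rc range of retained voxels into
    ``n_rc`` half-open segments (last closed); degree ranks partition
    |degree| over [0, 135] into ``n_deg`` bins of 13.5 deg, shared
    between hemispheres.  Ranks are 1-based; non-retained voxels get 0.
    Empty bins warn but are not an error.
    """
    if coords.retained is None:
        apply_ventral_exclusion(coords, keep_abs_degree_max)
    ret = coords.retained
    rc_rank = np.zeros(len(coords), dtype=int)
    deg_rank = np.zeros(len(coords), dtype=int)
    rc = coords.rc_mm[ret]
    lo, hi = rc.min(), rc.max()
    width = (hi - lo) / n_rc if hi > lo else 1.0
    r = np.minimum((rc - lo) // width, n_rc - 1).astype(int) + 1
    rc_rank[ret] = r
    dwidth = keep_abs_degree_max / n_deg
    d = np.minimum(np.abs(coords.degree_deg[ret]) // dwidth, n_deg - 1).astype(int) + 1
    deg_rank[ret] = d
    for name, ranks, n in (("rc", r, n_rc), ("degree", d, n_deg)):
        missing = set(range(1, n + 1)) - set(np.unique(ranks).tolist())
        if missing:
            warnings.warn(f"empty {name} rank bin(s): {sorted(missing)}", stacklevel=2)
    coords.rc_rank = rc_rank
    coords.degree_rank = deg_rank
    return coords


def flatten(
    coords: PagVoxelCoordinates,
    values: np.ndarray,
    radial_bins: np.ndarray | list[float] = (0.0, 1.0, 2.0, 3.0, 4.0),
    n_rc_cells: int = 14,
    n_deg_cells: int = 27,
    keep_abs_degree_max: float = DEFAULT_KEEP_ABS_DEGREE,
) -> dict[tuple[float, float], dict[str, np.ndarray]]:
    """Grid retained-voxel values onto (rc x signed-degree) flat maps.

    One map per radial annulus (default 1 mm bins, 0-4 mm).  Each cell
    averages its contributing voxels; empty cells are NaN.  Returns
    ``{(r_lo, r_hi): {"mean": 2D array, "count": 2D array}}`` with rc on
    axis 0 (caudal -> rostral) and signed degree on axis 1.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(coords):
        raise ValueError("one value per voxel is required")
    if coords.retained is None:
        apply_ventral_exclusion(coords, keep_abs_degree_max)
    ret = coords.retained
    rc = coords.rc_mm[ret]
    deg = coords.degree_deg[ret]
    rad = coords.radius_mm[ret]
    val = values[ret]

    lo, hi = rc.min(), rc.max()
    rc_width = (hi - lo) / n_rc_cells if hi > lo else 1.0
    rc_idx = np.minimum((rc - lo) // rc_width, n_rc_cells - 1).astype(int)
    dspan = 2 * keep_abs_degree_max
    d_idx = np.minimum(
        (deg + keep_abs_degree_max) // (dspan / n_deg_cells), n_deg_cells - 1
    ).astype(int)

    edges = np.asarray(radial_bins, dtype=float)
    maps: dict[tuple[float, float], dict[str, np.ndarray]] = {}
    for r_lo, r_hi in zip(edges[:-1], edges[1:]):
        sel = (rad >= r_lo) & (rad < r_hi)
        if r_hi == edges[-1]:
            sel = (rad >= r_lo) & (rad <= r_hi)
        total = np.zeros((n_rc_cells, n_deg_cells))
        count = np.zeros((n_rc_cells, n_deg_cells))
        np.add.at(total, (rc_idx[sel], d_idx[sel]), val[sel])
        np.add.at(count, (rc_idx[sel], d_idx[sel]), 1.0)
        with np.errstate(invalid="ignore"):
            mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        maps[(float(r_lo), float(r_hi))] = {"mean": mean, "count": count}
    return maps


def parameterize_shell(
    shell_mask: np.ndarray,
    affine: np.ndarray,
    n_rc: int = 4,
    n_deg: int = 10,
    keep_abs_degree_max: float = DEFAULT_KEEP_ABS_DEGREE,
    rostral_hint: np.ndarray = ROSTRAL_HINT,
) -> PagVoxelCoordinates:
    """Full geometry pass: axis fit, coordinates, exclusion, ranks."""
    origin, axis = fit_longitudinal_axis(shell_mask, affine, rostral_hint)
    coords = compute_cylindrical_coords(shell_mask, affine, origin, axis)
    apply_ventral_exclusion(coords, keep_abs_degree_max)
    assign_ranks(coords, n_rc=n_rc, n_deg=n_deg,
                 keep_abs_degree_max=keep_abs_degree_max)
    return coords
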