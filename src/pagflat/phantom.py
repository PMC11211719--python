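"""Midbrain phantom: aqueduct tube, hollow PAG shell, and ground truth.

The phantom is a small 1.1 mm isotropic grid holding a straight
CSF-filled tube (the cerebral aqueduct) surrounded by a hollow
gray-matter shell (the PAG).  The per-voxel ground-truth task effect on
the shell follows the topography the analysis is designed to detect: a
linear increase along the rostral-caudal axis and with absolute radial
degree, plus their interaction, scaled per condition so the moderate
(3-back) load amplifies the mild (1-back) pattern::

    beta(rc, theta) = s_cond * (b0 + b_rc*rc~ + b_deg*|theta~| + b_int*rc~*|theta~|)

with rc~ and |theta~| normalized to [0, 1], 0 deg at the dorsomedial
reference and bilateral symmetry in |theta|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import signed_degree


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size_mm: float = 1.1
    tube_length_mm: float = 14.0
    aqueduct_radius_mm: float = 1.2
    shell_thickness_mm: float = 3.0  # shell voxels stay within 3.3 mm of tube
    axis_obliquity_deg: float = 0.0  # tilt of the long axis about x, toward +y
    # effect coefficients for the 1-back condition, arbitrary units
    b0: float = 0.1
    b_rc: float = 0.5
    b_deg: float = 0.4
    b_int: float = 0.3
    condition_scale: dict[int, float] = field(
        default_factory=lambda: {1: 1.0, 3: 2.0}
    )
    # world position of the grid center (keeps the tube in the midbrain box)
    center_world_mm: tuple[float, float, float] = (0.0, -32.0, -2.0)
    ibi_epoch_means_s: dict[str, float] = field(
        default_factory=lambda: {"fixation": 0.90, "1back": 0.93, "3back": 0.87}
    )
    rr_epoch_means_bpm: dict[str, float] = field(
        default_factory=lambda: {"fixation": 14.0, "1back": 15.0, "3back": 16.5}
    )


@dataclass
class Phantom:
    config: PhantomConfig
    affine: np.ndarray
    aqueduct_mask: np.ndarray
    pag_truth_mask: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    truth_axis: np.ndarray
    truth_origin: np.ndarray
    truth_effect: dict[int, np.ndarray]  # condition -> per-voxel beta volume

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.aqueduct_mask.shape

    def world_coords(self, mask: np.ndarray) -> np.ndarray:
        """World-mm coordinates (n, 3) of voxel centers inside ``mask``."""
        ijk = np.argwhere(mask)
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ hom.T).T[:, :3]


def _rotation_about_x(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def generate_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Build the aqueduct/PAG phantom with its ground-truth effect maps.

    The tube runs through the grid center along +z, optionally tilted
    about x by ``axis_obliquity_deg``.  Raises if the shell would be
    thinner than one voxel.
    """
    cfg = config or PhantomConfig()
    if cfg.shell_thickness_mm < cfg.voxel_size_mm:
        raise ValueError("PAG shell must be at least one voxel thick")

    shape = tuple(cfg.shape)
    vs = cfg.voxel_size_mm
    affine = np.eye(4)
    affine[:3, :3] = np.diag([vs, vs, vs])
    center_ijk = (np.array(shape) - 1) / 2.0
    affine[:3, 3] = np.array(cfg.center_world_mm) - vs * center_ijk

    axis = _rotation_about_x(cfg.axis_obliquity_deg) @ np.array([0.0, 0.0, 1.0])
    axis /= np.linalg.norm(axis)
    origin = np.array(cfg.center_world_mm)

    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = vox * vs + affine[:3, 3]
    rel = world - origin
    axial = rel @ axis  # signed mm along the tube axis
    radial_vec = rel - np.outer(axial, axis)
    radial = np.linalg.norm(radial_vec, axis=1)

    half_len = cfg.tube_length_mm / 2.0
    in_length = np.abs(axial) <= half_len
    aqueduct = (radial <= cfg.aqueduct_radius_mm) & in_length
    outer = cfg.aqueduct_radius_mm + cfg.shell_thickness_mm
    shell = (radial > cfg.aqueduct_radius_mm) & (radial <= outer) & in_length

    aqueduct_mask = aqueduct.reshape(shape)
    shell_mask = shell.reshape(shape)

    gm = shell_mask.astype(float)
    csf = aqueduct_mask.astype(float)
    wm = np.clip(1.0 - gm - csf, 0.0, 1.0)

    # normalized cylindrical coordinates for the truth topography
    rc_norm = (axial + half_len) / cfg.tube_length_mm  # 0 caudal, 1 rostral
    degree = signed_degree(radial_vec, axis)
    deg_norm = np.abs(degree) / 180.0

    base = (
        cfg.b0
        + cfg.b_rc * rc_norm
        + cfg.b_deg * deg_norm
        + cfg.b_int * rc_norm * deg_norm
    )
    truth_effect = {}
    for cond, scale in cfg.condition_scale.items():
        vol = np.zeros(shape)
        vol.reshape(-1)[shell] = scale * base[shell]
        truth_effect[cond] = vol

    return Phantom(
        config=cfg,
        affine=affine,
        aqueduct_mask=aqueduct_mask,
        pag_truth_mask=shell_mask,
        gm=gm,
        wm=wm,
        csf=csf,
        truth_axis=axis,
        truth_origin=origin,
        truth_effect=truth_effect,
    )
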