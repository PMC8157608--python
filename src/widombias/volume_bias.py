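"""Two-level volume-detection bias with detailed translation/rotation averaging.

The configuration box is meshed into N x N x N cubic cells.  Each cell is
screened at its centre with a detection (B-) particle sharing the probe's
geometry:

* level one — the minimum distance between the probe placed at the centre
  (body-frame orientation) and any system atom must be strictly greater
  than ``d_min`` (default 1 A);
* level two — the Boltzmann factor of the real (A-) probe at the centre
  must be strictly greater than ``b_threshold`` (default 100).

Cells passing both levels are investigated further with the detailed
average: the probe is translated along 14 directions (the 6 face and 8
normalised corner vectors of the cell) by D/3 when the centre factor lies
below 10^4 and by D/4 at or above it, and at each translated point
evaluated in 17 orientations (90/180/270 degrees about the axes, 120/240
degrees about the body diagonals), 238 poses in all.

N_fv counts the free-volume (level-one) cells.  Every free cell
contributes to the estimate — the detailed average where level two
passed, the already-computed centre factor where it did not — and
level-one failures contribute nothing, which the free-volume fraction
corrects for:

    mu_ex = -k_B T ln[ (N_fv / N) * < w >_(free cells) ],
    w = detailed average  (centre factor > b_threshold)
      = centre factor     (otherwise).

With both criteria disabled this is a grid quadrature of the unbiased
average; the threshold concentrates the expensive pose stencil on the
cells that dominate the Boltzmann weight.  The biased path contains no
randomness: a fixed ensemble and criterion give a bit-identical estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import (Configuration, ForceField, MoleculeTemplate, Pose,
                    ThermoState, rotation_from_axis_angle)
from .config_gen import EnsembleSample
from .widom import (ConvergenceTrace, WidomEstimate,
                    estimate_from_config_means, insertion_boltzmann_batch,
                    random_rotations)


def translation_directions() -> np.ndarray:
    """The 14 unit translation directions: 6 faces + 8 normalised corners."""
    dirs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    corners = [(sx, sy, sz) for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)]
    out = np.array(dirs + corners, dtype=float)
    out[6:] /= math.sqrt(3.0)
    return out


def rotation_set() -> np.ndarray:
    """The 17 detail rotations: 90/180/270 deg about x, y, z plus 120/240 deg
    about the four body diagonals."""
    mats = []
    for axis in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
        for deg in (90, 180, 270):
            mats.append(rotation_from_axis_angle(axis, math.radians(deg)))
    for axis in ((1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)):
        for deg in (120, 240):
            mats.append(rotation_from_axis_angle(axis, math.radians(deg)))
    return np.array(mats)


@dataclass(frozen=True)
class CriterionConfig:
    """Thresholds and pose stencil of the two-level criterion.

    ``detail_bracket`` are the Boltzmann-factor brackets selecting the
    translation step: ``step_fractions[0] * D`` below the upper bracket,
    ``step_fractions[1] * D`` at or above it.  ``detection_probe`` optionally
    replaces the probe geometry for the level-one distance check (a virtual
    B-particle); the default uses the A-particle itself.
    ``detail_mode`` is ``"stencil"`` (deterministic 14 x 17 pose set) or
    ``"uniform"`` (``n_uniform`` random poses per accepted cell, used to
    cross-check the stencil against plain volume sampling).
    """

    d_min: float = 1.0
    b_threshold: float = 100.0
    detail_bracket: tuple[float, float] = (100.0, 10000.0)
    step_fractions: tuple[float, float] = (1.0 / 3.0, 1.0 / 4.0)
    include_center: bool = False
    detail_mode: str = "stencil"
    n_uniform: int = 238
    detection_probe: MoleculeTemplate | None = None
    translation_directions: np.ndarray = field(
        default_factory=translation_directions)
    rotation_set: np.ndarray = field(default_factory=rotation_set)

    def __post_init__(self) -> None:
        if self.d_min < 0 or self.b_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0 < self.step_fractions[0] < 0.5
                and 0 < self.step_fractions[1] < 0.5):
            raise ValueError("step fractions must lie in (0, 1/2)")
        if self.detail_mode not in ("stencil", "uniform"):
            raise ValueError("detail_mode must be 'stencil' or 'uniform'")
        dirs = np.asarray(self.translation_directions, float)
        if dirs.shape != (14, 3) or len({tuple(np.round(d, 12)) for d in dirs}) != 14:
            raise ValueError("translation set must hold 14 distinct directions")
        rots = np.asarray(self.rotation_set, float)
        if rots.shape != (17, 3, 3):
            raise ValueError("rotation set must hold 17 rotations")


@dataclass
class DetectionGrid:
    """Uniform cubic mesh over one configuration with per-cell state.

    ``status`` (flattened, C order over i, j, k) distinguishes level-one
    failures (0, overlapping), free cells whose centre factor stayed at or
    below the threshold (1) and cells accepted for the detailed average
    (2).  ``n_fv`` counts the free-volume cells (level one passed).
    """

    n_per_side: int
    cell_edge: float
    box: np.ndarray
    status: np.ndarray | None = None
    b_center: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.n_per_side ** 3

    @property
    def cell_volume(self) -> float:
        return self.cell_edge ** 3

    def _require_screened(self) -> np.ndarray:
        if self.status is None:
            raise ValueError("grid has not been screened yet")
        return self.status

    @property
    def free(self) -> np.ndarray:
        """Level-one pass mask (the free volume)."""
        return self._require_screened() >= 1

    @property
    def accepted(self) -> np.ndarray:
        """Mask of cells that receive the detailed average (both levels)."""
        return self._require_screened() == 2

    @property
    def n_fv(self) -> int:
        return int(np.count_nonzero(self.free))

    @property
    def n_detailed(self) -> int:
        return int(np.count_nonzero(self.accepted))

    @property
    def free_fraction(self) -> float:
        return self.n_fv / self.n_cells

    @property
    def accepted_fraction(self) -> float:
        return self.n_detailed / self.n_cells

    @property
    def v_fv(self) -> float:
        return self.n_fv * self.cell_volume

    def cell_center(self, i: int, j: int, k: int) -> np.ndarray:
        return (np.array([i, j, k]) + 0.5) * self.cell_edge

    def accepted_centers(self) -> np.ndarray:
        idx = np.flatnonzero(self.accepted)
        ijk = np.stack(np.unravel_index(idx, (self.n_per_side,) * 3), axis=1)
        return (ijk + 0.5) * self.cell_edge


def mesh_grid(config: Configuration, n_per_side: int) -> DetectionGrid:
    """Mesh a cubic configuration into n x n x n cells (centres at
    ((i+1/2) D, ...)); cells start undecided."""
    if n_per_side < 1:
        raise ValueError("n_per_side must be >= 1")
    box = config.box
    if not np.allclose(box, box[0], rtol=1e-9):
        raise ValueError("non-cubic box: a cubic mesh needs a cubic box "
                         "(use a per-axis mesh instead)")
    return DetectionGrid(n_per_side, float(box[0]) / n_per_side, box.copy())


def _detection_template(probe: MoleculeTemplate,
                        criterion: CriterionConfig) -> MoleculeTemplate:
    return criterion.detection_probe or probe


def first_level_check(config: Configuration, cell_center, probe: MoleculeTemplate,
                      d_min: float) -> bool:
    """Pass iff the minimum probe-site-to-system-site minimum-image distance
    is strictly greater than ``d_min`` (probe at body-frame orientation)."""
    if config.n_sites == 0:
        return True
    ppos = np.asarray(cell_center, float) + probe.body_coords
    dmin = _kernels.min_distance_kernel(
        np.ascontiguousarray(ppos), config.site_positions, config.box)
    return bool(dmin > d_min)


def second_level_check(config: Configuration, cell_center,
                       probe: MoleculeTemplate, ff: ForceField,
                       state: ThermoState,
                       b_threshold: float) -> tuple[bool, float]:
    """Boltzmann factor of the probe at the cell centre (body-frame
    orientation); pass iff strictly greater than ``b_threshold``.  A
    disabled threshold (<= 0) rejects only hard overlaps (infinite centre
    energy), never finite-energy centres whose factor underflows."""
    from .model import insertion_energy
    rec = insertion_energy(config, probe, Pose(np.asarray(cell_center, float)),
                           ff, state)
    if b_threshold <= 0.0:
        passed = math.isfinite(rec.delta_u)
    else:
        passed = rec.boltzmann > b_threshold
    return passed, rec.boltzmann


def detail_poses(center, cell_edge: float, b_center: float,
                 criterion: CriterionConfig) -> list[Pose]:
    """The detailed-average pose stencil for one accepted cell (238 poses;
    239 when the centre pose is included)."""
    center = np.asarray(center, float)
    lo, hi = criterion.step_fractions
    step = cell_edge * (hi if b_center >= criterion.detail_bracket[1] else lo)
    poses = []
    if criterion.include_center:
        poses.append(Pose(center))
    for direction in criterion.translation_directions:
        point = center + step * np.asarray(direction, float)
        for rot in criterion.rotation_set:
            poses.append(Pose(point, rot))
    return poses


def _screen_config(config: Configuration, probe: MoleculeTemplate,
                   ff: ForceField, state: ThermoState, n_per_side: int,
                   criterion: CriterionConfig) -> DetectionGrid:
    grid = mesh_grid(config, n_per_side)
    det = _detection_template(probe, criterion)
    pos, sig, eps, chg, mol = config.site_arrays()
    status = np.empty(grid.n_cells, dtype=np.int64)
    b_center = np.empty(grid.n_cells)
    _kernels.grid_screen_kernel(
        n_per_side, grid.cell_edge, np.asarray(det.body_coords, float),
        probe.sigmas, probe.epsilons, probe.charges,
        pos, sig, eps, chg, mol, config.molecule_centroids,
        config.box, ff.r_cut,
        ff.style_code, ff.coulomb_code, state.beta,
        criterion.d_min, criterion.b_threshold, status, b_center)
    grid.status = status
    grid.b_center = b_center
    return grid


def _detail_means_stencil(config: Configuration, probe: MoleculeTemplate,
                          ff: ForceField, state: ThermoState,
                          grid: DetectionGrid,
                          criterion: CriterionConfig) -> np.ndarray:
    centers = grid.accepted_centers()
    if len(centers) == 0:
        return np.empty(0)
    b_centers = grid.b_center[grid.accepted]
    rots = (np.eye(3)[None] if probe.is_monatomic
            else np.asarray(criterion.rotation_set, float))
    pos, sig, eps, chg, mol = config.site_arrays()
    out = np.empty(len(centers))
    _kernels.detailed_average_kernel(
        np.ascontiguousarray(centers), np.ascontiguousarray(b_centers),
        grid.cell_edge, criterion.detail_bracket[1],
        criterion.step_fractions[0], criterion.step_fractions[1],
        np.ascontiguousarray(criterion.translation_directions, dtype=float),
        np.ascontiguousarray(rots), criterion.include_center,
        np.asarray(probe.body_coords, float),
        probe.sigmas, probe.epsilons, probe.charges,
        pos, sig, eps, chg, mol, config.molecule_centroids,
        config.box, ff.r_cut,
        ff.style_code, ff.coulomb_code, state.beta, out)
    return out


def _detail_means_uniform(config: Configuration, probe: MoleculeTemplate,
                          ff: ForceField, state: ThermoState,
                          grid: DetectionGrid, criterion: CriterionConfig,
                          rng: np.random.Generator) -> np.ndarray:
    centers = grid.accepted_centers()
    means = np.empty(len(centers))
    d = grid.cell_edge
    for a, center in enumerate(centers):
        positions = center + (rng.random((criterion.n_uniform, 3)) - 0.5) * d
        rotations = (None if probe.is_monatomic
                     else random_rotations(rng, criterion.n_uniform))
        b = insertion_boltzmann_batch(config, probe, ff, state,
                                      positions, rotations)
        means[a] = b.mean()
    return means


def detailed_average(config: Configuration, probe: MoleculeTemplate,
                     ff: ForceField, state: ThermoState, cell_center,
                     cell_edge: float, criterion: CriterionConfig,
                     b_center: float | None = None) -> float:
    """Mean Boltzmann factor over the detail stencil of one accepted cell."""
    if b_center is None:
        _, b_center = second_level_check(config, cell_center, probe, ff, state,
                                         criterion.b_threshold)
    from .model import insertion_energy
    total = 0.0
    poses = detail_poses(cell_center, cell_edge, b_center, criterion)
    for pose in poses:
        total += insertion_energy(config, probe, pose, ff, state).boltzmann
    return total / len(poses)


@dataclass
class VolumeBiasReport:
    """Per-run diagnostics of the biased estimator."""

    grids: list[DetectionGrid]
    fractions: np.ndarray           # free-volume fraction N_fv/N per config
    n_fv: np.ndarray                # free-volume cell count per configuration
    n_detailed: np.ndarray          # cells given the detailed average
    detailed_weight_share: float    # share of total weight from detailed cells
    bias_bound: float               # threshold-capped centre-weight bound
    trace: ConvergenceTrace

    @property
    def mean_fraction(self) -> float:
        return float(self.fractions.mean())

    @property
    def mean_detailed_fraction(self) -> float:
        return float(self.n_detailed.mean()
                     / max(self.n_fv.mean(), 1.0))


def volume_bias_estimate(ensemble: EnsembleSample, probe: MoleculeTemplate,
                         ff: ForceField, state: ThermoState | None = None,
                         n_per_side: int = 50,
                         criterion: CriterionConfig | None = None,
                         rng=None,
                         block_size: int = 50,
                         keep_grids: bool = False
                         ) -> tuple[WidomEstimate, VolumeBiasReport]:
    """Free-volume-corrected biased estimate over an ensemble.

    Each configuration is meshed and every cell passes through the
    two-level screen.  The configuration's mean Boltzmann factor is

        m = (N_fv/N) * < w >_(free cells)

    where ``w`` is the detailed 14 x 17 average for cells whose centre
    factor exceeded the threshold and the centre factor itself for the
    remaining free cells (they were screened but not investigated
    further); level-one failures contribute zero weight.  Pooling,
    uncertainty and trace mirror the unbiased estimator.  ``rng`` is only
    consulted in ``detail_mode="uniform"``.
    """
    criterion = criterion or CriterionConfig()
    state = state or ensemble.state
    if criterion.detail_mode == "uniform":
        rng = np.random.default_rng(rng)
    n_cfg = len(ensemble)
    per_config = np.empty(n_cfg)
    fractions = np.empty(n_cfg)
    n_fv = np.empty(n_cfg, dtype=int)
    n_det = np.empty(n_cfg, dtype=int)
    grids: list[DetectionGrid] = []
    n_attempts = 0
    n_nonzero = 0
    weight_detailed = 0.0
    weight_total = 0.0
    for i, config in enumerate(ensemble.configurations):
        grid = _screen_config(config, probe, ff, state, n_per_side, criterion)
        fractions[i] = grid.free_fraction
        n_fv[i] = grid.n_fv
        n_det[i] = grid.n_detailed
        center_only = grid.status == 1
        w_sum = float(grid.b_center[center_only].sum())
        n_attempts += grid.n_fv
        n_nonzero += int(np.count_nonzero(grid.b_center[center_only]))
        if grid.n_detailed:
            if criterion.detail_mode == "stencil":
                means = _detail_means_stencil(config, probe, ff, state, grid,
                                              criterion)
            else:
                means = _detail_means_uniform(config, probe, ff, state, grid,
                                              criterion, rng)
            weight_detailed += float(means.sum())
            w_sum += float(means.sum())
            poses_per_cell = (criterion.n_uniform
                              if criterion.detail_mode == "uniform"
                              else 14 * 17 + int(criterion.include_center))
            n_attempts += grid.n_detailed * poses_per_cell
            n_nonzero += int(np.count_nonzero(means))
        weight_total += w_sum
        per_config[i] = w_sum / grid.n_cells
        if keep_grids:
            grids.append(grid)
        else:
            grid.status = None
            grid.b_center = None
    estimate, trace = estimate_from_config_means(
        per_config, state, n_attempts, n_nonzero, block_size)
    grand = per_config.mean()
    if grand > 0:
        # every centre-sampled (non-detailed) free cell carries at most
        # b_threshold at its centre; this bounds that share of the average
        bias_bound = float(criterion.b_threshold
                           * (fractions.mean()
                              - n_det.mean() / n_per_side ** 3) / grand)
        share = weight_detailed / weight_total if weight_total > 0 else 0.0
    else:
        bias_bound = math.inf
        share = 0.0
    report = VolumeBiasReport(grids, fractions, n_fv, n_det, share,
                              bias_bound, trace)
    return estimate, report
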