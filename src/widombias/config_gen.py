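"""Equilibrated NVT configuration ensembles and trajectory file I/O.

The sampler is rigid-body Metropolis Monte Carlo: one attempted random
translation (plus, for polyatomic species, one random rotation) per molecule
per sweep, accepted with probability ``min(1, exp(-beta dU))``.  Canonical
averages are sampler-independent, so this stands in for any equilibrium NVT
generator.  Energy bookkeeping is incremental; a full recompute is exposed
for verification.

Supported trajectory formats (all lengths written in A except GRO, which is
nm on disk): ``xyz`` (box on the comment line), ``extxyz`` (Lattice= field),
``gro``, ``lammps-dump`` (orthorhombic ``ITEM: BOX BOUNDS``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _kernels
from .model import (Configuration, ForceField, MoleculeTemplate, Pose,
                    ThermoState, _orthonormalize, total_energy)


@dataclass(frozen=True)
class MCSettings:
    """Metropolis run parameters (counts in sweeps, moves in A / radians)."""

    n_equilibration_sweeps: int = 1000
    n_samples: int = 50
    stride_sweeps: int = 20
    max_translation: float = 0.5
    max_rotation: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_equilibration_sweeps, self.n_samples, self.stride_sweeps) < 0:
            raise ValueError("counts must be non-negative")
        if self.max_translation <= 0 or self.max_rotation <= 0:
            raise ValueError("move sizes must be positive")


@dataclass
class EnsembleSample:
    """An ordered list of decorrelated configurations at one state point."""

    configurations: list[Configuration]
    state: ThermoState
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.configurations) < 1:
            raise ValueError("ensemble must contain at least one configuration")
        box0 = self.configurations[0].box
        for c in self.configurations:
            if not np.allclose(c.box, box0):
                raise ValueError("all configurations must share one box")

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def box(self) -> np.ndarray:
        return self.configurations[0].box


def build_initial_configuration(template: MoleculeTemplate, n_molecules: int,
                                state: ThermoState, box=None,
                                rng=None) -> Configuration:
    """Molecules on a simple-cubic lattice with random orientations.

    The box is derived from the state's number density when not given
    (``V = n/rho_n``, cubic).  Refuses lattices so dense that the spacing
    drops below ``0.8 * sigma_max`` (hard overlap on the lattice).
    """
    if n_molecules < 1:
        raise ValueError("need at least one molecule")
    if box is None:
        if state.number_density is None or state.number_density <= 0:
            raise ValueError("number density required to derive the box")
        edge = (n_molecules / state.number_density) ** (1.0 / 3.0)
        box = np.array([edge, edge, edge])
    box = np.asarray(box, dtype=float).reshape(3)
    rng = np.random.default_rng(rng)
    per_side = int(math.ceil(n_molecules ** (1.0 / 3.0)))
    spacing = float(np.min(box)) / per_side
    sigma_max = float(np.max(template.sigmas))
    if spacing < 0.8 * sigma_max:
        raise ValueError(
            f"lattice spacing {spacing:.3f} A < 0.8*sigma_max "
            f"({0.8 * sigma_max:.3f} A): density too high for lattice start")
    poses = []
    count = 0
    for i in range(per_side):
        for j in range(per_side):
            for k in range(per_side):
                if count >= n_molecules:
                    break
                position = (np.array([i, j, k]) + 0.5) * (box / per_side)
                if template.is_monatomic:
                    rot = np.eye(3)
                else:
                    quat = rng.standard_normal(4)
                    from .model import rotation_from_quaternion
                    rot = rotation_from_quaternion(quat)
                poses.append(Pose(position, rot))
                count += 1
    return Configuration(box, [template] * n_molecules, poses)


class _PackedSystem:
    """Mutable flat-array view of a single-species configuration."""

    def __init__(self, config: Configuration):
        templates = config.templates
        tpl = templates[0]
        if any(t is not tpl and t.name != tpl.name for t in templates):
            raise ValueError("the MC sampler requires a single-species system")
        self.template = tpl
        self.box = config.box.copy()
        self.centroids = np.array([p.position for p in config.poses])
        self.rotmats = np.array([p.rotation for p in config.poses])
        self.body = np.asarray(tpl.body_coords, dtype=float)
        n = len(templates)
        self.sigs = np.tile(tpl.sigmas, n)
        self.epss = np.tile(tpl.epsilons, n)
        self.qs = np.tile(tpl.charges, n)
        self.molid = np.repeat(np.arange(n, dtype=np.int64), tpl.n_sites)
        self.pos = config.site_positions.copy()

    def to_configuration(self) -> Configuration:
        n = self.centroids.shape[0]
        poses = [Pose(self.centroids[m], _orthonormalize(self.rotmats[m]))
                 for m in range(n)]
        return Configuration(self.box, [self.template] * n, poses)


def _run_sweep(packed: _PackedSystem, ff: ForceField, state: ThermoState,
               settings: MCSettings, rng: np.random.Generator):
    n_mol = packed.centroids.shape[0]
    do_rot = not packed.template.is_monatomic
    rand_trans = rng.random((n_mol, 3))
    if do_rot:
        rand_axis = rng.standard_normal((n_mol, 3))
        rand_angle = rng.random(n_mol)
    else:
        rand_axis = np.zeros((n_mol, 3))
        rand_angle = np.zeros(n_mol)
    rand_acc = rng.random(n_mol)
    d_e, n_acc = _kernels.mc_sweep_kernel(
        packed.centroids, packed.rotmats, packed.pos, packed.body,
        packed.sigs, packed.epss, packed.qs, packed.molid,
        packed.box, ff.r_cut, ff.style_code, ff.coulomb_code,
        state.beta, settings.max_translation, settings.max_rotation,
        rand_trans, rand_axis, rand_angle, rand_acc, do_rot)
    return d_e, n_acc / n_mol


def metropolis_sweep(config: Configuration, ff: ForceField, state: ThermoState,
                     settings: MCSettings, rng) -> tuple[Configuration, float]:
    """One sweep over a configuration; returns (updated config, acceptance)."""
    rng = np.random.default_rng(rng)
    packed = _PackedSystem(config)
    _, acc = _run_sweep(packed, ff, state, settings, rng)
    return packed.to_configuration(), acc


def sample_ensemble(template: MoleculeTemplate, n_molecules: int,
                    state: ThermoState, ff: ForceField,
                    settings: MCSettings, box=None,
                    initial: Configuration | None = None) -> EnsembleSample:
    """Equilibrate, then store ``n_samples`` configurations every
    ``stride_sweeps`` sweeps.  Bit-identical for a fixed seed."""
    rng = np.random.default_rng(settings.seed)
    if initial is None:
        initial = build_initial_configuration(template, n_molecules, state,
                                              box=box, rng=rng)
    packed = _PackedSystem(initial)
    energy = total_energy(initial, ff)
    acc_total = 0.0
    n_sweeps = 0
    for _ in range(settings.n_equilibration_sweeps):
        d_e, acc = _run_sweep(packed, ff, state, settings, rng)
        energy += d_e
        acc_total += acc
        n_sweeps += 1
    configs = []
    energies = []
    for s in range(settings.n_samples):
        if s > 0 or settings.n_equilibration_sweeps > 0:
            for _ in range(settings.stride_sweeps if s > 0 else 0):
                d_e, acc = _run_sweep(packed, ff, state, settings, rng)
                energy += d_e
                acc_total += acc
                n_sweeps += 1
        configs.append(packed.to_configuration())
        energies.append(energy)
    if not configs:
        raise ValueError("n_samples must be >= 1")
    provenance = {
        "generator": "metropolis-nvt",
        "seed": settings.seed,
        "n_equilibration_sweeps": settings.n_equilibration_sweeps,
        "n_samples": settings.n_samples,
        "stride_sweeps": settings.stride_sweeps,
        "max_translation": settings.max_translation,
        "max_rotation": settings.max_rotation,
        "acceptance_fraction": acc_total / max(n_sweeps, 1),
        "final_energy": energy,
        "sample_energies": energies,
    }
    return EnsembleSample(configs, state, provenance)


# ---------------------------------------------------------------------------
# trajectory formats
# ---------------------------------------------------------------------------

_FORMATS = ("xyz", "extxyz", "gro", "lammps-dump")


def _frame_labels(config: Configuration) -> list[str]:
    labels = []
    for tpl in config.templates:
        labels.extend(site.label for site in tpl.sites)
    return labels


def _write_xyz(ensemble: EnsembleSample, path: Path, extended: bool) -> None:
    lines = []
    for f, config in enumerate(ensemble.configurations):
        lines.append(str(config.n_sites))
        lx, ly, lz = config.box
        if extended:
            lines.append(
                f'Lattice="{lx:.8f} 0.0 0.0 0.0 {ly:.8f} 0.0 0.0 0.0 {lz:.8f}" '
                f'Properties=species:S:1:pos:R:3 pbc="T T T"')
        else:
            lines.append(f"box {lx:.8f} {ly:.8f} {lz:.8f} frame {f}")
        for label, xyz in zip(_frame_labels(config), config.site_positions):
            lines.append(f"{label} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}")
    path.write_text("\n".join(lines) + "\n")


def _write_gro(ensemble: EnsembleSample, path: Path) -> None:
    lines = []
    for f, config in enumerate(ensemble.configurations):
        lines.append(f"frame {f}")
        lines.append(f"{config.n_sites:5d}")
        atom = 0
        for m, tpl in enumerate(config.templates):
            for site in tpl.sites:
                xyz = config.site_positions[atom] / 10.0  # A -> nm
                lines.append(f"{(m + 1) % 100000:5d}{tpl.name[:5]:<5s}"
                             f"{site.label[:5]:>5s}{(atom + 1) % 100000:5d}"
                             f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}")
                atom += 1
        lx, ly, lz = config.box / 10.0
        lines.append(f"{lx:10.5f}{ly:10.5f}{lz:10.5f}")
    path.write_text("\n".join(lines) + "\n")


def _write_lammps_dump(ensemble: EnsembleSample, path: Path) -> None:
    lines = []
    for f, config in enumerate(ensemble.configurations):
        lines.append("ITEM: TIMESTEP")
        lines.append(str(f))
        lines.append("ITEM: NUMBER OF ATOMS")
        lines.append(str(config.n_sites))
        lines.append("ITEM: BOX BOUNDS pp pp pp")
        for edge in config.box:
            lines.append(f"0.0 {edge:.8f}")
        lines.append("ITEM: ATOMS id type x y z")
        atom = 0
        for tpl in config.templates:
            for t, _site in enumerate(tpl.sites):
                xyz = config.site_positions[atom]
                lines.append(f"{atom + 1} {t + 1} "
                             f"{xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}")
                atom += 1
    path.write_text("\n".join(lines) + "\n")


def write_ensemble(ensemble: EnsembleSample, path, format: str) -> None:
    """Write every configuration of the ensemble to one trajectory file."""
    path = Path(path)
    if format == "xyz":
        _write_xyz(ensemble, path, extended=False)
    elif format == "extxyz":
        _write_xyz(ensemble, path, extended=True)
    elif format == "gro":
        _write_gro(ensemble, path)
    elif format == "lammps-dump":
        _write_lammps_dump(ensemble, path)
    else:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")


def _poses_from_sites(coords: np.ndarray, template: MoleculeTemplate,
                      frame: int) -> list[Pose]:
    ms = template.n_sites
    if coords.shape[0] % ms != 0:
        raise ValueError(
            f"frame {frame}: {coords.shape[0]} sites not divisible by "
            f"template size {ms}")
    poses = []
    body = template.body_coords
    for m in range(coords.shape[0] // ms):
        block = coords[m * ms:(m + 1) * ms]
        centroid = block.mean(axis=0)
        if ms == 1:
            poses.append(Pose(centroid))
            continue
        off = block - centroid
        # Kabsch: proper rotation best mapping body-frame coords onto offsets
        b_mat = body.T @ off
        u, _, vt = np.linalg.svd(b_mat)
        rot = (u @ vt).T
        if np.linalg.det(rot) < 0:
            rot = (u @ np.diag([1.0, 1.0, -1.0]) @ vt).T
        poses.append(Pose(centroid, _orthonormalize(rot)))
    return poses


def _read_xyz_frames(text: str, frame_format: str):
    lines = text.splitlines()
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"frame {frame}: bad atom-count line") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        box = None
        if 'Lattice="' in comment:
            nums = [float(x) for x in
                    comment.split('Lattice="', 1)[1].split('"', 1)[0].split()]
            box = np.array([nums[0], nums[4], nums[8]])
        elif comment.strip().startswith("box "):
            parts = comment.split()
            box = np.array([float(parts[1]), float(parts[2]), float(parts[3])])
        if box is None:
            raise ValueError(f"frame {frame}: missing box record on comment line")
        body = lines[i + 2:i + 2 + n]
        if len(body) < n:
            raise ValueError(f"frame {frame}: truncated ({len(body)}/{n} atoms)")
        coords = np.empty((n, 3))
        for a, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"frame {frame}: malformed atom line {a}")
            coords[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
        yield box, coords
        i += 2 + n
        frame += 1


def _read_gro_frames(text: str):
    lines = text.splitlines()
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if i + 1 >= len(lines):
            raise ValueError(f"frame {frame}: truncated header")
        try:
            n = int(lines[i + 1].strip())
        except ValueError as exc:
            raise ValueError(f"frame {frame}: bad atom-count line") from exc
        body = lines[i + 2:i + 2 + n]
        if len(body) < n or i + 2 + n >= len(lines):
            raise ValueError(f"frame {frame}: truncated frame")
        coords = np.empty((n, 3))
        for a, line in enumerate(body):
            try:
                coords[a] = [float(line[20:28]), float(line[28:36]),
                             float(line[36:44])]
            except ValueError as exc:
                raise ValueError(f"frame {frame}: malformed atom line {a}") from exc
        box_parts = lines[i + 2 + n].split()
        if len(box_parts) < 3:
            raise ValueError(f"frame {frame}: missing box record")
        box = np.array([float(x) for x in box_parts[:3]])
        yield box * 10.0, coords * 10.0  # nm -> A
        i += 3 + n
        frame += 1


def _read_lammps_frames(text: str):
    lines = text.splitlines()
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise ValueError(f"frame {frame}: expected ITEM: TIMESTEP")
        n = int(lines[i + 3].strip())
        if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
            raise ValueError(f"frame {frame}: missing box record")
        box = np.empty(3)
        for d in range(3):
            lo, hi = (float(x) for x in lines[i + 5 + d].split()[:2])
            box[d] = hi - lo
        header = lines[i + 8].split()
        if header[:2] != ["ITEM:", "ATOMS"]:
            raise ValueError(f"frame {frame}: missing ITEM: ATOMS header")
        cols = header[2:]
        try:
            ix, iy, iz = cols.index("x"), cols.index("y"), cols.index("z")
            iid = cols.index("id")
        except ValueError as exc:
            raise ValueError(f"frame {frame}: need id x y z columns") from exc
        rows = lines[i + 9:i + 9 + n]
        if len(rows) < n:
            raise ValueError(f"frame {frame}: truncated atom table")
        coords = np.empty((n, 3))
        for row in rows:
            parts = row.split()
            a = int(parts[iid]) - 1
            coords[a] = [float(parts[ix]), float(parts[iy]), float(parts[iz])]
        yield box, coords
        i += 9 + n
        frame += 1


def read_ensemble(path, format: str, template: MoleculeTemplate,
                  state: ThermoState | None = None) -> EnsembleSample:
    """Read a trajectory written by :func:`write_ensemble` back into an
    ensemble of rigid-body configurations of ``template``.

    Rigid poses are recovered from the site coordinates (centroid + best-fit
    proper rotation), so a write/read round trip reproduces coordinates to
    the format's precision.
    """
    path = Path(path)
    text = path.read_text()
    if format in ("xyz", "extxyz"):
        frames = _read_xyz_frames(text, format)
    elif format == "gro":
        frames = _read_gro_frames(text)
    elif format == "lammps-dump":
        frames = _read_lammps_frames(text)
    else:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    configs = []
    for f, (box, coords) in enumerate(frames):
        poses = _poses_from_sites(coords, template, f)
        configs.append(Configuration(box, [template] * len(poses), poses))
    if not configs:
        raise ValueError(f"no frames found in {path}")
    if state is None:
        n = configs[0].n_molecules
        state = ThermoState(temperature=1.0,
                            number_density=n / configs[0].volume)
    return EnsembleSample(configs, state, {"source": str(path), "format": format})
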