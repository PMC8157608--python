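"""Synthetic fixture systems with analytically known excess chemical potentials.

Each fixture bundles a frozen or generatable ensemble with the probe and
force field that make its answer exact:

* ``ideal_gas`` — all epsilon and charges zero; mu_ex is exactly 0.
* ``hard_core_lattice`` — immobile hard cubic cores covering a chosen set of
  whole mesh cells, so the free-volume fraction f_free is an exact count and
  mu_ex = -k_B T ln(f_free).  Cores are cubes (Chebyshev-metric hard
  interaction) aligned with the detection mesh; a sphere cannot cover a cell
  exactly, a cube can.
* ``lj_dilute`` — Lennard-Jones argon at reduced density <= 0.05, where
  beta mu_ex approaches 2 B2(T) rho (second-virial limit).
* ``frozen_cavity`` — one deterministic configuration with an octahedral
  cage of attractive atoms around the box centre, guaranteeing a single
  known cell that passes both acceptance levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (Configuration, ForceField, MoleculeTemplate, Pose,
                    SiteSpec, ThermoState, argon)
from .config_gen import EnsembleSample, MCSettings, sample_ensemble

FIXTURE_NAMES = ("ideal_gas", "hard_core_lattice", "lj_dilute", "frozen_cavity")


@dataclass
class Fixture:
    """A named synthetic system plus everything needed to estimate on it."""

    name: str
    ensemble: EnsembleSample
    probe: MoleculeTemplate
    forcefield: ForceField
    expected: dict = field(default_factory=dict)


def _ideal_gas(n_molecules=64, n_configs=5, temperature=300.0,
               box_edge=12.0, seed=0) -> Fixture:
    template = MoleculeTemplate(
        "ghost", [SiteSpec("X", 0.0, 0.0, 0.0, 1.0)], np.zeros((1, 3)))
    rng = np.random.default_rng(seed)
    box = np.array([box_edge] * 3)
    configs = []
    for _ in range(n_configs):
        poses = [Pose(rng.random(3) * box) for _ in range(n_molecules)]
        configs.append(Configuration(box, [template] * n_molecules, poses))
    state = ThermoState(temperature,
                        number_density=n_molecules / float(np.prod(box)))
    ens = EnsembleSample(configs, state, {"fixture": "ideal_gas", "seed": seed})
    return Fixture("ideal_gas", ens, template, ForceField(r_cut=5.0),
                   {"mu_ex": 0.0})


def _hard_core_lattice(n_per_side=8, f_free=0.5, cell_edge=1.0,
                       temperature=300.0, seed=0) -> Fixture:
    """Hard cubic cores on cell centres; exactly countable free volume."""
    if not (0.0 < f_free <= 1.0):
        raise ValueError("f_free must lie in (0, 1]")
    n_cells = n_per_side ** 3
    n_blocked = int(round((1.0 - f_free) * n_cells))
    f_free_exact = 1.0 - n_blocked / n_cells
    rng = np.random.default_rng(seed)
    blocked = rng.choice(n_cells, size=n_blocked, replace=False)
    box = np.array([n_per_side * cell_edge] * 3)
    core = MoleculeTemplate(
        "core", [SiteSpec("C", cell_edge, 0.0, 0.0, 1.0)], np.zeros((1, 3)))
    poses = []
    for idx in sorted(blocked):
        i, j, k = np.unravel_index(idx, (n_per_side,) * 3)
        poses.append(Pose((np.array([i, j, k]) + 0.5) * cell_edge))
    if not poses:  # f_free == 1: keep one far-away zero-size core
        core = MoleculeTemplate(
            "core", [SiteSpec("C", 0.0, 0.0, 0.0, 1.0)], np.zeros((1, 3)))
        poses = [Pose(np.zeros(3))]
    config = Configuration(box, [core] * len(poses), poses)
    state = ThermoState(temperature, number_density=len(poses) / config.volume)
    probe = MoleculeTemplate(
        "point", [SiteSpec("P", 0.0, 0.0, 0.0, 1.0)], np.zeros((1, 3)))
    ens = EnsembleSample([config], state,
                         {"fixture": "hard_core_lattice", "seed": seed})
    kt = state.kt
    return Fixture(
        "hard_core_lattice", ens, probe,
        ForceField(r_cut=0.45 * box[0], pair_style="hard-cube"),
        {"f_free": f_free_exact,
         "mu_ex": -kt * math.log(f_free_exact) if f_free_exact > 0 else math.inf,
         "n_per_side": n_per_side})


def _lj_dilute(rho_star=0.02, temperature=320.0, n_molecules=128,
               n_configs=30, seed=0) -> Fixture:
    """Dilute LJ argon for the second-virial limit check.

    The default reduced density 0.02 keeps the second-order virial term
    (measurably ~ -7% here, with B3 of the truncated potential ~ 1.6
    sigma^6 at this temperature) well inside a 10% first-order band.
    """
    if rho_star > 0.05:
        raise ValueError("lj_dilute is meant for reduced density <= 0.05")
    template = argon()
    sigma = template.sites[0].sigma
    rho_n = rho_star / sigma ** 3
    state = ThermoState(temperature, number_density=rho_n)
    edge = (n_molecules / rho_n) ** (1 / 3)
    r_cut = min(10.0, 0.45 * edge)
    ff = ForceField(r_cut=r_cut)
    settings = MCSettings(n_equilibration_sweeps=200, n_samples=n_configs,
                          stride_sweeps=10, max_translation=0.45 * edge / 4,
                          max_rotation=0.5, seed=seed)
    ens = sample_ensemble(template, n_molecules, state, ff, settings)
    ens.provenance["fixture"] = "lj_dilute"
    return Fixture("lj_dilute", ens, template, ff,
                   {"rho_star": rho_star, "rho_n": rho_n})


def _frozen_cavity(temperature=300.0, box_edge=20.0, seed=0) -> Fixture:
    """Six attractive atoms in an octahedron around the box centre.

    Each cage atom sits at the LJ minimum distance from the centre, so the
    centre insertion energy is ~ -6 epsilon and its Boltzmann factor
    (~ e^6 at the chosen epsilon) clears the default second-level
    threshold of 100, while the centre is > 3 A from every atom.
    """
    sigma, eps = 3.0, 0.6
    r_min = 2.0 ** (1 / 6) * sigma
    box = np.array([box_edge] * 3)
    centre = box / 2.0
    template = MoleculeTemplate(
        "cage", [SiteSpec("Cg", sigma, eps, 0.0, 40.0)], np.zeros((1, 3)))
    offsets = r_min * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                                [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
    poses = [Pose(centre + off) for off in offsets]
    config = Configuration(box, [template] * 6, poses)
    state = ThermoState(temperature, number_density=6 / config.volume)
    probe = MoleculeTemplate(
        "guest", [SiteSpec("G", sigma, eps, 0.0, 40.0)], np.zeros((1, 3)))
    ens = EnsembleSample([config], state, {"fixture": "frozen_cavity"})
    kt = state.kt
    return Fixture("frozen_cavity", ens, probe, ForceField(r_cut=8.0),
                   {"center": centre, "delta_u_center": -6.0 * eps,
                    "boltzmann_center": math.exp(6.0 * eps / kt),
                    "mesh_n": 5})


_MAKERS = {
    "ideal_gas": _ideal_gas,
    "hard_core_lattice": _hard_core_lattice,
    "lj_dilute": _lj_dilute,
    "frozen_cavity": _frozen_cavity,
}


def make_fixture(name: str, **parameters) -> Fixture:
    """Build a named fixture; unknown names raise with the list of options."""
    try:
        maker = _MAKERS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; options: {', '.join(FIXTURE_NAMES)}")
    return maker(**parameters)
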