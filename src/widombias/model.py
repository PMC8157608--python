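"""Domain types, periodic-boundary geometry, and pairwise energy evaluation.

Unit conventions used throughout the package:

* lengths in angstrom (A), energies in kcal/mol, temperatures in kelvin,
  charges in elementary charges, masses in g/mol;
* mass densities cross the API boundary in kg/m^3, number densities are
  molecules per A^3;
* ``K_B`` is Boltzmann's constant in kcal/(mol K), so ``beta = 1/(K_B*T)``
  has units 1/(kcal/mol).

Boxes are orthorhombic and fully periodic.  Molecules are rigid bodies: a
:class:`MoleculeTemplate` carries body-frame site coordinates (centroid at
the origin) and a :class:`Pose` places one copy in the box.  Intramolecular
interactions are always excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

K_B = 0.0019872041            # kcal/(mol K)
COULOMB_CONSTANT = 332.06371  # kcal A / (mol e^2)
N_AVOGADRO = 6.02214076e23
BOLTZMANN_SI = 1.380649e-23   # J/K, for pressure/density conversions

_STYLE_CODES = {"lj": 0, "hard-sphere": 1, "hard-cube": 2}
_COULOMB_CODES = {"none": 0, "truncated-shifted": 1}


def number_density_from_mass(mass_density: float, molar_mass: float) -> float:
    """Convert a mass density (kg/m^3) to a number density (molecules/A^3)."""
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    return mass_density * 1.0e3 / molar_mass * N_AVOGADRO * 1.0e-30


def mass_density_from_number(number_density: float, molar_mass: float) -> float:
    """Inverse of :func:`number_density_from_mass`."""
    return number_density / (1.0e3 / molar_mass * N_AVOGADRO * 1.0e-30)


@dataclass(frozen=True)
class ThermoState:
    """One (T, rho) state point of the canonical ensemble.

    At most one of ``mass_density``/``number_density`` may be left out; with
    a molar mass both can be derived from each other through
    :meth:`from_mass_density`.
    """

    temperature: float                    # K
    mass_density: float | None = None     # kg/m^3
    number_density: float | None = None   # molecules/A^3

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError("temperature must be positive")
        if self.mass_density is None and self.number_density is None:
            raise ValueError("at least one of mass_density/number_density required")

    @property
    def beta(self) -> float:
        """1/(k_B T) in 1/(kcal/mol)."""
        return 1.0 / (K_B * self.temperature)

    @property
    def kt(self) -> float:
        """k_B T in kcal/mol."""
        return K_B * self.temperature

    @classmethod
    def from_mass_density(cls, temperature: float, mass_density: float,
                          molar_mass: float) -> "ThermoState":
        return cls(temperature, mass_density,
                   number_density_from_mass(mass_density, molar_mass))


@dataclass(frozen=True)
class SiteSpec:
    """One interaction site: Lennard-Jones parameters, charge, mass."""

    label: str
    sigma: float      # A
    epsilon: float    # kcal/mol
    charge: float     # e
    mass: float       # g/mol

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.epsilon < 0 or self.mass < 0:
            raise ValueError("sigma, epsilon and mass must be non-negative")


class MoleculeTemplate:
    """A rigid molecule: ordered sites plus body-frame coordinates.

    The body-frame centroid (unweighted mean of site positions) is placed at
    the origin on construction, so a :class:`Pose` position is always the
    molecular centroid.
    """

    def __init__(self, name: str, sites: Sequence[SiteSpec],
                 body_coords: np.ndarray) -> None:
        body = np.asarray(body_coords, dtype=float).reshape(len(sites), 3)
        if len(sites) == 0:
            raise ValueError("molecule template needs at least one site")
        self.name = name
        self.sites = tuple(sites)
        self.body_coords = body - body.mean(axis=0)
        self.body_coords.setflags(write=False)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def is_monatomic(self) -> bool:
        return self.n_sites == 1

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([s.sigma for s in self.sites])

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([s.epsilon for s in self.sites])

    @property
    def charges(self) -> np.ndarray:
        return np.array([s.charge for s in self.sites])

    @property
    def molar_mass(self) -> float:
        return float(sum(s.mass for s in self.sites))

    @property
    def total_charge(self) -> float:
        return float(sum(s.charge for s in self.sites))

    @property
    def has_charges(self) -> bool:
        return any(s.charge != 0.0 for s in self.sites)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MoleculeTemplate({self.name!r}, n_sites={self.n_sites})"


def rotation_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Proper rotation matrix from an axis (need not be normalised) and angle."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    x, y, z = axis / n
    c, s = math.cos(angle), math.sin(angle)
    cc = 1.0 - c
    return np.array([
        [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
        [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
        [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
    ])


def rotation_from_quaternion(q: np.ndarray) -> np.ndarray:
    """Rotation matrix from a (w, x, y, z) quaternion (normalised internally)."""
    q = np.asarray(q, dtype=float)
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _orthonormalize(rot: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) (polar decomposition via SVD)."""
    u, _, vt = np.linalg.svd(rot)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


@dataclass(frozen=True)
class Pose:
    """Placement of a rigid molecule: centroid position + proper rotation."""

    position: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, float).reshape(3))
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        object.__setattr__(self, "rotation", rot)
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-10):
            raise ValueError("rotation is not orthogonal within 1e-10")
        if abs(np.linalg.det(rot) - 1.0) > 1e-10:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def from_axis_angle(cls, position, axis, angle) -> "Pose":
        return cls(np.asarray(position, float), rotation_from_axis_angle(axis, angle))


@dataclass(frozen=True)
class ForceField:
    """Pairwise interaction model.

    ``pair_style`` is one of ``lj`` (12-6 Lennard-Jones with Lorentz-Berthelot
    combining, truncated at ``r_cut``), ``hard-sphere`` (infinite below the
    combined sigma, Euclidean metric) or ``hard-cube`` (infinite below the
    combined sigma in the Chebyshev metric; used by grid-exact fixtures).
    ``coulomb_style`` is ``none`` or ``truncated-shifted``: a
    molecule-centroid-based group cutoff in which every site pair of a
    molecule pair is included iff the two molecular centroids are within
    ``r_cut``, each included pair contributing
    ``q_i q_j C (1/r - 1/r_cut)``.  For neutral molecules the shift terms
    of one molecule pair sum to zero, so this is the neutral-group
    truncation (charge groups never get split at the cutoff sphere).  At
    the bare two-site level of :func:`pair_energy` each site is its own
    group, so the criterion degenerates to the site distance.
    Intramolecular interactions are excluded everywhere.
    """

    r_cut: float = 10.0
    pair_style: str = "lj"
    coulomb_style: str = "none"

    def __post_init__(self) -> None:
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.pair_style not in _STYLE_CODES:
            raise ValueError(f"unknown pair style {self.pair_style!r}")
        if self.coulomb_style not in _COULOMB_CODES:
            raise ValueError(f"unknown coulomb style {self.coulomb_style!r}")

    @property
    def style_code(self) -> int:
        return _STYLE_CODES[self.pair_style]

    @property
    def coulomb_code(self) -> int:
        return _COULOMB_CODES[self.coulomb_style]


@dataclass(frozen=True)
class InsertionRecord:
    """Result of one trial insertion: pose, energy change, Boltzmann factor."""

    pose: Pose
    delta_u: float      # kcal/mol
    boltzmann: float    # e^(-beta dU)


def wrap_position(position: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap a point into the primary cell [0, L_i)."""
    position = np.asarray(position, float)
    box = np.asarray(box, float)
    return position - box * np.floor(position / box)


class Configuration:
    """One periodic snapshot: box + a list of (template, Pose) molecules.

    Flat per-site arrays (positions, LJ parameters, charges, molecule index)
    are cached on construction; they are what the numerical kernels consume.
    Centroid positions are wrapped into ``[0, L_i)``; individual sites of a
    molecule may protrude past the box faces (minimum image handles them).
    """

    def __init__(self, box, templates: Sequence[MoleculeTemplate],
                 poses: Sequence[Pose]) -> None:
        self.box = np.asarray(box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if len(templates) != len(poses):
            raise ValueError("one pose per molecule required")
        self.templates = list(templates)
        self.poses = [Pose(wrap_position(p.position, self.box), p.rotation)
                      for p in poses]
        self._build_cache()

    def _build_cache(self) -> None:
        n_sites = sum(t.n_sites for t in self.templates)
        pos = np.empty((n_sites, 3))
        sig = np.empty(n_sites)
        eps = np.empty(n_sites)
        chg = np.empty(n_sites)
        mol = np.empty(n_sites, dtype=np.int64)
        at = 0
        for m, (tpl, pose) in enumerate(zip(self.templates, self.poses)):
            k = tpl.n_sites
            pos[at:at + k] = pose.position + tpl.body_coords @ pose.rotation.T
            sig[at:at + k] = tpl.sigmas
            eps[at:at + k] = tpl.epsilons
            chg[at:at + k] = tpl.charges
            mol[at:at + k] = m
            at += k
        self._site_pos = pos
        self._site_sigma = sig
        self._site_eps = eps
        self._site_charge = chg
        self._site_mol = mol
        self._mol_cent = np.array([p.position for p in self.poses]) \
            if self.poses else np.zeros((0, 3))

    @property
    def n_molecules(self) -> int:
        return len(self.templates)

    @property
    def n_sites(self) -> int:
        return self._site_pos.shape[0]

    @property
    def site_positions(self) -> np.ndarray:
        return self._site_pos

    @property
    def molecule_centroids(self) -> np.ndarray:
        """(n_molecules, 3) wrapped centroid positions (pose positions)."""
        return self._mol_cent

    def site_arrays(self):
        """(positions, sigma, epsilon, charge, molecule-index) flat arrays."""
        return (self._site_pos, self._site_sigma, self._site_eps,
                self._site_charge, self._site_mol)

    def without_molecule(self, index: int) -> "Configuration":
        templates = [t for i, t in enumerate(self.templates) if i != index]
        poses = [p for i, p in enumerate(self.poses) if i != index]
        return Configuration(self.box, templates, poses)

    def translated(self, shift) -> "Configuration":
        shift = np.asarray(shift, float)
        return Configuration(self.box, self.templates,
                             [Pose(p.position + shift, p.rotation) for p in self.poses])

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))


# ---------------------------------------------------------------------------
# geometry and pairwise energies
# ---------------------------------------------------------------------------

def minimum_image_vector(a, b, box) -> np.ndarray:
    """Shortest periodic image of (b - a); components in [-L_i/2, L_i/2)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    box = np.asarray(box, float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    d = b - a
    return d - box * np.floor(d / box + 0.5)


def pair_energy(site_i: SiteSpec, pos_i, site_j: SiteSpec, pos_j,
                ff: ForceField, box) -> float:
    """Energy of one site pair under minimum image, in kcal/mol.

    Lennard-Jones with Lorentz-Berthelot combining, truncated at ``r_cut``;
    Coulomb per the force field's configured style.  Exactly coincident
    repulsive sites return ``+inf`` (Boltzmann factor 0, never NaN).
    """
    d = minimum_image_vector(pos_i, pos_j, box)
    r2 = float(d @ d)
    rc = ff.r_cut
    if ff.pair_style == "hard-sphere":
        sij = 0.5 * (site_i.sigma + site_j.sigma)
        return math.inf if r2 < sij * sij else 0.0
    if ff.pair_style == "hard-cube":
        sij = 0.5 * (site_i.sigma + site_j.sigma)
        return math.inf if np.max(np.abs(d)) < sij else 0.0
    e = 0.0
    interacting = False
    eij = math.sqrt(site_i.epsilon * site_j.epsilon)
    if r2 < rc * rc:
        if eij > 0.0:
            interacting = True
            if r2 == 0.0:
                return math.inf
            sij = 0.5 * (site_i.sigma + site_j.sigma)
            s6 = (sij * sij / r2) ** 3
            e += 4.0 * eij * (s6 * s6 - s6)
        if ff.coulomb_code == 1:
            qq = site_i.charge * site_j.charge
            if qq != 0.0:
                interacting = True
                if r2 == 0.0:
                    return math.inf
                r = math.sqrt(r2)
                e += COULOMB_CONSTANT * qq * (1.0 / r - 1.0 / rc)
    if not interacting:
        return 0.0
    return e


def insertion_energy(config: Configuration, probe: MoleculeTemplate, pose: Pose,
                     ff: ForceField, state: ThermoState) -> InsertionRecord:
    """Energy change of inserting ``probe`` at ``pose`` into ``config``.

    Sums :func:`pair_energy` over every probe-site x existing-site pair under
    minimum image; the probe does not interact with its own periodic images.
    """
    if probe.n_sites == 0:  # defensive; template constructor forbids this
        raise ValueError("probe template is empty")
    from . import _kernels
    pos, sig, eps, chg, mol = config.site_arrays()
    centre = wrap_position(pose.position, config.box)
    probe_pos = centre + probe.body_coords @ pose.rotation.T
    du = _kernels.insertion_energy_kernel(
        probe_pos, probe.sigmas, probe.epsilons, probe.charges,
        centre[0], centre[1], centre[2],
        pos, sig, eps, chg, mol, config.molecule_centroids, -1,
        config.box, ff.r_cut, ff.style_code, ff.coulomb_code)
    boltzmann = math.exp(-state.beta * du) if np.isfinite(du) else 0.0
    return InsertionRecord(Pose(centre, pose.rotation), float(du), boltzmann)


def total_energy(config: Configuration, ff: ForceField) -> float:
    """Total intermolecular energy: half-sum over distinct site pairs."""
    from . import _kernels
    pos, sig, eps, chg, mol = config.site_arrays()
    return float(_kernels.total_energy_kernel(
        pos, sig, eps, chg, mol, config.molecule_centroids,
        config.box, ff.r_cut, ff.style_code, ff.coulomb_code))


# ---------------------------------------------------------------------------
# built-in species and the parameter-file reader
# ---------------------------------------------------------------------------

def argon() -> MoleculeTemplate:
    """Lennard-Jones argon: sigma 3.405 A, epsilon 0.238 kcal/mol."""
    return MoleculeTemplate(
        "argon", [SiteSpec("Ar", 3.405, 0.238, 0.0, 39.948)], np.zeros((1, 3)))


def tip3p_water() -> MoleculeTemplate:
    """Rigid 3-site TIP3P water (r_OH 0.9572 A, HOH angle 104.52 deg)."""
    r_oh = 0.9572
    half = math.radians(104.52 / 2.0)
    o = np.array([0.0, 0.0, 0.0])
    h1 = np.array([r_oh * math.sin(half), 0.0, r_oh * math.cos(half)])
    h2 = np.array([-r_oh * math.sin(half), 0.0, r_oh * math.cos(half)])
    sites = [
        SiteSpec("OW", 3.1507, 0.1521, -0.834, 15.9994),
        SiteSpec("HW1", 0.0, 0.0, 0.417, 1.008),
        SiteSpec("HW2", 0.0, 0.0, 0.417, 1.008),
    ]
    return MoleculeTemplate("tip3p", sites, np.stack([o, h1, h2]))


_BUILTIN_SPECIES = {"argon": argon, "tip3p": tip3p_water, "water": tip3p_water}


def builtin_species(name: str) -> MoleculeTemplate:
    try:
        return _BUILTIN_SPECIES[name]()
    except KeyError:
        raise ValueError(
            f"unknown species {name!r}; built-ins: {sorted(_BUILTIN_SPECIES)}")


def read_species_file(path) -> dict[str, MoleculeTemplate]:
    """Read molecule templates from a plain-text parameter file.

    Schema: ``[species-name]`` headers followed by one site per line,
    ``label sigma epsilon charge mass x y z`` (A, kcal/mol, e, g/mol, A).
    Blank lines and ``#`` comments are ignored.
    """
    species: dict[str, MoleculeTemplate] = {}
    name = None
    sites: list[SiteSpec] = []
    coords: list[list[float]] = []

    def flush():
        if name is not None:
            if not sites:
                raise ValueError(f"species block {name!r} has no sites")
            species[name] = MoleculeTemplate(name, sites, np.array(coords))

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            name = line[1:-1].strip()
            sites, coords = [], []
            continue
        if name is None:
            raise ValueError(f"line {lineno}: site line before any species header")
        parts = line.split()
        if len(parts) != 8:
            raise ValueError(
                f"line {lineno}: expected 'label sigma epsilon charge mass x y z'")
        label = parts[0]
        sigma, epsilon, charge, mass, x, y, z = map(float, parts[1:])
        sites.append(SiteSpec(label, sigma, epsilon, charge, mass))
        coords.append([x, y, z])
    flush()
    return species


def write_species_file(path, species: Iterable[MoleculeTemplate]) -> None:
    lines = []
    for tpl in species:
        lines.append(f"[{tpl.name}]")
        for site, xyz in zip(tpl.sites, tpl.body_coords):
            lines.append(
                f"{site.label} {site.sigma:.6g} {site.epsilon:.6g} "
                f"{site.charge:.6g} {site.mass:.6g} "
                f"{xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
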