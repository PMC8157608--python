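import numpy as np
import pytest

import widombias as wb


@pytest.fixture(scope="session")
def argon_template():
    return wb.argon()


@pytest.fixture(scope="session")
def water_template():
    return wb.tip3p_water()


@pytest.fixture(scope="session")
def argon_state():
    tpl = wb.argon()
    return wb.ThermoState.from_mass_density(320.0, 894.0, tpl.molar_mass)


@pytest.fixture(scope="session")
def argon_small_ensemble(argon_template, argon_state):
    """Frozen ensemble of 128 dense LJ argon atoms (quick shared input)."""
    ff = wb.ForceField(r_cut=8.0)
    settings = wb.MCSettings(n_equilibration_sweeps=400, n_samples=20,
                             stride_sweeps=10, max_translation=1.0, seed=42)
    ens = wb.sample_ensemble(argon_template, 128, argon_state, ff, settings)
    return ens, ff


def random_lj_configuration(n_atoms, box_edge, seed, sigma=3.405, eps=0.238,
                            min_sep=2.0):
    """Random monatomic LJ configuration with a minimum pair separation
    (rejection sampling keeps energies in a numerically sane range)."""
    rng = np.random.default_rng(seed)
    tpl = wb.MoleculeTemplate(
        "lj", [wb.SiteSpec("X", sigma, eps, 0.0, 39.948)], np.zeros((1, 3)))
    box = np.array([box_edge] * 3)
    points = []
    while len(points) < n_atoms:
        p = rng.random(3) * box
        ok = all(np.linalg.norm(wb.minimum_image_vector(p, q, box)) >= min_sep
                 for q in points)
        if ok:
            points.append(p)
    return wb.Configuration(box, [tpl] * n_atoms, [wb.Pose(p) for p in points])
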