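"""Long-range corrections, Ewald oracle, reference formulas."""

import math

import numpy as np
import pytest

import widombias as wb
from widombias.corrections import (EwaldContext, probe_dipole_moment,
                                   reaction_field_correction)
from widombias.model import COULOMB_CONSTANT


# ---------------------------------------------------------------------------
# dispersion tail
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rho,expected", [(416.0, -0.039), (727.0, -0.0681),
                                          (894.0, -0.0837)])
def test_argon_tail_reproduces_reference_column(argon_template, rho, expected):
    """The truncated-LJ tail with sigma 3.405 A, eps 0.238 kcal/mol,
    r_cut 10 A reproduces the tabulated argon corrections to the printed
    precision."""
    state = wb.ThermoState.from_mass_density(320.0, rho,
                                             argon_template.molar_mass)
    mu_p = wb.lj_tail_correction(state, argon_template, argon_template,
                                 wb.ForceField(r_cut=10.0))
    assert round(mu_p, 4) == pytest.approx(expected, abs=5e-5)


def test_tail_linear_in_density(argon_template):
    ff = wb.ForceField(r_cut=10.0)
    states = [wb.ThermoState(320.0, number_density=r)
              for r in (0.002, 0.004, 0.008)]
    values = [wb.lj_tail_correction(s, argon_template, argon_template, ff)
              for s in states]
    assert values[1] == pytest.approx(2 * values[0], rel=1e-12)
    assert values[2] == pytest.approx(4 * values[0], rel=1e-12)


def test_tail_vanishes_at_zero_density_and_large_cutoff(argon_template):
    zero = wb.ThermoState(320.0, number_density=0.0)
    assert wb.lj_tail_correction(zero, argon_template, argon_template,
                                 wb.ForceField(r_cut=10.0)) == 0.0
    state = wb.ThermoState(320.0, number_density=0.0135)
    far = wb.lj_tail_correction(state, argon_template, argon_template,
                                wb.ForceField(r_cut=1000.0))
    assert abs(far) < 1e-6


def test_tail_increases_toward_zero_with_cutoff(argon_template):
    state = wb.ThermoState(320.0, number_density=0.0135)
    values = [wb.lj_tail_correction(state, argon_template, argon_template,
                                    wb.ForceField(r_cut=rc))
              for rc in (6.0, 8.0, 10.0, 14.0)]
    assert all(v < 0 for v in values)
    assert values == sorted(values)  # strictly increasing toward 0


def test_water_tail_counts_only_lj_sites(water_template):
    """TIP3P hydrogens carry no LJ parameters; the tail is the O-O term."""
    state = wb.ThermoState.from_mass_density(315.0, 991.0,
                                             water_template.molar_mass)
    ff = wb.ForceField(r_cut=10.0)
    mu_p = wb.lj_tail_correction(state, water_template, water_template, ff)
    s, e = 3.1507, 0.1521
    expected = (16 / 3) * math.pi * state.number_density * e * s ** 3 \
        * ((s / 10.0) ** 9 / 3 - (s / 10.0) ** 3)
    assert mu_p == pytest.approx(expected, rel=1e-12)


def test_corrected_argon_mu_is_cutoff_robust(argon_template):
    """The tail correction compensates the truncation: corrected mu_ex of
    dense LJ argon computed at r_cut 8, 10 and 12 A agrees within combined
    statistical error (the central physical property of the correction)."""
    state = wb.ThermoState.from_mass_density(320.0, 894.0,
                                             argon_template.molar_mass)
    results = []
    for rc in (8.0, 10.0, 12.0):
        ff = wb.ForceField(r_cut=rc)
        settings = wb.MCSettings(n_equilibration_sweeps=600, n_samples=25,
                                 stride_sweeps=15, max_translation=1.0,
                                 seed=55)
        ens = wb.sample_ensemble(argon_template, 256, state, ff, settings)
        est, _ = wb.widom_unbiased(ens, argon_template, ff, 50_000, rng=56)
        mu_p = wb.lj_tail_correction(state, argon_template, argon_template,
                                     ff)
        est = wb.assemble_corrected_estimate(est, mu_p, 0.0)
        results.append((est.mu_ex_corrected, est.uncertainty))
    for (mu_a, u_a), (mu_b, u_b) in [(results[0], results[1]),
                                     (results[1], results[2]),
                                     (results[0], results[2])]:
        assert abs(mu_a - mu_b) < 3.0 * math.hypot(u_a, u_b) + 0.01


# ---------------------------------------------------------------------------
# electrostatic correction
# ---------------------------------------------------------------------------

def test_coulomb_correction_zero_for_apolar_probe(argon_template):
    state = wb.ThermoState(320.0, number_density=0.0135)
    assert wb.coulomb_correction(state, argon_template, argon_template,
                                 wb.ForceField(r_cut=10.0)) == 0.0


def test_coulomb_correction_continuous_in_charges(water_template):
    """Scaling all charges toward zero scales the correction to zero."""
    state = wb.ThermoState(315.0, number_density=0.033)
    ff = wb.ForceField(r_cut=10.0, coulomb_style="truncated-shifted")
    full = wb.coulomb_correction(state, water_template, water_template, ff)

    def scaled(f):
        sites = [wb.SiteSpec(s.label, s.sigma, s.epsilon, s.charge * f,
                             s.mass) for s in water_template.sites]
        return wb.MoleculeTemplate("w", sites, water_template.body_coords)

    half = wb.coulomb_correction(state, scaled(0.5), water_template, ff)
    zero = wb.coulomb_correction(state, scaled(0.0), water_template, ff)
    assert zero == 0.0
    assert half == pytest.approx(full / 4.0, rel=1e-9)  # quadratic in mu_d
    assert full < 0.0


def test_coulomb_correction_rejects_net_charge():
    ion = wb.MoleculeTemplate(
        "ion", [wb.SiteSpec("I", 3.0, 0.1, 1.0, 23.0)], np.zeros((1, 3)))
    state = wb.ThermoState(300.0, number_density=0.01)
    with pytest.raises(ValueError, match="neutral"):
        wb.coulomb_correction(state, ion, ion, wb.ForceField(r_cut=10.0))


def test_reaction_field_value_matches_onsager_formula(water_template):
    ff = wb.ForceField(r_cut=10.0)
    mu_d = probe_dipole_moment(water_template)
    assert mu_d == pytest.approx(2.347 / 4.8032, rel=1e-3)  # TIP3P dipole
    expected = -COULOMB_CONSTANT * 0.5 * mu_d ** 2 / 1000.0
    assert reaction_field_correction(water_template, ff) == \
        pytest.approx(expected, rel=1e-12)
    finite = reaction_field_correction(water_template, ff, epsilon_rf=80.0)
    assert finite == pytest.approx(expected * (79.0 / 161.0) / 0.5, rel=1e-12)


def test_ewald_matches_direct_image_sum_oracle():
    """Toy two-charge system + dipolar probe: the Ewald insertion energy
    equals the explicit image sum (spherically ordered, vacuum boundary)
    plus the tin-foil surface-dipole term, within 1e-3 kcal/mol."""
    L = 10.0
    box = np.array([L, L, L])
    dip = wb.MoleculeTemplate(
        "dip", [wb.SiteSpec("P", 0, 0, 0.5, 1.0),
                wb.SiteSpec("M", 0, 0, -0.5, 1.0)],
        np.array([[0.6, 0, 0], [-0.6, 0, 0]]))
    config = wb.Configuration(box, [dip], [wb.Pose((2.0, 2.0, 2.0))])
    probe_pos = np.array([[6.0, 6.0, 6.0], [6.9, 6.0, 6.0]])
    probe_q = np.array([0.417, -0.417])
    u_ewald = EwaldContext(config).probe_insertion_energy(probe_pos, probe_q)

    nmax = 24
    ns = np.arange(-nmax, nmax + 1)
    shifts = np.stack(np.meshgrid(ns, ns, ns, indexing="ij"),
                      axis=-1).reshape(-1, 3).astype(float)
    shifts = shifts[np.sum(shifts ** 2, axis=1) <= nmax ** 2] * L  # sphere
    sys_pos = config.site_positions
    sys_q = dip.charges
    u_ps = sum(qp * qs * np.sum(1.0 / np.linalg.norm(sp + shifts - pp, axis=1))
               for pp, qp in zip(probe_pos, probe_q)
               for sp, qs in zip(sys_pos, sys_q))
    nz = ~np.all(shifts == 0.0, axis=1)
    u_pp = sum(0.5 * probe_q[i] * probe_q[j]
               * np.sum(1.0 / np.linalg.norm(probe_pos[j] + shifts[nz]
                                             - probe_pos[i], axis=1))
               for i in range(2) for j in range(2))
    # vacuum-boundary sum carries the surface dipole term on top of the
    # tin-foil (conducting boundary) Ewald energy: subtract it
    m_sys = sys_q @ sys_pos
    m_probe = probe_q @ probe_pos
    surface = (2 * math.pi / (3 * L ** 3)) * (2 * m_sys @ m_probe
                                              + m_probe @ m_probe)
    u_direct = COULOMB_CONSTANT * (u_ps + u_pp - surface)
    assert u_ewald == pytest.approx(u_direct, abs=1e-3)


def test_fep_method_is_deterministic_and_needs_ensemble(water_template):
    state = wb.ThermoState.from_mass_density(315.0, 991.0,
                                             water_template.molar_mass)
    ff = wb.ForceField(r_cut=5.0, coulomb_style="truncated-shifted")
    with pytest.raises(ValueError, match="ensemble"):
        wb.coulomb_correction(state, water_template, water_template, ff,
                              method="fep")
    settings = wb.MCSettings(n_equilibration_sweeps=30, n_samples=2,
                             stride_sweeps=5, max_translation=0.3,
                             max_rotation=0.3, seed=2)
    ens = wb.sample_ensemble(water_template, 27, state, ff, settings)
    kwargs = dict(method="fep", n_subsample=16, n_configs_used=2, seed=5,
                  criterion=wb.CriterionConfig(d_min=0.8, b_threshold=0.0),
                  n_per_side=9)
    v1 = wb.coulomb_correction(state, water_template, water_template, ff,
                               ens, **kwargs)
    v2 = wb.coulomb_correction(state, water_template, water_template, ff,
                               ens, **kwargs)
    assert v1 == v2 and math.isfinite(v1)


# ---------------------------------------------------------------------------
# reference formulas and assembly
# ---------------------------------------------------------------------------

def test_reference_mu_ideal_gas_is_zero():
    state = wb.ThermoState(320.0, number_density=0.01)
    assert wb.reference_mu_from_zphi(state, 1.0, 1.0) == 0.0


def test_reference_mu_analytic_value():
    state = wb.ThermoState(320.0, number_density=0.01)
    z_phi = math.e
    assert wb.reference_mu_from_zphi(state, z_phi, 1.0) == \
        pytest.approx(wb.K_B * 320.0, rel=1e-12)
    assert wb.reference_mu_from_zphi(state, 0.9, 0.8) == \
        pytest.approx(state.kt * math.log(0.72), rel=1e-12)
    with pytest.raises(ValueError):
        wb.reference_mu_from_zphi(state, -1.0, 1.0)


def test_saturation_pressure_ideal_coexistence_is_zero():
    state = wb.ThermoState(320.0, number_density=1e-5)
    from widombias.model import BOLTZMANN_SI
    p_ideal_kpa = (1e-5 * 1e30) * BOLTZMANN_SI * 320.0 / 1e3
    assert wb.mu_from_saturation_pressure(state, p_ideal_kpa) == \
        pytest.approx(0.0, abs=1e-12)


def test_saturation_pressure_logarithm_law():
    state = wb.ThermoState(320.0, number_density=0.005)
    d = wb.mu_from_saturation_pressure(state, 52.8) \
        - wb.mu_from_saturation_pressure(state, 26.4)
    assert d == pytest.approx(state.kt * math.log(2.0), rel=1e-12)
    with pytest.raises(ValueError):
        wb.mu_from_saturation_pressure(state, -1.0)


def _raw_estimate(mu_raw, unc=0.0019):
    return wb.WidomEstimate(mu_ex_raw=mu_raw, uncertainty=unc,
                            temperature=320.0, n_attempts=100, n_nonzero=50,
                            per_configuration_means=np.full(5, 0.5))


def test_assemble_zero_corrections_is_identity():
    raw = _raw_estimate(0.4968)
    out = wb.assemble_corrected_estimate(raw, 0.0, 0.0)
    assert out.mu_ex_corrected == raw.mu_ex_raw


def test_assemble_row_arithmetic():
    """Corrected value is the plain sum of the raw estimate and the two
    tail corrections; uncertainty carries through."""
    out = wb.assemble_corrected_estimate(_raw_estimate(0.4968), -0.0837, 0.0)
    assert out.mu_ex_corrected == pytest.approx(0.4131, abs=1e-12)
    out2 = wb.assemble_corrected_estimate(_raw_estimate(-5.5414, 0.083),
                                          -0.0594, -0.3056)
    assert out2.mu_ex_corrected == pytest.approx(-5.9064, abs=1e-12)
    assert out2.uncertainty == 0.083
    assert out2.mu_ex_raw == -5.5414


def test_assemble_rejects_non_finite_raw():
    with pytest.raises(ValueError):
        wb.assemble_corrected_estimate(_raw_estimate(math.inf), -0.1, 0.0)


def test_reference_state_validation():
    with pytest.raises(ValueError):
        wb.ReferenceState(compression_factor=-1.0)
    ref = wb.ReferenceState(compression_factor=0.9, fugacity_coefficient=0.8)
    assert ref.compression_factor == 0.9
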