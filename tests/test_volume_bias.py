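"""Grid meshing, two-level criterion, detailed average, biased estimator."""

import math

import numpy as np
import pytest

import widombias as wb
from widombias.volume_bias import _screen_config

from conftest import random_lj_configuration


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

def test_mesh_unit_cells(argon_template):
    config = wb.Configuration(np.array([50.0] * 3), [argon_template],
                              [wb.Pose((1, 1, 1))])
    grid = wb.mesh_grid(config, 50)
    assert grid.cell_edge == pytest.approx(1.0, rel=1e-12)
    assert grid.cell_volume == pytest.approx(1.0, rel=1e-12)
    assert grid.n_cells == 125_000


def test_mesh_single_cell(argon_template):
    config = wb.Configuration(np.array([8.0] * 3), [argon_template],
                              [wb.Pose((1, 1, 1))])
    grid = wb.mesh_grid(config, 1)
    assert grid.n_cells == 1
    np.testing.assert_allclose(grid.cell_center(0, 0, 0), [4.0, 4.0, 4.0])


def test_mesh_centers_enumerable_by_hand(argon_template):
    config = wb.Configuration(np.array([6.0] * 3), [argon_template],
                              [wb.Pose((1, 1, 1))])
    grid = wb.mesh_grid(config, 3)
    expected = [(i + 0.5) * 2.0 for i in range(3)]
    for i in range(3):
        for j in range(3):
            for k in range(3):
                np.testing.assert_allclose(
                    grid.cell_center(i, j, k),
                    [expected[i], expected[j], expected[k]])


def test_mesh_rejects_non_cubic_box(argon_template):
    config = wb.Configuration(np.array([10.0, 12.0, 10.0]), [argon_template],
                              [wb.Pose((1, 1, 1))])
    with pytest.raises(ValueError, match="per-axis"):
        wb.mesh_grid(config, 10)


# ---------------------------------------------------------------------------
# two-level criterion
# ---------------------------------------------------------------------------

def test_first_level_empty_configuration_passes(argon_template):
    config = wb.Configuration(np.array([10.0] * 3), [], [])
    assert wb.first_level_check(config, (5, 5, 5), argon_template, 1.0)


def test_first_level_strict_at_boundary(argon_template):
    box = np.array([20.0] * 3)
    config = wb.Configuration(box, [argon_template], [wb.Pose((5, 5, 5))])
    # nearest atom exactly at d_min -> fail ("greater than" is strict)
    assert not wb.first_level_check(config, (6.0, 5, 5), argon_template, 1.0)
    assert wb.first_level_check(config, (6.0 + 1e-9, 5, 5), argon_template, 1.0)


def test_first_level_agrees_with_brute_force(water_template):
    rng = np.random.default_rng(12)
    box = np.array([14.0] * 3)
    config = random_lj_configuration(40, 14.0, seed=21)
    for _ in range(60):
        center = rng.random(3) * box
        got = wb.first_level_check(config, center, water_template, 1.0)
        probe_sites = center + water_template.body_coords
        dmin = min(
            np.linalg.norm(wb.minimum_image_vector(p, s, box))
            for p in probe_sites for s in config.site_positions)
        assert got == (dmin > 1.0)


def test_second_level_noninteracting_probe_fails_default():
    fix = wb.make_fixture("ideal_gas")
    config = fix.ensemble.configurations[0]
    ok, b = wb.second_level_check(config, (5, 5, 5), fix.probe,
                                  fix.forcefield, fix.ensemble.state, 100.0)
    assert b == 1.0 and not ok


def test_second_level_strict_boundary(argon_template, argon_state):
    """Pass iff B strictly exceeds the threshold: the exact centre factor
    used as its own threshold must fail; a hair lower passes."""
    box = np.array([20.0] * 3)
    config = wb.Configuration(box, [argon_template], [wb.Pose((5, 5, 5))])
    center = (5 + 2 ** (1 / 6) * 3.405, 5, 5)
    _, b = wb.second_level_check(config, center, argon_template,
                                 wb.ForceField(r_cut=9.0), argon_state, 0.0)
    assert b > 1.0
    ok_eq, _ = wb.second_level_check(config, center, argon_template,
                                     wb.ForceField(r_cut=9.0), argon_state, b)
    ok_lo, _ = wb.second_level_check(config, center, argon_template,
                                     wb.ForceField(r_cut=9.0), argon_state,
                                     b * (1 - 1e-9))
    assert not ok_eq and ok_lo


def test_frozen_cavity_center_cell_passes_both_levels():
    fix = wb.make_fixture("frozen_cavity")
    config = fix.ensemble.configurations[0]
    state = fix.ensemble.state
    center = fix.expected["center"]
    assert wb.first_level_check(config, center, fix.probe, 1.0)
    ok, b = wb.second_level_check(config, center, fix.probe, fix.forcefield,
                                  state, 100.0)
    assert ok
    assert b == pytest.approx(fix.expected["boltzmann_center"], rel=1e-9)


# ---------------------------------------------------------------------------
# pose stencil
# ---------------------------------------------------------------------------

def test_translation_directions_cardinality_and_norms():
    dirs = wb.translation_directions()
    assert dirs.shape == (14, 3)
    assert len({tuple(np.round(d, 12)) for d in dirs}) == 14
    np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)


def test_rotation_set_proper_and_distinct():
    rots = wb.rotation_set()
    assert rots.shape == (17, 3, 3)
    seen = set()
    for r in rots:
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)
        seen.add(tuple(np.round(r, 9).ravel()))
    assert len(seen) == 17
    assert not any(np.allclose(r, np.eye(3)) for r in rots)


def test_detail_pose_count_and_step_brackets():
    crit = wb.CriterionConfig()
    assert len(wb.detail_poses((5, 5, 5), 1.0, 5000.0, crit)) == 238
    assert len(wb.detail_poses((5, 5, 5), 1.0, 5000.0,
                               wb.CriterionConfig(include_center=True))) == 239
    for b_center, frac in ((5000.0, 1 / 3), (20_000.0, 1 / 4),
                           (10_000.0, 1 / 4)):
        poses = wb.detail_poses((5, 5, 5), 1.0, b_center, crit)
        steps = {round(np.linalg.norm(p.position - np.array([5., 5., 5.])), 9)
                 for p in poses}
        assert steps == {round(frac, 9)}


def test_monatomic_rotations_leave_energy_invariant(argon_template,
                                                    argon_state):
    config = random_lj_configuration(30, 14.0, seed=5)
    ff = wb.ForceField(r_cut=6.0)
    crit = wb.CriterionConfig()
    center = np.array([7.0, 7.0, 7.0])
    poses = wb.detail_poses(center, 1.0, 500.0, crit)
    b = [wb.insertion_energy(config, argon_template, p, ff,
                             argon_state).boltzmann for p in poses]
    full = np.mean(b)
    translations_only = np.mean(b[::17])  # one orientation per translation
    assert full == pytest.approx(translations_only, rel=1e-12)


def test_detailed_average_matches_explicit_enumeration(water_template):
    """Kernel detailed average for a planar rigid molecule near a wall of
    fixed atoms equals the explicit 238-pose enumeration."""
    state = wb.ThermoState(315.0, number_density=0.001)
    ff = wb.ForceField(r_cut=7.0, coulomb_style="truncated-shifted")
    box = np.array([16.0] * 3)
    wall = wb.MoleculeTemplate(
        "wall", [wb.SiteSpec("W", 3.0, 0.15, 0.1, 10.0),
                 wb.SiteSpec("W2", 3.0, 0.15, -0.1, 10.0)],
        np.array([[0.0, 0.0, 0.7], [0.0, 0.0, -0.7]]))
    poses = [wb.Pose((4.0, 4.0 + 2.0 * i, 8.0)) for i in range(4)]
    config = wb.Configuration(box, [wall] * 4, poses)
    crit = wb.CriterionConfig()
    center = np.array([8.0, 8.0, 8.0])
    _, b_center = wb.second_level_check(config, center, water_template, ff,
                                        state, 0.0)
    explicit = np.mean([
        wb.insertion_energy(config, water_template, p, ff, state).boltzmann
        for p in wb.detail_poses(center, 2.0, b_center, crit)])
    kernel = wb.detailed_average(config, water_template, ff, state, center,
                                 2.0, crit, b_center=b_center)
    assert kernel == pytest.approx(explicit, rel=1e-12)
    # and the batch path used by the estimator agrees too
    grid = wb.mesh_grid(config, 8)
    from widombias.volume_bias import _detail_means_stencil
    screened = _screen_config(config, water_template, ff, state, 8,
                              wb.CriterionConfig(d_min=1.0, b_threshold=0.0))
    centers = screened.accepted_centers()
    idx = np.flatnonzero(np.all(np.isclose(centers, center), axis=1))
    if len(idx):
        means = _detail_means_stencil(config, water_template, ff, state,
                                      screened, crit)
        assert means[idx[0]] == pytest.approx(explicit, rel=1e-10)


# ---------------------------------------------------------------------------
# biased estimator
# ---------------------------------------------------------------------------

def test_hard_core_lattice_biased_estimate_exact():
    """Blocked volume is a union of whole cells: accepted fraction equals
    f_free exactly and every accepted Boltzmann factor is 1."""
    fix = wb.make_fixture("hard_core_lattice", n_per_side=8, f_free=0.5,
                          seed=3)
    crit = wb.CriterionConfig(d_min=0.0, b_threshold=0.0)
    est, report = wb.volume_bias_estimate(
        fix.ensemble, fix.probe, fix.forcefield,
        n_per_side=fix.expected["n_per_side"], criterion=crit)
    kt = fix.ensemble.state.kt
    assert report.fractions[0] == pytest.approx(fix.expected["f_free"],
                                                abs=1e-15)
    assert est.mu_ex_raw == pytest.approx(kt * math.log(2.0), rel=1e-12)
    assert est.mu_ex_raw == pytest.approx(fix.expected["mu_ex"], rel=1e-12)


def test_fraction_bounds_and_threshold_monotonicity(argon_template,
                                                    argon_state):
    """Raising d_min or b_threshold never increases the accepted count."""
    config = random_lj_configuration(40, 12.0, seed=31)
    ff = wb.ForceField(r_cut=5.0)
    prev = None
    for d_min in (0.0, 0.5, 1.0, 1.5, 2.5):
        grid = _screen_config(config, argon_template, ff, argon_state, 10,
                              wb.CriterionConfig(d_min=d_min, b_threshold=0.0))
        assert 0.0 <= grid.accepted_fraction <= 1.0
        if prev is not None:
            assert grid.n_fv <= prev
        prev = grid.n_fv
    prev = None
    prev_det = None
    for b in (0.0, 1.0, 10.0, 100.0, 1e4):
        grid = _screen_config(config, argon_template, ff, argon_state, 10,
                              wb.CriterionConfig(d_min=0.0, b_threshold=b))
        if prev is not None:
            assert grid.n_fv <= prev          # free volume untouched by b
            assert grid.n_detailed <= prev_det  # refinement set shrinks
        prev = grid.n_fv
        prev_det = grid.n_detailed


def test_biased_path_is_deterministic(argon_small_ensemble, argon_template):
    ens, ff = argon_small_ensemble
    sub = wb.EnsembleSample(ens.configurations[:3], ens.state)
    crit = wb.CriterionConfig(d_min=0.5, b_threshold=1.0)
    e1, r1 = wb.volume_bias_estimate(sub, argon_template, ff, n_per_side=10,
                                     criterion=crit)
    e2, r2 = wb.volume_bias_estimate(sub, argon_template, ff, n_per_side=10,
                                     criterion=crit)
    assert e1.mu_ex_raw == e2.mu_ex_raw
    np.testing.assert_array_equal(r1.fractions, r2.fractions)


def test_all_rejected_gives_inf_sentinel(argon_template, argon_state):
    config = random_lj_configuration(30, 10.0, seed=7)
    ens = wb.EnsembleSample([config], argon_state)
    crit = wb.CriterionConfig(d_min=9.0, b_threshold=0.0)  # nothing passes
    with pytest.warns(UserWarning, match="estimator undefined"):
        est, report = wb.volume_bias_estimate(ens, argon_template,
                                              wb.ForceField(r_cut=4.5),
                                              n_per_side=8, criterion=crit)
    assert math.isinf(est.mu_ex_raw)
    assert report.n_fv[0] == 0
    assert math.isinf(report.bias_bound)


def test_estimator_equivalence_criteria_disabled(argon_small_ensemble,
                                                 argon_template):
    """Disabling both criteria and sampling cells uniformly reduces the
    biased estimator to the unbiased one (stratified uniform sampling)."""
    ens, ff = argon_small_ensemble
    sub = wb.EnsembleSample(ens.configurations[:8], ens.state)
    crit = wb.CriterionConfig(d_min=0.0, b_threshold=0.0,
                              detail_mode="uniform", n_uniform=60)
    biased, rep = wb.volume_bias_estimate(sub, argon_template, ff,
                                          n_per_side=6, criterion=crit, rng=3)
    # every cell must be accepted once the criteria are off
    np.testing.assert_allclose(rep.fractions, 1.0)
    unbiased, _ = wb.widom_unbiased(sub, argon_template, ff,
                                    6 ** 3 * 60, rng=4)
    se = math.hypot(biased.uncertainty, unbiased.uncertainty)
    assert abs(biased.mu_ex_raw - unbiased.mu_ex_raw) < 3 * se


def test_bias_bound_reported(argon_small_ensemble, argon_template):
    ens, ff = argon_small_ensemble
    sub = wb.EnsembleSample(ens.configurations[:3], ens.state)
    crit = wb.CriterionConfig(d_min=0.0, b_threshold=0.5)
    est, rep = wb.volume_bias_estimate(sub, argon_template, ff, n_per_side=8,
                                       criterion=crit)
    centre_frac = rep.fractions.mean() - rep.n_detailed.mean() / 8 ** 3
    expected = crit.b_threshold * centre_frac \
        / math.exp(-ens.state.beta * est.mu_ex_raw)
    assert rep.bias_bound == pytest.approx(expected, rel=1e-9)
    assert 0.0 <= rep.detailed_weight_share <= 1.0


def test_criterion_config_validation():
    with pytest.raises(ValueError):
        wb.CriterionConfig(d_min=-1.0)
    with pytest.raises(ValueError):
        wb.CriterionConfig(step_fractions=(0.6, 0.25))
    with pytest.raises(ValueError):
        wb.CriterionConfig(detail_mode="grid")
    bad_dirs = np.zeros((14, 3))
    with pytest.raises(ValueError, match="distinct"):
        wb.CriterionConfig(translation_directions=bad_dirs)
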