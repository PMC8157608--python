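"""End-to-end state-point drivers: generate an NVT ensemble, run an
estimator, apply long-range corrections.

These functions pin the study conditions used throughout the package:
512 Lennard-Jones argon atoms or 512 rigid TIP3P waters, r_cut 10 A,
50 decorrelated configurations per ensemble.  Argon defaults to the
unbiased estimator with 1.2e5 insertions per configuration; water to the
two-level volume-detection-bias estimator with a ~1 A mesh and the default
criterion (d_min 1 A, threshold 100, 14 x 17 detailed average).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config_gen import EnsembleSample, MCSettings, sample_ensemble
from .corrections import (assemble_corrected_estimate, coulomb_correction,
                          lj_tail_correction)
from .model import (ForceField, MoleculeTemplate, ThermoState, argon,
                    tip3p_water)
from .volume_bias import CriterionConfig, VolumeBiasReport, volume_bias_estimate
from .widom import ConvergenceTrace, WidomEstimate, widom_unbiased


@dataclass
class StatePointResult:
    """Everything one state-point run produced."""

    species: str
    state: ThermoState
    estimate: WidomEstimate          # corrections filled
    trace: ConvergenceTrace
    ensemble: EnsembleSample
    estimator: str
    report: VolumeBiasReport | None = None
    details: dict = field(default_factory=dict)


def run_state_point(template: MoleculeTemplate, state: ThermoState,
                    n_molecules: int, ff: ForceField, settings: MCSettings,
                    estimator: str = "unbiased",
                    n_insertions: int = 120_000,
                    n_per_side: int | None = None,
                    criterion: CriterionConfig | None = None,
                    seed: int = 0,
                    apply_corrections: bool = True,
                    coulomb_kwargs: dict | None = None) -> StatePointResult:
    """Generate an ensemble and estimate the self-insertion mu_ex."""
    gen_settings = MCSettings(
        n_equilibration_sweeps=settings.n_equilibration_sweeps,
        n_samples=settings.n_samples, stride_sweeps=settings.stride_sweeps,
        max_translation=settings.max_translation,
        max_rotation=settings.max_rotation, seed=seed)
    ensemble = sample_ensemble(template, n_molecules, state, ff, gen_settings)
    report = None
    if estimator == "unbiased":
        estimate, trace = widom_unbiased(
            ensemble, template, ff, n_insertions,
            rng=np.random.default_rng(seed + 1_000_003), state=state)
    elif estimator == "vbias":
        if n_per_side is None:
            n_per_side = max(2, int(round(float(ensemble.box[0]))))
        estimate, report = volume_bias_estimate(
            ensemble, template, ff, state, n_per_side=n_per_side,
            criterion=criterion)
        trace = report.trace
    else:
        raise ValueError("estimator must be 'unbiased' or 'vbias'")
    mu_p = mu_c = 0.0
    if apply_corrections and math.isfinite(estimate.mu_ex_raw):
        if ff.pair_style == "lj":
            mu_p = lj_tail_correction(state, template, template, ff)
        if template.has_charges and ff.coulomb_code == 1:
            kwargs = coulomb_kwargs or {}
            mu_c = coulomb_correction(state, template, template, ff, ensemble,
                                      seed=seed + 2_000_003, **kwargs)
        estimate = assemble_corrected_estimate(estimate, mu_p, mu_c)
    return StatePointResult(template.name, state, estimate, trace, ensemble,
                            estimator, report,
                            {"n_molecules": n_molecules, "seed": seed})


def argon_state_point(mass_density: float, temperature: float = 320.0,
                      n_molecules: int = 512, seed: int = 0,
                      n_insertions: int = 120_000,
                      estimator: str = "unbiased",
                      n_samples: int = 50) -> StatePointResult:
    """Self-insertion mu_ex of LJ argon at one (T, rho) state point."""
    template = argon()
    state = ThermoState.from_mass_density(temperature, mass_density,
                                          template.molar_mass)
    settings = MCSettings(n_equilibration_sweeps=1500, n_samples=n_samples,
                          stride_sweeps=40, max_translation=1.0,
                          max_rotation=0.5, seed=seed)
    return run_state_point(template, state, n_molecules, ForceField(r_cut=10.0),
                           settings, estimator=estimator,
                           n_insertions=n_insertions, seed=seed)


def water_state_point(mass_density: float = 991.0, temperature: float = 315.0,
                      n_molecules: int = 512, seed: int = 0,
                      estimator: str = "vbias",
                      n_samples: int = 50,
                      n_equilibration: int = 3000,
                      stride: int = 30,
                      n_insertions: int = 120_000,
                      n_per_side: int = 50,
                      criterion: CriterionConfig | None = None) -> StatePointResult:
    """Self-insertion mu_ex of rigid TIP3P water (volume-bias by default,
    50 x 50 x 50 detection mesh)."""
    template = tip3p_water()
    state = ThermoState.from_mass_density(temperature, mass_density,
                                          template.molar_mass)
    ff = ForceField(r_cut=10.0, coulomb_style="truncated-shifted")
    settings = MCSettings(n_equilibration_sweeps=n_equilibration,
                          n_samples=n_samples, stride_sweeps=stride,
                          max_translation=0.25, max_rotation=0.25, seed=seed)
    return run_state_point(template, state, n_molecules, ff, settings,
                           estimator=estimator, n_insertions=n_insertions,
                           n_per_side=n_per_side, criterion=criterion,
                           seed=seed)


def format_table_row(result: StatePointResult) -> str:
    """One fixed-width report row: T, rho, mu_ex_W +/- u, mu_ex_p, mu_ex_c,
    corrected mu_ex (the layout of the package's tabular report)."""
    e = result.estimate
    rho = result.state.mass_density
    rho_txt = f"{rho:8.1f}" if rho is not None else "     n/a"
    return (f"{result.species:<8s} {result.state.temperature:7.1f} {rho_txt} "
            f"{e.mu_ex_raw:10.4f} +/- {e.uncertainty:7.4f} "
            f"{e.mu_tail_lj:9.4f} {e.mu_tail_coulomb:9.4f} "
            f"{e.mu_ex_corrected:10.4f}")


TABLE_HEADER = (f"{'species':<8s} {'T/K':>7s} {'rho':>8s} "
                f"{'mu_ex_W':>10s} {'':>11s} {'mu_ex_p':>9s} {'mu_ex_c':>9s} "
                f"{'mu_ex':>10s}")
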