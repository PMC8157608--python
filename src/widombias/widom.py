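"""Unbiased Widom test-particle insertion.

The excess chemical potential of a species is estimated from equilibrium
configurations as

    mu_ex = -k_B T ln < e^(-beta dU) >

where dU is the energy of inserting a ghost copy of the probe at a uniformly
random position and orientation.  Configurations are pooled with equal
weight: each contributes the mean Boltzmann factor of its own insertions,
and the grand mean over configurations enters the logarithm (a flat pooling
over all insertions is available as ``pooling="flat"``; the two coincide
when every configuration receives the same number of attempts).

The ideal-gas term uses a thermal wavelength fixed at 1 A by convention; it
cancels in every excess-quantity comparison made here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .model import (Configuration, ForceField, K_B, MoleculeTemplate,
                    ThermoState)
from .config_gen import EnsembleSample


@dataclass(frozen=True)
class WidomEstimate:
    """A Widom estimate with its uncertainty and long-range corrections.

    ``mu_ex_raw`` is the truncated-potential estimate; ``mu_tail_lj`` and
    ``mu_tail_coulomb`` are the dispersion and electrostatic long-range
    corrections (zero until filled by the corrections module);
    ``mu_ex_corrected`` is always their sum.
    """

    mu_ex_raw: float
    uncertainty: float
    temperature: float
    n_attempts: int
    n_nonzero: int
    per_configuration_means: np.ndarray
    mu_tail_lj: float = 0.0
    mu_tail_coulomb: float = 0.0

    @property
    def mu_ex_corrected(self) -> float:
        return self.mu_ex_raw + self.mu_tail_lj + self.mu_tail_coulomb

    @property
    def kt(self) -> float:
        return K_B * self.temperature

    def with_corrections(self, mu_tail_lj: float,
                         mu_tail_coulomb: float) -> "WidomEstimate":
        return replace(self, mu_tail_lj=mu_tail_lj,
                       mu_tail_coulomb=mu_tail_coulomb)


@dataclass(frozen=True)
class ConvergenceTrace:
    """Cumulative estimate vs configurations processed, plus block means."""

    cumulative_mu: np.ndarray       # -kT ln(running mean), length n_configs
    block_mu: np.ndarray            # one mu per complete block
    block_size: int


def _mu_from_mean(mean_b: float, kt: float) -> float:
    if mean_b <= 0.0:
        return math.inf
    return -kt * math.log(mean_b)


def _trace_from_means(per_config: np.ndarray, kt: float,
                      block_size: int = 50) -> ConvergenceTrace:
    running = np.cumsum(per_config) / np.arange(1, len(per_config) + 1)
    with np.errstate(divide="ignore"):
        cumulative = np.where(running > 0, -kt * np.log(np.maximum(running, 1e-300)),
                              np.inf)
    n_blocks = len(per_config) // block_size
    block_mu = np.array([
        _mu_from_mean(per_config[b * block_size:(b + 1) * block_size].mean(), kt)
        for b in range(n_blocks)])
    return ConvergenceTrace(cumulative, block_mu, block_size)


def block_uncertainty(per_configuration_means, block_size: int = 50,
                      state: ThermoState | None = None,
                      kt: float | None = None) -> float:
    """Std of the per-block excess chemical potentials.

    Configurations are partitioned into consecutive blocks of ``block_size``
    (trailing partial block dropped); each block's mean Boltzmann factor is
    converted to a mu value and the sample standard deviation of those mu
    values is returned.  NaN when fewer than two complete blocks exist.
    """
    means = np.asarray(per_configuration_means, dtype=float)
    if kt is None:
        if state is None:
            raise ValueError("provide state or kt")
        kt = state.kt
    if len(means) < block_size:
        raise ValueError("need at least one complete block")
    n_blocks = len(means) // block_size
    if n_blocks < 2:
        return math.nan
    block_mu = [
        _mu_from_mean(means[b * block_size:(b + 1) * block_size].mean(), kt)
        for b in range(n_blocks)]
    return float(np.std(block_mu, ddof=1))


def _fallback_uncertainty(per_config: np.ndarray, kt: float) -> float:
    """Delta-method standard error of -kT ln(mean) over configurations."""
    grand = per_config.mean()
    if grand <= 0 or len(per_config) < 2:
        return math.nan
    sem = per_config.std(ddof=1) / math.sqrt(len(per_config))
    return kt * sem / grand


def estimate_from_config_means(per_config: np.ndarray, state: ThermoState,
                               n_attempts: int, n_nonzero: int,
                               block_size: int = 50) -> tuple[WidomEstimate,
                                                              ConvergenceTrace]:
    """Assemble an estimate + trace from per-configuration mean factors."""
    per_config = np.asarray(per_config, dtype=float)
    kt = state.kt
    grand = per_config.mean()
    if grand <= 0.0:
        warnings.warn("all insertion Boltzmann factors are zero; "
                      "estimator undefined (+inf sentinel)")
        mu = math.inf
    else:
        mu = -kt * math.log(grand)
    unc = math.nan
    if len(per_config) >= 2 * block_size:
        unc = block_uncertainty(per_config, block_size, kt=kt)
    if not np.isfinite(unc):
        unc = _fallback_uncertainty(per_config, kt)
    if not np.isfinite(unc):
        unc = 0.0 if np.isfinite(mu) else math.nan
    estimate = WidomEstimate(
        mu_ex_raw=mu, uncertainty=float(unc), temperature=state.temperature,
        n_attempts=n_attempts, n_nonzero=n_nonzero,
        per_configuration_means=per_config)
    return estimate, _trace_from_means(per_config, kt, block_size)


def random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniform random rotation matrices (quaternions from 4 normals)."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    rot = np.empty((n, 3, 3))
    rot[:, 0, 0] = 1 - 2 * (y * y + z * z)
    rot[:, 0, 1] = 2 * (x * y - w * z)
    rot[:, 0, 2] = 2 * (x * z + w * y)
    rot[:, 1, 0] = 2 * (x * y + w * z)
    rot[:, 1, 1] = 1 - 2 * (x * x + z * z)
    rot[:, 1, 2] = 2 * (y * z - w * x)
    rot[:, 2, 0] = 2 * (x * z - w * y)
    rot[:, 2, 1] = 2 * (y * z + w * x)
    rot[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return rot


def insertion_boltzmann_batch(config: Configuration, probe: MoleculeTemplate,
                              ff: ForceField, state: ThermoState,
                              positions: np.ndarray,
                              rotations: np.ndarray | None = None) -> np.ndarray:
    """Boltzmann factors for a batch of trial poses in one configuration."""
    positions = np.ascontiguousarray(positions, dtype=float)
    k = positions.shape[0]
    if rotations is None:
        rotations = np.broadcast_to(np.eye(3), (k, 3, 3))
    rotations = np.ascontiguousarray(rotations, dtype=float)
    pos, sig, eps, chg, mol = config.site_arrays()
    out = np.empty(k)
    _kernels.widom_batch_kernel(
        positions, rotations, np.asarray(probe.body_coords, float),
        probe.sigmas, probe.epsilons, probe.charges,
        pos, sig, eps, chg, mol, config.molecule_centroids,
        config.box, ff.r_cut,
        ff.style_code, ff.coulomb_code, state.beta, out)
    return out


def widom_unbiased(ensemble: EnsembleSample, probe: MoleculeTemplate,
                   ff: ForceField, n_insertions_per_config: int,
                   rng, state: ThermoState | None = None,
                   pooling: str = "per_config",
                   block_size: int = 50) -> tuple[WidomEstimate,
                                                  ConvergenceTrace]:
    """Unbiased Widom estimator over an ensemble.

    Poses are drawn uniformly over the box with uniform random orientations.
    Tail-correction fields of the returned estimate are zero; fill them with
    the corrections module.
    """
    if n_insertions_per_config < 1:
        raise ValueError("need at least one insertion per configuration")
    if pooling not in ("per_config", "flat"):
        raise ValueError("pooling must be 'per_config' or 'flat'")
    state = state or ensemble.state
    rng = np.random.default_rng(rng)
    per_config = np.empty(len(ensemble))
    n_attempts = 0
    n_nonzero = 0
    monatomic = probe.is_monatomic
    for i, config in enumerate(ensemble.configurations):
        positions = rng.random((n_insertions_per_config, 3)) * config.box
        rotations = None if monatomic else random_rotations(
            rng, n_insertions_per_config)
        b = insertion_boltzmann_batch(config, probe, ff, state,
                                      positions, rotations)
        per_config[i] = b.mean()
        n_attempts += len(b)
        n_nonzero += int(np.count_nonzero(b))
    # per_config and flat pooling coincide here (equal attempts per config);
    # the flag is honoured for future unequal designs
    return estimate_from_config_means(per_config, state, n_attempts,
                                      n_nonzero, block_size)


def ideal_chemical_potential(state: ThermoState) -> float:
    """mu_id = k_B T ln(rho Lambda^3) with Lambda fixed at 1 A."""
    rho = state.number_density
    if rho is None or rho <= 0:
        raise ValueError("positive number density required")
    return state.kt * math.log(rho)
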