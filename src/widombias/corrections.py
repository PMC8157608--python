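"""Long-range corrections and reference chemical-potential formulas.

``lj_tail_correction`` is the analytic chemical-potential tail of a
truncated 12-6 Lennard-Jones fluid,

    mu_tail = sum_j (16/3) pi rho_j eps_pj sigma_pj^3
              [ (1/3)(sigma_pj/r_c)^9 - (sigma_pj/r_c)^3 ]

summed over probe-site x solvent-site-type pairs (rho_j is the number
density of solvent site type j).  It vanishes as r_c grows and is exactly
linear in density.

``coulomb_correction`` restores the electrostatics lost to the production
truncated-shifted scheme.  The default convention is the analytic dipolar
reaction-field (Onsager) correction for a neutral dipolar probe whose
interactions are cut at r_c,

    mu_c = - C * f_RF * mu_d^2 / r_c^3,   f_RF = (eps - 1) / (2 eps + 1),

with mu_d the probe's permanent dipole (e A) and the conducting-boundary
limit f_RF = 1/2 as default: deterministic, continuous in the charges, and
zero for an apolar probe.  An alternative ``method="fep"`` re-scores a
weight-sampled subset of accepted insertions with full Ewald electrostatics
and exponentially averages the energy difference; it is exposed for
sensitivity analysis but is noisy at production cutoffs (the configurations
are generated under the truncated Hamiltonian, so re-scoring carries
kT-scale structure mismatch) and is not the default.

``reference_mu_from_zphi`` (mu_ex = k_B T ln(z phi)) and
``mu_from_saturation_pressure`` convert tabulated equation-of-state data
and saturation pressures into reference excess chemical potentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc as _erfc

from .model import (BOLTZMANN_SI, COULOMB_CONSTANT, Configuration, ForceField,
                    MoleculeTemplate, ThermoState)
from .config_gen import EnsembleSample
from .widom import WidomEstimate


@dataclass(frozen=True)
class ReferenceState:
    """Tabulated reference data for one state point."""

    compression_factor: float = 1.0      # z
    fugacity_coefficient: float = 1.0    # phi
    saturation_pressure: float = 0.0     # kPa
    fugacity: float = 0.0                # kPa

    def __post_init__(self) -> None:
        if self.compression_factor <= 0 or self.fugacity_coefficient <= 0:
            raise ValueError("z and phi must be positive")
        if self.saturation_pressure < 0 or self.fugacity < 0:
            raise ValueError("pressures must be non-negative")


def lj_tail_correction(state: ThermoState, probe: MoleculeTemplate,
                       solvent: MoleculeTemplate, ff: ForceField) -> float:
    """Dispersion long-range correction mu_ex_p in kcal/mol.

    ``state.number_density`` is the solvent molecule number density; each
    solvent site contributes at that density.
    """
    rho_mol = state.number_density
    if rho_mol is None:
        raise ValueError("state must carry a number density")
    rc = ff.r_cut
    total = 0.0
    for p in probe.sites:
        if p.epsilon <= 0:
            continue
        for s in solvent.sites:
            if s.epsilon <= 0:
                continue
            sij = 0.5 * (p.sigma + s.sigma)
            eij = math.sqrt(p.epsilon * s.epsilon)
            x3 = (sij / rc) ** 3
            total += (16.0 / 3.0) * math.pi * rho_mol * eij * sij ** 3 \
                * (x3 ** 3 / 3.0 - x3)
    return total


# ---------------------------------------------------------------------------
# Ewald electrostatics (correction channel, not the production path)
# ---------------------------------------------------------------------------

class EwaldContext:
    """Ewald summation set up for one configuration's charged sites.

    Parameters are chosen from the box when not given: real-space cutoff
    just under L_min/2, ``alpha = 3.6 / r_real`` (erfc at the cutoff
    ~ 4e-7) and a reciprocal cutoff with matched accuracy.
    """

    def __init__(self, config: Configuration, alpha: float | None = None,
                 n_kmax: int | None = None, r_real: float | None = None):
        box = config.box
        pos, _, _, chg, _ = config.site_arrays()
        charged = chg != 0.0
        self.box = box
        self.volume = float(np.prod(box))
        self.sys_pos = pos[charged]
        self.sys_q = chg[charged]
        self.r_real = r_real if r_real is not None else 0.4999 * float(np.min(box))
        self.alpha = alpha if alpha is not None else 3.6 / self.r_real
        if n_kmax is None:
            k_cut = 2.0 * self.alpha * math.sqrt(math.log(1e8))
            n_kmax = int(math.ceil(k_cut * float(np.max(box)) / (2 * math.pi)))
        self.n_kmax = n_kmax
        self._build_kspace()

    def _build_kspace(self) -> None:
        n = self.n_kmax
        rng = np.arange(-n, n + 1)
        nx, ny, nz = np.meshgrid(rng, rng, rng, indexing="ij")
        nvec = np.stack([nx.ravel(), ny.ravel(), nz.ravel()], axis=1)
        nvec = nvec[np.any(nvec != 0, axis=1)]
        kvec = 2.0 * math.pi * nvec / self.box
        k2 = np.sum(kvec ** 2, axis=1)
        keep = k2 <= (2.0 * math.pi * n / float(np.max(self.box))) ** 2
        kvec, k2 = kvec[keep], k2[keep]
        self.kvec = kvec
        self.a_k = np.exp(-k2 / (4.0 * self.alpha ** 2)) / k2
        # structure factor of the existing charges, chunked over k
        s_sys = np.empty(len(kvec), dtype=complex)
        for lo in range(0, len(kvec), 1024):
            hi = min(lo + 1024, len(kvec))
            phases = np.exp(1j * self.sys_pos @ kvec[lo:hi].T)
            s_sys[lo:hi] = self.sys_q @ phases
        self.s_sys = s_sys

    def probe_insertion_energy(self, probe_pos: np.ndarray,
                               probe_q: np.ndarray) -> float:
        """Full electrostatic insertion energy of a charge set, kcal/mol.

        Intramolecular probe interactions (minimum image) are excluded, as
        everywhere in the package; probe-image interactions are retained.
        """
        probe_pos = np.asarray(probe_pos, float).reshape(-1, 3)
        probe_q = np.asarray(probe_q, float)
        sel = probe_q != 0.0
        probe_pos, probe_q = probe_pos[sel], probe_q[sel]
        if len(probe_q) == 0:
            return 0.0
        a = self.alpha
        # real space: probe vs system
        e_real = 0.0
        if len(self.sys_q):
            d = probe_pos[:, None, :] - self.sys_pos[None, :, :]
            d -= self.box * np.floor(d / self.box + 0.5)
            r = np.sqrt(np.sum(d * d, axis=2))
            mask = r < self.r_real
            rr = np.where(mask, r, 1.0)
            contrib = np.where(mask, _erfc(a * rr) / rr, 0.0)
            e_real = float(np.einsum("i,j,ij->", probe_q, self.sys_q, contrib))
        # reciprocal: cross term + probe self structure factor
        s_p = np.empty(len(self.kvec), dtype=complex)
        for lo in range(0, len(self.kvec), 4096):
            hi = min(lo + 4096, len(self.kvec))
            phases = np.exp(1j * probe_pos @ self.kvec[lo:hi].T)
            s_p[lo:hi] = probe_q @ phases
        e_recip = (2.0 * math.pi / self.volume) * float(
            np.sum(self.a_k * (2.0 * np.real(np.conj(self.s_sys) * s_p)
                               + np.abs(s_p) ** 2)))
        # point self energy
        e_self = -a / math.sqrt(math.pi) * float(np.sum(probe_q ** 2))
        # remove the minimum-image intramolecular pair interactions
        e_intra = 0.0
        if len(probe_q) > 1:
            d = probe_pos[:, None, :] - probe_pos[None, :, :]
            d -= self.box * np.floor(d / self.box + 0.5)
            r = np.sqrt(np.sum(d * d, axis=2))
            iu = np.triu_indices(len(probe_q), k=1)
            from scipy.special import erf as _erf
            e_intra = -float(np.sum(probe_q[iu[0]] * probe_q[iu[1]]
                                    * _erf(a * r[iu]) / r[iu]))
        return COULOMB_CONSTANT * (e_real + e_recip + e_self + e_intra)


def truncated_shifted_coulomb_energy(config: Configuration,
                                     probe_pos: np.ndarray,
                                     probe_q: np.ndarray,
                                     ff: ForceField,
                                     probe_center: np.ndarray | None = None
                                     ) -> float:
    """Electrostatic part of the probe's insertion energy under the
    production scheme (molecule-centroid group cutoff, shifted), kcal/mol."""
    if ff.coulomb_code == 0:
        return 0.0
    pos, _, _, chg, mol = config.site_arrays()
    probe_pos = np.asarray(probe_pos, float).reshape(-1, 3)
    probe_q = np.asarray(probe_q, float)
    if probe_center is None:
        probe_center = probe_pos.mean(axis=0)
    rc = ff.r_cut
    # group inclusion: probe centroid vs molecular centroids
    g = config.molecule_centroids - probe_center
    g -= config.box * np.floor(g / config.box + 0.5)
    included = np.sum(g * g, axis=1) < rc * rc  # per molecule
    site_in = included[mol]
    d = probe_pos[:, None, :] - pos[None, :, :]
    d -= config.box * np.floor(d / config.box + 0.5)
    r = np.sqrt(np.sum(d * d, axis=2))
    mask = site_in[None, :] & (r > 0)
    rr = np.where(mask, r, 1.0)
    contrib = np.where(mask, 1.0 / rr - 1.0 / rc, 0.0)
    return COULOMB_CONSTANT * float(
        np.einsum("i,j,ij->", probe_q, chg, contrib))


def probe_dipole_moment(probe: MoleculeTemplate) -> float:
    """Magnitude of the probe's permanent dipole in e A (body frame)."""
    mu = probe.charges @ probe.body_coords
    return float(np.linalg.norm(mu))


def reaction_field_correction(probe: MoleculeTemplate, ff: ForceField,
                              epsilon_rf: float = math.inf) -> float:
    """Onsager reaction-field estimate of the electrostatics beyond r_cut."""
    f_rf = 0.5 if math.isinf(epsilon_rf) \
        else (epsilon_rf - 1.0) / (2.0 * epsilon_rf + 1.0)
    mu_d = probe_dipole_moment(probe)
    return -COULOMB_CONSTANT * f_rf * mu_d ** 2 / ff.r_cut ** 3


def coulomb_correction(state: ThermoState, probe: MoleculeTemplate,
                       solvent: MoleculeTemplate, ff: ForceField,
                       ensemble: EnsembleSample | None = None,
                       method: str = "reaction-field",
                       epsilon_rf: float = math.inf,
                       n_subsample: int = 256,
                       n_configs_used: int = 16,
                       n_per_side: int | None = None,
                       criterion=None,
                       seed: int = 0) -> float:
    """Electrostatic long-range correction mu_ex_c in kcal/mol.

    Returns 0 for an uncharged probe; refuses a probe with net charge
    (monopole insertion is ill-defined under periodic electrostatics).
    ``method`` selects the convention documented in the module docstring:
    ``"reaction-field"`` (analytic, default) or ``"fep"`` (Ewald re-scoring
    of a weight-sampled insertion subset; needs ``ensemble``).
    """
    if not probe.has_charges:
        return 0.0
    if abs(probe.total_charge) > 1e-9:
        raise ValueError("probe must be charge-neutral for the long-range "
                         "correction (monopole insertion unsupported)")
    if method == "reaction-field":
        return reaction_field_correction(probe, ff, epsilon_rf)
    if method != "fep":
        raise ValueError("method must be 'reaction-field' or 'fep'")
    if ensemble is None:
        raise ValueError("method='fep' needs a configuration ensemble")
    from .volume_bias import CriterionConfig, _screen_config
    criterion = criterion or CriterionConfig()
    rng = np.random.default_rng(seed)
    configs = ensemble.configurations[:max(1, min(n_configs_used, len(ensemble)))]
    if n_per_side is None:
        n_per_side = max(4, int(round(float(configs[0].box[0]))))
    candidates = []  # (config index, centre, weight)
    for ci, config in enumerate(configs):
        grid = _screen_config(config, probe, ff, state, n_per_side, criterion)
        centers = grid.accepted_centers()
        weights = grid.b_center[grid.accepted]
        for c, w in zip(centers, weights):
            candidates.append((ci, c, w))
    if not candidates:
        raise RuntimeError("no accepted insertion cells found; cannot "
                           "estimate the electrostatic correction")
    weights = np.array([c[2] for c in candidates])
    picks = rng.choice(len(candidates), size=n_subsample, replace=True,
                       p=weights / weights.sum())
    ewalds: dict[int, EwaldContext] = {}
    factors = np.empty(n_subsample)
    body = np.asarray(probe.body_coords, float)
    q = probe.charges
    for s, pick in enumerate(picks):
        ci, center, _w = candidates[pick]
        config = configs[ci]
        if ci not in ewalds:
            ewalds[ci] = EwaldContext(config)
        probe_pos = center + body
        u_full = ewalds[ci].probe_insertion_energy(probe_pos, q)
        u_trunc = truncated_shifted_coulomb_energy(config, probe_pos, q, ff,
                                                   probe_center=center)
        factors[s] = math.exp(-state.beta * (u_full - u_trunc))
    return -state.kt * math.log(float(factors.mean()))


# ---------------------------------------------------------------------------
# reference formulas
# ---------------------------------------------------------------------------

def reference_mu_from_zphi(state: ThermoState, z: float, phi: float) -> float:
    """mu_ex_R = k_B T ln(z * phi) from a compression factor and fugacity
    coefficient (equation-of-state reference data)."""
    if z <= 0 or phi <= 0:
        raise ValueError("z and phi must be positive")
    return state.kt * math.log(z * phi)


def mu_from_saturation_pressure(state: ThermoState, p_sat_kpa: float) -> float:
    """Excess chemical potential from the saturation-vapour-pressure
    approximation of the fugacity, with the ideal term at the liquid's own
    density subtracted: mu_ex ~ k_B T ln( P_sat / (rho_liq k_B T) )."""
    rho = state.number_density
    if rho is None or rho <= 0 or p_sat_kpa <= 0:
        raise ValueError("positive liquid density and pressure required")
    rho_si = rho * 1.0e30  # A^-3 -> m^-3
    ratio = p_sat_kpa * 1.0e3 / (rho_si * BOLTZMANN_SI * state.temperature)
    return state.kt * math.log(ratio)


def assemble_corrected_estimate(raw: WidomEstimate, mu_ex_p: float,
                                mu_ex_c: float) -> WidomEstimate:
    """Fill the tail-correction fields; corrected value is the plain sum and
    the raw value and uncertainty are carried through unchanged."""
    if not np.isfinite(raw.mu_ex_raw):
        raise ValueError("raw estimate must be finite before correction")
    return raw.with_corrections(mu_ex_p, mu_ex_c)
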