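"""Diffusion-encounter bookkeeping for extracellular seeds.

Stokes-Einstein diffusion of fibrillar seeds, the steady-state
diffusion-limited flux onto an absorbing spherical cell (Smoluchowski,
``J = 4 pi a D c_inf``), seed-concentration inventories in monomer
equivalents, the per-encounter seeding probability, and the secreted-
aggregate budget. Internally SI throughout; convenience converters handle
nM and litres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger(__name__)

K_B = 1.380649e-23  # J/K, exact
N_A = 6.02214076e23  # 1/mol, exact


def nM_to_per_m3(c_nM: float) -> float:
    """Number concentration (m^-3) of a c nM solution."""
    return c_nM * 1e-9 * N_A * 1e3


def per_m3_to_nM(c: float) -> float:
    return c / (1e-9 * N_A * 1e3)


@dataclass(frozen=True)
class TransportParams:
    """Physical constants and geometry for the encounter estimate.

    Defaults are the cell-culture conditions: 37 °C, DMEM + 10% FBS
    viscosity, ~50 nm effective hydrodynamic radius of a sonicated seed,
    10 µm cell radius, 4 h seeding exposure.
    """

    T: float = 310.15  # K
    eta: float = 0.94e-3  # Pa s
    R_H: float = 50e-9  # m
    a: float = 10e-6  # m (cell radius)
    c_inf_nM: float = 6.0  # far-field seed concentration
    duration_s: float = 4 * 3600.0

    def __post_init__(self):
        for name in ("T", "eta", "R_H", "a", "c_inf_nM", "duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def stokes_einstein(T: float, eta: float, R_H: float) -> float:
    """Diffusion coefficient D = k_B T / (6 pi eta R_H), m^2 s^-1."""
    if T <= 0 or eta <= 0 or R_H <= 0:
        raise ValueError("T, eta and R_H must be positive")
    return K_B * T / (6.0 * math.pi * eta * R_H)


def encounter_flux(a: float, D: float, c_inf_per_m3: float) -> float:
    """Steady-state diffusive flux J = 4 pi a D c_inf onto an absorbing
    sphere of radius ``a`` (m), in encounters per second."""
    if a <= 0 or D <= 0 or c_inf_per_m3 < 0:
        raise ValueError("a and D must be positive, c_inf non-negative")
    return 4.0 * math.pi * a * D * c_inf_per_m3


def encounters(J: float, duration_s: float) -> float:
    """Number of seed-cell encounters over an exposure time."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return J * duration_s


@dataclass(frozen=True)
class SeedInventory:
    """Seed bookkeeping from a monomer-equivalent concentration."""

    monomer_equiv_conc_M: float
    monomers_per_seed: float
    volume_L: float
    n_cells: float
    seed_conc_M: float
    seed_conc_nM: float
    seeds_total: float
    seeds_per_cell: float


def seed_inventory(
    monomer_equiv_conc_M: float,
    monomers_per_seed: float,
    volume_L: float,
    n_cells: float,
) -> SeedInventory:
    """Particle concentration and total/ per-cell seed numbers.

    A monomer-equivalent concentration divided by the number of monomers per
    seed gives the particle concentration; multiplied by volume and
    Avogadro's number it gives the absolute seed count.
    """
    if min(monomer_equiv_conc_M, monomers_per_seed, volume_L, n_cells) <= 0:
        raise ValueError("all inputs must be positive")
    conc = monomer_equiv_conc_M / monomers_per_seed
    total = conc * volume_L * N_A
    return SeedInventory(
        monomer_equiv_conc_M=monomer_equiv_conc_M,
        monomers_per_seed=monomers_per_seed,
        volume_L=volume_L,
        n_cells=n_cells,
        seed_conc_M=conc,
        seed_conc_nM=conc * 1e9,
        seeds_total=total,
        seeds_per_cell=total / n_cells,
    )


def seeding_probability(fraction_seeded: float, encounters_per_cell: float) -> dict:
    """Per-encounter seeding probability.

    The fraction of cells seeded (e.g. the fraction with >10 aggregates at
    24 h) divided by the number of seed encounters per cell during the
    exposure. Returns the probability and its decimal order of magnitude.
    """
    if not (0.0 <= fraction_seeded <= 1.0):
        raise ValueError("fraction_seeded must be in [0, 1]")
    if encounters_per_cell < 1:
        raise ValueError("need at least one encounter per cell")
    p = fraction_seeded / encounters_per_cell
    return {
        "probability": p,
        "log10_order": math.floor(math.log10(p)) if p > 0 else None,
    }


def secretion_budget(
    monomer_equiv_conc_M: float,
    volume_L: float,
    n_cells: float,
    days: float,
    monomers_per_agg: float = 30.0,
    species_fraction: float = 1.0,
) -> float:
    """Secreted aggregates per cell per day.

    Converts a measured extracellular monomer-equivalent concentration into
    aggregate numbers (assuming ``monomers_per_agg`` monomers per secreted
    aggregate, ~30 for small oligomers), scaled by the fraction attributable
    to the species of interest, divided by cell number and elapsed days.
    """
    if min(monomer_equiv_conc_M, volume_L, n_cells, days, monomers_per_agg) <= 0:
        raise ValueError("all inputs must be positive")
    if not (0 < species_fraction <= 1):
        raise ValueError("species_fraction must be in (0, 1]")
    n_agg = monomer_equiv_conc_M * volume_L * N_A / monomers_per_agg * species_fraction
    return n_agg / n_cells / days


def seeding_chain(params: TransportParams, fraction_seeded: float) -> dict:
    """Full encounter chain with every intermediate echoed.

    D (Stokes-Einstein) -> J (Smoluchowski flux at the far-field
    concentration) -> encounters over the exposure -> per-encounter seeding
    probability from the observed seeded-cell fraction.
    """
    D = stokes_einstein(params.T, params.eta, params.R_H)
    J = encounter_flux(params.a, D, nM_to_per_m3(params.c_inf_nM))
    n_enc = encounters(J, params.duration_s)
    prob = seeding_probability(fraction_seeded, n_enc)
    return {
        "D_m2_per_s": D,
        "J_per_s": J,
        "encounters": n_enc,
        "fraction_seeded": fraction_seeded,
        "seeding_probability": prob["probability"],
        "log10_order": prob["log10_order"],
        "params": {
            "T_K": params.T,
            "eta_Pa_s": params.eta,
            "R_H_m": params.R_H,
            "a_m": params.a,
            "c_inf_nM": params.c_inf_nM,
            "duration_s": params.duration_s,
        },
    }
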