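"""Free-energy dissipation and entropy-production accounting.

The free energy dissipated per reaction event is

    D = delta_G0 + RT ln(Q) + eta delta_G_ATP = RT ln(theta),

which is negative for any forward-running reaction (theta < 1) and zero at
equilibrium.  The community entropy production rate reported here is

    sigma = - sum_i sum_alpha D_i,alpha q_alpha,i N_i / T  >= 0,

i.e. the negated raw sum, so that entropy production is non-negative and
spikes upward when accumulated substrates are burned off; the raw signed
sum is retained for fidelity.

Reaction efficiency is the fraction of a reaction's standard free-energy
drop that is transduced to ATP rather than dissipated,
``epsilon = eta delta_G_ATP / (-delta_G0)``; species values are
nu-weighted means, community values population-weighted means.  (The
efficiency measure is a reconstruction; see docs/methods.md.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import GAS_CONSTANT

#: amounts below this floor (moles) are clipped when forming reaction
#: quotients, keeping ln(Q) finite while a product pool is still exactly
#: empty; far below any dynamically reachable amount so the sign of
#: D = RT ln(theta) stays consistent with the reaction direction
Q_FLOOR = 1.0e-300


def dissipation_per_event(delta_G0, Q, eta, delta_G_ATP, T):
    """Gibbs free energy dissipated per reaction event, J mol^-1.

    D = delta_G0 + RT ln(Q) + eta delta_G_ATP; equals RT ln(theta) with
    theta the thermodynamic factor, so D = 0 exactly at equilibrium.
    """
    Q = np.asarray(Q, dtype=float)
    if np.any(Q <= 0):
        raise ValueError("reaction quotient must be positive")
    D = (np.asarray(delta_G0, dtype=float) + GAS_CONSTANT * T * np.log(Q)
         + np.asarray(eta, dtype=float) * delta_G_ATP)
    return D if D.ndim else float(D)


def entropy_production_from_rates(flat, rates, N, C, cell):
    """sigma (J K^-1 s^-1), per-species sigma_i, and the raw signed sum.

    Uses precomputed RateBundle rows; metabolite amounts are floored at
    Q_FLOOR inside the reaction quotient so early empty product pools do
    not produce infinite logarithms (the affected rows carry negligible
    flux weight).
    """
    from .constants import N_AVOGADRO

    S = np.maximum(C[flat.sub], Q_FLOOR)
    W = np.maximum(C[flat.prod], Q_FLOOR)
    D = dissipation_per_event(flat.delta_G0, W / S, flat.eta,
                              cell.delta_G_ATP, cell.T)
    # q counts molecular events per cell; D is per mole of reaction
    terms = D * (rates.q / N_AVOGADRO) * N[flat.species] / cell.T
    signed = float(np.sum(terms))
    sigma_i = -np.bincount(flat.species, weights=terms, minlength=flat.B)
    return -signed, sigma_i, signed


def entropy_production(community, state):
    """Community entropy production rate at a state.

    Returns (sigma, sigma_i, signed_sum); sigma = sum(sigma_i) >= 0 for
    forward-running reactions.
    """
    from .kinetics import community_rates

    flat = community.flat()
    rates = community_rates(flat, np.maximum(state.C, 0.0), state.phi_R,
                            state.a, community.cell)
    return entropy_production_from_rates(flat, rates,
                                         np.maximum(state.N, 0.0),
                                         np.maximum(state.C, 0.0),
                                         community.cell)


def reaction_efficiency(species, network, cell):
    """nu-weighted mean efficiency of one species' reactions, in [0, 1]."""
    dG0 = network.delta_G0[species.reactions]
    eps = species.eta * cell.delta_G_ATP / (-dG0)
    if np.any(eps > 1.0 + 1e-12):
        warnings.warn("efficiency above 1 (eta beyond the zero-dissipation "
                      "point); capping", RuntimeWarning, stacklevel=2)
    eps = np.minimum(eps, 1.0)
    return float(np.sum(species.nu * eps))


def community_efficiency(community, N):
    """Population-weighted mean reaction efficiency across species."""
    N = np.maximum(np.asarray(N, dtype=float), 0.0)
    if N.sum() <= 0:
        return float("nan")
    eff = np.array([reaction_efficiency(sp, community.network, community.cell)
                    for sp in community.species])
    return float(np.sum(eff * N) / N.sum())


@dataclass
class ThermoReport:
    """Dissipation and efficiency summary at one community state."""

    D: np.ndarray            # per (species, reaction) row, J mol^-1
    sigma: float             # community entropy production rate, J K^-1 s^-1
    sigma_i: np.ndarray      # per-species breakdown
    signed_sum: float        # raw Eq-14-style sum (<= 0 when running forward)
    efficiency_i: np.ndarray
    efficiency: float


def thermo_report(community, state) -> ThermoReport:
    from .kinetics import community_rates

    flat = community.flat()
    cell = community.cell
    C = np.maximum(state.C, 0.0)
    rates = community_rates(flat, C, state.phi_R, state.a, cell)
    S = np.maximum(C[flat.sub], Q_FLOOR)
    W = np.maximum(C[flat.prod], Q_FLOOR)
    D = dissipation_per_event(flat.delta_G0, W / S, flat.eta,
                              cell.delta_G_ATP, cell.T)
    sigma, sigma_i, signed = entropy_production_from_rates(
        flat, rates, np.maximum(state.N, 0.0), C, cell)
    eff_i = np.array([reaction_efficiency(sp, community.network, cell)
                      for sp in community.species])
    return ThermoReport(D=D, sigma=sigma, sigma_i=sigma_i, signed_sum=signed,
                        efficiency_i=eff_i,
                        efficiency=community_efficiency(community, state.N))
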