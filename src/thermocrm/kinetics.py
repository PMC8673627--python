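"""Per-cell instantaneous rates: reversible catalysis, ATP production,
metabolite exchange, translation and growth.

All functions are pure and broadcast over numpy arrays.  The reaction rate
law is a reversible Michaelis-Menten form

    q = k E S (1 - theta) / (K_S + S (1 + r theta)),

where ``theta = (W/S)/K`` is the thermodynamic factor: 1 at equilibrium
(zero net rate), 0 far from equilibrium (plain Michaelis-Menten).  For very
large K the law is numerically indistinguishable from irreversible kinetics.
The law is used in the equivalent singularity-free form

    q = k E (S - W/K) / (K_S + S + r W/K),

which is smooth in (S, W) including S = 0 and is signed: a reaction pushed
beyond equilibrium by product excess (theta > 1) runs in reverse,
consuming ATP.  An optional clamped mode floors q at 0 (stalled rather
than reversed reactions) for sensitivity checks.

Cell-side rates implement a three-compartment proteome (ribosomal R,
metabolic P, housekeeping Q): growth is translation-limited,
``lambda = gamma(a) f_b phi_R / n_R``, with the elongation rate gamma
saturating in the internal energy pool a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ATP_GATE, N_AVOGADRO


def thermodynamic_factor(S, W, K):
    """Distance from equilibrium, theta = (W/S)/K.

    theta = 1 at equilibrium; -> 0 far from equilibrium.  ``S = 0`` with
    ``W > 0`` gives +inf (the reaction is fully blocked; the rate law
    clamps q to 0 there); ``S = 0, W = 0`` gives 0.
    """
    S = np.asarray(S, dtype=float)
    W = np.asarray(W, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("equilibrium constant must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(S > 0, (W / np.where(S > 0, S, 1.0)) / K,
                         np.where(W > 0, np.inf, 0.0))
    return theta if theta.ndim else float(theta)


def reaction_rate(E, S, W, k, K_S, r, K, *, clamp: bool = False):
    """Net reaction rate per cell (events s^-1) under reversible kinetics.

    Signed by default (negative past equilibrium); ``clamp=True`` floors
    the rate at 0 (reactions stall rather than reverse).
    """
    S = np.asarray(S, dtype=float)
    W = np.asarray(W, dtype=float)
    q = k * E * (S - W / K) / (K_S + S + r * W / K)
    if clamp:
        q = np.maximum(q, 0.0)
    return q if q.ndim else float(q)


def enzyme_copy_number(nu, phi_R, cell):
    """Enzyme copies per cell, E = m nu (1 - phi_R - phi_Q) / n_P.

    The metabolic proteome fraction phi_P = 1 - phi_R - phi_Q is shared
    among the species' reactions in proportion to the expression weights
    nu.  A transient numerical overshoot phi_R > 1 - phi_Q clamps E to 0.
    """
    phi_P = np.maximum(1.0 - np.asarray(phi_R, dtype=float) - cell.phi_Q, 0.0)
    E = cell.m * np.asarray(nu, dtype=float) * phi_P / cell.n_P
    return E if E.ndim else float(E)


def elongation_rate(a, cell):
    """Effective translation elongation rate gamma(a) = gamma_m a/(gamma_half + a)."""
    a = np.asarray(a, dtype=float)
    g = cell.gamma_m * a / (cell.gamma_half + a)
    return g if g.ndim else float(g)


def growth_rate(a, phi_R, cell):
    """Specific growth rate lambda = gamma(a) f_b phi_R / n_R (s^-1)."""
    lam = elongation_rate(a, cell) * cell.f_b * np.asarray(phi_R, dtype=float) / cell.n_R
    return lam if np.ndim(lam) else float(lam)


def ideal_ribosome_fraction(a, cell):
    """Target ribosome fraction phi_R* = a/(Omega_half + a) * (1 - phi_Q)."""
    a = np.asarray(a, dtype=float)
    phi = a / (cell.Omega_half + a) * (1.0 - cell.phi_Q)
    return phi if phi.ndim else float(phi)


def atp_production(eta, q):
    """ATP production rate J = sum_alpha eta_alpha q_alpha (per cell)."""
    return float(np.sum(np.asarray(eta, dtype=float) * np.asarray(q, dtype=float)))


@dataclass
class RateBundle:
    """All instantaneous rates for one community state.

    Reaction-level arrays are flat over (species, reaction) rows in the
    order given by ``FlatCommunity``; species-level arrays have length B.
    ``p`` and ``c`` are per-cell metabolite production/consumption rate
    tables of shape (B, M) in moles s^-1 cell^-1.
    """

    q: np.ndarray
    theta: np.ndarray
    E: np.ndarray
    J: np.ndarray
    lam: np.ndarray
    p: np.ndarray
    c: np.ndarray


def community_rates(flat, C, phi_R, a, cell, *, signed: bool = True) -> RateBundle:
    """Evaluate every rate in the community at metabolite amounts ``C``.

    Parameters
    ----------
    flat : FlatCommunity
        Flattened per-(species, reaction) parameter arrays.
    C : ndarray (M,)
        Metabolite amounts, moles.
    phi_R, a : ndarray (B,)
        Per-species ribosome fractions and internal energy pools.
    cell : CellParameters
    signed : bool
        Signed (reversible) rates by default; False clamps at 0.

    A reverse-running reaction consumes the product and regenerates the
    substrate, so its flux is booked with the roles swapped and the
    ``p``/``c`` tables stay non-negative.
    """
    C = np.maximum(C, 0.0)
    S = C[flat.sub]
    W = C[flat.prod]
    phi_P = np.maximum(1.0 - phi_R - cell.phi_Q, 0.0)
    E = cell.m * flat.nu * phi_P[flat.species] / cell.n_P

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(S > 0, W / np.where(S > 0, S, 1.0), np.inf)
    theta = np.where((S <= 0) & (W <= 0), 0.0, ratio) / flat.K
    q = flat.k * E * (S - W / flat.K) / (flat.K_S + S + flat.r * W / flat.K)
    if signed:
        aa = np.maximum(np.asarray(a, dtype=float), 0.0)
        gate = (aa / (aa + ATP_GATE))[flat.species]
        q = np.where(q < 0.0, q * gate, q)
    else:
        q = np.maximum(q, 0.0)

    J = np.bincount(flat.species, weights=flat.eta * q, minlength=flat.B)
    lam = growth_rate(a, phi_R, cell)

    mol = q / N_AVOGADRO  # moles of metabolite moved per cell per second
    fwd = np.maximum(mol, 0.0)
    rev = np.maximum(-mol, 0.0)
    B, M = flat.B, flat.M
    c = np.zeros((B, M))
    p = np.zeros((B, M))
    np.add.at(c, (flat.species, flat.sub), fwd)
    np.add.at(p, (flat.species, flat.prod), fwd)
    np.add.at(c, (flat.species, flat.prod), rev)
    np.add.at(p, (flat.species, flat.sub), rev)
    return RateBundle(q=q, theta=theta, E=E, J=J, lam=np.asarray(lam), p=p, c=c)
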