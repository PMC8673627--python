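"""Pairwise species interaction classification at steady state.

Each metabolite is perturbed in turn and the per-capita growth response of
every surviving species is measured, alongside every species' net impact
on that metabolite's concentration.  The sign pair classifies the directed
interaction (source j --beta--> target i):

    response +, impact +  ->  facilitation (j supplies a metabolite i uses)
    response +, impact -  ->  competition  (j removes a metabolite i uses)
    response -, impact +  ->  pollution    (j produces a metabolite that
                                            thermodynamically inhibits i)
    response -, impact -  ->  syntrophy    (j consumes a metabolite that
                                            inhibits i)

The response used is the quasi-steady growth rate: the target's ribosome
fraction is held at its steady-state value while its internal energy pool
re-equilibrates to the perturbed ATP production rate (da/dt = 0), and the
growth rate is evaluated at that balance point.  This captures the
instantaneous per-capita benefit or harm of a metabolite shift without
re-running community dynamics.  Interaction strength is
|response x impact|, rescaled per community by the maximum strength.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinetics import community_rates, growth_rate

SIGN_TABLE = {(1, 1): "facilitation", (1, -1): "competition",
              (-1, 1): "pollution", (-1, -1): "syntrophy"}
INTERACTION_TYPES = ("competition", "facilitation", "pollution", "syntrophy")


def _quasi_steady_lambda(J, phi_R, cell):
    """Growth rate after the energy pool relaxes to da/dt = 0.

    Solves J = (chi m + a) * lambda(a, phi_R) for a >= 0; the right-hand
    side rises monotonically from 0, so the root is unique.
    """
    if J <= 0 or phi_R <= 0:
        return 0.0

    def bal(a):
        return (cell.chi * cell.m + a) * growth_rate(a, phi_R, cell) - J

    a_hi = cell.gamma_half
    while bal(a_hi) < 0:
        a_hi *= 10.0
        if a_hi > 1e30:  # J beyond what translation can ever spend
            return growth_rate(np.inf, phi_R, cell)
    a_star = brentq(bal, 0.0, a_hi, xtol=1e-12, rtol=1e-12)
    return growth_rate(a_star, phi_R, cell)


def _lambda_qss_all(community, C, state):
    """Quasi-steady growth rate of every species at metabolite amounts C."""
    flat = community.flat()
    rates = community_rates(flat, C, state.phi_R, state.a, community.cell)
    return np.array([_quasi_steady_lambda(rates.J[i], state.phi_R[i],
                                          community.cell)
                     for i in range(flat.B)])


def perturbation_response(community, state, i: int, beta: int,
                          delta: float = 1.0e-3):
    """Central-difference sensitivity of species i's growth rate to C_beta.

    ``delta`` is the relative perturbation; when C_beta = 0 an absolute
    step (delta times the largest metabolite pool) is used instead and the
    difference is one-sided (flagged in the return value).

    Returns (response, flagged).
    """
    C = np.maximum(state.C, 0.0)
    flagged = False
    if C[beta] > 0:
        h = delta * C[beta]
        lo = C.copy()
        lo[beta] -= h
        hi = C.copy()
        hi[beta] += h
        width = 2 * h
    else:
        flagged = True
        h = delta * max(C.max(), 1.0e-6)
        lo = C.copy()
        hi = C.copy()
        hi[beta] += h
        width = h
    lam_hi = _lambda_qss_all(community, hi, state)[i]
    lam_lo = _lambda_qss_all(community, lo, state)[i]
    return (lam_hi - lam_lo) / width, flagged


def net_impact(community, state, j: int, beta: int) -> float:
    """Net rate at which species j changes C_beta, (p - c) N_j (mol s^-1).

    Positive means j is a net producer of the metabolite.
    """
    flat = community.flat()
    rates = community_rates(flat, np.maximum(state.C, 0.0), state.phi_R,
                            state.a, community.cell)
    return float((rates.p[j, beta] - rates.c[j, beta]) * max(state.N[j], 0.0))


def classify(community, state, delta: float = 1.0e-3,
             zero_tol: float = 1.0e-12,
             extinction_threshold: float | None = None):
    """All directed per-metabolite interaction records at a steady state.

    Returns (records, proportions): a DataFrame with one row per
    (source j, target i, metabolite beta) whose response and impact are
    both nonzero, and the per-community proportions of the four types.
    Responses or impacts below ``zero_tol`` of the community maximum count
    as zero.  Fewer than two survivors yield an empty table.
    """
    cfg = community.config
    thr = (extinction_threshold if extinction_threshold is not None
           else (cfg.extinction_threshold if cfg else 0.0))
    alive = np.flatnonzero(state.N > thr)
    empty = pd.DataFrame(columns=["source", "target", "metabolite", "type",
                                  "response", "impact", "strength",
                                  "strength_raw"])
    if len(alive) < 2:
        return empty, {k: np.nan for k in INTERACTION_TYPES}

    M = community.network.M
    flat = community.flat()
    rates = community_rates(flat, np.maximum(state.C, 0.0), state.phi_R,
                            state.a, community.cell)
    impact = (rates.p - rates.c) * np.maximum(state.N, 0.0)[:, None]

    resp = np.zeros((len(alive), M))
    for ii, i in enumerate(alive):
        for beta in range(M):
            resp[ii, beta], _ = perturbation_response(community, state, i,
                                                      beta, delta)
    resp_max = np.max(np.abs(resp))
    imp_max = np.max(np.abs(impact[alive]))
    if resp_max <= 0 or imp_max <= 0:
        return empty, {k: np.nan for k in INTERACTION_TYPES}

    ids = [sp.id for sp in community.species]
    rows = []
    for ii, i in enumerate(alive):
        for j in alive:
            if i == j:
                continue
            for beta in range(M):
                r_val = resp[ii, beta]
                m_val = impact[j, beta]
                if abs(r_val) <= zero_tol * resp_max:
                    continue
                if abs(m_val) <= zero_tol * imp_max:
                    continue
                itype = SIGN_TABLE[(int(np.sign(r_val)), int(np.sign(m_val)))]
                rows.append({"source": ids[j], "target": ids[i],
                             "metabolite": beta + 1, "type": itype,
                             "response": r_val, "impact": m_val,
                             "strength_raw": abs(r_val * m_val)})
    if not rows:
        return empty, {k: np.nan for k in INTERACTION_TYPES}
    records = pd.DataFrame(rows)
    records["strength"] = records["strength_raw"] / records["strength_raw"].max()
    counts = records["type"].value_counts()
    total = float(len(records))
    proportions = {k: float(counts.get(k, 0)) / total
                   for k in INTERACTION_TYPES}
    records = records[["source", "target", "metabolite", "type", "response",
                       "impact", "strength", "strength_raw"]]
    return records, proportions
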