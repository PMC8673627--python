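"""Metabolite free-energy hierarchy and the catabolic reaction network.

Metabolites form a ladder of decreasing standard free energy with uniform
spacing.  A catabolic reaction converts one metabolite into another one or two
positions lower on the ladder, so an ``M``-metabolite hierarchy admits exactly
``2M - 3`` reactions and is fully connected downward.  Each reaction carries a
standard Gibbs free-energy drop proportional to the number of levels it
descends.

Metabolites are labelled 1..M in all user-facing I/O (metabolite 1 is the
supplied, highest-energy substrate); indices are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ETA_MIN, GAS_CONSTANT


@dataclass(frozen=True)
class ReactionNetwork:
    """The metabolite hierarchy and its allowed descending reactions.

    Attributes
    ----------
    M : int
        Number of metabolites in the hierarchy.
    substrates, products : ndarray of int
        0-based metabolite indices per reaction, in canonical order
        (sorted by substrate, then product).  ``products - substrates``
        is 1 or 2 everywhere.
    delta_G0 : ndarray of float
        Standard Gibbs free-energy change per reaction, J mol^-1 (negative).
    delta_G_total : float
        Total free-energy span from metabolite 1 to metabolite M, J mol^-1
        (positive magnitude).
    """

    M: int
    substrates: np.ndarray
    products: np.ndarray
    delta_G0: np.ndarray
    delta_G_total: float

    @property
    def n_reactions(self) -> int:
        return len(self.substrates)

    @property
    def step_energy(self) -> float:
        """Free-energy drop of a single one-level step, J mol^-1 (positive)."""
        return self.delta_G_total / (self.M - 1)

    def reaction_labels(self) -> list[str]:
        """1-based human-readable labels, e.g. ``"1->2"``."""
        return [f"{s + 1}->{p + 1}" for s, p in zip(self.substrates, self.products)]

    def to_frame(self) -> pd.DataFrame:
        """One row per reaction with 1-based metabolite labels."""
        return pd.DataFrame(
            {
                "substrate": self.substrates + 1,
                "product": self.products + 1,
                "delta_G0": self.delta_G0,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReactionNetwork":
        df = pd.read_csv(path, sep="\t")
        subs = df["substrate"].to_numpy(dtype=int) - 1
        prods = df["product"].to_numpy(dtype=int) - 1
        dG0 = df["delta_G0"].to_numpy(dtype=float)
        M = int(prods.max()) + 1
        # total span recovered from the uniform one-step spacing
        one_step = dG0[prods - subs == 1]
        span = -float(one_step[0]) * (M - 1)
        return cls(M=M, substrates=subs, products=prods, delta_G0=dG0,
                   delta_G_total=span)


def build_network(M: int, delta_G_total: float) -> ReactionNetwork:
    """Construct the full reaction network on an ``M``-metabolite hierarchy.

    Parameters
    ----------
    M : int
        Number of metabolites (>= 2).
    delta_G_total : float
        Positive free-energy span between the top and bottom of the
        hierarchy, J mol^-1.  Spacing between adjacent metabolites is
        uniform: ``delta_G_total / (M - 1)`` per level.

    Returns
    -------
    ReactionNetwork
        Reactions enumerated canonically (by substrate, then product):
        every (s, p) with ``p - s`` in {1, 2}, giving ``2M - 3`` reactions.
    """
    if M < 2:
        raise ValueError(f"need at least 2 metabolites, got M={M}")
    if delta_G_total <= 0:
        raise ValueError(f"delta_G_total must be positive, got {delta_G_total}")
    step = delta_G_total / (M - 1)
    subs, prods = [], []
    for s in range(M):
        for p in (s + 1, s + 2):
            if p < M:
                subs.append(s)
                prods.append(p)
    subs = np.array(subs, dtype=np.intp)
    prods = np.array(prods, dtype=np.intp)
    dG0 = -step * (prods - subs).astype(float)
    return ReactionNetwork(M=M, substrates=subs, products=prods,
                           delta_G0=dG0, delta_G_total=float(delta_G_total))


def equilibrium_constant(delta_G0_alpha, eta, delta_G_ATP, T):
    """Equilibrium constant of a reaction transducing ``eta`` ATP per event.

    K = exp(-(delta_G0 + eta * delta_G_ATP) / RT) with delta_G_ATP > 0 the
    free energy stored per mole of ATP produced.  Transducing more of the
    reaction free energy to ATP (larger eta) leaves less to dissipate and
    moves the reaction closer to equilibrium (smaller K).

    Accepts scalars or arrays; broadcasts.
    """
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < 0):
        raise ValueError("eta must be non-negative")
    if T <= 0:
        raise ValueError("temperature must be positive")
    out = np.exp(-(np.asarray(delta_G0_alpha, dtype=float) + eta * delta_G_ATP)
                 / (GAS_CONSTANT * T))
    return out if out.ndim else float(out)


def eta_max(delta_G0_alpha, equilibrium_ratio, delta_G_ATP, T):
    """Largest admissible ATP yield for a reaction.

    Solves ``K(eta) = equilibrium_ratio`` for eta, i.e. the yield at which
    the reaction reaches equilibrium at the given product-to-substrate
    ratio; the sampling rule uses ratio 1e-2 for the reversible regime and
    1e5 for the Michaelis-Menten regime.

    Returns
    -------
    (eta, degenerate) : (float | ndarray, bool | ndarray)
        ``eta`` clipped below at the global minimum 1/3; ``degenerate`` is
        True where the unclipped solution fell below 1/3.
    """
    if np.any(np.asarray(equilibrium_ratio) <= 0):
        raise ValueError("equilibrium_ratio must be positive")
    raw = (-np.asarray(delta_G0_alpha, dtype=float)
           - GAS_CONSTANT * T * np.log(equilibrium_ratio)) / delta_G_ATP
    degenerate = raw < ETA_MIN
    eta = np.maximum(raw, ETA_MIN)
    if eta.ndim == 0:
        return float(eta), bool(degenerate)
    return eta, degenerate
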