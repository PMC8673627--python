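"""Orchestration helpers: run one assembly simulation or an ensemble, and
the canonical study regimes (desk-scale analogues of the headline system)."""

from __future__ import annotations

import dataclasses

import numpy as np

from .assembly import summarize
from .community import RegimeConfig, generate_community
from .dynamics import integrate, steady_state

#: per-level free-energy drop of the headline 25-metabolite hierarchies,
#: J mol^-1: total span divided by the 24 levels
STEP_HEADLINE = 5.0e6 / 24
STEP_HIGH = 1.5e7 / 24
STEP_LOW = 1.5e6 / 24


def headline_regime(M: int = 10, B: int = 50, **overrides) -> RegimeConfig:
    """Desk-scale analogue of the headline assembly run: reversible
    kinetics, per-step free-energy spacing of the 5.0e6 J mol^-1 span."""
    return RegimeConfig(M=M, B=B, delta_G_total=STEP_HEADLINE * (M - 1),
                        kinetics_mode="reversible", **overrides)


def comparison_regime(energy: str, mode: str, M: int = 15, B: int = 30,
                      **overrides) -> RegimeConfig:
    """One of the four free-energy x reversibility comparison regimes.

    ``energy`` is "high" (labile, 1.5e7 J mol^-1 total at 25 metabolites)
    or "low" (recalcitrant, 1.5e6); per-step spacing is preserved when the
    hierarchy is scaled down.  Ensembles of these regimes integrate with
    slightly relaxed solver tolerances: regime means are statistical and
    insensitive to the last two digits of each trajectory.
    """
    step = {"high": STEP_HIGH, "low": STEP_LOW}[energy]
    overrides.setdefault("rtol", 1e-6)
    overrides.setdefault("atol", 1e-9)
    overrides.setdefault("n_samples", 600)
    return RegimeConfig(M=M, B=B, delta_G_total=step * (M - 1),
                        kinetics_mode=mode, **overrides)


def run_assembly(config: RegimeConfig, seed: int | None = None):
    """Generate a random community under ``seed`` and integrate it.

    Returns (community, trajectory, final_state, convergence_report,
    summary).
    """
    community = generate_community(None, config, seed=seed)
    trajectory = integrate(community)
    state, report = steady_state(trajectory, community)
    summary = summarize(trajectory, community)
    return community, trajectory, state, report, summary


def run_ensemble(config: RegimeConfig, n_runs: int, base_seed: int | None = None):
    """Run ``n_runs`` independent assemblies with seeds spawned from
    ``base_seed`` and collect their summaries.

    Returns (summaries, results) where results holds the full per-run
    tuples from :func:`run_assembly`.
    """
    base = base_seed if base_seed is not None else config.seed
    seeds = np.random.SeedSequence(base).generate_state(n_runs) % (2 ** 31)
    results = []
    summaries = []
    for s in seeds:
        cfg = dataclasses.replace(config, seed=int(s))
        out = run_assembly(cfg, seed=int(s))
        results.append(out)
        summaries.append(out[-1])
    return summaries, results
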