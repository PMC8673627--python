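"""Post-assembly observables: functional groups, diversity, niche counts,
entropy spikes and cross-regime summaries."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

from . import thermo

#: metabolite amount (moles) counted as sufficient to support growth
SUPPORT_THRESHOLD = 1.0e-4
#: amount below which an accumulated metabolite counts as exhausted
EXHAUSTION_THRESHOLD = 2.0e-3


def functional_groups(community) -> np.ndarray:
    """Group label per species: substrate (1-based) of its most expressed
    reaction; ties resolve to the lowest substrate index."""
    subs = community.network.substrates
    out = np.empty(community.B, dtype=int)
    for i, sp in enumerate(community.species):
        best = np.max(sp.nu)
        cand = subs[sp.reactions[np.isclose(sp.nu, best)]]
        out[i] = cand.min() + 1
    return out


def inverse_simpson(abundances) -> float:
    """Effective number of types, 1 / sum(p_k^2)."""
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("abundances must not be all zero")
    p = x / total
    return float(1.0 / np.sum(p ** 2))


def group_abundance_series(trajectory, community) -> pd.DataFrame:
    """Relative abundance of each functional group over time."""
    groups = functional_groups(community)
    labels = np.unique(groups)
    N = np.maximum(trajectory.N, 0.0)
    out = {}
    tot = N.sum(axis=1)
    tot[tot == 0] = np.nan
    for g in labels:
        out[f"group_{g}"] = N[:, groups == g].sum(axis=1) / tot
    return pd.DataFrame(out, index=trajectory.t)


def substrates_diversified(trajectory, support_threshold: float | None = None) -> int:
    """Number of metabolites whose amount ever exceeds the support threshold."""
    thr = SUPPORT_THRESHOLD if support_threshold is None else support_threshold
    return int(np.sum(np.any(trajectory.C > thr, axis=0)))


def detect_entropy_spikes(t, sigma, prominence_frac: float = 0.05,
                          mode: str = "relative", floor_frac: float = 1.0e-3):
    """Count spikes in an entropy-production series.

    A spike is a local maximum whose prominence exceeds
    ``prominence_frac`` of the local series value (``mode="relative"``,
    default) or of the global series range (``mode="global"``).  The
    relative criterion is scale-free: spikes ride on a baseline that grows
    by orders of magnitude during assembly, and a burn-off of the smallest
    exhaustion-class metabolite pool (2e-3 moles consumed over one
    consumer e-folding time) perturbs the sustained dissipation flux by a
    few percent, hence the 5% default.  The series must be sampled densely
    enough to resolve burn windows of order one e-folding time.  Peaks
    where the series is below ``floor_frac`` of its maximum (the
    pre-establishment ramp) are ignored in relative mode.

    Returns (count, times of the spikes).
    """
    sigma = np.asarray(sigma, dtype=float)
    rng = float(sigma.max() - sigma.min()) if len(sigma) else 0.0
    if rng <= 0:
        return 0, np.array([])
    if mode == "global":
        peaks, _ = find_peaks(sigma, prominence=prominence_frac * rng)
    elif mode == "relative":
        cand, props = find_peaks(sigma, prominence=0)
        keep = ((props["prominences"] >= prominence_frac * sigma[cand])
                & (sigma[cand] >= floor_frac * sigma.max()))
        peaks = cand[keep]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return len(peaks), np.asarray(t)[peaks]


@dataclass
class AssemblySummary:
    """Scalar end-of-run observables for one assembly simulation."""

    survivors: int
    surviving_groups: int
    inverse_simpson_groups: float
    substrates_diversified: int
    survivors_per_substrate: float
    spike_count: int
    exhaustion_events: int
    final_sigma: float
    mean_growth_rate_peak: float
    final_efficiency: float

    def as_row(self) -> dict:
        return asdict(self)


def summarize(trajectory, community) -> AssemblySummary:
    cfg = trajectory.config or community.config
    thr = cfg.extinction_threshold if cfg else 0.0
    N_final = trajectory.N[-1]
    survivors = N_final > thr
    groups = functional_groups(community)
    n_sub = substrates_diversified(trajectory)
    spike_count, _ = detect_entropy_spikes(trajectory.t, trajectory.sigma)
    n_exhaust = int((trajectory.events["kind"] == "exhaustion").sum())

    if survivors.any():
        group_ab = pd.Series(np.maximum(N_final, 0.0)).groupby(groups).sum()
        inv_simp = inverse_simpson(group_ab.to_numpy())
        n_groups = int((group_ab > 0).sum())
        eff = thermo.community_efficiency(community, N_final)
    else:
        inv_simp, n_groups, eff = np.nan, 0, np.nan

    weights = np.maximum(trajectory.N, 0.0)
    wsum = weights.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_lam = np.where(wsum > 0,
                            (trajectory.lam * weights).sum(axis=1) / wsum, 0.0)
    return AssemblySummary(
        survivors=int(survivors.sum()),
        surviving_groups=n_groups,
        inverse_simpson_groups=float(inv_simp),
        substrates_diversified=n_sub,
        survivors_per_substrate=float(survivors.sum() / n_sub) if n_sub else np.nan,
        spike_count=spike_count,
        exhaustion_events=n_exhaust,
        final_sigma=float(trajectory.sigma[-1]),
        mean_growth_rate_peak=float(np.nanmax(mean_lam)),
        final_efficiency=float(eff),
    )


def regime_summary(rows, confidence: float = 0.99) -> pd.DataFrame:
    """Mean and t-based confidence interval per metric over an ensemble.

    ``rows`` is a list of AssemblySummary (or dicts).  Returns one row per
    metric with mean, CI half-width, and bounds.
    """
    df = pd.DataFrame([r.as_row() if hasattr(r, "as_row") else dict(r)
                       for r in rows])
    if len(df) < 2:
        raise ValueError("need at least 2 runs for a regime summary")
    out = []
    tcrit = stats.t.ppf(0.5 + confidence / 2, df=len(df) - 1)
    for col in df.columns:
        x = df[col].astype(float).dropna()
        mean = x.mean()
        half = tcrit * x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
        out.append({"metric": col, "mean": mean, "ci_half_width": half,
                    "ci_low": mean - half, "ci_high": mean + half,
                    "n": len(x)})
    return pd.DataFrame(out).set_index("metric")


def two_sample_test(x, y):
    """Plain Welch two-sample t-test between two ensembles of one metric."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float),
                          equal_var=False)
    return float(res.statistic), float(res.pvalue)
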