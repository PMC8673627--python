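"""Random community generation, shared cell parameters, and toy fixtures.

A community is a set of consumer species on one reaction network.  Each
species owns a small random subset of the network's reactions (1-5 by
default) with log-normally distributed kinetic parameters, uniform ATP
yields eta on [1/3, eta_max], and expression weights nu normalised to 1.
Cell-economy constants (translation, proteome partitioning) are shared by
every species in a community.

The regime (reversible vs Michaelis-Menten kinetics) enters only through
the eta sampling range: the maximum eta is set so a reaction equilibrates
at product/substrate ratio 1e-2 (reversible) or 1e5 (Michaelis-Menten).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .constants import ETA_MIN
from .kinetics import ideal_ribosome_fraction
from .network import ReactionNetwork, build_network, equilibrium_constant, eta_max


@dataclass(frozen=True)
class CellParameters:
    """Proteome and translation constants shared across species.

    Defaults describe an E. coli-like cell economy; amounts (enzyme copies,
    internal energy a) are per-cell molecule counts.

    gamma_m : maximum translation elongation rate, aa s^-1
    gamma_half : elongation half-saturation energy, molecules cell^-1
    Omega_half : ribosome-fraction half-saturation energy, molecules cell^-1
    phi_Q : housekeeping proteome fraction
    f_b : fraction of ribosomes bound and translating
    n_R : amino acids per ribosome
    n_P : amino acids per average metabolic protein
    m : total cell mass, amino acids
    chi : ATP consumed per elongation step
    T : temperature, K
    delta_G_ATP : free energy stored per mole of ATP, J mol^-1 (positive)
    """

    gamma_m: float = 21.0
    gamma_half: float = 5.0e8
    Omega_half: float = 1.0e8
    phi_Q: float = 0.45
    f_b: float = 0.7
    n_R: float = 7459.0
    n_P: float = 300.0
    m: float = 1.0e8
    chi: float = 29.0
    T: float = 293.15
    delta_G_ATP: float = 7.5e4

    def __post_init__(self):
        for name in ("gamma_m", "gamma_half", "Omega_half", "f_b", "n_R",
                     "n_P", "m", "chi", "T", "delta_G_ATP", "phi_Q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.phi_Q >= 1:
            raise ValueError("phi_Q must be < 1")
        if self.f_b > 1:
            raise ValueError("f_b must be <= 1")


#: equilibrium product/substrate ratio that defines eta_max, per regime
MODE_RATIOS = {"reversible": 1e-2, "michaelis_menten": 1e5}


@dataclass
class RegimeConfig:
    """One simulation regime: network size, sampling rules and chemostat rates.

    kappa is the supply rate of metabolite 1 (mol s^-1) unless an explicit
    ``supply`` vector is given; rho is the universal dilution rate (s^-1).
    """

    M: int = 25
    B: int = 250
    delta_G_total: float = 5.0e6
    kinetics_mode: str = "reversible"
    equilibrium_ratio: float | None = None
    kappa: float = 1.0e-5
    rho: float = 1.0e-5
    supply: list | None = None  # per-metabolite supply; default (kappa, 0, ...)
    d: float = 1.0e-5
    N_O_range: tuple = (1, 5)
    seed: int = 0
    t_final: float = 1.0e8
    extinction_threshold: float = 1.0e-2
    N0: float = 100.0
    a0: float = 2.0e8
    lognormal_k: tuple = (1.0, 1.0)      # (median s^-1, sigma of log)
    lognormal_K_S: tuple = (1.0e-4, 1.0)  # (median mol, sigma of log)
    lognormal_r: tuple = (10.0, 1.0)     # (median, sigma of log)
    rtol: float = 1.0e-8
    atol: float = 1.0e-12
    n_samples: int = 2000
    clamp_extinct: bool = True
    signed_rates: bool = True  # False: stall (clamp q at 0) past equilibrium
    use_jacobian: bool = False  # supply the analytic Jacobian to the solver
    fixture: str | None = None  # set when the community is a named fixture
    cell: CellParameters = field(default_factory=CellParameters)

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if self.kinetics_mode not in MODE_RATIOS:
            raise ValueError(
                f"unknown kinetics_mode {self.kinetics_mode!r}; "
                f"expected one of {sorted(MODE_RATIOS)}")
        if self.equilibrium_ratio is None:
            self.equilibrium_ratio = MODE_RATIOS[self.kinetics_mode]
        if isinstance(self.cell, dict):
            self.cell = CellParameters(**self.cell)
        lo, hi = self.N_O_range
        if not (1 <= lo <= hi):
            raise ValueError("N_O_range must satisfy 1 <= lo <= hi")

    def supply_vector(self) -> np.ndarray:
        v = np.zeros(self.M)
        if self.supply is None:
            v[0] = self.kappa
        else:
            s = np.asarray(self.supply, dtype=float)
            v[: len(s)] = s
        return v

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["N_O_range"] = list(d["N_O_range"])
        for key in ("lognormal_k", "lognormal_K_S", "lognormal_r"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RegimeConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        for key in ("N_O_range", "lognormal_k", "lognormal_K_S", "lognormal_r"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Species:
    """One consumer: its reaction subset and per-reaction parameters."""

    id: str
    reactions: np.ndarray   # indices into the network's canonical reaction list
    k: np.ndarray           # maximum forward rates, s^-1
    K_S: np.ndarray         # substrate half-saturations, mol
    r: np.ndarray           # reversibility factors
    eta: np.ndarray         # ATP per reaction event, >= 1/3
    nu: np.ndarray          # expression weights, sum to 1
    d: float                # biomass loss rate, s^-1
    eta_degenerate: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.reactions)
        if n < 1:
            raise ValueError("species needs at least one reaction")
        if len(set(self.reactions.tolist())) != n:
            raise ValueError("reaction indices must be distinct")
        for name in ("k", "K_S", "r", "eta", "nu"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} must have one entry per reaction")
        if np.any(self.k <= 0) or np.any(self.K_S <= 0) or np.any(self.r <= 0):
            raise ValueError("kinetic parameters must be strictly positive")
        if np.any(self.eta < ETA_MIN - 1e-12):
            raise ValueError("eta below the global minimum 1/3")
        if np.any(self.nu < 0) or abs(self.nu.sum() - 1.0) > 1e-12:
            raise ValueError("nu must be non-negative and sum to 1")


class FlatCommunity:
    """Flattened per-(species, reaction) arrays for fast rate evaluation."""

    def __init__(self, network: ReactionNetwork, species: list, cell: CellParameters):
        rows_sp, rows_rx = [], []
        for i, sp in enumerate(species):
            for rx in sp.reactions:
                rows_sp.append(i)
                rows_rx.append(rx)
        self.B = len(species)
        self.M = network.M
        self.species = np.array(rows_sp, dtype=np.intp)
        self.reaction = np.array(rows_rx, dtype=np.intp)
        self.sub = network.substrates[self.reaction]
        self.prod = network.products[self.reaction]
        self.delta_G0 = network.delta_G0[self.reaction]
        def cat(field):
            arrs = [getattr(sp, field) for sp in species]
            return np.concatenate(arrs) if arrs else np.zeros(0)

        self.k = cat("k")
        self.K_S = cat("K_S")
        self.r = cat("r")
        self.eta = cat("eta")
        self.nu = cat("nu")
        self.d = np.array([sp.d for sp in species])
        self.K = equilibrium_constant(self.delta_G0, self.eta,
                                      cell.delta_G_ATP, cell.T)


@dataclass
class Community:
    """A reaction network plus its consumer species and shared cell constants."""

    network: ReactionNetwork
    species: list
    cell: CellParameters
    config: RegimeConfig | None = None

    _flat: FlatCommunity | None = dataclasses.field(default=None, repr=False,
                                                    compare=False)

    @property
    def B(self) -> int:
        return len(self.species)

    def flat(self) -> FlatCommunity:
        if self._flat is None or self._flat.B != self.B:
            self._flat = FlatCommunity(self.network, self.species, self.cell)
        return self._flat

    def species_table(self) -> pd.DataFrame:
        """One row per (species, reaction) with every kinetic field."""
        rows = []
        labels = self.network.reaction_labels()
        for sp in self.species:
            for j, rx in enumerate(sp.reactions):
                rows.append({
                    "species": sp.id,
                    "reaction_index": int(rx),
                    "reaction": labels[rx],
                    "k": sp.k[j], "K_S": sp.K_S[j], "r": sp.r[j],
                    "eta": sp.eta[j], "nu": sp.nu[j], "d": sp.d,
                })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.species_table().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, network: ReactionNetwork,
                 cell: CellParameters | None = None,
                 config: RegimeConfig | None = None) -> "Community":
        df = pd.read_csv(path)
        cell = cell or (config.cell if config else CellParameters())
        species = []
        for sid, grp in df.groupby("species", sort=False):
            species.append(Species(
                id=str(sid),
                reactions=grp["reaction_index"].to_numpy(dtype=np.intp),
                k=grp["k"].to_numpy(float), K_S=grp["K_S"].to_numpy(float),
                r=grp["r"].to_numpy(float), eta=grp["eta"].to_numpy(float),
                nu=grp["nu"].to_numpy(float), d=float(grp["d"].iloc[0]),
            ))
        return cls(network=network, species=species, cell=cell, config=config)


def generate_species(network: ReactionNetwork, config: RegimeConfig,
                     rng: np.random.Generator, sid: str = "sp") -> Species:
    """Sample one random species per the ensemble protocol.

    Draw order is fixed (size, reaction set, k, K_S, r, nu, eta) so a given
    generator state maps deterministically to one species.
    """
    lo, hi = config.N_O_range
    n_O = int(rng.integers(lo, hi + 1))
    reactions = np.sort(rng.choice(network.n_reactions, size=n_O, replace=False))
    cell = config.cell

    def lognorm(median_sigma, size):
        median, sigma = median_sigma
        return rng.lognormal(mean=np.log(median), sigma=sigma, size=size)

    k = lognorm(config.lognormal_k, n_O)
    K_S = lognorm(config.lognormal_K_S, n_O)
    r = lognorm(config.lognormal_r, n_O)
    nu = rng.uniform(size=n_O)
    nu = nu / nu.sum()
    hi_eta, degenerate = eta_max(network.delta_G0[reactions],
                                 config.equilibrium_ratio,
                                 cell.delta_G_ATP, cell.T)
    hi_eta = np.atleast_1d(hi_eta)
    degenerate = np.atleast_1d(degenerate)
    eta = np.where(degenerate, ETA_MIN,
                   rng.uniform(ETA_MIN, np.maximum(hi_eta, ETA_MIN)))
    return Species(id=sid, reactions=reactions, k=k, K_S=K_S, r=r, eta=eta,
                   nu=nu, d=config.d, eta_degenerate=degenerate)


def generate_community(network: ReactionNetwork | None, config: RegimeConfig,
                       seed: int | None = None) -> Community:
    """Sample a B-species community under the config's master seed.

    Each species draws from its own seed stream (spawned from the master
    seed), so enlarging B leaves earlier species' parameters untouched.
    """
    if network is None:
        network = build_network(config.M, config.delta_G_total)
    if network.M != config.M:
        raise ValueError("network M does not match config M")
    master = np.random.SeedSequence(seed if seed is not None else config.seed)
    streams = master.spawn(config.B)
    width = len(str(config.B))
    species = [
        generate_species(network, config, np.random.default_rng(streams[i]),
                         sid=f"sp{i + 1:0{width}d}")
        for i in range(config.B)
    ]
    return Community(network=network, species=species, cell=config.cell,
                     config=config)


def initial_state(community: Community):
    """Equal-abundance initial condition (imported here to avoid a cycle)."""
    from .dynamics import CommunityState

    cfg = community.config or RegimeConfig(M=community.network.M,
                                           B=community.B)
    B, M = community.B, community.network.M
    a0 = np.full(B, cfg.a0)
    return CommunityState(
        C=np.zeros(M),
        N=np.full(B, cfg.N0),
        phi_R=np.asarray(ideal_ribosome_fraction(a0, community.cell)),
        a=a0,
        t=0.0,
    )


# ---------------------------------------------------------------------------
# Deterministic toy fixtures
# ---------------------------------------------------------------------------

#: Per-step free-energy drop used by both toy fixtures, J mol^-1.
FIXTURE_STEP = 7.5e4


def _fixture_species(sid, reaction, k, eta, d, K_S=1e-4, r=10.0):
    return Species(id=sid, reactions=np.array([reaction], dtype=np.intp),
                   k=np.array([k]), K_S=np.array([K_S]), r=np.array([r]),
                   eta=np.array([eta]), nu=np.array([1.0]), d=d)


def make_fixture(name: str, *, include: list | None = None) -> Community:
    """Deterministic three-metabolite demonstration communities.

    ``syntrophy_demo``: metabolite 1 supplied; A and B both run 1->2, A with
    the higher ATP yield (hence closer to equilibrium and more inhibited by
    metabolite 2); C runs 2->3.  Without C, accumulated metabolite 2 blocks
    A and B takes over; with C consuming metabolite 2, A's yield advantage
    wins and A+C coexist.

    ``pollution_demo``: metabolites 1 and 2 supplied; A runs 2->3 with a
    near-equilibrium yield, B runs the irreversible two-step 1->3.  Alone, A
    reaches a steady state; with B's extra production of metabolite 3, A is
    thermodynamically inhibited past its subsistence point and goes extinct.

    ``include`` optionally restricts the community to a subset of species
    ids (e.g. ``["A", "B"]``).
    """
    cell = CellParameters()
    d = 1.0e-5
    # canonical 3-metabolite network: reaction 0: 1->2, 1: 1->3, 2: 2->3
    network = build_network(3, 2 * FIXTURE_STEP)
    if name == "syntrophy_demo":
        supply = [1.0e-5, 0.0, 0.0]
        species = [
            _fixture_species("A", 0, k=5.0, eta=0.9, d=d),
            _fixture_species("B", 0, k=5.0, eta=0.5, d=d),
            _fixture_species("C", 2, k=5.0, eta=0.5, d=d),
        ]
    elif name == "pollution_demo":
        supply = [1.0e-5, 1.0e-5, 0.0]
        species = [
            _fixture_species("A", 2, k=0.5, eta=0.955, d=d),
            _fixture_species("B", 1, k=5.0, eta=1.0, d=d),
        ]
    else:
        raise ValueError(f"unknown fixture {name!r}; expected "
                         "'syntrophy_demo' or 'pollution_demo'")
    if include is not None:
        species = [sp for sp in species if sp.id in include]
    config = RegimeConfig(M=3, B=len(species), delta_G_total=2 * FIXTURE_STEP,
                          kappa=1.0e-5, rho=1.0e-4, supply=supply, d=d,
                          t_final=1.0e8, cell=cell, fixture=name)
    return Community(network=network, species=species, cell=cell, config=config)
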