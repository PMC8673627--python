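# Model and methods

## The model

`thermocrm` simulates the assembly of a closed microbial community on a
single supplied carbon substrate, with the thermodynamics of catabolism
made explicit. Three ingredients interact:

1. **A metabolite free-energy hierarchy.** M metabolites form a ladder of
   uniformly decreasing standard free energy, with total span ΔG_total
   (J mol⁻¹) from metabolite 1 (supplied) to metabolite M. Catabolic
   reactions convert a metabolite into one either one or two levels lower,
   so the network has exactly 2M − 3 reactions and is fully connected
   downward. A one-step reaction drops ΔG_total/(M−1); a two-step reaction
   drops twice that. "Labile" versus "recalcitrant" substrates are
   modelled purely as high versus low total span.

2. **Reversible catalysis with ATP transduction.** Each species carries a
   small random subset of reactions. A reaction transducing η ATP per
   event has equilibrium constant

       K = exp(−(ΔG⁰ + η ΔG_ATP)/RT),

   so capturing more free energy as ATP (larger η) leaves less to
   dissipate and pulls the reaction toward equilibrium. The net rate per
   cell is the reversible Michaelis–Menten form

       q = k E S (1 − θ) / (K_S + S(1 + rθ)),    θ = (W/S)/K,

   evaluated internally in the equivalent singularity-free form
   q = kE(S − W/K)/(K_S + S + rW/K). θ is the thermodynamic factor: 0 far
   from equilibrium (plain Michaelis–Menten), 1 at equilibrium (zero net
   rate). Beyond equilibrium (θ > 1) the rate is negative: the enzyme runs
   in reverse and the reverse flux consumes ATP. A configuration flag
   restores the stalled (clamped-at-zero) variant.

3. **Proteome-partitioned cells.** Each cell's proteome divides into
   housekeeping (fixed fraction φ_Q), ribosomes (φ_R), and metabolic
   enzymes (φ_P = 1 − φ_R − φ_Q). Growth is translation-limited,
   λ = γ(a) f_b φ_R/n_R, with elongation rate γ(a) = γ_m a/(γ_½ + a)
   saturating in the internal ATP pool a. The cell steers its ribosome
   fraction toward a target φ_R* = a/(Ω_½ + a)·(1 − φ_Q) on the timescale
   τ_g = log₂(100)/λ. Enzyme copy numbers are E = m ν φ_P/n_P, with
   expression weights ν summing to 1 over the species' reactions.

The community state is (C₁..C_M, N_i, φ_R,i, a_i): metabolite amounts
(moles in a fixed unit volume), population abundances (cells), ribosome
fractions, and per-cell ATP pools. The dynamics are

    dC_β/dt  = κ_β − ρ C_β + Σ_i (p_iβ − c_iβ) N_i
    dN_i/dt  = (λ_i − d_i) N_i
    dφ_R,i/dt = (φ_R* − φ_R,i)/τ_g
    da_i/dt  = J_i − χ m λ_i − a_i λ_i

with J_i = Σ_α η_α q_α the ATP production rate, χ m λ the translation
cost, and a λ the dilution of the pool by growth. Per-cell metabolite
fluxes p, c convert molecular reaction events to moles through Avogadro's
number; the mole/molecule split (metabolites in moles, intracellular
quantities in molecules per cell) is a bookkeeping convention, not a
physical assumption. Intracellular metabolite concentrations are assumed
equal to environmental ones (no transport step), which is conservative:
maintaining a gradient would cost more free energy than it contributes.

**Entropy production.** The free energy dissipated per reaction event is
D = ΔG⁰ + RT ln(W/S) + η ΔG_ATP, which equals RT ln θ identically, so D
and q always carry opposite signs. The reported community entropy
production rate is σ = −Σ_i Σ_α D q N_i / T ≥ 0 (the raw signed sum is
retained). Amounts are floored at 10⁻³⁰⁰ mol inside ln(W/S) so an exactly
empty product pool gives a large finite rather than infinite logarithm.

**Reaction efficiency** is reconstructed as ε = η ΔG_ATP / (−ΔG⁰), the
fraction of a reaction's standard free-energy drop captured as ATP,
ν-weighted within species and population-weighted across them. In the
reversible sampling regime η may exceed the standard-state
zero-dissipation point (equilibrium is defined at product/substrate ratio
10⁻², not 1), in which case ε caps at 1 with a warning.

**Interaction classification.** At steady state each metabolite is
perturbed in turn (relative step 10⁻³, two-sided) and each survivor's
quasi-steady growth rate is recomputed: φ_R held fixed, the ATP pool
re-equilibrated to da/dt = 0 (unique root by monotonicity), λ evaluated
there. The growth rate has no direct metabolite dependence in this model,
so the quasi-steady response is the natural instantaneous per-capita
response; its sign equals that of ∂J/∂C. Combined with each species' net
impact (p − c)N on the metabolite, the sign pair classifies the directed
interaction: (+,+) facilitation, (+,−) competition, (−,+) pollution,
(−,−) syntrophy. Strength is |response × impact|, rescaled per community
by its maximum. The response functional and strength formula are design
choices of this package; sign structure and orderings, not absolute
strengths, are the meaningful output.

## Random communities and regimes

Each species draws: a reaction count uniform on {1..5}; that many distinct
reactions uniformly; k, K_S, r log-normal (medians 1 s⁻¹, 10⁻⁴ mol, 10;
log-σ = 1); expression weights as normalised uniforms; and η uniform on
[1/3, η_max]. η_max solves K(η) = ratio with ratio 10⁻² (reversible
regime) or 10⁵ (Michaelis–Menten regime) — the only difference between
the two kinetic regimes. η ≥ 1/3 always (one ion pumped across a
membrane); reactions whose η_max falls below 1/3 are pinned there and
flagged. Every species has its own seed stream spawned from the master
seed, so enlarging a community never perturbs earlier draws.

## Parameter defaults and their rationale

No single authoritative set of values exists for these cellular and
chemostat constants, so all numeric defaults are package choices, set
once from physical scales and held fixed:

| parameter | default | rationale |
|---|---|---|
| γ_m | 21 aa s⁻¹ | bacterial maximal elongation rate |
| n_R | 7459 aa | ribosome protein mass |
| n_P | 300 aa | average metabolic protein |
| m | 10⁸ aa | total cell protein mass |
| φ_Q | 0.45 | housekeeping fraction |
| f_b | 0.7 | fraction of ribosomes translating |
| χ | 29 ATP aa⁻¹ | full biosynthetic cost per residue |
| γ_½, Ω_½ | 5×10⁸, 10⁸ ATP cell⁻¹ | sub-saturating at typical pools |
| ΔG_ATP | 7.5×10⁴ J mol⁻¹ | physiological ATP hydrolysis energy |
| T | 293.15 K | room temperature |
| κ | 10⁻⁵ mol s⁻¹ | supply of metabolite 1 |
| ρ | 10⁻⁵ s⁻¹ | dilution; see below |
| d | 10⁻⁵ s⁻¹ | biomass loss, ~5% of λ_max |
| N₀ | 100 cells | equal initial abundance |
| a₀ | 2×10⁸ | moderate sub-saturating pool |
| extinction threshold | 10⁻² cells | below any dynamical relevance |

These give growth rates λ ~ 10⁻⁴–10⁻³ s⁻¹ (doubling in hours), sustained
populations of 10¹³–10¹⁴ cells on the 0.1-mol substrate pool, and
metabolite amounts spanning the growth-support (10⁻⁴ mol) and exhaustion
(2×10⁻³ mol) thresholds used by the analyses. The dilution rate ρ sets
how sharply accumulated pools burn off: the ratio of a burn flux to the
sustained supply flux scales as λ/ρ, and ρ = 10⁻⁵ (λ/ρ ≈ 30) produces the
distinct entropy-production spikes that are the signature of sequential
substrate diversification; at ρ = 10⁻⁴ the spikes degrade into steps.

The reversible-rate ATP gate: reverse flux is scaled by a/(a + 10⁶)
(≈0.03% of the ATP cost of one cell mass), so a cell with an empty ATP
pool cannot pay for uphill catalysis. This regularisation removes a
discontinuous switch at a = 0 and is invisible at physiological pools.

## Numerical integration

The M + 3B ODE system is stiff (equilibrium constants span many orders of
magnitude). It is integrated with LSODA in chunks over a log-spaced grid
to t_final = 10⁸ s (relative tolerance 10⁻⁸, absolute 10⁻¹² per
component). Between chunks, species below the extinction threshold are
clamped to zero, logged, and removed from the active set. Sampled states
are cleaned of sub-round-off negative excursions (anything beyond −10⁻⁸
raises an error). An analytic Jacobian (verified against numerical
differentiation in the test suite) is available via `use_jacobian`; with
the ATP gate in place the default finite-difference path is faster on
most communities, so it is off by default. Growth-rate and
entropy-production series are reconstructed from 2000 sampled states —
dense enough to resolve pool burn-offs, which last of order one consumer
e-folding time (~10³–10⁴ s).

Ensemble comparisons across regimes integrate at relaxed tolerance
(rtol 10⁻⁶, atol 10⁻⁹, 600 samples): regime means of survivor and
substrate counts are unchanged relative to the tight settings, at about a
third of the cost.

## Spike detection

Entropy-production spikes are local maxima whose topographic prominence
exceeds 5% of the local series value. The criterion is relative rather
than range-based because the baseline grows by orders of magnitude during
assembly, and a global-range threshold silently scales with each run's
largest spike. The 5% default follows from the model's own scales: a pool
at the exhaustion threshold (2×10⁻³ mol) consumed over one consumer
e-folding time perturbs the sustained dissipation flux by a few percent.
Peaks in the pre-establishment regime (σ below 10⁻³ of its maximum) are
ignored. Sensitivity: thresholds between 2% and 10% change counts by
±1–2 per run at desk scale; the global-range mode is retained as an
option for comparison.

## The toy communities

Two deterministic three-metabolite fixtures demonstrate the thermodynamic
interaction types. Their kinetic parameters were constructed so that the
narratives are decided by thermodynamics rather than kinetic prowess:

- **Syntrophy demo.** A and B both run 1→2 with equal kinetics; A
  transduces more ATP (η = 0.9 vs 0.5) and is therefore ~2×10⁵-fold
  closer to equilibrium. Alone with B, the shared waste (metabolite 2)
  accumulates to ~10⁴ times the substrate level, fully blocking A while
  barely touching B: B wins. Adding C (2→3) keeps metabolite 2 near its
  subsistence level, the block lifts, and A's yield advantage excludes B:
  A and C coexist. The classifier records C→A syntrophy on metabolite 2.

- **Pollution demo.** Metabolites 1 and 2 are both supplied. A runs 2→3
  near equilibrium (η = 0.955, K ≈ 4) with deliberately modest kinetics
  (k = 0.5 s⁻¹, ~2× viability margin); B runs the effectively
  irreversible two-step 1→3. Alone, A settles into a steady state where
  its own waste holds it at λ = d. B's extra production of metabolite 3
  doubles the waste level, pushing A below subsistence at any achievable
  substrate level: A goes extinct through a species it shares no
  substrate with. The classifier records B→A pollution on metabolite 3.

## What the generator does and does not emulate

Synthetic communities reproduce the structural features the analyses
depend on: niche generation by sequential substrate diversification,
competitive exclusion, cross-feeding, thermodynamic inhibition, and the
rate–yield trade-off in η. They do not emulate immigration (closed
system), spatial structure, demographic noise, species-specific
translation constants, adaptive proteome reallocation, or uneven
free-energy spacing. Passing ensemble tests therefore demonstrates the
model's internal mechanisms at desk scale, not agreement with any
empirical community data.

## Desk-scale study conditions

The headline system (250 species, 25 metabolites, 250 replicates) is too
large for routine testing, so the packaged study conditions scale it
down while preserving the per-level free-energy spacing (ΔG_total scales
with M − 1):

- **Spike/diversification ensemble**: 20 communities, 50 species on 10
  metabolites, reversible kinetics at the 5.0×10⁶ J mol⁻¹ (per 24 levels)
  spacing.
- **Regime comparison**: 20 communities per regime, 30 species on 15
  metabolites, high (1.5×10⁷) vs low (1.5×10⁶ J mol⁻¹ per 24 levels)
  spans × reversible vs Michaelis–Menten. Fifteen levels are the smallest
  hierarchy on which the low-energy cascade genuinely stalls before the
  extinction wave — on 10 levels every regime fully diversifies the
  ladder and the diversification contrast is ceilinged away.

## Known limitations

- Absolute interaction strengths, efficiencies above the standard-state
  cap, and the entropy floor are reconstructions; only signs, orderings
  and counts should be compared across studies.
- A handful of communities host weakly damped consumer–resource
  oscillations and are flagged non-converged rather than forced to a
  steady state.
- The spike/diversification correlation at desk scale has modest
  statistical power (rank correlation ~0.4–0.6 over 20 runs); the
  full-scale system separates these quantities far more strongly.
- Survivor counts never exceed diversified substrates (competitive
  exclusion with shared saturation constants); models with distinct
  metabolic strategies can break this bound, this one cannot.
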