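# Methods

## Model

Three interacting populations on a homogeneous 1-D landscape: a partner
mutualist `P` and two competitors `F1`, `F2` that share it. Discrete
generations alternate a growth phase and a dispersal phase
(integro-difference dynamics): growth integrates a point-wise ODE system for
a duration `T`, dispersal convolves each species' density with its own
Gaussian kernel. The growth ODEs combine logistic self-limitation,
Lotka–Volterra competition between `F1` and `F2`, and bidirectional
consumer–resource mutualism with saturating benefit functions
(half-saturation `h`). A species' dependence `δ` splits its growth between an
intrinsic part `(1−δ) r` and a partner-derived part `δ α P/(h+P)`; benefits
are net benefits (costs are not modelled separately). `F1` is by convention
the more dependent competitor (`δ_F1 = 0.9` vs `δ_F2 = 0.1` by default).

Assumptions worth keeping in mind: space is homogeneous and effectively
unbounded (fronts never reach the habitat edge); dynamics are fully
deterministic (no demographic or environmental noise); kernels are Gaussian
and constant (no density-dependent dispersal); growth and dispersal do not
overlap in time.

## Default parameters

| symbol | meaning | default |
|---|---|---|
| `r_i` | intrinsic growth rate (per unit time) | 0.3 |
| `d_i` | intraspecific competition | 0.1 |
| `h_i` | half-saturation of benefits (density) | 0.3 |
| `α_F1P`, `α_F2P` | max benefit to a competitor from P | 0.5 |
| `α_PF1`, `α_PF2` | max benefit to P from a competitor | 0.01 |
| `δ_F1`, `δ_F2` | mutualism dependence | 0.9, 0.1 |
| `τ_12`, `τ_21` | interspecific competition | swept in [0, 0.4] |
| `σ_F1²`, `σ_F2²` | competitor kernel variances | 0.05 |
| `σ_P²` | mutualist kernel variance | 0.05 (swept 0–0.099) |
| `T` | growth-phase duration | 1.0 |
| — | introduced density / width | 0.1 on 1 cell |
| — | iterations per run | 500 |
| `ε` | occupancy threshold (density) | 1e-3 |

These defaults give a single-species carrying capacity `r/d = 3`, 30× the
introduced density, with all equilibrium densities in the 0.3–4 range.
`T` is formally a fraction of a generation; the attractors and outcome
classes are insensitive to it (speeds scale as `√T`), so 1.0 is used and the
field remains configurable.

## Numerics

- **Growth integration**: classical fixed-step RK4, vectorized over grid
  cells, `dt = T/20` (the dynamics are smooth and non-stiff at these
  magnitudes; RK4 at this step is ~1e-10 accurate per generation). A
  numba-compiled per-cell kernel carries the load; a pure-numpy reference
  implementation and an adaptive RK45 mode (scipy) are kept and
  cross-checked in the tests. The nonnegative orthant is invariant under the
  exact flow, so any tiny negative excursion is numerical and is clamped.
- **Density floor**: magnitudes below 1e-12 are set to exactly zero after
  each phase. Gaussian kernels have unbounded support, so without a floor
  every cell is nonzero after one step and "extinct everywhere" would be
  unattainable.
- **Kernels**: sampled Gaussians truncated at ±8σ and renormalized to sum
  exactly to 1 (truncation error < 1e-15; renormalization makes uniform
  fields exact fixed points of dispersal). `σ² = 0` degenerates to the
  identity kernel. Kernels narrower than two grid cells are built but
  flagged as under-resolved.
- **Dispersal**: zero-padded linear convolution via FFT
  (`scipy.signal.fftconvolve`), validated against a naive O(N·K) summation
  oracle to 1e-10. The boundary is absorbing; a clearance guard aborts any
  run whose populations approach within one truncation width of the edge,
  and landscapes are auto-sized as 1.2 × (iterations × speed bound) using
  the rigorous pulled-front bound `c ≤ sqrt(2 σ²_max r_max T)` with `r_max`
  the saturation-capped per-capita rate.
- **Grid**: `dx = 0.01`, odd cell count, exact center cell. Runs are
  bit-reproducible; the engine evaluates growth and dispersal only on the
  occupied support window (numerically identical to full-grid stepping,
  since floored fields are exactly zero outside it).
- **Edges and speeds**: a species' range edge is the outermost cell with
  density ≥ ε; speeds are trailing-window means of per-iteration edge
  displacement (left/right agreement is checked — dynamics are mirror
  symmetric). Steady state is reported when edge displacements vary by at
  most ~one cell over a 50-iteration window and the core density is static
  to 1e-6 per iteration; by default runs still execute the full 500
  iterations (early stopping is opt-in).

## Classification

Ranges are threshold masks (`density ≥ ε`), with no contiguity assumption;
all overlap algebra is mask-based. Decision order: both competitors empty →
degenerate; one empty → the other wins; mutual coverage ≥ 95% both ways →
local coexistence; exactly one species ≥ 95% covered (its range nested in
the other's) → local coexistence with dominance of the larger-ranged
species; otherwise regional coexistence. ρ is reported alongside rather than
used as the classifier, since a ρ interval can be realized by different
geometries. Labels for the canonical presets are verified to be invariant to
ε across [1e-4, 1e-2].

The 95%/5% split leaves boundary cases (e.g. both coverages at 0.94) that
the decision order above resolves deterministically: mutual-coverage checks
run before the nesting check, and nesting decides dominance direction.

## Protocol and problem sizes

Every reported quantity uses one frozen protocol: 500 iterations (300 for
the single-species logistic checks, which settle by ~130), `dx = 0.01`,
defaults above. Sweep grids: outcome maps use τ steps of 0.05 (0.08 for the
5×5 exclusion map, taken at cell centers of the [0, 0.4]² square so every
point is genuinely competitive); the coexistence-boundary sweep uses
symmetric τ steps of 0.005 over [0, 0.12]; the dominance-flip sweep uses
σ_P² steps of 0.01 over [0.01, 0.09] (finer grids are available via flags).

## Known limitations

- **Transient-sensitive labels near thresholds.** Coverage-based labels keep
  evolving while front speeds converge: with the 1e-12 floor, fronts ride
  extremely low-density tails and their speeds approach the asymptotic
  pulled-front value slowly. At the 500-iteration horizon, presets whose
  exclusive edge bands sit near the 5% dominance threshold (e.g.
  (τ_12, τ_21) = (0.05, 0.05) and (0.15, 0.05) with equal kernels) classify
  as plain local coexistence / nested dominance, and only cross into edge
  dominance / regional coexistence by roughly 800 iterations. The tests
  record this rather than hiding it.
- **Total exclusion of the dependent competitor requires an unreachable
  core.** Wherever the mutualist is established, `F1`'s per-capita growth
  `(1−δ_F1) r + δ_F1 α P/(h+P) − τ_12 F2` is strictly positive for weak
  competition, so `F1` can be confined (nested range) but not eliminated
  from a mutualist-occupied core; a "F2 wins everywhere" outcome at weak
  symmetric competition is not dynamically reachable in this model.
- The τ_12 = 0 axis is degenerate without the mutualist: `F1`'s dynamics
  decouple from `F2` and it persists at `(1−δ)r/d = 0.3`, so
  exclusion claims apply to the competitive interior τ_12 > (1−δ_F1)r_F1/K_F2
  ≈ 0.011.
- What determinism buys and costs: identical configs reproduce bit-identical
  trajectories, but there is no notion of variability — real co-invasions
  add demographic noise, heterogeneous habitat and non-Gaussian (often
  fat-tailed) dispersal, all out of scope here. Passing tests demonstrate
  internal consistency of this idealized model, not forecasts for any real
  system.
- 2-D landscapes, habitat edges interacting with fronts, evolution of
  dependence, and density-dependent ("dispersive") mutualisms are not
  modelled.
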