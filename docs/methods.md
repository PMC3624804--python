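# Methods

## Model class and assumptions

`spedre` estimates rate constants of deterministic mass-action ODE systems.
A model is a list of elementary reactions, each with at most two reactants,
at most two products and exactly one rate constant; the ODE for species *i*
is the signed sum of mass-action fluxes over the reactions touching it.
Catalytic mechanisms are written with the catalyst on both sides
(`E + S -> E + P`), which contributes one (net-zero) term to the catalyst's
own ODE. Concentrations are in arbitrary normalized units; no unit
conversion is performed. More general rate laws (Michaelis–Menten, Hill),
SBML I/O and stochastic simulation are out of scope.

The *degree* of an ODE is the number of reactions touching its species; the
network degree is the maximum over species. All cost guarantees of the
discrete stage are exponential in this degree only, so the method targets
low-degree networks (every generator in this package caps the degree at 4).

The estimation setting is **data-rich**: every species observed at every
timepoint of every experiment. The data loader rejects anything sparser.

## Derivative interpolation

Each (experiment, species) time course is fitted with a cubic spline —
interpolating with natural boundary conditions by default (`bc_type`
configurable to `not-a-knot`), or a smoothing spline when a positive
smoothing factor is supplied for noisy data. Derivatives are evaluated at
the observation timepoints themselves, not on a finer collocation grid.
Extrapolation outside the observation window is an error.

Spline derivatives are least reliable at the first and last observation,
where the boundary condition, not the data, dominates the curvature. The
derivative table therefore carries a boundary flag, and the estimation
pipeline by default builds no factors at boundary timepoints (below).

## Collocation objective

The error term for experiment *e*, species *i*, timepoint *tⱼ* is the
squared residual between the ODE right-hand side evaluated at the observed
(spline-smoothed, if smoothing is on) concentrations and the interpolated
derivative. The squared form is the default because it is smooth and
consistent with the least-squares refinement stage; an absolute-value form
is available (`form="abs"`). Only the parameters appearing in species *i*'s
ODE influence the term — this locality is what makes the objective
decomposable.

The full objective is the product of all error terms. The raw product is
numerically treacherous (it collapses to zero if any single term does, and
under/overflows at realistic problem sizes), so comparisons use the
normalized mean natural log of the floored terms,
(1/N)·Σ log max(ε, floor), with floor 10⁻¹² by default. The product form is
also an imperfect accuracy score: it rewards driving a single residual
through zero as much as improving all terms moderately. It is retained
because it is the objective that factorizes.

## Discretization and joint tables

Each parameter's domain is split into equidistant bins represented by their
midpoints (the canonical small-scale setup uses 10 bins on [0.05, 1.05],
midpoints 0.1 … 1.0). For every factor, the error term is evaluated at
*every* combination of adjacent-parameter midpoints — mass-action
right-hand sides are linear in each rate constant, so the grid is assembled
exactly from per-parameter coefficient × midpoint arrays — and converted to
a probability table by Boltzmann weighting p ∝ exp(−β·ε), normalized in log
space so that fully-underflowing tables still normalize.

The temperature β is shared globally across factors and defaults to
1 / max(median of all grid error values, 10⁻¹²). A single global scale
keeps the relative weighting of factors consistent, so the max-product
assignment tracks the product-of-errors objective; per-factor adaptive
temperatures were tried and rejected because they reweight factors
arbitrarily and can pull the MAP away from the objective's optimum. A fixed
β can be supplied instead.

Tables are computed once before propagation and never mutated. The total
cell count equals Σ_factors (bins)^degree and is recorded on the graph.

## Loopy belief propagation

Max-product message passing runs on the bipartite graph of parameter
(variable) nodes and error-term (factor) nodes, entirely in log space:

- **Variable → factor**: the variable's current full belief. This is the
  implemented variant's rule; the textbook exclusion rule (divide out the
  recipient factor's previous message) is available via `standard_bp=True`.
- **Factor → variable**: max-marginalization of [log table + incoming
  messages of the *other* variables] onto the recipient's axis, normalized,
  then stored in the recipient's message history (replacing that factor's
  previous message).
- **Belief update**: after each full factor sweep, every variable's belief
  becomes the normalized product of its stored incoming messages
  (current-sweep messages, Gauss–Seidel style).

Factors are processed in fixed lexicographic (experiment, species,
timepoint) order; messages and beliefs are renormalized after every update
so they remain valid distributions. Iteration stops when no normalized
message changes by more than `tol` (sup-norm, default 10⁻⁶) between
iterations, or at `max_iter` (default 100); hitting the cap flags
non-convergence without raising, since loopy propagation can oscillate on
cyclic graphs. Optional damping (linear-space convex combination with the
previous message) is off by default. Argmax ties break to the lowest bin
index, making the whole stage deterministic.

Boundary timepoints contribute no factors by default
(`use_boundary_timepoints=False` on the pipeline): endpoint derivative
estimates carry the boundary-condition bias, and treating them as evidence
was observed to displace single bins on ring benchmarks. The structural
`build_factor_graph` keeps all timepoints unless told otherwise, for
analyses that want the complete graph. Datasets with fewer than three
timepoints per experiment fall back to using all of them.

If any parameter's final top-two beliefs are within 10⁻³ the result is
flagged (with a warning) as weakly identified — equilibrium or otherwise
uninformative data produce near-tied beliefs rather than errors.

Note the max-product MAP optimizes Σ β·ε (the log of the product of table
probabilities), which coincides with the product-of-errors optimum only
when one bin combination dominates factor-by-factor — the intended
well-separated regime (dense sampling, truth near midpoints). The
brute-force comparison in the acceptance suite quantifies this agreement on
tiny enumerable problems.

## Local refinement

The MAP midpoints seed bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, TRF, finite-difference Jacobian) on the
residual vector √wᵢ·(x_sim − x̂), with simulations started from each
experiment's observed initial concentrations. Weights default to
wᵢ = 1/(per-species observed maximum)², putting species of different scales
on a comparable footing; uniform weights are a flag away. Bounds default to
the discretization bounds expanded by one bin width per side (floored at a
small positive rate). Integrator failure at a candidate vector yields a
large finite penalty residual (10⁶ per point) instead of an exception, so
the optimizer can back away. The final SSE never exceeds the starting SSE.

Simulation uses LSODA with rtol 10⁻⁸ / atol 10⁻¹⁰ — tight enough that
data-generation and fitting error is negligible against estimation error.

## Quality metrics

- **Weighted SSE**: Σ wᵢ (x_sim − x̂)² over experiments, species, timepoints.
- **Species MRE** (%): worst deviation normalized per (experiment, species)
  by the observed maximum of that time course. Range normalization is the
  default because pointwise division explodes near zero; the pointwise
  variant sits behind `pointwise=True`. Values above 100% mean a trajectory
  was missed by more than its own dynamic range. All-zero species are
  skipped with a warning.
- **PPE** (%): 100·|k̂−k|/k per parameter, aggregated by the **median** (the
  headline aggregate), defined only for simulated tests where truth exists.

## Synthetic benchmarks

- **Ring networks**: n unimolecular conversions in a cycle; every ODE has
  degree 2 at any size, isolating scaling from identifiability.
- **Random low-degree networks**: round(2n/3) bimolecular (A + B → C, three
  distinct species) plus n/3 unimolecular reactions, degree-capped at 4,
  resampled until every species participates; duplicate reactions are
  rejected because two copies of the same reaction leave only the sum of
  their rate constants identifiable.
- **Akt topology**: serum-driven PI3K activation, NOX/ROS production and
  antioxidant decay, reversible redox inactivation of PTEN, the PIP2/PIP3
  cycle, PIP3-dependent membrane recruitment of Akt and PDK1, Thr308
  phosphorylation by PDK1, return to the cytosol and PP2A
  dephosphorylation (16 species, 15 reactions, maximum degree 4). The rate
  constants are fixed unit-scale placeholders, overridable per name; the
  shipped model is topology-faithful, not kinetically calibrated, so
  quantitative results on it characterize the pipeline, not Akt biology.

Datasets are produced by simulating a scenario's network at its nominal
parameters from seeded random initial concentrations (uniform on
[0.1, 1.0]) on an equidistant grid — canonically 11 timepoints over 4 s —
with one experiment by default, and optionally snapping nominal rates to
bin midpoints so that exact bin recovery is well defined. Noise is
multiplicative Gaussian, x̂ = x·(1 + level·z) clipped at zero, because
percentage noise levels describe relative error; an additive model is not
provided. A scenario's seed fully determines its dataset.

What the generators do **not** emulate: measurement-specific error
structure (heteroscedastic counting noise, batch effects), missing or
unobserved species, non-mass-action kinetics, and realistic kinetic
constants for the Akt pathway. Passing tests on these benchmarks
demonstrate correctness and scaling of the algorithm in its intended
regime, not robustness on real proteomic data — on 20%-noise data all
methods, including refinement from the truth's neighbourhood, degrade
substantially.

## Problem sizes used in the shipped checks

The test and acceptance runs use ring sizes 10–50 (grids of 6–41
timepoints), twenty 3-species enumeration problems with 4 bins (4³–64
combinations each), three seeded 30-species random networks, and the Akt
topology at 0% and 20% noise — sizes at which the brute-force oracles are
enumerable and a full run completes in a couple of minutes on one CPU while
still exercising every scaling dimension (species, timepoints, bins,
degree).

## Known limitations

- High-degree hubs make table sizes (bins^degree) explode; the method is
  for low-degree networks.
- The product-of-errors objective can prefer parameter vectors that zero a
  single residual; it is a vehicle for decomposition, not a gold-standard
  accuracy score, and the discretized stage exists to seed local
  refinement rather than to finish the job.
- Loopy propagation carries no convergence guarantee; non-convergence is
  flagged and the damping knob is available.
- The data-rich requirement is strict: no missing observations, no latent
  species.
- Parameters whose reactions are unobservable from the data (equilibrium
  data, catalytic cancellations) yield near-uniform beliefs; the weak
  identification warning is the intended signal.
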