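# Methods

## Model

Three species: prey *X* (intermediate host), predator *Y* (definitive
host), free-living parasite *Z*.  Each host species is split into
uninfected and infected subpopulations (x_U, x_I, y_U, y_I); z counts
free-living parasites.  All processes are individual-level reactions:

| process | rate law | state change |
|---|---|---|
| prey birth (uninfected parent) | g_x x_U | x_U +1 |
| prey birth (infected parent) | g_x r_x x_I | x_U +1 (offspring uninfected) |
| prey competition (same type) | x(x−1)/K per type | one prey −1 |
| prey competition (cross) | x_I x_U /K each direction | one prey −1 |
| prey infection | Q_x S x_U z | x_U→x_I, z −1 |
| predation, all four pairings | f_y × prey × predator | prey −1, plus outcome |
| … predator offspring | branch prob. k_y (× r_p per infection, × r_e per exposure) | y_U +1 |
| … predator infection (eating x_I) | branch prob. Q_y | y_U→y_I, z +n_z |
| intrinsic deaths | d_x, d_y, d_z per head | that compartment −1 |

Branching outcomes of one encounter (infect or not, offspring or not) are
separate exclusive channels with probabilities folded into the rate
coefficients — distributionally identical to a two-stage draw.  Channels
whose product equals their reactants (failed prey infection, predation
outcomes beyond prey removal) are omitted.  A predator is a binary
infected/uninfected state: re-infection of an infected predator applies
the cost r_p twice in that encounter's reproduction probability (r_p²)
and releases n_z parasites, but introduces no "doubly infected" type.
The exposure cost r_e is transient — it only modifies the encounter in
which the exposure occurs.  Infection is assumed at least as costly as
exposure (r_p ≤ r_e, validated).  No vertical transmission, no age or
spatial structure, no evolving traits.

Same-type competition uses ordered-pair counts n(n−1)/K so that a lone
individual cannot compete with itself; the expected drift of the jump
process therefore equals the rate equations up to the exact correction
(x_U/K, x_I/K, 0, 0, 0), which the test suite asserts to 1e−9.

## Parameters (reference values)

g_x=2, r_x=1, d_x=0.1, K=2000, S=5·10⁻⁴, Q_x=1, n_z=6, d_z=0.09,
f_y=0.01, k_y=0.2, Q_y=1, r_p=1, r_e=1, d_y=1; initial abundances
(x_U, x_I, y_U, y_I, z) = (800, 0, 100, 0, 1000).  Rates are per
individual (encounter rates per pair) per unit time; r_x, r_p, r_e are
reproduction multipliers (1 = no cost); Q_x, Q_y are probabilities.
These are the package defaults; sweeps perturb one or two of them.

## Stochastic engine

Exact Gillespie direct method, one seeded NumPy/Numba RNG per
trajectory.  Ensembles derive replicate seeds as base_seed + replicate
index, so results are independent of execution order.  States are
recorded on a fixed grid (default Δt = 0.1) plus the terminal state —
event counts reach ~10⁶–10⁷ per run at these abundances, making
per-event storage pointless.  When every propensity vanishes the run
terminates early and is flagged `all_absorbed`.  No tau-leaping or
hybrid schemes: the scientific questions (extinction in deep cycle
valleys) live exactly where approximations fail, and exact simulation
is fast at these population sizes (~10⁷ events/s).

## Deterministic engine

LSODA via `scipy.integrate.odeint`, rtol 1e−8, atol 1e−10, states
clamped to zero before each right-hand-side evaluation and in the
output.  Tight tolerances matter because the cyclic regimes pass
through valleys many orders of magnitude below one individual and the
classifier reads tail behaviour.  Note an intrinsic limit: in exact
arithmetic the ODE flow preserves strict positivity, but valleys fall
below any floating-point resolution, so a numerically integrated cyclic
regime with extreme virulence (e.g. r_p = 0) eventually collapses onto
the prey-only manifold.  This is the behaviour any fixed-precision
integration of these equations exhibits, and it coincides with the
sub-individual extinction cutoff used for classification anyway; the
strict-positivity property is asserted only over early cycles where it
is numerically meaningful.

Long-run summaries are time-weighted (trapezoid) means and minima over
the trailing 20% of the run (`tail_fraction=0.2`); defaults t_max = 2000
for deterministic runs, 1000 for stochastic ensembles (both
configurable and recorded in sweep metadata).

## Equilibria

Parasite-free: x_U* = d_y/(k_y f_y), y_U* = (g_x − d_x − x_U*/K)/f_y —
the damped Lotka–Volterra focus; an error is raised when the predator is
not viable.  Interior equilibria: eliminating variables reduces
stationarity to a scalar equation in x_I built from Φ = λx_I + 1,
Ψ = (d_y − ϵx_I − ζλx_I²)/(γλx_I + δ) and Θ = αΨ + d_z with
α = Q_xS, β = Q_yf_y, γ = r_pk_yf_y, δ = k_yf_y, η = n_zQ_yf_y,
λ = β/d_y and the signed coefficients ϵ, ζ from the predator
reproduction terms.  The solver scans x_I over (0, K] on a 4000-point
log grid, brackets sign changes (poles split intervals), polishes with
Brent's method, and back-substitutes x_U* = Ψ, y_I* = λx_I*y_U*,
z* = ηx_I*(y_I*+y_U*)/Θ and y_U* in two algebraically equivalent forms.
A root is accepted only if all five components are strictly positive,
the two y_U* forms agree to 1e−6 relative, and the full five-equation
right-hand side vanishes below 1e−6 in max-norm — the scalar equation
proposes, the rate equations decide, which guards against roots
introduced by clearing denominators.  Stability is assessed only
dynamically (convergence of integrations), never symbolically.

Invasion: the dominant eigenvalue (real part) of the 3×3 Jacobian block
of the rare subsystem (x_I, y_I, z) at the parasite-free point, by
central finite differences (h = 1e−6).  A positive rate means a rare
parasite invades; with Q_x = 0 or Q_y = 0 it is nonpositive.  Invasion
(growth when rare) and long-run persistence (classification) are
deliberately exposed as separate quantities and not forced to agree.

## Outcome classification

Coexistence: prey_only / prey_predator / all_three.  Deterministic rule:
a species is extinct when its tail-mean total abundance drops below one
individual (the natural demographic unit; configurable) — needed because
the ODE never reaches exact zero.  Stochastic rule: extinction is an
exact zero of the total at the final state; the parasite is counted
across all life stages (z + x_I + y_I), which makes the rule coincide
with the absorbing set of the jump process.  Composition (only under
all_three): strict comparison of tail-mean x_I vs x_U and y_I vs y_U;
exact ties, a measure-zero event, count as uninfected-dominant.

## Threshold protocols and problem sizes

`tritroph.thresholds` locates eight reference boundaries, all with the
deterministic settings above and bisection to 0.005: the minimal Q_y and
Q_x for three-species coexistence (direct bisections in (0.05, 0.9) and
(0.01, 0.5)); the minimal Q_x and Q_y of the both-infected-dominant
region (row/column scans of the (Q_x, Q_y) plane at steps 0.05–0.1, each
row boundary bisected, minimum over rows); the plane-wide minimal Q_y of
the infected-predator/uninfected-prey band (columns Q_x = 0.15–0.8,
step 0.05 — the band is diagonal and its minimum sits at intermediate
Q_x); its lower Q_x edge at Q_y = 1 (fine scan, step 0.02); and the two
edges of the infected-prey/uninfected-predator region.  That last
outcome occupies a hairline diagonal sliver in Q_y (width ~0.002–0.005)
where both dominance ratios lie within a few percent of 1, so its
protocols use a fine Q_y scan (step 0.0025) per r_p column; its computed
minimal r_p is ≈ 0.78 under these equations and settings, and because
the two dominance crossings nearly coincide there, this particular edge
is far more sensitive to any modelling or classification variation than
the other seven (which are robust to the cutoff and horizon choices).
One shared runner caches every integration; the full set takes ~600
integrations (≈11 s).

## Known limitations

* Chaotic vs cyclic regimes are not distinguished (no Lyapunov
  exponents); the classifier only reads tail means.
* Deterministic "extinction" is cutoff-based and the printed boundaries
  shift by a few hundredths of a probability under different cutoff or
  horizon choices; boundaries are refined by bisection, not grid
  reading.
* The stochastic engine records on a sampling grid, so tail means (not
  extinction, which uses exact zeros) carry O(Δt) sampling error.
* Exact SSA cost grows linearly with total event rate; at K ≫ 10⁴ the
  engine would need leaping approximations that are out of scope.
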