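# Methods

## The model

Two heritable host strategies compete in a well-mixed plant population:
*mutualists* partner with a soil microbe (mycorrhizae or rhizobia),
trading carbon for nutrients, and *non-mutualists* forgo the
partnership.  Five non-negative constants define a game instance:

| symbol | meaning | role |
|---|---|---|
| `b_an` | benefit of freely available soil nutrients | strategy-independent |
| `b_mn` | benefit of microbially obtained nutrients | mutualists only |
| `c_r`  | cost of root production | paid by all |
| `c_t`  | cost of trade with the microbe | mutualists only |
| `n`    | competitors per focal plant (integer ≥ 1) | density knob |

Each contested nutrient pool is divided equally among the plants drawing
from it.  In a neighbourhood of `n + 1` plants, every plant nets the
baseline `b_an/(n+1) - c_r` from the free pool; a focal mutualist with
`k` mutualist neighbours additionally nets `b_mn/(k+1) - c_t`.  Because
the baseline is strategy-independent it cancels from all selective
comparisons, so the package works in the *simplified* game where the
non-mutualist payoff is identically zero; the *full* variant is kept for
completeness and its consistency (full − simplified = baseline in every
cell) is tested.

Benefits and costs are constants: there is no nutrient-availability
feedback, no trade-off between free and microbial nutrient acquisition
and no continuous investment strategy.  These are model assumptions, not
implementation shortcuts.

## Mean fitness and its closed form

Neighbourhoods are assembled at random from the population, so the
mutualist neighbour count of a focal plant is `k ~ Binomial(n, x)` at
population mutualist frequency `x` (the infinite-population,
with-replacement reading; the finite-population simulator converges to
it as the population grows).  Averaging the share over `k` uses the
identity `E[1/(k+1)] = (1 - (1-x)^(n+1)) / ((n+1) x)`, giving the
mutualist mean fitness

    W_M(x) = b_mn (1 - (1-x)^(n+1)) / (x (n+1)) - c_t.

The point `x = 0` is a removable singularity, defined by its limit
`b_mn - c_t` (a lone mutualist keeps the whole pool).  Numerically the
interior expression is evaluated as `-expm1((n+1) log1p(-x)) / ((n+1) x)`
to avoid catastrophic cancellation near `x = 0`; the test suite checks
the closed form against the explicit binomial sum to 1e-12 for
`n ≤ 12` on a 101-point grid.  `W_M` is strictly decreasing in `x`,
which is the engine of every result below.

## Regimes, equilibria, ESS

Since `W_N ≡ 0` in the simplified game, selection at `x` follows the
sign of `W_M(x)`, and the extreme values `W_M(0) = b_mn - c_t` and
`W_M(1) = b_mn/(n+1) - c_t` decide everything:

* `c_t > b_mn`: non-mutualist fixation (mutualism never pays);
* `c_t < b_mn/(n+1)` (equivalently `b_mn/c_t > n + 1`): mutualist
  fixation;
* `b_mn/(n+1) < c_t < b_mn`: coexistence — mutualism pays only when
  rare, so the unique interior root `x*` of `W_M` is globally stable and
  the mixed composition is the ESS.

Closed forms: `x* = 2(1 - c_t/b_mn)` for `n = 1` and
`x* = (3 - sqrt(12 c_t/b_mn - 3))/2` for `n = 2`.  For `n ≥ 3` the
equilibrium condition is a higher-degree polynomial (no radical solution
exists at all for `n ≥ 4`), so `interior_equilibrium_closed_form` raises
`NoClosedFormError` and the authoritative solver is Brent's bracketing
method on `[0, 1]` (default absolute tolerance 1e-10), with uniqueness
guaranteed by monotonicity.

The model uses strict inequalities; parameter sets landing *exactly* on
a threshold are structurally unstable and are reported as
`DEGENERATE_BOUNDARY` (relative tolerance 1e-9, configurable) rather
than silently binned into a fixation regime.

## Replicator dynamics

The dynamic behind the direction fields is the standard continuous-time
two-strategy replicator equation `dx/dt = x(1-x)(W_M(x) - W_N(x))`.
Trajectories use fixed-step classical RK4 with post-step clamping to
`[0, 1]` (default `dt = 0.01`), chosen over adaptive steppers for exact
run-to-run reproducibility; forward invariance and convergence to the
predicted stable state within 1e-4 are property-tested.  Best-response
analysis of the pairwise game treats indifference (payoff difference
below 1e-12) as the full best-response interval, never an arbitrary pure
strategy; the symmetric fixed points of the correspondence coincide with
the stable states of the replicator dynamics.

## The Wright-Fisher simulator (synthetic data)

The finite-population simulator is the package's synthetic-data
generator and its independent Monte-Carlo oracle.  It emulates exactly
the assumptions of the analytic model: a well-mixed population of
`pop_size` plants, fresh random neighbourhoods each generation (each
focal plant's `n` competitors drawn uniformly without replacement from
the rest of the population), realized simplified payoffs, and
non-overlapping generations with `pop_size` offspring sampled in
proportion to payoff (Wright-Fisher; the simplest process whose
deterministic limit is replicator-like).  Two exact reformulations keep
it fast without changing the process:

* payoffs depend on a neighbourhood only through its mutualist count, so
  that count is drawn from the hypergeometric law of uniform
  without-replacement sampling instead of enumerating neighbour
  identities;
* individuals of the same strategy are exchangeable, so the mutualist
  offspring count is drawn from the binomial marginal of the
  payoff-proportional multinomial.

Payoffs can be negative, so a constant `fitness_floor` (default
`c_t + 1`, which bounds every weight away from zero) is added before
reproduction.  An additive floor cancels from the fixed-point condition
of the payoff-proportional update — equal mean payoffs still mean equal
expected offspring — so the interior equilibrium of the deterministic
limit is unchanged; the floor only rescales selection strength relative
to drift.  Recovery tolerances are therefore statistical (3 Monte-Carlo
standard errors of the terminal frequency), reflecting drift, not a
systematic offset.

Frequencies 0 and 1 are absorbing (no mutation).  A single master seed
spawns one `SeedSequence` child stream per replicate, making results
bit-for-bit reproducible and replicates independent.

Default study conditions — 2000 plants, `x0 = 0.5`, 200 generations, 50
replicates — are large enough that the terminal-frequency standard error
at a coexistence equilibrium is a few parts in a thousand, and small
enough that a ten-parameter-set recovery sweep runs in seconds on one
CPU.  What the simulator does **not** emulate: spatial structure,
overlapping generations, mutation, symbiont-side evolution or partner
choice, and nutrient feedback on benefits.  Passing recovery therefore
validates the internal consistency of the analysis under the model's own
assumptions — not the model's fit to any field population.

## Phase diagrams

`compute_phase_grid` classifies a rectangular `(c_t, b_mn)` grid for one
`n` and attaches the equilibrium frequency to each cell (0 on
non-mutualist-fixation cells, 1 on mutualist-fixation cells, the
interior root on coexistence cells).  Classification is vectorized with
the same inequalities and boundary tolerance as `classify_regime`, and
tests assert cell-by-cell identity with the scalar classifier.  The
region-geometry consequences of crowding — the mutualist-fixation region
shrinks as `n` grows while the non-mutualist region (`c_t > b_mn`,
independent of `n`) and the mutualist-present region are invariant — are
asserted on fixed grids, default 200×200 over `(0.01, 5)²` (the offset
origin avoids the all-degenerate axis `b_mn = c_t = 0`).  Figure
rendering is a convenience layer with no tested contract beyond file
creation; axes orientation and colours are cosmetic.

## Numerical choices and edge cases

* `x = 0` mean fitness: analytic limit, not an epsilon hack.
* Root finding: `scipy.optimize.brentq` on the full bracket `[0, 1]`
  (the endpoint values are finite by the limit definition), `xtol`
  1e-10 by default, 1e-12 where tests compare against radicals.
* Boundary equality of `c_t` with a threshold: degenerate label at
  relative tolerance 1e-9.
* Replicator indifference/tie tolerance: 1e-12.
* CSV artifacts print floats with 12 significant digits so repeated runs
  diff cleanly.
* `b_mn = 0` games: non-mutualist fixation when `c_t > 0`, degenerate
  when `c_t = 0`.

## Known limitations

* The `n = 3` closed-form equilibrium (a cubic in disguise) is not
  implemented; the numeric solver is authoritative for all `n ≥ 3`.
* The degenerate-boundary label depends on a tolerance; parameter sets
  engineered to sit within 1e-9 (relative) of a threshold are reported
  as boundary cases even if strictly inside a regime.
* The best-response module covers the pairwise game only, matching the
  scope of the underlying two-player analysis.
* Interpreting `x*` across species boundaries (community-level
  coexistence) is outside the package's scope; `x*` is an intraspecific
  genotype frequency here.
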