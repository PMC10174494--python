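# Methods

## Model and assumptions

The package models discarded-drug recycling as a three-population
evolutionary game. Each population is large, bounded-rational, and adjusts
its strategy mix by imitation, so the share of each first-named strategy
(government strong regulation `x`, firm active participation `y`, consumer
active participation `z`) follows a one-dimensional replicator equation:
the share grows in proportion to its payoff advantage over the population
mean, with the logistic factor `p(1-p)` confining shares to `[0,1]`.

The stage game's payoffs are built from scalar parameters in abstract
currency units:

| symbols | meaning | default constraint |
|---|---|---|
| `A1`, `A2` | per-strategy incentives to active firms / consumers under strong regulation | `>= 0` |
| `F1` | fine on passive firms under strong regulation | `>= 0` |
| `C1`, `C3` | firm cost of active / passive participation | `C1 >= C3 >= 0` |
| `C2`, `C4` | consumer cost of active / passive participation | `C2 >= C4 >= 0` |
| `C5`, `C6` | cost of strong / weak regulation | `C5 >= C6 >= 0` |
| `R1..R6` | gross gains (firm active/passive are `R1`/`R3`, consumer `R2`/`R4`, government `R5`/`R6`) | unrestricted sign |
| `M1..M4` | externality losses from passivity (to government from firms `M1` / consumers `M3`; to consumers from firms `M2`; to firms from consumers `M4`) | `>= 0` |
| `B1`, `B2` | lump-sum subsidies to firms / consumers whenever regulation is strong | `>= 0` |

Modelling choices where the design was genuinely open:

* **Payoff cells are the canonical source of truth.** The 8-cell matrix is
  defined so that its bilinear aggregation reproduces the expected-payoff
  algebra and hence the replicator field exactly; this resolves two sign
  ambiguities in alternative tabulations of the same game (the firm subsidy
  `B1` and the government loss `M3` in the strong/active/passive cell) in
  favour of the algebra that the stability analysis rests on.
* **The symbol for the firm's loss from consumer passivity under weak
  regulation is `M4`** — the only reading consistent with the firm's
  replicator equation.
* **Lump-sum subsidies `B1`, `B2` are paid in every strong-regulation
  profile**, not conditioned on the recipient's behaviour; the per-strategy
  incentives `A1`, `A2` carry the behavioural conditioning.
* **Interior (mixed-strategy) rest points are not classified.** In an
  asymmetric game a mixed equilibrium is never evolutionarily stable, so
  only the eight cube vertices are analysed; `interior_gap_roots` reports
  the interior zeros of the firm/consumer gap functions for diagnostics
  only.

## Stability classification

At a vertex the Jacobian of the replicator field is exactly diagonal, so
the three eigenvalues are closed-form payoff-gap expressions: each equals
the local gap for its population, negated where the vertex plays the
first-named strategy. The Lyapunov indirect method then classifies a vertex
as asymptotically stable (all eigenvalues `< -eps`), unstable (all
`> eps`), or a saddle (mixed signs); any eigenvalue within `eps` of zero
(default `1e-9` on the payoff scale) makes the vertex non-hyperbolic and
linearisation inconclusive. Some descriptions of this game label particular
mixed-sign cases "unstable"; this package normalises terminology to the
sign-pattern rule above, which is what the eigenvalues actually support.

Regime classification (`classify_regime`) uses strict inequalities with the
same `eps`: parameter sets on a regime-defining equality return
`UNCLASSIFIED` rather than a guessed label. The regimes and their predicted
unique ESS vertex:

* high opportunity cost of passivity for both firm and consumer —
  `(0,1,1)` below the upper relative-gain threshold, `(1,1,1)` above it;
* strong regulation insufficient to deter passivity — `(0,0,0)` below the
  lower threshold, `(1,0,0)` above it;
* baseline (opportunism under weak regulation, regulation effective) —
  `(0,0,0)` below the lower threshold, `(1,1,1)` above the upper, and no
  stable vertex strictly inside the window between them.

## Numerical integration

Trajectories are computed with an adaptive explicit Runge–Kutta 4(5)
method (`scipy.integrate.solve_ivp`, `rtol 1e-8`, `atol 1e-10`), sampled on
a uniform grid (default spacing 0.1 time units) from the solver's
interpolant. Time is abstract replicator time. Sampled states are clipped
to the unit cube; the cube is forward-invariant analytically, so any
excursion beyond `1e-6` is treated as a solver failure rather than silently
repaired. Convergence to a vertex means Chebyshev distance below `1e-3`
sustained over the final 10 time units. The default horizon is 100 time
units, ample for the printed scenarios whose slowest stable eigenvalue has
magnitude 1; for sampled parameter sets with eigenvalues near zero the
consistency tests scale the horizon as `12 / min|lambda|`, the time needed
for the slowest linear mode to decay well inside the convergence tolerance.
Scenario simulations start from `(0.5, 0.5, 0.5)`: the scenario
descriptions fix no initial condition, and the cube centre is the natural
uninformative choice; the limiting vertex, not the transient, is the
reported result.

## Synthetic parameter generator

`sample_parameters` draws parameter sets inside a requested regime by
seeded rejection sampling. Every parameter except `R5` is uniform on
`[0, 20]` (the magnitude of the printed parameterizations; ranges are
overridable per parameter), with the cost orderings and the regime's
firm/consumer inequalities enforced by rejection. The government gain `R5`
is drawn conditionally: the relative gain `R5 - R6` is uniform on the
regime's admissible interval between the two thresholds (truncated to width
20 when unbounded), because the thresholds depend on six other sampled
parameters and plain rejection against them would discard almost every
draw in the high-gain regimes. Draws within `1e-6` of any regime-defining
equality are rejected so that every emitted set is hyperbolic. The stream
is `numpy`'s PCG64 generator keyed by the config seed; the same config
always reproduces the same parameter set.

What the generator emulates — and does not. It produces parameter sets that
satisfy the model's inequality regimes, nothing more: there is no empirical
recycling data behind the magnitudes, no correlation structure between
costs and gains, and no calibration target. Passing tests therefore show
that the theorems' predictions hold across each regime's parameter
polytope, not that any particular regime describes a real drug-recycling
market.

## Problem sizes

The test suite uses 1000 random draws for the payoff-gap identity, 200 for
the Jacobian/finite-difference check, 100 sampled parameter sets per regime
for theorem recovery, and interior grids up to `3^3` points for basin maps;
the acceptance script integrates each scenario once over 100 time units
(1001 samples). These sizes make every check exhaustive at the model's
scale — the model itself is three coupled scalar ODEs — while the whole
suite runs in well under a minute.

## Known limitations

* Two strategies per population; no mixed-population heterogeneity,
  multiple competing firms, or third-party recyclers.
* Payoffs are static: no discounting, learning-rate parameter, or noise in
  the imitation process (the replicator limit is deterministic).
* Non-hyperbolic cases are reported, not resolved; centre-manifold analysis
  on threshold boundaries is out of scope.
* Basin maps integrate a finite grid of initial conditions; they do not
  prove global convergence, although for every regime with a unique stable
  vertex the sampled interior points all reach it.
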