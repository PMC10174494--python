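# recyclegame

Evolutionary-game toolkit for the tripartite discarded-drug recycling
problem: a government choosing between **strong** and **weak** regulation,
drug-recycling firms choosing between **active** and **passive**
participation, and consumers choosing between **active** and **passive**
participation. The package is for researchers and policy modellers who want
to reproduce the model's stability results or explore new parameter sets:
it implements the payoff model, the three-population replicator dynamics,
eigenvalue-based stability classification of all pure-strategy equilibria,
and the inequality-regime analysis that predicts the long-run outcome.

## Model

Population shares `x`, `y`, `z` in `[0,1]` are the probabilities of strong
regulation, firm active participation and consumer active participation.
With bounded-rational agents imitating better-performing strategies, each
share follows a replicator equation driven by the payoff advantage of its
first-named strategy:

```
dx/dt = x(1-x) [ -y(A1+F1) - z A2 + R5 - C5 - B1 - B2 + F1 - R6 + C6 ]
dy/dt = y(1-y) [  x(A1+F1) + R1 - C1 - R3 + C3 ]
dz/dt = z(1-z) [  x A2     + R2 - C2 - R4 + C4 ]
```

The bracketed gaps come from an 8-cell payoff matrix over the pure strategy
profiles, built from incentives (`A1`, `A2`), a fine (`F1`), participation
and regulation costs (`C1..C6`), gross gains (`R1..R6`), externality losses
(`M1..M4`) and lump-sum subsidies (`B1`, `B2`). All eight cube vertices are
rest points; at a vertex the Jacobian is diagonal, so the Lyapunov indirect
method classifies each vertex from three closed-form eigenvalues. The
government's *relative gain* `R5 - R6`, compared against the thresholds
`C5 - C6 + B1 + B2 - F1` and `C5 - C6 + B1 + B2 + A1 + A2`, together with
the firm/consumer opportunism and enforcement inequalities, selects which
vertex (if any) is the unique evolutionarily stable strategy; between the
two thresholds under the baseline assumptions no vertex is stable.

## Worked example

Classify the high-relative-gain scenario (`R5 = 30`, `R6 = 14` on the
baseline parameter set) and simulate the slack-enforcement scenario:

```
$ recyclegame classify --scenario s6_1 --out demo
INFO regime T1_all_cooperate; stable vertices [[1, 1, 1]]

$ tail -n +2 demo/stability_table.csv
equilibrium,x,y,z,lambda1,lambda2,lambda3,stability,regime
E1,0,0,0,13,-3,-3,saddle,T1_all_cooperate
E2,0,0,1,9,-3,3,saddle,T1_all_cooperate
E3,0,1,0,5,3,-3,saddle,T1_all_cooperate
E4,0,1,1,1,3,3,unstable,T1_all_cooperate
E5,1,0,0,-13,5,1,saddle,T1_all_cooperate
E6,1,0,1,-9,5,-1,saddle,T1_all_cooperate
E7,1,1,0,-5,-5,1,saddle,T1_all_cooperate
E8,1,1,1,-1,-5,-1,asymptotically_stable,T1_all_cooperate
```

Only the all-cooperate vertex `E8 = (1,1,1)` has all three eigenvalues
negative: with the government's relative gain (16) above the upper threshold
(15), strong regulation plus active participation by firms and consumers is
the unique stable outcome. The same library calls are
`stability_table(params)` and `classify_regime(params)`.

```
$ recyclegame simulate --scenario s6_2 --out demo
INFO terminal state (0.0, 1.0, 1.0); limiting vertex (0, 1, 1)
```

In this scenario active participation nets firms and consumers more than
passivity even without enforcement, while the government's relative gain is
below the upper threshold, so the trajectory from `(0.5, 0.5, 0.5)` settles
at weak regulation with full participation. A sweep of the government gain
`R5` across both thresholds shows the regime transitions:

```
$ recyclegame sweep --scenario baseline --r5 15,20,25,30,35 --out demo
$ tail -n +2 demo/sweep.csv
R5,relative_gain,regime,stable_vertices
15,1,T2_all_defect,E1
20,6,NO_ESS_WINDOW,-
25,11,NO_ESS_WINDOW,-
30,16,T1_all_cooperate,E8
35,21,T1_all_cooperate,E8
```

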