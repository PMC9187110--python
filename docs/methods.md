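# Methods

## Model

The world is a square torus of side `grid_side`, every cell permanently
occupied by exactly one agent; the population size `N = grid_side²` never
changes. Agents do not move and die only by being replaced by a newborn.
A strict linear dominance hierarchy (a bijection agents ↔ ranks 1..N,
rank 1 most dominant) structures payoff division; it changes only through
births (maternal rank inheritance: offspring take the rank directly below
the parent, shifting everyone below down one) and deaths (survivors are
renumbered 1..N preserving relative order). Births within an update are
applied sequentially in uniformly random order, each insertion using the
parent's rank at that moment; the observable end state is a gapless
renumbering, whatever the intermediate interleaving.

Each update every cell hosts one hunting game between the cell's agent and
its four von Neumann neighbours, so each agent plays exactly five games per
update, holding a possibly different relative rank (position 1–5 by global
rank within the group) in each. The strategy genome has one site per
relative rank: the probability of choosing to group hunt at that position.
Decisions are drawn independently per game — the genome is defined on
relative rank, and relative rank varies across an agent's five games.

### Payoffs

Solo hunters roll independent Bernoulli(0.5) trials for the 5-point solo
payoff. The k group hunters in a game share a *single* success roll
(p = 0.5 for k ≥ 2, p = 0.05 for k = 1): the hunt succeeds or fails as a
unit, which keeps the conservation semantics of the shared pot coherent.
(The alternative reading — independent rolls per hunter — has identical
per-agent expectations; the analytic oracle in `expected_payoffs` is
agnostic between them.) On success the pot is `k × multiplier × 5` points,
so the per-capita average is conserved for every k; it is divided by
contiguous sharing rank i = 1..k with weights τ^(i−1), normalised to the
pot. τ = 1 is treated as an exact equal split rather than the 0/0 limit of
the geometric normalisation. Failed hunts pay nothing.

### Reproduction

Income per update is the arithmetic mean of the agent's five game payoffs.
Any agent holding ≥ 50 points when the reproduction phase starts is a birth
candidate ("reaching" the threshold is read as the closed bound). Each
surviving candidate births at most once per update, pays 50 and keeps the
remainder; a candidate displaced earlier in the same phase forfeits its
birth, and a same-phase newborn can itself be displaced. The offspring gets
a mutated genome copy (each site independently redrawn uniform [0, 1] with
probability 0.0005 — "0.05% per genome site" read literally), zero
resources, and a uniformly random cell among the 24 within Chebyshev
radius 2 of the parent (the square reading is forced: 5×5 − 1 = 24). The
displaced occupant's resources are destroyed. Newborns first hunt in the
following update.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `grid_side` | 60 | torus side; N = 3600 agents |
| `tolerance` τ | 1.0 | successive-share ratio in (0, 1]; lower = more despotic |
| `payoff_multiplier` m | 2.0 | group per-capita payoff as a multiple of solo (2.0 / 1.2 in the sweep) |
| `solo_payoff` | 5 pts | successful solo hunt |
| `solo_success` / `group_success` | 0.5 | per-hunt success probabilities |
| `lone_group_success` | 0.05 | success when only one agent joins the group hunt |
| `reproduction_cost` | 50 pts | paid per birth |
| `mutation_rate` | 0.0005 | per-site redraw probability at birth |
| `updates` / `sample_interval` / `window` | 10⁶ / 10³ / 10⁵ | full-scale schedule; window endpoints inclusive → 101 samples |
| `replicates` | 200 | per condition |

Initial genomes are uniform per site — the redraw distribution of the
mutation operator, imposing no strategy bias (the initial distribution is
otherwise a free choice). Initial ranks are a uniform permutation; initial
resources are zero.

## Randomness and determinism

One `numpy` PCG64 stream per replicate, seeded by
`SeedSequence((master_seed, replicate_index))`; a second spawned stream
serves the measurement-only probe that provides the update-0 sample (the
probe draws decisions from the initial genomes without crediting payoffs,
leaving the main stream untouched). Draw order within an update is fixed:
decision matrix (N×5, games in row-major cell order, members in canonical
centre/N/S/E/W order), group-success vector (N), solo matrix (N×5, drawn
for every slot regardless of decisions), then the candidate permutation and
per-birth placement/mutation draws. Identical (config, seed) pairs give
bit-identical trajectories and byte-identical CSV output.

## Metrics

The group-hunt rate of relative rank r at a sampled update is the fraction
of that update's games whose rank-r member chose to group hunt (each game
contributes exactly one decision per rank, so the denominator is the game
count). The population rate is the unweighted mean of the five rank rates.
Replicate summaries average the samples inside the inclusive terminal
window; condition summaries report the cross-replicate mean and ±2 SE.

## Scaled-down study sizes

Full scale (3600 agents × 10⁶ updates × 200 replicates × 10 conditions) is
a cluster workload. The package's own verification runs use desk scales,
chosen once:

* evolutionary end-state check: 30×30, 30,000 updates, τ = 1.0, m = 2.0,
  3,000-update window;
* generation-count extrapolation: 30×30, 20,000 updates, τ = 0.76,
  m = 1.2, generations = births / N × (10⁶ / updates);
* directional tolerance/rank trends: 20×20, 6,000 updates, 10 replicates
  per tolerance at m = 2.0.

At these scales roughly 1,500–2,500 generations elapse versus the
~20,000–50,000 of a full run. Selection on a genome site is weak (a site
change of 0.1 shifts relative income by ~1%), so after the initial sweep to
high group-hunting the approach to the full-scale quasi-equilibrium is
mutation-supply-limited: the τ = 1.0 / m = 2.0 end state lands around
0.82–0.93 population group-hunt rate depending on seed, short of the
near-1.0 plateau a 10⁶-update run reaches. The directional structure —
rates falling as tolerance falls, top ranks out-hunting bottom ranks under
despotic sharing — is already stable at desk scale and is what the tests
assert; desk-scale magnitudes should not be read as full-scale estimates.

## What the simulation does and does not capture

The generator *is* the study system (there is no external data): a
deliberately stylised fission-fusion society. It omits, among other
things, movement, aging and intrinsic death, kleptoparasites/cheaters,
partner choice, variable prey availability, and any rank dynamics beyond
birth/death — so passing tests validate the model's internal logic and its
evolutionary direction, not quantitative predictions about real carnivore
populations.

## Numerical choices

* Shares use the normalised geometric weights directly; conservation holds
  to 1e−9 and τ = 1 is special-cased exactly.
* Ranks are dense integer arrays; compaction is a double argsort (ranks are
  always distinct, so no tie-breaking is needed).
* The resource ledger (Σ resources = Σ income − 50 × births − Σ destroyed)
  is asserted in tests to 1e−6 over 500-update runs.
* `expected_payoffs` enumerates all 2⁵ decision profiles exactly; the
  Monte-Carlo resolver is checked against it within 3 SE at 10⁶ trials.

## Known limitations

* Desk-scale evolutionary magnitudes undershoot full-scale plateaus (see
  above); only directions are asserted.
* The engine is cell-indexed: agent "identity" is (cell, lineage), which is
  observationally equivalent to the id-based hierarchy contract but means
  per-individual life histories are not tracked.
* Single-process only; replicates are embarrassingly parallel but are run
  sequentially.
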