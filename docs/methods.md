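# Methods

## Model and assumptions

The simulator implements the elementary process of belief re-evaluation on a
two- or three-node signed belief network. A population of *N* agents holds
attitudes in [−1, 1] toward two concepts; a circulating piece of news links
the concepts with a fixed sign K0 ∈ {+1, −1}. The edge coherence
C = a1·a2·K0 measures how much the news increases (reassurance, C > 0) or
decreases (cognitive dissonance, C < 0) the consistency of the agent's
belief system. The model's assumptions, in order of importance:

- **No social interaction.** Agents never observe each other; the only
  driver is repeated exposure to the (type of) news. Polarization is an
  emergent statistical property of independent agents under a common signal.
- **One news type.** The connection sign is constant over a run; only the
  exposure schedule is random.
- **Hierarchical gate.** An attitude changes with probability 1 − |a|, so
  attitudes at exactly ±1 are absorbing for that coordinate. This is the
  sole mechanism making extreme attitudes sticky; the step size scale ρ is a
  separate knob (see below).
- **Synchronous edge update.** Both endpoint attitudes of an updating edge
  use the coherence computed from the pre-update values, with independent
  gate coins. Using an already-updated attitude for the second endpoint
  would be an extra modelling choice with no basis in the update rule.
- **Literal update formula.** The new value is
  sign(a)·(|a| + ρC) + Z_A, clamped to [−1, 1]. When dissonance exceeds the
  current commitment (|a| + ρC < 0) the formula flips the attitude's sign;
  we do not floor |a| + ρC at zero, because the rule is stated without a
  floor and flooring would silently change the near-neutral dynamics.
  sign(0) is defined as +1; whenever an endpoint attitude is 0 the coherence
  is 0, so this only fixes the direction the noise enters and keeps runs
  deterministic.

In new-belief mode, a third node (the dissonance-relieving belief) is linked
to concept 1 with sign K_NB. At an exposure event whose K0-coherence is
negative, an unadopted agent adopts with probability max(0, a1·a3·K_NB),
evaluated at the agent's post-K0-update a1 (the adoption decision happens
after the re-evaluation stage of the same event; the rule itself does not
fix this ordering, and at the event level the difference is one noise-scale
perturbation of a1). Adoption is permanent. Every adopter — including one
that just adopted — then runs the same gated update on the (a1, a3) edge.
Non-adopters' a3 is a latent predisposition and never changes; this is
asserted exactly in the tests. The new-belief edge is updated only at events
where the agent itself is selected.

## Parameters

| name | meaning | default | units/domain |
|---|---|---|---|
| `n_agents` (N) | population size | 100 | ≥ 1 |
| `n_steps` (T) | exposure events; one uniformly chosen agent per event | 50,000 | ≥ 1 |
| `k0` | sign of the concept1–concept2 link | −1 | ±1 |
| `k_nb` | sign of the concept1–new-belief link | −1 | ±1 |
| `za_magnitude` (Z_A) | attitude noise magnitude; sign equiprobable per gated update | 0.01 | ≥ 0 |
| `rho_mode` / `rho_value` (ρ) | coherence step scale: constant, or redrawn from U[0,1] per gated update | fixed, 1.0 | [0, 1] |
| `new_belief_enabled` | three-node mode | off | bool |
| `epsilons` (ε) | extremity thresholds for the metrics | 0.01, 0.05, 0.1 | (0, 1) |
| `snapshot_every` | recording cadence | T // 10 | ≥ 1 |
| `seed` | PCG64 seed; replicate i runs with seed base + i | 0 | < 2³¹ |

The defaults are the headline study conditions: N = 100, T = 50,000,
K0 = −1, Z_A = 0.01, ρ = 1. The three-node experiments use N = 1000,
T = 150,000, K_NB = −1; the limited-exposure condition is T = 10,000 at
N = 1000 (10 exposures per agent on average).

## Randomness and reproducibility

All randomness comes from one `numpy` PCG64 generator seeded from `seed`.
Draw order per event is fixed: agent index; then the K0-edge draws — gate
uniform, [ρ if uniform mode], noise sign for attitude 1, then the same for
attitude 2, batched as a single `rng.random(4 or 6)` call in that order;
then, in new-belief mode, the adoption uniform (drawn only when an unadopted
agent faces a dissonant event) and the new-belief-edge draws (only for
adopters). Gate uniforms are stored raw and compared with 1 − |a| at
application time, so a gate with probability 0 never opens and one with
probability 1 always does. Identical parameters and seed give bit-identical
trajectories; the manifest written next to every run suffices to reproduce
its files byte for byte. The pure pair `sample_edge_draws` /
`apply_exposure` is the seam used by the tests to drive events with
hand-crafted or mirrored randomness.

## Metrics and numerical choices

- **Extremity ratio**: fraction of attitude values with |a| ≥ 1 − ε,
  boundary inclusive (it matters only on a measure-zero set, but integer
  counts need a fixed convention), computed per concept and pooled over
  concepts 1 and 2.
- **Corner fractions**: fraction of agents with |a1 − s1| ≤ ε and
  |a2 − s2| ≤ ε for each corner (s1, s2) ∈ {±1}²; the same ε as the
  extremity metric, one threshold concept throughout. The boxes are disjoint
  for ε < 1, so the four fractions sum to at most 1.
- **Neutral fraction**: |a| ≤ ε; **adoption ratio**: fraction with the
  new belief adopted.
- Attitudes are serialized at full precision (shortest round-trip
  representation), so write → read is lossless and recomputing metrics from
  a saved attitude table reproduces the recorded metrics table bit for bit.
- Degenerate inputs: k ∉ {±1}, attitudes or coherence outside [−1, 1], ρ
  outside [0, 1] and ε outside (0, 1) raise `ValueError`; an empty attitude
  table is rejected by the metrics recomputation.

## What the simulation does and does not show

The initial population is i.i.d. uniform on [−1, 1] for all three attitudes
— the model's stated starting condition, not an empirical distribution. The
simulator therefore demonstrates the *mechanism* (consistency-seeking alone
polarizes an exposed population) under idealized conditions: one news type,
homogeneous agents (same Z_A and ρ for all), no social network, no
competing information. Passing tests show the dynamics is implemented
faithfully and its emergent statistics (corner split, monotone extremity
growth, threshold robustness) are stable across seeds; they say nothing
about real attitude distributions, heterogeneous media diets, or
interacting agents, all of which are outside the model.

## Test problem sizes

Deterministic and single-event properties run at miniature scale. The
stochastic suites use: 20 seeds at N = 100, T = 50,000 for the corner-split
check; 20 seeds per link sign at N = 1000, T = 50,000 for monotone extremity
growth (N matches the large-population condition; 50 exposures per agent is
well past the regime where the mean curve's shape is established, and the
monotonicity tolerance of 0.02 absorbs seed noise); 10⁵ Monte-Carlo events
against the exact 9-outcome enumeration of a single step (4 standard
errors); two full N = 1000, T = 150,000 new-belief runs for the frozen-a3
and permanent-adoption checks; N = 10,000 for the Kolmogorov–Smirnov check
of the uniform initialisation at the 1% critical value.

## Known limitations

- The event loop is scalar Python (one agent per event, by construction),
  so very long runs scale linearly: ~10⁶ events take a few seconds.
- Only the 2–3 node belief network is implemented; general modular or
  hierarchical belief graphs, continuous link weights, agent-to-agent edges
  and heterogeneous noise are out of scope.
- `uniform` ρ mode is provided but the reported behaviour and tests focus on
  the fixed ρ = 1 conditions.
- Snapshots are full population copies; with very large N and a fine
  snapshot cadence, memory grows accordingly.
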