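# beliefsim

An agent-based simulator of belief-system dynamics: how opinion polarization
can emerge in a population purely from people's drive to keep their beliefs
consistent, without any agent-to-agent interaction.

## The model

Each of *N* agents holds scalar attitudes *a*₁, *a*₂ ∈ [−1, 1] toward two
concepts (−1 total condemnation, +1 total support, ≈0 neutrality). A piece of
news circulates that links the two concepts with a sign *K*₀ ∈ {+1, −1}
(supportive or contradictory). The coherence this creates in agent *i*'s
belief system is

    Cᵢ = aᵢ,₁ · aᵢ,₂ · K₀

— positive *C* is reassurance, negative *C* is cognitive dissonance. At each
of *T* time steps one uniformly chosen agent is exposed to the news and
re-evaluates each attitude *k* ∈ {1, 2} with probability

    p = 1 − |aᵢ,ₖ|

(the hierarchical gate: extreme attitudes are hard to change). An attitude
that does change becomes

    aᵢ,ₖ ← sign(aᵢ,ₖ) · (|aᵢ,ₖ| + ρ·Cᵢ) + Z_A

clamped to the nearest threshold if it leaves [−1, 1], where ρ ∈ [0, 1]
scales the coherence step (fixed at 1 by default, or redrawn from U[0, 1]
per update) and Z_A is noise of fixed magnitude (default 0.01) and
equiprobable sign. Reassurance pushes attitudes toward the extremes;
dissonance pulls them back — and since reduced commitment also reduces the
dissonance the next exposure creates, the population drifts into the corner
states consistent with *K*₀ ((+1, −1)/(−1, +1) for *K*₀ = −1) and polarizes.

Optionally, a third node models a dissonance-relieving **new belief**
attached to concept 1 by a sign *K*_NB. An agent experiencing dissonance
(*C* < 0) adopts it with probability

    p(NB) = max(0, aᵢ,₁ · aᵢ,₃ · K_NB),

after which the same gated update runs on the concept1–new-belief edge;
non-adopters keep *a*₃ frozen at its latent initial value.

The package reports polarization metrics per snapshot: the ε-extremity ratio
(fraction of attitudes with |a| ≥ 1 − ε), fractions of agents within ε of
each (±1, ±1) corner, near-neutral mass (|a| ≤ ε) and the adoption ratio.

## Worked example

A baseline run — 100 agents, 50,000 exposures to news with a contradictory
link, noise 0.01:

```bash
beliefsim run --n 100 --steps 50000 --k0 -1 --za 0.01 --seed 7 --out demo/
```

prints

```
seed=7 t=50000 eps=0.01 extremity a1=1.000 a2=1.000 | corners pp=0.000 pm=0.490 mp=0.510 mm=0.000 | adoption=0.000 -> demo
```

Every attitude has become extreme (extremity ratio 1.0 even at the strictest
threshold ε = 0.01), and the initially uniform population has split almost
evenly between the two corners consistent with the negative link: 49% of
agents fully support concept 1 while rejecting concept 2 (`pm`), 51% the
reverse (`mp`), and the inconsistent corners are empty. `demo/` holds the
attitude table (`attitudes.csv`: t, agent_id, a1, a2, a3, adopted), the
metric time series (`metrics.csv`) and a `manifest.json` with all parameters
and the seed, from which the run can be reproduced bit-identically.

The same from Python:

```python
from beliefsim import ModelParams, NewsLink, run_simulation

record = run_simulation(ModelParams(n_agents=100, n_steps=50_000,
                                    link=NewsLink(k0=-1), seed=7))
record.final_metrics.corners[0.1]   # {'pp': 0.0, 'pm': 0.49, 'mp': 0.51, 'mm': 0.0}
```

The three-node variant (`--new-belief --knb -1 --n 1000 --steps 150000`)
additionally reports the adoption ratio of the dissonance-relieving belief.

Metrics can be recomputed from a saved run for any thresholds without
re-simulation:

```bash
beliefsim metrics --input demo/ --epsilon 0.2
```

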