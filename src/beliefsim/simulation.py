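"""Agent-based simulation of belief-system dynamics and opinion polarization.

A population of agents holds scalar attitudes in [-1, 1] toward two concepts
that a circulating piece of news links with a signed connection ``K0``
(supportive +1 or contradictory -1). The product of the two attitudes and the
link sign is the *coherence* the news creates in an agent's belief system:
positive coherence is reassurance, negative coherence is cognitive dissonance.
Exposed agents re-evaluate their attitudes to increase coherence — reassurance
pushes attitudes toward the extremes, dissonance pulls them back — under a
hierarchical gate that makes extreme attitudes hard to change. Optionally,
dissonant agents may adopt a third, dissonance-relieving belief attached to
concept 1 by a second signed link ``K_NB``.

The module is organised in the order the method runs:

1. defaults and logging,
2. core update mathematics (pure scalar functions),
3. domain types (agents, links, noise, parameters, population),
4. the stochastic event loop (initialisation, exposure events, full runs),
5. polarization metrics (extremity ratios, corner fractions, adoption),
6. configuration parsing and trajectory serialization.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    # core
    "coherence",
    "change_probability",
    "update_attitude",
    "adoption_probability",
    # types
    "AgentState",
    "NewsLink",
    "NoiseSpec",
    "ModelParams",
    "Population",
    "EdgeDraws",
    "TrajectoryRecord",
    "MetricsReport",
    # engine
    "init_population",
    "sample_edge_draws",
    "apply_exposure",
    "exposure_step",
    "new_belief_substep",
    "run_simulation",
    # metrics
    "extremity_ratio",
    "corner_fractions",
    "neutral_fraction",
    "adoption_ratio",
    "compute_metrics",
    # io
    "RunConfig",
    "ConfigError",
    "read_config",
    "write_trajectory",
    "read_trajectory",
    "attitudes_frame",
    "metrics_frame",
    "recompute_metrics_table",
]

# ---------------------------------------------------------------------------
# Defaults and logging
# ---------------------------------------------------------------------------

#: Baseline study conditions: a population of 100 agents exposed 50,000 times
#: to news creating a contradictory (-1) link, with attitude noise 0.01 and
#: the dissonance-step scale rho fixed at 1.
DEFAULT_N_AGENTS = 100
DEFAULT_N_STEPS = 50_000
DEFAULT_K0 = -1
DEFAULT_K_NB = -1
DEFAULT_ZA_MAGNITUDE = 0.01
DEFAULT_RHO_VALUE = 1.0
DEFAULT_EPSILONS = (0.01, 0.05, 0.1)

logger = logging.getLogger("beliefsim")
logger.addHandler(logging.NullHandler())


# ---------------------------------------------------------------------------
# Core update mathematics (pure scalar functions)
# ---------------------------------------------------------------------------

def _sign(a: float) -> float:
    """Sign of an attitude, with sign(0) := +1 for determinism."""
    return 1.0 if a >= 0.0 else -1.0


def _check_attitude(a: float, name: str = "attitude") -> None:
    if not -1.0 <= a <= 1.0:
        raise ValueError(f"{name} must lie in [-1, 1], got {a!r}")


def _check_link(k: int, name: str = "k") -> None:
    if k not in (1, -1):
        raise ValueError(f"{name} must be +1 or -1, got {k!r}")


def coherence(a_first: float, a_second: float, k: int) -> float:
    """Coherence created on a signed edge: ``a_first * a_second * k``.

    Negative values are cognitive dissonance, positive values reassurance.
    The result is always in [-1, 1] because both attitudes are.

    Parameters
    ----------
    a_first, a_second
        Attitudes in [-1, 1] at the two endpoints of the edge.
    k
        Sign of the edge, +1 (supportive) or -1 (contradictory).
    """
    _check_attitude(a_first, "a_first")
    _check_attitude(a_second, "a_second")
    _check_link(k)
    return a_first * a_second * k


def change_probability(a: float) -> float:
    """Probability ``1 - |a|`` that an attitude is open to change.

    This is the hierarchical gate: neutral attitudes (a = 0) always change,
    fully extreme attitudes (|a| = 1) never do.
    """
    _check_attitude(a)
    return 1.0 - abs(a)


def update_attitude(a: float, c: float, rho: float, za_draw: float) -> float:
    """Re-evaluate one attitude given the coherence ``c`` of an exposure.

    Computes ``sign(a) * (|a| + rho * c) + za_draw`` and clamps the result to
    the nearest threshold if it leaves [-1, 1]. Reassurance (c > 0) grows the
    attitude's magnitude, dissonance (c < 0) shrinks it; when the dissonance
    exceeds the current commitment (|a| + rho*c < 0) the literal formula
    flips the attitude's sign before noise — no flooring at zero is applied.

    ``za_draw`` is the signed realisation of the attitude noise (its sign is
    equiprobable; its magnitude is the configured noise level).
    """
    _check_attitude(a)
    if not -1.0 <= c <= 1.0:
        raise ValueError(f"coherence must lie in [-1, 1], got {c!r}")
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho!r}")
    raw = _sign(a) * (abs(a) + rho * c) + za_draw
    return min(1.0, max(-1.0, raw))


def adoption_probability(a1: float, a3: float, k_nb: int) -> float:
    """Probability ``max(0, a1 * a3 * k_nb)`` of adopting the new belief.

    The probability equals the reassurance the adoption would provide; if the
    new belief would itself create dissonance the probability is zero.
    """
    return max(0.0, coherence(a1, a3, k_nb))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AgentState:
    """Attitudes of a single agent.

    ``a1`` and ``a2`` are the attitudes toward the two linked concepts; ``a3``
    is the attitude toward the dissonance-relieving new belief, a latent
    predisposition that never changes until ``adopted`` becomes true.
    """

    a1: float
    a2: float
    a3: float = 0.0
    adopted: bool = False

    def __post_init__(self) -> None:
        _check_attitude(self.a1, "a1")
        _check_attitude(self.a2, "a2")
        _check_attitude(self.a3, "a3")


@dataclass(frozen=True)
class NewsLink:
    """Signed connection types carried by the news: concept1–concept2 (``k0``)
    and concept1–new-belief (``k_nb``, used only in new-belief mode)."""

    k0: int = DEFAULT_K0
    k_nb: int = DEFAULT_K_NB

    def __post_init__(self) -> None:
        _check_link(self.k0, "k0")
        _check_link(self.k_nb, "k_nb")


@dataclass(frozen=True)
class NoiseSpec:
    """Stochastic ingredients of the attitude update.

    ``za_magnitude`` is the fixed magnitude of the attitude noise; its sign is
    drawn +/- with equal probability at every gated update. ``rho`` scales the
    coherence step: in ``fixed`` mode it is the constant ``rho_value`` (1.0
    reproduces the headline results), in ``uniform`` mode it is redrawn from
    U[0, 1] at every gated update.
    """

    za_magnitude: float = DEFAULT_ZA_MAGNITUDE
    rho_mode: str = "fixed"
    rho_value: float = DEFAULT_RHO_VALUE

    def __post_init__(self) -> None:
        if self.za_magnitude < 0:
            raise ValueError(f"za_magnitude must be >= 0, got {self.za_magnitude!r}")
        if self.rho_mode not in ("fixed", "uniform"):
            raise ValueError(f"rho_mode must be 'fixed' or 'uniform', got {self.rho_mode!r}")
        if not 0.0 <= self.rho_value <= 1.0:
            raise ValueError(f"rho_value must lie in [0, 1], got {self.rho_value!r}")


@dataclass(frozen=True)
class ModelParams:
    """All parameters of one simulation run.

    ``n_steps`` counts exposure events; at each event one uniformly chosen
    agent acquires the news. ``snapshot_every`` sets the recording cadence
    (``None`` means ``max(1, n_steps // 10)``); snapshots are always taken at
    t = 0 and t = n_steps. ``epsilons`` are the extremity thresholds used by
    the recorded metrics.
    """

    n_agents: int = DEFAULT_N_AGENTS
    n_steps: int = DEFAULT_N_STEPS
    link: NewsLink = field(default_factory=NewsLink)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    new_belief_enabled: bool = False
    seed: int = 0
    snapshot_every: int | None = None
    epsilons: tuple[float, ...] = DEFAULT_EPSILONS

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError(f"n_agents must be >= 1, got {self.n_agents!r}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps!r}")
        if self.seed < 0:
            raise ValueError(f"seed must be >= 0, got {self.seed!r}")
        if self.snapshot_every is not None and self.snapshot_every < 1:
            raise ValueError(f"snapshot_every must be >= 1, got {self.snapshot_every!r}")
        if not self.epsilons:
            raise ValueError("epsilons must be a non-empty list of thresholds")
        for eps in self.epsilons:
            if not 0.0 < eps < 1.0:
                raise ValueError(f"every epsilon must lie in (0, 1), got {eps!r}")

    @property
    def snapshot_cadence(self) -> int:
        if self.snapshot_every is not None:
            return self.snapshot_every
        return max(1, self.n_steps // 10)

    def to_dict(self) -> dict:
        return {
            "n_agents": self.n_agents,
            "n_steps": self.n_steps,
            "k0": self.link.k0,
            "k_nb": self.link.k_nb,
            "za_magnitude": self.noise.za_magnitude,
            "rho_mode": self.noise.rho_mode,
            "rho_value": self.noise.rho_value,
            "new_belief_enabled": self.new_belief_enabled,
            "seed": self.seed,
            "snapshot_every": self.snapshot_every,
            "epsilons": list(self.epsilons),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParams":
        return cls(
            n_agents=int(d.get("n_agents", DEFAULT_N_AGENTS)),
            n_steps=int(d.get("n_steps", DEFAULT_N_STEPS)),
            link=NewsLink(k0=int(d.get("k0", DEFAULT_K0)),
                          k_nb=int(d.get("k_nb", DEFAULT_K_NB))),
            noise=NoiseSpec(
                za_magnitude=float(d.get("za_magnitude", DEFAULT_ZA_MAGNITUDE)),
                rho_mode=str(d.get("rho_mode", "fixed")),
                rho_value=float(d.get("rho_value", DEFAULT_RHO_VALUE)),
            ),
            new_belief_enabled=bool(d.get("new_belief_enabled", False)),
            seed=int(d.get("seed", 0)),
            snapshot_every=(None if d.get("snapshot_every") is None
                            else int(d["snapshot_every"])),
            epsilons=tuple(float(e) for e in d.get("epsilons", DEFAULT_EPSILONS)),
        )


@dataclass
class Population:
    """Attitudes of all agents at one instant, stored column-wise.

    Arrays are parallel over agents; ``t`` is the number of exposure events
    applied so far.
    """

    a1: np.ndarray
    a2: np.ndarray
    a3: np.ndarray
    adopted: np.ndarray
    t: int = 0

    @property
    def size(self) -> int:
        return self.a1.shape[0]

    def agent(self, i: int) -> AgentState:
        return AgentState(
            a1=float(self.a1[i]), a2=float(self.a2[i]),
            a3=float(self.a3[i]), adopted=bool(self.adopted[i]),
        )

    def set_agent(self, i: int, state: AgentState) -> None:
        self.a1[i] = state.a1
        self.a2[i] = state.a2
        self.a3[i] = state.a3
        self.adopted[i] = state.adopted

    def copy(self) -> "Population":
        return Population(self.a1.copy(), self.a2.copy(), self.a3.copy(),
                          self.adopted.copy(), self.t)

    @classmethod
    def from_agents(cls, agents: Sequence[AgentState], t: int = 0) -> "Population":
        return cls(
            a1=np.array([s.a1 for s in agents], dtype=float),
            a2=np.array([s.a2 for s in agents], dtype=float),
            a3=np.array([s.a3 for s in agents], dtype=float),
            adopted=np.array([s.adopted for s in agents], dtype=bool),
            t=t,
        )

    def __iter__(self) -> Iterator[AgentState]:
        return (self.agent(i) for i in range(self.size))


# ---------------------------------------------------------------------------
# Engine: stochastic event loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeDraws:
    """Random decisions for one gated update of the two endpoint attitudes of
    an edge, in draw order: gate uniform, rho, signed noise for the first
    endpoint, then the same for the second. Gate uniforms are kept raw because
    the opening probability depends on the attitude at application time."""

    u_gate_first: float
    rho_first: float
    za_first: float
    u_gate_second: float
    rho_second: float
    za_second: float


def sample_edge_draws(rng: np.random.Generator, noise: NoiseSpec) -> EdgeDraws:
    """Draw the per-edge randomness in the documented fixed order.

    In ``fixed`` rho mode four uniforms are consumed (gate and noise sign per
    endpoint); in ``uniform`` mode six (an extra rho per endpoint).
    """
    if noise.rho_mode == "uniform":
        u = rng.random(6)
        return EdgeDraws(
            u_gate_first=u[0], rho_first=u[1],
            za_first=noise.za_magnitude if u[2] < 0.5 else -noise.za_magnitude,
            u_gate_second=u[3], rho_second=u[4],
            za_second=noise.za_magnitude if u[5] < 0.5 else -noise.za_magnitude,
        )
    u = rng.random(4)
    return EdgeDraws(
        u_gate_first=u[0], rho_first=noise.rho_value,
        za_first=noise.za_magnitude if u[1] < 0.5 else -noise.za_magnitude,
        u_gate_second=u[2], rho_second=noise.rho_value,
        za_second=noise.za_magnitude if u[3] < 0.5 else -noise.za_magnitude,
    )


def _update_edge(a_first: float, a_second: float, k: int,
                 draws: EdgeDraws) -> tuple[float, float]:
    """Apply the gated attitude update to both endpoints of a signed edge.

    The coherence is computed once from the pre-update attitudes and shared by
    both endpoints (synchronous within the event); each endpoint's gate opens
    independently with probability ``1 - |a|``, and noise enters only when
    the gate opens.
    """
    c = coherence(a_first, a_second, k)
    new_first = a_first
    if draws.u_gate_first < change_probability(a_first):
        new_first = update_attitude(a_first, c, draws.rho_first, draws.za_first)
    new_second = a_second
    if draws.u_gate_second < change_probability(a_second):
        new_second = update_attitude(a_second, c, draws.rho_second, draws.za_second)
    return new_first, new_second


def init_population(params: ModelParams, rng: np.random.Generator) -> Population:
    """Initial population: all three attitudes i.i.d. uniform on [-1, 1].

    ``a3`` is always drawn, as the latent predisposition toward the new
    belief; no agent starts adopted.
    """
    n = params.n_agents
    return Population(
        a1=rng.uniform(-1.0, 1.0, n),
        a2=rng.uniform(-1.0, 1.0, n),
        a3=rng.uniform(-1.0, 1.0, n),
        adopted=np.zeros(n, dtype=bool),
        t=0,
    )


def new_belief_substep(state: AgentState, c_event: float, params: ModelParams,
                       rng: np.random.Generator) -> AgentState:
    """New-belief stage of an exposure event, for the selected agent.

    If the agent has not adopted and the event created dissonance
    (``c_event < 0``), it adopts with probability ``max(0, a1*a3*k_nb)``;
    adoption is permanent. Any adopter (including one that just adopted) then
    runs the same gated update on the concept1–new-belief edge.
    """
    adopted = state.adopted
    if not adopted and c_event < 0.0:
        p = adoption_probability(state.a1, state.a3, params.link.k_nb)
        if rng.random() < p:
            adopted = True
    if not adopted:
        return state
    draws = sample_edge_draws(rng, params.noise)
    a1, a3 = _update_edge(state.a1, state.a3, params.link.k_nb, draws)
    return AgentState(a1=a1, a2=state.a2, a3=a3, adopted=True)


def apply_exposure(pop: Population, idx: int, params: ModelParams,
                   draws: EdgeDraws, rng: np.random.Generator | None = None) -> None:
    """Apply one exposure event to agent ``idx`` with the given edge draws.

    This is the deterministic core of :func:`exposure_step`, exposed so that
    tests can drive the event with hand-crafted or replayed randomness. The
    new-belief sub-step (if enabled) draws its own randomness from ``rng``.
    Mutates ``pop`` in place and increments ``pop.t``.
    """
    a1 = float(pop.a1[idx])
    a2 = float(pop.a2[idx])
    c_event = coherence(a1, a2, params.link.k0)
    new1, new2 = _update_edge(a1, a2, params.link.k0, draws)
    pop.a1[idx] = new1
    pop.a2[idx] = new2
    if params.new_belief_enabled:
        if rng is None:
            raise ValueError("rng is required when new_belief_enabled")
        state = pop.agent(idx)
        pop.set_agent(idx, new_belief_substep(state, c_event, params, rng))
    pop.t += 1


def exposure_step(pop: Population, params: ModelParams,
                  rng: np.random.Generator) -> int:
    """One exposure event: a uniformly chosen agent acquires the news.

    Returns the index of the selected agent. Draw order per event: agent
    index, then the K0-edge draws (gate/rho/noise per attitude), then — in
    new-belief mode — the adoption coin (only for unadopted agents under
    dissonance) and the new-belief-edge draws (only for adopters).
    """
    idx = int(rng.integers(pop.size))
    draws = sample_edge_draws(rng, params.noise)
    apply_exposure(pop, idx, params, draws, rng)
    return idx


@dataclass
class MetricsReport:
    """Polarization metrics of one population snapshot.

    Per threshold epsilon: extremity ratios (fraction of attitude values with
    ``|a| >= 1 - eps``, per concept and pooled over concepts 1 and 2), the
    four corner fractions of the (a1, a2) plane keyed ``pp/pm/mp/mm`` (first
    letter: sign of a1), and neutral fractions (``|a| <= eps``). The adoption
    ratio is threshold-free.
    """

    t: int
    extremity: dict
    corners: dict
    neutral: dict
    adoption: float


@dataclass
class TrajectoryRecord:
    """Recorded output of one run: snapshots and metrics on a time grid.

    ``times`` is strictly increasing, starting at 0 and ending at ``n_steps``.
    ``selection_counts[i]`` is how many events selected agent ``i``;
    ``max_abs_attitude`` is the running maximum of every |attitude| observed
    after every event of the run (not just at snapshot times).
    """

    params: ModelParams
    times: list[int]
    snapshots: list[Population]
    metrics: list[MetricsReport]
    selection_counts: np.ndarray
    max_abs_attitude: float

    @property
    def final_population(self) -> Population:
        return self.snapshots[-1]

    @property
    def final_metrics(self) -> MetricsReport:
        return self.metrics[-1]


def run_simulation(params: ModelParams) -> TrajectoryRecord:
    """Run a full simulation from ``params.seed``; deterministic per params.

    Applies ``n_steps`` exposure events to a fresh uniform population,
    recording a snapshot and metrics at t = 0, every ``snapshot_cadence``
    events, and at t = n_steps.
    """
    rng = np.random.default_rng(params.seed)
    pop = init_population(params, rng)
    cadence = params.snapshot_cadence
    counts = np.zeros(params.n_agents, dtype=np.int64)
    track_a3 = params.new_belief_enabled

    times: list[int] = [0]
    snapshots: list[Population] = [pop.copy()]
    metrics: list[MetricsReport] = [compute_metrics(pop, params.epsilons)]
    max_abs = float(max(np.max(np.abs(pop.a1)), np.max(np.abs(pop.a2))))
    if track_a3:
        max_abs = max(max_abs, float(np.max(np.abs(pop.a3))))

    logger.info("run start: seed=%d n_agents=%d n_steps=%d k0=%+d nb=%s",
                params.seed, params.n_agents, params.n_steps,
                params.link.k0, params.new_belief_enabled)
    for step in range(1, params.n_steps + 1):
        idx = exposure_step(pop, params, rng)
        counts[idx] += 1
        m = max(abs(float(pop.a1[idx])), abs(float(pop.a2[idx])))
        if track_a3:
            m = max(m, abs(float(pop.a3[idx])))
        if m > max_abs:
            max_abs = m
        if step % cadence == 0 or step == params.n_steps:
            if times[-1] != step:
                times.append(step)
                snapshots.append(pop.copy())
                metrics.append(compute_metrics(pop, params.epsilons))
                logger.debug("t=%d recorded snapshot", step)
    logger.info("run done: seed=%d max|a|=%.6f", params.seed, max_abs)
    return TrajectoryRecord(params=params, times=times, snapshots=snapshots,
                            metrics=metrics, selection_counts=counts,
                            max_abs_attitude=max_abs)


# ---------------------------------------------------------------------------
# Polarization metrics
# ---------------------------------------------------------------------------

_CONCEPT_ARRAYS = {"a1": ("a1",), "a2": ("a2",), "a3": ("a3",),
                   "pooled": ("a1", "a2")}


def _check_eps(eps: float) -> None:
    if not 0.0 < eps < 1.0:
        raise ValueError(f"epsilon must lie in (0, 1), got {eps!r}")


def _concept_values(pop: Population, concept: str) -> np.ndarray:
    try:
        names = _CONCEPT_ARRAYS[concept]
    except KeyError:
        raise ValueError(
            f"concept must be one of {sorted(_CONCEPT_ARRAYS)}, got {concept!r}"
        ) from None
    return np.concatenate([getattr(pop, n) for n in names])


def extremity_ratio(pop: Population, eps: float, concept: str = "pooled") -> float:
    """Fraction of attitude values with ``|a| >= 1 - eps`` (inclusive)."""
    _check_eps(eps)
    values = _concept_values(pop, concept)
    return float(np.mean(np.abs(values) >= 1.0 - eps))


def neutral_fraction(pop: Population, eps: float, concept: str = "pooled") -> float:
    """Fraction of attitude values with ``|a| <= eps`` (near-neutral mass)."""
    _check_eps(eps)
    values = _concept_values(pop, concept)
    return float(np.mean(np.abs(values) <= eps))


def corner_fractions(pop: Population, eps: float) -> dict[str, float]:
    """Fraction of agents within an eps-box of each (a1, a2) corner.

    Keys ``pp, pm, mp, mm``: first letter the sign of the a1 corner, second
    of a2 (p = +1, m = -1). An agent belongs to corner (s1, s2) when
    ``|a1 - s1| <= eps`` and ``|a2 - s2| <= eps``; the boxes are disjoint for
    eps < 1 so the four fractions sum to at most 1.
    """
    _check_eps(eps)
    out: dict[str, float] = {}
    for key, (s1, s2) in (("pp", (1.0, 1.0)), ("pm", (1.0, -1.0)),
                          ("mp", (-1.0, 1.0)), ("mm", (-1.0, -1.0))):
        inside = (np.abs(pop.a1 - s1) <= eps) & (np.abs(pop.a2 - s2) <= eps)
        out[key] = float(np.mean(inside))
    return out


def adoption_ratio(pop: Population) -> float:
    """Fraction of agents that have adopted the new belief."""
    return float(np.mean(pop.adopted))


def compute_metrics(pop: Population, epsilons: Sequence[float]) -> MetricsReport:
    """Full metrics report for one snapshot over a list of thresholds."""
    extremity = {
        float(eps): {c: extremity_ratio(pop, eps, c)
                     for c in ("a1", "a2", "pooled")}
        for eps in epsilons
    }
    corners = {float(eps): corner_fractions(pop, eps) for eps in epsilons}
    neutral = {
        float(eps): {c: neutral_fraction(pop, eps, c) for c in ("a1", "a2")}
        for eps in epsilons
    }
    return MetricsReport(t=pop.t, extremity=extremity, corners=corners,
                         neutral=neutral, adoption=adoption_ratio(pop))


# ---------------------------------------------------------------------------
# Configuration and serialization
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    """Raised for unparsable or invalid run configuration."""


#: Keys accepted in a config file (model parameters + run plumbing).
_CONFIG_KEYS = frozenset({
    "n_agents", "n_steps", "k0", "k_nb", "za_magnitude", "rho_mode",
    "rho_value", "new_belief_enabled", "seed", "snapshot_every", "epsilons",
    "outdir", "out_format", "replicates",
})


@dataclass(frozen=True)
class RunConfig:
    """A run plan: model parameters plus output plumbing.

    ``params.seed`` is the base seed; replicate ``i`` runs with seed
    ``base + i`` so the plan is reproducible from the config alone.
    """

    params: ModelParams
    outdir: Path = Path("runs")
    out_format: str = "csv"
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.out_format not in ("csv", "json"):
            raise ConfigError(
                f"out_format must be 'csv' or 'json', got {self.out_format!r}")
        if self.replicates < 1:
            raise ConfigError(f"replicates must be >= 1, got {self.replicates!r}")

    def replicate_params(self, i: int) -> ModelParams:
        if not 0 <= i < self.replicates:
            raise ValueError(f"replicate index {i} out of range")
        return replace(self.params, seed=self.params.seed + i)


def config_from_mapping(raw: Mapping) -> RunConfig:
    """Build a validated RunConfig from a plain mapping, filling defaults."""
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        params = ModelParams.from_dict(raw)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid model parameters: {exc}") from exc
    return RunConfig(
        params=params,
        outdir=Path(raw.get("outdir", "runs")),
        out_format=str(raw.get("out_format", "csv")),
        replicates=int(raw.get("replicates", 1)),
    )


def read_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON config file into a validated RunConfig.

    Raises FileNotFoundError for a missing file, ConfigError with a
    descriptive message for parse or validation failures.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    return config_from_mapping(raw)


def attitudes_frame(record: TrajectoryRecord) -> pd.DataFrame:
    """Long attitude table: one row per (snapshot time, agent)."""
    frames = []
    for t, pop in zip(record.times, record.snapshots):
        frames.append(pd.DataFrame({
            "t": t,
            "agent_id": np.arange(pop.size),
            "a1": pop.a1,
            "a2": pop.a2,
            "a3": pop.a3,
            "adopted": pop.adopted,
        }))
    return pd.concat(frames, ignore_index=True)


_METRIC_COLUMNS = ["t", "eps", "extremity_a1", "extremity_a2", "extremity_pooled",
                   "corner_pp", "corner_pm", "corner_mp", "corner_mm",
                   "neutral_a1", "neutral_a2", "adoption_ratio"]


def metrics_frame(record: TrajectoryRecord) -> pd.DataFrame:
    """Long metrics table: one row per (snapshot time, epsilon)."""
    rows = []
    for report in record.metrics:
        for eps in sorted(report.extremity):
            rows.append({
                "t": report.t,
                "eps": eps,
                "extremity_a1": report.extremity[eps]["a1"],
                "extremity_a2": report.extremity[eps]["a2"],
                "extremity_pooled": report.extremity[eps]["pooled"],
                "corner_pp": report.corners[eps]["pp"],
                "corner_pm": report.corners[eps]["pm"],
                "corner_mp": report.corners[eps]["mp"],
                "corner_mm": report.corners[eps]["mm"],
                "neutral_a1": report.neutral[eps]["a1"],
                "neutral_a2": report.neutral[eps]["a2"],
                "adoption_ratio": report.adoption,
            })
    return pd.DataFrame(rows, columns=_METRIC_COLUMNS)


def recompute_metrics_table(attitudes: pd.DataFrame,
                            epsilons: Sequence[float]) -> pd.DataFrame:
    """Recompute the metrics table from a saved attitude table.

    Allows re-analysis with arbitrary epsilon lists without re-simulation.
    Raises ValueError on an empty table.
    """
    if attitudes.empty:
        raise ValueError("attitude table is empty; nothing to recompute")
    required = {"t", "agent_id", "a1", "a2", "a3", "adopted"}
    missing = required - set(attitudes.columns)
    if missing:
        raise ValueError(f"attitude table missing columns: {sorted(missing)}")
    rows = []
    for t, group in attitudes.groupby("t", sort=True):
        group = group.sort_values("agent_id")
        pop = Population(
            a1=group["a1"].to_numpy(dtype=float),
            a2=group["a2"].to_numpy(dtype=float),
            a3=group["a3"].to_numpy(dtype=float),
            adopted=group["adopted"].to_numpy(dtype=bool),
            t=int(t),
        )
        rows.append(compute_metrics(pop, epsilons))
    return metrics_frame(TrajectoryRecord(
        params=ModelParams(), times=[r.t for r in rows], snapshots=[],
        metrics=rows, selection_counts=np.zeros(0, dtype=np.int64),
        max_abs_attitude=float("nan")))


def _manifest_dict(record: TrajectoryRecord) -> dict:
    return {
        "format_version": 1,
        "params": record.params.to_dict(),
        "times": list(record.times),
        "selection_counts": [int(c) for c in record.selection_counts],
        "max_abs_attitude": record.max_abs_attitude,
    }


def write_trajectory(record: TrajectoryRecord, outdir: str | Path,
                     fmt: str = "csv") -> dict[str, Path]:
    """Serialize a run into ``outdir``; returns the written paths.

    CSV layout: ``attitudes.csv`` + ``metrics.csv`` + ``manifest.json``.
    JSON layout: a single ``run.json`` holding all three. Values round-trip
    losslessly (shortest-repr floats).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _manifest_dict(record)
    if fmt == "csv":
        att_path = outdir / "attitudes.csv"
        met_path = outdir / "metrics.csv"
        man_path = outdir / "manifest.json"
        attitudes_frame(record).to_csv(att_path, index=False)
        metrics_frame(record).to_csv(met_path, index=False)
        man_path.write_text(json.dumps(manifest, indent=2) + "\n")
        return {"attitudes": att_path, "metrics": met_path, "manifest": man_path}
    if fmt == "json":
        path = outdir / "run.json"
        payload = {
            "manifest": manifest,
            "attitudes": attitudes_frame(record).to_dict(orient="list"),
            "metrics": metrics_frame(record).to_dict(orient="list"),
        }
        path.write_text(json.dumps(payload) + "\n")
        return {"run": path}
    raise ValueError(f"unknown output format {fmt!r}")


def _record_from_frames(manifest: Mapping, attitudes: pd.DataFrame,
                        metrics: pd.DataFrame) -> TrajectoryRecord:
    params = ModelParams.from_dict(manifest["params"])
    times = [int(t) for t in manifest["times"]]
    snapshots = []
    for t in times:
        group = attitudes[attitudes["t"] == t].sort_values("agent_id")
        snapshots.append(Population(
            a1=group["a1"].to_numpy(dtype=float),
            a2=group["a2"].to_numpy(dtype=float),
            a3=group["a3"].to_numpy(dtype=float),
            adopted=group["adopted"].to_numpy(dtype=bool),
            t=t,
        ))
    reports = []
    for t in times:
        sub = metrics[metrics["t"] == t]
        extremity, corners, neutral = {}, {}, {}
        adoption = 0.0
        for _, row in sub.iterrows():
            eps = float(row["eps"])
            extremity[eps] = {"a1": float(row["extremity_a1"]),
                              "a2": float(row["extremity_a2"]),
                              "pooled": float(row["extremity_pooled"])}
            corners[eps] = {"pp": float(row["corner_pp"]),
                            "pm": float(row["corner_pm"]),
                            "mp": float(row["corner_mp"]),
                            "mm": float(row["corner_mm"])}
            neutral[eps] = {"a1": float(row["neutral_a1"]),
                            "a2": float(row["neutral_a2"])}
            adoption = float(row["adoption_ratio"])
        reports.append(MetricsReport(t=t, extremity=extremity, corners=corners,
                                     neutral=neutral, adoption=adoption))
    return TrajectoryRecord(
        params=params, times=times, snapshots=snapshots, metrics=reports,
        selection_counts=np.array(manifest["selection_counts"], dtype=np.int64),
        max_abs_attitude=float(manifest["max_abs_attitude"]),
    )


def read_trajectory(outdir: str | Path) -> TrajectoryRecord:
    """Read back a serialized run (either CSV or JSON layout)."""
    outdir = Path(outdir)
    run_json = outdir / "run.json"
    if run_json.exists():
        payload = json.loads(run_json.read_text())
        return _record_from_frames(payload["manifest"],
                                   pd.DataFrame(payload["attitudes"]),
                                   pd.DataFrame(payload["metrics"]))
    man_path = outdir / "manifest.json"
    if not man_path.exists():
        raise FileNotFoundError(f"no run found under {outdir}")
    manifest = json.loads(man_path.read_text())
    attitudes = pd.read_csv(outdir / "attitudes.csv")
    metrics = pd.read_csv(outdir / "metrics.csv")
    return _record_from_frames(manifest, attitudes, metrics)
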