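"""Size-penalized neuroevolution of logic-gate networks.

A population of one-hidden-layer networks (2 inputs, up to 30 hidden
units, 1 output; thresholds realized purely as bias connections on
otherwise zero-threshold neurons) is trained by gradient descent on a
gate's 4-row truth table and then evolved under the fitness

    F_lambda(G) = Q(G) - lambda * sigma(G)

where ``Q = 1 - MSE`` rewards task performance and ``sigma`` is the
fraction of surviving (nonzero) connections, biases included.  At
``lambda = 0`` evolution keeps essentially fully connected solutions;
increasing ``lambda`` biases the population toward the sparsest
networks that still implement the gate.  Selection is a wheel of
fortune on F, parents are cut at a single point in a fixed weight
flattening order and recomposed, mutation perturbs surviving weights,
and very small weights are pruned to exactly zero (pruned connections
stay zero during subsequent learning: the architecture is fixed within
each learning period).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "GateTask",
    "LayeredNetwork",
    "EvoConfig",
    "RatedNetwork",
    "random_network",
    "forward",
    "binarized",
    "train",
    "task_fitness_Q",
    "size_cost_sigma",
    "fitness_F",
    "implements_gate",
    "flatten_weights",
    "unflatten_weights",
    "crossover_networks",
    "mutate_and_prune",
    "evolve_networks",
    "active_hidden_units",
    "network_to_dot",
]


@dataclass(frozen=True)
class GateTask:
    """A two-input logic gate as a complete 4-row truth table."""

    name: str
    inputs: np.ndarray   # (4, 2)
    targets: np.ndarray  # (4,)

    def __post_init__(self):
        inputs = np.asarray(self.inputs, dtype=float)
        targets = np.asarray(self.targets, dtype=float)
        if inputs.shape != (4, 2) or targets.shape != (4,):
            raise ValueError("a gate task is a complete 4-row truth table")
        if sorted(map(tuple, inputs.tolist())) != [(0., 0.), (0., 1.), (1., 0.), (1., 1.)]:
            raise ValueError("inputs must enumerate {0,1}^2")
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "targets", targets)


@dataclass
class LayeredNetwork:
    """2 -> H -> 1 feedforward network with bias connections.

    ``w_in[j]`` are the two input weights of hidden unit ``j``; the bias
    arrays are the "hanging input" connections that realize firing
    thresholds.  Pruned connections are exactly zero.
    """

    w_in: np.ndarray      # (H, 2)
    b_hidden: np.ndarray  # (H,)
    w_out: np.ndarray     # (H,)
    b_out: float
    steepness: float = 1.0

    def __post_init__(self):
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        h = self.w_in.shape[0]
        if self.w_in.shape != (h, 2) or self.b_hidden.shape != (h,) or self.w_out.shape != (h,):
            raise ValueError("inconsistent layer dimensions")

    @property
    def hidden_size(self) -> int:
        return self.w_in.shape[0]

    @property
    def n_connections_total(self) -> int:
        """Connection count of the full architecture: 2H + H + H + 1."""
        return 4 * self.hidden_size + 1

    def copy(self) -> "LayeredNetwork":
        return LayeredNetwork(self.w_in.copy(), self.b_hidden.copy(),
                              self.w_out.copy(), float(self.b_out),
                              self.steepness)


def random_network(hidden: int, rng: np.random.Generator,
                   scale: float = 1.0, steepness: float = 1.0) -> LayeredNetwork:
    """Fully connected network with N(0, scale^2) weights."""
    return LayeredNetwork(
        w_in=rng.normal(0.0, scale, (hidden, 2)),
        b_hidden=rng.normal(0.0, scale, hidden),
        w_out=rng.normal(0.0, scale, hidden),
        b_out=float(rng.normal(0.0, scale)),
        steepness=steepness,
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def forward(net: LayeredNetwork, inputs: np.ndarray) -> np.ndarray:
    """Feedforward pass; accepts one input pair or a batch of them.

    Outputs lie strictly in (0, 1); the binarized prediction is
    ``output >= 0.5``.
    """
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    beta = net.steepness
    h = _sigmoid(beta * (x @ net.w_in.T + net.b_hidden))
    y = _sigmoid(beta * (h @ net.w_out + net.b_out))
    return y if np.ndim(inputs) > 1 else float(y[0])


def binarized(net: LayeredNetwork, inputs: np.ndarray) -> np.ndarray:
    return np.atleast_1d(forward(net, np.atleast_2d(inputs)) >= 0.5)


def train(net: LayeredNetwork, task: GateTask, epochs: int,
          rate: float, weight_decay: float = 0.0) -> LayeredNetwork:
    """Batch gradient descent on MSE over the 4 patterns.

    The architecture is fixed during learning: connections that are zero
    on entry are masked out of the update and stay exactly zero.  An
    optional L2 weight-decay term can apply the size cost directly to
    learning; it is off by default.  Raises on non-finite loss (a
    divergent learning rate).
    """
    net = net.copy()
    x, t = task.inputs, task.targets
    beta = net.steepness
    m_in = net.w_in != 0.0
    m_bh = net.b_hidden != 0.0
    m_out = net.w_out != 0.0
    m_bo = net.b_out != 0.0
    for _ in range(epochs):
        h = _sigmoid(beta * (x @ net.w_in.T + net.b_hidden))   # (4, H)
        y = _sigmoid(beta * (h @ net.w_out + net.b_out))       # (4,)
        err = y - t
        loss = float(np.mean(err ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError("training diverged (non-finite loss)")
        dz2 = (2.0 / len(t)) * err * beta * y * (1.0 - y)       # (4,)
        g_wout = h.T @ dz2
        g_bout = float(dz2.sum())
        dh = np.outer(dz2, net.w_out) * beta * h * (1.0 - h)    # (4, H)
        g_win = dh.T @ x
        g_bh = dh.sum(axis=0)
        if weight_decay:
            g_win = g_win + weight_decay * net.w_in
            g_bh = g_bh + weight_decay * net.b_hidden
            g_wout = g_wout + weight_decay * net.w_out
            g_bout = g_bout + weight_decay * net.b_out
        net.w_in -= rate * g_win * m_in
        net.b_hidden -= rate * g_bh * m_bh
        net.w_out -= rate * g_wout * m_out
        if m_bo:
            net.b_out -= rate * g_bout
    return net


def task_fitness_Q(net: LayeredNetwork, task: GateTask) -> float:
    """Unconstrained task fitness Q = 1 - MSE over the 4 patterns."""
    y = forward(net, task.inputs)
    return float(1.0 - np.mean((y - task.targets) ** 2))


def size_cost_sigma(net: LayeredNetwork) -> float:
    """Nonzero-connection fraction of the full architecture (biases included)."""
    nnz = (int(np.count_nonzero(net.w_in)) + int(np.count_nonzero(net.b_hidden))
           + int(np.count_nonzero(net.w_out)) + int(net.b_out != 0.0))
    return nnz / net.n_connections_total


def fitness_F(net: LayeredNetwork, task: GateTask, lam: float) -> float:
    """Size-penalized fitness F = Q - lambda * sigma."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return task_fitness_Q(net, task) - lam * size_cost_sigma(net)


def implements_gate(net: LayeredNetwork, task: GateTask) -> bool:
    """True iff the binarized outputs match the gate on all 4 rows."""
    return bool(np.all(binarized(net, task.inputs) == (task.targets >= 0.5)))


def active_hidden_units(net: LayeredNetwork) -> int:
    """Hidden units with a nonzero output connection and some nonzero input."""
    feeds_out = net.w_out != 0.0
    has_input = (net.w_in != 0.0).any(axis=1) | (net.b_hidden != 0.0)
    return int(np.count_nonzero(feeds_out & has_input))


# -- genetic operators ---------------------------------------------------

def flatten_weights(net: LayeredNetwork) -> np.ndarray:
    """Fixed genome order: per hidden unit its two input weights, then
    hidden biases, then hidden-to-output weights, then the output bias."""
    return np.concatenate([net.w_in.ravel(), net.b_hidden, net.w_out,
                           [net.b_out]])


def unflatten_weights(genome: np.ndarray, template: LayeredNetwork) -> LayeredNetwork:
    h = template.hidden_size
    genome = np.asarray(genome, dtype=float)
    if genome.shape != (4 * h + 1,):
        raise ValueError("genome length does not match architecture")
    return LayeredNetwork(
        w_in=genome[:2 * h].reshape(h, 2).copy(),
        b_hidden=genome[2 * h:3 * h].copy(),
        w_out=genome[3 * h:4 * h].copy(),
        b_out=float(genome[-1]),
        steepness=template.steepness,
    )


def crossover_networks(p1: LayeredNetwork, p2: LayeredNetwork,
                       rng: np.random.Generator, cut: int | None = None
                       ) -> tuple[LayeredNetwork, LayeredNetwork]:
    """Cut both parents at one uniformly chosen genome position and
    recompose the tails into two offspring."""
    if p1.hidden_size != p2.hidden_size:
        raise ValueError("parents must share an architecture")
    g1, g2 = flatten_weights(p1), flatten_weights(p2)
    if cut is None:
        cut = int(rng.integers(0, len(g1) + 1))
    c1 = np.concatenate([g1[:cut], g2[cut:]])
    c2 = np.concatenate([g2[:cut], g1[cut:]])
    return unflatten_weights(c1, p1), unflatten_weights(c2, p2)


def mutate_and_prune(net: LayeredNetwork, rng: np.random.Generator,
                     mutation_prob: float, mutation_scale: float,
                     prune_threshold: float) -> LayeredNetwork:
    """Gaussian-perturb surviving weights, then zero out very small ones.

    Each nonzero weight is perturbed independently with the configured
    probability; afterwards every weight with ``|w| < prune_threshold``
    is set to exactly zero (pruning never increases sigma)."""
    g = flatten_weights(net)
    alive = g != 0.0
    hit = alive & (rng.random(g.shape) < mutation_prob)
    g[hit] += rng.normal(0.0, mutation_scale, int(hit.sum()))
    g[np.abs(g) < prune_threshold] = 0.0
    return unflatten_weights(g, net)


# -- evolutionary loop ---------------------------------------------------

@dataclass
class EvoConfig:
    """Run parameters for the gate neuroevolution experiment."""

    population_size: int = 20
    hidden: int = 30
    lam: float = 0.0
    learning_epochs: int = 150
    learning_rate: float = 2.0
    prune_threshold: float = 0.05
    mutation_prob: float = 0.3
    mutation_scale: float = 0.3
    generations: int = 25
    init_scale: float = 1.0
    steepness: float = 1.0
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population size must be >= 2")
        for name in ("hidden", "learning_epochs", "generations"):
            if getattr(self, name) < 0 or (name == "hidden" and self.hidden < 1):
                raise ValueError(f"{name} must be positive")
        for name in ("mutation_prob",):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class RatedNetwork:
    net: LayeredNetwork
    F: float
    Q: float
    sigma: float
    exact: bool


def _wheel_of_fortune(scores: np.ndarray, rng: np.random.Generator,
                      eps: float = 1e-9) -> int:
    """Fitness-proportionate index draw on shifted scores.

    F can be negative for lambda > 0, so probabilities use
    ``F - min(F) + eps``; an all-equal population degrades to uniform."""
    w = np.asarray(scores, dtype=float)
    if len(w) == 0:
        raise ValueError("empty population")
    w = w - w.min() + eps
    return int(rng.choice(len(w), p=w / w.sum()))


def evolve_networks(config: EvoConfig, task: GateTask,
                    rng: np.random.Generator | None = None
                    ) -> tuple[RatedNetwork, list[dict]]:
    """Run the generational loop; returns the champion and the history.

    Each generation every member is trained to convergence on the fixed
    architecture, rated by F_lambda, and parents are drawn by the wheel
    of fortune; cut-and-recompose crossover, mutation and small-weight
    pruning produce the next generation, with the best member copied
    unchanged (elitism).  The champion is the highest-F network seen in
    any generation that exactly implements the gate (binarized outputs
    match all 4 rows); if none is found within the generation cap the
    best-F network overall is returned flagged non-exact.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = [random_network(config.hidden, rng, config.init_scale, config.steepness)
           for _ in range(config.population_size)]
    history: list[dict] = []
    champion: RatedNetwork | None = None
    best_any: RatedNetwork | None = None

    for gen in range(config.generations + 1):
        rated: list[RatedNetwork] = []
        for net in pop:
            trained = train(net, task, config.learning_epochs,
                            config.learning_rate, config.weight_decay)
            q = task_fitness_Q(trained, task)
            sig = size_cost_sigma(trained)
            rated.append(RatedNetwork(trained, q - config.lam * sig, q, sig,
                                      implements_gate(trained, task)))
        rated.sort(key=lambda r: r.F, reverse=True)
        for r in rated:
            if r.exact and (champion is None or r.F > champion.F):
                champion = r
        if best_any is None or rated[0].F > best_any.F:
            best_any = rated[0]
        history.append({
            "generation": gen,
            "best_F": rated[0].F,
            "best_Q": rated[0].Q,
            "best_sigma": rated[0].sigma,
            "mean_F": float(np.mean([r.F for r in rated])),
            "n_exact": sum(r.exact for r in rated),
            "champion_sigma": champion.sigma if champion else np.nan,
        })
        if gen == config.generations:
            break
        scores = np.array([r.F for r in rated])
        next_pop = [rated[0].net.copy()]  # elitism
        while len(next_pop) < config.population_size:
            i = _wheel_of_fortune(scores, rng)
            j = _wheel_of_fortune(scores, rng)
            c1, c2 = crossover_networks(rated[i].net, rated[j].net, rng)
            for child in (c1, c2):
                if len(next_pop) >= config.population_size:
                    break
                next_pop.append(mutate_and_prune(
                    child, rng, config.mutation_prob, config.mutation_scale,
                    config.prune_threshold))
        pop = next_pop

    return (champion if champion is not None else best_any), history


def network_to_dot(net: LayeredNetwork, name: str = "net") -> str:
    """Render the surviving connectivity as a GraphViz DOT digraph.

    Only nonzero connections appear; bias connections are drawn from
    dedicated "hanging input" nodes, mirroring the usual minimal-
    solution diagrams of evolved gate networks.
    """
    lines = [f"digraph {name} {{", "  rankdir=BT;",
             '  x0 [shape=box]; x1 [shape=box]; out [shape=doublecircle];']
    for j in range(net.hidden_size):
        used = (net.w_in[j] != 0.0).any() or net.b_hidden[j] != 0.0 \
            or net.w_out[j] != 0.0
        if not used:
            continue
        lines.append(f"  h{j} [shape=circle];")
        for i in range(2):
            if net.w_in[j, i] != 0.0:
                lines.append(f'  x{i} -> h{j} [label="{net.w_in[j, i]:.2f}"];')
        if net.b_hidden[j] != 0.0:
            lines.append(f"  bias_h{j} [shape=point];")
            lines.append(
                f'  bias_h{j} -> h{j} [label="{net.b_hidden[j]:.2f}"];')
        if net.w_out[j] != 0.0:
            lines.append(f'  h{j} -> out [label="{net.w_out[j]:.2f}"];')
    if net.b_out != 0.0:
        lines.append("  bias_out [shape=point];")
        lines.append(f'  bias_out -> out [label="{net.b_out:.2f}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
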