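"""Gate networks, gradient-descent learning and the size-penalized loop."""

import numpy as np
import pytest

from evoequiv import fixtures
from evoequiv.neuroevolution import (
    EvoConfig, LayeredNetwork, active_hidden_units, binarized,
    crossover_networks, evolve_networks, fitness_F, flatten_weights, forward,
    implements_gate, mutate_and_prune, random_network, size_cost_sigma,
    task_fitness_Q, train, unflatten_weights,
)


def _and_net(steepness=1.0):
    """Analytically constructed single-hidden-unit AND implementation."""
    return LayeredNetwork(w_in=np.array([[10.0, 10.0]]),
                          b_hidden=np.array([-15.0]),
                          w_out=np.array([10.0]), b_out=-5.0,
                          steepness=steepness)


@pytest.fixture(scope="module")
def tasks():
    return fixtures.gate_truth_tables()


# -- forward pass --------------------------------------------------------

def test_all_zero_weights_output_half():
    net = LayeredNetwork(np.zeros((3, 2)), np.zeros(3), np.zeros(3), 0.0)
    assert forward(net, np.array([1.0, 0.0])) == pytest.approx(0.5)


def test_hand_built_and_net_is_exact(tasks):
    and_task, xor_task = tasks
    net = _and_net()
    assert list(binarized(net, and_task.inputs)) == [False, False, False, True]
    assert implements_gate(net, and_task)
    assert not implements_gate(net, xor_task)


def test_outputs_bounded_in_open_unit_interval(rng):
    net = random_network(30, rng, scale=5.0)
    y = forward(net, np.array([[0., 0.], [0., 1.], [1., 0.], [1., 1.]]))
    assert np.all((y > 0) & (y < 1))


# -- training ------------------------------------------------------------

def test_zero_epochs_leaves_net_unchanged(tasks, rng):
    net = random_network(10, rng)
    trained = train(net, tasks[0], epochs=0, rate=0.5)
    assert np.array_equal(flatten_weights(trained), flatten_weights(net))


def test_loss_non_increasing_at_small_rate(tasks, rng):
    _, xor_task = tasks
    net = random_network(30, rng)
    losses = []
    for _ in range(40):
        losses.append(1.0 - task_fitness_Q(net, xor_task))
        net = train(net, xor_task, epochs=1, rate=0.02)
    diffs = np.diff(losses)
    assert np.all(diffs <= 1e-9)


def test_xor_training_converges_for_most_inits(tasks):
    _, xor_task = tasks
    hits = 0
    for seed in range(10):
        net = random_network(30, np.random.default_rng(seed))
        trained = train(net, xor_task, epochs=500, rate=0.8)
        hits += implements_gate(trained, xor_task)
    assert hits >= 8


def test_pruned_connections_stay_zero_during_training(tasks, rng):
    net = random_network(8, rng)
    net.w_in[2] = 0.0
    net.w_out[5] = 0.0
    trained = train(net, tasks[0], epochs=50, rate=0.5)
    assert np.all(trained.w_in[2] == 0.0) and trained.w_out[5] == 0.0


def test_non_finite_loss_raises(tasks, rng):
    net = random_network(30, rng, scale=3.0)
    net.w_in[0, 0] = np.nan  # degenerate weights surface as a training error
    with pytest.raises(FloatingPointError):
        train(net, tasks[1], epochs=5, rate=0.5)


# -- fitness terms --------------------------------------------------------

def test_Q_of_constant_half_net_is_three_quarters(tasks):
    net = LayeredNetwork(np.zeros((2, 2)), np.zeros(2), np.zeros(2), 0.0)
    for task in tasks:  # both gates are 0/1-valued, so MSE is exactly 0.25
        assert task_fitness_Q(net, task) == pytest.approx(0.75)


def test_Q_matches_independent_mse(tasks, rng):
    net = random_network(12, rng)
    y = forward(net, tasks[0].inputs)
    mse = float(np.mean((np.asarray(y) - tasks[0].targets) ** 2))
    assert task_fitness_Q(net, tasks[0]) == pytest.approx(1.0 - mse)


def test_sigma_full_and_empty_and_monotone(rng):
    full = random_network(30, rng)
    assert size_cost_sigma(full) == pytest.approx(1.0)
    empty = LayeredNetwork(np.zeros((30, 2)), np.zeros(30), np.zeros(30), 0.0)
    assert size_cost_sigma(empty) == 0.0
    pruned = full.copy()
    pruned.w_in[0, 0] = 0.0
    assert size_cost_sigma(pruned) < size_cost_sigma(full)


def test_F_reduces_to_Q_at_lambda_zero(tasks, rng):
    net = random_network(10, rng)
    assert fitness_F(net, tasks[0], 0.0) == pytest.approx(
        task_fitness_Q(net, tasks[0]))


def test_F_penalizes_size_at_positive_lambda(tasks, rng):
    net = random_network(10, rng)
    assert fitness_F(net, tasks[0], 0.5) == pytest.approx(
        task_fitness_Q(net, tasks[0]) - 0.5 * size_cost_sigma(net))


# -- genetic operators ----------------------------------------------------

def test_crossover_at_cut_zero_swaps_parents(rng):
    p1, p2 = random_network(6, rng), random_network(6, rng)
    c1, c2 = crossover_networks(p1, p2, rng, cut=0)
    assert np.array_equal(flatten_weights(c1), flatten_weights(p2))
    assert np.array_equal(flatten_weights(c2), flatten_weights(p1))


def test_self_crossover_copies_parent(rng):
    p = random_network(6, rng)
    c1, c2 = crossover_networks(p, p, rng)
    assert np.array_equal(flatten_weights(c1), flatten_weights(p))
    assert np.array_equal(flatten_weights(c2), flatten_weights(p))


def test_crossover_conserves_weight_multiset(rng):
    p1, p2 = random_network(9, rng), random_network(9, rng)
    c1, c2 = crossover_networks(p1, p2, rng)
    before = np.sort(np.concatenate([flatten_weights(p1), flatten_weights(p2)]))
    after = np.sort(np.concatenate([flatten_weights(c1), flatten_weights(c2)]))
    assert np.array_equal(before, after)


def test_crossover_rejects_architecture_mismatch(rng):
    with pytest.raises(ValueError):
        crossover_networks(random_network(5, rng), random_network(6, rng), rng)


def test_flatten_unflatten_roundtrip(rng):
    net = random_network(7, rng)
    again = unflatten_weights(flatten_weights(net), net)
    assert np.array_equal(flatten_weights(again), flatten_weights(net))


def test_mutation_off_without_small_weights_is_identity(rng):
    net = random_network(6, rng, scale=2.0)
    g = flatten_weights(net)
    g[np.abs(g) < 0.1] = 0.5  # clear sub-threshold weights
    net = unflatten_weights(g, net)
    out = mutate_and_prune(net, rng, mutation_prob=0.0, mutation_scale=0.3,
                           prune_threshold=0.05)
    assert np.array_equal(flatten_weights(out), flatten_weights(net))


def test_sub_threshold_weight_is_pruned_to_exact_zero(rng):
    net = random_network(6, rng, scale=2.0)
    net.w_in[1, 0] = 0.01
    out = mutate_and_prune(net, rng, mutation_prob=0.0, mutation_scale=0.3,
                           prune_threshold=0.05)
    assert out.w_in[1, 0] == 0.0


def test_pruning_never_increases_sigma(rng):
    for _ in range(20):
        net = random_network(8, rng, scale=0.3)
        out = mutate_and_prune(net, rng, mutation_prob=0.0,
                               mutation_scale=0.0, prune_threshold=0.2)
        assert size_cost_sigma(out) <= size_cost_sigma(net)


# -- gate exactness --------------------------------------------------------

def test_all_zero_net_implements_neither_gate(tasks):
    net = LayeredNetwork(np.zeros((30, 2)), np.zeros(30), np.zeros(30), 0.0)
    assert not implements_gate(net, tasks[0])
    assert not implements_gate(net, tasks[1])


def test_exactness_invariant_under_margin_preserving_rescale(tasks):
    net = _and_net()
    scaled = net.copy()
    scaled.w_out = scaled.w_out * 3.0
    scaled.b_out = scaled.b_out * 3.0  # preserves the sign of the output logit
    assert implements_gate(net, tasks[0]) == implements_gate(scaled, tasks[0])


# -- the evolutionary loop -------------------------------------------------

def test_evolution_is_reproducible_from_seed(tasks):
    cfg = EvoConfig(lam=0.05, generations=3, learning_epochs=40, seed=9)
    c1, h1 = evolve_networks(cfg, tasks[0])
    c2, h2 = evolve_networks(cfg, tasks[0])
    assert np.array_equal(flatten_weights(c1.net), flatten_weights(c2.net))
    assert h1 == h2


def test_champion_exact_flag_is_reverified(tasks):
    cfg = EvoConfig(lam=0.0, generations=4, seed=1)
    champ, _ = evolve_networks(cfg, tasks[1])
    if champ.exact:
        assert implements_gate(champ.net, tasks[1])


def test_xor_champion_keeps_at_least_two_hidden_units(tasks):
    cfg = EvoConfig(lam=0.1, generations=8, seed=2)
    champ, _ = evolve_networks(cfg, tasks[1])
    if champ.exact:
        assert active_hidden_units(champ.net) >= 2


def test_dot_export_shows_only_surviving_connections():
    from evoequiv.neuroevolution import network_to_dot
    net = _and_net()
    net.w_in[0, 1] = 0.0  # prune one input connection
    dot = network_to_dot(net)
    assert dot.startswith("digraph")
    assert "x0 -> h0" in dot and "x1 -> h0" not in dot
    assert "bias_h0" in dot and "h0 -> out" in dot
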