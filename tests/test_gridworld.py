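"""Robot physics: sensing, movement, journeys, wall coverage."""

import numpy as np
import pytest

from evoequiv import fixtures
from evoequiv.gridworld import (
    GridWorld, SensorReading, initial_state, is_perfect, move_table_for_program,
    move_table_from_truth_vector, program_controller, run_journey, sense,
    sensor_byte, step, wall_coverage_fitness,
)
from evoequiv.logic_expr import parse_expression, truth_vector

from _oracles import neighborhood_walls


def _room(h=7, w=7):
    """Closed empty room."""
    walls = np.zeros((h, w), dtype=bool)
    walls[0, :] = walls[-1, :] = walls[:, 0] = walls[:, -1] = True
    return GridWorld(walls)


# -- construction and the map format ------------------------------------

def test_world_requires_wall_and_free_cells():
    with pytest.raises(ValueError):
        GridWorld(np.zeros((4, 4), dtype=bool))
    with pytest.raises(ValueError):
        GridWorld(np.ones((4, 4), dtype=bool))


def test_ascii_roundtrip_and_topology_inference(closed_world, open_world):
    for world in (closed_world, open_world):
        again = GridWorld.from_ascii(world.to_ascii())
        assert again == world and again.topology == world.topology


def test_ascii_rejects_ragged_and_bad_chars():
    with pytest.raises(ValueError):
        GridWorld.from_ascii("##\n#")
    with pytest.raises(ValueError):
        GridWorld.from_ascii("##\n#x")


# -- sensing -------------------------------------------------------------

def test_sense_interior_of_room_is_all_clear():
    world = _room()
    assert not any(sense(world, (3, 3)))


def test_sense_below_long_wall():
    # robot one cell south of an east-west wall: n, ne, nw fire
    world = GridWorld.from_ascii("....\n####\n....\n....", topology="open")
    reading = sense(world, (2, 1))
    assert (reading.n, reading.ne, reading.nw) == (True, True, True)
    assert not any([reading.e, reading.se, reading.s, reading.sw, reading.w])


def test_sense_on_wall_cell_is_an_error(closed_world):
    with pytest.raises(ValueError):
        sense(closed_world, (0, 0))


def test_sense_matches_direct_grid_lookup(rng):
    offsets = (("n", -1, 0), ("ne", -1, 1), ("e", 0, 1), ("se", 1, 1),
               ("s", 1, 0), ("sw", 1, -1), ("w", 0, -1), ("nw", -1, -1))
    for _ in range(5):
        world = fixtures.random_world(rng, size=9, density=0.3)
        for pos in world.free_cells():
            reading = sense(world, pos)
            r, c = pos
            got = {(r + dr, c + dc)
                   for (_, dr, dc), hit in zip(offsets, reading) if hit}
            # open world: off-grid reads free, so every hit is a real wall cell
            assert got == neighborhood_walls(world, pos)


def test_sense_is_translation_consistent(closed_world):
    # pad the world with an extra free apron ring; readings shift with it
    walls = np.zeros((14, 14), dtype=bool)
    walls[1:13, 1:13] = closed_world.walls
    shifted = GridWorld(walls, topology="open")
    for pos in ((1, 1), (4, 7), (10, 5)):
        if closed_world.is_free(pos):
            assert sense(closed_world, pos) == sense(
                shifted, (pos[0] + 1, pos[1] + 1))


# -- movement ------------------------------------------------------------

def test_step_moves_into_free_cell():
    world = _room()
    st0 = initial_state(world, (3, 3))
    st1 = step(world, st0, "east")
    assert st1.position == (3, 4) and st1.steps == 1


def test_blocked_step_stays_and_counts():
    world = _room()
    st0 = initial_state(world, (1, 3))
    st1 = step(world, st0, "north")  # wall above
    assert st1.position == (1, 3) and st1.steps == 1


def test_walk_credits_match_neighborhood_union():
    world = _room()
    st = initial_state(world, (1, 1))
    expected = set(neighborhood_walls(world, (1, 1)))
    for move in ["east"] * 5 + ["south"] * 4:
        st = step(world, st, move)
        expected |= neighborhood_walls(world, st.position)
    assert st.credited == expected


# -- journeys and fitness -------------------------------------------------

def test_stay_controller_never_moves():
    world = _room()
    traj = run_journey(world, lambda reading: None, (3, 3), 10)
    assert len(traj) == 11
    assert all(s.position == (3, 3) for s in traj)


def test_zero_length_journey_is_single_state():
    traj = run_journey(_room(), lambda r: None, (3, 3), 0)
    assert len(traj) == 1


def test_stationary_far_from_wall_scores_zero():
    world = GridWorld.from_ascii(
        "#.......\n........\n........\n........\n........", topology="open")
    traj = run_journey(world, lambda r: None, (3, 4), 5)
    assert wall_coverage_fitness(world, traj) == 0


def test_coverage_is_monotone_in_prefix_length(closed_world):
    ctrl = fixtures.reference_wall_follower()
    traj = run_journey(closed_world, ctrl, (5, 5), 80)
    scores = [wall_coverage_fitness(closed_world, traj[:k + 1])
              for k in range(0, 81, 8)]
    assert scores == sorted(scores)


def test_reference_follower_hugs_wall_after_contact(closed_world):
    ctrl = fixtures.reference_wall_follower()
    traj = run_journey(closed_world, ctrl, (6, 3), 100)
    touched = [bool(closed_world.wall_neighbors(s.position)) for s in traj]
    first = touched.index(True)
    assert all(touched[first:])


def test_full_perimeter_walk_covers_all_walls(closed_world):
    ctrl = fixtures.reference_wall_follower()
    traj = run_journey(closed_world, ctrl, (5, 5), 150)
    assert wall_coverage_fitness(closed_world, traj) == closed_world.n_wall_cells


def test_positions_stay_on_free_cells_under_any_controller(rng):
    world = fixtures.random_world(rng, size=8, density=0.25)
    moves = ["north", "east", "south", "west", None]
    controller = lambda reading: moves[int(rng.integers(5))]
    start = world.free_cells()[0]
    for s in run_journey(world, controller, start, 60):
        assert world.is_free(s.position)


# -- perfection ----------------------------------------------------------

def test_reference_follower_is_perfect_on_closed_map(closed_world):
    assert is_perfect(closed_world, fixtures.reference_wall_follower())


def test_always_north_is_not_perfect(closed_world):
    assert not is_perfect(closed_world, lambda reading: "north")


def test_stay_controller_is_not_perfect(closed_world):
    assert not is_perfect(closed_world, lambda reading: None)


def test_fast_path_agrees_with_generic_simulation(closed_world):
    # move-table fast path and per-step simulation must agree
    ctrl = program_controller(parse_expression("If[north, !n, If[east, !e, w]]"))
    generic = lambda reading: ctrl(reading)  # hides the move_table attribute
    assert is_perfect(closed_world, ctrl, budget=60) == is_perfect(
        closed_world, generic, budget=60)


# -- program controllers --------------------------------------------------

def test_move_table_compilation_routes_match():
    for text in ("If[north, !n, If[east, !e, If[south, !s, !w]]]",
                 "n&&east||!n&&north", "True", "False"):
        expr = parse_expression(text)
        assert np.array_equal(move_table_for_program(expr),
                              move_table_from_truth_vector(truth_vector(expr)))


def test_constant_true_program_always_moves_north():
    # "True" answers yes to the first interrogated direction: north
    ctrl = program_controller(parse_expression("True"))
    reading = SensorReading(*([False] * 8))
    assert ctrl(reading) == "north"


def test_constant_false_program_never_moves():
    ctrl = program_controller(parse_expression("False"))
    assert ctrl(SensorReading(*([False] * 8))) is None


def test_sensor_byte_packs_n_as_msb():
    assert sensor_byte(SensorReading(True, *[False] * 7)) == 128
    assert sensor_byte(SensorReading(*[False] * 7, True)) == 1


def test_trajectory_export_lists_new_wall_credits(tmp_path, closed_world):
    from evoequiv.gridworld import write_trajectory
    ctrl = fixtures.reference_wall_follower()
    traj = run_journey(closed_world, ctrl, (5, 5), 12)
    path = tmp_path / "traj.tsv"
    write_trajectory(path, closed_world, traj)
    lines = path.read_text().splitlines()
    assert lines[0] == "step\trow\tcol\tnew_wall_cells"
    assert len(lines) == 14
    credited = set()
    for ln in lines[1:]:
        cells = ln.split("\t")[3]
        new = {tuple(map(int, c.split(","))) for c in cells.split(";") if c}
        assert not (new & credited)  # each wall cell is reported once
        credited |= new
    assert credited == traj[-1].credited
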