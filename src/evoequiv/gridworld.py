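"""Grid world for the wall-following robot.

The robot lives on a rectangular grid of wall and free cells, senses
wall contact in the eight compass directions (space-fixed, not
robot-relative), and moves one cell north/east/south/west per step.  A
journey is fitness-rated by how many distinct wall cells the robot
"visits", where visiting means standing 8-adjacent to the wall cell —
the robot can never occupy a wall cell itself.

Coordinates are (row, column), 0-based, with north = row - 1 and
east = column + 1.  A *closed* world is fully bordered by wall; an
*open* world has free boundary cells, and anything beyond the stored
grid is treated as free space that the robot cannot enter (stored open
maps should therefore include a generous free apron around the wall so
that roaming outside the labyrinth is representable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .logic_expr import BoolExpr, truth_vector, evaluate_on_columns

__all__ = [
    "COMPASS8",
    "MOVES",
    "MOVE_ORDER",
    "GridWorld",
    "SensorReading",
    "RobotState",
    "sense",
    "sensor_byte",
    "initial_state",
    "step",
    "run_journey",
    "wall_coverage_fitness",
    "is_perfect",
    "program_controller",
    "move_table_from_truth_vector",
    "move_table_for_program",
    "write_trajectory",
]

#: The eight sensor directions, in the same order as the first eight
#: entries of the variable vocabulary, with (row, col) offsets.
COMPASS8: tuple[tuple[str, int, int], ...] = (
    ("n", -1, 0), ("ne", -1, 1), ("e", 0, 1), ("se", 1, 1),
    ("s", 1, 0), ("sw", 1, -1), ("w", 0, -1), ("nw", -1, -1),
)

#: The four one-step moves.
MOVES: dict[str, tuple[int, int]] = {
    "north": (-1, 0), "east": (0, 1), "south": (1, 0), "west": (0, -1),
}

#: Fixed priority order in which a boolean program is interrogated for
#: its candidate moves.
MOVE_ORDER: tuple[str, ...] = ("north", "east", "south", "west")

STAY = 4  # move-table code for "no direction answered true"


class SensorReading(NamedTuple):
    """Wall-occupancy of the eight neighbour cells."""

    n: bool
    ne: bool
    e: bool
    se: bool
    s: bool
    sw: bool
    w: bool
    nw: bool

    def as_assignment(self, move: str) -> dict[str, bool]:
        """Full 12-variable assignment: sensors plus a one-hot move flag."""
        a = dict(zip(self._fields, self))
        for m in MOVE_ORDER:
            a[m] = (m == move)
        return a


@dataclass(frozen=True)
class RobotState:
    """Robot position plus the wall cells credited so far."""

    position: tuple[int, int]
    credited: frozenset[tuple[int, int]]
    steps: int = 0


class GridWorld:
    """Rectangular occupancy grid.

    Parameters
    ----------
    walls:
        2-D boolean array, ``True`` for wall cells.
    topology:
        ``"closed"`` (fully wall-bordered; off-grid counts as wall) or
        ``"open"`` (off-grid counts as free but unvisitable).  If omitted
        it is inferred from the boundary.
    """

    def __init__(self, walls: np.ndarray, topology: str | None = None):
        walls = np.asarray(walls, dtype=bool)
        if walls.ndim != 2 or min(walls.shape) < 2:
            raise ValueError("walls must be a 2-D grid of at least 2x2 cells")
        if not walls.any():
            raise ValueError("world must contain at least one wall cell")
        if walls.all():
            raise ValueError("world must contain at least one free cell")
        border_all_wall = (walls[0].all() and walls[-1].all()
                           and walls[:, 0].all() and walls[:, -1].all())
        if topology is None:
            topology = "closed" if border_all_wall else "open"
        if topology not in ("closed", "open"):
            raise ValueError(f"unknown topology {topology!r}")
        if topology == "closed" and not border_all_wall:
            raise ValueError("closed topology requires a complete wall border")
        self.walls = walls
        self.walls.setflags(write=False)
        self.topology = topology
        self._cache: _WorldCache | None = None

    # -- geometry ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.walls.shape

    @property
    def n_wall_cells(self) -> int:
        return int(self.walls.sum())

    def in_bounds(self, pos: tuple[int, int]) -> bool:
        r, c = pos
        return 0 <= r < self.walls.shape[0] and 0 <= c < self.walls.shape[1]

    def is_wall(self, pos: tuple[int, int]) -> bool:
        """Wall-occupancy as seen by the sensors (off-grid: closed=wall, open=free)."""
        if not self.in_bounds(pos):
            return self.topology == "closed"
        return bool(self.walls[pos])

    def is_free(self, pos: tuple[int, int]) -> bool:
        """True iff the robot may occupy ``pos`` (in-bounds free cell)."""
        return self.in_bounds(pos) and not self.walls[pos]

    def free_cells(self) -> list[tuple[int, int]]:
        return [tuple(p) for p in np.argwhere(~self.walls)]

    def wall_cells(self) -> list[tuple[int, int]]:
        return [tuple(p) for p in np.argwhere(self.walls)]

    def wall_neighbors(self, pos: tuple[int, int]) -> frozenset[tuple[int, int]]:
        """In-grid wall cells 8-adjacent to ``pos``."""
        r, c = pos
        out = []
        for _, dr, dc in COMPASS8:
            q = (r + dr, c + dc)
            if self.in_bounds(q) and self.walls[q]:
                out.append(q)
        return frozenset(out)

    # -- ASCII map format ---------------------------------------------

    @classmethod
    def from_ascii(cls, text: str, topology: str | None = None) -> "GridWorld":
        """Parse a map: '#' = wall, '.' = free, one row per line."""
        rows = [ln for ln in text.splitlines() if ln.strip()]
        if not rows:
            raise ValueError("empty map")
        width = len(rows[0])
        if any(len(r) != width for r in rows):
            raise ValueError("map rows must all have the same length")
        bad = {ch for r in rows for ch in r} - {"#", "."}
        if bad:
            raise ValueError(f"unexpected map characters: {sorted(bad)}")
        walls = np.array([[ch == "#" for ch in r] for r in rows], dtype=bool)
        return cls(walls, topology)

    def to_ascii(self) -> str:
        return "\n".join("".join("#" if w else "." for w in row)
                         for row in self.walls) + "\n"

    @classmethod
    def from_file(cls, path, topology: str | None = None) -> "GridWorld":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_ascii(fh.read(), topology)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_ascii())

    def __eq__(self, other) -> bool:
        if not isinstance(other, GridWorld):
            return NotImplemented
        return (self.topology == other.topology
                and self.walls.shape == other.walls.shape
                and bool((self.walls == other.walls).all()))

    def __repr__(self) -> str:
        h, w = self.shape
        return f"GridWorld({h}x{w}, {self.topology}, {self.n_wall_cells} wall cells)"

    # -- fast-simulation cache ----------------------------------------

    def cache(self) -> "_WorldCache":
        if self._cache is None:
            self._cache = _WorldCache(self)
        return self._cache


# -- sensing and movement ------------------------------------------------

def sense(world: GridWorld, position: tuple[int, int]) -> SensorReading:
    """Read the eight wall-contact sensors at ``position`` (a free cell)."""
    if not world.is_free(position):
        raise ValueError(f"robot position {position} is not a free cell")
    r, c = position
    return SensorReading(*(world.is_wall((r + dr, c + dc))
                           for _, dr, dc in COMPASS8))


def sensor_byte(reading: SensorReading) -> int:
    """Pack a reading into 8 bits, ``n`` as the most significant."""
    b = 0
    for v in reading:
        b = (b << 1) | int(v)
    return b


def initial_state(world: GridWorld, start: tuple[int, int]) -> RobotState:
    if not world.is_free(start):
        raise ValueError(f"start {start} is not a free cell")
    return RobotState(start, world.wall_neighbors(start), 0)


def step(world: GridWorld, state: RobotState, move: str | None) -> RobotState:
    """Advance one step.

    Moves into wall cells or off the grid are blocked: the position is
    unchanged but the step counter still advances.  ``move=None`` means
    deliberately staying put.  The wall-credit set absorbs all wall cells
    8-adjacent to the (possibly unchanged) position.
    """
    if move is None:
        target = state.position
    else:
        dr, dc = MOVES[move]
        r, c = state.position
        target = (r + dr, c + dc)
        if not world.is_free(target):
            target = state.position
    credited = state.credited | world.wall_neighbors(target)
    return RobotState(target, credited, state.steps + 1)


Controller = Callable[[SensorReading], "str | None"]


def run_journey(world: GridWorld, controller: Controller,
                start: tuple[int, int], journey_length: int) -> list[RobotState]:
    """Simulate a fixed-length journey; returns ``journey_length + 1`` states."""
    if journey_length < 0:
        raise ValueError("journey_length must be >= 0")
    state = initial_state(world, start)
    trajectory = [state]
    for _ in range(journey_length):
        move = controller(sense(world, state.position))
        state = step(world, state, move)
        trajectory.append(state)
    return trajectory


def wall_coverage_fitness(world: GridWorld, trajectory: Sequence[RobotState]) -> int:
    """Distinct wall cells 8-adjacent to any visited position."""
    covered: set[tuple[int, int]] = set()
    for st in trajectory:
        covered |= world.wall_neighbors(st.position)
    return len(covered)


def default_budget(world: GridWorld) -> int:
    """Journey budget heuristic for perfection checks: 4x the wall count."""
    return 4 * world.n_wall_cells


def is_perfect(world: GridWorld, controller: Controller,
               budget: int | None = None) -> bool:
    """True iff every free start reaches full wall coverage within budget.

    Full coverage means crediting *all* wall cells of the world.  With a
    move-table controller (see :func:`program_controller`) the check runs
    on the vectorized fast path; any other callable is simulated
    directly.
    """
    if budget is None:
        budget = default_budget(world)
    total = world.n_wall_cells
    table = getattr(controller, "move_table", None)
    if table is not None:
        cache = world.cache()
        return bool(np.all(cache.coverage_all_starts(table, budget) == total))
    for start in world.free_cells():
        traj = run_journey(world, controller, start, budget)
        if wall_coverage_fitness(world, traj) < total:
            return False
    return True


# -- boolean programs as controllers -------------------------------------

def move_table_from_truth_vector(tv: np.ndarray) -> np.ndarray:
    """Compile a program's truth vector into a 256-entry move table.

    A program is asked, for each direction in the fixed priority order
    (north, east, south, west), whether to take that move, with the
    direction variables one-hot; the first "True" wins, otherwise the
    robot stays.  Because the answer depends only on the 8 sensor bits,
    the whole policy is a table indexed by the packed sensor byte, with
    values 0..3 (index into ``MOVE_ORDER``) or ``STAY``.
    """
    tv = np.asarray(tv, dtype=bool)
    s = np.arange(256)
    table = np.full(256, STAY, dtype=np.uint8)
    # assignment index = sensor_byte << 4 | one-hot nibble (north=8 .. west=1)
    for k, onehot in enumerate((8, 4, 2, 1)):
        hit = tv[(s << 4) | onehot] & (table == STAY)
        table[hit] = k
    return table


_POLICY_COLUMNS: np.ndarray | None = None


def _policy_columns() -> np.ndarray:
    """(12, 1024) assignment batch covering every (sensor byte, one-hot move).

    Column ``s * 4 + k`` binds the eight sensors to the bits of ``s``
    (``n`` most significant) and one-hots direction ``MOVE_ORDER[k]``.
    """
    global _POLICY_COLUMNS
    if _POLICY_COLUMNS is None:
        s = np.repeat(np.arange(256), 4)
        k = np.tile(np.arange(4), 256)
        cols = np.empty((12, 1024), dtype=bool)
        for i in range(8):
            cols[i] = (s >> (7 - i)) & 1
        for j in range(4):
            cols[8 + j] = k == j
        cols.setflags(write=False)
        _POLICY_COLUMNS = cols
    return _POLICY_COLUMNS


def move_table_for_program(program: BoolExpr) -> np.ndarray:
    """Compile a program directly into its 256-entry move table.

    Equivalent to ``move_table_from_truth_vector(truth_vector(program))``
    but evaluates only the 1,024 assignments the policy can ever see.
    """
    answers = evaluate_on_columns(program, _policy_columns()).reshape(256, 4)
    table = np.full(256, STAY, dtype=np.uint8)
    for k in range(4):
        hit = answers[:, k] & (table == STAY)
        table[hit] = k
    return table


def program_controller(program: BoolExpr) -> Controller:
    """Wrap a boolean program as a journey controller."""
    table = move_table_for_program(program)

    def controller(reading: SensorReading) -> str | None:
        code = table[sensor_byte(reading)]
        return None if code == STAY else MOVE_ORDER[code]

    controller.move_table = table
    controller.program = program
    return controller


class _WorldCache:
    """Precomputed per-cell arrays for fast batched journey simulation.

    Cells are indexed 0..n-1 over *free* cells.  For a move-table
    controller the one-step transition is a fixed map on free cells, so
    journeys from all starts advance with one fancy-indexing op per step.
    """

    def __init__(self, world: GridWorld):
        self.world = world
        free = world.free_cells()
        self.free = free
        self.index = {pos: i for i, pos in enumerate(free)}
        walls = world.wall_cells()
        wall_id = {pos: j for j, pos in enumerate(walls)}
        n = len(free)
        self.sensor_bytes = np.empty(n, dtype=np.int64)
        self.neighbor = np.empty((n, 4), dtype=np.int64)
        self.wall_adj = np.zeros((n, len(walls)), dtype=bool)
        for i, pos in enumerate(free):
            self.sensor_bytes[i] = sensor_byte(sense(world, pos))
            r, c = pos
            for k, m in enumerate(MOVE_ORDER):
                dr, dc = MOVES[m]
                q = (r + dr, c + dc)
                self.neighbor[i, k] = self.index.get(q, i)  # blocked -> stay
            for q in world.wall_neighbors(pos):
                self.wall_adj[i, wall_id[q]] = True

    def transition(self, move_table: np.ndarray) -> np.ndarray:
        """Next-cell index for every free cell under the given policy."""
        codes = np.asarray(move_table)[self.sensor_bytes]
        nxt = np.arange(len(self.free), dtype=np.int64)
        moving = codes != STAY
        nxt[moving] = self.neighbor[moving, codes[moving]]
        return nxt

    def coverage(self, move_table: np.ndarray, starts: np.ndarray,
                 journey_length: int) -> np.ndarray:
        """Distinct-wall-cell coverage of a journey from each start index."""
        nxt = self.transition(move_table)
        pos = np.asarray(starts, dtype=np.int64).copy()
        visited = np.zeros((len(pos), len(self.free)), dtype=bool)
        visited[np.arange(len(pos)), pos] = True
        for _ in range(journey_length):
            pos = nxt[pos]
            visited[np.arange(len(pos)), pos] = True
        return (visited @ self.wall_adj).astype(bool).sum(axis=1)

    def coverage_all_starts(self, move_table: np.ndarray,
                            journey_length: int) -> np.ndarray:
        return self.coverage(move_table, np.arange(len(self.free)),
                             journey_length)


def write_trajectory(path, world: GridWorld, trajectory: Sequence[RobotState]) -> None:
    """Export a trajectory as TSV: step, row, column, newly credited wall cells."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("step\trow\tcol\tnew_wall_cells\n")
        seen: set[tuple[int, int]] = set()
        for st in trajectory:
            new = sorted(st.credited - seen)
            seen |= st.credited
            cells = ";".join(f"{r},{c}" for r, c in new)
            fh.write(f"{st.steps}\t{st.position[0]}\t{st.position[1]}\t{cells}\n")
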