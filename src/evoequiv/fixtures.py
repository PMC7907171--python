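"""Packaged study inputs and synthetic test surfaces.

Everything the pipeline consumes ships with the package or is generated
programmatically: transcriptions of the three published champion
wall-following programs (Sol1-Sol3), representative closed and open
labyrinth maps, seed-reproducible random worlds, the AND/XOR gate truth
tables, and a hand-written reference wall-follower used as an oracle.

Transcription notes
-------------------
Sol2 and Sol3 appear twice each in the original listing (identical
duplicated blocks); a single copy of each is stored and both parse
without intervention.  Sol1's listing ends with a dangling ", ||south"
after the bracket-balanced expression has already closed; the packaged
``sol1.txt`` is the bracket-balanced expression with that dangling tail
dropped as typesetting debris.  This is the only reading whose
exhaustive disagreement counts with Sol2 and Sol3 (2,328 and 2,312 of
4,096 states) are both consistent with the reported bound of more than
2,000; attaching "||south" as a top-level disjunct instead gives 2,000
and 1,568.  The verbatim printed fragment is kept as
``sol1_printed.txt`` so the judgment can be audited.  Italic markers
(``*s*`` etc.) around single-letter variables are typesetting and are
ignored by the parser.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from . import logic_expr, gridworld
from .logic_expr import BoolExpr, parse_expression
from .gridworld import (GridWorld, SensorReading, MOVE_ORDER, sense,
                        sensor_byte)
from .neuroevolution import GateTask

__all__ = [
    "fixture_text",
    "printed_solution_texts",
    "printed_solutions",
    "reference_labyrinths",
    "random_world",
    "gate_truth_tables",
    "reference_wall_follower",
    "reference_wall_follower_program",
    "program_from_rule",
]

_DATA = resources.files("evoequiv") / "data"


def fixture_text(name: str) -> str:
    """Raw text of a packaged fixture file."""
    return (_DATA / name).read_text(encoding="utf-8")


def printed_solution_texts() -> dict[str, str]:
    """The packaged program texts, keyed Sol1/Sol2/Sol3 (plus Sol1_printed)."""
    return {
        "Sol1": fixture_text("sol1.txt"),
        "Sol2": fixture_text("sol2.txt"),
        "Sol3": fixture_text("sol3.txt"),
        "Sol1_printed": fixture_text("sol1_printed.txt"),
    }


def printed_solutions() -> tuple[BoolExpr, BoolExpr, BoolExpr]:
    """Parsed ASTs of the three champion programs."""
    texts = printed_solution_texts()
    return tuple(parse_expression(texts[k]) for k in ("Sol1", "Sol2", "Sol3"))


def reference_labyrinths() -> tuple[GridWorld, GridWorld]:
    """A closed labyrinth (wall ring with a protruding internal wall) and
    an open one (free-bordered wall figure with a roaming apron)."""
    closed = GridWorld.from_ascii(fixture_text("closed_labyrinth.txt"))
    open_ = GridWorld.from_ascii(fixture_text("open_labyrinth.txt"))
    assert closed.topology == "closed" and open_.topology == "open"
    return closed, open_


def random_world(rng: np.random.Generator, size: int = 10,
                 density: float = 0.2) -> GridWorld:
    """Seed-reproducible random open world.

    Wall cells are sampled i.i.d. with the given density (cell (0, 0) is
    always a wall, so the density -> 0 limit leaves exactly that seed
    cell); free cells outside the largest 4-connected free component are
    then filled in, guaranteeing a single connected free region.
    """
    if size < 4:
        raise ValueError("size must be >= 4")
    if not 0.0 < density < 1.0:
        raise ValueError("density must be in (0, 1)")
    walls = rng.random((size, size)) < density
    walls[0, 0] = True
    free = np.argwhere(~walls)
    if len(free) == 0:  # pragma: no cover - density < 1 makes this vanishing
        raise ValueError("degenerate draw: no free cells")
    # flood-fill components of the free region, keep the largest
    labels = np.full(walls.shape, -1, dtype=int)
    sizes: list[int] = []
    for seed in map(tuple, free):
        if labels[seed] != -1:
            continue
        label = len(sizes)
        stack, count = [seed], 0
        labels[seed] = label
        while stack:
            r, c = stack.pop()
            count += 1
            for q in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if (0 <= q[0] < size and 0 <= q[1] < size
                        and not walls[q] and labels[q] == -1):
                    labels[q] = label
                    stack.append(q)
        sizes.append(count)
    keep = int(np.argmax(sizes))
    walls[(labels != keep) & ~walls] = True
    return GridWorld(walls, "open")


def gate_truth_tables() -> tuple[GateTask, GateTask]:
    """The canonical 4-row AND and XOR tasks."""
    inputs = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    and_task = GateTask("AND", inputs, np.array([0., 0., 0., 1.]))
    xor_task = GateTask("XOR", inputs, np.array([0., 1., 1., 0.]))
    return and_task, xor_task


# -- reference wall-follower ---------------------------------------------

def _wall_follow_rule(s: SensorReading) -> str | None:
    """Memoryless clockwise wall-following policy (wall kept on the left).

    Orthogonal-contact rules handle straight runs and concave corners,
    diagonal-only contact wraps convex corners, and with no wall in reach
    the robot drifts north until first contact.
    """
    if s.n and not s.e:
        return "east"
    if s.e and not s.s:
        return "south"
    if s.s and not s.w:
        return "west"
    if s.w and not s.n:
        return "north"
    if s.ne and not s.n and not s.e:
        return "east"
    if s.se and not s.s and not s.e:
        return "south"
    if s.sw and not s.s and not s.w:
        return "west"
    if s.nw and not s.n and not s.w:
        return "north"
    if not (s.n and s.e and s.s and s.w):
        # boxed in on some sides only: drift north if possible, else stay
        return "north" if not s.n else None
    return None


def reference_wall_follower() -> gridworld.Controller:
    """The hand-written oracle controller (not an evolved program)."""
    table = np.empty(256, dtype=np.uint8)
    for b in range(256):
        reading = SensorReading(*(bool((b >> (7 - i)) & 1) for i in range(8)))
        move = _wall_follow_rule(reading)
        table[b] = gridworld.STAY if move is None else MOVE_ORDER.index(move)

    def controller(reading: SensorReading) -> str | None:
        code = table[sensor_byte(reading)]
        return None if code == gridworld.STAY else MOVE_ORDER[code]

    controller.move_table = table
    return controller


def program_from_rule(rule) -> BoolExpr:
    """Synthesize a boolean program implementing a sensors -> move policy.

    Builds, for each direction d, the exact disjunctive normal form over
    the eight sensor variables of "the policy picks d", and nests the
    four predicates under the one-hot move interrogation: the resulting
    program behaves identically to the policy under
    :func:`evoequiv.gridworld.program_controller` semantics.
    """
    sensors = [name for name, _, _ in gridworld.COMPASS8]
    minterms: dict[str, list[BoolExpr]] = {m: [] for m in MOVE_ORDER}
    for b in range(256):
        bits = [bool((b >> (7 - i)) & 1) for i in range(8)]
        move = rule(SensorReading(*bits))
        if move is None:
            continue
        lits = [logic_expr.var(v) if bit else logic_expr.not_(logic_expr.var(v))
                for v, bit in zip(sensors, bits)]
        term = lits[0]
        for lit in lits[1:]:
            term = logic_expr.and_(term, lit)
        minterms[move].append(term)

    def dnf(terms: list[BoolExpr]) -> BoolExpr:
        if not terms:
            return logic_expr.FALSE
        out = terms[0]
        for t in terms[1:]:
            out = logic_expr.or_(out, t)
        return out

    expr = logic_expr.FALSE
    for move in reversed(MOVE_ORDER):
        expr = logic_expr.if_(logic_expr.var(move), dnf(minterms[move]), expr)
    return expr


def reference_wall_follower_program() -> BoolExpr:
    """The reference policy expressed as a boolean program tree."""
    return program_from_rule(_wall_follow_rule)
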