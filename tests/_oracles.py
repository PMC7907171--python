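"""Independently coded reference implementations used only as test oracles.

Nothing here imports the production evaluation paths it is used to
check: the interpreter below is a naive per-assignment recursion, the
sensor oracle indexes the grid directly, and the expression generator
is a plain recursive sampler.
"""

import random

from evoequiv.logic_expr import BoolExpr, VARIABLES, var, const, not_, and_, or_, if_


def interpret(node: BoolExpr, env: dict) -> bool:
    """Brute-force recursive interpreter (independent of the package's
    evaluator and of its vectorized truth-vector path)."""
    if node.kind == "const":
        return bool(node.value)
    if node.kind == "var":
        return bool(env[node.name])
    vals = [interpret(child, env) for child in node.children]
    if node.kind == "not":
        return not vals[0]
    if node.kind == "and":
        return vals[0] and vals[1]
    if node.kind == "or":
        return vals[0] or vals[1]
    if node.kind == "if":
        return vals[1] if vals[0] else vals[2]
    raise AssertionError(f"unknown kind {node.kind}")


def random_expression(rnd: random.Random, depth: int) -> BoolExpr:
    """Uniform-ish random tree, independent of the GP generator."""
    if depth <= 0 or rnd.random() < 0.3:
        if rnd.random() < 0.15:
            return const(rnd.random() < 0.5)
        return var(rnd.choice(VARIABLES))
    kind = rnd.choice(["not", "and", "or", "if"])
    if kind == "not":
        return not_(random_expression(rnd, depth - 1))
    if kind == "and":
        return and_(random_expression(rnd, depth - 1),
                    random_expression(rnd, depth - 1))
    if kind == "or":
        return or_(random_expression(rnd, depth - 1),
                   random_expression(rnd, depth - 1))
    return if_(random_expression(rnd, depth - 1),
               random_expression(rnd, depth - 1),
               random_expression(rnd, depth - 1))


def neighborhood_walls(world, position) -> set:
    """Direct grid scan of the 8-neighbourhood (sensor/credit oracle)."""
    r, c = position
    found = set()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            q = (r + dr, c + dc)
            if (0 <= q[0] < world.shape[0] and 0 <= q[1] < world.shape[1]
                    and world.walls[q]):
                found.add(q)
    return found


def leaf_multiset(expr: BoolExpr):
    """Multiset of leaf tokens, by textual scan of the serialized tree."""
    out = []
    for node in expr.walk():
        if node.kind == "var":
            out.append(node.name)
        elif node.kind == "const":
            out.append(str(node.value))
    return sorted(out)
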