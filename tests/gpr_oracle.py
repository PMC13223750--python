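"""Independent table-driven GPR evaluator and random tree generator.

Used as the oracle side of the dual-route check on GPR evaluation: this
implementation is iterative (explicit postorder table), never recursive, and
shares no code with kynpath.gpr.reaction_activity_score.
"""

import math

import numpy as np

from kynpath.gpr import And, Gene, Or


def table_eval(tree, expr, or_mode="sum"):
    """Bottom-up evaluation over an explicit postorder node table."""
    postorder = []
    stack = [(tree, False)]
    while stack:
        node, expanded = stack.pop()
        if isinstance(node, Gene) or expanded:
            postorder.append(node)
        else:
            stack.append((node, True))
            for child in node.children:
                stack.append((child, False))
    table = {}
    for node in postorder:
        if isinstance(node, Gene):
            v = expr.get(node.symbol, math.nan)
            table[id(node)] = float(v) if v is not None else math.nan
        else:
            vals = [table[id(c)] for c in node.children]
            measured = [v for v in vals if not math.isnan(v)]
            if not measured:
                table[id(node)] = math.nan
            elif isinstance(node, And):
                table[id(node)] = min(measured)
            else:
                table[id(node)] = sum(measured) if or_mode == "sum" else max(measured)
    return table[id(tree)]


GENE_POOL = [f"G{i}" for i in range(8)]


def random_gpr(rng: np.random.Generator, max_leaves: int = 6):
    """Random GPR tree with between 1 and max_leaves leaves."""
    n_leaves = int(rng.integers(1, max_leaves + 1))
    leaves = [Gene(GENE_POOL[int(rng.integers(0, len(GENE_POOL)))]) for _ in range(n_leaves)]
    nodes = leaves
    while len(nodes) > 1:
        k = int(rng.integers(2, min(3, len(nodes)) + 1))
        picked = [nodes.pop(int(rng.integers(0, len(nodes)))) for _ in range(k)]
        combo = And(tuple(picked)) if rng.random() < 0.5 else Or(tuple(picked))
        nodes.append(combo)
    return nodes[0]


def random_expr(rng: np.random.Generator, p_missing: float = 0.25):
    """Random gene -> TPM mapping over the pool, with some genes unmeasured."""
    return {
        g: float(rng.uniform(0, 100))
        for g in GENE_POOL
        if rng.random() >= p_missing
    }
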