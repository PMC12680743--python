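"""Shared fixtures and independent oracles.

The grammar oracle works on a plain-tuple representation of expressions
(('ko', id) / ('or', [...]) / ('and', [...]) / ('opt', node) / ('gap',)),
built by its own random generator and evaluated by its own recursion — it
never touches the package's parser or evaluator, so agreement between the
two is a genuine cross-check of both parsing and evaluation.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from modcomm.synthetic_data import SyntheticSpec, simulate

# --- tuple-expression oracle ----------------------------------------------


def make_random_expr(rng: np.random.Generator, kos: list[str], depth: int = 0):
    """Random expression over a fixed KO alphabet as a plain tuple tree."""
    roll = rng.random()
    if depth >= 2 or roll < 0.45:
        return ("ko", kos[rng.integers(0, len(kos))])
    if roll < 0.65:
        n = int(rng.integers(2, 4))
        return ("or", [make_random_expr(rng, kos, depth + 1) for _ in range(n)])
    if roll < 0.9:
        n = int(rng.integers(2, 4))
        children = [make_random_expr(rng, kos, depth + 1) for _ in range(n)]
        if rng.random() < 0.3:
            children.append(("opt", make_random_expr(rng, kos, depth + 2)))
        return ("and", children)
    return ("gap",)


def make_random_module_tuples(rng: np.random.Generator, kos: list[str],
                              max_steps: int = 4) -> list:
    n_steps = int(rng.integers(1, max_steps + 1))
    return [make_random_expr(rng, kos) for _ in range(n_steps)]


def tuple_to_string(node) -> str:
    kind = node[0]
    if kind == "ko":
        return node[1]
    if kind == "gap":
        return "--"
    if kind == "or":
        parts = []
        for c in node[1]:
            s = tuple_to_string(c)
            parts.append(f"({s})" if c[0] in ("or", "and") else s)
        return ",".join(parts)
    if kind == "and":
        parts = []
        for i, c in enumerate(node[1]):
            if c[0] == "opt":
                inner = tuple_to_string(c[1])
                if c[1][0] in ("or", "and"):
                    inner = f"({inner})"
                parts.append("-" + inner)
            else:
                s = tuple_to_string(c)
                if c[0] in ("or", "and"):
                    s = f"({s})"
                parts.append(s if i == 0 else "+" + s)
        return "".join(parts)
    raise ValueError(node)


def module_tuples_to_string(steps: list) -> str:
    out = []
    for s in steps:
        text = tuple_to_string(s)
        # a bare OR at step level needs no parens; AND chains neither
        out.append(text)
    return " ".join(out)


def oracle_satisfied(node, kos: set) -> bool:
    kind = node[0]
    if kind == "ko":
        return node[1] in kos
    if kind == "gap" or kind == "opt":
        return True
    if kind == "or":
        return any(oracle_satisfied(c, kos) for c in node[1])
    if kind == "and":
        required = [c for c in node[1] if c[0] != "opt"]
        return all(oracle_satisfied(c, kos) for c in required)
    raise ValueError(node)


def oracle_fractional(node, kos: set) -> float:
    kind = node[0]
    if kind == "ko":
        return float(node[1] in kos)
    if kind == "gap" or kind == "opt":
        return 1.0
    if kind == "or":
        return max(oracle_fractional(c, kos) for c in node[1])
    if kind == "and":
        required = [c for c in node[1] if c[0] != "opt"]
        if not required:
            return 1.0
        return sum(oracle_fractional(c, kos) for c in required) / len(required)
    raise ValueError(node)


def oracle_module_completeness(steps: list, kos: set, mode: str) -> float:
    if mode == "binary":
        return sum(oracle_satisfied(s, kos) for s in steps) / len(steps)
    return sum(oracle_fractional(s, kos) for s in steps) / len(steps)


def all_subsets(items):
    for r in range(len(items) + 1):
        yield from (set(c) for c in itertools.combinations(items, r))


SMALL_KOS = [f"K0000{i}" for i in range(1, 7)]  # six-KO alphabet


# --- shared fixtures -------------------------------------------------------

@pytest.fixture(scope="session")
def fixture_200():
    """The default synthetic study: ~200 species, 27 modules, strata
    0.15/0.45/0.80, complementary gt3 communities, negative couplings."""
    return simulate(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def small_fixture():
    spec = SyntheticSpec(
        seed=7,
        community_sizes=tuple([1] * 6 + [2] * 3 + [3] * 2 + [4, 5]),
        n_samples=6,
    )
    return simulate(spec)
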