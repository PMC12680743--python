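"""Parsing and evaluation of KEGG-style biosynthesis module definitions.

A module definition is a single line of text describing an ordered pathway.
Top-level space-separated units are *steps* (typically one reaction each).
Within a step, commas separate alternative enzymes or branches (OR), ``+``
joins the subunits of a protein complex (AND), ``-`` marks the following
component as optional (dispensable for satisfaction), and parentheses group
sub-expressions — including multi-step sequences that act as a single
alternative.  The literal token ``--`` is the conventional placeholder for a
step with no known enzyme and always counts as satisfied.

Operator binding, loosest to tightest: space (sequence / step separator),
comma (alternatives), ``+``/``-`` (complex chain).  So ``K1,K2 K3`` is two
steps, the first an OR, while ``(K1,K2 K3)`` inside a step is the sequence
AND(OR(K1,K2), K3).

Completeness is evaluated against a genome's KO set in two modes:

binary
    a step is satisfied or not; module completeness is the fraction of
    satisfied steps.
fractional
    a continuous analogue in [0, 1]: a KO contributes its presence, OR takes
    the best alternative (max), AND averages its required components.  This
    treats anabolic capability as a spectrum: a genome holding two of three
    complex subunits scores 2/3 rather than 0.

Both evaluators are pure functions of (expression, KO set).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Literal

__all__ = [
    "KOLeaf",
    "NoEnzyme",
    "OrNode",
    "AndNode",
    "Optional",
    "StepExpression",
    "ModuleDefinition",
    "ModuleParseError",
    "parse_definition",
    "render",
    "step_satisfied",
    "step_completeness_fractional",
    "module_completeness",
]

KO_PATTERN = re.compile(r"K\d{5}$")

ScoringMode = Literal["binary", "fractional"]


class ModuleParseError(ValueError):
    """Raised when a definition string violates the grammar."""

    def __init__(self, message: str, position: int | None = None,
                 module_id: str | None = None):
        loc = f" at position {position}" if position is not None else ""
        mod = f" in module {module_id}" if module_id else ""
        super().__init__(f"{message}{loc}{mod}")
        self.position = position
        self.module_id = module_id


# --- expression tree -------------------------------------------------------

@dataclass(frozen=True)
class KOLeaf:
    ko: str


@dataclass(frozen=True)
class NoEnzyme:
    """The ``--`` placeholder: a step with no associated enzyme."""


@dataclass(frozen=True)
class OrNode:
    children: tuple["StepExpression", ...]


@dataclass(frozen=True)
class AndNode:
    children: tuple["StepExpression", ...]


@dataclass(frozen=True)
class Optional:
    """Wrapper marking a component as dispensable (``-X`` in the grammar)."""

    child: "StepExpression"


StepExpression = KOLeaf | NoEnzyme | OrNode | AndNode | Optional


@dataclass(frozen=True)
class ModuleDefinition:
    """A parsed module: ordered steps plus identity and category."""

    module_id: str
    steps: tuple[StepExpression, ...]
    category: str | None = None
    name: str | None = None
    step_ids: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        if not self.steps:
            raise ValueError(f"module {self.module_id} has no steps")
        object.__setattr__(
            self, "step_ids",
            tuple(f"{self.module_id}_{i + 1:02d}" for i in range(len(self.steps))),
        )

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def kos(self) -> frozenset[str]:
        """All KO ids referenced anywhere in the definition."""
        out: set[str] = set()
        for step in self.steps:
            out.update(_collect_kos(step))
        return frozenset(out)


def _collect_kos(node: StepExpression) -> Iterator[str]:
    if isinstance(node, KOLeaf):
        yield node.ko
    elif isinstance(node, (OrNode, AndNode)):
        for c in node.children:
            yield from _collect_kos(c)
    elif isinstance(node, Optional):
        yield from _collect_kos(node.child)


# --- tokenizer / parser ----------------------------------------------------

_TOKEN_RE = re.compile(r"--|K\d{5}|[(),+\- ]")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            bad = re.match(r"\S+", text[pos:]).group(0)
            raise ModuleParseError(f"unrecognized token {bad!r}", pos)
        tok = m.group(0)
        if tok != " " or (tokens and tokens[-1][0] != " "):
            tokens.append((tok, pos))
        pos = m.end()
    # trim boundary spaces
    while tokens and tokens[0][0] == " ":
        tokens.pop(0)
    while tokens and tokens[-1][0] == " ":
        tokens.pop()
    return tokens


class _Parser:
    """Recursive descent over the token stream.

    sequence := alternation (SPACE alternation)*
    alternation := chain (',' chain)*
    chain := ['-'] item (('+'|'-') item)*
    item := KO | '--' | '(' sequence ')'
    """

    def __init__(self, tokens: list[tuple[str, int]]):
        self.tokens = tokens
        self.i = 0

    def _peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _pos(self) -> int:
        if self.i < len(self.tokens):
            return self.tokens[self.i][1]
        return self.tokens[-1][1] + 1 if self.tokens else 0

    def _advance(self) -> str:
        tok = self.tokens[self.i][0]
        self.i += 1
        return tok

    def parse_sequence(self) -> list[StepExpression]:
        parts = [self.parse_alternation()]
        while self._peek() == " ":
            self._advance()
            parts.append(self.parse_alternation())
        return parts

    def parse_alternation(self) -> StepExpression:
        alts = [self.parse_chain()]
        while self._peek() == ",":
            self._advance()
            if self._peek() in (None, ",", ")", " "):
                raise ModuleParseError("empty alternative", self._pos())
            alts.append(self.parse_chain())
        if len(alts) == 1:
            return alts[0]
        return OrNode(tuple(alts))

    def parse_chain(self) -> StepExpression:
        items: list[StepExpression] = []
        # a leading '-' marks the first item optional (rare but legal)
        if self._peek() == "-":
            self._advance()
            items.append(Optional(self.parse_item()))
        else:
            items.append(self.parse_item())
        while self._peek() in ("+", "-"):
            op = self._advance()
            if self._peek() in (None, "+", "-", ",", ")", " "):
                raise ModuleParseError(f"dangling operator {op!r}", self._pos())
            item = self.parse_item()
            items.append(Optional(item) if op == "-" else item)
        if len(items) == 1:
            return items[0]
        return AndNode(tuple(items))

    def parse_item(self) -> StepExpression:
        tok = self._peek()
        if tok is None:
            raise ModuleParseError("unexpected end of definition", self._pos())
        if tok == "(":
            self._advance()
            inner = self.parse_sequence()
            if self._peek() != ")":
                raise ModuleParseError("unbalanced parentheses", self._pos())
            self._advance()
            if len(inner) == 1:
                return inner[0]
            return AndNode(tuple(inner))
        if tok == "--":
            self._advance()
            return NoEnzyme()
        if KO_PATTERN.match(tok):
            self._advance()
            return KOLeaf(tok)
        raise ModuleParseError(f"unexpected token {tok!r}", self._pos())


def parse_definition(definition: str, module_id: str = "M00000",
                     category: str | None = None,
                     name: str | None = None) -> ModuleDefinition:
    """Parse a definition string into an ordered-step :class:`ModuleDefinition`.

    Raises :class:`ModuleParseError` (with character position and module id)
    on unbalanced parentheses, dangling operators or empty alternatives.
    """
    definition = " ".join(definition.split())  # normalize whitespace
    if definition.count("(") != definition.count(")"):
        raise ModuleParseError("unbalanced parentheses", module_id=module_id)
    try:
        tokens = _tokenize(definition)
        if not tokens:
            raise ModuleParseError("empty definition")
        parser = _Parser(tokens)
        steps = parser.parse_sequence()
        if parser.i != len(parser.tokens):
            raise ModuleParseError("trailing input", parser._pos())
    except ModuleParseError as err:
        raise ModuleParseError(str(err).split(" at position")[0],
                               err.position, module_id) from None
    return ModuleDefinition(module_id=module_id, steps=tuple(steps),
                            category=category, name=name)


# --- canonical rendering ---------------------------------------------------

def render(node_or_module: StepExpression | ModuleDefinition) -> str:
    """Render a tree (or whole module) back to a canonical definition string.

    ``parse_definition(render(m)) `` reproduces an identical tree.
    """
    if isinstance(node_or_module, ModuleDefinition):
        return " ".join(_render(s, top=True) for s in node_or_module.steps)
    return _render(node_or_module, top=True)


def _render(node: StepExpression, top: bool = False) -> str:
    if isinstance(node, KOLeaf):
        return node.ko
    if isinstance(node, NoEnzyme):
        return "--"
    if isinstance(node, Optional):
        # only legal inside a chain; rendered by the AndNode branch
        return "-" + _render_item(node.child)
    if isinstance(node, OrNode):
        text = ",".join(_render_chain(c) for c in node.children)
        return text if top else f"({text})"
    if isinstance(node, AndNode):
        parts = []
        for i, c in enumerate(node.children):
            if isinstance(c, Optional):
                parts.append("-" + _render_item(c.child))
            elif i == 0:
                parts.append(_render_item(c))
            else:
                parts.append("+" + _render_item(c))
        return "".join(parts)
    raise TypeError(f"not an expression node: {node!r}")


def _render_chain(node: StepExpression) -> str:
    if isinstance(node, (OrNode,)):
        return f"({_render(node, top=True)})"
    return _render(node, top=False)


def _render_item(node: StepExpression) -> str:
    if isinstance(node, (OrNode, AndNode)):
        return f"({_render(node, top=True)})"
    return _render(node, top=False)


# --- evaluation ------------------------------------------------------------

def step_satisfied(step: StepExpression, kos: frozenset[str] | set[str]) -> bool:
    """Binary satisfaction of one step expression by a KO set.

    OR is true if any alternative is true; AND if every non-optional child
    is true; a KO leaf iff the KO is present; ``--`` always; optional
    components never affect the outcome.  An AND whose children are all
    optional is vacuously satisfied.
    """
    if isinstance(step, KOLeaf):
        return step.ko in kos
    if isinstance(step, NoEnzyme):
        return True
    if isinstance(step, Optional):
        return True
    if isinstance(step, OrNode):
        return any(step_satisfied(c, kos) for c in step.children)
    if isinstance(step, AndNode):
        return all(step_satisfied(c, kos)
                   for c in step.children if not isinstance(c, Optional))
    raise TypeError(f"not an expression node: {step!r}")


def step_completeness_fractional(step: StepExpression,
                                 kos: frozenset[str] | set[str]) -> float:
    """Continuous completeness of one step in [0, 1].

    Leaf → presence indicator; OR → max over alternatives; AND → mean over
    non-optional children; ``--`` → 1.  An AND of only optional components
    scores 1 (nothing is required).
    """
    if isinstance(step, KOLeaf):
        return 1.0 if step.ko in kos else 0.0
    if isinstance(step, NoEnzyme):
        return 1.0
    if isinstance(step, Optional):
        return 1.0
    if isinstance(step, OrNode):
        return max(step_completeness_fractional(c, kos) for c in step.children)
    if isinstance(step, AndNode):
        required = [c for c in step.children if not isinstance(c, Optional)]
        if not required:
            return 1.0
        return sum(step_completeness_fractional(c, kos)
                   for c in required) / len(required)
    raise TypeError(f"not an expression node: {step!r}")


def module_completeness(module: ModuleDefinition,
                        kos: frozenset[str] | set[str],
                        mode: ScoringMode = "binary") -> float:
    """Module completeness in [0, 1] against a genome's KO set.

    ``binary``: fraction of steps whose expression is satisfied.
    ``fractional``: mean of per-step continuous completeness; always at
    least the binary value.
    """
    if mode == "binary":
        return sum(step_satisfied(s, kos) for s in module.steps) / module.n_steps
    if mode == "fractional":
        return sum(step_completeness_fractional(s, kos)
                   for s in module.steps) / module.n_steps
    raise ValueError(f"unknown scoring mode {mode!r}")
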