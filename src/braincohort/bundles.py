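"""Logic bundles: boolean expressions over streamline crossing predicates.

A fiber bundle is defined by which regions its streamlines do or do not
traverse: "the fibers that go through structure A or ROI B but that don't
cross structure C" is the expression ``(A | B) & ~C``.  Leaves name either a
sphere ROI or a set of labels in an anatomical label map; operators are
``&`` (intersection), ``|`` (union) and ``~`` (complement **within the
supplied whole-brain universe**, matching the "don't cross" reading on a
finite fiber set).  Precedence is ``~`` > ``&`` > ``|``; parentheses group.

Crossing is tested along the whole trajectory.  For label maps the polyline
is densified to half the minimum voxel spacing so no traversed voxel can be
skipped, and each point is assigned to its nearest voxel (labels are
categorical — no interpolation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError, UnknownReferenceError, ValidationError
from .imaging import LabelMap, StreamlineSet
from .roi import SphereROI, densify_polyline, streamlines_crossing_sphere
from .spaces import world_to_voxel

# ---------------------------------------------------------------------------
# Expression tree + parser
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Leaf:
    name: str


@dataclass(frozen=True)
class Not:
    child: "BundleExpr"


@dataclass(frozen=True)
class And:
    left: "BundleExpr"
    right: "BundleExpr"


@dataclass(frozen=True)
class Or:
    left: "BundleExpr"
    right: "BundleExpr"


BundleExpr = Leaf | Not | And | Or

_TOKEN = re.compile(r"\s*(?:(?P<ident>[A-Za-z_][A-Za-z0-9_]*)|(?P<op>[&|~()]))")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise ParseError(f"unexpected character {stripped[0]!r}",
                             len(text) - len(stripped))
        tokens.append((m.group("ident") or m.group("op"), m.start("ident")
                       if m.group("ident") else m.start("op")))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent over:  or := and ('|' and)* ;  and := unary ('&' unary)* ;
    unary := '~' unary | ident | '(' or ')'."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def pos(self):
        return self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.text)

    def take(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> BundleExpr:
        if not self.tokens:
            raise ParseError("empty expression", 0)
        expr = self.parse_or()
        if self.i < len(self.tokens):
            raise ParseError(f"unexpected token {self.peek()!r}", self.pos())
        return expr

    def parse_or(self) -> BundleExpr:
        node = self.parse_and()
        while self.peek() == "|":
            self.take()
            node = Or(node, self.parse_and())
        return node

    def parse_and(self) -> BundleExpr:
        node = self.parse_unary()
        while self.peek() == "&":
            self.take()
            node = And(node, self.parse_unary())
        return node

    def parse_unary(self) -> BundleExpr:
        tok = self.peek()
        if tok is None:
            raise ParseError("dangling operator", len(self.text))
        if tok == "~":
            self.take()
            return Not(self.parse_unary())
        if tok == "(":
            open_pos = self.pos()
            self.take()
            node = self.parse_or()
            if self.peek() != ")":
                raise ParseError("unbalanced parenthesis", open_pos)
            self.take()
            return node
        if tok in {"&", "|", ")"}:
            raise ParseError(f"unexpected token {tok!r}", self.pos())
        self.take()
        return Leaf(tok)


def parse_bundle_expr(text: str) -> BundleExpr:
    """Parse expression text into a canonical tree (n-ary ops folded left)."""
    return _Parser(text).parse()


def format_bundle_expr(expr: BundleExpr) -> str:
    """Pretty-print a tree; re-parsing the output gives an equivalent tree."""
    if isinstance(expr, Leaf):
        return expr.name
    if isinstance(expr, Not):
        inner = format_bundle_expr(expr.child)
        return f"~{inner}" if isinstance(expr.child, (Leaf, Not)) else f"~({inner})"
    op = "&" if isinstance(expr, And) else "|"

    def wrap(child, right: bool):
        s = format_bundle_expr(child)
        needs = isinstance(expr, And) and isinstance(child, Or)
        # the grammar folds left, so a right child of the same operator
        # must keep its parentheses to reproduce the tree shape
        needs = needs or (right and type(child) is type(expr))
        return f"({s})" if needs else s

    return f"{wrap(expr.left, False)} {op} {wrap(expr.right, True)}"


# ---------------------------------------------------------------------------
# Crossing predicates + evaluation
# ---------------------------------------------------------------------------


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def streamline_crosses_label(line: np.ndarray, lm: LabelMap,
                             labels: set[int]) -> bool:
    """True iff the densified polyline visits a voxel whose label is in the set.

    Points are assigned to the nearest voxel with round-half-away-from-zero
    on the continuous voxel index; points falling outside the grid simply do
    not cross.
    """
    if not labels:
        raise ValidationError("label set must be non-empty")
    spacing = np.linalg.norm(lm.voxel_to_world.linear, axis=0)
    dense = densify_polyline(np.asarray(line, dtype=float), float(spacing.min()) / 2.0)
    vox = _round_half_away(world_to_voxel(lm.voxel_to_world, dense)).astype(int)
    shape = np.array(lm.data.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    if not np.any(inside):
        return False
    v = vox[inside]
    hit = lm.data[v[:, 0], v[:, 1], v[:, 2]]
    return bool(np.isin(hit, list(labels)).any())


@dataclass
class EvalContext:
    """Everything a bundle expression's leaves can refer to, in one space."""

    universe: StreamlineSet
    structures: dict[str, tuple[LabelMap, set[int]]] = field(default_factory=dict)
    rois: dict[str, SphereROI] = field(default_factory=dict)

    def leaf_ids(self, name: str) -> frozenset[int]:
        """Id-set of universe streamlines crossing the named structure/ROI."""
        if name in self.rois:
            hit = streamlines_crossing_sphere(self.universe, self.rois[name])
            return frozenset(int(i) for i in hit.ids)
        if name in self.structures:
            lm, labels = self.structures[name]
            return frozenset(
                int(i) for line, i in zip(self.universe.streamlines,
                                          self.universe.ids)
                if streamline_crosses_label(line, lm, labels))
        raise UnknownReferenceError(
            f"expression leaf {name!r} matches no structure or ROI in context")


def _eval_ids(expr: BundleExpr, ctx: EvalContext,
              cache: dict[str, frozenset[int]], universe: frozenset[int]) -> frozenset[int]:
    if isinstance(expr, Leaf):
        if expr.name not in cache:
            cache[expr.name] = ctx.leaf_ids(expr.name)
        return cache[expr.name]
    if isinstance(expr, Not):
        return universe - _eval_ids(expr.child, ctx, cache, universe)
    left = _eval_ids(expr.left, ctx, cache, universe)
    right = _eval_ids(expr.right, ctx, cache, universe)
    return left & right if isinstance(expr, And) else left | right


def eval_bundle(expr: BundleExpr | str, ctx: EvalContext) -> StreamlineSet:
    """Evaluate a logic-bundle expression to a subset of the universe.

    Leaf results are memoized per call (a leaf appearing twice is tested
    once); the result preserves the original streamline ids and ordering.
    """
    if isinstance(expr, str):
        expr = parse_bundle_expr(expr)
    universe_ids = frozenset(int(i) for i in ctx.universe.ids)
    ids = _eval_ids(expr, ctx, {}, universe_ids)
    return ctx.universe.subset(ids)
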