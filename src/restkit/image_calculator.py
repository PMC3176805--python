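"""A small expression calculator over images and image groups.

Expressions refer to individual images as ``i1, i2, ...`` and to groups
of images as ``g1, g2, ...``.  Supported constructs: elementwise
``+ - * /`` (with the MATLAB spellings ``.*`` and ``./`` accepted as
synonyms), comparisons ``> < >= <=`` yielding {0,1} masks, parentheses,
numeric literals, and the functions ``mean(g)``, ``std(g)`` (sample
standard deviation, n-1 denominator) and ``corr(a, b, "temporal" |
"spatial")``.

Group semantics: a group op a scalar/image applies per member; a group
op a group applies pairwise to corresponding members (equal sizes
required, pairing by the caller's binding order — conventionally sorted
filename order).  ``mean``/``std`` reduce a group to one image.
Typical uses: ``g1 - 1``, ``g1 .* (i1 > 100)`` (mask a group by a
binarized image), ``(i1 - mean(g1)) ./ std(g1)`` (a z-score map of one
subject against a group).

Division by zero yields 0 at those voxels with a QC count — never NaN.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = ["parse", "evaluate", "corr_group", "CalcExpression", "ParseError", "CalcResult"]


class ParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass
class Node:
    kind: str  # num | operand | binop | unary | call
    value: object = None
    children: Tuple["Node", ...] = ()


CalcExpression = Node

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<op>\.\*|\./|>=|<=|[-+*/><(),])"
    r"|(?P<name>[A-Za-z_]\w*)"
    r"|(?P<str>'[^']*'|\"[^\"]*\"))"
)


def _tokenize(text: str) -> List[Tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            at = len(text) - len(stripped)
            raise ParseError(f"unexpected character {text[at]!r}", at + 1)
        if m.end() == m.start():  # only whitespace left
            break
        for kind in ("num", "op", "name", "str"):
            val = m.group(kind)
            if val is not None:
                tokens.append((kind, val, m.start(kind) + 1))
                break
        pos = m.end()
    return tokens


_FUNCTIONS = {"mean", "std", "corr"}


class _Parser:
    """Recursive descent; precedence comparison < additive < multiplicative < unary."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> Optional[Tuple[str, str, int]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> Tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of expression", len(self.text) + 1)
        self.i += 1
        return tok

    def expect(self, op: str) -> None:
        tok = self.peek()
        if tok is None or tok[0] != "op" or tok[1] != op:
            at = tok[2] if tok else len(self.text) + 1
            raise ParseError(f"expected {op!r}", at)
        self.i += 1

    def parse(self) -> Node:
        node = self.comparison()
        if self.peek() is not None:
            tok = self.peek()
            raise ParseError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def comparison(self) -> Node:
        node = self.additive()
        while (tok := self.peek()) and tok[0] == "op" and tok[1] in (">", "<", ">=", "<="):
            self.next()
            node = Node("binop", tok[1], (node, self.additive()))
        return node

    def additive(self) -> Node:
        node = self.multiplicative()
        while (tok := self.peek()) and tok[0] == "op" and tok[1] in ("+", "-"):
            self.next()
            node = Node("binop", tok[1], (node, self.multiplicative()))
        return node

    def multiplicative(self) -> Node:
        node = self.unary()
        while (tok := self.peek()) and tok[0] == "op" and tok[1] in ("*", "/", ".*", "./"):
            self.next()
            op = {"*": "*", ".*": "*", "/": "/", "./": "/"}[tok[1]]
            node = Node("binop", op, (node, self.unary()))
        return node

    def unary(self) -> Node:
        tok = self.peek()
        if tok and tok[0] == "op" and tok[1] in ("+", "-"):
            self.next()
            child = self.unary()
            return child if tok[1] == "+" else Node("unary", "-", (child,))
        return self.atom()

    def atom(self) -> Node:
        tok = self.next()
        kind, val, at = tok
        if kind == "num":
            return Node("num", float(val))
        if kind == "op" and val == "(":
            node = self.comparison()
            self.expect(")")
            return node
        if kind == "name":
            if val in _FUNCTIONS:
                self.expect("(")
                args: List[Node] = [self.comparison()]
                while (t := self.peek()) and t[0] == "op" and t[1] == ",":
                    self.next()
                    nxt = self.peek()
                    if nxt and nxt[0] == "str":
                        self.next()
                        args.append(Node("num", nxt[1].strip("'\"")))
                    else:
                        args.append(self.comparison())
                self.expect(")")
                if val in ("mean", "std") and len(args) != 1:
                    raise ParseError(f"{val}() takes exactly one group argument", at)
                if val == "corr" and len(args) not in (2, 3):
                    raise ParseError("corr() takes (a, b[, mode])", at)
                return Node("call", val, tuple(args))
            if re.fullmatch(r"[ig]\d+", val):
                return Node("operand", val)
            raise ParseError(f"unknown name {val!r}", at)
        raise ParseError(f"unexpected token {val!r}", at)


def parse(expr: str) -> CalcExpression:
    """Parse a calculator expression into an AST; errors carry a position."""
    if not expr or not expr.strip():
        raise ParseError("empty expression", 1)
    return _Parser(expr).parse()


def unparse(node: Node) -> str:
    """Render an AST back to canonical expression text."""
    if node.kind == "num":
        return repr(node.value) if isinstance(node.value, str) else f"{node.value:g}"
    if node.kind == "operand":
        return str(node.value)
    if node.kind == "unary":
        return f"(-{unparse(node.children[0])})"
    if node.kind == "binop":
        a, b = node.children
        return f"({unparse(a)} {node.value} {unparse(b)})"
    if node.kind == "call":
        return f"{node.value}({', '.join(unparse(c) for c in node.children)})"
    raise ValueError(node.kind)


# ---------------------------------------------------------------------------
# evaluation

Image = np.ndarray
Group = List[np.ndarray]
CalcResult = Union[float, Image, Group, pd.DataFrame]


class _QC:
    def __init__(self) -> None:
        self.div_zero_voxels = 0


def _collect_operands(node: Node, out: set) -> None:
    if node.kind == "operand":
        out.add(node.value)
    for c in node.children:
        _collect_operands(c, out)


def _binop(op: str, a, b, qc: _QC):
    if isinstance(a, list) and isinstance(b, list):
        if len(a) != len(b):
            raise ValueError(f"group arity mismatch: {len(a)} vs {len(b)}")
        return [_binop(op, x, y, qc) for x, y in zip(a, b)]
    if isinstance(a, list):
        return [_binop(op, x, b, qc) for x in a]
    if isinstance(b, list):
        return [_binop(op, a, y, qc) for y in b]
    if op == "+":
        return a + b
    if op == "-":
        return a - b
    if op == "*":
        return a * b
    if op == "/":
        b_arr = np.asarray(b, dtype=float)
        zero = b_arr == 0
        n_zero = int(np.count_nonzero(zero))
        if n_zero:
            qc.div_zero_voxels += n_zero * (np.size(a) // max(np.size(b_arr), 1) or 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                out = np.where(zero, 0.0, a / np.where(zero, 1.0, b_arr))
            return out
        return a / b
    if op in (">", "<", ">=", "<="):
        fn = {">": np.greater, "<": np.less, ">=": np.greater_equal, "<=": np.less_equal}[op]
        return fn(a, b).astype(float)
    raise ValueError(op)


def _eval(node: Node, bindings: Dict[str, Union[Image, Group]], qc: _QC):
    if node.kind == "num":
        return node.value
    if node.kind == "operand":
        name = node.value
        if name not in bindings:
            raise ValueError(f"unbound operand {name!r}")
        val = bindings[name]
        if str(name).startswith("g"):
            return [np.asarray(v, dtype=float) for v in val]
        return np.asarray(val, dtype=float)
    if node.kind == "unary":
        child = _eval(node.children[0], bindings, qc)
        return [-c for c in child] if isinstance(child, list) else -child
    if node.kind == "binop":
        a = _eval(node.children[0], bindings, qc)
        b = _eval(node.children[1], bindings, qc)
        return _binop(node.value, a, b, qc)
    if node.kind == "call":
        if node.value in ("mean", "std"):
            arg = _eval(node.children[0], bindings, qc)
            if not isinstance(arg, list):
                raise ValueError(f"{node.value}() needs a group argument")
            stack = np.stack(arg)
            return stack.mean(axis=0) if node.value == "mean" else stack.std(axis=0, ddof=1)
        if node.value == "corr":
            a = _eval(node.children[0], bindings, qc)
            b = _eval(node.children[1], bindings, qc)
            mode = "temporal"
            if len(node.children) == 3:
                mode = str(node.children[2].value)
            return corr_group(a if isinstance(a, list) else [a],
                              b if isinstance(b, list) else [b], mode=mode)
    raise ValueError(node.kind)


def evaluate(
    ast: Union[CalcExpression, str],
    bindings: Dict[str, Union[Image, Group]],
) -> Tuple[CalcResult, Dict[str, int]]:
    """Evaluate an expression (or AST) against operand bindings.

    Bindings map ``i<k>`` to one array and ``g<k>`` to a list of arrays
    sharing one grid.  Returns (result, qc) where the result type
    follows the root node: image, group of images, or — for spatial
    correlation — a table.
    """
    if isinstance(ast, str):
        ast = parse(ast)
    needed: set = set()
    _collect_operands(ast, needed)
    missing = sorted(needed - set(bindings))
    if missing:
        raise ValueError(f"unbound operand(s): {missing}")
    shapes = set()
    for name in needed:
        val = bindings[name]
        items = val if str(name).startswith("g") else [val]
        for item in items:
            shapes.add(np.asarray(item).shape)
    if len(shapes) > 1:
        raise ValueError(f"operands on different grids: {sorted(shapes)}")
    qc = _QC()
    result = _eval(ast, bindings, qc)
    return result, {"div_zero_voxels": qc.div_zero_voxels}


def corr_group(g1: Group, g2: Group, mode: str = "temporal",
               mask: Optional[np.ndarray] = None) -> Union[Image, pd.DataFrame]:
    """Correlate two image groups temporally or spatially.

    ``temporal``: per-voxel Pearson r across the group/time dimension.
    Two single 4D images correlate their per-voxel time series; two
    groups of 3D images correlate across subjects (e.g. ReHo vs ALFF
    voxel-wise across participants).  Zero-variance voxels get r = 0.

    ``spatial``: one r per corresponding image pair, over all voxels
    (restricted to ``mask`` if given), returned as a table with columns
    (pair, r, n_voxels).
    """
    if mode not in ("temporal", "spatial"):
        raise ValueError("mode must be 'temporal' or 'spatial'")
    g1 = [np.asarray(v, dtype=float) for v in g1]
    g2 = [np.asarray(v, dtype=float) for v in g2]
    if mode == "temporal":
        a = g1[0] if len(g1) == 1 and g1[0].ndim == 4 else np.stack(g1, axis=-1)
        b = g2[0] if len(g2) == 1 and g2[0].ndim == 4 else np.stack(g2, axis=-1)
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
        if a.shape[-1] < 3:
            raise ValueError("temporal correlation needs series length >= 3")
        ac = a - a.mean(axis=-1, keepdims=True)
        bc = b - b.mean(axis=-1, keepdims=True)
        sa = np.sqrt((ac**2).sum(axis=-1))
        sb = np.sqrt((bc**2).sum(axis=-1))
        bad = (sa == 0) | (sb == 0)
        denom = np.where(bad, 1.0, sa * sb)
        r = (ac * bc).sum(axis=-1) / denom
        r[bad] = 0.0
        return np.clip(r, -1.0, 1.0)
    if len(g1) != len(g2):
        raise ValueError(f"group arity mismatch: {len(g1)} vs {len(g2)}")
    rows = []
    for k, (a, b) in enumerate(zip(g1, g2)):
        sel = mask.astype(bool) if mask is not None else np.ones(a.shape, dtype=bool)
        av, bv = a[sel], b[sel]
        flagged = av.std() == 0 or bv.std() == 0
        r = 0.0 if flagged else float(np.corrcoef(av, bv)[0, 1])
        rows.append({"pair": k + 1, "r": r, "n_voxels": int(sel.sum()),
                     "zero_variance": bool(flagged)})
    return pd.DataFrame(rows)
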