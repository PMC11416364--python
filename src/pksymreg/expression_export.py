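"""Closed-form expression trees extracted from pruned networks.

The tree node set mirrors exactly what the network can express — constants,
normalized covariate symbols, +, *, guarded division, guarded power and
absolute value — and evaluation applies the *same* guard conventions as the
network, so an extracted tree reproduces the network forward pass to
floating-point accuracy.  The |.| produced by the output base expression is
dropped only when interval arithmetic over the normalized covariate domain
proves the argument sign-definite.

Also ships the published propofol covariate model as an executable fixture
(rate constants in 1/s, V1 in L, covariates normalized by age 88 y,
weight 160 kg, BMI 52.8 kg/m^2; gender/site encoded ±0.5).
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._exceptions import EvaluationError
from .pk_model import PARAM_NAMES, PKRates
from .symreg_network import (
    COVARIATE_NAMES,
    EPS_DIV,
    EPS_POW,
    NormalizationSpec,
    SymRegNetworkBank,
    normalize,
)

__all__ = [
    "Expr", "Const", "Var", "Add", "Mul", "Div", "Pow", "AbsOp",
    "ExpressionTree", "extract_expression", "evaluate_expression",
    "published_trees", "published_model", "render", "parse",
]

#: symbols used in rendered expressions, by covariate index
VAR_NAMES = ("AGE_n", "WGT_n", "BMI_n", "SEX", "SITE")


# ---------------------------------------------------------------------------
# nodes
# ---------------------------------------------------------------------------


class Expr:
    def eval(self, env: Mapping[str, float]) -> float:  # pragma: no cover
        raise NotImplementedError

    def variables(self) -> set:
        out: set = set()
        for c in getattr(self, "children", ()):
            out |= c.variables()
        return out

    def __repr__(self) -> str:
        return f"<{type(self).__name__}: {render(self)}>"


@dataclass(repr=False)
class Const(Expr):
    value: float
    children = ()

    def eval(self, env):
        return self.value


@dataclass(repr=False)
class Var(Expr):
    name: str
    children = ()

    def eval(self, env):
        try:
            return env[self.name]
        except KeyError:
            raise EvaluationError(f"no value supplied for symbol {self.name!r}")

    def variables(self):
        return {self.name}


@dataclass(repr=False)
class Add(Expr):
    children: tuple

    def eval(self, env):
        return sum(c.eval(env) for c in self.children)


@dataclass(repr=False)
class Mul(Expr):
    children: tuple

    def eval(self, env):
        out = 1.0
        for c in self.children:
            out *= c.eval(env)
        return out


@dataclass(repr=False)
class Div(Expr):
    """num / den with the network's denominator guard."""

    children: tuple  # (num, den)

    def eval(self, env):
        num, den = (c.eval(env) for c in self.children)
        g = math.copysign(max(abs(den), EPS_DIV), 1.0 if den >= 0 else -1.0)
        return num / g


@dataclass(repr=False)
class Pow(Expr):
    """|base|^expo with |base| floored at EPS_POW (the network's power guard)."""

    children: tuple  # (base, expo)

    def eval(self, env):
        base, expo = (c.eval(env) for c in self.children)
        return max(abs(base), EPS_POW) ** expo


@dataclass(repr=False)
class AbsOp(Expr):
    children: tuple  # (arg,)

    def eval(self, env):
        return abs(self.children[0].eval(env))


#: an ExpressionTree maps each PK parameter name to its root node
ExpressionTree = dict


# ---------------------------------------------------------------------------
# constant folding
# ---------------------------------------------------------------------------


def _is_const(e: Expr, v: float | None = None) -> bool:
    return isinstance(e, Const) and (v is None or e.value == v)


def fold(e: Expr) -> Expr:
    """Bottom-up constant folding plus zero/one elimination."""
    if isinstance(e, (Const, Var)):
        return e
    kids = tuple(fold(c) for c in e.children)
    if all(isinstance(k, Const) for k in kids):
        return Const(type(e)(kids).eval({}))
    if isinstance(e, Add):
        flat = []
        for k in kids:
            flat.extend(k.children if isinstance(k, Add) else (k,))
        csum = sum(k.value for k in flat if isinstance(k, Const))
        rest = [k for k in flat if not isinstance(k, Const)]
        if csum != 0.0:
            rest.append(Const(csum))
        if not rest:
            return Const(0.0)
        return rest[0] if len(rest) == 1 else Add(tuple(rest))
    if isinstance(e, Mul):
        flat = []
        for k in kids:
            flat.extend(k.children if isinstance(k, Mul) else (k,))
        if any(_is_const(k, 0.0) for k in flat):
            return Const(0.0)
        cprod = 1.0
        rest = []
        for k in flat:
            if isinstance(k, Const):
                cprod *= k.value
            else:
                rest.append(k)
        if cprod != 1.0 or not rest:
            rest.insert(0, Const(cprod))
        return rest[0] if len(rest) == 1 else Mul(tuple(rest))
    return type(e)(kids)


# ---------------------------------------------------------------------------
# interval arithmetic (used to prove sign-definiteness for abs-elimination)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Iv:
    lo: float
    hi: float

    def __add__(self, o):
        return _Iv(self.lo + o.lo, self.hi + o.hi)

    def __mul__(self, o):
        c = (self.lo * o.lo, self.lo * o.hi, self.hi * o.lo, self.hi * o.hi)
        return _Iv(min(c), max(c))

    def scale(self, a: float):
        return _Iv(a * self.lo, a * self.hi) if a >= 0 else _Iv(a * self.hi, a * self.lo)

    def shift(self, a: float):
        return _Iv(self.lo + a, self.hi + a)


def _iv_abs(iv: _Iv) -> _Iv:
    if iv.lo >= 0:
        return iv
    if iv.hi <= 0:
        return _Iv(-iv.hi, -iv.lo)
    return _Iv(0.0, max(-iv.lo, iv.hi))


def _iv_pow(base: _Iv, expo: _Iv) -> _Iv:
    a = _iv_abs(base)
    a = _Iv(max(a.lo, EPS_POW), max(a.hi, EPS_POW))
    la = _Iv(math.log(a.lo), math.log(a.hi))
    prod = expo * la
    return _Iv(math.exp(prod.lo), math.exp(prod.hi))


def _iv_div(num: _Iv, den: _Iv) -> _Iv:
    if den.lo > 0 or den.hi < 0:
        lo = math.copysign(max(abs(den.lo), EPS_DIV), den.lo)
        hi = math.copysign(max(abs(den.hi), EPS_DIV), den.hi)
    else:  # straddles zero: guarded denominator reaches ±EPS_DIV
        return num * _Iv(-1.0 / EPS_DIV, 1.0 / EPS_DIV)
    inv = _Iv(1.0 / hi, 1.0 / lo)
    return num * inv


def _iv_affine(W, b, ivs):
    out = []
    for i in range(W.shape[0]):
        acc = _Iv(b[i], b[i])
        for j, iv in enumerate(ivs):
            acc = acc + iv.scale(float(W[i, j]))
        out.append(acc)
    return out


def _output_interval(net, domains) -> _Iv:
    """Interval of the final pre-|.| scalar z3 over the covariate box."""
    l1, l2, l3 = net.layers
    z1 = _iv_affine(l1.W, l1.b, domains)
    x2 = [z1[0], z1[1] * z1[2], _iv_pow(z1[3], z1[4])]
    z2 = _iv_affine(l2.W, l2.b, x2)
    x3 = [z2[0], z2[1] * z2[2], _iv_div(z2[3], z2[4].shift(1.0))]
    z3 = _iv_affine(l3.W, l3.b, x3)
    return z3[0]


_DEFAULT_DOMAINS = (
    _Iv(0.0, 1.0), _Iv(0.0, 1.0), _Iv(0.0, 1.0), _Iv(-0.5, 0.5), _Iv(-0.5, 0.5),
)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def _affine_trees(W, b, W_mask, b_mask, inputs):
    out = []
    for i in range(W.shape[0]):
        terms = []
        for j, x in enumerate(inputs):
            if W_mask[i, j]:
                terms.append(Mul((Const(float(W[i, j])), x)))
        if b_mask[i]:
            terms.append(Const(float(b[i])))
        out.append(Add(tuple(terms)) if terms else Const(0.0))
    return out


def extract_expression(bank: SymRegNetworkBank) -> ExpressionTree:
    """Transcribe each network into a closed-form tree (any mask state).

    Masked entries are omitted, constants are folded, and the output |.| is
    dropped (or replaced by sign flip) only when interval arithmetic over the
    normalized covariate domain proves the argument sign-definite.
    """
    trees: ExpressionTree = {}
    for name, net in bank.networks.items():
        l1, l2, l3 = net.layers
        phi = [Var(VAR_NAMES[j]) for j in range(net.n_phi)]
        z1 = _affine_trees(l1.W, l1.b, l1.W_mask, l1.b_mask, phi)
        x2 = [z1[0], Mul((z1[1], z1[2])), Pow((z1[3], z1[4]))]
        z2 = _affine_trees(l2.W, l2.b, l2.W_mask, l2.b_mask, x2)
        x3 = [z2[0], Mul((z2[1], z2[2])),
              Div((z2[3], Add((z2[4], Const(1.0)))))]
        z3 = _affine_trees(l3.W, l3.b, l3.W_mask, l3.b_mask, x3)[0]
        iv = _output_interval(net, _DEFAULT_DOMAINS[: net.n_phi])
        if iv.lo >= 0.0:
            tree: Expr = z3
        elif iv.hi <= 0.0:
            tree = Mul((Const(-1.0), z3))
        else:
            tree = AbsOp((z3,))
        trees[name] = fold(tree)
    return trees


def evaluate_expression(
    tree: Expr,
    raw_covariates: Mapping[str, object],
    spec: NormalizationSpec | None = None,
) -> float:
    """Evaluate a tree on raw covariates, normalizing with the given spec."""
    spec = spec or NormalizationSpec()
    missing = {"age", "weight", "bmi", "gender", "site"} - set(raw_covariates)
    needed = tree.variables()
    # sampling-site / gender symbols may be absent if unused by the tree
    required_raw = set()
    for sym in needed:
        required_raw.add(COVARIATE_NAMES[VAR_NAMES.index(sym)])
    if required_raw & missing:
        raise EvaluationError(
            f"missing covariates {sorted(required_raw & missing)}"
        )
    full = dict(raw_covariates)
    full.setdefault("age", 0.0)
    full.setdefault("weight", spec.weight_max)
    full.setdefault("bmi", spec.bmi_max)
    full.setdefault("gender", next(iter(spec.gender_map)))
    full.setdefault("site", next(iter(spec.site_map)))
    import warnings as _w

    with _w.catch_warnings():
        if missing:  # defaults are placeholders; don't warn about them
            _w.simplefilter("ignore")
        vec = normalize(full, spec)
    env = dict(zip(VAR_NAMES, vec))
    return float(tree.eval(env))


# ---------------------------------------------------------------------------
# the published covariate model (executable fixture)
# ---------------------------------------------------------------------------


def published_trees() -> ExpressionTree:
    """The published six-parameter covariate model as expression trees.

    Gender enters through the ±0.5 SEX symbol, which reproduces the printed
    per-gender coefficient pairs (e.g. 0.00416 * (±0.5) = ±0.00208).  The
    sampling-site covariate was pruned away and does not appear.
    """
    a, w, b, s = Var("AGE_n"), Var("WGT_n"), Var("BMI_n"), Var("SEX")

    def lin(*terms):
        return Add(tuple(
            Mul((Const(c), *syms)) if syms else Const(c) for c, *syms in terms
        ))

    k10 = lin((0.00441, w), (0.00342,))
    k12 = AbsOp((Div((
        lin((0.158, a), (-0.00431, b), (-0.188,)),
        lin((0.64, a), (-0.0174, b), (-0.743,)),
    )),))
    k13 = Div((
        lin((0.0058, a, a), (0.00416, s, a), (0.0026,)),
        lin((2.75, a, a), (1.97, s, a), (0.601,)),
    ))
    k21 = AbsOp((lin(
        (0.00408, b, b), (-8.16e-4, b), (-0.0057, b, w), (0.00218,)
    ),))
    k31 = lin((4.52e-5,), (3.84e-5, s, a))
    V1 = lin((0.0596, a), (18.7, w), (-13.7, w, w), (-3.5, a, w), (-0.0557,))
    return {"k10": k10, "k12": k12, "k13": k13, "k21": k21, "k31": k31, "V1": V1}


_PUBLISHED = None


def published_model(raw_covariates: Mapping[str, object]) -> PKRates:
    """Evaluate the published covariate model on raw covariates.

    Requires age [y], weight [kg], bmi [kg/m^2] and gender {M,F}; the
    sampling site is accepted but has no effect (it was pruned).
    """
    global _PUBLISHED
    if _PUBLISHED is None:
        _PUBLISHED = published_trees()
    spec = NormalizationSpec()
    cov = dict(raw_covariates)
    cov.setdefault("site", "A")
    theta = [evaluate_expression(_PUBLISHED[n], cov, spec) for n in PARAM_NAMES]
    return PKRates.from_array(np.array(theta))


# ---------------------------------------------------------------------------
# rendering and parsing
# ---------------------------------------------------------------------------


def _fmt(v: float, sig: int | None) -> str:
    if sig is None:
        return repr(v)
    if v == 0:
        return "0"
    return f"{v:.{sig}g}"


def _render_text(e: Expr, sig: int | None) -> str:
    if isinstance(e, Const):
        return _fmt(e.value, sig)
    if isinstance(e, Var):
        return e.name
    if isinstance(e, Add):
        return "(" + " + ".join(_render_text(c, sig) for c in e.children) + ")"
    if isinstance(e, Mul):
        return "*".join(_render_text(c, sig) for c in e.children)
    if isinstance(e, Div):
        n, d = e.children
        return f"({_render_text(n, sig)})/({_render_text(d, sig)})"
    if isinstance(e, Pow):
        b, x = e.children
        return f"({_render_text(b, sig)})**({_render_text(x, sig)})"
    if isinstance(e, AbsOp):
        return f"abs({_render_text(e.children[0], sig)})"
    raise TypeError(type(e))


def _render_latex(e: Expr, sig: int | None) -> str:
    if isinstance(e, Const):
        return _fmt(e.value, sig)
    if isinstance(e, Var):
        name, sub = (e.name.split("_") + [""])[:2]
        return rf"\mathrm{{{name}}}_{{{sub}}}" if sub else rf"\mathrm{{{name}}}"
    if isinstance(e, Add):
        return r"\left(" + " + ".join(_render_latex(c, sig) for c in e.children) + r"\right)"
    if isinstance(e, Mul):
        return r" \cdot ".join(_render_latex(c, sig) for c in e.children)
    if isinstance(e, Div):
        n, d = e.children
        return rf"\frac{{{_render_latex(n, sig)}}}{{{_render_latex(d, sig)}}}"
    if isinstance(e, Pow):
        b, x = e.children
        return rf"\left|{_render_latex(b, sig)}\right|^{{{_render_latex(x, sig)}}}"
    if isinstance(e, AbsOp):
        return rf"\left|{_render_latex(e.children[0], sig)}\right|"
    raise TypeError(type(e))


def render(tree: Expr, format: str = "text", digits: int | None = None) -> str:
    """Deterministic serialization; ``digits`` rounds for display only.

    The default full-precision text form round-trips through :func:`parse`
    to a tree that evaluates identically.
    """
    if format == "text":
        return _render_text(tree, digits)
    if format == "latex":
        return _render_latex(tree, digits if digits is not None else 3)
    raise ValueError(f"unknown format {format!r}")


def _from_ast(node: ast.AST) -> Expr:
    if isinstance(node, ast.Expression):
        return _from_ast(node.body)
    if isinstance(node, ast.Constant):
        return Const(float(node.value))
    if isinstance(node, ast.Name):
        return Var(node.id)
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
        inner = _from_ast(node.operand)
        if isinstance(inner, Const):
            return Const(-inner.value)
        return Mul((Const(-1.0), inner))
    if isinstance(node, ast.BinOp):
        lhs, rhs = _from_ast(node.left), _from_ast(node.right)
        if isinstance(node.op, ast.Add):
            return Add((lhs, rhs))
        if isinstance(node.op, ast.Sub):
            return Add((lhs, Mul((Const(-1.0), rhs))))
        if isinstance(node.op, ast.Mult):
            return Mul((lhs, rhs))
        if isinstance(node.op, ast.Div):
            return Div((lhs, rhs))
        if isinstance(node.op, ast.Pow):
            return Pow((lhs, rhs))
    if (
        isinstance(node, ast.Call)
        and isinstance(node.func, ast.Name)
        and node.func.id == "abs"
        and len(node.args) == 1
    ):
        return AbsOp((_from_ast(node.args[0]),))
    raise EvaluationError(f"cannot parse expression node {ast.dump(node)}")


def parse(text: str) -> Expr:
    """Parse the text rendering back into an equivalent tree."""
    try:
        node = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise EvaluationError(f"invalid expression syntax: {exc}") from exc
    return _from_ast(node)
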