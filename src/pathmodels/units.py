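"""Dimensional analysis for generated rate expressions.

A unit is a mapping from base-unit symbol (``mole``, ``second``, ``litre``)
to an exponent.  Exponents may be sympy expressions: the cooperativity
exponent of a saturable law is a parameter, so an intermediate term can
legitimately have dimension ``mole**h``, as long as the full expression
reduces to substance/time.
"""

from __future__ import annotations

import sympy

from .common import UnitDerivationError

Unit = dict[str, object]

DIMENSIONLESS: Unit = {}
SUBSTANCE: Unit = {"mole": 1}
SUBSTANCE_PER_TIME: Unit = {"mole": 1, "second": -1}
PER_TIME: Unit = {"second": -1}


def unit_mul(*units: Unit) -> Unit:
    out: dict[str, object] = {}
    for u in units:
        for k, v in u.items():
            out[k] = sympy.simplify(out.get(k, 0) + v)
    return _clean(out)


def unit_pow(u: Unit, exponent) -> Unit:
    return _clean({k: sympy.simplify(v * exponent) for k, v in u.items()})


def unit_div(a: Unit, b: Unit) -> Unit:
    return unit_mul(a, unit_pow(b, -1))


def unit_eq(a: Unit, b: Unit) -> bool:
    keys = set(a) | set(b)
    return all(sympy.simplify(sympy.sympify(a.get(k, 0)) - sympy.sympify(b.get(k, 0))) == 0 for k in keys)


def _clean(u: Unit) -> Unit:
    return {k: v for k, v in u.items() if sympy.simplify(v) != 0}


def format_unit(u: Unit) -> str:
    if not u:
        return "dimensionless"
    parts = []
    for k in sorted(u):
        v = sympy.nsimplify(u[k])
        parts.append(k if v == 1 else f"{k}^{v}")
    return " ".join(parts)


def parse_unit(text: str) -> Unit:
    """Parse unit strings like ``mole second^-1``, ``1/second`` or
    ``dimensionless``."""
    text = text.strip()
    if not text or text == "dimensionless":
        return {}
    if "/" in text:
        num, _, den = text.partition("/")
        return unit_div(parse_unit(num), parse_unit(den))
    out: Unit = {}
    for token in text.replace("*", " ").split():
        if token == "1":
            continue
        if "^" in token:
            base, _, exp = token.partition("^")
            out = unit_mul(out, {base: sympy.Rational(exp)})
        else:
            out = unit_mul(out, {token: 1})
    return out


def dimension_of(expr: sympy.Expr, dims: dict[sympy.Symbol, Unit]) -> Unit:
    """Dimension of ``expr`` given the dimensions of its free symbols.

    Raises :class:`UnitDerivationError` on inconsistent sums or on a power
    whose dimension cannot be expressed (dimensionful base with a
    dimensionful exponent).
    """
    if expr.is_Number:
        return {}
    if expr.is_Symbol:
        if expr not in dims:
            raise UnitDerivationError(f"no unit known for symbol {expr}")
        return dims[expr]
    if expr.is_Add:
        terms = [dimension_of(a, dims) for a in expr.args]
        for t in terms[1:]:
            if not unit_eq(terms[0], t):
                raise UnitDerivationError(
                    f"inconsistent addends in {expr}: "
                    f"{format_unit(terms[0])} vs {format_unit(t)}"
                )
        return terms[0]
    if expr.is_Mul:
        return unit_mul(*[dimension_of(a, dims) for a in expr.args])
    if expr.is_Pow:
        base, exp = expr.args
        exp_dim = dimension_of(exp, dims)
        if exp_dim:
            raise UnitDerivationError(f"dimensionful exponent in {expr}")
        return unit_pow(dimension_of(base, dims), exp)
    raise UnitDerivationError(f"cannot derive units of {expr}")
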