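"""Gene-protein-reaction (GPR) boolean rule parsing and evaluation.

Rules use the conventional syntax ``(gA and gB) or gC`` where ``and``
joins subunits of a complex and ``or`` joins isozymes.  For mapping
continuous abundances onto reactions the standard convention applies:
AND takes the minimum of its operands (a complex is limited by its
scarcest subunit), OR takes the sum (isozyme capacities add).
"""

from __future__ import annotations

import re

__all__ = ["parse_gpr", "gpr_genes", "evaluate_gpr", "GPRSyntaxError"]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class GPRSyntaxError(ValueError):
    pass


def _tokenize(rule: str) -> list[str]:
    return _TOKEN_RE.findall(rule)


def parse_gpr(rule: str):
    """Parse a rule into a nested AST of tuples.

    AST nodes are ``("gene", name)``, ``("and", [children])`` or
    ``("or", [children])``.  ``or`` binds looser than ``and``.  An empty
    rule parses to ``None``.
    """
    tokens = _tokenize(rule)
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and():
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def parse_atom():
        tok = peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of rule: {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRSyntaxError(f"unbalanced parentheses in {rule!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r} in {rule!r}")
        return ("gene", take())

    node = parse_or()
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens in {rule!r}")
    return node


def gpr_genes(rule: str) -> set[str]:
    """All gene identifiers appearing in a rule."""
    node = parse_gpr(rule)
    out: set[str] = set()

    def walk(n):
        if n is None:
            return
        kind = n[0]
        if kind == "gene":
            out.add(n[1])
        else:
            for child in n[1]:
                walk(child)

    walk(node)
    return out


def evaluate_gpr(rule: str, expression: dict[str, float],
                 missing_value: float = 0.0) -> float | None:
    """Map gene abundances through a rule (AND=min, OR=sum).

    Genes absent from *expression* contribute *missing_value*.  Returns
    ``None`` for an empty rule.
    """
    node = parse_gpr(rule)
    if node is None:
        return None

    def walk(n) -> float:
        kind = n[0]
        if kind == "gene":
            return float(expression.get(n[1], missing_value))
        values = [walk(child) for child in n[1]]
        return min(values) if kind == "and" else sum(values)

    return walk(node)
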