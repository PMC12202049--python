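"""Tiny selection-expression language.

Grammar (case-insensitive keywords)::

    expr    := or_expr
    or_expr := and_expr ("or" and_expr)*
    and_expr:= not_expr ("and" not_expr)*
    not_expr:= "not" not_expr | primary
    primary := "(" expr ")"
             | "all" | "none"
             | "chain" ID ("," ID)*
             | "resi" RANGE ("," RANGE)*      RANGE := N | N-N
             | "element" SYM ("," SYM)*

Examples: ``chain A``, ``element C and chain B``, ``not all``,
``resi 1-10 or resi 40``.
"""

from __future__ import annotations

import re

from .model import MoleculeSystem, Selection
from .periodic import normalize_element

__all__ = ["select", "SelectionSyntaxError"]


class SelectionSyntaxError(ValueError):
    """Malformed selection expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(r"\s*(?:(\()|(\))|(,)|([A-Za-z0-9_'\-]+))")


class _Tokenizer:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.tokens: list[tuple[str, int]] = []
        self._tokenize()
        self.cursor = 0

    def _tokenize(self) -> None:
        pos = 0
        while pos < len(self.text):
            m = _TOKEN_RE.match(self.text, pos)
            if m is None or m.end() == pos:
                stripped = self.text[pos:].lstrip()
                if not stripped:
                    break
                at = len(self.text) - len(stripped)
                raise SelectionSyntaxError(f"unexpected character {stripped[0]!r}", at)
            tok = next(g for g in m.groups() if g is not None)
            self.tokens.append((tok, m.start() + (m.end() - m.start() - len(tok))))
            pos = m.end()

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.cursor] if self.cursor < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression", len(self.text))
        self.cursor += 1
        return tok


def _parse_value_list(tz: _Tokenizer) -> list[str]:
    values = [tz.next()[0]]
    while True:
        nxt = tz.peek()
        if nxt is None or nxt[0] != ",":
            break
        tz.next()
        values.append(tz.next()[0])
    return values


def _parse_primary(tz: _Tokenizer, system: MoleculeSystem) -> set[int]:
    tok, at = tz.next()
    low = tok.lower()
    if tok == "(":
        result = _parse_or(tz, system)
        closing = tz.next()
        if closing[0] != ")":
            raise SelectionSyntaxError("expected ')'", closing[1])
        return result
    if low == "all":
        return set(range(system.n_atoms))
    if low == "none":
        return set()
    if low == "chain":
        wanted = set(_parse_value_list(tz))
        return {a.index for a in system.atoms if a.chain_id in wanted}
    if low == "element":
        wanted = {normalize_element(v) for v in _parse_value_list(tz)}
        return {a.index for a in system.atoms if normalize_element(a.element) in wanted}
    if low == "resi":
        out: set[int] = set()
        for rng in _parse_value_list(tz):
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", rng)
            if m is None:
                raise SelectionSyntaxError(f"bad residue range {rng!r}", at)
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            out |= {a.index for a in system.atoms if lo <= a.residue_seq <= hi}
        return out
    raise SelectionSyntaxError(f"unexpected token {tok!r}", at)


def _parse_not(tz: _Tokenizer, system: MoleculeSystem) -> set[int]:
    nxt = tz.peek()
    if nxt is not None and nxt[0].lower() == "not":
        tz.next()
        return set(range(system.n_atoms)) - _parse_not(tz, system)
    return _parse_primary(tz, system)


def _parse_and(tz: _Tokenizer, system: MoleculeSystem) -> set[int]:
    result = _parse_not(tz, system)
    while True:
        nxt = tz.peek()
        if nxt is None or nxt[0].lower() != "and":
            return result
        tz.next()
        result &= _parse_not(tz, system)


def _parse_or(tz: _Tokenizer, system: MoleculeSystem) -> set[int]:
    result = _parse_and(tz, system)
    while True:
        nxt = tz.peek()
        if nxt is None or nxt[0].lower() != "or":
            return result
        tz.next()
        result |= _parse_and(tz, system)


def select(system: MoleculeSystem, expr: str) -> Selection:
    """Evaluate a selection expression against a system.

    Raises :class:`SelectionSyntaxError` (with character position) on a
    malformed expression.  The result is deterministic: indices ascending.
    """
    tz = _Tokenizer(expr)
    if tz.peek() is None:
        raise SelectionSyntaxError("empty expression", 0)
    result = _parse_or(tz, system)
    trailing = tz.peek()
    if trailing is not None:
        raise SelectionSyntaxError(f"unexpected trailing token {trailing[0]!r}", trailing[1])
    return Selection(tuple(sorted(result)))
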