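"""A tiny independent DOT-language grammar checker.

Recognizes the subset of DOT used for tree export (digraph with node,
edge, and attribute statements) with its own tokenizer and recursive
descent parser — no code shared with the package's renderer.
"""

from __future__ import annotations

import re


class DotSyntaxError(ValueError):
    pass


_TOKEN_RE = re.compile(
    r"""
    \s+
  | "(?:[^"\\]|\\.)*"          # quoted string
  | ->                          # edge operator
  | [{}\[\];=,]                 # punctuation
  | [A-Za-z_][A-Za-z0-9_]*      # identifier
  | -?(?:\.\d+|\d+(?:\.\d*)?)   # numeral
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise DotSyntaxError(f"cannot tokenize at offset {pos}: {text[pos:pos+20]!r}")
        tok = m.group(0)
        if not tok.isspace():
            tokens.append(tok)
        pos = m.end()
    return tokens


def _is_id(tok: str) -> bool:
    return bool(
        tok
        and tok not in ("{", "}", "[", "]", ";", "=", ",", "->")
        and (tok[0] == '"' or re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*|-?(?:\.\d+|\d+(?:\.\d*)?)", tok))
    )


def parse_dot(text: str) -> dict:
    """Parse a digraph; returns {"nodes": set of ids, "edges": list of pairs}.

    Raises DotSyntaxError on any grammar violation.
    """
    toks = _tokenize(text)
    i = 0

    def expect(val=None, pred=None, what=""):
        nonlocal i
        if i >= len(toks):
            raise DotSyntaxError(f"unexpected end of input, expected {what or val}")
        tok = toks[i]
        if val is not None and tok != val:
            raise DotSyntaxError(f"expected {val!r}, got {tok!r}")
        if pred is not None and not pred(tok):
            raise DotSyntaxError(f"expected {what}, got {tok!r}")
        i += 1
        return tok

    def parse_attrs():
        nonlocal i
        expect("[")
        while toks[i] != "]":
            expect(pred=_is_id, what="attribute name")
            expect("=")
            expect(pred=_is_id, what="attribute value")
            if toks[i] in (",", ";"):
                i += 1
        expect("]")

    expect("digraph")
    if toks[i] != "{":
        expect(pred=_is_id, what="graph name")
    expect("{")
    nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    while i < len(toks) and toks[i] != "}":
        first = expect(pred=_is_id, what="node id or keyword")
        if i < len(toks) and toks[i] == "->":
            i += 1
            second = expect(pred=_is_id, what="edge target")
            if i < len(toks) and toks[i] == "[":
                parse_attrs()
            edges.append((first, second))
            nodes.update((first, second))
        else:
            if i < len(toks) and toks[i] == "[":
                parse_attrs()
            if first not in ("node", "edge", "graph"):
                nodes.add(first)
        if i < len(toks) and toks[i] == ";":
            i += 1
    expect("}")
    if i != len(toks):
        raise DotSyntaxError("trailing tokens after closing brace")
    return {"nodes": nodes, "edges": edges}
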