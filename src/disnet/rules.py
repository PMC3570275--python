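"""Parser for Boolean rule files in the ``$node[i]`` syntax.

Grammar (whitespace-insensitive; ``#`` starts a comment to end of line)::

    program   := statement+
    statement := "$node[" INT "]" "=" or_expr ";"
    or_expr   := and_expr ("|" and_expr)*
    and_expr  := not_expr ("&" not_expr)*
    not_expr  := "!" not_expr | atom
    atom      := "$node[" INT "]" | "(" or_expr ")"

Precedence NOT > AND > OR.  A file defines a network of N nodes, where N is
the number of statements; each of nodes 1..N must be defined exactly once,
and every literal index must lie in 1..N.

The AST is a nested tuple form: ``("lit", j)``, ``("not", x)``,
``("and", x, y)``, ``("or", x, y)`` with 1-based node indices.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import RuleParseError, RuleStructureError

Ast = tuple  # ("lit", j) | ("not", Ast) | ("and", Ast, Ast) | ("or", Ast, Ast)


@dataclass(frozen=True)
class Token:
    kind: str  # NODE, NOT, AND, OR, LPAR, RPAR, EQ, SEMI, EOF
    value: int | None
    line: int
    column: int


def _tokenize(text: str) -> list[Token]:
    tokens: list[Token] = []
    line, col = 1, 1
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "\n":
            line += 1
            col = 1
            i += 1
            continue
        if ch in " \t\r":
            i += 1
            col += 1
            continue
        if ch == "#":
            while i < n and text[i] != "\n":
                i += 1
            continue
        start_col = col
        simple = {"!": "NOT", "&": "AND", "|": "OR", "(": "LPAR", ")": "RPAR", "=": "EQ", ";": "SEMI"}
        if ch in simple:
            tokens.append(Token(simple[ch], None, line, start_col))
            i += 1
            col += 1
            continue
        if ch == "$":
            if not text.startswith("$node[", i):
                raise RuleParseError("expected '$node[' after '$'", line, start_col)
            j = i + len("$node[")
            k = j
            while k < n and text[k].isdigit():
                k += 1
            if k == j:
                raise RuleParseError("expected node index after '$node['", line, start_col)
            if k >= n or text[k] != "]":
                raise RuleParseError("missing ']' in node reference", line, start_col)
            tokens.append(Token("NODE", int(text[j:k]), line, start_col))
            col += (k + 1 - i)
            i = k + 1
            continue
        raise RuleParseError(f"unexpected character {ch!r}", line, start_col)
    tokens.append(Token("EOF", None, line, col))
    return tokens


class _Parser:
    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> Token:
        return self.tokens[self.pos]

    def take(self, kind: str, what: str) -> Token:
        tok = self.tokens[self.pos]
        if tok.kind != kind:
            raise RuleParseError(f"expected {what}, found {tok.kind}", tok.line, tok.column)
        self.pos += 1
        return tok

    def parse_program(self) -> list[tuple[int, Ast]]:
        statements = []
        while self.peek().kind != "EOF":
            statements.append(self.parse_statement())
        if not statements:
            tok = self.peek()
            raise RuleParseError("empty rule file", tok.line, tok.column)
        return statements

    def parse_statement(self) -> tuple[int, Ast]:
        target = self.take("NODE", "'$node[i]' target")
        self.take("EQ", "'='")
        expr = self.parse_or()
        self.take("SEMI", "';'")
        return target.value, expr

    def parse_or(self) -> Ast:
        left = self.parse_and()
        while self.peek().kind == "OR":
            self.pos += 1
            left = ("or", left, self.parse_and())
        return left

    def parse_and(self) -> Ast:
        left = self.parse_not()
        while self.peek().kind == "AND":
            self.pos += 1
            left = ("and", left, self.parse_not())
        return left

    def parse_not(self) -> Ast:
        if self.peek().kind == "NOT":
            self.pos += 1
            return ("not", self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> Ast:
        tok = self.peek()
        if tok.kind == "NODE":
            self.pos += 1
            return ("lit", tok.value)
        if tok.kind == "LPAR":
            self.pos += 1
            expr = self.parse_or()
            self.take("RPAR", "')'")
            return expr
        raise RuleParseError(
            f"expected '$node[j]', '!' or '(', found {tok.kind}", tok.line, tok.column
        )


def parse_statements(text: str) -> dict[int, Ast]:
    """Parse rule text into {node index: AST}; structural checks applied.

    N is the number of statements; nodes 1..N must each be defined exactly
    once and all literal indices must be in range.
    """
    statements = _Parser(_tokenize(text)).parse_program()
    n = len(statements)
    rules: dict[int, Ast] = {}
    for idx, expr in statements:
        if idx in rules:
            raise RuleStructureError(f"node {idx} defined more than once")
        if not 1 <= idx <= n:
            raise RuleStructureError(
                f"node index {idx} out of range 1..{n} (N = number of statements)"
            )
        rules[idx] = expr
    missing = [i for i in range(1, n + 1) if i not in rules]
    if missing:
        raise RuleStructureError(f"missing definitions for nodes: {missing}")
    for idx, expr in rules.items():
        for j in literal_occurrences(expr):
            if not 1 <= j <= n:
                raise RuleStructureError(
                    f"rule for node {idx} references $node[{j}] outside 1..{n}"
                )
    return rules


def literal_occurrences(ast: Ast) -> list[int]:
    """All literal node indices in an AST, with multiplicity."""
    if ast[0] == "lit":
        return [ast[1]]
    if ast[0] == "not":
        return literal_occurrences(ast[1])
    return literal_occurrences(ast[1]) + literal_occurrences(ast[2])


def regulator_set(ast: Ast) -> set[int]:
    """Distinct node indices appearing in an AST."""
    return set(literal_occurrences(ast))


def evaluate(ast: Ast, bits: "list[int] | tuple[int, ...]") -> int:
    """Evaluate an AST on a state; ``bits[j-1]`` is node j's value."""
    op = ast[0]
    if op == "lit":
        return bits[ast[1] - 1]
    if op == "not":
        return 1 - evaluate(ast[1], bits)
    if op == "and":
        return evaluate(ast[1], bits) & evaluate(ast[2], bits)
    return evaluate(ast[1], bits) | evaluate(ast[2], bits)


def unparse(ast: Ast) -> str:
    """Render an AST back to rule syntax (fully parenthesized)."""
    op = ast[0]
    if op == "lit":
        return f"$node[{ast[1]}]"
    if op == "not":
        return f"!({unparse(ast[1])})"
    glue = " & " if op == "and" else " | "
    return f"({unparse(ast[1])}{glue}{unparse(ast[2])})"
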