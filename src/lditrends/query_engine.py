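"""Boolean, field-restricted, phrase-based literature queries.

Implements the query dialect used for technique searches: double-quoted
phrases, ``AND`` / ``OR`` / ``NOT`` (case-insensitive, NOT binding
tighter than AND, AND tighter than OR), parentheses, and an optional
``METHODS:`` prefix restricting a term to the methods section. Unprefixed
terms search title, abstract and methods text.

Matching semantics: text is tokenized by splitting on any non-ASCII-
alphanumeric character, lower-cased, and a phrase matches iff its token
sequence occurs contiguously in one field. Hyphens and slashes are thus
token boundaries, so the term ``MALDI`` matches "MALDI-TOF" and the
phrase "laser desorption/ionization" matches both the slashed and the
spaced spelling. ``MS`` only ever matches as a whole token. This
tokenizer is a documented dialect choice approximating the upstream
search engine; it is not claimed identical to it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources as _ilres
from typing import Dict, Iterable, List, Optional, Tuple, Union

from .corpus_model import Corpus, Publication


class Field(Enum):
    ALL = "ALL"
    METHODS = "METHODS"


@dataclass(frozen=True)
class Term:
    phrase: str
    field: Field = Field.ALL

    def __post_init__(self):
        if not self.phrase.strip():
            raise ValueError("TERM phrase must be non-empty")


@dataclass(frozen=True)
class And:
    children: Tuple["QueryNode", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND requires at least 2 children")


@dataclass(frozen=True)
class Or:
    children: Tuple["QueryNode", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR requires at least 2 children")


@dataclass(frozen=True)
class Not:
    child: "QueryNode"


QueryNode = Union[Term, And, Or, Not]

#: guard conjoined with every technique query
GUARD_QUERY = '(METHODS:"mass spectrometry" OR METHODS:"MS")'

_TOKEN_SPLIT = re.compile(r"[^0-9A-Za-z]+")


def tokenize(text: str) -> Tuple[str, ...]:
    """Lower-cased tokens of *text*; any non-alphanumeric is a boundary."""
    return tuple(t for t in _TOKEN_SPLIT.split(text.lower()) if t)


@lru_cache(maxsize=4096)
def _phrase_tokens(phrase: str) -> Tuple[str, ...]:
    return tokenize(phrase)


# ---------------------------------------------------------------------------
# Parsing


class QueryParseError(ValueError):
    """Query syntax error; carries the character position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


_QUOTES_OPEN = {'"', "“", "‘"}
_QUOTES_CLOSE = {'"', "”", "’"}
_KEYWORDS = {"AND", "OR", "NOT"}


def _lex(text: str) -> List[Tuple[str, str, int]]:
    """Tokens as (kind, value, pos); kind in {LPAREN, RPAREN, OP, TERM}."""
    out: List[Tuple[str, str, int]] = []
    i, n = 0, len(text)

    def read_quoted(start: int) -> Tuple[str, int]:
        j = start + 1
        while j < n and text[j] not in _QUOTES_CLOSE:
            j += 1
        if j >= n:
            raise QueryParseError("unterminated quoted phrase", start)
        return text[start + 1 : j], j + 1

    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "(":
            out.append(("LPAREN", ch, i))
            i += 1
            continue
        if ch == ")":
            out.append(("RPAREN", ch, i))
            i += 1
            continue
        if ch in _QUOTES_OPEN:
            phrase, i2 = read_quoted(i)
            out.append(("TERM", f"ALL\x00{phrase}", i))
            i = i2
            continue
        # bare word, possibly METHODS:-prefixed, possibly METHODS:"..."
        j = i
        while j < n and not text[j].isspace() and text[j] not in '()' and text[j] not in _QUOTES_OPEN:
            j += 1
        word = text[i:j]
        upper = word.upper()
        if upper in _KEYWORDS:
            out.append(("OP", upper, i))
            i = j
            continue
        if upper.startswith("METHODS:"):
            rest = word[len("METHODS:") :]
            if rest:
                out.append(("TERM", f"METHODS\x00{rest}", i))
                i = j
            elif j < n and text[j] in _QUOTES_OPEN:
                phrase, i2 = read_quoted(j)
                out.append(("TERM", f"METHODS\x00{phrase}", i))
                i = i2
            else:
                raise QueryParseError("METHODS: prefix with no term", i)
            continue
        out.append(("TERM", f"ALL\x00{word}", i))
        i = j
    return out


class _Parser:
    def __init__(self, tokens: List[Tuple[str, str, int]], length: int):
        self.tokens = tokens
        self.pos = 0
        self.length = length

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise QueryParseError("unexpected end of query", self.length)
        self.pos += 1
        return tok

    def parse(self) -> QueryNode:
        node = self.expr()
        tok = self._peek()
        if tok is not None:
            raise QueryParseError(f"unexpected {tok[1]!r}", tok[2])
        return node

    def expr(self) -> QueryNode:
        children = [self.and_expr()]
        while (tok := self._peek()) and tok[0] == "OP" and tok[1] == "OR":
            self._next()
            children.append(self.and_expr())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def and_expr(self) -> QueryNode:
        children = [self.not_expr()]
        while (tok := self._peek()) and tok[0] == "OP" and tok[1] == "AND":
            self._next()
            children.append(self.not_expr())
        return children[0] if len(children) == 1 else And(tuple(children))

    def not_expr(self) -> QueryNode:
        tok = self._peek()
        if tok and tok[0] == "OP" and tok[1] == "NOT":
            self._next()
            return Not(self.not_expr())
        return self.atom()

    def atom(self) -> QueryNode:
        tok = self._next()
        kind, value, pos = tok
        if kind == "LPAREN":
            node = self.expr()
            closing = self._peek()
            if closing is None or closing[0] != "RPAREN":
                raise QueryParseError("unbalanced parentheses", pos)
            self._next()
            return node
        if kind == "RPAREN":
            raise QueryParseError("unbalanced parentheses", pos)
        if kind == "OP":
            raise QueryParseError(f"dangling operator {value}", pos)
        field_s, phrase = value.split("\x00", 1)
        if not phrase.strip():
            raise QueryParseError("empty phrase", pos)
        return Term(phrase=phrase, field=Field[field_s])


def parse_query(text: str) -> QueryNode:
    """Parse a query string into an AST (:class:`QueryParseError` on syntax)."""
    tokens = _lex(text)
    if not tokens:
        raise QueryParseError("empty query", 0)
    return _Parser(tokens, len(text)).parse()


# ---------------------------------------------------------------------------
# Matching

_FIELDS_ALL = ("title", "abstract", "methods_text")
_FIELDS_METHODS = ("methods_text",)


def _field_tokens(pub: Publication, attr: str):
    cache = pub._token_cache
    if cache is None:
        cache = pub._token_cache = {}
    entry = cache.get(attr)
    if entry is None:
        toks = tokenize(getattr(pub, attr))
        entry = cache[attr] = (toks, frozenset(toks))
    return entry


def _contains_seq(haystack: Tuple[str, ...], needle: Tuple[str, ...]) -> bool:
    k = len(needle)
    if k == 0:
        return False
    if k == 1:
        return needle[0] in haystack
    first = needle[0]
    for i in range(len(haystack) - k + 1):
        if haystack[i] == first and haystack[i : i + k] == needle:
            return True
    return False


def _match_term(pub: Publication, term: Term) -> bool:
    needle = _phrase_tokens(term.phrase)
    if not needle:
        return False
    attrs = _FIELDS_METHODS if term.field is Field.METHODS else _FIELDS_ALL
    for attr in attrs:
        toks, tokset = _field_tokens(pub, attr)
        if all(t in tokset for t in needle) and _contains_seq(toks, needle):
            return True
    return False


def match(pub: Publication, q: QueryNode) -> bool:
    """Evaluate query *q* against one publication."""
    if isinstance(q, Term):
        return _match_term(pub, q)
    if isinstance(q, And):
        return all(match(pub, c) for c in q.children)
    if isinstance(q, Or):
        return any(match(pub, c) for c in q.children)
    if isinstance(q, Not):
        return not match(pub, q.child)
    raise TypeError(f"not a query node: {q!r}")


def count_matches(corpus: Corpus, q: QueryNode) -> int:
    """Number of publications in *corpus* matching *q*."""
    return sum(1 for pub in corpus.publications if match(pub, q))


def matching_publications(corpus: Corpus, q: QueryNode) -> List[Publication]:
    return [pub for pub in corpus.publications if match(pub, q)]


def cooccurrence(corpus: Corpus, a: QueryNode, b: QueryNode) -> int:
    """Publications matching both *a* and *b* (symmetric)."""
    return count_matches(corpus, And((a, b)))


# ---------------------------------------------------------------------------
# Built-in technique query set

_TABLE1_RESOURCE = "technique_queries.tsv"


@lru_cache(maxsize=1)
def load_technique_query_strings() -> Dict[str, str]:
    """The shipped named technique query strings (shorthand -> query text)."""
    text = (
        _ilres.files("lditrends.resources").joinpath(_TABLE1_RESOURCE).read_text("utf-8")
    )
    out: Dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, query = line.split("\t", 1)
        out[name] = query
    return out


def technique_query_set(with_guard: bool = True) -> Dict[str, QueryNode]:
    """Parsed technique queries, each AND-ed with the mass-spectrometry guard.

    The guard requires "mass spectrometry" or "MS" in the methods section;
    set ``with_guard=False`` for the raw technique terms alone.
    """
    guard = parse_query(GUARD_QUERY)
    out: Dict[str, QueryNode] = {}
    for name, text in load_technique_query_strings().items():
        node = parse_query(text)
        out[name] = And((node, guard)) if with_guard else node
    return out
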