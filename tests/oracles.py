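"""Independent reference implementations used only as test oracles.

Deliberately written via different routes than the package: phrase
matching by padded-substring search on whitespace-normalized text
instead of token-sequence scanning, and random boolean query trees
built directly as AST nodes (never via the parser).
"""

import re

import numpy as np

from lditrends.query_engine import And, Field, Not, Or, Term


def _normalize(text: str) -> str:
    return " " + " ".join(t for t in re.split(r"[^0-9A-Za-z]+", text.lower()) if t) + " "


def naive_term_match(pub, phrase: str, field: Field) -> bool:
    needle = _normalize(phrase).strip()
    if not needle:
        return False
    fields = (
        [pub.methods_text]
        if field is Field.METHODS
        else [pub.title, pub.abstract, pub.methods_text]
    )
    return any(f" {needle} " in _normalize(f) for f in fields)


def naive_match(pub, node) -> bool:
    if isinstance(node, Term):
        return naive_term_match(pub, node.phrase, node.field)
    if isinstance(node, And):
        return all(naive_match(pub, c) for c in node.children)
    if isinstance(node, Or):
        return any(naive_match(pub, c) for c in node.children)
    if isinstance(node, Not):
        return not naive_match(pub, node.child)
    raise TypeError(node)


def naive_count(corpus, node) -> int:
    return sum(naive_match(p, node) for p in corpus.publications)


def random_query_tree(rng: np.random.Generator, vocab, depth: int = 3):
    """Random boolean tree over phrases from *vocab* (AST built directly)."""
    if depth == 0 or rng.random() < 0.35:
        phrase = vocab[int(rng.integers(0, len(vocab)))]
        field = Field.METHODS if rng.random() < 0.4 else Field.ALL
        return Term(phrase=phrase, field=field)
    kind = rng.integers(0, 3)
    if kind == 2:
        return Not(random_query_tree(rng, vocab, depth - 1))
    n_children = int(rng.integers(2, 4))
    children = tuple(random_query_tree(rng, vocab, depth - 1) for _ in range(n_children))
    return And(children) if kind == 0 else Or(children)


def random_corpus(rng: np.random.Generator, vocab, n_pubs: int):
    """Random publications whose fields are short word soups from *vocab*."""
    from lditrends.corpus_model import Corpus, Publication

    def soup(k):
        return " ".join(vocab[int(i)] for i in rng.integers(0, len(vocab), k))

    pubs = [
        Publication(
            pub_id=f"R{i}",
            title=soup(int(rng.integers(2, 6))),
            abstract=soup(int(rng.integers(5, 15))),
            methods_text=soup(int(rng.integers(5, 15))),
        )
        for i in range(n_pubs)
    ]
    return Corpus(publications=pubs)
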