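"""VOSviewer input-file generation with metadata imputation.

VOSviewer consumes plain tab-separated text: a corpus file (one
title+abstract per line), an aligned scores file used for map overlays,
and a thesaurus file of term replacements/exclusions. VOSviewer rejects
missing values, so publication years are resolved through a fallback
chain of record fields — pubYear, journal year of publication, first
publication date, electronic publication date, first index date — and
finally imputed with 2006, the median publication year of the source
literature database. Missing citation counts are imputed as zero. A
third score, citations divided by publication age in years, highlights
"hot" topics.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources as _ilres
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .corpus_model import YEAR_MIN, Corpus, Publication, _current_year

#: database-wide median publication year used when all year fields are absent
MEDIAN_YEAR_FALLBACK = 2006

#: default reference year for publication ages (the reproduction query date)
DEFAULT_REFERENCE_YEAR = 2023

PROVENANCE_LABELS = (
    "pubYear",
    "journal_year",
    "first_pub_date",
    "electronic_pub_date",
    "first_index_date",
    "imputed_median",
)

SCORE_HEADER = ["id", "publication year", "citations", "citations per year"]


@dataclass
class ScoreRecord:
    pub_id: str
    resolved_year: int
    year_provenance: str
    citations: int
    citations_per_age: float

    def __post_init__(self):
        if self.year_provenance not in PROVENANCE_LABELS:
            raise ValueError(f"unknown provenance {self.year_provenance!r}")
        if self.citations < 0 or self.citations_per_age < 0:
            raise ValueError(f"{self.pub_id}: negative citation score")


_YEAR_PREFIX = re.compile(r"^(\d{4})")


def _year_from_date(value: Optional[str], pub_id: str, label: str) -> Optional[int]:
    if value is None:
        return None
    m = _YEAR_PREFIX.match(value.strip())
    year = int(m.group(1)) if m else None
    if year is None or not (YEAR_MIN <= year <= _current_year()):
        warnings.warn(
            f"publication {pub_id!r}: unparseable {label} {value!r}; "
            "treated as absent",
            stacklevel=3,
        )
        return None
    return year


def resolve_year(
    pub: Publication, fallback: int = MEDIAN_YEAR_FALLBACK
) -> Tuple[int, str]:
    """Resolve the publication year through the field fallback chain.

    Returns ``(year, provenance)``; the first present (and parseable)
    field in the documented order wins, date fields contributing their
    year component. With all five fields absent the database-median
    *fallback* is returned with provenance ``imputed_median``.
    """
    if pub.pub_year is not None:
        return pub.pub_year, "pubYear"
    if pub.journal_year is not None:
        return pub.journal_year, "journal_year"
    for attr, label in (
        ("first_pub_date", "first_pub_date"),
        ("electronic_pub_date", "electronic_pub_date"),
        ("first_index_date", "first_index_date"),
    ):
        year = _year_from_date(getattr(pub, attr), pub.pub_id, label)
        if year is not None:
            return year, label
    return fallback, "imputed_median"


def compute_scores(
    pub: Publication,
    reference_year: int = DEFAULT_REFERENCE_YEAR,
    fallback: int = MEDIAN_YEAR_FALLBACK,
) -> ScoreRecord:
    """Per-publication VOSviewer scores with the imputation rules applied.

    Age is ``reference_year - resolved_year`` clamped to at least one
    year, so same-year publications get a well-defined citations-per-age.
    """
    year, provenance = resolve_year(pub, fallback=fallback)
    citations = pub.cited_by_count if pub.cited_by_count is not None else 0
    age = max(reference_year - year, 1)
    return ScoreRecord(
        pub_id=pub.pub_id,
        resolved_year=year,
        year_provenance=provenance,
        citations=citations,
        citations_per_age=citations / age,
    )


def score_corpus(
    corpus_or_pubs, reference_year: int = DEFAULT_REFERENCE_YEAR
) -> List[ScoreRecord]:
    pubs = (
        corpus_or_pubs.publications
        if isinstance(corpus_or_pubs, Corpus)
        else list(corpus_or_pubs)
    )
    return [compute_scores(p, reference_year) for p in pubs]


def _sanitize(text: str) -> str:
    return re.sub(r"[\t\r\n]+", " ", text)


def write_scores_file(records: Sequence[ScoreRecord], path) -> None:
    """Tab-separated scores file: header plus one complete row per record."""
    if not records:
        raise ValueError("refusing to write an empty scores file")
    for rec in records:
        if rec.citations_per_age != rec.citations_per_age:  # NaN guard
            raise ValueError(f"record {rec.pub_id}: unresolved score")
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("\t".join(SCORE_HEADER) + "\n")
        for rec in records:
            handle.write(
                f"{rec.pub_id}\t{rec.resolved_year}\t{rec.citations}\t"
                f"{rec.citations_per_age!r}\n"
            )


def read_scores_file(path) -> List[Tuple[str, int, int, float]]:
    """Parse a written scores file back into (id, year, citations, cpa)."""
    lines = Path(path).read_text("utf-8").splitlines()
    if lines[0].split("\t") != SCORE_HEADER:
        raise ValueError("not a scores file")
    out = []
    for line in lines[1:]:
        pub_id, year, citations, cpa = line.split("\t")
        out.append((pub_id, int(year), int(citations), float(cpa)))
    return out


def write_corpus_file(
    pubs: Sequence[Publication], path, records: Optional[Sequence[ScoreRecord]] = None
) -> None:
    """Tab-separated title/abstract file, row-aligned with the scores file.

    When *records* is given, the row order is checked against it and a
    misalignment raises.
    """
    if records is not None:
        if len(records) != len(pubs) or any(
            p.pub_id != r.pub_id for p, r in zip(pubs, records)
        ):
            raise ValueError("corpus file rows misaligned with scores file")
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for pub in pubs:
            handle.write(f"{_sanitize(pub.title)}\t{_sanitize(pub.abstract)}\n")


def write_thesaurus(excluded_terms: Sequence[str], path) -> None:
    """Thesaurus file excluding terms (header ``label\treplace by``;
    excluded terms map to an empty replacement). Duplicates are dropped,
    first occurrence wins."""
    path = Path(path)
    seen, terms = set(), []
    for term in excluded_terms:
        key = term.strip().lower()
        if key and key not in seen:
            seen.add(key)
            terms.append(term.strip())
    with path.open("w", encoding="utf-8") as handle:
        handle.write("label\treplace by\n")
        for term in terms:
            handle.write(f"{term}\t\n")


def default_thesaurus_terms() -> List[str]:
    """Shipped exclusion list of uninformative terms (month and country
    names); editable resource, one term per line."""
    text = (
        _ilres.files("lditrends.resources")
        .joinpath("thesaurus_terms.txt")
        .read_text("utf-8")
    )
    return [t.strip() for t in text.splitlines() if t.strip() and not t.startswith("#")]


def normalized_min_occurrences(
    n_pubs: int, base_n: int, base_threshold: int = 10
) -> int:
    """Minimum term-occurrence threshold scaled by corpus size.

    The base threshold applying to a corpus of *base_n* publications is
    scaled proportionally to *n_pubs* and rounded half-up, with a floor
    of 1.
    """
    if base_n < 1:
        raise ValueError("base_n must be >= 1")
    import math

    scaled = math.floor(base_threshold * n_pubs / base_n + 0.5)
    return max(scaled, 1)


def provenance_frequencies(records: Sequence[ScoreRecord]) -> Dict[str, int]:
    out = {label: 0 for label in PROVENANCE_LABELS}
    for rec in records:
        out[rec.year_provenance] += 1
    return out
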