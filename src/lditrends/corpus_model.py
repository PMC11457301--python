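"""Corpus data model and readers/writers for publication records.

The record dialect mirrors Europe PMC core fields (``pubYear``,
``citedByCount``, ``firstPublicationDate``, ``electronicPublicationDate``,
``firstIndexDate``, ``journalInfo.yearOfPublication``) so archived API
output can be ingested unchanged. Records are line-delimited JSON; the
ChEBI annotation table and the chemical-entity table are tab-separated
text with a header row. Empty strings and missing keys are both treated
as absent — downstream imputation (e.g. for VOSviewer scores) is an
export-time rule, never applied at load time.
"""

from __future__ import annotations

import datetime
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Set

YEAR_MIN = 1900

_CHEBI_RE = re.compile(r"^CHEBI:\d+$")


class CorpusError(ValueError):
    """Malformed corpus, annotation or entity input."""


def _current_year() -> int:
    return datetime.date.today().year


def _check_year(value: Optional[int], name: str, pub_id: str) -> None:
    if value is None:
        return
    if not (YEAR_MIN <= value <= _current_year()):
        raise CorpusError(
            f"publication {pub_id!r}: {name}={value} outside [{YEAR_MIN}, "
            f"{_current_year()}]"
        )


@dataclass
class Annotation:
    """A text-mined ChEBI entity mention attached to one publication."""

    chebi_id: str
    term: str
    count: int

    def __post_init__(self) -> None:
        if not _CHEBI_RE.match(self.chebi_id):
            raise CorpusError(f"bad ChEBI identifier {self.chebi_id!r}")
        if self.count < 1:
            raise CorpusError(
                f"annotation {self.chebi_id}: count must be >= 1, got {self.count}"
            )


@dataclass
class Publication:
    """One literature record with text fields, metadata and annotations.

    Optional fields are ``None`` when the source record lacked them;
    they are never silently defaulted.
    """

    pub_id: str
    title: str = ""
    abstract: str = ""
    methods_text: str = ""
    pub_year: Optional[int] = None
    journal_year: Optional[int] = None
    first_pub_date: Optional[str] = None
    electronic_pub_date: Optional[str] = None
    first_index_date: Optional[str] = None
    cited_by_count: Optional[int] = None
    annotations: List[Annotation] = field(default_factory=list)
    # token cache populated lazily by the query engine; not part of identity
    _token_cache: Optional[dict] = field(
        default=None, init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not self.pub_id:
            raise CorpusError("pub_id must be non-empty")
        _check_year(self.pub_year, "pub_year", self.pub_id)
        _check_year(self.journal_year, "journal_year", self.pub_id)
        if self.cited_by_count is not None and self.cited_by_count < 0:
            raise CorpusError(
                f"publication {self.pub_id!r}: negative cited_by_count"
            )

    def invalidate_cache(self) -> None:
        self._token_cache = None


@dataclass
class ChemicalEntity:
    """A ChEBI chemical with structure data and ontology roles."""

    chebi_id: str
    name: str
    formula: str = ""
    smiles: Optional[str] = None
    roles: Set[str] = field(default_factory=set)
    mw: Optional[float] = None
    logp: Optional[float] = None

    def __post_init__(self) -> None:
        if not _CHEBI_RE.match(self.chebi_id):
            raise CorpusError(f"bad ChEBI identifier {self.chebi_id!r}")
        if self.mw is not None and self.mw <= 0:
            raise CorpusError(f"{self.chebi_id}: mw must be positive")


@dataclass
class Corpus:
    publications: List[Publication] = field(default_factory=list)
    entities: Dict[str, ChemicalEntity] = field(default_factory=dict)
    #: annotation rows whose pub_id did not resolve at load time
    orphan_annotations: List[tuple] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.publications)

    def __iter__(self) -> Iterator[Publication]:
        return iter(self.publications)

    def get(self, pub_id: str) -> Optional[Publication]:
        return self._index().get(pub_id)

    def _index(self) -> Dict[str, Publication]:
        return {p.pub_id: p for p in self.publications}

    def unresolved_chebi_ids(self) -> Set[str]:
        """ChEBI ids referenced by annotations but absent from entities."""
        referenced = {
            a.chebi_id for p in self.publications for a in p.annotations
        }
        return referenced - set(self.entities)


# ---------------------------------------------------------------------------
# JSONL publication records

_OPTIONAL_INT = {"pubYear": "pub_year", "citedByCount": "cited_by_count"}
_OPTIONAL_DATE = {
    "firstPublicationDate": "first_pub_date",
    "electronicPublicationDate": "electronic_pub_date",
    "firstIndexDate": "first_index_date",
}
_TEXT = {"title": "title", "abstractText": "abstract", "methodsText": "methods_text"}


def _absent(value) -> bool:
    return value is None or (isinstance(value, str) and value.strip() == "")


def _parse_int(value, key: str, lineno: int) -> int:
    try:
        return int(str(value).strip())
    except (TypeError, ValueError):
        raise CorpusError(f"line {lineno}: field {key!r} is not an integer: {value!r}")


def record_to_publication(rec: dict, lineno: int = 0) -> Publication:
    if _absent(rec.get("id")):
        raise CorpusError(f"line {lineno}: record has no 'id'")
    kwargs: dict = {"pub_id": str(rec["id"])}
    for key, attr in _TEXT.items():
        if not _absent(rec.get(key)):
            kwargs[attr] = str(rec[key])
    for key, attr in _OPTIONAL_INT.items():
        if not _absent(rec.get(key)):
            kwargs[attr] = _parse_int(rec[key], key, lineno)
    ji = rec.get("journalInfo") or {}
    if isinstance(ji, dict) and not _absent(ji.get("yearOfPublication")):
        kwargs["journal_year"] = _parse_int(
            ji["yearOfPublication"], "journalInfo.yearOfPublication", lineno
        )
    for key, attr in _OPTIONAL_DATE.items():
        if not _absent(rec.get(key)):
            kwargs[attr] = str(rec[key]).strip()
    try:
        return Publication(**kwargs)
    except CorpusError as exc:
        raise CorpusError(f"line {lineno}: {exc}") from exc


def publication_to_record(pub: Publication) -> dict:
    rec: dict = {"id": pub.pub_id}
    for key, attr in _TEXT.items():
        if getattr(pub, attr):
            rec[key] = getattr(pub, attr)
    if pub.pub_year is not None:
        rec["pubYear"] = pub.pub_year
    if pub.cited_by_count is not None:
        rec["citedByCount"] = pub.cited_by_count
    if pub.journal_year is not None:
        rec["journalInfo"] = {"yearOfPublication": pub.journal_year}
    for key, attr in _OPTIONAL_DATE.items():
        if getattr(pub, attr) is not None:
            rec[key] = getattr(pub, attr)
    return rec


def read_corpus(path) -> Corpus:
    """Read line-delimited publication records into a :class:`Corpus`.

    Raises :class:`CorpusError` naming the offending line for malformed
    JSON and for duplicate ``pub_id`` values.
    """
    path = Path(path)
    publications: List[Publication] = []
    seen: Set[str] = set()
    with path.open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: malformed record: {exc}") from exc
            pub = record_to_publication(rec, lineno)
            if pub.pub_id in seen:
                raise CorpusError(f"line {lineno}: duplicate pub_id {pub.pub_id!r}")
            seen.add(pub.pub_id)
            publications.append(pub)
    return Corpus(publications=publications)


def write_corpus(corpus: Corpus, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for pub in corpus.publications:
            handle.write(json.dumps(publication_to_record(pub), ensure_ascii=False))
            handle.write("\n")


# ---------------------------------------------------------------------------
# Annotation table (TSV: pub_id, chebi_id, term, count)

_ANNOTATION_COLUMNS = ["pub_id", "chebi_id", "term", "count"]


def read_annotations(path, corpus: Corpus) -> Corpus:
    """Attach ChEBI annotation rows to the matching publications.

    Duplicate ``(pub_id, chebi_id)`` rows have their counts summed (the
    annotation source reports per-sentence hits). Rows referencing an
    unknown ``pub_id`` are collected on ``corpus.orphan_annotations`` and
    reported with a warning, never dropped silently.
    """
    path = Path(path)
    index = corpus._index()
    merged: Dict[tuple, List] = {}
    orphans: List[tuple] = []
    with path.open("r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != _ANNOTATION_COLUMNS:
            raise CorpusError(
                f"annotation table must have columns {_ANNOTATION_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise CorpusError(f"line {lineno}: expected 4 columns, got {len(parts)}")
            pub_id, chebi_id, term, count_s = parts
            count = _parse_int(count_s, "count", lineno)
            if count <= 0:
                raise CorpusError(f"line {lineno}: count must be positive, got {count}")
            if pub_id not in index:
                orphans.append((pub_id, chebi_id, term, count))
                continue
            key = (pub_id, chebi_id)
            if key in merged:
                merged[key][1] += count
            else:
                merged[key] = [term, count]
    for (pub_id, chebi_id), (term, count) in merged.items():
        index[pub_id].annotations.append(Annotation(chebi_id, term, count))
    corpus.orphan_annotations.extend(orphans)
    if orphans:
        warnings.warn(
            f"{len(orphans)} annotation row(s) referenced unknown publications "
            "and were kept as orphans",
            stacklevel=2,
        )
    return corpus


def write_annotations(corpus: Corpus, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("\t".join(_ANNOTATION_COLUMNS) + "\n")
        for pub in corpus.publications:
            for ann in pub.annotations:
                handle.write(f"{pub.pub_id}\t{ann.chebi_id}\t{ann.term}\t{ann.count}\n")


# ---------------------------------------------------------------------------
# Entity table (TSV: chebi_id, name, formula, smiles, roles, mw, logp)

_ENTITY_COLUMNS = ["chebi_id", "name", "formula", "smiles", "roles", "mw", "logp"]


def read_entities(path) -> Dict[str, ChemicalEntity]:
    """Load the per-ChEBI structure table into a chebi_id -> entity map.

    An unparseable molecular formula does not reject the row: the entity
    is loaded with molecular weight unavailable and a warning is issued.
    """
    from .property_landscape import parse_formula  # local import: avoids cycle

    path = Path(path)
    entities: Dict[str, ChemicalEntity] = {}
    with path.open("r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != _ENTITY_COLUMNS:
            raise CorpusError(
                f"entity table must have columns {_ENTITY_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_ENTITY_COLUMNS):
                raise CorpusError(
                    f"line {lineno}: expected {len(_ENTITY_COLUMNS)} columns"
                )
            chebi_id, name, formula, smiles, roles_s, mw_s, logp_s = parts
            roles = {r.strip() for r in roles_s.split(";") if r.strip()}
            mw = float(mw_s) if mw_s.strip() else None
            logp = float(logp_s) if logp_s.strip() else None
            entity = ChemicalEntity(
                chebi_id=chebi_id,
                name=name,
                formula=formula,
                smiles=smiles.strip() or None,
                roles=roles,
                mw=mw,
                logp=logp,
            )
            if formula.strip() and mw is None:
                try:
                    parse_formula(formula)
                except ValueError:
                    warnings.warn(
                        f"line {lineno}: formula {formula!r} unparseable; "
                        f"molecular weight unavailable for {chebi_id}",
                        stacklevel=2,
                    )
            entities[chebi_id] = entity
    return entities


def write_entities(entities: Dict[str, ChemicalEntity], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("\t".join(_ENTITY_COLUMNS) + "\n")
        for entity in entities.values():
            handle.write(
                "\t".join(
                    [
                        entity.chebi_id,
                        entity.name,
                        entity.formula,
                        entity.smiles or "",
                        ";".join(sorted(entity.roles)),
                        "" if entity.mw is None else repr(entity.mw),
                        "" if entity.logp is None else repr(entity.logp),
                    ]
                )
                + "\n"
            )
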