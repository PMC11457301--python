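"""Matrix co-occurrence enrichment statistics.

For each candidate matrix substance (searched as an OR over its synonyms
across all text fields) this module counts the publications mentioning
the substance, the co-occurrences with the ionization-technique query,
and the co-occurrences with the technique plus three analyte contexts:
"small molecule(s)" (SM), "peptide(s) OR protein(s)" (PP) and
"oligomer(s) OR polymer(s)" (OP). Enrichment uses the field's simple
rule: a substance is flagged when its technique co-occurrence fraction
is at least five times the background rate (the mean fraction over
common non-matrix chemicals) and it co-occurs in at least 10
publications. SM/PP and SM/OP ratios summarize whether a matrix is
preferentially applied to small molecules.

Ratios with a zero denominator are carried as ``None`` (undefined), not
zero, and never raise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources as _ilres
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .corpus_model import Corpus
from .query_engine import And, Or, QueryNode, Term, count_matches, parse_query

#: analyte-context queries, plural-inclusive, unrestricted fields
CONTEXT_QUERY_STRINGS: Dict[str, str] = {
    "SM": '"small molecule" OR "small molecules"',
    "PP": "peptide OR peptides OR protein OR proteins",
    "OP": "oligomer OR oligomers OR polymer OR polymers",
}


def context_queries() -> Dict[str, QueryNode]:
    return {k: parse_query(v) for k, v in CONTEXT_QUERY_STRINGS.items()}


@dataclass
class Substance:
    """A chemical searched by name and synonyms (unrestricted fields)."""

    name: str
    synonyms: List[str] = field(default_factory=list)
    chebi_id: Optional[str] = None
    curated_matrix: bool = False

    def all_terms(self) -> List[str]:
        terms = [self.name] + [s for s in self.synonyms if s.strip()]
        # preserve order, drop case-insensitive duplicates
        seen, out = set(), []
        for t in terms:
            key = t.strip().lower()
            if key and key not in seen:
                seen.add(key)
                out.append(t.strip())
        return out


def substance_query(substance: Substance) -> QueryNode:
    """OR over the substance's synonyms; matrix searches are not
    METHODS-restricted."""
    terms = [Term(t) for t in substance.all_terms()]
    if not terms:
        raise ValueError(f"substance {substance.name!r} has no synonyms")
    return terms[0] if len(terms) == 1 else Or(tuple(terms))


@dataclass
class CooccurrenceRow:
    substance: str
    synonyms: List[str]
    total: int
    with_technique: int
    with_sm: int
    with_pp: int
    with_op: int
    enriched: bool = False

    def __post_init__(self):
        if not (0 <= self.with_technique <= self.total):
            raise ValueError(
                f"{self.substance}: with_technique={self.with_technique} "
                f"outside [0, total={self.total}]"
            )
        for name in ("with_sm", "with_pp", "with_op"):
            if getattr(self, name) > self.with_technique:
                raise ValueError(
                    f"{self.substance}: {name} exceeds with_technique"
                )

    @property
    def technique_fraction(self) -> Optional[float]:
        return context_ratio(self.with_technique, self.total)

    @property
    def sm_pp(self) -> Optional[float]:
        return context_ratio(self.with_sm, self.with_pp)

    @property
    def sm_op(self) -> Optional[float]:
        return context_ratio(self.with_sm, self.with_op)


@dataclass
class BackgroundRate:
    """Technique co-occurrence background over non-matrix chemicals."""

    mean_percent: float
    sd_percent: float
    n_substances: int
    fractions_percent: Dict[str, float]


def build_cooccurrence_table(
    corpus: Corpus,
    substances: Sequence[Substance],
    technique: QueryNode,
    contexts: Optional[Dict[str, QueryNode]] = None,
) -> List[CooccurrenceRow]:
    """One row per substance, sorted by technique co-occurrences, descending.

    ``with_sm``/``with_pp``/``with_op`` count publications matching the
    substance AND the technique AND the respective context query.
    """
    if contexts is None:
        contexts = context_queries()
    rows: List[CooccurrenceRow] = []
    for substance in substances:
        sq = substance_query(substance)
        total = count_matches(corpus, sq)
        with_tech_q = And((sq, technique))
        with_technique = count_matches(corpus, with_tech_q)
        joint = {
            key: count_matches(corpus, And((with_tech_q, contexts[key])))
            for key in ("SM", "PP", "OP")
        }
        rows.append(
            CooccurrenceRow(
                substance=substance.name,
                synonyms=substance.all_terms(),
                total=total,
                with_technique=with_technique,
                with_sm=joint["SM"],
                with_pp=joint["PP"],
                with_op=joint["OP"],
            )
        )
    rows.sort(key=lambda r: (-r.with_technique, -r.total, r.substance))
    return rows


def background_rate(
    corpus: Corpus, nonmatrix: Sequence[Substance], technique: QueryNode
) -> BackgroundRate:
    """Mean and sample SD of technique co-occurrence percent over the
    non-matrix baseline chemicals. Chemicals matching no publication are
    excluded with a warning (their fraction is undefined)."""
    fractions: Dict[str, float] = {}
    for substance in nonmatrix:
        sq = substance_query(substance)
        total = count_matches(corpus, sq)
        if total == 0:
            warnings.warn(
                f"background substance {substance.name!r} matches no "
                "publications; excluded",
                stacklevel=2,
            )
            continue
        joint = count_matches(corpus, And((sq, technique)))
        fractions[substance.name] = 100.0 * joint / total
    if len(fractions) < 2:
        raise ValueError(
            "background rate needs at least 2 substances with matches"
        )
    values = list(fractions.values())
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return BackgroundRate(
        mean_percent=mean,
        sd_percent=sd,
        n_substances=n,
        fractions_percent=fractions,
    )


def flag_enriched(
    rows: Sequence[CooccurrenceRow],
    background: BackgroundRate,
    fold: float = 5.0,
    min_count: int = 10,
) -> List[CooccurrenceRow]:
    """Apply the enrichment rule: technique fraction >= fold x background
    mean AND at least *min_count* technique co-occurrences."""
    if background.mean_percent <= 0:
        raise ValueError("background mean must be positive")
    threshold = fold * background.mean_percent / 100.0
    out = []
    for row in rows:
        frac = row.technique_fraction
        enriched = (
            frac is not None
            and frac >= threshold
            and row.with_technique >= min_count
        )
        out.append(replace(row, enriched=enriched))
    return out


def context_ratio(numerator: int, denominator: int) -> Optional[float]:
    """numerator/denominator, or ``None`` when the denominator is zero."""
    if denominator == 0:
        return None
    return numerator / denominator


def pooled_weighted_average(
    rows: Sequence[CooccurrenceRow],
    context: str = "PP",
    mode: str = "pooled",
) -> Optional[float]:
    """Weighted average of SM/<context> over the table.

    ``mode="pooled"`` (default) is the pooled ratio sum(SM)/sum(context)
    over rows with a nonzero context count — equivalently a per-row-ratio
    mean weighted by the context counts, hence always within the range of
    the defined per-row ratios and equal to the row ratio for a single
    row. ``mode="row_weighted"`` is the mean of per-row ratios weighted by
    each row's technique co-occurrence count.
    """
    if context not in ("PP", "OP"):
        raise ValueError("context must be 'PP' or 'OP'")
    attr = "with_pp" if context == "PP" else "with_op"
    defined = [r for r in rows if getattr(r, attr) > 0]
    if not defined:
        return None
    if mode == "pooled":
        num = sum(r.with_sm for r in defined)
        den = sum(getattr(r, attr) for r in defined)
        return num / den
    if mode == "row_weighted":
        weights = [r.with_technique for r in defined]
        if sum(weights) == 0:
            return None
        ratios = [r.with_sm / getattr(r, attr) for r in defined]
        return sum(w * x for w, x in zip(weights, ratios)) / sum(weights)
    raise ValueError(f"unknown mode {mode!r}")


def expected_ratio(n_context_a: int, n_context_b: int) -> Optional[float]:
    """Corpus-size ratio a/b to 3 decimals; ``None`` for a zero denominator.

    This is the ratio naively expected for SM/PP (or SM/OP) if matrix
    mentions were independent of analyte context.
    """
    if n_context_b == 0:
        return None
    return round(n_context_a / n_context_b, 3)


def excess_over_expected(weighted: float, expected: float) -> float:
    """Percent excess of the observed weighted ratio over the expected one."""
    if expected <= 0:
        raise ValueError("expected ratio must be positive")
    return 100.0 * (weighted - expected) / expected


# ---------------------------------------------------------------------------
# Shipped substance lists and reference counts


def _read_substances_text(text: str) -> List[Substance]:
    out: List[Substance] = []
    lines = text.splitlines()
    header = lines[0].split("\t")
    expected = ["name", "synonyms", "chebi_id", "is_curated_matrix", "is_matrix"]
    if header != expected:
        raise ValueError(f"substance table must have columns {expected}")
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        name, synonyms_s, chebi_id, curated_s, _is_matrix = line.split("\t")
        out.append(
            Substance(
                name=name,
                synonyms=[s.strip() for s in synonyms_s.split(";") if s.strip()],
                chebi_id=chebi_id.strip() or None,
                curated_matrix=curated_s.strip() == "1",
            )
        )
    return out


def read_substances(path) -> List[Substance]:
    return _read_substances_text(Path(path).read_text("utf-8"))


def _load_resource_substances(is_matrix: bool) -> List[Substance]:
    text = (
        _ilres.files("lditrends.resources").joinpath("substances.tsv").read_text("utf-8")
    )
    lines = text.splitlines()
    keep = []
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        if (line.split("\t")[4].strip() == "1") == is_matrix:
            keep.append(line)
    return _read_substances_text("\n".join([lines[0]] + keep))


def default_matrix_substances() -> List[Substance]:
    """The candidate MALDI matrix substances shipped with the package."""
    return _load_resource_substances(is_matrix=True)


def default_nonmatrix_substances() -> List[Substance]:
    """The 10 common non-matrix baseline chemicals."""
    return _load_resource_substances(is_matrix=False)


def load_reference_counts() -> List[CooccurrenceRow]:
    """The published co-occurrence counts for the 19 enriched matrices.

    SM/PP and SM/OP counts are not published individually, only their
    ratios, so the context fields are zero here; the rows carry the
    (with_technique, total) pairs needed for fraction and enrichment
    arithmetic.
    """
    text = (
        _ilres.files("lditrends.resources")
        .joinpath("reference_matrix_counts.tsv")
        .read_text("utf-8")
    )
    rows: List[CooccurrenceRow] = []
    lines = text.splitlines()
    assert lines[0].split("\t") == [
        "name",
        "with_maldi",
        "total",
        "sm_pp",
        "sm_op",
        "curated",
    ]
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        name, with_maldi, total, _sm_pp, _sm_op, _curated = line.split("\t")
        rows.append(
            CooccurrenceRow(
                substance=name,
                synonyms=[name],
                total=int(total),
                with_technique=int(with_maldi),
                with_sm=0,
                with_pp=0,
                with_op=0,
            )
        )
    return rows


def write_table(rows: Sequence[CooccurrenceRow], path, decimals: int = 3) -> None:
    """Write the co-occurrence table as TSV.

    Ratios use *decimals* places (2 matches the published table style,
    3 is the machine default); undefined ratios are written as ``NA``.
    """

    def fmt(x: Optional[float]) -> str:
        return "NA" if x is None else f"{x:.{decimals}f}"

    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write(
            "substance\twith_technique\ttotal\ttechnique_fraction\t"
            "with_sm\twith_pp\twith_op\tsm_pp\tsm_op\tenriched\n"
        )
        for r in rows:
            handle.write(
                "\t".join(
                    [
                        r.substance,
                        str(r.with_technique),
                        str(r.total),
                        fmt(r.technique_fraction),
                        str(r.with_sm),
                        str(r.with_pp),
                        str(r.with_op),
                        fmt(r.sm_pp),
                        fmt(r.sm_op),
                        "1" if r.enriched else "0",
                    ]
                )
                + "\n"
            )
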