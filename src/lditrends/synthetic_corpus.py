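"""Seeded synthetic literature corpora with exact ground truth.

Emulates the structure of a mass-spectrometry literature corpus without
any download: latent per-publication technique labels drive injection of
technique phrases into methods sections (together with the "mass
spectrometry" guard phrase), matrix-substance mentions follow
conditional probabilities given the technique label, common non-matrix
chemicals co-occur with the technique at a configurable ~1% background
rate, analyte classes with distinct molecular-weight/logP distributions
supply ChEBI-style annotations, year metadata is populated through the
five-field fallback chain with configurable missingness, and citation
counts are overdispersed (negative binomial) with age-proportional
means so the citations-per-age score has a flat expectation.

Phrase injection is lossless by construction: surrounding filler text is
drawn from a fixed vocabulary disjoint from every query token, and no
injected phrase may be a token-subsequence of another (validated at
configuration time). Counting the generated text with the query engine
therefore reproduces the recorded ground truth exactly.

One global seed feeds counter-derived per-publication substreams, so
corpora are byte-identical across runs for a fixed configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .corpus_model import Annotation, ChemicalEntity, Corpus, Publication
from .enrichment_stats import CooccurrenceRow, Substance
from .query_engine import tokenize

#: phrases injected per analyte context; each matches the corresponding
#: plural-inclusive context query
CONTEXT_PHRASES: Dict[str, str] = {
    "SM": "small molecules",
    "PP": "peptides",
    "OP": "polymers",
}

GUARD_PHRASE = "mass spectrometry"

#: fixed filler vocabulary; disjoint from every query token (validated)
FILLER_WORDS: Tuple[str, ...] = (
    "study", "results", "sample", "measured", "observed", "reported",
    "values", "signal", "baseline", "control", "experiment", "assay",
    "method", "described", "procedure", "buffer", "gradient", "column",
    "instrument", "settings", "replicates", "averaged", "figure",
    "table", "dataset", "collected", "prepared", "dissolved", "mixed",
    "incubated", "temperature", "minutes", "hours", "analysis",
    "performed", "standard", "curve", "calibration", "obtained",
    "discussed", "evaluated", "compared", "groups", "conditions",
    "significant", "increase", "decrease", "overall",
)


class AnalyteClass(BaseModel):
    """A compound class with lognormal MW and normal logP distributions."""

    name: str
    n_entities: int = Field(default=20, ge=1)
    mw_log_mu: float = 5.2  # ln(Da)
    mw_log_sigma: float = Field(default=0.4, gt=0)
    logp_mu: float = 0.5
    logp_sigma: float = Field(default=1.0, gt=0)
    mention_rate: float = Field(default=0.3, ge=0.0, le=1.0)


class CitationModel(BaseModel):
    """Negative-binomial citations with mean proportional to age."""

    mean_per_year: float = Field(default=0.8, ge=0.0)
    dispersion: float = Field(default=1.2, gt=0.0)
    missing_rate: float = Field(default=0.02, ge=0.0, le=1.0)


class GeneratorConfig(BaseModel):
    n_publications: int = Field(default=10_000, ge=1)
    technique_prevalence: Dict[str, float] = Field(
        default_factory=lambda: {"MALDI": 0.08}
    )
    focal_technique: str = "MALDI"
    #: substance -> technique -> P(mention | technique label fired)
    matrix_given_technique: Dict[str, Dict[str, float]] = Field(
        default_factory=lambda: {
            "hydroxycinnamic acid": {"MALDI": 0.35},
            "dihydroxybenzoic acid": {"MALDI": 0.25},
            "sinapic acid": {"MALDI": 0.10},
            "aminoacridine": {"MALDI": 0.06},
            "diphenylanthracene": {"MALDI": 0.005},
        }
    )
    #: substance -> P(mention | no relevant technique fired)
    substance_base_rate: Dict[str, float] = Field(
        default_factory=lambda: {
            "hydroxycinnamic acid": 0.0005,
            "dihydroxybenzoic acid": 0.003,
            "sinapic acid": 0.004,
            "aminoacridine": 0.002,
            "diphenylanthracene": 0.005,
        }
    )
    substance_synonyms: Dict[str, List[str]] = Field(
        default_factory=lambda: {"sinapic acid": ["sinapinic acid"]}
    )
    #: non-matrix chemical -> marginal mention probability
    nonmatrix_marginal: Dict[str, float] = Field(
        default_factory=lambda: {
            "adenosine": 0.03,
            "alanine": 0.04,
            "ascorbic acid": 0.03,
            "chlorophyll": 0.02,
            "cholesterol": 0.05,
            "cisplatin": 0.02,
            "cocaine": 0.02,
            "glucose": 0.08,
            "nicotine": 0.03,
            "water": 0.15,
        }
    )
    #: P(focal technique | non-matrix chemical mentioned)
    background_rate: float = Field(default=0.01, ge=0.0, le=1.0)
    context_given_technique: Dict[str, float] = Field(
        default_factory=lambda: {"SM": 0.30, "PP": 0.50, "OP": 0.15}
    )
    context_base_rate: Dict[str, float] = Field(
        default_factory=lambda: {"SM": 0.05, "PP": 0.10, "OP": 0.04}
    )
    analyte_classes: List[AnalyteClass] = Field(
        default_factory=lambda: [
            AnalyteClass(
                name="small_metabolites", n_entities=30,
                mw_log_mu=math.log(180.0), mw_log_sigma=0.35,
                logp_mu=0.5, logp_sigma=1.2, mention_rate=0.5,
            ),
            AnalyteClass(
                name="lipids", n_entities=20,
                mw_log_mu=math.log(700.0), mw_log_sigma=0.25,
                logp_mu=6.0, logp_sigma=2.0, mention_rate=0.2,
            ),
            AnalyteClass(
                name="oligosaccharides", n_entities=15,
                mw_log_mu=math.log(600.0), mw_log_sigma=0.5,
                logp_mu=-2.3, logp_sigma=0.3, mention_rate=0.15,
            ),
        ]
    )
    year_range: Tuple[int, int] = (1990, 2023)
    year_missing_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    #: categorical weights over the five year sources, given not missing
    year_field_weights: List[float] = Field(
        default_factory=lambda: [0.70, 0.10, 0.10, 0.05, 0.05]
    )
    citation_model: CitationModel = Field(default_factory=CitationModel)
    reference_year: int = 2023
    seed: int = Field(default=1, ge=0)

    @model_validator(mode="after")
    def _validate(self) -> "GeneratorConfig":
        for name, p in self.technique_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"technique prevalence {name}: {p} not in [0,1]")
        if self.focal_technique not in self.technique_prevalence:
            raise ValueError(
                f"focal technique {self.focal_technique!r} has no prevalence"
            )
        for sub, by_tech in self.matrix_given_technique.items():
            if sub not in self.substance_base_rate:
                raise ValueError(f"matrix {sub!r} lacks a base rate")
            for tech, p in by_tech.items():
                if tech not in self.technique_prevalence:
                    raise ValueError(f"{sub!r}: unknown technique {tech!r}")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{sub!r}|{tech!r}: {p} not in [0,1]")
        for table in (
            self.substance_base_rate,
            self.nonmatrix_marginal,
            self.context_given_technique,
            self.context_base_rate,
        ):
            for key, p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability {key!r}={p} not in [0,1]")
        if set(self.context_given_technique) != set(CONTEXT_PHRASES) or set(
            self.context_base_rate
        ) != set(CONTEXT_PHRASES):
            raise ValueError(f"context rates must cover {sorted(CONTEXT_PHRASES)}")
        p_focal = self.technique_prevalence[self.focal_technique]
        if p_focal > 0:
            for chem, m in self.nonmatrix_marginal.items():
                if self.background_rate * m / p_focal > 1.0:
                    raise ValueError(
                        f"non-matrix chemical {chem!r}: implied "
                        "P(mention|technique) exceeds 1"
                    )
        if p_focal < 1.0:
            for chem, m in self.nonmatrix_marginal.items():
                if (1 - self.background_rate) * m / (1 - p_focal) > 1.0:
                    raise ValueError(
                        f"non-matrix chemical {chem!r}: implied "
                        "P(mention|no technique) exceeds 1"
                    )
        if len(self.year_field_weights) != 5:
            raise ValueError("year_field_weights must have 5 entries")
        if min(self.year_field_weights) < 0 or sum(self.year_field_weights) <= 0:
            raise ValueError("year_field_weights must be non-negative, sum > 0")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (min, max)")
        self._validate_phrases()
        return self

    # -- phrase-collision validation -------------------------------------
    def _phrase_groups(self) -> Dict[str, List[str]]:
        groups: Dict[str, List[str]] = {
            f"technique:{t}": [t] for t in self.technique_prevalence
        }
        groups["guard"] = [GUARD_PHRASE]
        for key, phrase in CONTEXT_PHRASES.items():
            groups[f"context:{key}"] = [phrase]
        for sub in list(self.matrix_given_technique) + list(self.nonmatrix_marginal):
            groups[f"substance:{sub}"] = [sub] + self.substance_synonyms.get(sub, [])
        return groups

    def _validate_phrases(self) -> None:
        groups = self._phrase_groups()
        tokenized = {
            g: [tokenize(p) for p in phrases] for g, phrases in groups.items()
        }
        all_tokens = {t for seqs in tokenized.values() for s in seqs for t in s}
        filler_overlap = all_tokens & set(FILLER_WORDS)
        if filler_overlap:
            raise ValueError(
                f"filler vocabulary collides with query tokens: {filler_overlap}"
            )
        names = [g for g in tokenized if g != "guard"]
        for i, ga in enumerate(names):
            for gb in names[i + 1 :]:
                for sa in tokenized[ga]:
                    for sb in tokenized[gb]:
                        if _contains(sa, sb) or _contains(sb, sa):
                            raise ValueError(
                                f"injected phrases collide across groups "
                                f"{ga!r} and {gb!r}"
                            )

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        data = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        return cls(**data)


def _contains(haystack: Tuple[str, ...], needle: Tuple[str, ...]) -> bool:
    k = len(needle)
    if k == 0 or k > len(haystack):
        return False
    return any(haystack[i : i + k] == needle for i in range(len(haystack) - k + 1))


# ---------------------------------------------------------------------------
# Ground truth containers


@dataclass
class PubTruth:
    pub_id: str
    techniques: Set[str]
    substances: Set[str]
    contexts: Set[str]
    latent_year: int
    year_provenance: str
    citations: int
    citations_missing: bool
    annotations: List[Tuple[str, int]] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Realized latent state of a generated corpus."""

    per_pub: List[PubTruth]
    entities: Dict[str, ChemicalEntity]
    entity_class: Dict[str, str]
    config: GeneratorConfig

    def substance_counts(
        self, substance: str, technique: Optional[str] = None
    ) -> Dict[str, int]:
        technique = technique or self.config.focal_technique
        total = with_tech = 0
        ctx = {key: 0 for key in CONTEXT_PHRASES}
        for pub in self.per_pub:
            if substance not in pub.substances:
                continue
            total += 1
            if technique in pub.techniques:
                with_tech += 1
                for key in ctx:
                    if key in pub.contexts:
                        ctx[key] += 1
        return {
            "total": total,
            "with_technique": with_tech,
            "with_sm": ctx["SM"],
            "with_pp": ctx["PP"],
            "with_op": ctx["OP"],
        }

    def class_property_moments(self) -> Dict[str, Dict[str, float]]:
        """Realized per-class MW/logP moments over publication-entity pairs."""
        values: Dict[str, List[Tuple[float, float]]] = {}
        for pub in self.per_pub:
            for chebi_id, _count in pub.annotations:
                cls = self.entity_class.get(chebi_id)
                if cls is None:
                    continue
                entity = self.entities[chebi_id]
                values.setdefault(cls, []).append((entity.mw, entity.logp))
        out: Dict[str, Dict[str, float]] = {}
        for cls, pairs in values.items():
            mw = np.array([p[0] for p in pairs])
            logp = np.array([p[1] for p in pairs])
            out[cls] = {
                "n_pairs": float(len(pairs)),
                "mw_mean": float(mw.mean()),
                "mw_sd": float(mw.std(ddof=1)) if len(pairs) > 1 else 0.0,
                "logp_mean": float(logp.mean()),
                "logp_sd": float(logp.std(ddof=1)) if len(pairs) > 1 else 0.0,
            }
        return out


def truth_summary(
    truth: GroundTruth,
    substances: Optional[Sequence[str]] = None,
    technique: Optional[str] = None,
) -> List[CooccurrenceRow]:
    """Exact realized co-occurrence table (same sort order as the
    pipeline's) against which pipeline estimates are compared."""
    if substances is None:
        substances = list(truth.config.matrix_given_technique)
    rows = []
    for name in substances:
        counts = truth.substance_counts(name, technique)
        rows.append(
            CooccurrenceRow(
                substance=name,
                synonyms=[name] + truth.config.substance_synonyms.get(name, []),
                **counts,
            )
        )
    rows.sort(key=lambda r: (-r.with_technique, -r.total, r.substance))
    return rows


def implied_technique_given_substance(
    config: GeneratorConfig, substance: str, technique: Optional[str] = None
) -> float:
    """P(technique | substance mentioned) implied by the generative model
    for a substance conditioned on a single technique."""
    technique = technique or config.focal_technique
    p_t = config.technique_prevalence[technique]
    q = config.matrix_given_technique[substance][technique]
    b = config.substance_base_rate[substance]
    denom = p_t * q + (1 - p_t) * b
    if denom == 0:
        raise ValueError(f"{substance!r} is never mentioned under this model")
    return p_t * q / denom


def config_substances(config: GeneratorConfig) -> Tuple[List[Substance], List[Substance]]:
    """(matrix, non-matrix) substance lists matching the generator model."""
    matrices = [
        Substance(name=name, synonyms=config.substance_synonyms.get(name, []))
        for name in config.matrix_given_technique
    ]
    nonmatrix = [
        Substance(name=name, synonyms=config.substance_synonyms.get(name, []))
        for name in config.nonmatrix_marginal
    ]
    return matrices, nonmatrix


# ---------------------------------------------------------------------------
# Generation


def _approx_formula(mw: float) -> str:
    carbons = max(1, int(round(mw / 13.0)))
    hydrogens = max(0, int(round((mw - 12.011 * carbons) / 1.008)))
    return f"C{carbons}H{hydrogens}" if hydrogens else f"C{carbons}"


def _make_entities(
    config: GeneratorConfig,
) -> Tuple[Dict[str, ChemicalEntity], Dict[str, str], Dict[str, str]]:
    """Entities for analyte classes, matrix substances and non-matrix
    chemicals. Returns (entities, chebi->class, substance->chebi)."""
    rng = np.random.default_rng([config.seed, 1_000_003])
    entities: Dict[str, ChemicalEntity] = {}
    entity_class: Dict[str, str] = {}
    substance_entity: Dict[str, str] = {}
    next_id = 9_000_001
    for cls in config.analyte_classes:
        for k in range(cls.n_entities):
            chebi_id = f"CHEBI:{next_id}"
            next_id += 1
            mw = float(np.exp(rng.normal(cls.mw_log_mu, cls.mw_log_sigma)))
            logp = float(rng.normal(cls.logp_mu, cls.logp_sigma))
            entities[chebi_id] = ChemicalEntity(
                chebi_id=chebi_id,
                name=f"{cls.name}-{k:03d}",
                formula=_approx_formula(mw),
                mw=round(mw, 3),
                logp=round(logp, 3),
            )
            entity_class[chebi_id] = cls.name
    for name in list(config.matrix_given_technique) + list(config.nonmatrix_marginal):
        chebi_id = f"CHEBI:{next_id}"
        next_id += 1
        mw = float(np.exp(rng.normal(math.log(220.0), 0.25)))
        logp = float(rng.normal(1.5, 1.0))
        roles = (
            {"MALDI matrix material"}
            if name in config.matrix_given_technique
            else set()
        )
        entities[chebi_id] = ChemicalEntity(
            chebi_id=chebi_id,
            name=name,
            formula=_approx_formula(mw),
            roles=roles,
            mw=round(mw, 3),
            logp=round(logp, 3),
        )
        substance_entity[name] = chebi_id
    return entities, entity_class, substance_entity


def _filler(rng: np.random.Generator, n: int) -> List[str]:
    return [FILLER_WORDS[i] for i in rng.integers(0, len(FILLER_WORDS), n)]


_DATE_SUFFIX = {
    "first_pub_date": "-03-15",
    "electronic_pub_date": "-05-01",
    "first_index_date": "-06-20",
}

_YEAR_SOURCES = (
    "pubYear",
    "journal_year",
    "first_pub_date",
    "electronic_pub_date",
    "first_index_date",
)


def generate_corpus(config: GeneratorConfig) -> Tuple[Corpus, GroundTruth]:
    """Generate a corpus and its exact ground truth; deterministic for a
    fixed configuration (including its seed)."""
    entities, entity_class, substance_entity = _make_entities(config)
    p_focal = config.technique_prevalence[config.focal_technique]
    weights = np.asarray(config.year_field_weights, dtype=float)
    weights = weights / weights.sum()
    publications: List[Publication] = []
    per_pub: List[PubTruth] = []

    for i in range(config.n_publications):
        rng = np.random.default_rng([config.seed, i])
        pub_id = f"SYN{i:07d}"

        fired = {
            t for t, p in config.technique_prevalence.items() if rng.random() < p
        }
        focal_fired = config.focal_technique in fired

        substances: Set[str] = set()
        for name, by_tech in config.matrix_given_technique.items():
            relevant = [by_tech[t] for t in by_tech if t in fired]
            p = max(relevant) if relevant else config.substance_base_rate[name]
            if rng.random() < p:
                substances.add(name)
        for name, m in config.nonmatrix_marginal.items():
            if focal_fired:
                p = config.background_rate * m / p_focal if p_focal > 0 else 0.0
            else:
                p = (
                    (1 - config.background_rate) * m / (1 - p_focal)
                    if p_focal < 1
                    else 0.0
                )
            if rng.random() < p:
                substances.add(name)

        contexts = {
            key
            for key in CONTEXT_PHRASES
            if rng.random()
            < (
                config.context_given_technique[key]
                if focal_fired
                else config.context_base_rate[key]
            )
        }

        annotations: List[Tuple[str, int]] = []
        for cls in config.analyte_classes:
            if rng.random() < cls.mention_rate:
                pool = [c for c, n in entity_class.items() if n == cls.name]
                chebi_id = pool[int(rng.integers(0, len(pool)))]
                count = 1 + int(rng.poisson(0.7))
                annotations.append((chebi_id, count))
        for name in substances:
            annotations.append((substance_entity[name], 1))

        # ---- metadata
        latent_year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
        year_missing = rng.random() < config.year_missing_rate
        if year_missing:
            provenance = "imputed_median"
        else:
            source_idx = int(rng.choice(5, p=weights))
            provenance = _YEAR_SOURCES[source_idx]

        age = max(config.reference_year - latent_year, 1)
        cm = config.citation_model
        mean = cm.mean_per_year * age
        if mean > 0:
            p_nb = cm.dispersion / (cm.dispersion + mean)
            citations = int(rng.negative_binomial(cm.dispersion, p_nb))
        else:
            citations = 0
        citations_missing = rng.random() < cm.missing_rate

        # ---- text assembly
        title = " ".join(_filler(rng, 5))
        abstract_words = _filler(rng, 6)
        for name in sorted(substances):
            synonyms = [name] + config.substance_synonyms.get(name, [])
            phrase = synonyms[int(rng.integers(0, len(synonyms)))]
            abstract_words += [phrase] + _filler(rng, 2)
        for key in sorted(contexts):
            abstract_words += [CONTEXT_PHRASES[key]] + _filler(rng, 2)
        abstract = " ".join(abstract_words)
        methods_words = _filler(rng, 4)
        for t in sorted(fired):
            methods_words += [t] + _filler(rng, 1)
        if fired:
            methods_words += [GUARD_PHRASE] + _filler(rng, 2)
        methods = " ".join(methods_words)

        kwargs: dict = {}
        if not year_missing:
            chain = _YEAR_SOURCES[source_idx:]
            if "pubYear" in chain:
                kwargs["pub_year"] = latent_year
            if "journal_year" in chain:
                kwargs["journal_year"] = latent_year
            for attr in ("first_pub_date", "electronic_pub_date", "first_index_date"):
                if attr in chain:
                    kwargs[attr] = f"{latent_year}{_DATE_SUFFIX[attr]}"
        if not citations_missing:
            kwargs["cited_by_count"] = citations

        pub = Publication(
            pub_id=pub_id,
            title=title,
            abstract=abstract,
            methods_text=methods,
            annotations=[
                Annotation(chebi_id, entities[chebi_id].name, count)
                for chebi_id, count in annotations
            ],
            **kwargs,
        )
        publications.append(pub)
        per_pub.append(
            PubTruth(
                pub_id=pub_id,
                techniques=fired,
                substances=substances,
                contexts=contexts,
                latent_year=latent_year,
                year_provenance=provenance,
                citations=citations,
                citations_missing=citations_missing,
                annotations=annotations,
            )
        )

    corpus = Corpus(publications=publications, entities=entities)
    truth = GroundTruth(
        per_pub=per_pub,
        entities=entities,
        entity_class=entity_class,
        config=config,
    )
    return corpus, truth
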