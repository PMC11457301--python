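"""Molecular-property landscapes of text-mined chemical annotations.

Places every ChEBI entity annotated in a corpus slice (e.g. the
publications matching one ionization-technique query) in the
(logP, molecular weight) plane and bins the occurrence density on a 2D
grid, after removing known matrix substances (entities carrying the
ChEBI role "MALDI matrix material") which trivially co-occur with the
technique terms. Molecular weight comes from an explicit entity value
or is computed from the Hill-notation formula with standard atomic
weights; logP comes from an explicit entity value or a Wildman–Crippen
atomic-contribution estimate of the SMILES. Entities with neither are
excluded with a warning, never silently.

Axis convention: x = logP, y = molecular weight (Da), so a compound
class with a shared logP and varying mass appears as a vertical line.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .corpus_model import ChemicalEntity, Corpus
from .query_engine import QueryNode, match

logger = logging.getLogger(__name__)

MATRIX_ROLE = "MALDI matrix material"

#: default grid: logP in [-10, 15] step 0.5; MW in [0, 1500] Da step 25
DEFAULT_LOGP_EDGES = np.arange(-10.0, 15.0 + 0.25, 0.5)
DEFAULT_MW_EDGES = np.arange(0.0, 1500.0 + 12.5, 25.0)

WEIGHTING_MODES = ("paper_chebi_pairs", "recognitions")


# ---------------------------------------------------------------------------
# Molecular properties

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-notation molecular formula into element -> count.

    Dot-separated components are summed; a trailing charge sign is
    ignored. Raises ``ValueError`` on empty or unparseable input.
    """
    from rdkit import Chem

    # strip a trailing charge ("+", "-3"); bare trailing digits are counts
    cleaned = re.sub(r"[+-]\d*$", "", formula.strip())
    if not cleaned:
        raise ValueError("empty molecular formula")
    table = Chem.GetPeriodicTable()
    counts: Dict[str, int] = {}
    for part in cleaned.split("."):
        pos = 0
        for m in _FORMULA_TOKEN.finditer(part):
            if m.start() != pos:
                raise ValueError(f"unparseable formula {formula!r}")
            symbol, count_s = m.groups()
            try:
                table.GetAtomicNumber(symbol)
            except Exception:
                raise ValueError(
                    f"unknown element {symbol!r} in formula {formula!r}"
                ) from None
            counts[symbol] = counts.get(symbol, 0) + (int(count_s) if count_s else 1)
            pos = m.end()
        if pos != len(part):
            raise ValueError(f"unparseable formula {formula!r}")
    if not counts:
        raise ValueError(f"unparseable formula {formula!r}")
    return counts


def compute_mw(formula: str) -> float:
    """Average molecular weight in Da from a formula, to 3 decimals."""
    from rdkit import Chem

    table = Chem.GetPeriodicTable()
    total = sum(
        count * table.GetAtomicWeight(symbol)
        for symbol, count in parse_formula(formula).items()
    )
    return round(total, 3)


def compute_logp(smiles: str) -> float:
    """Wildman–Crippen logP estimate of a SMILES structure.

    Deterministic atomic-contribution sum; raises ``ValueError`` when the
    structure does not parse.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import Crippen

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return float(Crippen.MolLogP(mol))


def entity_mw(entity: ChemicalEntity) -> Optional[float]:
    """MW with precedence: explicit field > computed from formula > None."""
    if entity.mw is not None:
        return entity.mw
    if entity.formula.strip():
        try:
            return compute_mw(entity.formula)
        except ValueError:
            return None
    return None


def entity_logp(entity: ChemicalEntity) -> Optional[float]:
    """logP with precedence: explicit field > computed from SMILES > None."""
    if entity.logp is not None:
        return entity.logp
    if entity.smiles:
        try:
            return compute_logp(entity.smiles)
        except ValueError:
            return None
    return None


# ---------------------------------------------------------------------------
# Property points

@dataclass
class PropertyPoint:
    chebi_id: str
    mw: float
    logp: float
    n_papers: int
    n_recognitions: int

    def __post_init__(self):
        if self.mw <= 0:
            raise ValueError(f"{self.chebi_id}: mw must be positive")
        if self.n_papers < 1 or self.n_recognitions < self.n_papers:
            raise ValueError(f"{self.chebi_id}: inconsistent annotation counts")

    def weight(self, mode: str) -> int:
        if mode == "paper_chebi_pairs":
            return self.n_papers
        if mode == "recognitions":
            return self.n_recognitions
        raise ValueError(f"unknown weighting mode {mode!r}")


def collect_points(
    corpus: Corpus,
    entities: Optional[Dict[str, ChemicalEntity]] = None,
    technique: Optional[QueryNode] = None,
) -> Tuple[List[PropertyPoint], Set[str]]:
    """Aggregate annotations of the (optionally technique-sliced) corpus.

    Returns one point per annotated entity with resolvable MW and logP,
    plus the set of ChEBI ids excluded for missing structure data (also
    warned about).
    """
    if entities is None:
        entities = corpus.entities
    pubs = [
        p for p in corpus.publications if technique is None or match(p, technique)
    ]
    papers: Dict[str, int] = {}
    recognitions: Dict[str, int] = {}
    for pub in pubs:
        for ann in pub.annotations:
            papers[ann.chebi_id] = papers.get(ann.chebi_id, 0) + 1
            recognitions[ann.chebi_id] = recognitions.get(ann.chebi_id, 0) + ann.count
    points: List[PropertyPoint] = []
    excluded: Set[str] = set()
    for chebi_id, n_papers in papers.items():
        entity = entities.get(chebi_id)
        mw = entity_mw(entity) if entity else None
        logp = entity_logp(entity) if entity else None
        if mw is None or logp is None:
            excluded.add(chebi_id)
            continue
        points.append(
            PropertyPoint(
                chebi_id=chebi_id,
                mw=mw,
                logp=logp,
                n_papers=n_papers,
                n_recognitions=recognitions[chebi_id],
            )
        )
    if excluded:
        warnings.warn(
            f"{len(excluded)} annotated entities lacked usable structure "
            "data and were excluded from the landscape",
            stacklevel=2,
        )
    points.sort(key=lambda p: p.chebi_id)
    return points, excluded


def filter_matrix_role(
    points: Sequence[PropertyPoint],
    entities: Dict[str, ChemicalEntity],
    role: str = MATRIX_ROLE,
) -> List[PropertyPoint]:
    """Remove points whose entity carries the given ontology role."""
    kept = [
        p
        for p in points
        if role not in (entities.get(p.chebi_id).roles if entities.get(p.chebi_id) else set())
    ]
    removed = len(points) - len(kept)
    if removed:
        logger.info("filter_matrix_role: removed %d role-bearing entities", removed)
    if points and not kept:
        warnings.warn("all points carried the matrix role; landscape is empty",
                      stacklevel=2)
    return kept


# ---------------------------------------------------------------------------
# Landscape grid

@dataclass
class LandscapeGrid:
    logp_edges: np.ndarray
    mw_edges: np.ndarray
    weights: np.ndarray  # shape (len(logp_edges)-1, len(mw_edges)-1)
    totals: Dict[str, int]
    weighting: str
    n_out_of_range: int = 0

    def __post_init__(self):
        if np.any(np.diff(self.logp_edges) <= 0) or np.any(np.diff(self.mw_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")


def build_landscape(
    points: Sequence[PropertyPoint],
    logp_edges: Optional[np.ndarray] = None,
    mw_edges: Optional[np.ndarray] = None,
    weighting: str = "paper_chebi_pairs",
) -> LandscapeGrid:
    """Bin property points into a (logP x MW) occurrence-density grid.

    Cell weight is the sum of each in-cell point's weight under the
    chosen mode: one per annotating publication (``paper_chebi_pairs``)
    or one per named-entity recognition (``recognitions``). Out-of-range
    points are counted and reported, never silently clipped.
    """
    if weighting not in WEIGHTING_MODES:
        raise ValueError(f"unknown weighting mode {weighting!r}")
    logp_edges = DEFAULT_LOGP_EDGES if logp_edges is None else np.asarray(logp_edges, float)
    mw_edges = DEFAULT_MW_EDGES if mw_edges is None else np.asarray(mw_edges, float)
    x = np.array([p.logp for p in points], dtype=float)
    y = np.array([p.mw for p in points], dtype=float)
    w = np.array([p.weight(weighting) for p in points], dtype=float)
    if len(points):
        in_range = (
            (x >= logp_edges[0]) & (x <= logp_edges[-1])
            & (y >= mw_edges[0]) & (y <= mw_edges[-1])
        )
        hist, _, _ = np.histogram2d(
            x[in_range], y[in_range], bins=[logp_edges, mw_edges],
            weights=w[in_range],
        )
        n_out = int((~in_range).sum())
    else:
        hist = np.zeros((len(logp_edges) - 1, len(mw_edges) - 1))
        n_out = 0
    if n_out:
        logger.info("build_landscape: %d points outside the grid range", n_out)
    totals = {
        "unique_chebis": len(points),
        "papers": int(sum(p.n_papers for p in points)),
        "recognitions": int(sum(p.n_recognitions for p in points)),
    }
    return LandscapeGrid(
        logp_edges=logp_edges,
        mw_edges=mw_edges,
        weights=hist,
        totals=totals,
        weighting=weighting,
        n_out_of_range=n_out,
    )


def landscape_from_corpus(
    corpus: Corpus,
    entities: Optional[Dict[str, ChemicalEntity]] = None,
    technique: Optional[QueryNode] = None,
    logp_edges: Optional[np.ndarray] = None,
    mw_edges: Optional[np.ndarray] = None,
    weighting: str = "paper_chebi_pairs",
    remove_matrix_role: bool = True,
) -> Tuple[LandscapeGrid, List[PropertyPoint]]:
    """Convenience pipeline: slice, aggregate, filter matrix role, bin."""
    if entities is None:
        entities = corpus.entities
    points, _ = collect_points(corpus, entities, technique)
    if remove_matrix_role:
        points = filter_matrix_role(points, entities)
    grid = build_landscape(points, logp_edges, mw_edges, weighting)
    return grid, points


def property_summary(
    points: Sequence[PropertyPoint], weighting: str = "paper_chebi_pairs"
) -> Tuple[float, float]:
    """Weighted mean (MW, logP) over points, each to 2 decimals."""
    if not points:
        raise ValueError("property_summary of an empty point list is undefined")
    w = np.array([p.weight(weighting) for p in points], dtype=float)
    mw = np.array([p.mw for p in points])
    logp = np.array([p.logp for p in points])
    return (
        round(float(np.average(mw, weights=w)), 2),
        round(float(np.average(logp, weights=w)), 2),
    )


# ---------------------------------------------------------------------------
# Output

def write_grid(grid: LandscapeGrid, tsv_path, json_path=None) -> None:
    """TSV of (logp_edge, mw_edge, weight) for nonempty cells plus a JSON
    sidecar with totals and settings."""
    tsv_path = Path(tsv_path)
    with tsv_path.open("w", encoding="utf-8") as handle:
        handle.write("logp_edge\tmw_edge\tweight\n")
        nz = np.argwhere(grid.weights > 0)
        for i, j in nz:
            handle.write(
                f"{grid.logp_edges[i]!r}\t{grid.mw_edges[j]!r}\t{grid.weights[i, j]!r}\n"
            )
    if json_path is not None:
        sidecar = {
            "totals": grid.totals,
            "weighting": grid.weighting,
            "n_out_of_range": grid.n_out_of_range,
            "logp_edges": [float(e) for e in grid.logp_edges],
            "mw_edges": [float(e) for e in grid.mw_edges],
        }
        Path(json_path).write_text(json.dumps(sidecar, indent=1), "utf-8")


def plot_landscape(grid: LandscapeGrid, path, title: str = "") -> None:
    """Render the density grid as a heat map (logP on x, MW on y)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    display = np.log1p(grid.weights.T)
    ax.pcolormesh(grid.logp_edges, grid.mw_edges, display, cmap="viridis")
    ax.set_xlabel("logP")
    ax.set_ylabel("molecular weight (Da)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
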