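import numpy as np
import pytest

from lditrends.corpus_model import Annotation, ChemicalEntity, Corpus, Publication
from lditrends.property_landscape import (
    PropertyPoint,
    build_landscape,
    collect_points,
    compute_logp,
    compute_mw,
    entity_logp,
    filter_matrix_role,
    landscape_from_corpus,
    parse_formula,
    property_summary,
)
from lditrends.query_engine import parse_query


class TestMolecularWeight:
    def test_water(self):
        assert compute_mw("H2O") == pytest.approx(18.015, abs=1e-3)

    def test_glucose(self):
        assert compute_mw("C6H12O6") == pytest.approx(180.156, abs=1e-3)

    def test_additive_over_formula_concatenation(self):
        assert compute_mw("C2H6O") + compute_mw("H2O") == pytest.approx(
            compute_mw("C2H6O.H2O"), abs=2e-3
        )

    def test_charge_suffix_ignored(self):
        assert compute_mw("Na+") == pytest.approx(compute_mw("Na"))

    @pytest.mark.parametrize("bad", ["", "Xx3", "12C", "C6H12?"])
    def test_unparseable_formula_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)


class TestLogP:
    def test_methane_single_carbon_contributions(self):
        # one unfunctionalized sp3 carbon plus four hydrocarbon hydrogens
        assert compute_logp("C") == pytest.approx(0.6361, abs=1e-4)

    def test_unparseable_smiles_rejected(self):
        with pytest.raises(ValueError, match="SMILES"):
            compute_logp("not-a-smiles(((")

    def test_precomputed_value_bypasses_structure(self):
        entity = ChemicalEntity("CHEBI:1", "x", "C6H6", smiles="c1ccccc1", logp=1.5)
        assert entity_logp(entity) == 1.5

    def test_computed_from_smiles_when_no_explicit_value(self):
        entity = ChemicalEntity("CHEBI:1", "benzene", "C6H6", smiles="c1ccccc1")
        assert entity_logp(entity) == pytest.approx(compute_logp("c1ccccc1"))


def _point(chebi, mw, logp, n_papers=1, n_recognitions=1):
    return PropertyPoint(chebi, mw, logp, n_papers, n_recognitions)


class TestMatrixRoleFilter:
    ENTITIES = {
        "CHEBI:1": ChemicalEntity("CHEBI:1", "chca", "C10H7NO3",
                                  roles={"MALDI matrix material"}),
        "CHEBI:2": ChemicalEntity("CHEBI:2", "glucose", "C6H12O6"),
    }

    def test_role_bearing_entity_removed(self):
        points = [_point("CHEBI:1", 189.0, 1.4), _point("CHEBI:2", 180.0, -3.2)]
        kept = filter_matrix_role(points, self.ENTITIES)
        assert [p.chebi_id for p in kept] == ["CHEBI:2"]

    def test_identity_without_role_bearers(self):
        points = [_point("CHEBI:2", 180.0, -3.2)]
        assert filter_matrix_role(points, self.ENTITIES) == points

    def test_all_removed_warns(self):
        points = [_point("CHEBI:1", 189.0, 1.4)]
        with pytest.warns(UserWarning, match="empty"):
            assert filter_matrix_role(points, self.ENTITIES) == []


class TestLandscapeGrid:
    def test_two_entities_two_cells_conserved(self):
        points = [_point("CHEBI:1", 100.0, -2.0, 3, 5),
                  _point("CHEBI:2", 900.0, 5.0, 2, 2)]
        grid = build_landscape(points)
        assert (grid.weights > 0).sum() == 2
        assert grid.weights.sum() == 5  # paper-entity pairs
        assert grid.totals == {"unique_chebis": 2, "papers": 5, "recognitions": 7}

    def test_constant_logp_class_falls_on_vertical_line(self):
        points = [_point(f"CHEBI:{i}", mw, -2.3) for i, mw in
                  enumerate([150, 400, 650, 900, 1150], start=1)]
        grid = build_landscape(points)
        occupied_columns = np.unique(np.argwhere(grid.weights > 0)[:, 0])
        assert len(occupied_columns) == 1

    def test_weighting_modes_coincide_for_single_counts(self):
        points = [_point("CHEBI:1", 100.0, 0.0), _point("CHEBI:2", 300.0, 1.0)]
        a = build_landscape(points, weighting="paper_chebi_pairs")
        b = build_landscape(points, weighting="recognitions")
        assert np.array_equal(a.weights, b.weights)

    def test_out_of_range_points_counted_not_clipped(self):
        points = [_point("CHEBI:1", 5000.0, 0.0), _point("CHEBI:2", 100.0, 0.0)]
        grid = build_landscape(points)
        assert grid.n_out_of_range == 1
        assert grid.weights.sum() == 1

    def test_empty_point_set_zero_totals(self):
        grid = build_landscape([])
        assert grid.weights.sum() == 0
        assert grid.totals == {"unique_chebis": 0, "papers": 0, "recognitions": 0}


class TestPropertySummary:
    def test_equal_weight_means(self):
        points = [_point("CHEBI:1", 100.0, 0.0), _point("CHEBI:2", 300.0, 1.0)]
        assert property_summary(points) == (200.00, 0.50)

    def test_single_point_returns_its_values(self):
        (mw, logp) = property_summary([_point("CHEBI:1", 123.456, -1.234)])
        assert (mw, logp) == (123.46, -1.23)

    def test_recognition_weighting(self):
        points = [_point("CHEBI:1", 100.0, 0.0, 1, 3),
                  _point("CHEBI:2", 300.0, 1.0, 1, 1)]
        assert property_summary(points, "recognitions") == (150.00, 0.25)

    def test_empty_is_undefined(self):
        with pytest.raises(ValueError):
            property_summary([])


class TestCollectPoints:
    def _corpus(self):
        pubs = [
            Publication("A", methods_text="MALDI mass spectrometry",
                        annotations=[Annotation("CHEBI:2", "glucose", 2),
                                     Annotation("CHEBI:3", "mystery", 1)]),
            Publication("B", methods_text="other",
                        annotations=[Annotation("CHEBI:2", "glucose", 1)]),
        ]
        entities = {
            "CHEBI:2": ChemicalEntity("CHEBI:2", "glucose", "C6H12O6",
                                      smiles="OCC1OC(O)C(O)C(O)C1O"),
            "CHEBI:3": ChemicalEntity("CHEBI:3", "mystery", ""),
        }
        return Corpus(publications=pubs, entities=entities)

    def test_structureless_entity_excluded_with_warning(self):
        corpus = self._corpus()
        with pytest.warns(UserWarning, match="excluded"):
            points, excluded = collect_points(corpus)
        assert excluded == {"CHEBI:3"}
        (point,) = points
        assert (point.n_papers, point.n_recognitions) == (2, 3)
        assert point.mw == pytest.approx(180.156, abs=1e-3)

    def test_technique_slice_restricts_papers(self):
        corpus = self._corpus()
        with pytest.warns(UserWarning):
            points, _ = collect_points(corpus, technique=parse_query("MALDI"))
        (point,) = points
        assert (point.n_papers, point.n_recognitions) == (1, 2)


def test_generated_corpus_landscape_excludes_matrix_entities(generated):
    config, corpus, truth = generated
    technique = parse_query(config.focal_technique)
    grid, points = landscape_from_corpus(corpus, technique=technique)
    kept_ids = {p.chebi_id for p in points}
    for chebi_id, entity in corpus.entities.items():
        if "MALDI matrix material" in entity.roles:
            assert chebi_id not in kept_ids
    assert grid.totals["unique_chebis"] == len(points)
    # conservation: grid weight equals point weight minus out-of-range
    assert grid.weights.sum() + sum(
        p.n_papers for p in points
        if not (-10 <= p.logp <= 15 and 0 <= p.mw <= 1500)
    ) == sum(p.n_papers for p in points)


def test_class_mean_recovery_against_generator_truth(generated):
    """property_summary over one analyte class recovers the realized
    ground-truth class mean (and the two agree within 3 SE of config)."""
    config, corpus, truth = generated
    moments = truth.class_property_moments()
    points, _ = collect_points(corpus)
    for cls in config.analyte_classes:
        cls_points = [
            p for p in points if truth.entity_class.get(p.chebi_id) == cls.name
        ]
        mw_mean, logp_mean = property_summary(cls_points, "paper_chebi_pairs")
        realized = moments[cls.name]
        assert mw_mean == pytest.approx(realized["mw_mean"], abs=0.01)
        assert logp_mean == pytest.approx(realized["logp_mean"], abs=0.01)
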