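import math

import numpy as np
import pandas as pd
import pytest

from cpifusion.screening import (
    add_lipinski_column,
    apply_candidate_filters,
    lipinski_violations,
    screen,
    select_top_fraction,
)


def make_table(n, rng=None, with_props=False):
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "compound_id": [f"c{i:05d}" for i in range(n)],
            "predicted_affinity": rng.normal(6.0, 1.0, size=n),
        }
    )
    if with_props:
        df["docking_score"] = rng.uniform(-10, -4, size=n)
        df["qikprop_stars"] = rng.integers(0, 9, size=n)
    return df


class TestTopFraction:
    def test_whole_table_when_fraction_one(self):
        table = make_table(10)
        assert len(select_top_fraction(table, 1.0)) == 10

    def test_floor_can_select_zero_with_warning(self, caplog):
        table = make_table(7)
        with caplog.at_level("WARNING"):
            out = select_top_fraction(table, 0.10)
        assert len(out) == 0
        assert any("0 compounds" in r.message for r in caplog.records)

    @pytest.mark.parametrize("n,fraction", [(31, 0.1), (100, 0.25), (999, 0.1), (50, 0.333)])
    def test_size_is_floor_of_fraction(self, n, fraction, rng):
        out = select_top_fraction(make_table(n, rng), fraction)
        assert len(out) == math.floor(fraction * n)

    def test_selected_scores_dominate_unselected(self, rng):
        table = make_table(200, rng)
        out = select_top_fraction(table, 0.1)
        cut = out["predicted_affinity"].min()
        unselected = table[~table["compound_id"].isin(out["compound_id"])]
        assert (unselected["predicted_affinity"] <= cut).all()

    def test_ties_at_cut_broken_by_compound_id(self):
        table = pd.DataFrame(
            {
                "compound_id": ["z", "a", "m", "b"],
                "predicted_affinity": [5.0, 5.0, 5.0, 5.0],
            }
        )
        out = select_top_fraction(table, 0.5)
        assert out["compound_id"].tolist() == ["a", "b"]

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            select_top_fraction(make_table(0), 0.1)

    def test_bad_fraction_is_error(self):
        with pytest.raises(ValueError):
            select_top_fraction(make_table(5), 0.0)


class TestCandidateFilters:
    @pytest.mark.parametrize(
        "docking,stars,kept",
        [
            (-7.0, 4, False),  # boundary docking excluded (strict)
            (-7.3, 4, True),
            (-8.1, 5, False),  # boundary stars excluded (strict)
            (-6.9, 0, False),
            (-7.5, 4.0, True),
        ],
    )
    def test_strict_boundaries(self, docking, stars, kept):
        table = pd.DataFrame(
            {
                "compound_id": ["c1"],
                "predicted_affinity": [6.0],
                "docking_score": [docking],
                "qikprop_stars": [stars],
            }
        )
        assert len(apply_candidate_filters(table)) == (1 if kept else 0)

    def test_inclusive_mode_keeps_boundary(self):
        table = pd.DataFrame(
            {
                "compound_id": ["c1"],
                "predicted_affinity": [6.0],
                "docking_score": [-7.0],
                "qikprop_stars": [5],
            }
        )
        assert len(apply_candidate_filters(table, strict=False)) == 1

    def test_constructed_fixture_count(self):
        # 20 rows, exactly 6 satisfy both strict rules by construction
        rows = []
        for i in range(20):
            passing = i < 6
            rows.append(
                {
                    "compound_id": f"c{i:02d}",
                    "predicted_affinity": 6.0,
                    "docking_score": -8.0 if passing else -6.0,
                    "qikprop_stars": 2 if passing else 6,
                }
            )
        out = apply_candidate_filters(pd.DataFrame(rows))
        assert len(out) == 6

    def test_missing_values_dropped_and_counted(self, caplog):
        table = pd.DataFrame(
            {
                "compound_id": ["c1", "c2", "c3"],
                "predicted_affinity": [6.0, 6.0, 6.0],
                "docking_score": [-8.0, None, -9.0],
                "qikprop_stars": [1, 2, None],
            }
        )
        with caplog.at_level("INFO"):
            out = apply_candidate_filters(table)
        assert out["compound_id"].tolist() == ["c1"]
        assert any("2 rows" in r.message for r in caplog.records)

    def test_missing_column_is_error(self):
        with pytest.raises(ValueError, match="docking_score"):
            apply_candidate_filters(make_table(3))

    def test_non_numeric_threshold_is_error(self, rng):
        with pytest.raises(TypeError):
            apply_candidate_filters(make_table(3, rng, with_props=True), docking_threshold="-7")

    def test_idempotent(self, rng):
        table = make_table(50, rng, with_props=True)
        once = apply_candidate_filters(table)
        twice = apply_candidate_filters(once)
        assert once.equals(twice)

    def test_pipeline_composition_equals_set_intersection(self, rng):
        table = make_table(300, rng, with_props=True)
        cascade = screen(table, fraction=0.2)
        top_ids = set(select_top_fraction(table, 0.2)["compound_id"])
        pass_ids = set(apply_candidate_filters(table)["compound_id"])
        assert set(cascade["compound_id"]) == top_ids & pass_ids


class TestLipinski:
    @pytest.mark.parametrize(
        "props,expected",
        [
            ((500, 5, 5, 10), 0),  # boundary values are compliant
            ((600, 5, 5, 10), 1),
            ((600, 6, 7, 12), 4),
            ((300, 2, 1, 4), 0),
            ((501, 5.1, 6, 11), 4),
        ],
    )
    def test_violation_counts(self, props, expected):
        assert lipinski_violations(*props) == expected

    def test_missing_property_named_in_error(self):
        with pytest.raises(ValueError, match="logP"):
            lipinski_violations(400, float("nan"), 2, 5)

    def test_table_annotation(self):
        table = pd.DataFrame(
            {
                "compound_id": ["c1", "c2"],
                "predicted_affinity": [6.0, 7.0],
                "mw": [400, 600],
                "logp": [2.0, 6.0],
                "hbd": [1, 6],
                "hba": [3, 11],
            }
        )
        out = add_lipinski_column(table)
        assert out["lipinski_violations"].tolist() == [0, 4]
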