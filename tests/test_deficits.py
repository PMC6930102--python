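"""Deficit schemas, FI computation, categorisation and saturation checks."""

import numpy as np
import pandas as pd
import pytest
import yaml
from hypothesis import given, settings, strategies as st

from frailtykit import (
    DeficitVector,
    IllegalResponseError,
    SchemaError,
    build_prospective_schema,
    categorize,
    compute_fi,
    compute_fi_frame,
    load_schema,
    map_deficits,
    map_deficits_frame,
    saturation_check,
)
from conftest import best_responses, worst_responses


class TestSchemaStructure:
    def test_retrospective_has_43_items(self, retro_schema):
        assert retro_schema.n_items == 43

    def test_maxima_decompose_14_25_4(self, retro_schema):
        assert retro_schema.max_contribution("comorbidity") == 14
        assert retro_schema.max_contribution("sf36") == 25
        assert retro_schema.max_contribution("eq5d") == 4
        assert retro_schema.max_contribution() == 43

    def test_prospective_has_36_items(self, prosp_schema):
        assert prosp_schema.n_items == 36

    def test_wrong_item_count_rejected(self, tmp_path):
        payload = {
            "name": "short",
            "items": [
                {"id": f"d{i}", "source": "battery", "mapping": {"Yes": 1, "No": 0}}
                for i in range(35)
            ],
        }
        path = tmp_path / "short.yaml"
        path.write_text(yaml.safe_dump(payload))
        with pytest.raises(SchemaError, match="35"):
            build_prospective_schema(path)

    def test_score_outside_allowed_set_rejected(self, tmp_path):
        payload = {
            "name": "bad",
            "items": [{"id": "x", "source": "battery", "mapping": {"Yes": 0.7, "No": 0}}],
        }
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(payload))
        with pytest.raises(SchemaError, match="'x'"):
            load_schema(path)


class TestMapping:
    def test_q1_fair_scores_half(self, retro_schema):
        rec = best_responses(retro_schema)
        rec["q1"] = "Fair"
        v = map_deficits(rec, retro_schema)
        scores = dict(zip(v.item_ids, v.scores))
        assert scores["sf36_q1"] == 0.5

    def test_best_responses_give_zero_deficits(self, retro_schema):
        v = map_deficits(best_responses(retro_schema), retro_schema)
        assert v.total == 0.0 and v.n_answered == 43

    def test_worst_responses_give_43(self, retro_schema):
        v = map_deficits(worst_responses(retro_schema), retro_schema)
        assert v.total == 43.0

    def test_missing_source_propagates_to_missing_item(self, retro_schema):
        rec = best_responses(retro_schema)
        del rec["q1"]
        rec["mobility"] = None
        v = map_deficits(rec, retro_schema)
        assert v.n_answered == 41

    def test_illegal_label_names_item(self, retro_schema):
        rec = best_responses(retro_schema)
        rec["q2"] = "way worse"
        with pytest.raises(IllegalResponseError, match="sf36_q2"):
            map_deficits(rec, retro_schema)

    def test_comorbidity_absent_differs_from_missing(self, retro_schema):
        rec = best_responses(retro_schema)
        rec["diabetes"] = "absent"
        rec["cancer"] = ""
        v = map_deficits(rec, retro_schema)
        scores = dict(zip(v.item_ids, v.scores))
        assert scores["cmb_diabetes"] == 0.0
        assert np.isnan(scores["cmb_cancer"])
        assert v.n_answered == 42


class TestFI:
    def _vector(self, scores):
        ids = tuple(f"i{k}" for k in range(len(scores)))
        return DeficitVector("toy", ids, np.array(scores, float))

    def test_fi_is_sum_over_nonmissing(self):
        v = self._vector([0.1] * 43)  # deficit sum 4.3 over n = 43
        r = compute_fi(v)
        assert r.fi == pytest.approx(0.1) and r.n_items == 43

    def test_denominator_uses_answered_count(self):
        scores = [0.5] * 7 + [np.nan] * 8 + [0.0] * 28
        v = self._vector(scores)
        r = compute_fi(v, floor=0.8)
        assert r.n_items == 35 and r.fi == pytest.approx(3.5 / 35)

    def test_zero_deficits_is_nonfrail(self):
        r = compute_fi(self._vector([0.0] * 43))
        assert r.fi == 0.0 and r.category == "non-frail"

    def test_below_completeness_floor_fi_missing(self):
        scores = [1.0] * 10 + [np.nan] * 33
        r = compute_fi(self._vector(scores), floor=0.8)
        assert r.fi is None and r.category is None

    def test_no_answers_fi_undefined(self):
        r = compute_fi(self._vector([np.nan] * 5))
        assert r.fi is None

    def test_frame_and_record_paths_agree(self, retro_schema, small_cohort):
        frame = compute_fi_frame(map_deficits_frame(small_cohort, retro_schema), retro_schema)
        for idx in [0, 75, 149]:
            rec = compute_fi(map_deficits(small_cohort.iloc[idx].to_dict(), retro_schema))
            assert frame.loc[idx, "fi"] == pytest.approx(rec.fi)
            assert frame.loc[idx, "category"] == rec.category

    @settings(max_examples=60, derandomize=True)
    @given(data=st.data())
    def test_raising_one_item_never_decreases_fi(self, data):
        n = data.draw(st.integers(5, 20))
        scores = data.draw(
            st.lists(st.sampled_from([0.0, 0.5, 1.0]), min_size=n, max_size=n)
        )
        pos = data.draw(st.integers(0, n - 1))
        if scores[pos] == 1.0:
            return
        raised = list(scores)
        raised[pos] = data.draw(st.sampled_from([s for s in (0.5, 1.0) if s > scores[pos]]))
        before = compute_fi(self._vector(scores), floor=0.0).fi
        after = compute_fi(self._vector(raised), floor=0.0).fi
        assert after >= before


class TestCategorize:
    @pytest.mark.parametrize(
        "fi, expected",
        [
            (0.0, "non-frail"),
            (0.08, "non-frail"),
            (0.08 + 1e-9, "pre-frail"),
            (0.25, "pre-frail"),
            (0.25 + 1e-9, "frail"),
            (0.26, "frail"),
            (1.0, "frail"),
        ],
    )
    def test_boundary_semantics(self, fi, expected):
        assert categorize(fi) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize(1.2)


class TestSaturation:
    def test_universal_deficit_in_young_stratum_flagged(self):
        scores = pd.DataFrame({"a": [1.0] * 10, "b": [0.0] * 10})
        ages = pd.Series([52] * 5 + [75] * 5)
        report = saturation_check(scores, ages)
        assert bool(report.loc["a", "saturated"])
        assert report.loc["b", "prevalence_young"] == 0.0
        assert not bool(report.loc["b", "saturated"])

    def test_empty_young_stratum_not_evaluable(self):
        scores = pd.DataFrame({"a": [1.0, 0.0]})
        report = saturation_check(scores, pd.Series([70, 80]))
        assert (report["status"] == "not-evaluable").all()

    def test_prevalences_match_generating_rates(self):
        # counting oracle: Bernoulli items with known per-stratum rates
        rng = np.random.default_rng(2024)
        n = 4000
        ages = np.concatenate([np.full(n, 55), np.full(n, 75)])
        rates = {"low": (0.1, 0.3), "high": (0.85, 0.9)}
        scores = pd.DataFrame(
            {
                item: np.concatenate(
                    [
                        rng.binomial(1, ry, size=n).astype(float),
                        rng.binomial(1, ro, size=n).astype(float),
                    ]
                )
                for item, (ry, ro) in rates.items()
            }
        )
        report = saturation_check(scores, pd.Series(ages), threshold=0.8)
        for item, (ry, ro) in rates.items():
            se = np.sqrt(ry * (1 - ry) / n)
            assert report.loc[item, "prevalence_young"] == pytest.approx(ry, abs=4 * se + 1e-9)
        assert not bool(report.loc["low", "saturated"])
        assert bool(report.loc["high", "saturated"])
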