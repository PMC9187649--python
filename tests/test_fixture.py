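"""Deterministic reconstruction of the survey dataset from its marginals."""

import pandas as pd
import pytest

from resmon import Verdict, compliance, fixtures
from resmon.fixtures import FixtureSpec, build_survey_dataset, survey_spec


class TestSurveyReconstruction:
    def test_dataset_shape(self, survey):
        assert len(survey["samples"]) == 1146
        assert len(survey["measurements"]) == 91
        assert len({s.sample_id for s in survey["samples"]}) == 1146

    def test_deterministic_no_seed(self, survey):
        again = build_survey_dataset()
        assert again[0] == survey["samples"]
        assert again[1] == survey["measurements"]
        assert again[2] == survey["mrl_table"]

    def test_one_residue_per_contaminated_sample(self, survey):
        sids = [m.sample_id for m in survey["measurements"]]
        assert len(sids) == len(set(sids))

    def test_violating_samples_count(self, survey, survey_classified, cfg):
        _, sample_verdicts = survey_classified
        assert sum(v is Verdict.ABOVE_MRL for v in sample_verdicts.values()) == 11

    def test_occurrence_rows_reproduced_bit_exactly(self, survey, survey_classified, cfg):
        _, sample_verdicts = survey_classified
        rows = {
            r.product: r
            for r in compliance.occurrence_by_commodity(survey["samples"], sample_verdicts, cfg)
        }
        ref = fixtures.load_occurrence_reference()
        for r in ref.itertuples(index=False):
            got = rows[r.product]
            assert (
                got.n_total, got.n_without, got.pct_without,
                got.n_below, got.pct_with, got.n_above, got.pct_above,
            ) == (r.n_total, r.n_without, r.pct_without,
                  r.n_below, r.pct_with, r.n_above, r.pct_above), r.product
        total = rows["Total"]
        assert (total.pct_without, total.pct_with, total.pct_above) == (92.1, 7.9, 1.0)

    def test_incidence_rows_reproduced(self, survey, survey_classified, cfg):
        verdicts, _ = survey_classified
        rows = {
            r.pesticide: r
            for r in compliance.incidence_by_pesticide(
                survey["samples"], survey["measurements"], verdicts, cfg,
                fixtures.survey_function_classes(),
            )
        }
        ref = fixtures.load_incidence_reference()
        assert len(rows) == len(ref) == 32
        for r in ref.itertuples(index=False):
            got = rows[r.pesticide]
            assert (got.n_detected, got.pct_detected, got.n_above) == (
                r.n_detected, r.pct_detected, r.n_above), r.pesticide
            assert (got.conc_min, got.conc_max) == (r.conc_min, r.conc_max), r.pesticide
            assert got.function_class.value == r.function_class
            if r.pesticide == "Diazinon":
                # found in a single commodity, so only one of the two
                # published MRL endpoints is realisable
                assert got.mrl_min == got.mrl_max == r.mrl_min
            else:
                assert (got.mrl_min, got.mrl_max) == (r.mrl_min, r.mrl_max), r.pesticide

    def test_detection_total_equals_contaminated_sample_total(self):
        spec = survey_spec()
        occ, inc = spec.occurrence, spec.incidence
        assert int(occ.n_below.sum() + occ.n_above.sum()) == int(inc.n_detected.sum()) == 91

    def test_every_pair_has_a_detection(self, survey, survey_classified):
        verdicts, _ = survey_classified
        commodity = {s.sample_id: s.commodity for s in survey["samples"]}
        realized = {(m.pesticide, commodity[m.sample_id]) for m in survey["measurements"]}
        assert realized == set(survey_spec().allowed_pairs)


class TestSmallSpecs:
    def single_commodity_spec(self, n_total=5, n_without=4, n_below=1, n_above=0):
        occurrence = pd.DataFrame(
            [{"group": "vegetable", "product": "Spinach", "n_total": n_total,
              "n_without": n_without, "n_below": n_below, "n_above": n_above}]
        )
        incidence = pd.DataFrame(
            [{"pesticide": "Procymidone", "function_class": "F",
              "n_detected": n_below + n_above, "n_above": n_above,
              "conc_min": 0.5, "conc_max": 0.5, "mrl_min": 2.0, "mrl_max": 2.0}]
        )
        exposure = pd.DataFrame(
            [{"pesticide": "Procymidone", "commodity": "Spinach",
              "arfd": 0.1, "esti": 1e-4, "ahq": 0.1, "adi": 0.1, "edi": 1e-4, "hq": 0.1}]
        )
        return FixtureSpec(occurrence, incidence,
                           [("Procymidone", "Spinach")], exposure)

    def test_single_commodity_round_trip(self, cfg):
        samples, measurements, mrl_table, _, _ = build_survey_dataset(
            self.single_commodity_spec()
        )
        assert len(samples) == 5 and len(measurements) == 1
        _, sample_verdicts = compliance.classify_dataset(samples, measurements, mrl_table, cfg)
        rows = compliance.occurrence_by_commodity(samples, sample_verdicts, cfg)
        row = rows[0]
        assert (row.n_without, row.n_below, row.n_above) == (4, 1, 0)

    def test_inconsistent_marginals_rejected(self):
        spec = self.single_commodity_spec()
        spec.incidence.loc[0, "n_detected"] = 3  # 3 detections, 1 contaminated sample
        with pytest.raises(ValueError, match="impossible|disagree"):
            build_survey_dataset(spec)

    def test_counts_not_summing_rejected(self):
        spec = self.single_commodity_spec()
        spec.occurrence.loc[0, "n_without"] = 2
        with pytest.raises(ValueError, match="sum"):
            build_survey_dataset(spec)
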