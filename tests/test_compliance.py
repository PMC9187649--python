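"""MRL resolution, residue/sample classification and summary tables."""

from collections import Counter

import numpy as np
import pytest

from resmon import (
    AnalysisConfig,
    FunctionClass,
    Group,
    MRLEntry,
    MRLSource,
    ResidueMeasurement,
    SampleRecord,
    Verdict,
    compliance,
)
from resmon.compliance import (
    IncidenceRow,
    classify_residue,
    classify_sample,
    function_class_breakdown,
    incidence_by_pesticide,
    occurrence_by_commodity,
    resolve_mrl,
)


class TestResolveMRL:
    def test_unregistered_pair_falls_to_pls_default(self):
        table = [MRLEntry("Chlorfenapyr", "Lettuce leaves", 1.0)]
        entry = resolve_mrl("Fenobucarb", "Aster scaber", table)
        assert entry.mrl == 0.01 and entry.source is MRLSource.PLS_DEFAULT

    def test_registered_entry_wins(self):
        table = [MRLEntry("Chlorfenapyr", "Aster scaber", 1.0)]
        entry = resolve_mrl("Chlorfenapyr", "Aster scaber", table)
        assert entry.mrl == 1.0 and entry.source is MRLSource.REGISTERED

    def test_empty_table_total_fallback(self):
        entry = resolve_mrl("anything", "anywhere", [])
        assert entry.mrl == 0.01 and entry.source is MRLSource.PLS_DEFAULT

    def test_custom_pls_default(self):
        cfg = AnalysisConfig(pls_default_mrl=0.05)
        assert resolve_mrl("X", "Y", [], cfg).mrl == 0.05


class TestClassifyResidue:
    mrl = MRLEntry("X", "C", 0.01)

    def test_violation_is_strictly_above(self):
        m = ResidueMeasurement("s", "X", 0.364, lod=0.005)
        assert classify_residue(m, self.mrl).value is Verdict.ABOVE_MRL

    def test_below_lod_is_not_detected(self):
        m = ResidueMeasurement("s", "X", 0.0005, lod=0.004)
        assert classify_residue(m, self.mrl).value is Verdict.NOT_DETECTED

    def test_equal_to_mrl_is_compliant(self):
        m = ResidueMeasurement("s", "X", 0.01, lod=0.005)
        assert classify_residue(m, self.mrl).value is Verdict.BELOW_MRL

    def test_monotone_in_concentration(self):
        mrl = MRLEntry("X", "C", 0.5)
        concs = np.linspace(0, 1.0, 101)
        sev = [classify_residue(ResidueMeasurement("s", "X", float(c), lod=0.1), mrl).value.severity
               for c in concs]
        assert sev == sorted(sev)


class TestClassifySample:
    def test_empty_is_clean(self):
        assert classify_sample([]) is Verdict.NOT_DETECTED

    def test_worst_verdict_wins(self):
        assert classify_sample([Verdict.BELOW_MRL, Verdict.ABOVE_MRL]) is Verdict.ABOVE_MRL
        assert classify_sample([Verdict.NOT_DETECTED, Verdict.BELOW_MRL]) is Verdict.BELOW_MRL


class TestOccurrence:
    def make(self, product, tallies):
        samples, verdicts = [], {}
        i = 0
        for verdict, n in tallies.items():
            for _ in range(n):
                sid = f"{product}-{i}"
                samples.append(SampleRecord(sid, product, Group.VEGETABLE))
                verdicts[sid] = verdict
                i += 1
        return samples, verdicts

    def test_aster_scaber_percentages(self):
        samples, verdicts = self.make(
            "Aster scaber",
            {Verdict.NOT_DETECTED: 37, Verdict.BELOW_MRL: 6, Verdict.ABOVE_MRL: 3},
        )
        row = occurrence_by_commodity(samples, verdicts)[0]
        assert (row.n_total, row.pct_without, row.pct_with, row.pct_above) == (46, 80.4, 19.6, 6.5)
        assert row.pct_below == 13.0  # unambiguous below-only rate, 6/46

    def test_all_clean(self):
        samples, verdicts = self.make("Pear", {Verdict.NOT_DETECTED: 10})
        row = occurrence_by_commodity(samples, verdicts)[0]
        assert (row.pct_without, row.pct_with, row.pct_above) == (100.0, 0.0, 0.0)

    def test_counts_sum_and_total_row(self):
        s1, v1 = self.make("A", {Verdict.NOT_DETECTED: 3, Verdict.BELOW_MRL: 2})
        s2, v2 = self.make("B", {Verdict.ABOVE_MRL: 1})
        rows = occurrence_by_commodity(s1 + s2, {**v1, **v2})
        total = rows[-1]
        assert total.product == "Total"
        assert total.n_total == 6 and total.n_without == 3 and total.n_above == 1
        for row in rows:
            assert row.n_without + row.n_below + row.n_above == row.n_total

    def test_unclassified_sample_rejected(self):
        samples, verdicts = self.make("A", {Verdict.NOT_DETECTED: 2})
        del verdicts[samples[0].sample_id]
        with pytest.raises(ValueError, match="unclassified"):
            occurrence_by_commodity(samples, verdicts)

    def test_matches_brute_force_tally_on_random_data(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(1, 50))
            products = [f"P{int(rng.integers(3))}" for _ in range(n)]
            verdict_pool = list(Verdict)
            samples = [SampleRecord(f"s{i}", p, Group.VEGETABLE)
                       for i, p in enumerate(products)]
            verdicts = {s.sample_id: verdict_pool[int(rng.integers(3))] for s in samples}
            rows = {r.product: r for r in occurrence_by_commodity(samples, verdicts)}
            # exhaustive per-sample tally as oracle
            tally = Counter((s.commodity, verdicts[s.sample_id]) for s in samples)
            for product in set(products):
                row = rows[product]
                assert row.n_without == tally[(product, Verdict.NOT_DETECTED)]
                assert row.n_below == tally[(product, Verdict.BELOW_MRL)]
                assert row.n_above == tally[(product, Verdict.ABOVE_MRL)]


class TestIncidence:
    def test_single_detection_range_collapses(self):
        samples = [SampleRecord("s1", "Chard", Group.VEGETABLE)]
        mrl = MRLEntry("Chlorfluazuron", "Chard", 5.0)
        measurements = [ResidueMeasurement("s1", "Chlorfluazuron", 0.32, lod=0.005)]
        verdicts = [classify_residue(measurements[0], mrl)]
        row = incidence_by_pesticide(samples, measurements, verdicts)[0]
        assert row.conc_min == row.conc_max == 0.32
        assert row.mrl_min == row.mrl_max == 5.0
        assert row.n_detected == 1 and row.n_above == 0

    def test_not_detected_measurements_excluded(self):
        samples = [SampleRecord("s1", "Chard", Group.VEGETABLE)]
        mrl = MRLEntry("X", "Chard", 5.0)
        m = ResidueMeasurement("s1", "X", 0.001, lod=0.005)
        rows = incidence_by_pesticide(samples, [m], [classify_residue(m, mrl)])
        assert rows == []


class TestFunctionClassBreakdown:
    def row(self, pesticide, cls):
        return IncidenceRow(pesticide, cls, 1, 0.1, 0, 0.0, 0.1, 0.1, 1.0, 1.0)

    def test_survey_composition_percentages(self):
        rows = (
            [self.row(f"F{i}", FunctionClass.FUNGICIDE) for i in range(15)]
            + [self.row(f"I{i}", FunctionClass.INSECTICIDE) for i in range(14)]
            + [self.row(f"H{i}", FunctionClass.HERBICIDE) for i in range(2)]
            + [self.row("G0", FunctionClass.GROWTH_REGULATOR)]
        )
        out = function_class_breakdown(rows)
        assert out[FunctionClass.FUNGICIDE] == (15, 46.9)
        # 100 * 14/32 = 43.75 -> 43.8 under round-half-up
        assert out[FunctionClass.INSECTICIDE] == (14, 43.8)
        assert out[FunctionClass.HERBICIDE] == (2, 6.3)
        assert out[FunctionClass.GROWTH_REGULATOR] == (1, 3.1)

    def test_single_pesticide_is_total(self):
        out = function_class_breakdown([self.row("X", FunctionClass.FUNGICIDE)])
        assert out[FunctionClass.FUNGICIDE] == (1, 100.0)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="function class"):
            function_class_breakdown([self.row("X", None)])
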