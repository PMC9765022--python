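"""Cell-number conversion, filters, aggregation and composition comparison."""

import math

import pytest

from syndna import (
    DEFAULT_CONSTANTS,
    SampleCounts,
    TaxonProfile,
    aggregate_genus,
    cells_from_mass,
    compare,
    coverage_filter,
    fit_calibration,
    quantify,
    relative_abundance,
)
from syndna.calibration import CalibrationPoint


def make_model(slope=1.0, intercept=-6.0):
    cpms = (10, 100, 1000)
    points = [
        CalibrationPoint(f"p{i}", 10 ** (intercept + slope * math.log10(c)), c)
        for i, c in enumerate(cpms)
    ]
    return fit_calibration(points, sample_id="toy")


class TestCellsFromMass:
    def test_one_genome_mass_gives_one_cell(self):
        genome = 2_000_000
        mass_ng = genome * DEFAULT_CONSTANTS.bp_mass \
            / DEFAULT_CONSTANTS.avogadro * 1e9
        assert cells_from_mass(mass_ng, genome) == pytest.approx(1.0, rel=1e-12)

    def test_zero_mass_zero_cells(self):
        assert cells_from_mass(0.0, 1_000_000) == 0.0

    def test_linearity(self):
        one = cells_from_mass(1e-6, 3_000_000)
        assert cells_from_mass(2e-6, 3_000_000) == pytest.approx(2 * one)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cells_from_mass(1.0, 0)
        with pytest.raises(ValueError):
            cells_from_mass(-1.0, 1000)


class TestQuantify:
    def test_identical_taxa_split_evenly(self):
        counts = SampleCounts("s", {"a": 100, "b": 100}, 10_000)
        profiles = quantify(counts, make_model(), {"a": 2e6, "b": 2e6})
        assert [p.percent for p in profiles] == pytest.approx([50.0, 50.0])

    def test_zero_count_taxon_kept_with_zero_cells(self):
        counts = SampleCounts("s", {"a": 100}, 10_000)
        profiles = quantify(counts, make_model(), {"a": 2e6, "b": 2e6})
        by_id = {p.taxon_id: p for p in profiles}
        assert by_id["b"].cells == 0.0
        assert by_id["a"].percent == pytest.approx(100.0)

    def test_taxon_without_genome_length_excluded_with_warning(self):
        counts = SampleCounts("s", {"a": 100, "mystery": 50}, 10_000)
        with pytest.warns(UserWarning, match="genome length"):
            profiles = quantify(counts, make_model(), {"a": 2e6})
        assert {p.taxon_id for p in profiles} == {"a"}

    def test_monotone_in_counts_for_positive_slope(self):
        model = make_model(slope=1.2)
        lo = SampleCounts("s", {"a": 100, "b": 100}, 10_000)
        hi = SampleCounts("s", {"a": 150, "b": 100}, 10_000)
        cells_lo = {p.taxon_id: p.cells
                    for p in quantify(lo, model, {"a": 2e6, "b": 2e6})}
        cells_hi = {p.taxon_id: p.cells
                    for p in quantify(hi, model, {"a": 2e6, "b": 2e6})}
        assert cells_hi["a"] > cells_lo["a"]
        assert cells_hi["b"] == pytest.approx(cells_lo["b"])

    def test_ratio_follows_power_law_in_counts_and_lengths(self):
        # cells_a / cells_b = (X_a/X_b)^slope * Y_b/Y_a under the model
        slope = 1.3
        model = make_model(slope=slope)
        counts = SampleCounts("s", {"a": 400, "b": 100}, 10_000)
        lengths = {"a": 2e6, "b": 5e6}
        cells = {p.taxon_id: p.cells for p in quantify(counts, model, lengths)}
        expected = (400 / 100) ** slope * lengths["b"] / lengths["a"]
        assert cells["a"] / cells["b"] == pytest.approx(expected, rel=1e-9)

    def test_ploidy_divides_cells(self):
        counts = SampleCounts("s", {"a": 100, "b": 100}, 10_000)
        profiles = quantify(counts, make_model(), {"a": 2e6, "b": 2e6},
                            ploidy={"a": 2.0, "b": 1.0})
        by_id = {p.taxon_id: p for p in profiles}
        assert by_id["b"].cells == pytest.approx(2 * by_id["a"].cells)


class TestCoverageFilter:
    def _profiles(self, breadths):
        ps = []
        for i, b in enumerate(breadths):
            ps.append(TaxonProfile(f"t{i}", 1e6, 10, 1e-3,
                                   coverage_breadth=b, cells=100.0))
        return ps

    def test_strict_threshold(self):
        out = coverage_filter(self._profiles([0.005, 0.02]), 0.01)
        assert [p.taxon_id for p in out] == ["t1"]
        assert out[0].percent == pytest.approx(100.0)

    def test_boundary_value_excluded(self):
        out = coverage_filter(self._profiles([0.01, 0.02]), 0.01)
        assert [p.taxon_id for p in out] == ["t1"]

    def test_zero_threshold_keeps_covered_taxa(self):
        out = coverage_filter(self._profiles([0.005, 0.02]), 0.0)
        assert len(out) == 2

    def test_survivor_percents_resum_to_100(self):
        out = coverage_filter(self._profiles([0.005, 0.5, 0.7]), 0.01)
        assert sum(p.percent for p in out) == pytest.approx(100.0, abs=1e-9)

    def test_unknown_breadth_kept_with_warning(self):
        with pytest.warns(UserWarning, match="breadth"):
            out = coverage_filter(self._profiles([None, 0.005]), 0.01)
        assert [p.taxon_id for p in out] == ["t0"]


class TestAggregateGenus:
    def test_cells_sum_within_genus(self):
        ps = [TaxonProfile("A1", 1e6, 10, 1e-3, cells=100.0),
              TaxonProfile("A2", 1e6, 5, 5e-4, cells=50.0),
              TaxonProfile("B1", 1e6, 5, 5e-4, cells=50.0)]
        out = aggregate_genus(ps, {"A1": "A", "A2": "A", "B1": "B"})
        by_id = {p.taxon_id: p for p in out}
        assert by_id["A"].cells == pytest.approx(150.0)
        assert sum(p.cells for p in out) == pytest.approx(200.0)
        assert sum(p.percent for p in out) == pytest.approx(100.0, abs=1e-9)

    def test_singleton_genus_identity(self):
        ps = [TaxonProfile("A1", 1e6, 10, 1e-3, cells=100.0)]
        out = aggregate_genus(ps, {"A1": "A"})
        assert out[0].cells == 100.0 and out[0].percent == 100.0

    def test_unmapped_species_rejected(self):
        ps = [TaxonProfile("A1", 1e6, 10, 1e-3, cells=100.0)]
        with pytest.raises(KeyError):
            aggregate_genus(ps, {})


class TestRelativeAbundance:
    def test_equal_counts_equal_percents(self):
        sc = SampleCounts("s", {"a": 10, "b": 10}, 100)
        assert relative_abundance(sc, ["a", "b"]) == {"a": 50.0, "b": 50.0}

    def test_single_taxon_is_everything(self):
        sc = SampleCounts("s", {"a": 10}, 100)
        assert relative_abundance(sc, ["a"]) == {"a": 100.0}

    def test_sums_to_100_over_taxon_set(self, toy_counts):
        ra = relative_abundance(toy_counts, ["taxA", "taxB"])
        assert sum(ra.values()) == pytest.approx(100.0, abs=1e-9)

    def test_total_denominator_matches_sequenced_reads(self, toy_counts):
        ra = relative_abundance(toy_counts, ["taxA"], denominator="total")
        assert ra["taxA"] == pytest.approx(40.0)


class TestCompare:
    def test_percent_error_arithmetic(self):
        rows, _ = compare({"x": 14.532, "y": 9.508},
                          {"x": 14.6, "y": 10.3})
        by_id = {r.taxon_id: r for r in rows}
        assert by_id["x"].pct_error == pytest.approx(0.47, abs=0.005)
        assert by_id["y"].pct_error == pytest.approx(7.69, abs=0.005)

    def test_predicted_denominator_mode(self):
        rows, _ = compare({"x": 8.0, "y": 10.0}, {"x": 10.0, "y": 10.0},
                          error_denominator="predicted")
        by_id = {r.taxon_id: r for r in rows}
        assert by_id["x"].pct_error == pytest.approx(25.0)

    def test_perfect_prediction(self):
        rows, summary = compare({"a": 30.0, "b": 70.0},
                                {"a": 30.0, "b": 70.0})
        assert all(r.pct_error == 0.0 for r in rows)
        assert all(r.log_ratio == 0.0 for r in rows)

    def test_constant_vectors_have_no_correlation(self):
        _, summary = compare({"a": 50.0, "b": 50.0, "c": 50.0},
                             {"a": 50.0, "b": 50.0, "c": 50.0})
        assert summary["pearson_r"] is None

    def test_zero_expected_flagged_and_excluded(self):
        rows, summary = compare(
            {"a": 10.0, "b": 20.0, "c": 30.0, "d": 40.0},
            {"a": 0.0, "b": 25.0, "c": 35.0, "d": 40.0})
        by_id = {r.taxon_id: r for r in rows}
        assert by_id["a"].flagged and by_id["a"].pct_error is None
        assert summary["n"] == 3

    def test_mismatched_taxon_sets_rejected(self):
        with pytest.raises(ValueError):
            compare({"a": 1.0}, {"b": 1.0})

    def test_log_ratio_sign(self):
        rows, _ = compare({"a": 20.0, "b": 5.0}, {"a": 10.0, "b": 10.0})
        by_id = {r.taxon_id: r for r in rows}
        assert by_id["a"].log_ratio == pytest.approx(math.log10(2))
        assert by_id["b"].log_ratio == pytest.approx(-math.log10(2))
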