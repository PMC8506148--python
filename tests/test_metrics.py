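"""HWE expansion, coverage, detectability, detection rate and summaries."""
import itertools

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from cpgx_eval import (
    Diplotype,
    FrequencyTable,
    GeneModel,
    StarAllele,
    TestPanel,
    altered_diplotype_set,
    coverage_percentage,
    detection_rate,
    evaluate_panels,
    hwe_diplotype_expansion,
    is_detectable,
    population_altered_frequency,
    summarize,
)
from cpgx_eval.errors import MissingDataError, ValidationError
from cpgx_eval.metrics import default_call_fraction, rank_tests
from cpgx_eval.model import STATUS_NOT_APPLICABLE
from cpgx_eval.simulate import SimulationConfig, interval_rule_set, simulate_bundle


class TestHweExpansion:
    def test_direct_arithmetic(self, toy_haps):
        dips = hwe_diplotype_expansion(toy_haps)
        expected = {
            "*1/*1": 0.25,
            "*1/*2": 0.30,
            "*1/*3": 0.20,
            "*2/*2": 0.09,
            "*2/*3": 0.12,
            "*3/*3": 0.04,
        }
        for ident, f in expected.items():
            assert dips.get(ident, "POP1") == pytest.approx(f, abs=1e-12)

    def test_matches_exhaustive_gamete_enumeration(self, toy_haps):
        """Independent check: sum over ordered gamete pairs, folded to unordered."""
        p = {a: toy_haps.get(a, "POP1") for a in toy_haps.identifiers}
        folded: dict[str, float] = {}
        for a, b in itertools.product(p, p):
            key = str(Diplotype("CYPX", a, b))
            folded[key] = folded.get(key, 0.0) + p[a] * p[b]
        dips = hwe_diplotype_expansion(toy_haps)
        assert set(dips.identifiers) == set(folded)
        for ident, f in folded.items():
            assert dips.get(ident, "POP1") == pytest.approx(f, abs=1e-12)

    def test_degenerate_single_allele(self):
        t = FrequencyTable("G", "haplotype", ("P",), {("*1", "P"): 1.0})
        dips = hwe_diplotype_expansion(t)
        assert dips.identifiers == ("*1/*1",)
        assert dips.get("*1/*1", "P") == 1.0

    def test_output_mass_conserved(self, toy_haps):
        dips = hwe_diplotype_expansion(toy_haps)
        assert dips.population_total("POP1") == pytest.approx(1.0, abs=1e-9)

    def test_incomplete_column_requires_renormalize(self):
        t = FrequencyTable("G", "haplotype", ("P",), {("*1", "P"): 0.6, ("*2", "P"): 0.2})
        with pytest.raises(ValidationError, match="renormalize"):
            hwe_diplotype_expansion(t)
        dips = hwe_diplotype_expansion(t, renormalize=True)
        assert dips.population_total("P") == pytest.approx(1.0, abs=1e-9)

    def test_missing_population_stays_missing(self):
        t = FrequencyTable("G", "haplotype", ("P1", "P2"), {("*1", "P1"): 1.0})
        dips = hwe_diplotype_expansion(t)
        assert dips.is_population_missing("P2")

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=6))
    def test_mass_conservation_property(self, weights):
        total = sum(weights)
        freqs = {(f"*{i + 1}", "P"): w / total for i, w in enumerate(weights)}
        t = FrequencyTable("G", "haplotype", ("P",), freqs)
        dips = hwe_diplotype_expansion(t, renormalize=True)
        assert dips.population_total("P") == pytest.approx(1.0, abs=1e-9)


class TestCoverage:
    def test_cyp2c9_fourteen_of_sixty_one(self):
        """A 14-variant panel over a 61-variant universe covers ~23%."""
        known = frozenset(f"rs{i}" for i in range(61))
        m = GeneModel(
            gene="CYP2C9",
            alleles=(StarAllele("CYP2C9", "*1", activity_value=1.0),),
            known_variants=known,
        )
        panel = TestPanel("t", {"CYP2C9": frozenset(sorted(known)[:14])})
        cov = coverage_percentage(panel, "CYP2C9", m)
        assert cov == pytest.approx(100 * 14 / 61)
        assert round(cov) == 23

    def test_full_and_empty_intersection(self, toy_model):
        full = TestPanel("full", {"CYPX": toy_model.known_variants})
        assert coverage_percentage(full, "CYPX", toy_model) == 100.0
        decoy = TestPanel("none", {"CYPX": frozenset({"not_a_variant"})})
        assert coverage_percentage(decoy, "CYPX", toy_model) == 0.0

    def test_empty_universe_undefined(self):
        m = GeneModel(gene="G", alleles=(StarAllele("G", "*1", activity_value=1.0),))
        with pytest.raises(ValidationError, match="coverage"):
            coverage_percentage(TestPanel("t", {"G": frozenset({"v"})}), "G", m)


class TestDetectability:
    def test_reference_side_detectable_by_default(self, toy_model, toy_panel):
        assert is_detectable(Diplotype("CYPX", "*1", "*2"), toy_panel, toy_model)

    def test_uncovered_allele_blocks_detection(self, toy_model, toy_panel):
        assert not is_detectable(Diplotype("CYPX", "*1", "*3"), toy_panel, toy_model)

    def test_one_sided_coverage_insufficient(self, toy_model, toy_panel):
        assert not is_detectable(Diplotype("CYPX", "*2", "*3"), toy_panel, toy_model)

    def test_all_defining_variants_required(self):
        m = GeneModel(
            gene="G",
            alleles=(
                StarAllele("G", "*1", activity_value=1.0),
                StarAllele("G", "*2", frozenset({"v1", "v2"}), 0.0, "no"),
            ),
            known_variants=frozenset({"v1", "v2"}),
        )
        partial = TestPanel("t", {"G": frozenset({"v1"})})
        dip = Diplotype("G", "*1", "*2")
        assert not is_detectable(dip, partial, m)
        assert is_detectable(dip, partial, m, mode="any")


class TestDetectionRate:
    def test_toy_values(self, toy_dips, toy_model, toy_rules, toy_panel):
        altered = altered_diplotype_set(toy_dips, toy_model, toy_rules)
        paf = population_altered_frequency(toy_dips, altered, "POP1")
        assert paf == pytest.approx(0.75, abs=1e-12)
        rate = detection_rate(toy_dips, altered, toy_panel, toy_model, "POP1")
        assert rate == pytest.approx(52.0, abs=1e-9)

    def test_full_panel_gives_hundred(self, toy_dips, toy_model, toy_rules):
        altered = altered_diplotype_set(toy_dips, toy_model, toy_rules)
        full = TestPanel("full", {"CYPX": frozenset({"v2", "v3"})})
        assert detection_rate(toy_dips, altered, full, toy_model, "POP1") == pytest.approx(
            100.0
        )

    def test_empty_panel_gives_zero(self, toy_dips, toy_model, toy_rules):
        altered = altered_diplotype_set(toy_dips, toy_model, toy_rules)
        decoy = TestPanel("none", {"CYPX": frozenset({"decoy"})})
        # every altered diplotype carries a non-reference allele -> nothing detectable
        assert detection_rate(toy_dips, altered, decoy, toy_model, "POP1") == 0.0

    def test_zero_denominator_is_undefined_not_zero(self, toy_dips, toy_model, toy_panel):
        assert detection_rate(toy_dips, frozenset(), toy_panel, toy_model, "POP1") is None

    def test_missing_population_raises(self, toy_model, toy_rules, toy_panel):
        t = FrequencyTable("CYPX", "diplotype", ("POP1", "POP2"), {("*1/*1", "POP1"): 1.0})
        with pytest.raises(MissingDataError):
            detection_rate(t, frozenset(), toy_panel, toy_model, "POP2")

    def test_default_call_fraction_diagnostic(self, toy_dips, toy_model, toy_rules, toy_panel):
        altered = altered_diplotype_set(toy_dips, toy_model, toy_rules)
        frac = default_call_fraction(toy_dips, altered, toy_panel, toy_model, "POP1")
        # detectable altered = {*1/*2: .30 (default *1 side), *2/*2: .09}
        assert frac == pytest.approx(0.30 / 0.39, abs=1e-9)


class TestMonotonicity:
    @settings(
        derandomize=True,
        max_examples=25,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_growing_panel_never_decreases_rates(self, seed):
        config = SimulationConfig(seed=seed, n_alleles=5, n_populations=2)
        from cpgx_eval.simulate import simulate_gene_model, simulate_population_frequencies

        model = simulate_gene_model(config)
        haps = simulate_population_frequencies(model, config)
        dips = hwe_diplotype_expansion(haps, renormalize=True)
        rules = interval_rule_set(config.gene)
        altered = altered_diplotype_set(dips, model, rules)
        variants = sorted(model.known_variants)
        prev_cov, prev_rate = {}, {}
        for k in range(1, len(variants) + 1):
            panel = TestPanel("grow", {config.gene: frozenset(variants[:k])})
            cov = coverage_percentage(panel, config.gene, model)
            assert 0.0 <= cov <= 100.0
            assert cov >= prev_cov.get("grow", 0.0)
            prev_cov["grow"] = cov
            for pop in haps.populations:
                paf = population_altered_frequency(dips, altered, pop)
                rate = detection_rate(dips, altered, panel, model, pop)
                if rate is None:
                    assert paf == 0.0
                    continue
                assert 0.0 <= rate <= 100.0
                assert rate >= prev_rate.get(pop, 0.0) - 1e-12
                prev_rate[pop] = rate
                detectable = paf * rate / 100.0
                assert detectable <= paf + 1e-12


class TestEvaluatePanels:
    def test_cross_product_cell_count(self, toy_model, toy_haps, toy_rules):
        panels = [
            TestPanel("A", {"CYPX": frozenset({"v2"})}),
            TestPanel("B", {"CYPX": frozenset({"v3"})}),
        ]
        pops = tuple(f"P{i}" for i in range(9))
        freqs = {(a, p): f for p in pops for a, f in
                 {"*1": 0.5, "*2": 0.3, "*3": 0.2}.items()}
        table = FrequencyTable("CYPX", "haplotype", pops, freqs)
        matrix = evaluate_panels(panels, {"CYPX": toy_model}, {"CYPX": table}, toy_rules)
        assert len(matrix.results()) == 18

    def test_omitted_gene_marked_not_applicable(self, toy_model, toy_haps, toy_rules, cyp3a5_model):
        other_table = FrequencyTable(
            "CYP3A5", "haplotype", ("POP1",), {("*1", "POP1"): 0.3, ("*3", "POP1"): 0.7}
        )
        panel = TestPanel("A", {"CYPX": frozenset({"v2"})})
        from cpgx_eval import PhenotypeRule, PhenotypeRuleSet, default_translation_table

        rules = PhenotypeRuleSet.from_rules(
            list(toy_rules.rules.values())
            + [
                PhenotypeRule(
                    "CYP3A5",
                    "categorical",
                    altered_categories=frozenset({"intermediate", "extensive"}),
                )
            ]
        )
        matrix = evaluate_panels(
            [panel],
            {"CYPX": toy_model, "CYP3A5": cyp3a5_model},
            {"CYPX": toy_haps, "CYP3A5": other_table},
            rules,
            default_translation_table(),
        )
        cell = matrix.get("A", "CYP3A5", "POP1")
        assert cell.status == STATUS_NOT_APPLICABLE
        assert cell.detection_rate_pct is None

    def test_tier_panels_share_the_test_code_path(self, toy_model, toy_haps, toy_rules):
        """AMP tier allele sets evaluated as panels are bona fide test rows."""
        tier = TestPanel("AMP_Tier1", {"CYPX": frozenset({"v2"})})
        test = TestPanel("some_test", {"CYPX": frozenset({"v2"})})
        matrix = evaluate_panels(
            [test, tier], {"CYPX": toy_model}, {"CYPX": toy_haps}, toy_rules
        )
        t1 = matrix.get("AMP_Tier1", "CYPX", "POP1")
        t2 = matrix.get("some_test", "CYPX", "POP1")
        assert t1.detection_rate_pct == t2.detection_rate_pct == pytest.approx(52.0)

    def test_matrix_equals_brute_force_on_toy(self, toy_model, toy_haps, toy_rules):
        from cpgx_eval import brute_force_oracle

        panels = [
            TestPanel("A", {"CYPX": frozenset({"v2"})}),
            TestPanel("B", {"CYPX": frozenset({"v2", "v3"})}),
        ]
        matrix = evaluate_panels(panels, {"CYPX": toy_model}, {"CYPX": toy_haps}, toy_rules)
        for panel in panels:
            oracle = brute_force_oracle(toy_model, toy_haps, panel, toy_rules, "POP1")
            cell = matrix.get(panel.test_name, "CYPX", "POP1")
            assert cell.detection_rate_pct == pytest.approx(
                oracle.detection_rate_pct, abs=1e-9
            )


class TestSummaries:
    def _matrix(self, rates):
        from cpgx_eval.metrics import DetectionMatrix
        from cpgx_eval.model import DetectionResult

        tests = [f"t{i}" for i in range(len(rates))]
        cells = {
            (t, "G", "P"): DetectionResult(t, "G", "P", 50.0, 0.5, 0.5 * r / 100, r)
            for t, r in zip(tests, rates)
        }
        return DetectionMatrix(tuple(tests), ("G",), ("P",), cells)

    def test_mean_and_range(self):
        s = summarize(self._matrix([40.0, 60.0]), by="gene")
        row = s.iloc[0]
        assert row["mean_detection_rate_pct"] == 50.0
        assert row["min_detection_rate_pct"] == 40.0
        assert row["max_detection_rate_pct"] == 60.0

    def test_uniform_hundreds(self):
        s = summarize(self._matrix([100.0, 100.0, 100.0]), by="gene")
        row = s.iloc[0]
        assert row["mean_detection_rate_pct"] == 100.0
        assert row["min_detection_rate_pct"] == row["max_detection_rate_pct"] == 100.0

    def test_singleton_mean(self):
        s = summarize(self._matrix([52.0]), by="test")
        assert s.iloc[0]["mean_detection_rate_pct"] == 52.0

    def test_undefined_cells_excluded_and_counted(self, toy_model, toy_haps, toy_rules):
        t = FrequencyTable(
            "CYPX", "diplotype", ("POP1", "POP2"),
            {("*1/*1", "POP1"): 1.0, ("*1/*1", "POP2"): 0.25, ("*1/*2", "POP2"): 0.75},
        )
        panel = TestPanel("A", {"CYPX": frozenset({"v2"})})
        matrix = evaluate_panels([panel], {"CYPX": toy_model}, {"CYPX": t}, toy_rules)
        s = summarize(matrix, by="test")
        row = s.iloc[0]
        # POP1 has zero altered mass -> undefined, excluded from the mean
        assert row["n_defined"] == 1
        assert row["n_excluded"] == 1
        assert row["mean_detection_rate_pct"] == pytest.approx(100.0)

    def test_rank_tests_breaks_ties_by_name(self, toy_model, toy_haps, toy_rules):
        panels = [
            TestPanel("zeta", {"CYPX": frozenset({"v2"})}),
            TestPanel("alpha", {"CYPX": frozenset({"v2"})}),
            TestPanel("full", {"CYPX": frozenset({"v2", "v3"})}),
        ]
        matrix = evaluate_panels(panels, {"CYPX": toy_model}, {"CYPX": toy_haps}, toy_rules)
        assert rank_tests(matrix, "CYPX", "POP1") == ("full", "alpha", "zeta")
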