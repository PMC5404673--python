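"""Flag engine truth-table equivalence, filter expressions and presets."""

from __future__ import annotations

import itertools
from types import SimpleNamespace

import pytest

from _oracles import oracle_flags
from vardesk.filters import (AssayConfig, FilterError, FlagResult,
                             apply_filter, artefact_filter_retention,
                             assign_flags, assign_zygosity, call_record,
                             merge_replicate_history, panel_frequency,
                             parse_filter, preset_filter, replicate_singleton,
                             retained_fraction)
from vardesk.variants import GenomicVariant, RegionSet, VariantCall


def make_call(vaf=0.5, total=1000, key="chr1:100:A:T", sample="S1_R1"):
    chrom, pos, ref, alt = key.split(":")
    alt_depth = round(vaf * total)
    return VariantCall(GenomicVariant(chrom, int(pos), ref, alt), sample,
                       total, alt_depth, alt_depth / total if total else 0.0)


def grid_call(vaf, total_depth, alt_depth, chrom="chr1", pos=100):
    """A duck-typed call with independent vaf/depth axes for grid probing."""
    return SimpleNamespace(
        variant=GenomicVariant(chrom, pos, "A", "T"),
        sample_id="S", vaf=vaf, total_depth=total_depth, alt_depth=alt_depth)


SOMATIC = AssayConfig("A1", sample_type="somatic",
                      roi=RegionSet([("chr1", 50, 150)]),
                      blacklist={"chr1:100:A:T"})


class TestFlagTruthTable:
    def test_grid_matches_independent_per_rule_oracle(self):
        """3^9 grid spanning below/at/above every documented threshold."""
        cfg = AssayConfig("A1", sample_type="somatic")
        axes = {
            "vaf": (0.079, 0.08, 0.081),
            "total_depth": (99, 100, 101),
            "alt_depth": (19, 20, 21),
            "gmaf": (0.009, 0.01, 0.011),
            "panel_frac": (7 / 20, 0.34, 0.40),
            "in_roi": (True, False, True),
            "blacklisted": (False, True, False),
            "consequence_benign": (False, True, False),
            "singleton": (False, True, False),
        }
        roi = RegionSet([("chr1", 50, 150)])
        n = 0
        for combo in itertools.product(*axes.values()):
            d = dict(zip(axes.keys(), combo))
            d["min_vaf"] = cfg.min_vaf
            call = grid_call(d["vaf"], d["total_depth"], d["alt_depth"],
                             pos=100 if d["in_roi"] else 500)
            fr = assign_flags(
                call, AssayConfig("A1", sample_type="somatic", roi=roi,
                                  blacklist={call.variant.key} if d["blacklisted"] else set()),
                annotations={"gmaf": d["gmaf"],
                             "consequence": ("synonymous_variant"
                                             if d["consequence_benign"]
                                             else "missense_variant")},
                replicate_partner_keys=(set() if d["singleton"]
                                        else {call.variant.key}),
                panel_frac=d["panel_frac"])
            assert fr.flags == oracle_flags(d), d
            assert not fr.unevaluable
            n += 1
        assert n == 3 ** 9

    def test_boundary_values_do_not_fire(self):
        """VAF 8%, depth 100/20, GMAF 1%, panel 35% are strict thresholds."""
        call = grid_call(0.08, 100, 20)
        fr = assign_flags(call, AssayConfig("A1", roi=RegionSet([("chr1", 1, 1000)])),
                          annotations={"gmaf": 0.01, "consequence": "missense_variant"},
                          replicate_partner_keys={call.variant.key},
                          panel_frac=7 / 20)
        assert fr.flags == {"pass"}

    def test_low_vaf_somatic_example(self):
        call = make_call(vaf=0.07, total=500, key="chr1:100:A:G")
        fr = assign_flags(call, SOMATIC,
                          annotations={"gmaf": None, "consequence": "missense_variant"},
                          replicate_partner_keys={call.variant.key},
                          panel_frac=0.1)
        assert fr.flags == {"vaf"}

    def test_compound_failure_example(self):
        call = grid_call(19 / 99, 99, 19)
        fr = assign_flags(call, AssayConfig("A1", roi=RegionSet([("chr1", 1, 1000)])),
                          annotations={"gmaf": 0.02, "consequence": "missense_variant"},
                          replicate_partner_keys=set(), panel_frac=0.4)
        assert fr.flags == {"vrd", "vad", "gmaf", "pnl", "sin"}

    def test_missing_inputs_reported_unevaluable_never_passed(self):
        call = make_call(vaf=0.5, key="chr1:60:A:T")
        fr = assign_flags(call, AssayConfig("A1"), annotations={},
                          replicate_partner_keys=None, panel_frac=None)
        assert fr.unevaluable == {"oor", "con", "gmaf", "pnl", "sin"}
        assert "pass" in fr.flags and not fr.passed

    def test_germline_threshold_is_fifteen_percent(self):
        cfg = AssayConfig("G1", sample_type="germline")
        assert cfg.min_vaf == 0.15
        call = make_call(vaf=0.10, key="chr1:60:A:T")
        fr = assign_flags(call, cfg, annotations={"gmaf": 0.0, "consequence": "x"},
                          replicate_partner_keys={call.variant.key}, panel_frac=0.0)
        assert "vaf" in fr.flags

    def test_pass_iff_no_other_flag(self):
        with pytest.raises(FilterError):
            FlagResult(flags={"pass", "vaf"})


class TestPanelFrequency:
    def test_printed_boundary_seven_of_twenty(self):
        history = {f"S{i}": ({"K"} if i < 7 else set()) for i in range(20)}
        assert panel_frequency("K", history) == 0.35
        # strict >35%: 7/20 must NOT fire, 8/20 must
        assert not panel_frequency("K", history) > 0.35
        history["S7"].add("K")
        assert panel_frequency("K", history) == 0.40 > 0.35

    def test_absent_key_zero(self):
        assert panel_frequency("K", {"a": set(), "b": set()}) == 0.0

    def test_empty_history_is_an_error(self):
        with pytest.raises(FilterError):
            panel_frequency("K", {})

    def test_replicates_counted_once(self):
        merged = merge_replicate_history({
            "P1_R1": {"K"}, "P1_R2": {"K"}, "P2_R1": set(), "P2_R2": set(),
        })
        assert set(merged) == {"P1", "P2"}
        assert panel_frequency("K", merged) == 0.5


class TestReplicateSingleton:
    @pytest.mark.parametrize("a, b, expected", [
        ({"K"}, set(), True),
        ({"K"}, {"K"}, False),
        (set(), set(), False),
    ])
    def test_membership_cases(self, a, b, expected):
        assert replicate_singleton("K", a, b) is expected


class TestFilterExpressions:
    RECORDS = [
        {"gene": "BRAF", "vaf": 0.4, "filter_flags": frozenset({"pass"}),
         "consequence": "missense_variant", "gmaf": 0.0},
        {"gene": "KRAS", "vaf": 0.05, "filter_flags": frozenset({"vaf", "blk"}),
         "consequence": "missense_variant", "gmaf": 0.0},
        {"gene": "TP53", "vaf": 0.3, "filter_flags": frozenset({"blk"}),
         "consequence": "synonymous_variant", "gmaf": 0.2},
        {"gene": "NRAS", "vaf": 0.2, "filter_flags": frozenset({"pass"}),
         "consequence": "missense_variant", "gmaf": 0.0},
        {"gene": "EGFR", "vaf": 0.15, "filter_flags": frozenset({"sin"}),
         "consequence": "missense_variant", "gmaf": 0.0},
    ]

    def test_gene_list_membership(self):
        expr = parse_filter("[Gene 'Is In' BRAF,KRAS,NRAS]")
        assert [r["gene"] for r in apply_filter(expr, self.RECORDS)] == \
            ["BRAF", "KRAS", "NRAS"]

    def test_empty_text_matches_all(self):
        assert apply_filter(parse_filter(""), self.RECORDS) == self.RECORDS

    def test_multi_clause_conjunction(self):
        expr = parse_filter("[VAF 'Greater Than' 0.10][filter_flags 'Not In' blk]")
        got = [r["gene"] for r in apply_filter(expr, self.RECORDS)]
        # hand evaluation: vaf>0.10 keeps BRAF,TP53,NRAS,EGFR; no-blk drops TP53
        assert got == ["BRAF", "NRAS", "EGFR"]

    def test_flag_not_in_excludes_blacklisted(self):
        expr = parse_filter("[filter_flags 'Not In' blk]")
        assert len(apply_filter(expr, self.RECORDS)) == 3

    def test_inputs_not_mutated_and_partitioned(self):
        import copy
        before = copy.deepcopy(self.RECORDS)
        expr = parse_filter("[VAF 'Less Than' 0.2]")
        kept = apply_filter(expr, self.RECORDS)
        assert self.RECORDS == before
        dropped = [r for r in self.RECORDS if r not in kept]
        assert len(kept) + len(dropped) == len(self.RECORDS)

    def test_unknown_operator_and_attribute_rejected(self):
        with pytest.raises(FilterError, match="operator"):
            parse_filter("[Gene 'Frobs' BRAF]")
        with pytest.raises(FilterError, match="attribute"):
            parse_filter("[Nope 'Equals' 1]", known_attributes=["gene", "vaf"])

    def test_type_mismatch_names_clause(self):
        expr = parse_filter("[Gene 'Greater Than' 5]")
        with pytest.raises(FilterError, match="Gene"):
            apply_filter(expr, self.RECORDS)


class TestPresets:
    def test_colorectal_clauses(self):
        cfg = AssayConfig("A1")
        expr = preset_filter("Colorectal", cfg)
        got = [r["gene"] for r in apply_filter(expr, TestFilterExpressions.RECORDS)]
        # BRAF passes all six clauses; KRAS is blacklisted+low-vaf-flag is
        # irrelevant (only blk/sin/pnl/consequence/gmaf/genes are clauses) ->
        # KRAS dropped for blk; NRAS clean
        assert got == ["BRAF", "NRAS"]

    def test_gist_gene_list(self):
        expr = preset_filter("GIST", AssayConfig("A1"))
        genes = next(c for c in expr.clauses if c.attribute == "gene")
        assert genes.operand == ("KIT", "PDGFRA")

    def test_unknown_preset_lists_names(self):
        with pytest.raises(FilterError, match="Colorectal"):
            preset_filter("Sarcoma", AssayConfig("A1"))


class TestZygosity:
    @pytest.mark.parametrize("vaf, expected", [
        (0.50, "heterozygous"), (0.99, "homozygous"), (0.20, "other"),
        (0.35, "heterozygous"), (0.65, "heterozygous"), (0.85, "homozygous"),
    ])
    def test_band_membership(self, vaf, expected):
        cfg = AssayConfig("G1", sample_type="germline")
        assert assign_zygosity(make_call(vaf=vaf, key="chr1:60:A:T"), cfg) == expected

    def test_somatic_not_applicable(self):
        assert assign_zygosity(make_call(), AssayConfig("A1")) == "not_applicable"


class TestRetention:
    def test_reported_myeloid_retention(self):
        """66,210 pre-filter calls reduce to 13,649 (20.6%) after the
        replicate/panel/depth artefact cascade."""
        assert round(100 * retained_fraction(13649, 66210), 1) == 20.6

    def test_cascade_removes_exactly_the_violators(self):
        pairs = [
            ("keep", FlagResult({"pass"})),
            ("sin", FlagResult({"sin"})),
            ("pnl", FlagResult({"pnl"})),
            ("vrd", FlagResult({"vrd", "vaf"})),
            ("vad", FlagResult({"vad"})),
            ("keep2", FlagResult({"gmaf"})),  # gmaf not part of this cascade
        ]
        kept, frac = artefact_filter_retention(pairs)
        assert kept == ["keep", "keep2"]
        assert frac == pytest.approx(2 / 6)
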