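"""Parsing, ratio ranking and node aggregation of the two-sample RPPA panel."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rppacra.rppa import (
    FINITE,
    UNDEFINED_HIGH,
    UNINFORMATIVE,
    MappingError,
    RppaEndpoint,
    RppaFormatError,
    RppaTable,
    RppaValidationError,
    SelectionError,
    aggregate_phosphosites,
    compute_ratio,
    parse_mapping,
    parse_rppa_table,
    select_calibration_proteins,
    select_divergent,
)


def make_endpoint(antibody, l, s, catalog="X"):
    return RppaEndpoint(catalog_id=catalog, antibody=antibody,
                        value_lOS=l, value_sOS=s)


class TestComputeRatio:
    @pytest.mark.parametrize(
        "l, s, expected",
        [
            (25336.48, 6075.38, 0.24),   # low-side divergent phospho site
            (36680.49, 0.00, 0.00),      # vanished signal in the s-OS sample
            (9339.43, 33189.87, 3.55),   # high-side divergent phospho site
        ],
    )
    def test_panel_values_to_2dp(self, l, s, expected):
        ratio, flag = compute_ratio(l, s)
        assert flag == FINITE
        assert ratio == pytest.approx(expected, abs=0.005)

    def test_zero_denominator_flags_undefined_high(self):
        ratio, flag = compute_ratio(0.0, 15994.50)
        assert flag == UNDEFINED_HIGH and math.isnan(ratio)

    def test_double_zero_is_uninformative(self):
        _, flag = compute_ratio(0.0, 0.0)
        assert flag == UNINFORMATIVE

    def test_negative_intensity_rejected(self):
        with pytest.raises(RppaValidationError):
            compute_ratio(-1.0, 5.0)

    @given(x=st.floats(min_value=1e-6, max_value=1e9))
    @settings(max_examples=50, deadline=None)
    def test_identical_values_give_unit_ratio(self, x):
        ratio, flag = compute_ratio(x, x)
        assert flag == FINITE and ratio == pytest.approx(1.0)


class TestFixtureTable:
    def test_has_51_endpoints(self, table):
        assert len(table) == 51

    def test_recomputed_ratios_match_printed_column(self, table):
        """Every row with nonzero denominator reproduces the printed ratio."""
        checked = 0
        for e in table:
            if e.printed_ratio is None or e.value_lOS == 0:
                continue
            assert e.ratio == pytest.approx(e.printed_ratio, abs=0.005), e.antibody
            checked += 1
        assert checked == 50  # all but the zero-denominator row

    def test_antibody_names_unique(self, table):
        names = [e.antibody for e in table]
        assert len(set(names)) == len(names)

    def test_empty_input_is_a_format_error(self):
        with pytest.raises(RppaFormatError):
            parse_rppa_table("")

    def test_missing_column_is_a_format_error(self):
        with pytest.raises(RppaFormatError, match="missing required"):
            parse_rppa_table("catalog_id,antibody,l_OS\nX,a,1.0\n")

    def test_negative_intensity_is_a_validation_error(self):
        text = "catalog_id,antibody,company,dilution,l_OS,s_OS\nX,a,c,1:1,-1,2\n"
        with pytest.raises(RppaValidationError):
            parse_rppa_table(text)

    def test_tsv_dialect(self):
        text = "catalog_id\tantibody\tcompany\tdilution\tl_OS\ts_OS\nX\ta\tc\t1:1\t2\t4\n"
        t = parse_rppa_table(text)
        assert t.get("a").ratio == pytest.approx(2.0)


class TestSelectDivergent:
    def test_twofold_rule_flags_20_endpoints(self, table):
        sel = select_divergent(table, fold=2.0)
        assert len(sel.divergent_endpoints) == 20
        assert len(sel.up_in_sOS) == 4
        assert len(sel.down_in_sOS) == 16

    def test_monotone_in_fold(self, table):
        """Raising the threshold never adds endpoints."""
        prev = None
        for fold in (1.5, 2.0, 3.0, 5.0, 10.0):
            sel = {e.antibody for e in select_divergent(table, fold).divergent_endpoints}
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_identical_samples_select_nothing(self):
        t = RppaTable([make_endpoint(f"a{i}", 10.0, 10.0, str(i)) for i in range(5)])
        sel = select_divergent(t, 2.0)
        assert not sel.divergent_endpoints

    def test_near_unity_threshold_takes_everything_off_unity(self):
        t = RppaTable([
            make_endpoint("up", 1.0, 1.5, "1"),
            make_endpoint("flat", 2.0, 2.0, "2"),
            make_endpoint("down", 3.0, 2.0, "3"),
        ])
        sel = select_divergent(t, 1.0 + 1e-9)
        assert {e.antibody for e in sel.divergent_endpoints} == {"up", "down"}

    def test_fold_must_exceed_one(self, table):
        with pytest.raises(ValueError):
            select_divergent(table, 1.0)


class TestAggregation:
    def test_geometric_mean_of_phosphosites(self, table, mapping):
        agg = aggregate_phosphosites(table, mapping)
        ckit = table.get("c-Kit (Y703)").ratio * table.get("cKit (Y719)").ratio
        assert agg["cKIT"]["ratio"] == pytest.approx(math.sqrt(ckit))
        assert agg["cKIT"]["ratio"] == pytest.approx(2.69, abs=0.01)
        # T412 is excluded from the p70S6K aggregate (distinct site set)
        p70 = table.get("p70S6 Kinase (S371)").ratio * table.get("p70S6 Kinase (T389)").ratio
        assert agg["p70S6K"]["ratio"] == pytest.approx(math.sqrt(p70))
        assert agg["p70S6K"]["ratio"] == pytest.approx(0.41, abs=0.01)

    def test_single_endpoint_node_is_its_own_ratio(self, table, mapping):
        agg = aggregate_phosphosites(table, mapping)
        assert agg["mTOR"]["ratio"] == pytest.approx(table.get("mTOR (S2448)").ratio)

    def test_row_order_invariance(self, table, mapping):
        reversed_table = RppaTable(list(table)[::-1])
        a = aggregate_phosphosites(table, mapping)
        b = aggregate_phosphosites(reversed_table, mapping)
        assert a == b

    def test_unmapped_endpoint_raises_naming_it(self, mapping):
        t = RppaTable([make_endpoint("mystery (Y1)", 1.0, 2.0)])
        with pytest.raises(MappingError, match="mystery"):
            aggregate_phosphosites(t, mapping)

    def test_yaml_mapping_dialect(self, tmp_path):
        from rppacra.rppa import load_mapping

        p = tmp_path / "map.yaml"
        p.write_text("'a (S1)': {node: A}\n'b': {node: B, excluded: true}\n")
        m = load_mapping(p)
        assert m["a (S1)"].node == "A" and not m["a (S1)"].excluded
        assert m["b"].excluded

    def test_node_with_no_finite_ratio_is_flagged(self):
        mapping = parse_mapping("antibody,node,excluded\ng (S1),G,false\n")
        t = RppaTable([make_endpoint("g (S1)", 0.0, 5.0)])
        agg = aggregate_phosphosites(t, mapping)
        assert agg["G"]["flag"] == "no-finite-ratio"


class TestCalibrationSelection:
    def test_panel_selects_the_four_divergent_model_proteins(
        self, table, default_model, mapping
    ):
        sel = select_calibration_proteins(
            table, default_model.node_names(), k_per_side=2, mapping=mapping
        )
        assert sel.calibration_proteins == {
            "BAD": 1, "cKIT": 1, "RAF": -1, "p70S6K": -1,
        }

    def test_k1_takes_the_extremes(self, table, default_model, mapping):
        sel = select_calibration_proteins(
            table, default_model.node_names(), k_per_side=1, mapping=mapping
        )
        assert sel.calibration_proteins == {"BAD": 1, "RAF": -1}

    def test_flat_table_is_a_selection_error(self, mapping):
        mapping = parse_mapping(
            "antibody,node,excluded\na,A,false\nb,B,false\nc,C,false\nd,D,false\n"
        )
        t = RppaTable([make_endpoint(n, 5.0, 5.0, n) for n in "abcd"])
        with pytest.raises(SelectionError):
            select_calibration_proteins(t, ["A", "B", "C", "D"], 1, mapping)

    def test_too_few_model_endpoints_is_a_selection_error(
        self, table, mapping
    ):
        with pytest.raises(SelectionError):
            select_calibration_proteins(table, ["ERK"], 2, mapping)
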