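"""Criteria engine: classification bands, deviations, tallies, baselines."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phantomqa import tables
from phantomqa.criteria import (
    CRITERIA,
    CriteriaConfig,
    Level,
    build_baseline,
    classify_hu,
    classify_uniformity,
    default_config,
    deviation_beyond_range,
    evaluate_protocol,
    exposure_stability,
    summarize_failures,
    tally_verdicts,
)


@pytest.fixture(scope="module")
def config():
    return default_config()


class TestClassifyUniformity:
    @pytest.mark.parametrize(
        "value,level",
        [
            (4.05, Level.PASS),
            (4.98, Level.PASS),
            (5.10, Level.MINOR),
            (5.0, Level.MINOR),   # band edge: 5 is already a minor deviation
            (7.0, Level.MINOR),   # band edge: 7 still minor
            (7.65, Level.MAJOR),
            (8.17, Level.MAJOR),
        ],
    )
    def test_band_edges(self, value, level):
        assert classify_uniformity(value).level is level

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_uniformity(-0.1)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 50, allow_nan=False))
    def test_total_function(self, value):
        assert classify_uniformity(value).level in Level


class TestClassifyHu:
    def test_water_inside_band(self, config):
        assert classify_hu("water", -3.1, config).level is Level.PASS

    def test_water_outside_band(self, config):
        assert classify_hu("water", -11.6, config).level is not Level.PASS

    def test_upper_bound_inclusive(self, config):
        hi = config.hu_ranges["water"][1]
        assert classify_hu("water", hi, config).level is Level.PASS

    def test_unknown_material(self, config):
        with pytest.raises(KeyError):
            classify_hu("lead", 0.0, config)

    def test_minor_band_when_configured(self):
        cfg = CriteriaConfig(
            hu_ranges={"water": (-7.0, 7.0)},
            hu_minor_bands={"water": (-10.0, 10.0)},
        )
        assert classify_hu("water", 8.5, cfg).level is Level.MINOR
        assert classify_hu("water", 12.0, cfg).level is Level.MAJOR


class TestDeviationBeyondRange:
    @pytest.mark.parametrize(
        "value,rng,expected",
        [
            (0.0, (-7.0, 7.0), 0.0),
            (-11.6, (-7.0, 7.0), 4.6),
            (831.0, (850.0, 970.0), 19.0),
        ],
    )
    def test_known_values(self, value, rng, expected):
        assert deviation_beyond_range(value, rng) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None)
    @given(
        v1=st.floats(-2000, 2000),
        v2=st.floats(-2000, 2000),
    )
    def test_zero_on_band_and_1_lipschitz(self, v1, v2):
        rng = (-7.0, 7.0)
        d1 = deviation_beyond_range(v1, rng)
        d2 = deviation_beyond_range(v2, rng)
        assert d1 >= 0
        if rng[0] <= v1 <= rng[1]:
            assert d1 == 0.0
        assert abs(d1 - d2) <= abs(v1 - v2) + 1e-9


@pytest.fixture(scope="module")
def body():
    t2 = tables.load_protocol_scorecards()
    return t2[t2["phantom"] == "body"]


@pytest.fixture(scope="module")
def t2():
    return tables.load_protocol_scorecards()


@pytest.fixture(scope="module")
def exposure_table():
    t3 = tables.load_exposure_series()
    return {
        proto: {m: grp[m].tolist() for m in ("acrylic", "air", "bone", "polyethylene", "water")}
        for proto, grp in t3.groupby("protocol")
    }


class TestSummaries:
    """Deviation summaries over the published body-phantom columns."""

    @pytest.mark.parametrize(
        "material,mean,sd",
        [("acrylic", 9.4, 4.8), ("bone", 32.7, 28.6), ("water", 7.2, 3.6)],
    )
    def test_failing_hu_summaries_to_one_decimal(self, body, config, material, mean, sd):
        s = summarize_failures(body[material], config.hu_ranges[material])
        assert round(s.mean, 1) == mean
        assert round(s.sd, 1) == sd

    def test_air_summary_from_lower_bound(self, body, config):
        """The air column's published summary is measured from the lower
        passing bound even though the failures violate the upper bound."""
        s = summarize_failures(body["air"], config.hu_ranges["air"], bound="lower")
        assert round(s.mean, 1) == 40.6
        assert round(s.sd, 1) == 3.3

    def test_all_inside_gives_empty_summary(self, config):
        s = summarize_failures([0.0, 1.0, -2.0], config.hu_ranges["water"])
        assert s.n_failing == 0 and s.mean is None and s.sd is None


class TestEvaluateAndTally:
    def test_head_phantom_head_protocol_all_pass(self, t2, config):
        row = t2[(t2["phantom"] == "head") & (t2["protocol"] == "Head")].iloc[0]
        pv = evaluate_protocol(row, config.protocol_class("Head"), config)
        assert pv.overall_pass
        assert pv.n_no_deviation == 9

    def test_body_uniformity_tally(self, t2, config):
        body = t2[t2["phantom"] == "body"]
        pvs = [
            evaluate_protocol(r, config.protocol_class(r["protocol"]), config)
            for r in body.to_dict("records")
        ]
        assert tally_verdicts(pvs, "hu_uniformity") == (2, 5, 4)

    def test_head_phantom_full_pass_count(self, t2, config):
        head = t2[t2["phantom"] == "head"]
        pvs = [
            evaluate_protocol(r, config.protocol_class(r["protocol"]), config)
            for r in head.to_dict("records")
        ]
        assert sum(pv.overall_pass for pv in pvs) == 8

    def test_typo_row_is_major_either_way(self, config):
        # the published value prints ambiguously as 8.7r5
        assert classify_uniformity(8.75).level is Level.MAJOR
        assert classify_uniformity(8.7).level is Level.MAJOR

    def test_missing_metric_rejected(self, config):
        with pytest.raises(KeyError, match="missing metric"):
            evaluate_protocol({"water": 0.0}, "adult_head", config)

    def test_empty_tally(self):
        assert tally_verdicts([], "water") == (0, 0, 0)


class TestBaseline:
    def test_head_acrylic_baseline(self, config):
        t2 = tables.load_protocol_scorecards()
        head = t2[t2["phantom"] == "head"]
        bl = build_baseline({m: head[m].tolist() for m in ("acrylic", "air")})
        assert round(bl.baselines["acrylic"], 1) == 116.7
        assert round(bl.baselines["air"], 1) == -998.6

    def test_single_value_baseline(self):
        bl = build_baseline({"water": [3.0]})
        assert bl.baselines["water"] == 3.0

    def test_tolerance_rule(self):
        bl = build_baseline({"bone": [900.0, 920.0]})  # baseline 910
        assert bl.check("bone", 955.0)
        assert not bl.check("bone", 961.0)


class TestExposureStability:
    def test_max_range_is_bone_at_1_3(self, exposure_table):
        rng, (proto, mat) = exposure_stability(exposure_table)
        assert round(rng, 1) == 1.3
        assert (proto, mat) == ("Pediatric head", "bone")

    def test_identical_entries_zero_range(self, exposure_table):
        col = exposure_table["Pediatric head"]["air"]
        assert max(col) - min(col) == 0.0
        rng, _ = exposure_stability({"p": {"air": col}})
        assert rng == 0.0

    def test_single_exposure_rejected(self):
        with pytest.raises(ValueError, match=">= 2 exposures"):
            exposure_stability({"p": {"water": [0.0]}})


def test_criteria_names_partition(config):
    assert len(CRITERIA) == 9
    # every configured material has a valid band
    for mat, (lo, hi) in config.hu_ranges.items():
        assert lo < hi, mat
    assert math.isclose(config.scaling_tolerance_pct, 1.0)
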