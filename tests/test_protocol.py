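"""Experiment orchestration: metrics arithmetic, test shapes, determinism."""

import dataclasses
import json

import numpy as np
import pytest

from octband import protocol
from octband.enums import GroupLabel, LayerName, RegionName
from octband.errors import OctbandError, ValidationError
from octband.protocol import (
    ConfusionCounts,
    TestConfig,
    TestId,
    confusion_metrics,
    scan_counts,
)
from octband.worked_examples import reproduce_worked_examples


@pytest.fixture(scope="module")
def quick_cfg(fast_brbf):
    return TestConfig(
        test_id=TestId.TEST1,
        layers=(LayerName.GCL_IPL,),
        rng_seed=3,
        brbf_config=fast_brbf,
    )


# fast_brbf is function-scoped in conftest; redefine at module scope here
@pytest.fixture(scope="module")
def fast_brbf():
    from octband.brbf import BRBFConfig

    return BRBFConfig(mcmc_iterations=1600, burn_in=500, thinning=2)


# ------------------------------- metric arithmetic ------------------------


@pytest.mark.parametrize(
    "counts, sens, spec, ppv",
    [
        ((48, 6, 10, 33), 0.89, 0.23, 0.59),  # an RNFL-like column
        ((20, 3, 33, 5), 0.87, 0.87, 0.80),  # an RPE-like column
        ((1, 1, 1, 1), 0.50, 0.50, 0.50),
    ],
)
def test_confusion_metrics_reference_columns(counts, sens, spec, ppv):
    m = confusion_metrics(ConfusionCounts(*counts))
    assert round(m["sensitivity"], 2) == sens
    assert round(m["specificity"], 2) == spec
    assert round(m["ppv"], 2) == ppv


def test_symmetric_counts_percent_correct():
    m = confusion_metrics(ConfusionCounts(1, 1, 1, 1))
    assert m["percent_correct"] == 50.0


def test_zero_denominator_reported_undefined_not_zero():
    m = confusion_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=0))
    assert m["sensitivity"] == "undefined"
    assert "sensitivity" in m["undefined"] and "ppv" in m["undefined"]
    assert m["specificity"] == 1.0


def test_all_published_worked_examples_reproduce():
    results = reproduce_worked_examples()
    assert len(results) > 30
    assert all(r["match"] for r in results)


@pytest.mark.parametrize("eyes, scans", [(48, 288), (0, 0), (155, 930)])
def test_scan_counts_are_six_per_eye(eyes, scans):
    assert scan_counts(eyes) == scans


def test_scan_counts_on_confusion_counts():
    c = ConfusionCounts(tp=49, fn=5, tn=35, fp=8)
    assert c.scans() == {"tp": 294, "fn": 30, "tn": 210, "fp": 48}


def test_negative_counts_rejected():
    with pytest.raises(ValidationError):
        ConfusionCounts(tp=-1, fn=0, tn=0, fp=0)


# ------------------------------- experiment shapes ------------------------


def test_test1_shape_on_default_cohort(default_cohort, quick_cfg):
    rows = protocol.run_reference_band_experiment(default_cohort, quick_cfg)
    (row,) = rows
    # 20 healthy train -> 54 healthy + 43 MDR test eyes
    assert row.counts.tp + row.counts.fn == 54
    assert row.counts.tn + row.counts.fp == 43
    assert row.counts.total == 97


def test_test3_shape_on_default_cohort(default_cohort, fast_brbf):
    cfg = TestConfig(
        test_id=TestId.TEST3,
        layers=(LayerName.RPE,),
        rng_seed=3,
        brbf_config=fast_brbf,
    )
    rows = protocol.run_reference_band_experiment(default_cohort, cfg)
    (row,) = rows
    # 20 MDR train -> 23 MDR + 38 DM test eyes
    assert row.counts.tp + row.counts.fn == 23
    assert row.counts.tn + row.counts.fp == 38
    assert row.counts.total == 61


def test_metrics_consistent_with_counts(default_cohort, quick_cfg):
    (row,) = protocol.run_reference_band_experiment(default_cohort, quick_cfg)
    c = row.counts
    assert row.metrics["sensitivity"] == c.tp / (c.tp + c.fn)
    assert row.metrics["specificity"] == c.tn / (c.tn + c.fp)


def test_end_to_end_determinism(default_cohort, quick_cfg):
    r1 = protocol.run_reference_band_experiment(default_cohort, quick_cfg)
    r2 = protocol.run_reference_band_experiment(default_cohort, quick_cfg)
    assert [r.to_dict() for r in r1] == [r.to_dict() for r in r2]


def test_repeats_add_mean_row(small_cohort, fast_brbf):
    cfg = TestConfig(
        test_id=TestId.TEST1,
        n_train=15,
        layers=(LayerName.OPL,),
        rng_seed=1,
        n_repeats=3,
        brbf_config=fast_brbf,
    )
    rows = protocol.run_reference_band_experiment(small_cohort, cfg)
    assert [r.repeat for r in rows] == [0, 1, 2, -1]
    assert rows[-1].counts.total == pytest.approx(15 + 18, abs=1)


def test_missing_layer_raises_listing_layers(small_cohort, quick_cfg):
    cfg = dataclasses.replace(quick_cfg, region=RegionName.FOVEOLA)
    with pytest.raises(OctbandError, match="GCL_IPL"):
        protocol.run_reference_band_experiment(small_cohort, cfg)


def test_train_size_exceeding_group_rejected(small_cohort, fast_brbf):
    cfg = TestConfig(
        test_id=TestId.TEST1,
        n_train=30,  # equals the reduced healthy group size
        layers=(LayerName.OPL,),
        brbf_config=fast_brbf,
    )
    with pytest.raises(ValidationError, match="n_train"):
        protocol.run_reference_band_experiment(small_cohort, cfg)


# ------------------------------- Test 2 -----------------------------------


def test_test2_nested_sizes_and_shrinking_test_sets(default_cohort, fast_brbf):
    cfg = TestConfig(
        test_id=TestId.TEST2,
        layers=(LayerName.GCL_IPL,),
        rng_seed=5,
        brbf_config=fast_brbf,
    )
    results = protocol.run_test2(default_cohort, cfg)
    totals = {s: results[s][0].counts.total for s in (20, 30, 40)}
    assert totals == {20: 97, 30: 87, 40: 77}
    # nested training: positive-condition test eyes shrink by exactly the delta
    for s in (20, 30, 40):
        row = results[s][0]
        assert row.counts.tp + row.counts.fn == 74 - s
        assert row.counts.tn + row.counts.fp == 43
    stability = protocol.test2_stability(results)
    assert set(stability) == {"GCL_IPL"}
    assert stability["GCL_IPL"]["tn_delta"] <= 43


def test_test2_membership_determinism(default_cohort, fast_brbf):
    cfg = TestConfig(
        test_id=TestId.TEST2,
        layers=(LayerName.OPL,),
        rng_seed=8,
        brbf_config=fast_brbf,
    )
    a = protocol.run_test2(default_cohort, cfg)
    b = protocol.run_test2(default_cohort, cfg)
    for s in (20, 30, 40):
        assert a[s][0].to_dict() == b[s][0].to_dict()


def test_test2_rejects_nonstandard_sizes(fast_brbf):
    cfg = TestConfig(
        test_id=TestId.TEST2, train_sizes=(20, 25), brbf_config=fast_brbf
    )
    with pytest.raises(ValidationError, match="train_sizes"):
        cfg.validate()


# ------------------------------- reporting --------------------------------


def test_report_roundtrip_and_layout(default_cohort, quick_cfg):
    rows = protocol.run_reference_band_experiment(default_cohort, quick_cfg)
    js, md = protocol.report(rows, quick_cfg)
    payload = json.loads(js)
    assert payload["rows"][0]["counts_eyes"] == rows[0].counts.to_dict()
    assert payload["config"]["c"] == pytest.approx(1.65)
    assert md.splitlines()[0].count("|") == len(rows) + 2
    js2, md2 = protocol.report(rows, quick_cfg)
    assert js == js2 and md == md2


def test_report_rejects_empty():
    with pytest.raises(ValidationError):
        protocol.report([], TestConfig())


def test_band_coverage_selection_via_coverage_parameter():
    cfg = TestConfig(coverage=0.95)
    assert cfg.band_c == pytest.approx(1.96, abs=0.01)
    with pytest.raises(ValidationError, match="not both"):
        TestConfig(c=1.65, coverage=0.9).validate()
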