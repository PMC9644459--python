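"""Scoring engine: bucketing, exclusion rules, aggregation, comparison."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from devicemcda.scoring import (
    DeviceProfile,
    ScoringError,
    SpecCount,
    compare_devices,
    fulfillment_percentage,
    score_device,
    select_option,
)

from conftest import top_profile


class TestFulfillmentPercentage:
    @pytest.mark.parametrize(
        "met, req, expected", [(16, 20, 80.0), (20, 20, 100.0), (13, 20, 65.0), (0, 7, 0.0)]
    )
    def test_worked_examples(self, met, req, expected):
        assert fulfillment_percentage(met, req) == expected

    @pytest.mark.parametrize("met, req", [(21, 20), (-1, 20), (5, 0)])
    def test_invalid_counts(self, met, req):
        with pytest.raises(ScoringError):
            fulfillment_percentage(met, req)


class TestSelectOption:
    @pytest.mark.parametrize(
        "criterion_id, evidence, option_id, fraction",
        [
            ("technical", 100.0, "full", 1.0),
            ("technical", 95.0, "f90", 0.8),
            ("technical", 80.0, "f80", 0.6),
            ("technical", SpecCount(16, 20), "f80", 0.6),
            ("technical", 70.0, "f70", 0.1),
            ("technical", 65.0, "below70", 0.0),
            ("supply_reliability", 90.5, "above90", 1.0),
            ("supply_reliability", 90.0, "f70_90", 0.8),
            ("supply_reliability", 70.0, "f70_90", 0.8),
            ("supply_reliability", 69.9, "f50_70", 0.6),
            ("supply_reliability", "never_supplied", "never_supplied", 0.5),
            ("supply_reliability", 49.0, "below50", 0.1),
            ("refund_replacement", 0, "stagnant1", 1.0),
            ("refund_replacement", 2, "stagnant2", 0.7),
            ("refund_replacement", 3, "stagnant3", 0.5),
            ("refund_replacement", 4, "stagnant4", 0.2),
            ("refund_replacement", 9, "stagnant4", 0.2),
            ("pharmacovigilance", "none", "none", 0.0),
            ("country_of_origin", "ref_one", "ref_one", 0.75),
        ],
    )
    def test_published_scoring_table(
        self, default_tool, criterion_id, evidence, option_id, fraction
    ):
        opt = select_option(default_tool.criterion(criterion_id), evidence)
        assert opt.option_id == option_id
        assert opt.score_fraction == fraction

    def test_pharmacovigilance_none_is_exclusion(self, default_tool):
        opt = select_option(default_tool.criterion("pharmacovigilance"), "none")
        assert opt.is_exclusion

    def test_ce_only_requires_local_product(self, default_tool):
        crit = default_tool.criterion("reference_use")
        assert select_option(crit, "ce_only", is_local_product=True).score_fraction == 0.5
        with pytest.raises(ScoringError, match="local"):
            select_option(crit, "ce_only", is_local_product=False)

    @pytest.mark.parametrize("evidence", [-1.0, 101.0])
    def test_percentage_out_of_range(self, default_tool, evidence):
        with pytest.raises(ScoringError):
            select_option(default_tool.criterion("technical"), evidence)

    def test_unknown_option_rejected(self, default_tool):
        with pytest.raises(ScoringError):
            select_option(default_tool.criterion("country_of_origin"), "nope")

    def test_number_on_categorical_criterion_rejected(self, default_tool):
        with pytest.raises(ScoringError, match="categorical"):
            select_option(default_tool.criterion("country_of_origin"), 50.0)

    def test_bucketing_partitions_the_measurement_domain(self, default_tool):
        """Every legal measurement maps to exactly one bucket."""
        for c in default_tool.criteria:
            if not c.bucket_rules:
                continue
            values = (
                range(0, 12)
                if c.measurement_kind == "stagnant_count"
                else np.arange(0.0, 100.01, 0.25)
            )
            for v in values:
                hits = [r for r in c.bucket_rules if r.interval.contains(float(v))]
                assert len(hits) == 1, (c.criterion_id, v, hits)


class TestScoreDevice:
    def test_all_top_options_total_exactly_100(self, default_tool):
        a = score_device(top_profile(default_tool), default_tool)
        assert not a.excluded
        assert a.total == 100.0

    def test_weighted_sum_worked_example(self, default_tool):
        # fractions by rank: 0.8, 1.0, 0.75, 0.8, 1.0, 1.0, 0.7, 0.7
        profile = DeviceProfile(
            "d1",
            evidence={
                "technical": "f90",
                "country_of_origin": "ref_both",
                "reference_use": "ce_plus_freesale",
                "supply_reliability": "f70_90",
                "previous_use": "upa_listed",
                "instant_replacement": "provided",
                "pharmacovigilance": "moderate",
                "refund_replacement": "stagnant2",
            },
        )
        a = score_device(profile, default_tool)
        assert a.total == pytest.approx(85.475, abs=1e-9)

    def test_low_technical_fulfilment_excludes(self, default_tool):
        profile = replace(
            top_profile(default_tool), evidence={
                **top_profile(default_tool).evidence, "technical": 65.0
            }
        )
        a = score_device(profile, default_tool)
        assert a.excluded
        assert a.total is None  # exclusion is not a zero score
        assert any("technical" in r for r in a.exclusion_reasons)
        # audit trail survives exclusion
        assert len(a.scores) == 8
        assert sum(s.points for s in a.scores if not s.excluded_here) > 0

    def test_missing_evidence_lists_the_criteria(self, default_tool):
        profile = DeviceProfile("d1", evidence={"technical": 100.0})
        with pytest.raises(ScoringError, match="country_of_origin"):
            score_device(profile, default_tool)

    @given(data=st.data())
    @settings(derandomize=True, max_examples=80)
    def test_upgrading_one_criterion_never_lowers_the_total(self, default_tool, data):
        evidence = {}
        for c in default_tool.criteria:
            opts = [o.option_id for o in c.non_exclusion_options]
            evidence[c.criterion_id] = data.draw(
                st.sampled_from(opts), label=c.criterion_id
            )
        base = DeviceProfile("d", evidence=evidence, is_local_product=True)
        total0 = score_device(base, default_tool).total
        cid = data.draw(st.sampled_from(default_tool.criterion_ids), label="upgrade")
        crit = default_tool.criterion(cid)
        current = crit.option(evidence[cid]).score_fraction
        better = [
            o.option_id
            for o in crit.non_exclusion_options
            if o.score_fraction >= current
        ]
        upgraded = replace(base, evidence={**evidence, cid: data.draw(
            st.sampled_from(better), label="better")})
        assert score_device(upgraded, default_tool).total >= total0 - 1e-12


class TestCompareDevices:
    def test_five_devices_sorted_by_total(self, default_tool):
        from devicemcda.fixtures import ProfileSpec, gen_profiles

        profiles, _ = gen_profiles(ProfileSpec(n_devices=5, seed=11), default_tool)
        report = compare_devices(profiles, default_tool)
        totals = [a.total for a in report.assessments]
        assert len(totals) + len(report.excluded) == 5
        assert totals == sorted(totals, reverse=True)

    def test_single_profile(self, default_tool):
        report = compare_devices([top_profile(default_tool)], default_tool)
        assert len(report.assessments) == 1
        assert report.ties == ()

    def test_identical_profiles_tie_is_annotated(self, default_tool):
        pair = [top_profile(default_tool, "a"), top_profile(default_tool, "b")]
        report = compare_devices(pair, default_tool)
        assert report.assessments[0].total == report.assessments[1].total
        assert report.ties == (frozenset({"a", "b"}),)

    def test_excluded_devices_segregated_with_reasons(self, default_tool):
        bad = replace(
            top_profile(default_tool, "bad"),
            evidence={**top_profile(default_tool).evidence, "pharmacovigilance": "none"},
        )
        report = compare_devices([top_profile(default_tool, "ok"), bad], default_tool)
        assert [a.device_id for a in report.assessments] == ["ok"]
        assert [a.device_id for a in report.excluded] == ["bad"]
        assert report.excluded[0].exclusion_reasons

    def test_per_device_errors_collected_not_fatal(self, default_tool):
        broken = DeviceProfile("broken", evidence={"technical": 100.0})
        report = compare_devices([top_profile(default_tool), broken], default_tool)
        assert "broken" in report.errors
        assert len(report.assessments) == 1

    def test_empty_input_is_an_error(self, default_tool):
        with pytest.raises(ScoringError):
            compare_devices([], default_tool)
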