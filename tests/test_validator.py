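import math

import numpy as np
import pytest

from nxmxkit.model import FieldSpec, ProvenanceBlock
from nxmxkit.synth import MUTATION_RULES, make_rotation_fixture, mutate
from nxmxkit.validator import NullKind, check_names, check_times, is_null, validate


class TestValidateFixtures:
    def test_compliant_rotation_fixture(self, rotation_ds):
        report = validate(rotation_ds, "required")
        assert report.verdict
        assert report.findings == []

    def test_compliant_hierarchical_fixture(self, hierarchical_ds):
        assert validate(hierarchical_ds, "required").verdict

    def test_dark_run_sample_name_dot_is_compliant(self, rotation_ds):
        rotation_ds.sample.name = "."
        report = validate(rotation_ds, "required")
        assert report.verdict

    def test_missing_start_time_single_error(self, rotation_ds):
        rotation_ds.provenance.start_time = None
        errors = validate(rotation_ds, "required").errors()
        assert len(errors) == 1
        assert errors[0].rule_id == "start_time_missing"

    def test_levels_nest(self, rotation_ds):
        rotation_ds.provenance.time_zone = None
        assert validate(rotation_ds, "required").findings == []
        warnings = validate(rotation_ds, "recommended").findings
        assert any(f.rule_id == "time_zone_missing" for f in warnings)

    def test_idempotent_and_side_effect_free(self, rotation_ds):
        broken = mutate(rotation_ds, "non-utc-time")
        first = validate(broken, "recommended")
        second = validate(broken, "recommended")
        assert first.findings == second.findings


class TestMutationBijection:
    @pytest.mark.parametrize("mutation_id", sorted(MUTATION_RULES))
    def test_each_mutation_trips_exactly_its_rule(self, mutation_id):
        """Every catalogue mutation yields exactly one error, and that
        error's rule id is the one the catalogue declares (no-op: zero)."""
        ds = make_rotation_fixture()
        _, expected_rule = MUTATION_RULES[mutation_id]
        errors = validate(mutate(ds, mutation_id), "required").errors()
        if expected_rule is None:
            assert errors == []
        else:
            assert [f.rule_id for f in errors] == [expected_rule]

    def test_catalogue_covers_at_least_ten_rules(self):
        rules = {r for _, r in MUTATION_RULES.values() if r is not None}
        assert len(rules) >= 10

    def test_unknown_mutation_rejected(self, rotation_ds):
        with pytest.raises(KeyError):
            mutate(rotation_ds, "no-such-mutation")

    def test_mutation_does_not_touch_original(self, rotation_ds):
        mutate(rotation_ds, "drop-start-time")
        assert rotation_ds.provenance.start_time is not None


class TestCheckTimes:
    def _prov(self, **kw):
        base = dict(
            start_time="2019-11-06T10:00:00Z",
            end_time_estimated="2019-11-06T10:05:00Z",
            end_time="2019-11-06T10:04:58Z",
        )
        base.update(kw)
        return ProvenanceBlock(**base)

    def test_valid_times_no_findings(self):
        assert check_times(self._prov()) == []

    def test_offset_timestamp_rejected(self):
        findings = check_times(self._prov(start_time="2019-11-06T10:00:00+02:00"))
        assert [f.rule_id for f in findings] == ["time_not_utc"]

    def test_naive_timestamp_rejected(self):
        findings = check_times(self._prov(end_time="2019-11-06T10:04:58"))
        assert [f.rule_id for f in findings] == ["time_not_utc"]

    def test_end_before_start_is_error(self):
        findings = check_times(self._prov(end_time_estimated="2019-11-06T09:00:00Z"))
        assert [f.rule_id for f in findings] == ["time_order"]

    def test_absent_end_time_is_warning_only(self):
        findings = check_times(self._prov(end_time=None))
        assert [(f.rule_id, f.severity) for f in findings] == [
            ("end_time_missing", "warning")
        ]

    def test_generator_end_estimate_consistent(self, rotation_ds):
        """end_time_estimated = start + n_frames/frame_rate by construction,
        so the fixture produces no timing findings."""
        assert check_times(rotation_ds.provenance) == []


class TestCheckNames:
    def test_full_names_no_findings(self):
        prov = ProvenanceBlock(
            instrument_name="Diamond Light Source Beamline I04",
            instrument_short_name="I04",
            source_name="Diamond Light Source",
            source_short_name="DLS",
            time_zone="Europe/London",
        )
        assert check_names(prov) == []

    def test_missing_source_name_is_error(self):
        prov = ProvenanceBlock(
            instrument_name="x", instrument_short_name="x", time_zone="Etc/UTC"
        )
        assert [f.rule_id for f in check_names(prov)] == ["source_name_missing"]

    def test_missing_short_name_and_time_zone_are_warnings(self):
        prov = ProvenanceBlock(
            instrument_name="Beamline", source_name="Facility", source_short_name="F"
        )
        findings = check_names(prov)
        assert all(f.severity == "warning" for f in findings)
        assert {f.rule_id for f in findings} == {"short_name_missing", "time_zone_missing"}


class TestIsNull:
    @pytest.mark.parametrize(
        "value,spec,expected",
        [
            (".", FieldSpec("sensor_material", value_kind="text"), NullKind.ABSENT),
            ("?", FieldSpec("sensor_material", value_kind="text"), NullKind.PLACEHOLDER),
            ("Si", FieldSpec("sensor_material", value_kind="text"), NullKind.NOT_NULL),
            (float("nan"), FieldSpec("sensor_thickness", value_kind="float"), NullKind.ABSENT),
            (0.45, FieldSpec("sensor_thickness", value_kind="float"), NullKind.NOT_NULL),
            (-1, FieldSpec("counts", value_kind="int", int_min=0), NullKind.ABSENT),
            (7, FieldSpec("counts", value_kind="int", int_min=0), NullKind.NOT_NULL),
            (300, FieldSpec("counts", value_kind="int", int_min=0, int_max=255), NullKind.ABSENT),
        ],
    )
    def test_null_classification_table(self, value, spec, expected):
        null, kind = is_null(value, spec)
        assert kind is expected
        assert null is (expected is not NullKind.NOT_NULL)

    def test_type_mismatch_raises(self):
        with pytest.raises(TypeError):
            is_null(3.5, FieldSpec("counts", value_kind="int", int_min=0))

    def test_nan_vector_is_null(self):
        null, kind = is_null(
            np.full(3, np.nan), FieldSpec("vec", value_kind="vector")
        )
        assert null and kind is NullKind.ABSENT

    def test_negative_count_array_semantics(self):
        """A -1 pixel in a photon-counting frame is the integer null."""
        spec = FieldSpec("/entry/data/data", value_kind="int", int_min=0)
        assert is_null(-1, spec) == (True, NullKind.ABSENT)
        assert not math.isnan(-1)  # distinct mechanism from the float null
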