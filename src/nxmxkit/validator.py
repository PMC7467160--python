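"""Compliance checking of a data set against the NXmx core rules.

Rules follow the standard's requirement levels: *required* rules fail with
``error`` severity (and flip the compliance verdict), *recommended* rules
with ``warning``, *optional* rules with ``info``.  Problems are always
reported as findings, never raised, so a broken file yields a complete
report.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Optional

import numpy as np

from .model import (
    TERMINATOR,
    CycleError,
    DanglingReferenceError,
    FieldSpec,
    NXmxDataSet,
    ProvenanceBlock,
    resolve_depends_on,
)

__all__ = [
    "Finding",
    "ValidationReport",
    "NullKind",
    "validate",
    "is_null",
    "check_times",
    "check_names",
    "LEVELS",
]

LEVELS = ("required", "recommended", "optional")

_SEVERITY_FOR_LEVEL = {"required": "error", "recommended": "warning", "optional": "info"}


@dataclass(frozen=True)
class Finding:
    path: str
    rule_id: str
    severity: str  # error | warning | info
    message: str


@dataclass
class ValidationReport:
    findings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        # deterministic ordering: by path, then rule id
        self.findings = sorted(self.findings, key=lambda f: (f.path, f.rule_id))

    @property
    def counts(self) -> dict:
        out = {"error": 0, "warning": 0, "info": 0}
        for f in self.findings:
            out[f.severity] += 1
        return out

    @property
    def verdict(self) -> bool:
        """Compliant iff no required-level rule failed."""
        return self.counts["error"] == 0

    def errors(self) -> list:
        return [f for f in self.findings if f.severity == "error"]

    def to_dict(self) -> dict:
        return {
            "schema_version": "1",
            "verdict": self.verdict,
            "counts": self.counts,
            "findings": [vars(f) for f in self.findings],
        }


# ---------------------------------------------------------------------------
# null-value semantics


class NullKind(Enum):
    NOT_NULL = "not-null"
    ABSENT = "absent-null"  # value genuinely unavailable
    PLACEHOLDER = "placeholder-null"  # "?": a value is intended to be filled in


def is_null(value, spec: FieldSpec):
    """Classify a field value against the standard's null conventions.

    Text fields: "." means the value is absent, "?" that one should be
    provided later.  Floats: IEEE NaN is the null.  Integers have no general
    null, so values outside the declared [int_min, int_max] range (e.g. a
    negative photon count) act as nulls.  Returns ``(bool, NullKind)``.
    """
    if spec.value_kind in ("text", "timestamp"):
        if not isinstance(value, str):
            raise TypeError(f"expected text for {spec.path_pattern}, got {type(value)}")
        if value == ".":
            return True, NullKind.ABSENT
        if value == "?":
            return True, NullKind.PLACEHOLDER
        return False, NullKind.NOT_NULL
    if spec.value_kind == "float":
        v = float(value)
        if math.isnan(v):
            return True, NullKind.ABSENT
        return False, NullKind.NOT_NULL
    if spec.value_kind == "int":
        if isinstance(value, (float, np.floating)) and not float(value).is_integer():
            raise TypeError(f"expected integer for {spec.path_pattern}")
        v = int(value)
        if spec.int_min is not None and v < spec.int_min:
            return True, NullKind.ABSENT
        if spec.int_max is not None and v > spec.int_max:
            return True, NullKind.ABSENT
        return False, NullKind.NOT_NULL
    if spec.value_kind == "vector":
        arr = np.asarray(value, dtype=float)
        if np.isnan(arr).all():
            return True, NullKind.ABSENT
        return False, NullKind.NOT_NULL
    raise TypeError(f"unsupported value_kind {spec.value_kind!r}")


# ---------------------------------------------------------------------------
# timestamp rules

_ISO_Z = re.compile(r"^\d{4}-\d{2}-\d{2}T\d{2}:\d{2}:\d{2}(\.\d+)?Z$")


def _parse_utc(text: str) -> Optional[datetime]:
    if not _ISO_Z.match(text):
        return None
    try:
        return datetime.fromisoformat(text.replace("Z", "+00:00"))
    except ValueError:
        return None


def check_times(prov: ProvenanceBlock) -> list:
    """Findings for the collection timestamps.

    start_time and end_time_estimated are required; end_time is optional
    but recommended once observed; all must be ISO 8601 UTC with the 'Z'
    suffix; end times must not precede the start.
    """
    findings = []
    parsed = {}
    for fname, required in (
        ("start_time", True),
        ("end_time_estimated", True),
        ("end_time", False),
    ):
        value = getattr(prov, fname)
        path = f"/entry/{fname}"
        if value is None:
            if required:
                findings.append(
                    Finding(path, f"{fname}_missing", "error", f"required field {fname} is absent")
                )
            else:
                findings.append(
                    Finding(
                        path,
                        "end_time_missing",
                        "warning",
                        "end_time is optional but should be included once observed",
                    )
                )
            continue
        ts = _parse_utc(value)
        if ts is None:
            findings.append(
                Finding(
                    path,
                    "time_not_utc",
                    "error",
                    f"{fname} {value!r} is not an ISO 8601 UTC time with the 'Z' suffix",
                )
            )
        else:
            parsed[fname] = ts
    start = parsed.get("start_time")
    if start is not None:
        for fname in ("end_time_estimated", "end_time"):
            end = parsed.get(fname)
            if end is not None and end < start:
                findings.append(
                    Finding(
                        f"/entry/{fname}",
                        "time_order",
                        "error",
                        f"{fname} precedes start_time",
                    )
                )
    return findings


def check_names(prov: ProvenanceBlock) -> list:
    """Findings for instrument/source naming and the beamline time zone."""
    findings = []
    if prov.instrument_name is None:
        findings.append(
            Finding(
                "/entry/instrument/name",
                "instrument_name_missing",
                "error",
                "required instrument name is absent",
            )
        )
    elif prov.instrument_short_name is None:
        findings.append(
            Finding(
                "/entry/instrument/name@short_name",
                "short_name_missing",
                "warning",
                "instrument name lacks its short_name acronym attribute",
            )
        )
    if prov.source_name is None:
        findings.append(
            Finding(
                "/entry/source/name",
                "source_name_missing",
                "error",
                "required source (facility) name is absent",
            )
        )
    elif prov.source_short_name is None:
        findings.append(
            Finding(
                "/entry/source/name@short_name",
                "short_name_missing",
                "warning",
                "source name lacks its short_name acronym attribute",
            )
        )
    if prov.time_zone is None:
        findings.append(
            Finding(
                "/entry/instrument/time_zone",
                "time_zone_missing",
                "warning",
                "beamline time_zone absent: local times cannot be recovered",
            )
        )
    return findings


# ---------------------------------------------------------------------------
# structural rules


def _check_sample(ds: NXmxDataSet) -> list:
    if ds.sample is None:
        return [
            Finding(
                "/entry/sample",
                "sample_missing",
                "error",
                "the NXsample group is always required (name '.' for sample-less runs)",
            )
        ]
    findings = []
    if ds.sample.name in (".", "?"):
        findings.append(
            Finding(
                "/entry/sample/name",
                "placeholder_null" if ds.sample.name == "?" else "null_sample",
                "info",
                "sample name is a null value (no sample, e.g. a dark run)",
            )
        )
    return findings


def _check_beam(ds: NXmxDataSet) -> list:
    path = "/entry/instrument/beam/incident_wavelength"
    if ds.beam is None or ds.beam.incident_wavelength is None or math.isnan(
        ds.beam.incident_wavelength
    ):
        return [
            Finding(path, "wavelength_missing", "error", "incident wavelength is absent")
        ]
    if ds.beam.incident_wavelength <= 0:
        return [
            Finding(
                path,
                "wavelength_not_positive",
                "error",
                f"incident wavelength {ds.beam.incident_wavelength} Å is not positive",
            )
        ]
    return []


def _check_axes(ds: NXmxDataSet) -> list:
    findings = []
    for path, axis in ds.axes.items():
        norm = float(np.linalg.norm(axis.vector))
        if abs(norm - 1.0) > 1e-6:
            findings.append(
                Finding(
                    path,
                    "vector_not_unit",
                    "error",
                    f"axis vector has norm {norm:.9g}, expected 1",
                )
            )
    return findings


def _check_chains(ds: NXmxDataSet) -> list:
    """Every depends_on chain must resolve to the '.' fixed point."""
    findings = []
    leaves = []
    if ds.sample is not None and ds.sample.depends_on != TERMINATOR:
        leaves.append("/entry/sample")
    for det in ds.detectors:
        for module in det.modules:
            for attr in ("fast_pixel_direction", "slow_pixel_direction"):
                if getattr(module, attr) is not None:
                    leaves.append(det.module_path(module, attr))
    seen = set()
    for leaf in leaves:
        try:
            resolve_depends_on(ds, leaf)
        except (DanglingReferenceError, CycleError) as exc:
            key = str(exc)
            if key in seen:  # one finding per offending reference
                continue
            seen.add(key)
            findings.append(Finding(leaf, "depends_on_unresolved", "error", str(exc)))
    return findings


def _check_modules(ds: NXmxDataSet) -> list:
    findings = []
    data_shape = ds.data.shape if ds.data is not None else None
    for det in ds.detectors:
        for module in det.modules:
            base = f"/entry/instrument/{det.name}/{module.name}"
            for attr in ("fast_pixel_direction", "slow_pixel_direction"):
                if getattr(module, attr) is None:
                    findings.append(
                        Finding(
                            f"{base}/{attr}",
                            "pixel_direction_missing",
                            "error",
                            f"module {module.name} lacks its {attr}",
                        )
                    )
            if data_shape is not None and len(data_shape) == 3:
                ns, nf = data_shape[1], data_shape[2]
                if (
                    module.data_origin[0] + module.data_size[0] > ns
                    or module.data_origin[1] + module.data_size[1] > nf
                ):
                    findings.append(
                        Finding(
                            f"{base}/data_origin",
                            "module_outside_data",
                            "error",
                            f"module {module.name} slice exceeds the image array "
                            f"({ns}×{nf} slow×fast)",
                        )
                    )
    return findings


def _check_data(ds: NXmxDataSet) -> list:
    if ds.data is None:
        return [
            Finding(
                "/entry/data/data",
                "data_missing",
                "error",
                "no image data reference in the data set",
            )
        ]
    return []


def validate(dataset: NXmxDataSet, level: str = "required") -> ValidationReport:
    """Check a data set against the NXmx core rules.

    ``level`` selects how deep to go: ``required`` applies only the rules
    whose violation makes the data set non-compliant; ``recommended`` adds
    warnings; ``optional`` adds informational findings.  The report is
    deterministic and the function has no side effects.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    depth = LEVELS.index(level)
    findings = []
    findings += check_times(dataset.provenance)
    findings += check_names(dataset.provenance)
    findings += _check_sample(dataset)
    findings += _check_beam(dataset)
    findings += _check_axes(dataset)
    findings += _check_chains(dataset)
    findings += _check_modules(dataset)
    findings += _check_data(dataset)
    keep = {"error"}
    if depth >= 1:
        keep.add("warning")
    if depth >= 2:
        keep.add("info")
    return ValidationReport([f for f in findings if f.severity in keep])
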