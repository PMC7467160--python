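"""In-memory model of an NXmx diffraction data set.

The model mirrors the structure of a NeXus/HDF5 NXmx file: provenance
(instrument, source, collection times), beam, sample, one or more detector
trees built from positioning axes, and a reference to the image data.
Every positioning axis lives in a flat ``axes`` dictionary keyed by its
absolute HDF5 path; elements point at their supporting axis through a
``depends_on`` path, forming chains that terminate at the beamline fixed
point, written ``"."``.
"""

from __future__ import annotations

import math
import posixpath
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

import numpy as np

#: depends_on value marking the fixed point of the beamline.
TERMINATOR = "."

UNIT_TOL = 1e-6


class NXmxError(Exception):
    """Base class for model-level errors."""


class DanglingReferenceError(NXmxError):
    """A depends_on path does not resolve to any axis in the data set."""


class CycleError(NXmxError):
    """A depends_on chain revisits an axis."""


class UnitConversionError(NXmxError):
    """A units string is not recognised for the requested dimension."""


# ---------------------------------------------------------------------------
# unit handling: settings are normalised to degrees (rotations) and
# millimetres (translations) on construction / read.

_LENGTH_TO_MM = {
    "mm": 1.0,
    "millimeter": 1.0,
    "millimetre": 1.0,
    "m": 1000.0,
    "meter": 1000.0,
    "metre": 1000.0,
    "cm": 10.0,
    "um": 1e-3,
    "micron": 1e-3,
    "micrometer": 1e-3,
    "nm": 1e-6,
    "angstrom": 1e-7,
    "A": 1e-7,
}

_ANGLE_TO_DEG = {
    "deg": 1.0,
    "degree": 1.0,
    "degrees": 1.0,
    "rad": 180.0 / math.pi,
    "radian": 180.0 / math.pi,
    "radians": 180.0 / math.pi,
}

_WAVELENGTH_TO_ANGSTROM = {
    "angstrom": 1.0,
    "A": 1.0,
    "nm": 10.0,
    "pm": 1e-2,
    "m": 1e10,
}


def length_to_mm(value, units: str):
    """Convert a length (scalar or array) to millimetres."""
    try:
        factor = _LENGTH_TO_MM[units]
    except KeyError:
        raise UnitConversionError(f"unknown length unit {units!r}") from None
    return np.asarray(value, dtype=float) * factor


def angle_to_degrees(value, units: str):
    """Convert an angle (scalar or array) to degrees."""
    try:
        factor = _ANGLE_TO_DEG[units]
    except KeyError:
        raise UnitConversionError(f"unknown angle unit {units!r}") from None
    return np.asarray(value, dtype=float) * factor


def wavelength_to_angstrom(value, units: str) -> float:
    try:
        factor = _WAVELENGTH_TO_ANGSTROM[units]
    except KeyError:
        raise UnitConversionError(f"unknown wavelength unit {units!r}") from None
    return float(value) * factor


def _vec3(v) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {arr.shape}")
    return arr


def as_unit_vector(v, tol: float = UNIT_TOL, what: str = "vector") -> np.ndarray:
    arr = _vec3(v)
    norm = float(np.linalg.norm(arr))
    if abs(norm - 1.0) > tol:
        raise ValueError(f"{what} must be unit length (|v| = {norm:.9g})")
    return arr


def resolve_path(base: str, ref: str) -> str:
    """Resolve a depends_on reference against the referring element's path.

    Absolute references and the ``"."`` terminator pass through unchanged;
    relative references are joined to the parent group of ``base``.
    """
    if ref == TERMINATOR or ref.startswith("/"):
        return ref
    return posixpath.normpath(posixpath.join(posixpath.dirname(base), ref))


# ---------------------------------------------------------------------------
# domain types


@dataclass
class AxisDefinition:
    """One named positioning axis of an NXtransformations chain.

    ``vector`` is the dimensionless unit direction of the axis, ``offset``
    the translation from the base of the parent axis to the base of this
    one.  ``setting`` is the axis position: an angle in degrees for
    rotations, a length in mm for translations; it may be a scalar or a
    per-frame array.
    """

    name: str  # absolute HDF5 path, e.g. /entry/sample/transformations/omega
    transformation_type: str  # "rotation" | "translation"
    vector: np.ndarray
    offset: np.ndarray = None  # type: ignore[assignment]
    offset_units: str = "mm"
    setting: Union[float, np.ndarray] = 0.0
    setting_units: Optional[str] = None
    depends_on: str = TERMINATOR

    def __post_init__(self) -> None:
        if self.transformation_type not in ("rotation", "translation"):
            raise ValueError(
                f"unknown transformation_type {self.transformation_type!r}"
            )
        self.vector = as_unit_vector(self.vector, what=f"axis {self.name} vector")
        self.offset = _vec3(self.offset if self.offset is not None else (0, 0, 0))
        if self.setting_units is None:
            self.setting_units = (
                "deg" if self.transformation_type == "rotation" else "mm"
            )
        if np.ndim(self.setting) == 0:
            self.setting = float(self.setting)
        else:
            self.setting = np.asarray(self.setting, dtype=float)

    @property
    def is_rotation(self) -> bool:
        return self.transformation_type == "rotation"

    def offset_mm(self) -> np.ndarray:
        return length_to_mm(self.offset, self.offset_units)

    def setting_at(self, frame: int = 0) -> float:
        """The axis setting for one frame (scalar settings ignore the index)."""
        if np.ndim(self.setting) == 0:
            return float(self.setting)
        return float(np.asarray(self.setting)[frame])


@dataclass
class RigidTransform:
    """Rotation plus translation mapping child-frame coordinates to parent."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = _vec3(self.translation)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        det = np.linalg.det(self.rotation)
        if err > 1e-9 or abs(det - 1.0) > 1e-9:
            raise ValueError(
                f"rotation not proper orthonormal (max |R Rᵀ − I| = {err:.3g}, "
                f"det = {det:.12g})"
            )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        """Transform one point or an (..., 3) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def rotate(self, vectors) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        """Composition: ``(A @ B)(p) == A(B(p))``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def as_matrix(self) -> np.ndarray:
        """4×4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class PixelDirection:
    """A module readout direction: unit vector, pixel pitch and parent axis."""

    vector: np.ndarray
    pitch_mm: float
    depends_on: str

    def __post_init__(self) -> None:
        self.vector = as_unit_vector(self.vector, what="pixel direction")
        self.pitch_mm = float(self.pitch_mm)
        if self.pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")


@dataclass
class DetectorModuleSpec:
    """A leaf sensor panel (NXdetector_module).

    ``data_origin``/``data_size`` are (slow, fast), 0-based, and slice the
    frame array; the fast and slow pixel directions orient the panel in
    space via their depends_on chains.
    """

    name: str
    data_origin: tuple  # (slow, fast)
    data_size: tuple  # (slow, fast)
    fast_pixel_direction: Optional[PixelDirection]
    slow_pixel_direction: Optional[PixelDirection]
    module_offset: Optional[AxisDefinition] = None

    def __post_init__(self) -> None:
        self.data_origin = (int(self.data_origin[0]), int(self.data_origin[1]))
        self.data_size = (int(self.data_size[0]), int(self.data_size[1]))
        if min(self.data_size) <= 0:
            raise ValueError("data_size must be positive")
        if min(self.data_origin) < 0:
            raise ValueError("data_origin must be non-negative")
        f, s = self.fast_pixel_direction, self.slow_pixel_direction
        if f is not None and s is not None:
            if abs(float(np.dot(f.vector, s.vector))) >= 1 - 1e-9:
                raise ValueError(
                    f"module {self.name}: fast and slow directions are parallel"
                )


@dataclass
class BeamDescriptor:
    """Incident beam: wavelength plus the Beam and Gravity named directions.

    Beam points source → sample; in the McStas frame it is canonically
    (0, 0, 1) and Gravity (pointing down) is (0, −1, 0).
    """

    incident_wavelength: float  # Å; NaN = not known
    beam_direction: np.ndarray = None  # type: ignore[assignment]
    gravity_direction: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.incident_wavelength = float(self.incident_wavelength)
        bd = self.beam_direction if self.beam_direction is not None else (0, 0, 1)
        gd = self.gravity_direction if self.gravity_direction is not None else (0, -1, 0)
        self.beam_direction = as_unit_vector(bd, what="beam direction")
        self.gravity_direction = as_unit_vector(gd, what="gravity direction")


@dataclass
class ProvenanceBlock:
    """Where and when the data were collected.

    Timestamps are ISO 8601 UTC strings with the 'Z' suffix; time_zone is
    the beamline's IANA zone so local times can be recovered.  Fields are
    Optional so that partially parsed or deliberately broken data sets can
    be represented and then judged by the validator.
    """

    instrument_name: Optional[str] = None
    instrument_short_name: Optional[str] = None
    source_name: Optional[str] = None
    source_short_name: Optional[str] = None
    start_time: Optional[str] = None
    end_time_estimated: Optional[str] = None
    end_time: Optional[str] = None
    time_zone: Optional[str] = None


@dataclass
class SampleBlock:
    """The NXsample group; always present, with name "." for sample-less runs."""

    name: str = TERMINATOR
    depends_on: str = TERMINATOR


@dataclass
class FieldSpec:
    """Requirement level and null-value conventions for one NXmx field."""

    path_pattern: str
    requirement: str = "required"  # required | recommended | optional
    value_kind: str = "text"  # text | float | int | timestamp | vector
    null_forms: tuple = (".", "?")
    int_min: Optional[int] = None
    int_max: Optional[int] = None

    def __post_init__(self) -> None:
        if self.requirement not in ("required", "recommended", "optional"):
            raise ValueError(f"unknown requirement {self.requirement!r}")
        if self.value_kind not in ("text", "float", "int", "timestamp", "vector"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")


@dataclass
class Scan:
    """A single-axis rotation scan description (stills have increment 0)."""

    axis_path: str
    start_deg: float = 0.0
    increment_deg: float = 0.0
    n_frames: int = 1
    per_frame: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.increment_deg < 0:
            raise ValueError("increment must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        if self.per_frame is not None:
            self.per_frame = np.asarray(self.per_frame, dtype=float)


@dataclass
class DataReference:
    """Reference to the image array (frames × slow × fast).

    ``array`` holds the payload for in-memory (synthetic) data sets; after
    reading from disk the payload stays on disk and is fetched lazily from
    ``source_file``/``source_dataset``.
    """

    path: str = "/entry/data/data"
    shape: Optional[tuple] = None
    dtype: str = "int32"
    link: str = "internal"  # internal | external | virtual
    array: Optional[np.ndarray] = None
    source_file: Optional[str] = None
    source_dataset: Optional[str] = None

    def materialize(self) -> np.ndarray:
        if self.array is not None:
            return self.array
        if self.source_file is None:
            raise NXmxError("image data not loaded (metadata-only read)")
        import h5py

        with h5py.File(self.source_file, "r") as fh:
            return fh[self.source_dataset or "/data"][()]


@dataclass
class DetectorTree:
    """One detector element: its supporting axis and its module leaves."""

    name: str  # e.g. ELE_D0
    depends_on: str
    modules: list = field(default_factory=list)

    def module_path(self, module: DetectorModuleSpec, leaf: str) -> str:
        return f"/entry/instrument/{self.name}/{module.name}/{leaf}"


@dataclass
class NXmxDataSet:
    """The whole data set: provenance, beam, sample, detectors, image data."""

    provenance: ProvenanceBlock = field(default_factory=ProvenanceBlock)
    beam: Optional[BeamDescriptor] = None
    sample: Optional[SampleBlock] = None
    detectors: list = field(default_factory=list)
    axes: dict = field(default_factory=dict)  # path -> AxisDefinition
    data: Optional[DataReference] = None
    scan: Optional[Scan] = None
    frame: str = "mcstas"  # laboratory-frame convention of all vectors
    notes: list = field(default_factory=list)

    # -- element lookup ----------------------------------------------------

    def add_axis(self, axis: AxisDefinition) -> AxisDefinition:
        self.axes[axis.name] = axis
        return axis

    def iter_modules(self) -> Iterator[tuple]:
        for det in self.detectors:
            for module in det.modules:
                yield det, module

    def depends_on_of(self, path: str) -> str:
        """The depends_on value of the element at ``path``.

        Elements with a depends_on are: axes, module pixel directions and
        module offsets, the sample group, and detector elements.
        """
        if path in self.axes:
            return self.axes[path].depends_on
        if self.sample is not None and path == "/entry/sample":
            return self.sample.depends_on
        for det in self.detectors:
            if path == f"/entry/instrument/{det.name}":
                return det.depends_on
            for module in det.modules:
                base = f"/entry/instrument/{det.name}/{module.name}"
                if path == f"{base}/fast_pixel_direction":
                    if module.fast_pixel_direction is None:
                        break
                    return module.fast_pixel_direction.depends_on
                if path == f"{base}/slow_pixel_direction":
                    if module.slow_pixel_direction is None:
                        break
                    return module.slow_pixel_direction.depends_on
                if path == f"{base}/module_offset":
                    if module.module_offset is None:
                        break
                    return module.module_offset.depends_on
        raise DanglingReferenceError(f"no element with a depends_on at {path!r}")


def resolve_depends_on(dataset: NXmxDataSet, leaf_path: str) -> list:
    """Follow the depends_on chain from ``leaf_path`` up to the fixed point.

    Returns the supporting axes ordered leaf → root; an element whose
    depends_on is "." yields an empty chain.  Raises
    :class:`DanglingReferenceError` for unresolvable references and
    :class:`CycleError` if an axis is reachable from itself.
    """
    chain: list = []
    seen = set()
    current = leaf_path
    ref = dataset.depends_on_of(current)
    while True:
        ref = resolve_path(current, ref)
        if ref == TERMINATOR:
            return chain
        if ref in seen:
            raise CycleError(f"depends_on cycle through {ref!r}")
        axis = dataset.axes.get(ref)
        if axis is None:
            raise DanglingReferenceError(
                f"depends_on of {current!r} points at missing axis {ref!r}"
            )
        seen.add(ref)
        chain.append(axis)
        current = ref
        ref = axis.depends_on


def goniometer_chain(dataset: NXmxDataSet) -> list:
    """The sample positioning axes, leaf → root (empty for fixed samples)."""
    if dataset.sample is None or dataset.sample.depends_on == TERMINATOR:
        return []
    return resolve_depends_on(dataset, "/entry/sample")


def principal_goniometer_axis(dataset: NXmxDataSet) -> Optional[AxisDefinition]:
    """The outermost (closest to the fixed point) sample rotation axis."""
    rotations = [ax for ax in goniometer_chain(dataset) if ax.is_rotation]
    return rotations[-1] if rotations else None


# ---------------------------------------------------------------------------
# deep equality, used by round-trip tests and the CLI diff output


def _eq(a, b) -> bool:
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        return np.array_equal(np.asarray(a), np.asarray(b))
    if isinstance(a, float) and isinstance(b, float):
        return (math.isnan(a) and math.isnan(b)) or a == b
    return a == b


def axes_equal(a: AxisDefinition, b: AxisDefinition) -> bool:
    return all(
        _eq(getattr(a, f), getattr(b, f))
        for f in (
            "name",
            "transformation_type",
            "vector",
            "offset",
            "offset_units",
            "setting",
            "setting_units",
            "depends_on",
        )
    )


def datasets_equal(a: NXmxDataSet, b: NXmxDataSet, compare_data: bool = True) -> bool:
    """Deep metadata equality; image payloads compared by value if requested."""
    if a.provenance != b.provenance or a.sample != b.sample or a.frame != b.frame:
        return False
    if (a.beam is None) != (b.beam is None):
        return False
    if a.beam is not None:
        if not (
            _eq(a.beam.incident_wavelength, b.beam.incident_wavelength)
            and _eq(a.beam.beam_direction, b.beam.beam_direction)
            and _eq(a.beam.gravity_direction, b.beam.gravity_direction)
        ):
            return False
    if set(a.axes) != set(b.axes):
        return False
    if not all(axes_equal(a.axes[k], b.axes[k]) for k in a.axes):
        return False
    if len(a.detectors) != len(b.detectors):
        return False
    for da, db in zip(a.detectors, b.detectors):
        if da.name != db.name or da.depends_on != db.depends_on:
            return False
        if len(da.modules) != len(db.modules):
            return False
        for ma, mb in zip(da.modules, db.modules):
            if (
                ma.name != mb.name
                or ma.data_origin != mb.data_origin
                or ma.data_size != mb.data_size
            ):
                return False
            for attr in ("fast_pixel_direction", "slow_pixel_direction"):
                pa, pb = getattr(ma, attr), getattr(mb, attr)
                if (pa is None) != (pb is None):
                    return False
                if pa is not None and not (
                    _eq(pa.vector, pb.vector)
                    and pa.pitch_mm == pb.pitch_mm
                    and pa.depends_on == pb.depends_on
                ):
                    return False
    if compare_data:
        if (a.data is None) != (b.data is None):
            return False
        if a.data is not None:
            if not np.array_equal(a.data.materialize(), b.data.materialize()):
                return False
    return True
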