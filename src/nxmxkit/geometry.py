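"""Laboratory-frame geometry: axis chains, pixel positions, reciprocal space.

Positions are in millimetres in the McStas laboratory frame (Z along the
incident beam, Y up, origin at the sample); scattering vectors are in Å⁻¹
with the crystallographic convention |q| = 2 sin θ / λ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .model import (
    AxisDefinition,
    BeamDescriptor,
    DetectorModuleSpec,
    DetectorTree,
    NXmxDataSet,
    RigidTransform,
    Scan,
    resolve_depends_on,
)

__all__ = [
    "axis_transform",
    "compose_chain",
    "module_transform",
    "pixel_lab_position",
    "beam_center",
    "detector_distance",
    "scattering_vector",
    "frame_settings",
    "BeamCenterResult",
]


def axis_transform(axis: AxisDefinition, setting: Optional[float] = None) -> RigidTransform:
    """The rigid transform realised by one axis at the given setting.

    A rotation axis rotates right-handedly about its unit vector by the
    setting (degrees); a translation axis translates by setting · vector
    (mm).  The axis offset (the displacement from the base of the parent
    axis) is applied after the axis motion in the parent frame:
    ``T = Translate(offset) ∘ Motion(setting)``.
    """
    if setting is None:
        setting = axis.setting_at(0)
    offset = axis.offset_mm()
    if axis.is_rotation:
        rot = Rotation.from_rotvec(np.radians(setting) * axis.vector).as_matrix()
        return RigidTransform(rot, offset)
    return RigidTransform(np.eye(3), offset + setting * axis.vector)


def compose_chain(chain, settings=None) -> RigidTransform:
    """Compose a leaf → root axis chain into one child-to-lab transform.

    The leaf axis acts first: ``P_lab = T_root · … · T_leaf · P_local``.
    ``settings`` (if given) supplies one scalar per axis in chain order;
    otherwise each axis's stored setting (frame 0) is used.
    """
    if settings is None:
        settings = [None] * len(chain)
    if len(settings) != len(chain):
        raise ValueError(
            f"got {len(settings)} settings for a chain of {len(chain)} axes"
        )
    total = RigidTransform.identity()
    for axis, s in zip(chain, settings):
        total = axis_transform(axis, s) @ total
    return total


def module_transform(
    dataset: NXmxDataSet,
    detector: DetectorTree,
    module: DetectorModuleSpec,
    frame: int = 0,
) -> RigidTransform:
    """Module-local → lab transform for one frame, via the fast-direction chain."""
    leaf = detector.module_path(module, "fast_pixel_direction")
    chain = resolve_depends_on(dataset, leaf)
    settings = [ax.setting_at(frame) for ax in chain]
    return compose_chain(chain, settings)


def pixel_lab_position(
    module: DetectorModuleSpec,
    chain_transform: RigidTransform,
    i,
    j,
) -> np.ndarray:
    """Lab position (mm) of the centre of pixel (i=slow, j=fast).

    The module origin is the centre of pixel (0, 0).  ``i`` and ``j`` may be
    arrays (broadcast together) for vectorised evaluation.
    """
    i = np.asarray(i)
    j = np.asarray(j)
    ns, nf = module.data_size
    if np.any(i < 0) or np.any(i >= ns) or np.any(j < 0) or np.any(j >= nf):
        raise IndexError(
            f"pixel index out of range for module {module.name} "
            f"(size {ns}×{nf} slow×fast)"
        )
    fast = module.fast_pixel_direction
    slow = module.slow_pixel_direction
    local = (
        i[..., None] * slow.pitch_mm * slow.vector
        + j[..., None] * fast.pitch_mm * fast.vector
    )
    return chain_transform.apply(local)


@dataclass
class BeamCenterResult:
    """Beam/module-plane intersection in one module's pixel coordinates."""

    module: str
    intersects: bool
    slow: Optional[float] = None  # fractional pixels
    fast: Optional[float] = None
    inside: bool = False
    point_mm: Optional[np.ndarray] = None
    distance_mm: Optional[float] = None


def _module_plane(dataset, detector, module, frame):
    t = module_transform(dataset, detector, module, frame)
    origin = t.apply(np.zeros(3))
    fast = t.rotate(module.fast_pixel_direction.vector) * module.fast_pixel_direction.pitch_mm
    slow = t.rotate(module.slow_pixel_direction.vector) * module.slow_pixel_direction.pitch_mm
    return origin, fast, slow


def beam_center(
    dataset: NXmxDataSet,
    detector: Optional[DetectorTree] = None,
    beam: Optional[BeamDescriptor] = None,
    frame: int = 0,
) -> list:
    """Intersect the beam ray with each module plane of a detector.

    Returns one :class:`BeamCenterResult` per module with the fractional
    (slow, fast) pixel coordinates of the intersection; modules whose plane
    is parallel to the beam get ``intersects=False``, and ``inside`` flags
    whether the intersection falls within the module bounds.
    """
    if detector is None:
        detector = dataset.detectors[0]
    if beam is None:
        beam = dataset.beam
    b = beam.beam_direction
    results = []
    for module in detector.modules:
        origin, fast, slow = _module_plane(dataset, detector, module, frame)
        normal = np.cross(fast, slow)
        denom = float(np.dot(b, normal))
        if abs(denom) < 1e-12 * np.linalg.norm(normal):
            results.append(BeamCenterResult(module.name, intersects=False))
            continue
        t = float(np.dot(origin, normal)) / denom
        point = t * b
        # express point - origin in the (fast, slow) in-plane basis
        coeffs, *_ = np.linalg.lstsq(
            np.stack([fast, slow], axis=1), point - origin, rcond=None
        )
        fast_px, slow_px = float(coeffs[0]), float(coeffs[1])
        ns, nf = module.data_size
        inside = -0.5 <= slow_px <= ns - 0.5 and -0.5 <= fast_px <= nf - 0.5
        results.append(
            BeamCenterResult(
                module.name,
                intersects=True,
                slow=slow_px,
                fast=fast_px,
                inside=inside,
                point_mm=point,
                distance_mm=abs(t),
            )
        )
    return results


def detector_distance(
    dataset: NXmxDataSet,
    detector: Optional[DetectorTree] = None,
    beam: Optional[BeamDescriptor] = None,
    frame: int = 0,
) -> float:
    """Distance (mm) from the lab origin to the beam-centre point.

    Measured along the beam to the first module plane it intersects.
    """
    for res in beam_center(dataset, detector, beam, frame):
        if res.intersects:
            return res.distance_mm
    raise ValueError("beam does not intersect any module plane")


def scattering_vector(pixel_lab, wavelength: float, beam_direction) -> np.ndarray:
    """Momentum transfer q = (ŝ − b̂)/λ in Å⁻¹ for a pixel at ``pixel_lab``.

    ŝ is the unit vector from the sample toward the pixel, b̂ the incident
    beam direction; |q| = 2 sin θ / λ where 2θ is the scattering angle.
    """
    if not wavelength > 0:
        raise ValueError("wavelength must be positive")
    p = np.asarray(pixel_lab, dtype=float)
    norm = np.linalg.norm(p, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("pixel position coincides with the sample origin")
    s_hat = p / norm
    b_hat = np.asarray(beam_direction, dtype=float)
    return (s_hat - b_hat) / wavelength


def frame_settings(scan: Scan, frame_index: int) -> dict:
    """Per-axis settings for one frame of a scan.

    An explicit per-frame array in the file wins over the start + k·increment
    reconstruction; the returned setting is the angle at the *start* of the
    frame.  Stills (increment 0, no array) return the constant start value.
    """
    if frame_index < 0:
        raise ValueError("frame_index must be non-negative")
    if scan.per_frame is not None:
        value = float(scan.per_frame[frame_index])
    else:
        value = scan.start_deg + frame_index * scan.increment_deg
    return {scan.axis_path: value}
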