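"""The McStas and imgCIF/CBF laboratory frames, and conversion between them.

McStas (the NeXus standard frame): Z along the incident beam, Y up, X
completing a right-handed system (pointing left as seen from the source).
CBF (the imgCIF standard frame): X along the principal goniometer axis,
Z toward the source — if the beam is not orthogonal to X, Z is the
component of the Source vector orthogonal to X — and Y = Z × X.

For the common beamline layout (horizontal goniometer axis opposite McStas
X, beam along McStas Z) the two frames differ by exactly a 180° rotation
about the vertical axis; the code always computes the actual rotation and
never assumes that value.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .model import NXmxDataSet, RigidTransform, principal_goniometer_axis

__all__ = [
    "FrameConvention",
    "MCSTAS",
    "cbf_basis",
    "mcstas_basis",
    "frame_rotation",
    "rotation_angle_deg",
    "rotation_axis",
    "convert_dataset",
]


@dataclass
class FrameConvention:
    """An orthonormal right-handed laboratory basis.

    ``basis`` rows are the frame's X, Y, Z axes expressed in a common
    reference frame, so coordinates transform as ``c = basis @ v_ref``.
    """

    name: str
    basis: np.ndarray
    origin_rule: str = (
        "origin on the beam at the closest approach of the rotation axis"
    )

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=float).reshape(3, 3)
        err = np.abs(self.basis @ self.basis.T - np.eye(3)).max()
        det = float(np.linalg.det(self.basis))
        if err > 1e-12 or abs(det - 1.0) > 1e-12:
            raise ValueError(
                f"basis must be right-handed orthonormal "
                f"(max deviation {err:.3g}, det {det:.15g})"
            )


#: The reference frame itself: all model vectors are stored in McStas.
MCSTAS = FrameConvention("mcstas", np.eye(3))


def _normalize(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def cbf_basis(goniometer_axis_mcstas, source_mcstas) -> FrameConvention:
    """Construct the CBF frame from the goniometer axis and Source vector.

    Both inputs are unit vectors in McStas coordinates.  X is the principal
    goniometer axis; Z is the component of Source orthogonal to X
    (Gram–Schmidt, so Z·X = 0 exactly even for a tilted beam); Y = Z × X.
    """
    x = _normalize(np.asarray(goniometer_axis_mcstas, dtype=float))
    s = _normalize(np.asarray(source_mcstas, dtype=float))
    z_raw = s - np.dot(s, x) * x
    if np.linalg.norm(z_raw) < 1e-9:
        raise ValueError(
            "goniometer axis is parallel to the beam: CBF frame is degenerate"
        )
    z = _normalize(z_raw)
    y = np.cross(z, x)
    return FrameConvention("cbf", np.stack([x, y, z]))


def mcstas_basis(beam_direction, gravity_direction) -> FrameConvention:
    """Reconstruct the McStas basis from the named Beam and Gravity axes.

    Z is the beam direction; Y is the component of −Gravity orthogonal to Z;
    X = Y × Z.  Inputs may be expressed in any frame, allowing conversion
    back to McStas from a converted data set.
    """
    z = _normalize(np.asarray(beam_direction, dtype=float))
    up = -np.asarray(gravity_direction, dtype=float)
    y_raw = up - np.dot(up, z) * z
    if np.linalg.norm(y_raw) < 1e-9:
        raise ValueError("gravity is parallel to the beam: frame is degenerate")
    y = _normalize(y_raw)
    x = np.cross(y, z)
    return FrameConvention("mcstas", np.stack([x, y, z]))


def frame_rotation(frm: FrameConvention, to: FrameConvention) -> RigidTransform:
    """Pure rotation taking coordinates in ``frm`` to coordinates in ``to``."""
    return RigidTransform(to.basis @ frm.basis.T, np.zeros(3))


def rotation_angle_deg(rotation: np.ndarray) -> float:
    """Rotation angle in degrees from the matrix trace."""
    cos = (float(np.trace(rotation)) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def rotation_axis(rotation: np.ndarray) -> np.ndarray:
    """Unit rotation axis (eigenvector of eigenvalue 1; sign right-handed)."""
    r = np.asarray(rotation, dtype=float)
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    axis = v[:, np.argmax(w)]
    # fix sign from the antisymmetric part when the angle is not 0 or 180°
    anti = np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]])
    if np.linalg.norm(anti) > 1e-9:
        axis = _normalize(anti)
    return _normalize(axis)


def _target_convention(dataset: NXmxDataSet, to: str, principal_axis=None) -> FrameConvention:
    """Build the target basis from axes expressed in the data set's current frame."""
    beam = dataset.beam
    if to == "mcstas":
        return mcstas_basis(beam.beam_direction, beam.gravity_direction)
    if to == "cbf":
        if principal_axis is None:
            gonio = principal_goniometer_axis(dataset)
            if gonio is not None:
                principal_axis = gonio.vector
        if principal_axis is None:
            # stills: no goniometer defines X; fall back to the horizontal
            # axis opposite McStas X, reconstructed in the current frame
            mc = mcstas_basis(beam.beam_direction, beam.gravity_direction)
            principal_axis = -mc.basis[0]
            dataset.notes.append(
                "cbf X axis defaulted to -X_mcstas (no goniometer axis present)"
            )
        return cbf_basis(principal_axis, -beam.beam_direction)
    raise ValueError(f"unknown frame convention {to!r}")


def convert_dataset(dataset: NXmxDataSet, to: str, principal_axis=None) -> NXmxDataSet:
    """Re-express every geometric vector of a data set in another frame.

    Rotates all axis vectors and offsets, the Beam and Gravity directions
    and the module pixel directions; scalar settings and image data are
    untouched.  Returns a new data set; the applied rotation is recorded in
    its notes.
    """
    out = copy.deepcopy(dataset)
    if to == out.frame:
        return out
    conv = _target_convention(out, to, principal_axis)
    rot = RigidTransform(conv.basis, np.zeros(3))
    for axis in out.axes.values():
        axis.vector = rot.rotate(axis.vector)
        axis.offset = rot.rotate(axis.offset)
    if out.beam is not None:
        out.beam.beam_direction = rot.rotate(out.beam.beam_direction)
        out.beam.gravity_direction = rot.rotate(out.beam.gravity_direction)
    for _, module in out.iter_modules():
        for pd in (module.fast_pixel_direction, module.slow_pixel_direction):
            if pd is not None:
                pd.vector = rot.rotate(pd.vector)
        if module.module_offset is not None:
            module.module_offset.vector = rot.rotate(module.module_offset.vector)
            module.module_offset.offset = rot.rotate(module.module_offset.offset)
    out.frame = to
    angle = rotation_angle_deg(rot.rotation)
    if angle > 1e-12:
        ax = rotation_axis(rot.rotation)
        out.notes.append(
            f"converted {dataset.frame} -> {to}: rotation {angle:.6f} deg about "
            f"({ax[0]:.6f}, {ax[1]:.6f}, {ax[2]:.6f})"
        )
    else:
        out.notes.append(f"converted {dataset.frame} -> {to}: identity rotation")
    return out
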