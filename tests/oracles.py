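"""Independent brute-force oracles used to cross-check the geometry code.

Everything here is built from first principles (explicit Rodrigues formula,
4×4 homogeneous matrices, quaternion extraction) and deliberately shares no
code path with the package under test.
"""

import numpy as np


def rodrigues(axis, angle_deg):
    """Rotation matrix about a unit axis, right-handed, via the explicit
    Rodrigues formula R = I cosθ + sinθ [k]× + (1 − cosθ) k kᵀ."""
    k = np.asarray(axis, dtype=float)
    theta = np.radians(angle_deg)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return (
        np.cos(theta) * np.eye(3)
        + np.sin(theta) * kx
        + (1 - np.cos(theta)) * np.outer(k, k)
    )


def homogeneous(rotation, translation):
    m = np.eye(4)
    m[:3, :3] = rotation
    m[:3, 3] = translation
    return m


def axis_matrix(axis_def, setting):
    """4×4 matrix of one axis: Translate(offset) ∘ Motion(setting)."""
    offset = np.asarray(axis_def.offset, dtype=float)
    if axis_def.transformation_type == "rotation":
        return homogeneous(rodrigues(axis_def.vector, setting), offset)
    return homogeneous(np.eye(3), offset + setting * np.asarray(axis_def.vector))


def chain_matrix(chain, settings):
    """Brute-force product T_root · … · T_leaf as a 4×4 matrix."""
    total = np.eye(4)
    for axis_def, s in zip(chain, settings):
        total = axis_matrix(axis_def, s) @ total
    return total


def quaternion_angle_deg(rotation):
    """Rotation angle from the scalar quaternion component w = cos(θ/2),
    extracted via the standard trace/off-diagonal construction."""
    r = np.asarray(rotation, dtype=float)
    t = np.trace(r)
    if t > 0:
        w = 0.5 * np.sqrt(1.0 + t)
    else:
        # |w| from the largest diagonal element; the angle needs only |w|
        i = int(np.argmax(np.diag(r)))
        j, k = (i + 1) % 3, (i + 2) % 3
        x = 0.5 * np.sqrt(max(1.0 + r[i, i] - r[j, j] - r[k, k], 0.0))
        w = (r[k, j] - r[j, k]) / (4.0 * x) if x > 0 else 0.0
    w = min(abs(w), 1.0)
    return float(np.degrees(2.0 * np.arccos(w)))


def random_unit_vector(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
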