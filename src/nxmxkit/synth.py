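"""Synthetic, fully compliant NXmx data sets — and controlled mutants.

Two templates are provided: a single-axis rotation series on one detector
module (the synchrotron use case) and a hierarchical stills detector with
the JUNGFRAU-16M topology of 4 quadrants × 8 modules × 8 ASICs (the XFEL
use case), with a depends_on chain rail → detector → quadrant → module →
ASIC whose offsets lie in the detector X–Y plane and whose axis vectors
point along Z.  Image content is cosmetic — a seeded Poisson background
with a few Gaussian spots — since validation and geometry only consume
metadata; panel sizes are kept desk-scale because the standard exercises
topology, not pixel count.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .model import (
    TERMINATOR,
    AxisDefinition,
    BeamDescriptor,
    DataReference,
    DetectorModuleSpec,
    DetectorTree,
    NXmxDataSet,
    PixelDirection,
    ProvenanceBlock,
    SampleBlock,
    Scan,
)

__all__ = [
    "RotationFixtureParams",
    "HierarchicalFixtureParams",
    "make_rotation_fixture",
    "make_hierarchical_fixture",
    "mutate",
    "MUTATION_RULES",
]

_DET_TRANS = "/entry/instrument/ELE_D0/transformations"


@dataclass
class RotationFixtureParams:
    """Parameters of the single-module rotation fixture."""

    n_frames: int = 5
    start_angle: float = 0.0  # deg
    increment: float = 0.1  # deg
    wavelength: float = 0.9795  # Å
    distance: float = 200.0  # mm
    beam_center: tuple = (1225.54, 1306.17)  # (slow, fast) px
    pixel_pitch: float = 0.075  # mm
    module_size: tuple = (64, 60)  # (slow, fast) px
    frame_rate: float = 100.0  # Hz, used for end_time_estimated
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        if self.increment < 0:
            raise ValueError("increment must be non-negative")
        for name in ("wavelength", "distance", "pixel_pitch", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class HierarchicalFixtureParams:
    """Parameters of the JF16M-like hierarchical stills fixture.

    Defaults reproduce the JF16M topology — 4 quadrants of 8 modules, each
    module carrying 8 ASICs in a 4 × 2 arrangement — at toy panel sizes.
    The inter-panel gap is an arbitrary positive synthetic value; real
    JUNGFRAU gap dimensions are not modelled.
    """

    n_quadrants: int = 4
    modules_per_quadrant: int = 8
    asics_per_module: tuple = (4, 2)  # (rows along slow, cols along fast)
    asic_size: tuple = (8, 16)  # (slow, fast) px
    gap: float = 0.3  # mm between adjacent ASICs
    pixel_pitch: float = 0.075  # mm
    distance: float = 120.0  # mm
    wavelength: float = 1.33  # Å
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_quadrants,
            self.modules_per_quadrant,
            min(self.asics_per_module),
            min(self.asic_size),
            self.n_frames,
        ) < 1:
            raise ValueError("all counts must be at least 1")
        if min(self.gap, 0.0) < 0 or self.pixel_pitch <= 0 or self.distance <= 0:
            raise ValueError("gap must be non-negative; pitch and distance positive")


def _images(rng, n_frames: int, shape, n_spots: int = 6) -> np.ndarray:
    """Poisson background plus a few Gaussian Bragg-like spots, int32."""
    ns, nf = shape
    ii, jj = np.mgrid[0:ns, 0:nf]
    frames = []
    for _ in range(n_frames):
        img = rng.poisson(1.0, size=shape).astype(np.int32)
        for _ in range(n_spots):
            ci, cj = rng.uniform(0, ns), rng.uniform(0, nf)
            amp = rng.uniform(50, 500)
            sig = rng.uniform(0.8, 2.0)
            img += rng.poisson(
                amp * np.exp(-((ii - ci) ** 2 + (jj - cj) ** 2) / (2 * sig**2))
            ).astype(np.int32)
        frames.append(img)
    return np.stack(frames)


def _provenance(start: str, end_est: str, end: str, instrument: str, short: str) -> ProvenanceBlock:
    return ProvenanceBlock(
        instrument_name=instrument,
        instrument_short_name=short,
        source_name="Synthetic Light Source",
        source_short_name="SYNLS",
        start_time=start,
        end_time_estimated=end_est,
        end_time=end,
        time_zone="Etc/UTC",
    )


def _end_times(start_iso: str, n_frames: int, frame_rate: float):
    from datetime import datetime, timedelta

    start = datetime.fromisoformat(start_iso.replace("Z", "+00:00"))
    # estimate: start plus frames divided by the frame rate
    end = start + timedelta(seconds=n_frames / frame_rate)
    fmt = "%Y-%m-%dT%H:%M:%SZ"
    return start.strftime(fmt), end.strftime(fmt)


def make_rotation_fixture(params: RotationFixtureParams = None) -> NXmxDataSet:
    """A compliant single-axis rotation series on one detector module.

    The goniometer is a single omega rotation about the horizontal −X axis
    with a per-frame angle array start + k·increment; the detector sits
    ``distance`` mm downstream of the sample with its module offset chosen
    so that the straight-through beam crosses the module plane at the
    requested fractional (slow, fast) beam centre.
    """
    if params is None:
        params = RotationFixtureParams()
    rng = np.random.default_rng(params.seed)
    ds = NXmxDataSet()

    start_iso = "2026-03-02T10:00:00Z"
    start, end_est = _end_times(start_iso, params.n_frames, params.frame_rate)
    ds.provenance = _provenance(
        start, end_est, end_est, "Synthetic Beamline S01", "S01"
    )
    ds.beam = BeamDescriptor(params.wavelength)
    ds.sample = SampleBlock(
        name="synthetic rotation sample",
        depends_on="/entry/sample/transformations/omega",
    )

    angles = params.start_angle + params.increment * np.arange(params.n_frames)
    omega = ds.add_axis(
        AxisDefinition(
            name="/entry/sample/transformations/omega",
            transformation_type="rotation",
            vector=(-1.0, 0.0, 0.0),
            setting=angles,
            depends_on=TERMINATOR,
        )
    )
    ds.scan = Scan(
        axis_path=omega.name,
        start_deg=params.start_angle,
        increment_deg=params.increment,
        n_frames=params.n_frames,
        per_frame=angles,
    )

    rail = ds.add_axis(
        AxisDefinition(
            name=f"{_DET_TRANS}/AXIS_RAIL",
            transformation_type="translation",
            vector=(0.0, 0.0, 1.0),
            setting=params.distance,
            depends_on=TERMINATOR,
        )
    )
    # module placed so that the beam axis crosses the panel plane at the
    # requested fractional pixel coordinates (fast ‖ −X, slow ‖ −Y)
    bc_slow, bc_fast = params.beam_center
    pitch = params.pixel_pitch
    module_axis = ds.add_axis(
        AxisDefinition(
            name=f"{_DET_TRANS}/AXIS_D0M0",
            transformation_type="translation",
            vector=(0.0, 0.0, 1.0),
            setting=0.0,
            offset=(bc_fast * pitch, bc_slow * pitch, 0.0),
            depends_on=rail.name,
        )
    )

    module = DetectorModuleSpec(
        name="ARRAY_D0M0",
        data_origin=(0, 0),
        data_size=params.module_size,
        fast_pixel_direction=PixelDirection((-1.0, 0.0, 0.0), pitch, module_axis.name),
        slow_pixel_direction=PixelDirection((0.0, -1.0, 0.0), pitch, module_axis.name),
    )
    ds.detectors.append(
        DetectorTree(name="ELE_D0", depends_on=rail.name, modules=[module])
    )

    shape = (params.n_frames,) + tuple(params.module_size)
    ds.data = DataReference(
        shape=shape,
        dtype="int32",
        link="external",
        array=_images(rng, params.n_frames, params.module_size),
    )
    return ds


def _hier_layout(p: HierarchicalFixtureParams):
    """Grid layout (mm) for quadrants in 2×2, modules stacked along slow."""
    rows, cols = p.asics_per_module
    ws = p.asic_size[0] * p.pixel_pitch  # ASIC extent along slow
    wf = p.asic_size[1] * p.pixel_pitch  # along fast
    mod_f = cols * wf + (cols - 1) * p.gap
    mod_s = rows * ws + (rows - 1) * p.gap
    gap_m = 2 * p.gap
    quad_f = mod_f
    quad_s = p.modules_per_quadrant * mod_s + (p.modules_per_quadrant - 1) * gap_m
    gap_q = 4 * p.gap
    q_cols = 2 if p.n_quadrants > 1 else 1
    q_rows = -(-p.n_quadrants // q_cols)
    total_f = q_cols * quad_f + (q_cols - 1) * gap_q
    total_s = q_rows * quad_s + (q_rows - 1) * gap_q
    return {
        "ws": ws,
        "wf": wf,
        "mod_f": mod_f,
        "mod_s": mod_s,
        "gap_m": gap_m,
        "quad_f": quad_f,
        "quad_s": quad_s,
        "gap_q": gap_q,
        "q_cols": q_cols,
        "total_f": total_f,
        "total_s": total_s,
    }


def make_hierarchical_fixture(params: HierarchicalFixtureParams = None) -> NXmxDataSet:
    """A compliant stills data set on a hierarchical multi-panel detector.

    Builds the four-level transformation chain rail → detector → quadrant →
    module → ASIC; quadrant/module/ASIC axes point along Z and carry their
    positioning purely in X–Y offset vectors, with group names following the
    D{d}Q{q}M{m}A{a} scheme.  Every ASIC is an independent
    NXdetector_module slicing a packed (frames × slow × fast) image array.
    """
    if params is None:
        params = HierarchicalFixtureParams()
    p = params
    rng = np.random.default_rng(p.seed)
    L = _hier_layout(p)
    rows, cols = p.asics_per_module
    asic_s, asic_f = p.asic_size

    ds = NXmxDataSet()
    start, end_est = _end_times("2026-03-03T02:00:00Z", p.n_frames, 100.0)
    ds.provenance = _provenance(
        start, end_est, end_est, "Synthetic XFEL fixed-target station", "SXF1"
    )
    ds.beam = BeamDescriptor(p.wavelength)
    ds.sample = SampleBlock(name=TERMINATOR, depends_on=TERMINATOR)  # stills, no goniometer

    rail = ds.add_axis(
        AxisDefinition(
            name=f"{_DET_TRANS}/AXIS_RAIL",
            transformation_type="translation",
            vector=(0.0, 0.0, 1.0),
            setting=p.distance,
            depends_on=TERMINATOR,
        )
    )
    det_axis = ds.add_axis(
        AxisDefinition(
            name=f"{_DET_TRANS}/AXIS_D0",
            transformation_type="rotation",
            vector=(0.0, 0.0, 1.0),
            setting=0.0,
            depends_on=rail.name,
        )
    )

    fast_vec, slow_vec = np.array([-1.0, 0, 0]), np.array([0, -1.0, 0])

    def to_xy(u, v):
        """Grid coords (u along fast, v along slow, mm) → lab X–Y offset."""
        return (u - L["total_f"] / 2) * fast_vec + (v - L["total_s"] / 2) * slow_vec

    det = DetectorTree(name="ELE_D0", depends_on=rail.name)
    mod_px_s, mod_px_f = rows * asic_s, cols * asic_f
    for q in range(p.n_quadrants):
        qr, qc = divmod(q, L["q_cols"])
        qu = qc * (L["quad_f"] + L["gap_q"])
        qv = qr * (L["quad_s"] + L["gap_q"])
        q_center = to_xy(qu + L["quad_f"] / 2, qv + L["quad_s"] / 2)
        q_axis = ds.add_axis(
            AxisDefinition(
                name=f"{_DET_TRANS}/AXIS_D0Q{q}",
                transformation_type="rotation",
                vector=(0.0, 0.0, 1.0),
                setting=0.0,
                offset=q_center,
                depends_on=det_axis.name,
            )
        )
        for m in range(p.modules_per_quadrant):
            mu = qu
            mv = qv + m * (L["mod_s"] + L["gap_m"])
            m_center = to_xy(mu + L["mod_f"] / 2, mv + L["mod_s"] / 2)
            m_axis = ds.add_axis(
                AxisDefinition(
                    name=f"{_DET_TRANS}/AXIS_D0Q{q}M{m}",
                    transformation_type="rotation",
                    vector=(0.0, 0.0, 1.0),
                    setting=0.0,
                    offset=m_center - q_center,
                    depends_on=q_axis.name,
                )
            )
            for a in range(rows * cols):
                ar, ac = divmod(a, cols)
                au = mu + ac * (L["wf"] + p.gap)
                av = mv + ar * (L["ws"] + p.gap)
                # position of the centre of pixel (0, 0) of this ASIC
                p00 = to_xy(au + p.pixel_pitch / 2, av + p.pixel_pitch / 2)
                a_axis = ds.add_axis(
                    AxisDefinition(
                        name=f"{_DET_TRANS}/AXIS_D0Q{q}M{m}A{a}",
                        transformation_type="rotation",
                        vector=(0.0, 0.0, 1.0),
                        setting=0.0,
                        offset=p00 - m_center,
                        depends_on=m_axis.name,
                    )
                )
                global_m = q * p.modules_per_quadrant + m
                det.modules.append(
                    DetectorModuleSpec(
                        name=f"ARRAY_D0Q{q}M{m}A{a}",
                        data_origin=(global_m * mod_px_s + ar * asic_s, ac * asic_f),
                        data_size=(asic_s, asic_f),
                        fast_pixel_direction=PixelDirection(
                            fast_vec, p.pixel_pitch, a_axis.name
                        ),
                        slow_pixel_direction=PixelDirection(
                            slow_vec, p.pixel_pitch, a_axis.name
                        ),
                    )
                )
    ds.detectors.append(det)

    total_px_s = p.n_quadrants * p.modules_per_quadrant * mod_px_s
    total_px_f = cols * asic_f
    shape = (p.n_frames, total_px_s, total_px_f)
    ds.data = DataReference(
        shape=shape,
        dtype="int32",
        link="external",
        array=_images(rng, p.n_frames, (total_px_s, total_px_f)),
    )
    return ds


# ---------------------------------------------------------------------------
# mutation catalogue: each entry introduces exactly one targeted defect and
# maps to the single validator rule it must trip (None for the no-op).

def _drop_start_time(ds):
    ds.provenance.start_time = None


def _drop_end_time_estimated(ds):
    ds.provenance.end_time_estimated = None


def _non_utc_time(ds):
    ds.provenance.start_time = "2026-03-02T12:00:00+02:00"


def _end_before_start(ds):
    ds.provenance.end_time_estimated = "2001-01-01T00:00:00Z"
    ds.provenance.end_time = None  # keep exactly one defect (warning-level absence)


def _drop_instrument_name(ds):
    ds.provenance.instrument_name = None
    ds.provenance.instrument_short_name = None


def _drop_source_name(ds):
    ds.provenance.source_name = None
    ds.provenance.source_short_name = None


def _drop_sample(ds):
    ds.sample = None


def _dangling_depends_on(ds):
    axis = sorted(ds.axes)[0]
    ds.axes[axis].depends_on = "/entry/instrument/ELE_D0/transformations/NO_SUCH_AXIS"


def _non_unit_vector(ds):
    axis = ds.axes[sorted(ds.axes)[0]]
    axis.vector = axis.vector * 2.0  # bypasses construction-time checking


def _negative_wavelength(ds):
    ds.beam.incident_wavelength = -1.0


def _drop_wavelength(ds):
    ds.beam.incident_wavelength = float("nan")


def _drop_fast_pixel_direction(ds):
    ds.detectors[0].modules[0].fast_pixel_direction = None


def _drop_data(ds):
    ds.data = None


def _noop(ds):
    pass


#: mutation id -> (mutator, rule id of the single error it must produce)
MUTATION_RULES = {
    "drop-start-time": (_drop_start_time, "start_time_missing"),
    "drop-end-time-estimated": (_drop_end_time_estimated, "end_time_estimated_missing"),
    "non-utc-time": (_non_utc_time, "time_not_utc"),
    "end-before-start": (_end_before_start, "time_order"),
    "drop-instrument-name": (_drop_instrument_name, "instrument_name_missing"),
    "drop-source-name": (_drop_source_name, "source_name_missing"),
    "drop-sample": (_drop_sample, "sample_missing"),
    "dangling-depends-on": (_dangling_depends_on, "depends_on_unresolved"),
    "non-unit-vector": (_non_unit_vector, "vector_not_unit"),
    "negative-wavelength": (_negative_wavelength, "wavelength_not_positive"),
    "drop-wavelength": (_drop_wavelength, "wavelength_missing"),
    "drop-fast-pixel-direction": (_drop_fast_pixel_direction, "pixel_direction_missing"),
    "drop-data": (_drop_data, "data_missing"),
    "noop": (_noop, None),
}


def mutate(dataset: NXmxDataSet, mutation_id: str) -> NXmxDataSet:
    """Return a copy of ``dataset`` with exactly one targeted defect."""
    try:
        mutator, _ = MUTATION_RULES[mutation_id]
    except KeyError:
        raise KeyError(
            f"unknown mutation {mutation_id!r}; known: {sorted(MUTATION_RULES)}"
        ) from None
    out = copy.deepcopy(dataset)
    mutator(out)
    return out
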