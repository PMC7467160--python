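import numpy as np
import pytest

from nxmxkit.geometry import (
    axis_transform,
    beam_center,
    compose_chain,
    detector_distance,
    frame_settings,
    module_transform,
    pixel_lab_position,
    scattering_vector,
)
from nxmxkit.model import (
    AxisDefinition,
    BeamDescriptor,
    DetectorModuleSpec,
    DetectorTree,
    NXmxDataSet,
    PixelDirection,
    Scan,
)
from nxmxkit.synth import RotationFixtureParams, make_rotation_fixture

from oracles import chain_matrix, random_unit_vector


def _axis(name="/t/a", ttype="rotation", vector=(0, 1, 0), offset=(0, 0, 0), **kw):
    return AxisDefinition(
        name=name, transformation_type=ttype, vector=vector, offset=offset, **kw
    )


class TestAxisTransform:
    def test_zero_rotation_is_identity(self):
        t = axis_transform(_axis(), 0.0)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-15)
        np.testing.assert_allclose(t.translation, 0, atol=1e-15)

    def test_right_handed_rotation_about_y(self):
        # +90° about Y carries +X into -Z
        t = axis_transform(_axis(vector=(0, 1, 0)), 90.0)
        np.testing.assert_allclose(t.apply([1, 0, 0]), [0, 0, -1], atol=1e-12)

    def test_translation_with_offset(self):
        ax = _axis(ttype="translation", vector=(0, 0, -1), offset=(1, 2, 0))
        np.testing.assert_allclose(
            axis_transform(ax, 200.0).apply([0, 0, 0]), [1, 2, -200], atol=1e-12
        )

    def test_offset_units_converted(self):
        ax = _axis(ttype="translation", vector=(0, 0, 1), offset=(0.001, 0, 0))
        ax.offset_units = "m"
        np.testing.assert_allclose(
            axis_transform(ax, 0.0).translation, [1.0, 0, 0], atol=1e-12
        )


class TestComposeChain:
    def test_empty_chain_is_identity(self):
        t = compose_chain([])
        np.testing.assert_array_equal(t.rotation, np.eye(3))

    def test_single_axis_equals_axis_transform(self):
        ax = _axis(vector=(1, 0, 0), offset=(0, 1, 2))
        a = compose_chain([ax], [30.0])
        b = axis_transform(ax, 30.0)
        np.testing.assert_allclose(a.as_matrix(), b.as_matrix(), atol=1e-15)

    def test_settings_length_mismatch(self):
        with pytest.raises(ValueError, match="settings"):
            compose_chain([_axis()], [1.0, 2.0])

    def test_matches_homogeneous_matrix_oracle(self, rng):
        """1000 seeded random chains of depth 1-6 against a brute-force
        4x4 homogeneous-matrix product."""
        worst_t, worst_r = 0.0, 0.0
        for _ in range(1000):
            depth = int(rng.integers(1, 7))
            chain, settings = [], []
            for k in range(depth):
                ttype = "rotation" if rng.random() < 0.5 else "translation"
                chain.append(
                    _axis(
                        name=f"/t/ax{k}",
                        ttype=ttype,
                        vector=random_unit_vector(rng),
                        offset=rng.normal(scale=50.0, size=3),
                    )
                )
                settings.append(float(rng.normal(scale=180.0)))
            got = compose_chain(chain, settings).as_matrix()
            want = chain_matrix(chain, settings)
            worst_r = max(worst_r, np.abs(got[:3, :3] - want[:3, :3]).max())
            worst_t = max(worst_t, np.abs(got[:3, 3] - want[:3, 3]).max())
        assert worst_r < 1e-12
        assert worst_t < 1e-9

    def test_rotation_stays_orthonormal_at_depth_20(self, rng):
        total = compose_chain(
            [
                _axis(name=f"/t/a{k}", vector=random_unit_vector(rng))
                for k in range(20)
            ],
            list(rng.normal(scale=360.0, size=20)),
        )
        r = total.rotation
        assert np.abs(r @ r.T - np.eye(3)).max() < 1e-9
        assert abs(np.linalg.det(r) - 1.0) < 1e-9


def _flat_module(ns=16, nf=24, pitch=0.075):
    return DetectorModuleSpec(
        "ARRAY",
        (0, 0),
        (ns, nf),
        PixelDirection((-1, 0, 0), pitch, "."),
        PixelDirection((0, -1, 0), pitch, "."),
    )


class TestPixelLabPosition:
    def test_pixel_zero_at_module_origin(self):
        from nxmxkit.model import RigidTransform

        module = _flat_module()
        pos = pixel_lab_position(module, RigidTransform.identity(), 0, 0)
        np.testing.assert_allclose(pos, [0, 0, 0], atol=1e-15)

    def test_translated_detector_hand_computation(self):
        ax = _axis(ttype="translation", vector=(0, 0, -1))
        t = axis_transform(ax, 200.0)
        module = _flat_module()
        for i, j in [(0, 0), (3, 7), (15, 23)]:
            np.testing.assert_allclose(
                pixel_lab_position(module, t, i, j),
                [-0.075 * j, -0.075 * i, -200.0],
                atol=1e-12,
            )

    def test_out_of_range_raises(self):
        from nxmxkit.model import RigidTransform

        with pytest.raises(IndexError):
            pixel_lab_position(_flat_module(), RigidTransform.identity(), 16, 0)

    def test_affine_in_indices(self, rotation_ds):
        """position(i+1,j) - position(i,j) is constant across the module."""
        det = rotation_ds.detectors[0]
        module = det.modules[0]
        t = module_transform(rotation_ds, det, module)
        ii, jj = np.mgrid[0:10, 0:10]
        pos = pixel_lab_position(module, t, ii, jj)
        dslow = np.diff(pos, axis=0)
        dfast = np.diff(pos, axis=1)
        assert np.abs(dslow - dslow[0, 0]).max() < 1e-12
        assert np.abs(dfast - dfast[0, 0]).max() < 1e-12

    def test_hierarchical_leaf_is_vector_sum_of_offsets(self, hierarchical_ds):
        """Pixel (0,0) of each panel equals the sum of quadrant + module +
        ASIC offsets pushed through the rail translation (all axes at 0°,
        offsets in the X-Y plane)."""
        from nxmxkit.model import resolve_depends_on

        det = hierarchical_ds.detectors[0]
        for module in det.modules[:: 37]:
            leaf = det.module_path(module, "fast_pixel_direction")
            chain = resolve_depends_on(hierarchical_ds, leaf)
            t = module_transform(hierarchical_ds, det, module)
            pos = pixel_lab_position(module, t, 0, 0)
            expected = sum(a.offset_mm() for a in chain[:-1])  # X-Y plane offsets
            expected = expected + chain[-1].setting_at(0) * chain[-1].vector
            np.testing.assert_allclose(pos, expected, atol=1e-9)
            assert pos[2] == pytest.approx(120.0)  # rail distance, offsets in X-Y


class TestBeamCenterAndDistance:
    def test_fixture_recovery_to_sub_micro_pixel(self, rotation_ds):
        res = [r for r in beam_center(rotation_ds) if r.intersects][0]
        assert res.slow == pytest.approx(1225.54, abs=1e-6)
        assert res.fast == pytest.approx(1306.17, abs=1e-6)

    def test_centered_module_reports_center_pixel(self):
        params = RotationFixtureParams(beam_center=(31.5, 29.5), module_size=(64, 60))
        ds = make_rotation_fixture(params)
        res = beam_center(ds)[0]
        assert res.inside
        assert (res.slow, res.fast) == (pytest.approx(31.5), pytest.approx(29.5))

    def test_beam_parallel_to_plane_marked_no_intersection(self, rotation_ds):
        ds = rotation_ds
        ds.beam = BeamDescriptor(ds.beam.incident_wavelength, beam_direction=(1, 0, 0))
        res = beam_center(ds)[0]
        assert not res.intersects

    def test_distance_recovers_generator_translation(self, rotation_ds):
        assert detector_distance(rotation_ds) == pytest.approx(200.0, abs=1e-9)

    def test_tilted_detector_closed_form(self):
        """Tilting the whole detector 10° about the vertical axis at the
        chain root leaves the plane at perpendicular distance 200 mm, so the
        along-beam path to the intersection is 200/cos(10°) (ray/plane
        closed form)."""
        ds = make_rotation_fixture()
        tilt = AxisDefinition(
            name="/entry/instrument/ELE_D0/transformations/AXIS_TILT",
            transformation_type="rotation",
            vector=(0, 1, 0),
            setting=10.0,
            depends_on=".",
        )
        ds.add_axis(tilt)
        ds.axes["/entry/instrument/ELE_D0/transformations/AXIS_RAIL"].depends_on = tilt.name
        assert detector_distance(ds) == pytest.approx(
            200.0 / np.cos(np.radians(10)), rel=1e-12
        )

    def test_zero_translation_gives_zero_distance(self):
        ds = make_rotation_fixture()
        rail = ds.axes["/entry/instrument/ELE_D0/transformations/AXIS_RAIL"]
        rail.setting = 0.0
        mod = ds.axes["/entry/instrument/ELE_D0/transformations/AXIS_D0M0"]
        mod.offset = np.zeros(3)
        assert detector_distance(ds) == pytest.approx(0.0, abs=1e-12)


class TestScatteringVector:
    def test_forward_beam_pixel_has_zero_q(self):
        q = scattering_vector([0, 0, 150.0], 1.0, (0, 0, 1))
        np.testing.assert_allclose(q, 0, atol=1e-15)

    @pytest.mark.parametrize("two_theta", [0.0, 30.0, 90.0, 120.0])
    @pytest.mark.parametrize("wavelength", [0.5, 1.0, 2.0])
    def test_magnitude_closed_form(self, two_theta, wavelength):
        """|q| = 2 sin(theta) / lambda on a grid of scattering angles."""
        tt = np.radians(two_theta)
        pixel = 180.0 * np.array([np.sin(tt), 0, np.cos(tt)])
        q = scattering_vector(pixel, wavelength, (0, 0, 1))
        assert np.linalg.norm(q) == pytest.approx(
            2 * np.sin(tt / 2) / wavelength, abs=1e-12
        )

    def test_ninety_degree_example(self):
        q = scattering_vector([100.0, 0, 0], 1.0, (0, 0, 1))
        assert np.linalg.norm(q) == pytest.approx(np.sqrt(2), abs=1e-8)

    def test_magnitude_rotation_invariant(self, rng):
        from oracles import rodrigues, random_unit_vector

        pixel = np.array([25.0, -13.0, 170.0])
        beam = np.array([0.0, 0.0, 1.0])
        q0 = np.linalg.norm(scattering_vector(pixel, 1.2, beam))
        for _ in range(20):
            r = rodrigues(random_unit_vector(rng), float(rng.uniform(0, 360)))
            q1 = np.linalg.norm(scattering_vector(r @ pixel, 1.2, r @ beam))
            assert q1 == pytest.approx(q0, abs=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            scattering_vector([0, 0, 100.0], -1.0, (0, 0, 1))
        with pytest.raises(ValueError):
            scattering_vector([0, 0, 0], 1.0, (0, 0, 1))


class TestFrameSettings:
    def test_start_plus_increment(self):
        scan = Scan(axis_path="/t/omega", start_deg=0.0, increment_deg=0.1, n_frames=20)
        assert frame_settings(scan, 10) == {"/t/omega": pytest.approx(1.0)}

    def test_stills_constant(self):
        scan = Scan(axis_path="/t/omega", start_deg=12.5, increment_deg=0.0, n_frames=3)
        assert frame_settings(scan, 0) == frame_settings(scan, 2)

    def test_per_frame_array_takes_precedence(self):
        arr = np.array([5.0, 7.0, 11.0])
        scan = Scan(
            axis_path="/t/omega", start_deg=0.0, increment_deg=0.1, n_frames=3, per_frame=arr
        )
        for k in range(3):
            assert frame_settings(scan, k)["/t/omega"] == arr[k]
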