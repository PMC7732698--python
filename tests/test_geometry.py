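import numpy as np
import pytest
from hypothesis import assume, given, strategies as st

from fabdyn import (
    ToyFabSpec,
    abangle_measures,
    angle_series,
    build_toy_fab,
    ch1_cl_angle,
    elbow_angle,
    fit_domain_plane,
    iter_animated_frames,
    load_reference,
    torsion_angle,
)
from fabdyn.errors import DegenerateGeometryError, SamplingError
from fabdyn.series import AngleSeries
from conftest import apply_rigid, random_rigid_transform


def brute_force_dihedral(p1, p2, p3, p4):
    """Independent oracle: normal-vector construction with an explicit
    arccos magnitude and a separate sign test (no atan2)."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1 /= np.linalg.norm(n1)
    n2 /= np.linalg.norm(n2)
    ang = np.degrees(np.arccos(np.clip(np.dot(n1, n2), -1, 1)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return 180.0 if ang == -180.0 else ang


class TestTorsion:
    @pytest.mark.parametrize("p4,expected", [
        ((1, 1, 0), 0.0),       # planar cis
        ((-1, 1, 0), 180.0),    # planar trans
        ((0, 1, 1), -90.0),     # right angle, sign fixed by convention
    ])
    def test_reference_configurations(self, p4, expected):
        val = torsion_angle((1, 0, 0), (0, 0, 0), (0, 1, 0), p4)
        assert val == pytest.approx(expected, abs=1e-12)

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            torsion_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))
        with pytest.raises(DegenerateGeometryError):
            torsion_angle((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 300:
            pts = rng.uniform(-10, 10, size=(4, 3))
            try:
                ours = torsion_angle(*pts)
            except DegenerateGeometryError:
                continue
            assert ours == pytest.approx(brute_force_dihedral(*pts), abs=1e-9)
            checked += 1

    @given(st.integers(0, 10_000))
    def test_reversal_invariance(self, seed):
        """A dihedral reads the same from either end of the four-point
        chain (this is what makes cis/trans assignments direction-free)."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-5, 5, size=(4, 3))
        try:
            fwd = torsion_angle(*pts)
        except DegenerateGeometryError:
            assume(False)
        rev = torsion_angle(*pts[::-1])
        assert rev == pytest.approx(fwd, abs=1e-9)

    @given(st.integers(0, 10_000))
    def test_mirror_antisymmetry(self, seed):
        """Reflecting the four points flips the dihedral's sign."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-5, 5, size=(4, 3))
        try:
            fwd = torsion_angle(*pts)
        except DegenerateGeometryError:
            assume(False)
        if abs(abs(fwd) - 180.0) < 1e-9:  # ±180 is the same dihedral
            return
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert torsion_angle(*mirrored) == pytest.approx(-fwd, abs=1e-9)


class TestComTorsions:
    @pytest.mark.parametrize("elbow,ch1cl", [
        (160.0, 100.0),
        (-120.0, -45.0),
        (180.0, 0.5),
    ])
    def test_constructive_round_trip(self, elbow, ch1cl):
        fab = build_toy_fab(ToyFabSpec(elbow_deg=elbow, ch1cl_deg=ch1cl))
        assert elbow_angle(fab.frame, fab.partition) == pytest.approx(
            elbow, abs=1e-6)
        assert ch1_cl_angle(fab.frame, fab.partition) == pytest.approx(
            ch1cl, abs=1e-6)

    def test_rigid_transform_invariance(self, toy_fab):
        rng = np.random.default_rng(5)
        base_e = elbow_angle(toy_fab.frame, toy_fab.partition)
        base_c = ch1_cl_angle(toy_fab.frame, toy_fab.partition)
        for _ in range(10):
            rot, t = random_rigid_transform(rng)
            moved = apply_rigid(toy_fab.frame, rot, t)
            assert elbow_angle(moved, toy_fab.partition) == pytest.approx(
                base_e, abs=1e-9)
            assert ch1_cl_angle(moved, toy_fab.partition) == pytest.approx(
                base_c, abs=1e-9)


class TestDomainPlane:
    def test_planar_points_normal(self):
        pts = np.array([[0, 0, 0], [4, 0, 0], [4, 3, 0], [0, 3, 0]], float)
        frame = fit_domain_plane(pts)
        assert abs(np.dot(frame.plane_normal, [0, 0, 1])) == pytest.approx(1.0)
        np.testing.assert_allclose(frame.origin, [2, 1.5, 0])

    def test_collinear_rejected(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], float)
        with pytest.raises(DegenerateGeometryError):
            fit_domain_plane(pts)

    def test_thick_cloud_rejected(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 3))  # isotropic: no plane
        with pytest.raises(DegenerateGeometryError):
            fit_domain_plane(pts)

    def test_axes_rotate_with_the_cloud(self):
        """Principal axes follow a rotation of the input, up to the fixed
        sign rule; checked against an independent eigendecomposition."""
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.uniform(-9, 9, 40),
                               rng.uniform(-4, 4, 40),
                               rng.uniform(-0.2, 0.2, 40)])
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(rng=rng)
        f0 = fit_domain_plane(pts)
        f1 = fit_domain_plane(rot.apply(pts))
        for a0, a1 in ((f0.axis1, f1.axis1), (f0.axis2, f1.axis2)):
            assert abs(np.dot(rot.apply(a0), a1)) == pytest.approx(1.0, abs=1e-9)
        # independent oracle: eigenvectors of the covariance matrix
        centered = pts - pts.mean(axis=0)
        w, v = np.linalg.eigh(centered.T @ centered)
        assert abs(np.dot(v[:, -1], f0.axis1)) == pytest.approx(1.0, abs=1e-9)
        assert abs(np.dot(v[:, -2], f0.axis2)) == pytest.approx(1.0, abs=1e-9)


class TestAbangle:
    def test_self_consistency_identity_registration(self, toy_fab):
        """A structure carrying the reference cores in the canonical pose
        must reproduce the canonical frame geometry exactly."""
        ref = load_reference()
        m = abangle_measures(toy_fab.frame, toy_fab.partition, ref)
        fh, fl = ref.h_frame, ref.l_frame
        c = fh.origin - fl.origin
        canon_hl = torsion_angle(fh.origin + fh.axis1, fh.origin,
                                 fl.origin, fl.origin + fl.axis1)
        # toy fab prescribes dc = 16 exactly; canonical dc is |c| ≈ 16
        assert m.dc == pytest.approx(16.0, abs=1e-9)
        assert m.HL == pytest.approx(canon_hl, abs=1e-6)

    def test_rotation_about_c_shifts_hl_only(self):
        base = build_toy_fab(ToyFabSpec(vhvl_rotation_deg=0.0))
        rot10 = build_toy_fab(ToyFabSpec(vhvl_rotation_deg=10.0))
        m0 = abangle_measures(base.frame, base.partition)
        m1 = abangle_measures(rot10.frame, rot10.partition)
        assert m1.HL - m0.HL == pytest.approx(10.0, abs=1e-6)
        assert m1.dc == pytest.approx(m0.dc, abs=1e-9)

    def test_translation_along_c_changes_dc_only(self, toy_fab):
        m0 = abangle_measures(toy_fab.frame, toy_fab.partition)
        ref = load_reference()
        c_hat = ref.h_frame.origin - ref.l_frame.origin
        c_hat /= np.linalg.norm(c_hat)
        # move the whole light domain 2 Å away from the heavy domain
        frame = toy_fab.frame
        coords = frame.coords.copy()
        vl_mask = (frame.chain_ids == "L") & (frame.res_ids <= 24)
        coords[vl_mask] -= 2.0 * c_hat
        m1 = abangle_measures(frame.with_coords(coords), toy_fab.partition)
        assert m1.dc == pytest.approx(m0.dc + 2.0, abs=1e-6)
        for name in ("HL", "HC1", "HC2", "LC1", "LC2"):
            assert m1.as_dict()[name] == pytest.approx(
                m0.as_dict()[name], abs=1e-6)

    def test_prescribed_dc(self):
        fab = build_toy_fab(ToyFabSpec(dc_angstrom=18.5))
        m = abangle_measures(fab.frame, fab.partition)
        assert m.dc == pytest.approx(18.5, abs=1e-6)

    def test_rigid_transform_invariance(self, toy_fab):
        rng = np.random.default_rng(9)
        m0 = abangle_measures(toy_fab.frame, toy_fab.partition).as_dict()
        for _ in range(5):
            rot, t = random_rigid_transform(rng)
            m1 = abangle_measures(apply_rigid(toy_fab.frame, rot, t),
                                  toy_fab.partition).as_dict()
            for k in m0:
                assert m1[k] == pytest.approx(m0[k], abs=1e-9)


class TestAngleSeries:
    def test_constant_trajectory(self, toy_fab):
        const = AngleSeries(np.full(5, 160.0), dt_ps=10.0, name="elbow")
        frames = list(iter_animated_frames(toy_fab, const))
        s = angle_series(frames, "elbow", toy_fab.partition)
        np.testing.assert_allclose(s.values, 160.0, atol=1e-9)
        assert s.dt_ps == 10.0
        assert s.periodic

    def test_prescribed_waveform_recovered(self, toy_fab):
        t = np.arange(50) * 20.0  # ps
        wave = 160.0 + 5.0 * np.sin(2 * np.pi * t / 1000.0)
        frames = iter_animated_frames(
            toy_fab, AngleSeries(wave, dt_ps=20.0, name="elbow"))
        s = angle_series(frames, "elbow", toy_fab.partition)
        np.testing.assert_allclose(s.values, wave, atol=1e-6)

    def test_single_frame_rejected(self, toy_fab):
        with pytest.raises(SamplingError):
            angle_series([toy_fab.frame], "elbow", toy_fab.partition)

    def test_dc_flagged_aperiodic(self, toy_fab):
        const = AngleSeries(np.full(3, 160.0), dt_ps=1.0, name="elbow")
        frames = list(iter_animated_frames(toy_fab, const))
        s = angle_series(frames, "dc", toy_fab.partition)
        assert not s.periodic
        np.testing.assert_allclose(s.values, 16.0, atol=1e-9)
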