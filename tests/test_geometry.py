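import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coilforge import (
    DomainError, HelixParameters, StructureModel, build_collagen_strand,
    build_helix_backbone, default_shr, measure_parameters, pitch_angle,
    superhelix_point,
)
from coilforge._errors import BuildError
from coilforge.geometry import (
    ALPHA_MINOR_RADIUS, ALPHA_RISE_PER_RESIDUE, normalize_angle,
)

from .conftest import CANONICAL_REG, CANONICAL_SEQ


class TestDefaultSuperHelicalRotation:
    @pytest.mark.parametrize("i, n, expected", [
        (1, 4, 0.0),        # helix 1 of a tetramer sits at 0 degrees
        (3, 4, 180.0),      # helix 3 of a tetramer sits at 180 degrees
        (2, 3, 120.0),
        (1, 2, 0.0),
        (1, 7, 0.0),
        (4, 4, 270.0),
    ])
    def test_symmetric_default(self, i, n, expected):
        assert default_shr(i, n) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("i, n", [(0, 4), (5, 4), (-1, 3), (1, 1), (2, 0)])
    def test_out_of_range(self, i, n):
        with pytest.raises(DomainError):
            default_shr(i, n)


class TestPitchAngle:
    def test_quarter_pi(self):
        # pitch equal to the circumference gives atan(1) = 45 degrees
        assert pitch_angle(5.0, 2 * math.pi * 5.0) == pytest.approx(45.0)

    def test_closed_form(self):
        # independent evaluation of atan(2 pi r / P)
        expected = math.degrees(math.atan(2 * math.pi * 7.0 / 200.0))
        assert pitch_angle(7.0, 200.0) == pytest.approx(expected)
        assert expected == pytest.approx(12.41, abs=0.01)

    def test_straight_limit(self):
        assert pitch_angle(5.0, 1e12) == pytest.approx(0.0, abs=1e-6)

    def test_sign_follows_handedness(self):
        assert pitch_angle(5.0, -200.0) < 0 < pitch_angle(5.0, 200.0)

    def test_zero_pitch_rejected(self):
        with pytest.raises(DomainError):
            pitch_angle(5.0, 0.0)


class TestSuperhelixPoint:
    def test_phase_zero(self):
        p = HelixParameters(radius=5.0, pitch=140.0)
        assert superhelix_point(0.0, p) == pytest.approx([5.0, 0.0, 0.0])

    def test_full_turn(self):
        p = HelixParameters(radius=5.0, pitch=140.0)
        assert superhelix_point(140.0, p) == pytest.approx([5.0, 0.0, 140.0],
                                                           abs=1e-9)

    def test_quarter_turn_handedness(self):
        right = HelixParameters(radius=5.0, pitch=140.0)
        left = HelixParameters(radius=5.0, pitch=-140.0)
        assert superhelix_point(35.0, right) == pytest.approx([0.0, 5.0, 35.0],
                                                              abs=1e-9)
        assert superhelix_point(35.0, left) == pytest.approx([0.0, -5.0, 35.0],
                                                             abs=1e-9)

    @given(z=st.floats(-200, 200), shr=st.floats(-179, 179),
           r=st.floats(1, 15), pitch=st.floats(60, 500))
    @settings(max_examples=50, deadline=None)
    def test_point_on_cylinder(self, z, shr, r, pitch):
        p = HelixParameters(radius=r, pitch=pitch, super_helical_rotation=shr)
        x, y, _ = superhelix_point(z, p)
        assert math.hypot(x, y) == pytest.approx(r, rel=1e-9)


class TestHelixBackbone:
    def test_minimum_length(self):
        p = HelixParameters(radius=5.0, pitch=-180.0, sequence="AAA")
        with pytest.raises(BuildError):
            build_helix_backbone(p)

    def test_backbone_complete_and_radius_bounded(self):
        p = HelixParameters(radius=5.0, pitch=-180.0, sequence="A" * 28)
        model = build_helix_backbone(p)
        for res in model.chains[0].residues:
            assert res.has_backbone()
        ca = model.chains[0].ca_coords()
        dist = np.hypot(ca[:, 0], ca[:, 1])
        assert np.all(dist >= 5.0 - 2.6) and np.all(dist <= 5.0 + 2.6)

    def test_virtual_ca_bond(self):
        p = HelixParameters(radius=5.0, pitch=-180.0, sequence="A" * 28)
        ca = build_helix_backbone(p).chains[0].ca_coords()
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(np.abs(d - 3.8) <= 0.2)

    def test_straight_limit_recovers_alpha_helix(self):
        """With no supercoiling the chain must be an ideal straight helix:
        rise/residue ~1.495 A and ~3.6 residues per turn, measured by an
        independent cylinder + phase fit of the Calpha trace."""
        p = HelixParameters(radius=5.0, pitch=1e9, sequence="A" * 40)
        ca = build_helix_backbone(p).chains[0].ca_coords()
        # the minor-helix axis here is the line x=5, y=0
        z = ca[:, 2]
        rise = np.diff(z).mean()
        assert rise == pytest.approx(ALPHA_RISE_PER_RESIDUE, abs=0.01)
        radial = ca[:, :2] - [5.0, 0.0]
        assert np.hypot(*radial.T).mean() == pytest.approx(
            ALPHA_MINOR_RADIUS, abs=0.05)
        phases = np.unwrap(np.arctan2(ca[:, 1], radial[:, 0]))
        per_res = abs(np.degrees(np.diff(phases)).mean())
        assert 360.0 / per_res == pytest.approx(3.6, abs=0.2)

    def test_antiparallel_points_down(self):
        par = HelixParameters(radius=5.0, pitch=-180.0, sequence="A" * 28)
        anti = HelixParameters(radius=5.0, pitch=-180.0, sequence="A" * 28,
                               orientation="antiparallel")
        ca_p = build_helix_backbone(par).chains[0].ca_coords()
        ca_a = build_helix_backbone(anti).chains[0].ca_coords()
        assert ca_p[-1, 2] > ca_p[0, 2]
        assert ca_a[-1, 2] < ca_a[0, 2]
        # N terminus of the flipped chain starts at the top of the z range
        assert ca_a[0, 2] == pytest.approx(ca_p[-1, 2], abs=1.0)


class TestCollagenStrand:
    def test_ca_spacing(self):
        p = HelixParameters(radius=3.0, pitch=85.0, sequence="GPO" * 9)
        ca = build_collagen_strand(p).chains[0].ca_coords()
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(np.abs(d - 3.8) <= 0.3)

    def test_zshift_is_pure_translation(self):
        base = HelixParameters(radius=3.0, pitch=85.0, sequence="GPO" * 9)
        moved = HelixParameters(radius=3.0, pitch=85.0, sequence="GPO" * 9,
                                z_shift=2.9)
        m0 = build_collagen_strand(base).chains[0]
        m1 = build_collagen_strand(moved).chains[0]
        for r0, r1 in zip(m0.residues, m1.residues):
            for atom in r0.atoms:
                np.testing.assert_allclose(
                    r1.atoms[atom] - r0.atoms[atom], [0.0, 0.0, 2.9],
                    atol=1e-12)

    def test_three_strands_no_steric_overlap(self):
        chains = []
        for i, shr in enumerate((0.0, 120.0, 240.0)):
            p = HelixParameters(radius=3.0, pitch=85.0,
                                super_helical_rotation=shr,
                                sequence="GPO" * 9)
            chains.append(build_collagen_strand(p, chain_id="ABC"[i]).chains[0])
        xyz = [np.vstack([list(r.atoms.values()) for r in c.residues])
               for c in chains]
        for i in range(3):
            for j in range(i + 1, 3):
                diff = xyz[i][:, None, :] - xyz[j][None, :, :]
                assert np.linalg.norm(diff, axis=-1).min() >= 2.0

    def test_minimum_length(self):
        p = HelixParameters(radius=3.0, pitch=85.0, sequence="GP")
        with pytest.raises(BuildError):
            build_collagen_strand(p)


class TestMeasureParameters:
    def test_round_trip_single(self, dimer_backbone):
        mp = measure_parameters(dimer_backbone, "A", register=CANONICAL_REG)
        assert mp.supercoiling_detected
        assert mp.radius == pytest.approx(4.9, abs=0.2)
        assert mp.pitch == pytest.approx(-180.0, rel=0.05)
        assert mp.interface_angle == pytest.approx(26.0, abs=3.0)

    def test_straight_helix_flagged(self):
        p = HelixParameters(radius=5.0, pitch=1e9, sequence="A" * 28)
        mp = measure_parameters(build_helix_backbone(p))
        assert not mp.supercoiling_detected
        assert math.isinf(mp.pitch)

    def test_rigid_motion_invariance(self, dimer_backbone, rotation_matrix):
        moved = dimer_backbone.transformed(rotation_matrix,
                                           np.array([11.0, -3.0, 42.0]))
        a = measure_parameters(dimer_backbone, "A", register=CANONICAL_REG)
        b = measure_parameters(moved, "A", register=CANONICAL_REG)
        assert b.radius == pytest.approx(a.radius, rel=1e-6)
        assert b.pitch == pytest.approx(a.pitch, rel=1e-6)
        assert b.interface_angle == pytest.approx(a.interface_angle, abs=1e-4)

    def test_too_short_chain_rejected(self):
        p = HelixParameters(radius=5.0, pitch=-180.0, sequence="A" * 8)
        from coilforge import AnalysisError
        with pytest.raises(AnalysisError):
            measure_parameters(build_helix_backbone(p))


class TestAngleNormalization:
    @given(angle=st.floats(-1e6, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_range(self, angle):
        out = normalize_angle(angle)
        assert -180.0 <= out < 180.0

    def test_invariant_values(self):
        assert normalize_angle(180.0) == -180.0
        assert normalize_angle(-180.0) == -180.0
        assert normalize_angle(359.0) == pytest.approx(-1.0)
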