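import json

import numpy as np
import pytest

from coilforge import (
    AssemblySpec, HelixParameters, ValidationError, build_assembly,
    spec_from_json, spec_to_json, validate_spec,
)
from coilforge.builder import basic_spec, chain_id_for

from .conftest import CANONICAL_REG, CANONICAL_SEQ, rmsd


class TestValidation:
    def test_hydroxyproline_rejected_outside_collagen(self):
        spec = basic_spec(2, 4.9, -180.0, 26.0, "GPOGPO" + "A" * 8)
        with pytest.raises(ValidationError, match="'O'.*collagen"):
            validate_spec(spec)

    def test_hydroxyproline_allowed_in_collagen(self):
        helices = [HelixParameters(radius=3.0, pitch=85.0, sequence="GPO" * 5,
                                   helix_index=i + 1) for i in range(3)]
        spec = AssemblySpec(mode="advanced", fold="collagen",
                            oligomer_state=3, helices=helices)
        assert validate_spec(spec).helices[0].sequence == "GPO" * 5

    def test_collagen_locked_to_three_chains(self):
        with pytest.raises(ValidationError):
            AssemblySpec(mode="advanced", fold="collagen", oligomer_state=4,
                         helices=[])

    def test_register_length_mismatch(self):
        # the mismatch is caught at parameter construction, never silently
        with pytest.raises(ValidationError, match="register"):
            HelixParameters(radius=4.9, pitch=-180.0, sequence="A" * 14,
                            register="abc")
        assert validate_spec(basic_spec(2, 4.9, -180.0, 26.0, "A" * 14))

    def test_basic_mode_applies_symmetric_rotations(self):
        spec = basic_spec(4, 6.8, -180.0, 26.0, CANONICAL_SEQ, CANONICAL_REG)
        shrs = [h.super_helical_rotation for h in spec.helices]
        # stored on [-180, 180): 0, 90, 180 -> -180, 270 -> -90
        assert shrs == pytest.approx([0.0, 90.0, -180.0, -90.0])

    def test_register_auto_assignment_warns(self):
        spec = AssemblySpec(
            mode="advanced", fold="coiled_coil", oligomer_state=2,
            helices=[HelixParameters(radius=4.9, pitch=-180.0,
                                     sequence="A" * 14, helix_index=i + 1)
                     for i in range(2)])
        model, report = build_assembly(spec)
        assert any("register" in w for w in report.warnings)
        assert report.spec.helices[0].register == "abcdefg" * 2

    def test_oligomer_state_minimum(self):
        with pytest.raises(ValidationError):
            AssemblySpec(mode="basic", oligomer_state=1, helices=[])


class TestBuildAssembly:
    def test_chain_count_and_ids(self):
        spec = basic_spec(4, 6.8, -180.0, 26.0, CANONICAL_SEQ, CANONICAL_REG)
        model, _ = build_assembly(spec)
        assert [c.chain_id for c in model.chains] == ["A", "B", "C", "D"]

    def test_chain_ids_beyond_26(self):
        assert chain_id_for(25) == "Z"
        assert chain_id_for(26) == "AA"
        assert chain_id_for(27) == "AB"

    def test_heterodimer_sequences_threaded(self):
        spec = AssemblySpec(
            mode="advanced", fold="coiled_coil", oligomer_state=2,
            helices=[
                HelixParameters(radius=4.9, pitch=-180.0, sequence="EIAALEQ" * 2,
                                register="gabcdef" * 2, helix_index=1),
                HelixParameters(radius=4.9, pitch=-180.0, sequence="KIAALKQ" * 2,
                                register="gabcdef" * 2,
                                super_helical_rotation=180.0, helix_index=2),
            ])
        model, _ = build_assembly(spec)
        assert model.chains[0].residues[0].name == "GLU"
        assert model.chains[1].residues[0].name == "LYS"

    def test_zshift_is_axial_translation(self):
        base = basic_spec(2, 4.9, -180.0, 26.0, CANONICAL_SEQ, CANONICAL_REG)
        slipped = AssemblySpec(
            mode="advanced", fold="coiled_coil", oligomer_state=2,
            helices=[base.helices[0],
                     HelixParameters(**{**base.helices[1].__dict__,
                                        "z_shift": 2.5})])
        m0, _ = build_assembly(base)
        m1, _ = build_assembly(slipped)
        for r0, r1 in zip(m0.chains[1].residues, m1.chains[1].residues):
            for atom in r0.atoms:
                np.testing.assert_allclose(r1.atoms[atom] - r0.atoms[atom],
                                           [0.0, 0.0, 2.5], atol=1e-12)

    def test_antiparallel_chain_runs_opposite(self):
        spec = AssemblySpec(
            mode="advanced", fold="coiled_coil", oligomer_state=2,
            helices=[
                HelixParameters(radius=4.9, pitch=-180.0,
                                sequence=CANONICAL_SEQ, register=CANONICAL_REG,
                                helix_index=1),
                HelixParameters(radius=4.9, pitch=-180.0,
                                sequence=CANONICAL_SEQ, register=CANONICAL_REG,
                                orientation="antiparallel",
                                super_helical_rotation=180.0, helix_index=2),
            ])
        model, _ = build_assembly(spec)
        va = (model.chains[0].ca_coords()[-1] - model.chains[0].ca_coords()[0])
        vb = (model.chains[1].ca_coords()[-1] - model.chains[1].ca_coords()[0])
        assert float(va @ vb) < 0

    def test_determinism(self, canonical_dimer_spec):
        m1, _ = build_assembly(canonical_dimer_spec)
        m2, _ = build_assembly(canonical_dimer_spec)
        assert rmsd(m1, m2) == 0.0

    def test_symmetry_of_basic_nmers(self):
        """A symmetric n-mer is invariant under rotation by 360/n about the
        axis combined with cyclic chain relabelling."""
        for n in (2, 3, 5):
            spec = basic_spec(n, 6.8, -180.0, 26.0, CANONICAL_SEQ,
                              CANONICAL_REG)
            model, _ = build_assembly(spec)
            ang = np.radians(360.0 / n)
            R = np.array([[np.cos(ang), -np.sin(ang), 0],
                          [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
            rotated = model.transformed(R)
            for i, chain in enumerate(rotated.chains):
                target = model.chains[(i + 1) % n]
                for r_rot, r_tgt in zip(chain.residues, target.residues):
                    for atom in r_rot.atoms:
                        np.testing.assert_allclose(
                            r_rot.atoms[atom], r_tgt.atoms[atom], atol=1e-6)


class TestJsonSchema:
    def test_round_trip_identity(self, canonical_dimer_spec):
        doc = spec_to_json(canonical_dimer_spec)
        again = spec_from_json(doc)
        assert again == canonical_dimer_spec

    def test_missing_required_key_named(self):
        doc = {"oligomer_state": 2, "helices": [
            {"radius": 4.9, "sequence": "A" * 14}]}
        with pytest.raises(ValidationError, match="pitch"):
            spec_from_json(doc)

    def test_unknown_key_rejected_with_accepted_list(self):
        doc = {"oligomer_state": 2, "wiggle": 1, "helices": []}
        with pytest.raises(ValidationError, match="wiggle"):
            spec_from_json(doc)

    def test_numeric_string_coerced(self):
        doc = {"mode": "advanced", "oligomer_state": "2", "helices": [
            {"radius": "5.0", "pitch": -180.0, "sequence": "A" * 14},
            {"radius": 5.0, "pitch": -180.0, "sequence": "A" * 14},
        ]}
        spec = spec_from_json(json.dumps(doc))
        assert spec.helices[0].radius == 5.0

    def test_malformed_json(self):
        with pytest.raises(ValidationError, match="malformed"):
            spec_from_json("{not json")


class TestPromotion:
    def test_basic_to_advanced_preserves_model(self, canonical_dimer_spec):
        """Re-declaring a basic spec as advanced (parameters carried over
        unchanged) must build bit-identical coordinates."""
        promoted = AssemblySpec(mode="advanced", fold="coiled_coil",
                                oligomer_state=2,
                                helices=list(canonical_dimer_spec.helices))
        m_basic, _ = build_assembly(canonical_dimer_spec)
        m_adv, _ = build_assembly(promoted)
        assert rmsd(m_basic, m_adv) == 0.0
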