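"""Repeat segmentation, internal two-fold analysis, and binding-mode verdicts."""

import numpy as np
import pytest

from cohdoc.calcium import detect_calcium_sites
from cohdoc.errors import FingerprintError, GenerationError
from cohdoc.geometry import rmsd_unfitted
from cohdoc.interface import interface_report
from cohdoc.pipeline import analyze_complex
from cohdoc.secondary import assign_secondary_structure
from cohdoc.structure import Chain, chain_sequence
from cohdoc.symmetry import (
    DOC1A_FRAME_SEQUENCE,
    RepeatSegmentation,
    assess_dual_binding,
    build_rotated_model,
    internal_symmetry_superpose,
    map_symmetry_mates,
    segment_repeats,
    sequence_fingerprint,
)
from cohdoc.synthetic import (
    DockerinSpec,
    make_asymmetric_dockerin,
    make_cohesin_plateau,
    make_symmetric_dockerin,
)

from conftest import make_beta_hairpin, make_ideal_helix


def analysis_pieces(structure):
    chain = structure.chain("D")
    ss = assign_secondary_structure(chain)
    sites = detect_calcium_sites(structure, chain)
    seg = segment_repeats(chain, sites, ss)
    sup = internal_symmetry_superpose(chain, seg)
    return chain, ss, sites, seg, sup


class TestSegmentation:
    def test_symmetric_fixture_gives_equal_repeats(self, symmetric_dockerin):
        chain, _, _, seg, _ = analysis_pieces(symmetric_dockerin)
        len1 = seg.repeat1[1] - seg.repeat1[0]
        len2 = seg.repeat2[1] - seg.repeat2[0]
        assert len1 == len2
        assert seg.helix1[0] >= seg.repeat1[0] and seg.helix1[1] <= seg.repeat1[1]
        assert seg.helix3[0] >= seg.repeat2[0] and seg.helix3[1] <= seg.repeat2[1]
        assert not seg.low_confidence

    def test_linker_lies_between_repeats(self, symmetric_dockerin):
        _, _, _, seg, _ = analysis_pieces(symmetric_dockerin)
        assert seg.repeat1[1] < seg.linker[0] <= seg.linker[1] < seg.repeat2[0]

    def test_without_two_sites_falls_back_to_midpoint(self, symmetric_dockerin):
        chain = symmetric_dockerin.chain("D")
        ss = assign_secondary_structure(chain)
        seg = segment_repeats(chain, [], ss)
        assert seg.low_confidence
        assert seg.repeat1[1] < seg.repeat2[0]

    def test_longer_linker_spec_reports_longer_linker(self):
        short = DockerinSpec()
        long = DockerinSpec(linker_length=8)
        seg_s = analysis_pieces(make_symmetric_dockerin(short))[3]
        seg_l = analysis_pieces(make_symmetric_dockerin(long))[3]
        assert seg_l.linker_length > seg_s.linker_length


class TestInternalSuperposition:
    def test_exactly_duplicated_repeats_superpose_as_a_two_fold(
        self, symmetric_dockerin
    ):
        _, _, _, _, sup = analysis_pieces(symmetric_dockerin)
        assert sup.rmsd < 0.1
        assert sup.transform.angle_degrees == pytest.approx(180.0, abs=1.0)

    def test_unrelated_folds_give_large_rmsd(self):
        helix = make_ideal_helix(16, chain_id="D")
        hairpin = make_beta_hairpin(8)
        merged = Chain("D", [])
        for k, res in enumerate(helix.residues):
            res.auth_number = 1 + k
            merged.residues.append(res)
        for k, res in enumerate(hairpin.residues):
            res.auth_number = 40 + k
            res.atoms = [a for a in res.atoms]
            merged.residues.append(res)
        seg = RepeatSegmentation(
            repeat1=(1, 16), repeat2=(40, 55),
            helix1=(1, 16), helix2=None, helix3=(40, 55), linker=None,
        )
        sup = internal_symmetry_superpose(merged, seg)
        assert sup.rmsd > 2.0


class TestRotatedModel:
    def test_two_fold_idempotence(self, symmetric_dockerin):
        chain, _, _, _, sup = analysis_pieces(symmetric_dockerin)
        once = build_rotated_model(chain, sup.transform)
        twice = build_rotated_model(once, sup.transform)
        P = np.array([r.atom("CA").position for r in chain.polymer_residues()])
        Q = np.array([r.atom("CA").position for r in twice.polymer_residues()])
        assert rmsd_unfitted(P, Q) < 0.2

    def test_rotation_preserves_sequence_and_atom_count(self, symmetric_dockerin):
        chain, _, _, _, sup = analysis_pieces(symmetric_dockerin)
        rotated = build_rotated_model(chain, sup.transform)
        assert chain_sequence(rotated) == chain_sequence(chain)
        assert sum(len(r.atoms) for r in rotated.residues) == sum(
            len(r.atoms) for r in chain.residues
        )

    def test_paired_atoms_overlay_at_the_internal_rmsd(self, symmetric_dockerin):
        chain, _, _, _, sup = analysis_pieces(symmetric_dockerin)
        moved, target = [], []
        for (auth2, _n2, atom2), (auth1, _n1, atom1) in sup.pairing:
            moved.append(sup.transform.apply(chain.residue(auth2).atom(atom2).position))
            target.append(chain.residue(auth1).atom(atom1).position)
        assert rmsd_unfitted(np.array(moved), np.array(target)) == pytest.approx(
            sup.rmsd, abs=1e-9
        )


class TestMateMapping:
    def test_symmetric_fixture_all_pairs_conserved(self, symmetric_dockerin):
        chain, _, _, seg, sup = analysis_pieces(symmetric_dockerin)
        mates = map_symmetry_mates(seg, sup, chain)
        assert mates
        assert all(p.compatibility == "conserved" for p in mates)

    def test_nonpolar_to_polar_substitution_maps_incompatible(self):
        structure = make_asymmetric_dockerin(DockerinSpec(substitutions=[(17, "Q")]))
        chain, _, _, seg, sup = analysis_pieces(structure)
        mates = map_symmetry_mates(seg, sup, chain)
        changed = [
            p for p in mates
            if p.position_name == "VAL" and p.mate_name == "GLN"
        ]
        assert len(changed) == 1
        assert changed[0].compatibility == "incompatible"

    def test_within_class_substitution_maps_compatible(self):
        structure = make_asymmetric_dockerin(DockerinSpec(substitutions=[(13, "V")]))
        chain, _, _, seg, sup = analysis_pieces(structure)
        mates = map_symmetry_mates(seg, sup, chain)
        changed = [p for p in mates if p.position_name == "ILE" and p.mate_name == "VAL"]
        assert changed and changed[0].compatibility == "compatible"


def full_verdict(doc_structure, spec):
    complex_ = make_cohesin_plateau(doc_structure, spec)
    return analyze_complex(complex_, "D", "C")["verdict"]


class TestVerdicts:
    def test_symmetric_dockerin_is_dual_mode(self, symmetric_dockerin, default_spec):
        assert full_verdict(symmetric_dockerin, default_spec) == "dual"

    def test_substituted_contact_mate_flips_to_single(self):
        spec = DockerinSpec(substitutions=[(17, "Q")])
        assert full_verdict(make_asymmetric_dockerin(spec), spec) == "single"

    def test_compatible_substitution_keeps_dual(self):
        spec = DockerinSpec(substitutions=[(13, "V")])
        assert full_verdict(make_asymmetric_dockerin(spec), spec) == "dual"

    def test_empty_interface_is_indeterminate(self, symmetric_dockerin, default_spec):
        complex_ = make_cohesin_plateau(symmetric_dockerin, default_spec,
                                        translate=20.0)
        report = analyze_complex(complex_, "D", "C")
        assert report["verdict"] == "indeterminate"

    def test_making_incompatible_pairs_conserved_never_flips_dual_to_single(self):
        spec = DockerinSpec(substitutions=[(17, "Q")])
        structure = make_asymmetric_dockerin(spec)
        chain, _, _, seg, sup = analysis_pieces(structure)
        complex_ = make_cohesin_plateau(structure, spec)
        report = interface_report(
            complex_, "D", "C", helix_ranges=seg.helix_ranges
        )
        mates = map_symmetry_mates(
            seg, sup, chain, contact_positions=report.contact_residues("D")
        )
        base = assess_dual_binding(chain, report, mates, seg, sup).verdict
        assert base == "single"
        for pair in mates:
            if pair.compatibility == "incompatible":
                pair.compatibility = "conserved"
        relaxed = assess_dual_binding(chain, report, mates, seg, sup).verdict
        assert relaxed == "dual"


class TestGeneratorGrid:
    @pytest.mark.parametrize(
        "new_residue, expected",
        [
            ("Q", "single"),   # polar vs nonpolar Val
            ("D", "single"),   # negative
            ("K", "single"),   # positive
            ("S", "single"),   # polar
            ("A", "dual"),     # nonpolar
            ("L", "dual"),
            ("F", "dual"),
            ("M", "dual"),
        ],
    )
    def test_contact_mate_substitutions_classify_perfectly(
        self, new_residue, expected
    ):
        spec = DockerinSpec(substitutions=[(17, new_residue)])
        structure = make_asymmetric_dockerin(spec)
        assert full_verdict(structure, spec) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_verdicts_stable_under_coordinate_jitter(self, seed):
        jitter = 0.3 * (seed % 5 + 1) / 5.0  # 0.06 .. 0.30 Å
        sym_spec = DockerinSpec(coordinate_jitter=jitter, seed=seed)
        assert full_verdict(make_symmetric_dockerin(sym_spec), sym_spec) == "dual"
        asym_spec = DockerinSpec(
            substitutions=[(17, "Q")], coordinate_jitter=jitter, seed=seed
        )
        assert full_verdict(make_asymmetric_dockerin(asym_spec), asym_spec) == "single"


class TestFingerprint:
    def test_reference_frame_reads_ile39_val43(self):
        fp = sequence_fingerprint(DOC1A_FRAME_SEQUENCE)
        assert fp.position_11 == "I"
        assert fp.position_15 == "V"
        assert fp.nonpolar_pass
        assert fp.helix1_positions[19] == "Q"
        assert fp.helix3_positions[55] == "Q"

    def test_polar_residue_at_15_fails_the_nonpolar_check(self):
        seq = DOC1A_FRAME_SEQUENCE[:14] + "Q" + DOC1A_FRAME_SEQUENCE[15:]
        fp = sequence_fingerprint(seq)
        assert fp.position_15 == "Q"
        assert not fp.nonpolar_pass

    def test_nonpolar_substitution_at_11_still_passes(self):
        seq = DOC1A_FRAME_SEQUENCE[:10] + "M" + DOC1A_FRAME_SEQUENCE[11:]
        fp = sequence_fingerprint(seq)
        assert fp.position_11 == "M"
        assert fp.nonpolar_pass

    def test_low_coverage_raises(self):
        with pytest.raises(FingerprintError):
            sequence_fingerprint("AAAA")


class TestSpecValidation:
    def test_symmetric_generator_rejects_substitutions(self):
        with pytest.raises(GenerationError):
            make_symmetric_dockerin(DockerinSpec(substitutions=[(17, "Q")]))

    def test_asymmetric_generator_requires_substitutions(self):
        with pytest.raises(GenerationError):
            make_asymmetric_dockerin(DockerinSpec())

    def test_unknown_residue_code_rejected(self):
        with pytest.raises(GenerationError):
            DockerinSpec(substitutions=[(17, "Z")])

    def test_out_of_range_position_rejected(self):
        with pytest.raises(GenerationError):
            DockerinSpec(substitutions=[(99, "Q")])
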