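"""Docking metrics: superposition, contacts, DockQ, atomic accuracy,
TM-score and the simplified secondary-structure assignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepdock.dockmetrics import (
    assign_secondary_structure, atomic_accuracy, categorize_dockq, dockq,
    native_contacts, peptide_rmsd_after_protein_alignment, superpose_kabsch,
    tm_score,
)
from pepdock.structio import select_atoms
from pepdock.synthgen import (
    PerturbationSpec, ToyComplexSpec, _build_chain, _transform_chain,
    make_toy_complex, perturb_prediction,
)
from .oracles import oracle_dockq, oracle_tm_score, scipy_superpose


class TestSuperposition:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        sup = superpose_kabsch(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_translation_recovered(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        sup = superpose_kabsch(pts, pts + [5.0, 0.0, 0.0])
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.translation, [-5.0, 0.0, 0.0], atol=1e-9)

    def test_matches_independent_scipy_fit(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            ref = rng.normal(size=(10, 3)) * 5
            axis = rng.normal(size=3)
            angle = rng.uniform(0, np.pi)
            from scipy.spatial.transform import Rotation
            mov = ref @ Rotation.from_rotvec(axis / np.linalg.norm(axis) * angle).as_matrix()
            mov += rng.normal(0, 0.3, size=mov.shape)
            _, oracle_rmsd = scipy_superpose(ref, mov)
            assert superpose_kabsch(ref, mov).rmsd == pytest.approx(oracle_rmsd, abs=1e-3)

    def test_collinear_rejected(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError, match="degenerate"):
            superpose_kabsch(line, line + 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            superpose_kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestContacts:
    def test_distant_peptide_has_no_contacts(self, helix_complex):
        import copy
        far = copy.deepcopy(helix_complex)
        _transform_chain(far.peptide, np.eye(3), np.array([0.0, 50.0, 0.0]))
        assert len(native_contacts(far)) == 0

    def test_matches_brute_force_enumeration(self, helix_complex):
        from .oracles import _residue_contacts
        assert native_contacts(helix_complex).pairs == frozenset(
            _residue_contacts(helix_complex)
        )

    def test_monotone_in_cutoff(self, helix_complex):
        small = native_contacts(helix_complex, 4.0).pairs
        large = native_contacts(helix_complex, 6.0).pairs
        assert small <= large


class TestDockQ:
    def test_self_comparison_is_exactly_one(self, helix_complex):
        result = dockq(helix_complex, helix_complex)
        assert result.score == 1.0
        assert result.category == "high"
        assert result.fnat == 1.0

    def test_score_formula_consistent_with_components(self, helix_complex):
        pred = perturb_prediction(helix_complex, PerturbationSpec(translation=3.0, seed=4))
        r = dockq(helix_complex, pred)
        expected = (
            r.fnat + 1 / (1 + (r.irmsd / 1.5) ** 2) + 1 / (1 + (r.lrmsd / 8.5) ** 2)
        ) / 3
        assert r.score == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_independent_oracle(self, helix_complex, seed):
        spec = PerturbationSpec(
            translation=float(seed), rotation=10.0 * seed,
            internal_noise_sigma=0.1 * seed, seed=seed,
        )
        pred = perturb_prediction(helix_complex, spec)
        assert dockq(helix_complex, pred).score == pytest.approx(
            oracle_dockq(helix_complex, pred), abs=1e-3
        )

    def test_no_native_contacts_is_an_error(self, helix_complex):
        import copy
        far = copy.deepcopy(helix_complex)
        _transform_chain(far.peptide, np.eye(3), np.array([0.0, 80.0, 0.0]))
        with pytest.raises(ValueError, match="no inter-chain contacts"):
            dockq(far, far)

    def test_monotone_under_growing_translation(self, helix_complex):
        scores = []
        for t in (0.0, 1.0, 2.0, 4.0, 8.0, 16.0):
            pred = perturb_prediction(helix_complex, PerturbationSpec(translation=t, seed=9))
            scores.append(dockq(helix_complex, pred).score)
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestCategories:
    @pytest.mark.parametrize("score,expected", [
        (0.10, "poor"), (0.2299, "poor"), (0.23, "acceptable"), (0.30, "acceptable"),
        (0.49, "acceptable"), (0.4901, "medium"), (0.80, "medium"),
        (0.8001, "high"), (0.85, "high"), (1.0, "high"),
    ])
    def test_boundaries(self, score, expected):
        assert categorize_dockq(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_dockq(1.2)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=200, derandomize=True)
    def test_category_consistent_with_thresholds(self, score):
        cat = categorize_dockq(score)
        assert cat == ("poor" if score < 0.23 else "acceptable" if score <= 0.49
                       else "medium" if score <= 0.80 else "high")


class TestPeptideRmsd:
    def test_identity_is_zero(self, helix_complex):
        assert peptide_rmsd_after_protein_alignment(
            helix_complex, helix_complex
        ) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("t", [1.0, 4.0])
    def test_rigid_translation_recovered_exactly(self, helix_complex, t):
        pred = perturb_prediction(helix_complex, PerturbationSpec(translation=t, seed=3))
        assert peptide_rmsd_after_protein_alignment(
            helix_complex, pred
        ) == pytest.approx(t, abs=1e-6)

    def test_rotated_peptide_matches_per_atom_formula(self, helix_complex):
        pred = perturb_prediction(helix_complex, PerturbationSpec(rotation=25.0, seed=5))
        nat = select_atoms(helix_complex.peptide, "backbone").coords
        # receptor untouched by the perturbation, so the aligning transform is
        # the identity and the direct per-atom evaluation needs no fit
        mov = select_atoms(pred.peptide, "backbone").coords
        direct = math.sqrt(float(np.mean(np.sum((mov - nat) ** 2, axis=1))))
        assert peptide_rmsd_after_protein_alignment(
            helix_complex, pred
        ) == pytest.approx(direct, abs=1e-6)


class TestAtomicAccuracy:
    def test_identity_passes(self, helix_complex):
        r = atomic_accuracy(helix_complex, helix_complex)
        assert r.passed and r.clash_count == 0 and r.fnat == 1.0

    def test_translated_peptide_fails(self, helix_complex):
        pred = perturb_prediction(helix_complex, PerturbationSpec(translation=5.0, seed=6))
        r = atomic_accuracy(helix_complex, pred)
        assert not r.passed
        assert r.peptide_allatom_rmsd >= 2.0

    def test_clash_detected_when_peptide_pushed_into_receptor(self, helix_complex):
        import copy
        pred = copy.deepcopy(helix_complex)
        # drive the peptide straight through the interface
        _transform_chain(pred.peptide, np.eye(3), np.array([0.0, -4.0, 0.0]))
        r = atomic_accuracy(helix_complex, pred)
        assert r.clash_count > 0 and not r.passed

    @pytest.mark.parametrize("seed", range(4))
    def test_passed_flag_consistent_with_components(self, helix_complex, seed):
        pred = perturb_prediction(
            helix_complex,
            PerturbationSpec(translation=0.5 * seed, internal_noise_sigma=0.05 * seed,
                             seed=seed),
        )
        r = atomic_accuracy(helix_complex, pred)
        assert r.passed == (
            r.fnat > 0.9 and r.clash_count == 0
            and r.peptide_allatom_rmsd < 2.0 and r.interface_allatom_rmsd < 3.0
        )


class TestTmScore:
    def test_identical_chains_score_one(self, helix_complex):
        assert tm_score(helix_complex.receptor, helix_complex.receptor) == pytest.approx(1.0)

    def test_invariant_under_rigid_motion(self, helix_complex):
        import copy
        from scipy.spatial.transform import Rotation
        moved = copy.deepcopy(helix_complex)
        rot = Rotation.from_euler("xyz", [0.4, -0.8, 1.2]).as_matrix()
        _transform_chain(moved.receptor, rot, np.array([10.0, -5.0, 3.0]))
        assert tm_score(helix_complex.receptor, moved.receptor) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("sigma", [0.5, 1.5])
    def test_agrees_with_multistart_optimisation_oracle(self, helix_complex, sigma):
        import copy
        rng = np.random.default_rng(int(sigma * 10))
        pred = copy.deepcopy(helix_complex)
        for res in pred.receptor.residues:
            for atom in res.atoms:
                atom.coords = atom.coords + rng.normal(0, sigma, 3)
        ours = tm_score(helix_complex.receptor, pred.receptor)
        nat = select_atoms(helix_complex.receptor, "CA").coords
        prd = select_atoms(pred.receptor, "CA").coords
        assert ours == pytest.approx(oracle_tm_score(nat, prd), abs=0.02)

    def test_too_short_chain_rejected(self):
        chain = _build_chain("AA", [(-60.0, -45.0)] * 2, "A", "receptor")
        with pytest.raises(ValueError):
            tm_score(chain, chain)


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_h(self):
        chain = _build_chain("A" * 10, [(-60.0, -45.0)] * 10, "A", "receptor")
        labels = assign_secondary_structure(chain).labels
        assert labels == "L" + "H" * 8 + "L"

    def test_ideal_strand_interior_is_e(self):
        chain = _build_chain("A" * 10, [(-120.0, 135.0)] * 10, "A", "receptor")
        labels = assign_secondary_structure(chain).labels
        assert labels == "L" + "E" * 8 + "L"

    def test_alternating_dihedrals_break_runs(self):
        dihedrals = [(-60.0, -45.0), (-120.0, 135.0)] * 5
        chain = _build_chain("A" * 10, dihedrals, "A", "receptor")
        assert assign_secondary_structure(chain).labels == "L" * 10

    def test_label_length_matches_chain(self, strand_complex):
        labels = assign_secondary_structure(strand_complex.receptor).labels
        assert len(labels) == len(strand_complex.receptor)
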