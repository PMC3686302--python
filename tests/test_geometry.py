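"""Superposition, TM-score, and functional-labeling rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metathread as mt
from metathread.geometry import _fes_stoichiometry

from conftest import random_rotation


def quaternion_rmsd(moving, fixed):
    """Independent minimal-RMSD oracle via the quaternion characteristic polynomial.

    The optimal superposition RMSD is sqrt((G_a + G_b - 2 lambda_max) / n)
    where lambda_max is the largest eigenvalue of the 4x4 key matrix built
    from the covariance of the centered point sets.
    """
    m = moving - moving.mean(axis=0)
    f = fixed - fixed.mean(axis=0)
    r = m.T @ f
    key = np.array(
        [
            [r[0, 0] + r[1, 1] + r[2, 2], r[1, 2] - r[2, 1], r[2, 0] - r[0, 2], r[0, 1] - r[1, 0]],
            [r[1, 2] - r[2, 1], r[0, 0] - r[1, 1] - r[2, 2], r[0, 1] + r[1, 0], r[0, 2] + r[2, 0]],
            [r[2, 0] - r[0, 2], r[0, 1] + r[1, 0], -r[0, 0] + r[1, 1] - r[2, 2], r[1, 2] + r[2, 1]],
            [r[0, 1] - r[1, 0], r[0, 2] + r[2, 0], r[1, 2] + r[2, 1], -r[0, 0] - r[1, 1] + r[2, 2]],
        ]
    )
    lam = np.linalg.eigvalsh(key).max()
    val = ((m**2).sum() + (f**2).sum() - 2.0 * lam) / len(m)
    return math.sqrt(max(val, 0.0))


class TestKabsch:
    def test_identity_case(self, rng):
        pts = rng.normal(size=(8, 3))
        sup = mt.kabsch_superpose(pts, pts)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(sup.translation, 0.0, atol=1e-12)
        assert sup.rmsd < 1e-12

    def test_recovers_exact_rigid_motion(self, rng):
        pts = rng.normal(size=(12, 3))
        theta = np.pi / 2
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = pts @ rot.T + np.array([5.0, 0.0, 0.0])
        sup = mt.kabsch_superpose(pts, moved)
        assert sup.rmsd < 1e-9
        assert np.allclose(sup.apply(pts), moved, atol=1e-9)
        assert np.allclose(sup.rotation, rot, atol=1e-9)

    def test_matches_quaternion_oracle_under_noise(self, rng):
        pts = rng.normal(size=(10, 3)) * 5.0
        moved = pts @ random_rotation(rng).T + rng.uniform(-10, 10, 3)
        moved += rng.normal(0.0, 0.5, size=moved.shape)
        sup = mt.kabsch_superpose(pts, moved)
        assert sup.rmsd == pytest.approx(quaternion_rmsd(pts, moved), abs=1e-9)

    def test_rotation_proper_orthogonal_even_for_reflection_bait(self, rng):
        pts = rng.normal(size=(20, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])  # improper image
        sup = mt.kabsch_superpose(pts, mirrored)
        assert np.allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_beats_random_rigid_transforms(self, rng):
        moving = rng.normal(size=(15, 3)) * 4.0
        fixed = moving @ random_rotation(rng).T + rng.normal(0, 1, size=(15, 3))
        best = mt.kabsch_superpose(moving, fixed).rmsd
        for _ in range(1000):
            rot = random_rotation(rng)
            trans = rng.uniform(-5, 5, 3)
            rmsd = np.sqrt(((moving @ rot.T + trans - fixed) ** 2).sum() / len(moving))
            assert best <= rmsd + 1e-12

    @pytest.mark.parametrize(
        "moving, fixed",
        [
            (np.zeros((2, 3)), np.zeros((2, 3))),  # too few pairs
            (np.c_[np.arange(5.0), np.zeros(5), np.zeros(5)],) * 2,  # collinear
        ],
    )
    def test_degenerate_inputs_rejected(self, moving, fixed):
        with pytest.raises(ValueError):
            mt.kabsch_superpose(moving, fixed)


class TestTmScore:
    def test_perfect_superposition_scores_one(self):
        assert mt.tm_score([0.0] * 50, 50) == pytest.approx(1.0)

    def test_all_distances_at_d0_score_half(self):
        d0 = 1.24 * (50 - 15) ** (1 / 3) - 1.8
        assert mt.tm_score([d0] * 50, 50) == pytest.approx(0.5)

    def test_d0_formula_and_floor(self):
        assert mt.geometry.tm_d0(20) == pytest.approx(
            max(0.5, 1.24 * 5 ** (1 / 3) - 1.8)
        )
        assert mt.geometry.tm_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8)
        assert mt.geometry.tm_d0(10) == 0.5  # formula is negative here

    def test_invariant_under_joint_rigid_motion(self, rng):
        a = rng.normal(size=(40, 3)) * 5.0
        b = a + rng.normal(0.0, 1.0, size=a.shape)
        d_before = np.linalg.norm(a - b, axis=1)
        rot, trans = random_rotation(rng), rng.uniform(-10, 10, 3)
        d_after = np.linalg.norm((a @ rot.T + trans) - (b @ rot.T + trans), axis=1)
        assert abs(mt.tm_score(d_before, 40) - mt.tm_score(d_after, 40)) < 1e-9

    def test_errors(self):
        with pytest.raises(ValueError):
            mt.tm_score([], 10)
        with pytest.raises(ValueError):
            mt.tm_score([1.0] * 11, 10)


class TestOptimizeTmSuperposition:
    def test_identical_structures_score_one(self):
        s = mt.make_toy_structure(50, "helix", seed=1)
        pairs = [(i, i) for i in range(50)]
        sup = mt.optimize_tm_superposition(s, s, pairs)
        assert sup.tm_score == pytest.approx(1.0)

    def test_displaced_loop_beats_all_pair_kabsch(self):
        target = mt.make_toy_structure(50, "helix", seed=2)
        tpl_xyz = target.ca_coords.copy()
        tpl_xyz[20:25] += np.array([20.0, 0.0, 0.0])  # one 20 A displaced loop
        template = mt.Structure(id="loop", residues=list(target.residues), ca_coords=tpl_xyz)
        pairs = [(i, i) for i in range(50)]
        sup = mt.optimize_tm_superposition(template, target, pairs)
        plain = mt.kabsch_superpose(tpl_xyz, target.ca_coords)
        d_plain = np.linalg.norm(plain.apply(tpl_xyz) - target.ca_coords, axis=1)
        assert sup.tm_score > mt.tm_score(d_plain, 50)

    def test_unrelated_structures_score_below_threshold(self):
        below = 0
        for trial in range(100):
            a = mt.make_toy_structure(50, "coil", seed=trial)
            b = mt.make_toy_structure(50, "coil", seed=10_000 + trial)
            sup = mt.optimize_tm_superposition(a, b, [(i, i) for i in range(50)])
            below += sup.tm_score < mt.TM_SCORE_THRESHOLD
        assert below >= 95


class TestSequenceIdentity:
    def nw_identity_oracle(self, a, b):
        """Exhaustive DP with the same scoring (BLOSUM62, -11/-1 affine gaps)."""
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        neg = -1e9
        n, m = len(a), len(b)
        M = np.full((n + 1, m + 1), neg)
        X = np.full((n + 1, m + 1), neg)  # gap in b
        Y = np.full((n + 1, m + 1), neg)  # gap in a
        M[0, 0] = 0.0
        for i in range(1, n + 1):
            X[i, 0] = -11.0 - (i - 1) * 1.0
        for j in range(1, m + 1):
            Y[0, j] = -11.0 - (j - 1) * 1.0
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                s = blosum[a[i - 1], b[j - 1]]
                M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
                X[i, j] = max(M[i - 1, j] - 11.0, X[i - 1, j] - 1.0)
                Y[i, j] = max(M[i, j - 1] - 11.0, Y[i, j - 1] - 1.0)
        # traceback for identity count and alignment length
        best = max(M[n, m], X[n, m], Y[n, m])
        # recover one optimal path
        i, j, state = n, m, int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
        ident = cols = 0
        while i > 0 or j > 0:
            if state == 0 and i > 0 and j > 0:
                s = blosum[a[i - 1], b[j - 1]]
                prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
                state_next = int(np.argmax(prev))
                ident += a[i - 1] == b[j - 1]
                cols += 1
                i, j, state = i - 1, j - 1, state_next
            elif state == 1 and i > 0:
                state = 0 if abs(X[i, j] - (M[i - 1, j] - 11.0)) < 1e-9 else 1
                cols += 1
                i -= 1
            else:
                state = 0 if abs(Y[i, j] - (M[i, j - 1] - 11.0)) < 1e-9 else 2
                cols += 1
                j -= 1
        return best, 100.0 * ident / cols

    def test_identical_sequences(self):
        assert mt.sequence_identity("ACDEFG", "ACDEFG") == 100.0

    def test_no_identities(self):
        assert mt.sequence_identity("AAAA", "CCCC") == 0.0

    def test_symmetric_and_self_identity(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        s = "".join(rng.choice(list(aas), size=30))
        assert mt.sequence_identity(s, s) == 100.0
        t = "".join(rng.choice(list(aas), size=25))
        assert mt.sequence_identity(s, t) == pytest.approx(mt.sequence_identity(t, s))

    def test_matches_dp_oracle_with_deletion(self):
        a, b = "ACDEFGHIK", "ACDFGHIK"
        _, expected = self.nw_identity_oracle(a, b)
        assert mt.sequence_identity(a, b) == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mt.sequence_identity("", "ACD")


class TestPartnerDistance:
    def test_coincident_and_direct(self):
        ident = mt.kabsch_superpose(np.eye(3), np.eye(3))
        assert mt.min_partner_distance([[0, 0, 0]], [[0, 0, 0]], ident) == pytest.approx(0.0, abs=1e-12)
        assert mt.min_partner_distance([[0, 0, 0]], [[2, 0, 0]], ident) == pytest.approx(2.0)

    def test_matches_brute_force_minimum(self, rng):
        ident = mt.kabsch_superpose(np.eye(3), np.eye(3))
        for n in (5, 20, 50):
            a = rng.normal(size=(n, 3)) * 10
            b = rng.normal(size=(n, 3)) * 10
            brute = min(np.linalg.norm(p - q) for p in a for q in b)
            assert mt.min_partner_distance(a, b, ident) == pytest.approx(brute, abs=1e-9)

    def test_applies_superposition(self, rng):
        rot, trans = random_rotation(rng), np.array([3.0, -1.0, 2.0])
        sup = mt.Superposition(rotation=rot, translation=trans, pairs=[], rmsd=0.0)
        tpl = rng.normal(size=(4, 3))
        tgt = tpl @ rot.T + trans
        assert mt.min_partner_distance(tpl, tgt, sup) < 1e-9


class TestLocationRule:
    @pytest.mark.parametrize(
        "aspect, tm, dist, expected",
        [
            (mt.BindingAspect.METAL, 0.5, 1.5, True),
            (mt.BindingAspect.LIGAND, 0.35, 1.0, False),   # TM below 0.4
            (mt.BindingAspect.DNA, 0.6, 6.5, False),       # distance above 6
            (mt.BindingAspect.LIGAND, 0.4, 4.0, True),     # both thresholds inclusive
            (mt.BindingAspect.METAL, 0.4, 2.0, True),
            (mt.BindingAspect.METAL, 0.4, 2.01, False),
            (mt.BindingAspect.FE_S, 0.9, 3.0, True),
            (mt.BindingAspect.FE_S, 0.9, 3.01, False),
            (mt.BindingAspect.PROTEIN, 0.4, 6.0, True),
            (mt.BindingAspect.PROTEIN, 0.39999, 6.0, False),
            (mt.BindingAspect.DNA, 0.4, 6.0, True),
        ],
    )
    def test_threshold_grid(self, aspect, tm, dist, expected):
        assert mt.evaluate_location(aspect, tm, dist) is expected

    @given(
        tm_lo=st.floats(0.4, 1.0),
        tm_hi=st.floats(0.0, 0.6),
        dist=st.floats(0.0, 10.0),
        shrink=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_tm_and_distance(self, tm_lo, tm_hi, dist, shrink):
        for aspect in mt.BindingAspect:
            # decreasing distance never flips true -> false
            if mt.evaluate_location(aspect, tm_lo, dist):
                assert mt.evaluate_location(aspect, tm_lo, dist * shrink)
            # increasing TM never flips true -> false
            thr = mt.DISTANCE_THRESHOLDS[aspect]
            if mt.evaluate_location(aspect, tm_hi, min(dist, thr)):
                assert mt.evaluate_location(aspect, min(tm_hi + 0.3, 1.0), min(dist, thr))


class TestTanimoto:
    def test_identical_disjoint_and_half(self):
        a = np.zeros(1024, bool)
        a[:10] = True
        assert mt.tanimoto(a, a) == 1.0
        b = np.zeros(1024, bool)
        b[10:20] = True
        assert mt.tanimoto(a, b) == 0.0
        c = np.zeros(1024, bool)
        c[:5] = True  # |A|=5
        d = np.zeros(1024, bool)
        d[2:6] = True  # |B|=4, overlap {2,3,4} = 3 -> 3/6
        assert mt.tanimoto(c, d) == pytest.approx(0.5)
        assert mt.tanimoto(c, d) >= mt.TANIMOTO_THRESHOLD

    @given(st.lists(st.booleans(), min_size=8, max_size=64))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, bits):
        a = np.array(bits)
        b = np.roll(a, 3)
        if not (a | b).any():
            return
        tc = mt.tanimoto(a, b)
        assert tc == pytest.approx(mt.tanimoto(b, a))
        assert 0.0 <= tc <= 1.0

    def test_all_zero_pair_rejected(self):
        z = np.zeros(16, bool)
        with pytest.raises(ValueError):
            mt.tanimoto(z, z)


class TestNucleotideComposition:
    @pytest.mark.parametrize(
        "seq, expected",
        [("ATATAT", "AT_RICH"), ("GCGCGC", "GC_RICH"), ("ATGC", "BALANCED"), ("atgcA", "AT_RICH")],
    )
    def test_classes(self, seq, expected):
        assert mt.classify_nucleotide_composition(seq) == expected

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            mt.classify_nucleotide_composition("ATGN")


class TestInterfaces:
    def test_distant_chains_have_empty_interface(self):
        a = mt.make_toy_structure(20, "strand", seed=1)
        b_xyz = a.ca_coords + np.array([0.0, 100.0, 0.0])
        b = mt.Structure(id="b", residues=list(a.residues), ca_coords=b_xyz)
        assert mt.extract_interface(a, b, 8.0) == frozenset()

    def test_parallel_strands_fully_interfacial(self):
        a = mt.make_toy_structure(15, "strand", seed=1)
        b_xyz = a.ca_coords + np.array([0.0, 5.0, 0.0])
        b = mt.Structure(id="b", residues=list(a.residues), ca_coords=b_xyz)
        assert mt.extract_interface(a, b, 8.0) == frozenset(range(15))

    def test_matches_brute_force_scan(self, rng):
        a = mt.make_toy_structure(30, "coil", seed=5)
        b = mt.make_toy_structure(25, "coil", seed=6)
        expected = frozenset(
            i
            for i in range(30)
            if any(np.linalg.norm(a.ca_coords[i] - q) <= 8.0 for q in b.ca_coords)
        )
        assert mt.extract_interface(a, b, 8.0) == expected

    def test_overlap_score_fixture(self):
        ident = mt.Superposition(
            rotation=np.eye(3), translation=np.zeros(3),
            pairs=[(i, i) for i in range(10)], rmsd=0.0,
        )
        target_if = {0, 1, 2, 3}
        assert mt.interface_overlap_score(target_if, target_if, ident) == 1.0
        assert mt.interface_overlap_score(target_if, set(), ident) == 0.0
        assert mt.interface_overlap_score(target_if, {0, 1}, ident) == 0.5
        with pytest.raises(ValueError):
            mt.interface_overlap_score(set(), {1}, ident)


class TestFeaturesRule:
    def metal(self, element):
        return mt.BoundPartner(
            aspect=mt.BindingAspect.METAL, atoms=[[0, 0, 0]], element=element
        )

    def test_metal_identity(self):
        assert mt.evaluate_features(mt.BindingAspect.METAL, self.metal("Zn"), self.metal("Zn"))
        assert not mt.evaluate_features(mt.BindingAspect.METAL, self.metal("Zn"), self.metal("Cu"))

    @pytest.mark.parametrize(
        "score, expected", [(0.191, True), (0.3, True), (0.19, False), (0.0, False)]
    )
    def test_protein_interface_score_inclusive(self, score, expected):
        p = mt.BoundPartner(aspect=mt.BindingAspect.PROTEIN, atoms=[[0, 0, 0]])
        assert mt.evaluate_features(mt.BindingAspect.PROTEIN, p, p, score) is expected

    @pytest.mark.parametrize(
        "tc, expected", [(0.5, True), (0.6, True), (0.45, False)]
    )
    def test_ligand_tanimoto_threshold(self, tc, expected):
        fa, fb = mt.simulate_fingerprint_pair(1024, tc, seed=9)
        pa = mt.BoundPartner(aspect=mt.BindingAspect.LIGAND, atoms=[[0, 0, 0]], fingerprint=fa)
        pb = mt.BoundPartner(aspect=mt.BindingAspect.LIGAND, atoms=[[0, 0, 0]], fingerprint=fb)
        assert mt.evaluate_features(mt.BindingAspect.LIGAND, pa, pb) is expected

    @pytest.mark.parametrize(
        "at_a, at_b, expected",
        [(0.8, 0.7, True), (0.2, 0.3, True), (0.8, 0.2, False), (0.5, 0.5, False)],
    )
    def test_dna_composition_match_balanced_matches_nothing(self, at_a, at_b, expected):
        pa = mt.BoundPartner(
            aspect=mt.BindingAspect.DNA, atoms=[[0, 0, 0]], sequence=mt.simulate_dna(20, at_a, 1)
        )
        pb = mt.BoundPartner(
            aspect=mt.BindingAspect.DNA, atoms=[[0, 0, 0]], sequence=mt.simulate_dna(20, at_b, 2)
        )
        assert mt.evaluate_features(mt.BindingAspect.DNA, pa, pb) is expected

    def test_fes_stoichiometry_rule(self):
        fe2s2 = mt.BoundPartner(aspect=mt.BindingAspect.FE_S, atoms=np.zeros((4, 3)), name="FES")
        fe4s4 = mt.BoundPartner(aspect=mt.BindingAspect.FE_S, atoms=np.zeros((8, 3)), name="SF4")
        assert _fes_stoichiometry(fe2s2) == (2, 2)
        assert _fes_stoichiometry(fe4s4) == (4, 4)
        assert mt.evaluate_features(mt.BindingAspect.FE_S, fe2s2, fe2s2)
        assert not mt.evaluate_features(mt.BindingAspect.FE_S, fe2s2, fe4s4)

    def test_aspect_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mt.evaluate_features(mt.BindingAspect.METAL, self.metal("Zn"),
                                 mt.BoundPartner(aspect=mt.BindingAspect.LIGAND, atoms=[[0, 0, 0]]))


class TestLabelTemplate:
    def test_self_template_is_doubly_positive(self, zinc_target):
        lab = mt.label_template(
            zinc_target, zinc_target.het_groups[0], zinc_target, zinc_target.het_groups[0]
        )
        assert lab.location_positive and lab.features_positive
        assert lab.tm_score == pytest.approx(1.0)
        assert lab.partner_distance == pytest.approx(0.0)

    def test_distant_partner_breaks_location(self, zinc_target):
        template, _, _ = mt.make_template_from_target(
            zinc_target, coord_noise_sd=0.2, partner_shift=20.0, rigid_seed=11
        )
        lab = mt.label_template(
            zinc_target, zinc_target.het_groups[0], template, template.het_groups[0]
        )
        assert lab.tm_score >= mt.TM_SCORE_THRESHOLD
        assert not lab.location_positive

    def test_location_true_features_false_for_wrong_metal(self, zinc_target):
        template, _, _ = mt.make_template_from_target(
            zinc_target, coord_noise_sd=0.2, partner_shift=0.0, rigid_seed=12
        )
        template.het_groups[0].element = "Fe"
        lab = mt.label_template(
            zinc_target, zinc_target.het_groups[0], template, template.het_groups[0]
        )
        assert lab.location_positive
        assert not lab.features_positive
        assert lab.metal_match is False


class TestDatasetFilters:
    def test_chain_length_window(self):
        metal = mt.BoundPartner(aspect=mt.BindingAspect.METAL, atoms=[[0, 0, 0]], element="Zn")
        assert not mt.passes_dataset_filters(mt.make_toy_structure(49, seed=1), metal)
        assert mt.passes_dataset_filters(mt.make_toy_structure(50, seed=1), metal)
        assert mt.passes_dataset_filters(mt.make_toy_structure(600, seed=1), metal)
        assert not mt.passes_dataset_filters(mt.make_toy_structure(601, seed=1), metal)

    def test_ligand_heavy_atom_window_and_covalency(self):
        s = mt.make_toy_structure(100, seed=2)
        small = mt.BoundPartner(aspect=mt.BindingAspect.LIGAND, atoms=np.zeros((6, 3)))
        ok = mt.BoundPartner(aspect=mt.BindingAspect.LIGAND, atoms=np.zeros((7, 3)))
        big = mt.BoundPartner(aspect=mt.BindingAspect.LIGAND, atoms=np.zeros((61, 3)))
        covalent = mt.BoundPartner(
            aspect=mt.BindingAspect.LIGAND, atoms=np.zeros((10, 3)), covalent=True
        )
        assert not mt.passes_dataset_filters(s, small)
        assert mt.passes_dataset_filters(s, ok)
        assert not mt.passes_dataset_filters(s, big)
        assert not mt.passes_dataset_filters(s, covalent)

    def test_partner_specific_rules(self):
        s = mt.make_toy_structure(300, seed=3)
        assert mt.passes_dataset_filters(
            s, mt.BoundPartner(aspect=mt.BindingAspect.PROTEIN, atoms=np.zeros((30, 3)),
                               interface_residues=frozenset(range(25))))
        assert not mt.passes_dataset_filters(
            s, mt.BoundPartner(aspect=mt.BindingAspect.PROTEIN, atoms=np.zeros((30, 3)),
                               interface_residues=frozenset(range(19))))
        assert mt.passes_dataset_filters(
            s, mt.BoundPartner(aspect=mt.BindingAspect.DNA, atoms=np.zeros((30, 3)),
                               sequence="ATGCATGCAT"))
        assert not mt.passes_dataset_filters(
            s, mt.BoundPartner(aspect=mt.BindingAspect.DNA, atoms=np.zeros((30, 3)),
                               sequence="ATGCATGCA"))
        assert not mt.passes_dataset_filters(
            s, mt.BoundPartner(aspect=mt.BindingAspect.METAL, atoms=[[0, 0, 0]], element="Ni"))
        assert mt.passes_dataset_filters(
            s, mt.BoundPartner(aspect=mt.BindingAspect.FE_S, atoms=np.zeros((4, 3)), name="FES"))
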