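"""Anchor bonds, chain matching, template alignment, topomer placement,
pose perturbation, rigid-body RMS."""

import numpy as np
import pytest
from rdkit import Chem
from scipy.spatial.transform import Rotation

from tcomfa import chem_io
from tcomfa.alignment import (
    TemplateAligner,
    enumerate_anchor_bonds,
    match_chains,
    randomize_pose,
    rigid_fit_rms,
    separate_templates,
    topomer_place,
)
from tcomfa.chem_io import embed_3d

from conftest import mol


class TestAnchorBonds:
    def test_methane_has_none(self):
        assert enumerate_anchor_bonds(mol("C")) == []

    def test_ethylbenzene_oriented_acyclic_anchors(self):
        anchors = enumerate_anchor_bonds(mol("CCc1ccccc1"))
        # two acyclic heavy-heavy single bonds, both orientations
        assert len(anchors) == 4
        assert all((j, i) in anchors for i, j in anchors)

    def test_benzene_falls_back_to_ring_bonds(self):
        anchors = enumerate_anchor_bonds(mol("c1ccccc1"))
        assert len(anchors) == 12

    def test_deterministic_order(self):
        m = mol("CCOc1ccccc1")
        assert enumerate_anchor_bonds(m) == enumerate_anchor_bonds(m)


class TestMatchChains:
    def test_identity_match_covers_all_heavy_atoms(self):
        m = mol("CCOc1ccc(Cl)cc1")
        anchor = enumerate_anchor_bonds(m)[0]
        match = match_chains(m, m, anchor, anchor)
        assert match.matched_count == m.GetNumHeavyAtoms()
        assert match.mapping == {i: i for i in match.mapping}

    def test_extra_methyl_stays_unmatched(self):
        template = mol("CCc1ccccc1")
        candidate = mol("CCc1ccccc1C")  # template plus one methyl
        t_anchor = enumerate_anchor_bonds(template)[0]
        c_anchor = t_anchor  # same atom numbering for the shared core
        match = match_chains(candidate, template, c_anchor, t_anchor)
        assert match.matched_count == template.GetNumHeavyAtoms()

    def test_topology_only_matching_counts_element_identity_separately(self):
        template = mol("CCO")
        candidate = mol("CCN")
        match = match_chains(candidate, template, (0, 1), (0, 1))
        assert match.matched_count == 3
        assert match.element_identical_count(candidate, template) == 2

    def test_mapping_is_injective_and_anchored(self, small_series):
        templates, mols = small_series
        t = templates[0]
        for m in mols[:5]:
            ca = enumerate_anchor_bonds(m)[0]
            ta = enumerate_anchor_bonds(t)[0]
            match = match_chains(m, t, ca, ta)
            assert len(set(match.mapping.values())) == len(match.mapping)
            assert match.mapping[ca[0]] == ta[0]
            assert match.mapping[ca[1]] == ta[1]


class TestAlignToTemplates:
    def test_self_alignment_reproduces_template_coordinates(self, small_series):
        templates, _ = small_series
        aligner = TemplateAligner(templates)
        for t in templates:
            two_d = Chem.MolFromSmiles(Chem.MolToSmiles(Chem.RemoveHs(t)))
            res = aligner.align(two_d, seed=0)
            assert res.ok
            t_heavy = chem_io.coordinates(t, heavy_only=True)
            a_heavy = chem_io.coordinates(res.mol, heavy_only=True)
            # matched heavy atoms carry copied coordinates: compare as sets
            # via nearest-distance (atom numbering differs between the two)
            d = np.linalg.norm(a_heavy[:, None] - t_heavy[None, :], axis=2)
            assert d.min(axis=1).max() <= 1e-6

    def test_larger_shared_core_wins(self):
        big = embed_3d(mol("CCc1ccc2ccccc2c1", "big"), seed=1)
        small = embed_3d(mol("CCCC", "small"), seed=1)
        aligner = TemplateAligner([small, big])
        res = aligner.align(mol("CCc1ccc2ccccc2c1O"), seed=1)
        assert res.ok
        assert res.template_id == "big"

    def test_single_heavy_atom_candidate_fails(self, aligner):
        res = aligner.align(mol("C"), seed=0)
        assert not res.ok

    def test_matched_and_topomer_atoms_partition_heavy_atoms(self, aligner, small_series):
        _, mols = small_series
        for m in mols[:6]:
            res = aligner.align(m, seed=0)
            assert res.ok
            heavy = {a.GetIdx() for a in res.mol.GetAtoms() if a.GetAtomicNum() > 1}
            assert set(res.matched_atoms) | set(res.topomer_atoms) == heavy
            assert set(res.matched_atoms) & set(res.topomer_atoms) == set()

    def test_matched_count_monotone_in_template_set(self, small_series):
        templates, mols = small_series
        one = TemplateAligner(templates[:1])
        all_three = TemplateAligner(templates)
        for m in mols[:6]:
            m1 = one.best_match(m)
            m3 = all_three.best_match(m)
            assert m3.matched_count >= m1.matched_count


class TestTopomerPlace:
    def test_nothing_to_place_is_identity(self):
        m = embed_3d(mol("CCO"), seed=1)
        heavy = Chem.RemoveHs(m)
        before = chem_io.coordinates(heavy)
        out, placed = topomer_place(heavy, set(range(heavy.GetNumAtoms())), ref_mol=m)
        assert placed == []
        np.testing.assert_array_equal(chem_io.coordinates(out), before)

    def test_repeated_invocation_bit_identical(self):
        m = Chem.RemoveHs(embed_3d(mol("CCCCc1ccccc1"), seed=1))
        placed = {a.GetIdx() for a in m.GetAtoms() if a.GetIsAromatic()}
        out1, _ = topomer_place(Chem.Mol(m), set(placed))
        out2, _ = topomer_place(Chem.Mol(m), set(placed))
        np.testing.assert_array_equal(chem_io.coordinates(out1), chem_io.coordinates(out2))

    def test_equivalent_roots_get_identical_local_geometry(self):
        # p-dipropylbenzene: ring placed, both propyl chains topomer-placed;
        # expressed in each root's own frame the chains must coincide
        m = Chem.RemoveHs(embed_3d(mol("CCCc1ccc(CCC)cc1"), seed=1))
        ring = {a.GetIdx() for a in m.GetAtoms() if a.GetIsAromatic()}
        out, _ = topomer_place(Chem.Mol(m), set(ring))
        xyz = chem_io.coordinates(out)
        ranks = list(Chem.CanonicalRankAtoms(out, breakTies=True))
        chains = []
        for root in sorted(ring):
            chain = _attached_chain(out, root, ring)
            if chain:
                chains.append(_local_chain_coords(out, root, chain, ring, xyz, ranks))
        assert len(chains) == 2
        np.testing.assert_allclose(chains[0], chains[1], atol=1e-9)

    def test_independent_of_unplaced_input_coordinates(self):
        m = Chem.RemoveHs(embed_3d(mol("CCCCc1ccccc1"), seed=1))
        placed = {a.GetIdx() for a in m.GetAtoms() if a.GetIsAromatic()}
        ref = embed_3d(Chem.Mol(m), seed=0)
        scrambled = Chem.Mol(m)
        conf = scrambled.GetConformer()
        from rdkit.Geometry import Point3D

        for i in range(scrambled.GetNumAtoms()):
            if i not in placed:
                conf.SetAtomPosition(i, Point3D(99.0 + i, -99.0, 42.0))
        out1, _ = topomer_place(Chem.Mol(m), set(placed), ref_mol=ref)
        out2, _ = topomer_place(scrambled, set(placed), ref_mol=ref)
        np.testing.assert_array_equal(chem_io.coordinates(out1), chem_io.coordinates(out2))

    def test_disconnected_remainder_raises(self):
        m = Chem.RemoveHs(embed_3d(mol("CC.OO", "frag"), seed=1))
        # keep only one fragment placed: the other has no placed neighbor
        with pytest.raises(ValueError):
            topomer_place(m, {0, 1}, ref_mol=None)


def _attached_chain(m, root, ring):
    """Chain atoms hanging off ``root``, in BFS order from the root."""
    out = []
    frontier = [n.GetIdx() for n in m.GetAtomWithIdx(root).GetNeighbors()
                if n.GetIdx() not in ring and n.GetAtomicNum() > 1]
    seen = set(frontier)
    while frontier:
        a = frontier.pop(0)
        out.append(a)
        for n in m.GetAtomWithIdx(a).GetNeighbors():
            i = n.GetIdx()
            if i not in seen and i not in ring and n.GetAtomicNum() > 1:
                seen.add(i)
                frontier.append(i)
    return out


def _local_chain_coords(m, root, chain, ring, xyz, ranks):
    """Chain coordinates in the root's canonical frame: origin at the root,
    x toward the root from its preferred (lowest-rank) placed neighbor b,
    z along the normal of the (a, b, root) plane."""
    nbs = sorted((n.GetIdx() for n in m.GetAtomWithIdx(root).GetNeighbors()
                  if n.GetIdx() in ring), key=lambda i: ranks[i])
    b = nbs[0]
    b_nbs = sorted((n.GetIdx() for n in m.GetAtomWithIdx(b).GetNeighbors()
                    if n.GetIdx() in ring and n.GetIdx() != root),
                   key=lambda i: ranks[i])
    a = b_nbs[0]
    x = xyz[root] - xyz[b]
    x /= np.linalg.norm(x)
    ab = xyz[b] - xyz[a]
    n = np.cross(ab, x)
    n /= np.linalg.norm(n)
    mvec = np.cross(n, x)
    frame = np.column_stack([x, mvec, n])
    return (xyz[chain] - xyz[root]) @ frame


class TestSeparateTemplates:
    def test_single_template_unchanged(self, small_series):
        templates, _ = small_series
        (out,) = separate_templates(templates[:1], min_gap=3.0)
        np.testing.assert_array_equal(
            chem_io.coordinates(out), chem_io.coordinates(templates[0])
        )

    def test_overlapping_copies_pushed_apart(self):
        benzene = embed_3d(mol("c1ccccc1"), seed=1)
        out = separate_templates([benzene, Chem.Mol(benzene)], min_gap=3.0)
        a = chem_io.coordinates(out[0], heavy_only=True)
        b = chem_io.coordinates(out[1], heavy_only=True)
        assert np.linalg.norm(a[:, None] - b[None, :], axis=2).min() >= 3.0

    def test_intramolecular_geometry_rigid(self, small_series):
        templates, _ = small_series
        out = separate_templates(templates, min_gap=3.0)
        for before, after in zip(templates, out):
            xa = chem_io.coordinates(before)
            xb = chem_io.coordinates(after)
            da = np.linalg.norm(xa[:, None] - xa[None, :], axis=2)
            db = np.linalg.norm(xb[:, None] - xb[None, :], axis=2)
            np.testing.assert_allclose(da, db, atol=1e-9)


class TestRandomizePose:
    def test_deterministic_per_seed(self):
        m = embed_3d(mol("CCCCOc1ccccc1"), seed=2)
        a = randomize_pose(m, seed=9)
        b = randomize_pose(m, seed=9)
        np.testing.assert_array_equal(chem_io.coordinates(a), chem_io.coordinates(b))

    def test_bond_lengths_preserved(self):
        m = embed_3d(mol("CCCCOc1ccccc1"), seed=2)
        out = randomize_pose(m, seed=9)
        xyz0, xyz1 = chem_io.coordinates(m), chem_io.coordinates(out)
        for bond in m.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            d0 = np.linalg.norm(xyz0[i] - xyz0[j])
            d1 = np.linalg.norm(xyz1[i] - xyz1[j])
            assert abs(d0 - d1) < 1e-6

    def test_heavy_atom_centroid_at_origin(self):
        m = embed_3d(mol("CCCCOc1ccccc1"), seed=2)
        out = randomize_pose(m, seed=9)
        centroid = chem_io.coordinates(out, heavy_only=True).mean(axis=0)
        np.testing.assert_allclose(centroid, 0.0, atol=1e-9)

    def test_changes_conformation(self):
        m = embed_3d(mol("CCCCOc1ccccc1"), seed=2)
        out = randomize_pose(m, seed=9)
        assert not np.allclose(chem_io.coordinates(m), chem_io.coordinates(out))


class TestRigidFitRMS:
    def test_identical_sets_give_zero(self, rng):
        a = rng.normal(size=(10, 3))
        assert rigid_fit_rms(a, a.copy()) == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_gives_zero(self, rng):
        a = rng.normal(size=(10, 3))
        assert rigid_fit_rms(a, a + np.array([5.0, 5.0, 5.0])) == pytest.approx(0.0, abs=1e-9)

    def test_rotated_translated_copy_gives_zero(self, rng):
        a = rng.normal(size=(10, 3))
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        assert rigid_fit_rms(a, a @ R.T + 2.5) == pytest.approx(0.0, abs=1e-9)

    def test_perturbed_set_matches_independent_oracle(self, rng):
        a = rng.normal(size=(10, 3)) * 3.0
        b = a.copy()
        b[4, 0] += 1.0  # one atom displaced 1 Å along x
        R = Rotation.from_euler("zyx", [0.7, 0.2, -0.5]).as_matrix()
        b = b @ R.T + np.array([1.0, -2.0, 0.5])
        # independent superposition oracle: quaternion-based align_vectors
        rot, _ = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
        resid = (b - b.mean(0)) @ rot.as_matrix().T - (a - a.mean(0))
        oracle = np.sqrt(np.mean(np.sum(resid**2, axis=1)))
        assert rigid_fit_rms(a, b) == pytest.approx(oracle, abs=1e-6)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            rigid_fit_rms(np.zeros((2, 3)), np.zeros((2, 3)))
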