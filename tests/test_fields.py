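"""Lattice regions, field evaluation, column pretreatment."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import RWMol
from rdkit.Geometry import Point3D

from tcomfa import chem_io
from tcomfa.fields import (
    COULOMB_KCAL,
    VDW_PARAMS,
    FieldPretreater,
    FieldTable,
    Probe,
    Region,
    build_region,
    compute_fields,
    field_table,
    trim_region,
)


def atom_at(symbol: str, xyz, charge: float = 0.0) -> Chem.Mol:
    """Single free atom with an explicit position and partial charge."""
    em = RWMol()
    a = Chem.Atom(symbol)
    a.SetNoImplicit(True)
    em.AddAtom(a)
    m = em.GetMol()
    conf = Chem.Conformer(1)
    conf.SetAtomPosition(0, Point3D(*xyz))
    m.AddConformer(conf)
    m.GetAtomWithIdx(0).SetProp("_GasteigerCharge", str(charge))
    return m


def lj_closed_form(r: float, r_star_atom: float, eps_atom: float, probe: Probe) -> float:
    rij = r_star_atom + probe.r_star
    eij = np.sqrt(eps_atom * probe.epsilon)
    return eij * ((rij / r) ** 12 - 2.0 * (rij / r) ** 6)


class TestRegion:
    def test_single_atom_margin_2_spacing_2_gives_27_points(self):
        m = atom_at("C", (0.0, 0.0, 0.0))
        region = build_region([m], margin=2.0, spacing=2.0)
        assert region.counts == (3, 3, 3)
        assert region.n_total == 27
        np.testing.assert_array_equal(region.origin, [-2.0, -2.0, -2.0])

    def test_zero_margin_single_point(self):
        m = atom_at("C", (0.0, 0.0, 0.0))
        region = build_region([m], margin=0.0, spacing=2.0)
        assert region.counts == (1, 1, 1)

    def test_union_monotonicity(self):
        a = atom_at("C", (0.0, 0.0, 0.0))
        b = atom_at("C", (7.0, 1.0, -3.0))
        ra = build_region([a])
        rboth = build_region([a, b])
        lo_a, hi_a = ra.origin, ra.origin + (np.array(ra.counts) - 1) * ra.spacing
        lo_u, hi_u = rboth.origin, rboth.origin + (np.array(rboth.counts) - 1) * rboth.spacing
        assert np.all(lo_u <= lo_a) and np.all(hi_u >= hi_a)

    def test_outermost_points_at_or_beyond_box_faces(self):
        m = atom_at("C", (0.3, 0.0, 0.0))
        region = build_region([m], margin=2.0, spacing=2.0)
        atom = np.array([0.3, 0.0, 0.0])
        hi = region.origin + (np.array(region.counts) - 1) * region.spacing
        assert np.all(region.origin <= atom - 2.0 + 1e-9)
        assert np.all(hi >= atom + 2.0 - 1e-9)

    def test_no_molecule_raises(self):
        with pytest.raises(ValueError):
            build_region([])


class TestTrimRegion:
    def test_full_box_trim_is_identity(self):
        region = Region(np.zeros(3), 2.0, (3, 3, 3))
        out = trim_region(region, keep_lo=(0, 0, 0), keep_hi=(4, 4, 4))
        assert out.n_retained == 27

    def test_trim_to_central_point(self):
        region = Region(np.zeros(3), 2.0, (3, 3, 3))
        out = trim_region(region, keep_lo=(2, 2, 2), keep_hi=(2, 2, 2))
        assert out.n_retained == 1
        np.testing.assert_array_equal(out.points(), [[2.0, 2.0, 2.0]])

    def test_field_table_columns_track_retained_points(self):
        region = Region(np.zeros(3), 2.0, (3, 3, 3))
        trimmed = trim_region(region, keep_lo=(0, 0, 0), keep_hi=(2, 2, 2))
        m = atom_at("C", (1.0, 1.0, 1.0))
        table = field_table([m], trimmed)
        assert table.X.shape[1] == 2 * trimmed.n_retained

    def test_empty_trim_raises(self):
        region = Region(np.zeros(3), 2.0, (3, 3, 3))
        with pytest.raises(ValueError):
            trim_region(region, keep_lo=(99, 99, 99))


class TestComputeFields:
    def test_steric_matches_lj_closed_form_at_4A(self):
        m = atom_at("C", (0.0, 0.0, 0.0))
        region = Region(np.array([4.0, 0.0, 0.0]), 1.0, (1, 1, 1))
        steric, elec = compute_fields(m, region)
        r_star, eps = VDW_PARAMS["C"]
        expected = lj_closed_form(4.0, r_star, eps, Probe())
        assert steric[0] == pytest.approx(expected, abs=1e-9)

    def test_point_inside_atom_hits_cap_exactly(self):
        m = atom_at("C", (0.0, 0.0, 0.0))
        region = Region(np.array([0.1, 0.0, 0.0]), 1.0, (1, 1, 1))
        steric, elec = compute_fields(m, region, steric_cutoff=30.0)
        assert steric[0] == 30.0
        assert np.isnan(elec[0])  # flagged for imputation

    def test_neutral_atom_has_zero_electrostatics(self):
        m = atom_at("C", (0.0, 0.0, 0.0), charge=0.0)
        region = Region(np.array([4.0, 0.0, 0.0]), 1.0, (1, 1, 1))
        _, elec = compute_fields(m, region)
        assert elec[0] == 0.0

    def test_coulomb_closed_form(self):
        m = atom_at("O", (0.0, 0.0, 0.0), charge=-0.4)
        region = Region(np.array([5.0, 0.0, 0.0]), 1.0, (1, 1, 1))
        _, elec = compute_fields(m, region)
        # distance-dependent dielectric eps(r) = r gives q/r^2
        assert elec[0] == pytest.approx(COULOMB_KCAL * (-0.4) / 25.0, abs=1e-9)

    def test_two_atom_field_is_sum_of_single_atom_fields(self):
        a = atom_at("C", (0.0, 0.0, 0.0), charge=0.2)
        b = atom_at("N", (3.0, 0.0, 0.0), charge=-0.2)
        em = RWMol()
        for sym in ("C", "N"):
            at = Chem.Atom(sym)
            at.SetNoImplicit(True)
            em.AddAtom(at)
        both = em.GetMol()
        conf = Chem.Conformer(2)
        conf.SetAtomPosition(0, Point3D(0.0, 0.0, 0.0))
        conf.SetAtomPosition(1, Point3D(3.0, 0.0, 0.0))
        both.AddConformer(conf)
        both.GetAtomWithIdx(0).SetProp("_GasteigerCharge", "0.2")
        both.GetAtomWithIdx(1).SetProp("_GasteigerCharge", "-0.2")
        region = Region(np.array([6.0, 1.0, 0.0]), 1.0, (2, 1, 1))
        sa, ea = compute_fields(a, region)
        sb, eb = compute_fields(b, region)
        sab, eab = compute_fields(both, region)
        np.testing.assert_allclose(sab, sa + sb, atol=1e-9)
        np.testing.assert_allclose(eab, ea + eb, atol=1e-9)

    def test_translation_equivariance(self):
        m = atom_at("C", (0.5, -0.25, 1.0), charge=0.3)
        shift = np.array([8.0, -4.0, 2.0])
        m2 = atom_at("C", tuple(np.array([0.5, -0.25, 1.0]) + shift), charge=0.3)
        r1 = Region(np.array([3.0, 1.0, 0.0]), 2.0, (2, 2, 2))
        r2 = Region(np.array([3.0, 1.0, 0.0]) + shift, 2.0, (2, 2, 2))
        s1, e1 = compute_fields(m, r1)
        s2, e2 = compute_fields(m2, r2)
        np.testing.assert_allclose(s1, s2, atol=1e-9)
        np.testing.assert_allclose(e1, e2, atol=1e-9)

    def test_missing_charges_raise(self):
        m = chem_io.embed_3d(Chem.MolFromSmiles("CC"), seed=1)
        region = Region(np.zeros(3), 2.0, (2, 2, 2))
        with pytest.raises(ValueError):
            compute_fields(m, region)


def _toy_table(X):
    n_pts = X.shape[1] // 2
    region = Region(np.zeros(3), 2.0, (n_pts, 1, 1))
    return FieldTable(X, region, [str(i) for i in range(X.shape[0])])


class TestPretreat:
    def test_constant_column_dropped(self, rng):
        X = rng.normal(scale=5.0, size=(10, 4))
        X[:, 1] = 7.0
        pt = FieldPretreater(min_sigma=2.0, scaling="none").fit(_toy_table(X))
        assert not pt.keep_[1]

    def test_centering_only_when_no_scaling(self, rng):
        X = rng.normal(scale=5.0, size=(12, 6))
        pt = FieldPretreater(min_sigma=0.0, scaling="none").fit(_toy_table(X))
        out = pt.transform(X)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0), X.std(axis=0), atol=1e-9)

    def test_comfa_std_equalizes_block_variance(self, rng):
        X = np.hstack(
            [rng.normal(scale=8.0, size=(15, 3)), rng.normal(scale=2.5, size=(15, 3))]
        )
        pt = FieldPretreater(min_sigma=0.0, scaling="comfa-std").fit(_toy_table(X))
        out = pt.transform(X)
        steric_var = out[:, pt.blocks_ == "s"].var(axis=0, ddof=1).sum()
        elec_var = out[:, pt.blocks_ == "e"].var(axis=0, ddof=1).sum()
        assert steric_var == pytest.approx(elec_var, abs=1e-9)

    def test_flagged_cells_imputed_with_training_column_mean(self, rng):
        X = rng.normal(scale=5.0, size=(8, 4))
        X[2, 3] = np.nan
        table = _toy_table(X)
        pt = FieldPretreater(min_sigma=0.0, scaling="none").fit(table)
        col_mean = np.nanmean(X[:, 3])
        out = pt.transform(X)
        assert pt.keep_.all()
        assert out[2, 3] == pytest.approx(col_mean - pt.center_[3])

    def test_prediction_rows_use_training_parameters(self, rng):
        X_train = rng.normal(scale=5.0, size=(10, 4))
        X_new = rng.normal(loc=3.0, scale=5.0, size=(5, 4))
        pt = FieldPretreater(min_sigma=0.0, scaling="none").fit(_toy_table(X_train))
        out = pt.transform(X_new)
        # centered with TRAINING means: new rows keep their own offset
        np.testing.assert_allclose(
            out, X_new - X_train.mean(axis=0), atol=1e-12
        )

    def test_all_columns_dropped_raises(self):
        X = np.ones((5, 4))
        with pytest.raises(ValueError):
            FieldPretreater(min_sigma=2.0).fit(_toy_table(X))

    def test_single_row_raises(self):
        with pytest.raises(ValueError):
            FieldPretreater().fit(_toy_table(np.ones((1, 4))))
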