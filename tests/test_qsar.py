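import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hit2lead.chem_io import Compound
from hit2lead.qsar import (
    CHANNELS,
    FieldPLS,
    GridSpec,
    align_rigid,
    compute_fields,
    cross_validate,
    descriptor_matrix,
    f_statistic,
    field_maps,
    fit_pls,
    kabsch,
    pic50,
)
from hit2lead.synthetic import gen_qsar


class TestPic50:
    @pytest.mark.parametrize(
        "ic50, expected",
        [(1e-6, 6.0), (2.5e-6, 5.60206), (1.0, 0.0)],
    )
    def test_values(self, ic50, expected):
        assert pic50(ic50) == pytest.approx(expected, abs=1e-5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pic50(0.0)


def _random_compound(rng, cid="c", n=8):
    xyz = rng.normal(scale=2.0, size=(n, 3))
    conf = [("C", *map(float, p)) for p in xyz]
    return Compound(cid, "C" * n, conformer=conf)


class TestAlignment:
    def test_rigid_motion_recovered_to_machine_precision(self):
        rng = np.random.default_rng(0)
        ref = _random_compound(rng, "ref")
        R = Rotation.random(random_state=1).as_matrix()
        t = np.array([3.0, -1.0, 2.0])
        moved = Compound(
            "m", ref.smiles,
            conformer=[(e, *(R @ np.array([x, y, z]) + t)) for e, x, y, z in ref.conformer],
        )
        mapping = [[(i, i) for i in range(8)]]
        aligned = align_rigid([moved], ref, mapping)
        assert aligned.rmsds[0] <= 1e-6

    def test_reflection_forces_proper_rotation(self):
        # mirrored 4-point set cannot be superposed by any proper rotation
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 3.0]])
        mirrored = pts * np.array([1, 1, -1.0])
        R, t = kabsch(mirrored, pts)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        rmsd = np.sqrt(np.mean(np.sum((mirrored @ R.T + t - pts) ** 2, axis=1)))
        # brute-force over many random proper rotations confirms this is minimal
        best = np.inf
        for rs in range(500):
            Q = Rotation.random(random_state=rs).as_matrix()
            qc = mirrored - mirrored.mean(axis=0)
            moved = qc @ Q.T + pts.mean(axis=0)
            best = min(best, np.sqrt(np.mean(np.sum((moved - pts) ** 2, axis=1))))
        assert rmsd > 0
        assert rmsd <= best + 1e-9

    def test_already_aligned_gives_identity_transform(self):
        rng = np.random.default_rng(2)
        ref = _random_compound(rng, "ref")
        aligned = align_rigid([ref], ref, [[(i, i) for i in range(8)]])
        new = np.array([[x, y, z] for _e, x, y, z in aligned.compounds[0].conformer])
        old = np.array([[x, y, z] for _e, x, y, z in ref.conformer])
        assert np.allclose(new, old, atol=1e-10)

    def test_fewer_than_three_mapped_atoms_rejected(self):
        rng = np.random.default_rng(3)
        ref = _random_compound(rng, "ref")
        with pytest.raises(ValueError, match="3 mapped"):
            align_rigid([ref], ref, [[(0, 0), (1, 1)]])

    def test_common_rigid_motion_invariance(self):
        # applying one rigid motion to reference and all compounds leaves
        # the aligned geometry (relative to the reference) unchanged
        rng = np.random.default_rng(4)
        ref = _random_compound(rng, "ref")
        comp = _random_compound(rng, "c")
        mapping = [[(i, i) for i in range(8)]]
        a1 = align_rigid([comp], ref, mapping)
        R = Rotation.random(random_state=9).as_matrix()
        t = np.array([1.0, 2.0, 3.0])

        def move(c):
            return Compound(
                c.id, c.smiles,
                conformer=[(e, *(R @ np.array([x, y, z]) + t)) for e, x, y, z in c.conformer],
            )

        a2 = align_rigid([move(comp)], move(ref), mapping)
        assert a1.rmsds[0] == pytest.approx(a2.rmsds[0], abs=1e-9)


class TestFields:
    def test_molecule_without_donors_has_zero_donor_channel(self):
        comp = Compound(
            "alkane", "CCCC",
            conformer=[("C", 1.5 * i, 0.0, 0.0) for i in range(4)],
        )
        fg = compute_fields([comp], spacing=2.0)[0]
        assert np.all(fg.channels["donor"] == 0)
        assert fg.channels["hydrophobic"].max() > 0

    def test_donor_channel_matches_bruteforce_gaussian_sum(self):
        from rdkit import Chem

        from hit2lead.pharmacophore import embed_compound

        meoh = embed_compound(Compound("m", "CO"))
        grid = GridSpec.enclosing([meoh], spacing=1.0, margin=3.0)
        fg = compute_fields([meoh], grid=grid, alpha=0.5)[0]
        # independent oracle: locate the hydroxyl H and sum the kernel by hand
        mol = Chem.AddHs(meoh.to_mol(with_coords=True), addCoords=True)
        h_pos = [
            np.array(mol.GetConformer().GetAtomPosition(nb.GetIdx()))
            for atom in mol.GetAtoms() if atom.GetSymbol() == "O"
            for nb in atom.GetNeighbors() if nb.GetSymbol() == "H"
        ]
        assert len(h_pos) == 1
        pts = grid.points()
        expected = np.exp(-0.5 * np.sum((pts - h_pos[0]) ** 2, axis=1))
        assert np.allclose(fg.channels["donor"], expected, atol=1e-12)

    def test_larger_alpha_decreases_off_center_values(self):
        comp = Compound("c", "CC", conformer=[("C", 0, 0, 0), ("C", 1.5, 0, 0)])
        grid = GridSpec.enclosing([comp], spacing=1.0, margin=3.0)
        lo = compute_fields([comp], grid=grid, alpha=0.5)[0].channels["hydrophobic"]
        hi = compute_fields([comp], grid=grid, alpha=1.0)[0].channels["hydrophobic"]
        assert np.all(hi <= lo + 1e-15)
        assert hi.sum() < lo.sum()

    def test_conformer_outside_grid_rejected(self):
        comp = Compound("c", "CC", conformer=[("C", 0, 0, 0), ("C", 50.0, 0, 0)])
        grid = GridSpec(origin=(-3, -3, -3), spacing=1.0, dims=(7, 7, 7))
        with pytest.raises(ValueError, match="outside"):
            compute_fields([comp], grid=grid)

    def test_field_order_matches_compound_order(self):
        ds = gen_qsar(3, n_compounds=6)
        fields = compute_fields(ds.compounds, grid=ds.grid)
        X = descriptor_matrix(fields)
        X_rev = descriptor_matrix(compute_fields(ds.compounds[::-1], grid=ds.grid))
        assert np.allclose(X, X_rev[::-1])


class TestFieldPLS:
    def test_single_descriptor_exact_fit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 1))
        y = 2.5 * X[:, 0] + 1.0
        m = FieldPLS(n_factors=1).fit(X, y)
        assert m.r2_ == pytest.approx(1.0, abs=1e-12)
        assert m.rmse_ == pytest.approx(0.0, abs=1e-9)

    def test_full_factor_pls_equals_least_squares_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(size=10)
        m = FieldPLS(n_factors=3).fit(X, y)
        beta = np.linalg.lstsq(np.column_stack([np.ones(10), X]), y, rcond=None)[0]
        assert np.max(np.abs(m.coefficients_ - beta[1:])) <= 1e-8
        assert abs(m.intercept_ - beta[0]) <= 1e-8

    def test_f_statistic_reproduces_printed_value(self):
        # r2 = 0.94, 4 factors, n = 39 -> 133.17, within 0.2% of 133.0
        assert f_statistic(0.94, 4, 39) == pytest.approx(133.0, rel=0.002)

    def test_under_determined_rejected(self):
        X = np.eye(4)
        with pytest.raises(ValueError, match="under-determined"):
            FieldPLS(n_factors=4).fit(X, np.arange(4.0))

    def test_degenerate_response_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="degenerate"):
            FieldPLS(n_factors=2).fit(X, np.ones(10))

    def test_constant_columns_dropped(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.normal(size=20), np.full(20, 7.0), rng.normal(size=20)])
        m = FieldPLS(n_factors=2).fit(X, X[:, 0] - X[:, 2])
        assert list(m.kept_columns_) == [0, 2]
        assert m.coefficients_[1] == 0.0

    def test_coefficient_recovery_when_identifiable(self):
        # p < n, full factors: PLS == OLS, so the planted coefficients are
        # recovered exactly from noiseless data
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 8))
        beta = np.zeros(8)
        beta[[1, 4, 6]] = [2.0, -1.0, 0.5]
        y = X @ beta
        m = FieldPLS(n_factors=8).fit(X, y)
        cos = (m.coefficients_ @ beta) / (
            np.linalg.norm(m.coefficients_) * np.linalg.norm(beta)
        )
        assert cos >= 0.99
        assert np.allclose(m.predict(X), y, atol=1e-8)

    def test_predict_dimension_checked(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 3))
        m = FieldPLS(n_factors=2).fit(X, X[:, 0])
        with pytest.raises(ValueError):
            m.predict(np.zeros((2, 5)))


class TestCrossValidate:
    def test_noiseless_linear_q2_is_essentially_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        y = X @ [1.0, 2.0, -1.0]
        rep = cross_validate(X, y, k=5, n_repeats=3, n_factors=3, seed=11)
        assert rep.q2 >= 0.999

    def test_pure_noise_q2_negative_in_expectation(self):
        rng = np.random.default_rng(1)
        q2s = []
        for s in range(60):
            X = rng.normal(size=(20, 5))
            y = rng.normal(size=20)
            q2s.append(cross_validate(X, y, k=5, n_repeats=2, n_factors=2, seed=s).q2)
        assert np.mean(q2s) < 0

    def test_q2_matches_bruteforce_fold_oracle(self):
        ds = gen_qsar(5, n_compounds=30, target_r2=0.9)
        X, y = ds.X, ds.y
        k, n_repeats, nf, seed = 5, 3, 4, 77
        rep = cross_validate(X, y, k=k, n_repeats=n_repeats, n_factors=nf, seed=seed)
        # explicit independent loop over the same seeded partitions
        rng = np.random.default_rng(seed)
        press = 0.0
        for _ in range(n_repeats):
            perm = rng.permutation(len(y))
            for i in range(0, len(y), k):
                fold = perm[i : i + k]
                train = np.setdiff1d(perm, fold)
                m = FieldPLS(n_factors=nf).fit(X[train], y[train])
                press += float(np.sum((y[fold] - m.predict(X[fold])) ** 2))
        q2_brute = 1.0 - press / (n_repeats * np.sum((y - y.mean()) ** 2))
        assert abs(rep.q2 - q2_brute) <= 1e-10

    def test_noiseless_generated_series_fits_and_generalizes(self):
        # the planted channel-level signal is captured by a 4-factor model
        # and predicts held-out compounds from the same series
        ds = gen_qsar(13, n_compounds=40)
        assert fit_pls(ds.X, ds.y, n_factors=4).r2_ >= 0.99
        assert fit_pls(ds.X, ds.y, n_factors=8).r2_ >= 0.995
        rep = cross_validate(ds.X, ds.y, k=5, n_repeats=3, n_factors=4, seed=2)
        assert rep.q2 >= 0.95

    def test_q2_not_above_training_r2(self):
        ds = gen_qsar(9, n_compounds=30, target_r2=0.9)
        rep = cross_validate(ds.X, ds.y, seed=5)
        r2 = fit_pls(ds.X, ds.y).r2_
        assert rep.q2 <= r2 + 1e-8

    def test_fold_size_validated(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            cross_validate(X, np.arange(4.0), k=4)


class TestFieldMaps:
    def test_export_has_one_row_per_point_and_channel(self):
        ds = gen_qsar(2, n_compounds=12)
        m = fit_pls(ds.X, ds.y)
        df = field_maps(m, ds.grid)
        assert len(df) == 4 * ds.grid.n_points
        assert set(df["channel"]) == set(CHANNELS)

    def test_favorable_region_has_positive_coefficient(self):
        # y built to increase with the hydrophobic channel: the summed
        # hydrophobic-channel coefficients must be positive
        ds = gen_qsar(4, n_compounds=20)
        w = ds.beta[ds.beta != 0][0]
        m = fit_pls(ds.X, ds.y)
        df = field_maps(m, ds.grid)
        total = df.loc[df["channel"] == "hydrophobic", "coefficient"].sum()
        assert np.sign(total) == np.sign(w)

    def test_unfitted_model_rejected(self):
        with pytest.raises(RuntimeError):
            field_maps(FieldPLS(), GridSpec((0, 0, 0), 1.0, (2, 2, 2)))
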