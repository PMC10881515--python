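"""Aggregation hierarchy, sphering, effect scores, effect bands."""

import numpy as np
import pandas as pd
import pytest

from morphoprof import (
    ProfileTable,
    aggregate_profiles,
    apply_sphering,
    cosine_similarity,
    effect_scores,
    fit_sphering,
    make_profile_table,
    select_effect_band,
)


def _cells_table(records):
    meta = pd.DataFrame(
        [r[0] for r in records],
        columns=["Metadata_Plate", "Metadata_Well", "Metadata_Site", "Treatment", "Control"],
    )
    feats = np.array([r[1] for r in records], dtype=float)
    return make_profile_table(feats, meta, level="cell")


class TestAggregation:
    def test_site_median_well_mean(self):
        t = _cells_table([
            (("P1", "A01", 1, "T1", False), (0, 0)),
            (("P1", "A01", 1, "T1", False), (2, 2)),
            (("P1", "A01", 1, "T1", False), (10, 10)),
            (("P1", "A01", 2, "T1", False), (4, 4)),
        ])
        site = aggregate_profiles(t, "site")
        assert sorted(map(tuple, site.features)) == [(2.0, 2.0), (4.0, 4.0)]
        well = aggregate_profiles(t, "well")
        np.testing.assert_allclose(well.features, [[3.0, 3.0]])

    def test_treatment_mean_over_wells(self):
        t = _cells_table([
            (("P1", "A01", 1, "T1", False), (2, 2)),
            (("P2", "A01", 1, "T1", False), (4, 4)),
            (("P1", "A02", 1, "DMSO", True), (0, 0)),
        ])
        tr = aggregate_profiles(t, "treatment")
        row = tr.data.set_index("Treatment").loc["T1"]
        assert (row[tr.feature_columns] == 3.0).all()

    def test_permutation_invariance(self, rng):
        records = [
            (("P1", "A01", s, "T1", False), tuple(rng.normal(size=3)))
            for s in (1, 1, 1, 2, 2)
        ]
        a = aggregate_profiles(_cells_table(records), "well").features
        b = aggregate_profiles(
            _cells_table([records[i] for i in rng.permutation(len(records))]), "well"
        ).features
        np.testing.assert_allclose(a, b)

    def test_matches_brute_force_on_random_input(self, rng):
        records = []
        for p in ("P1", "P2"):
            for w in ("A01", "A02"):
                for s in (1, 2):
                    for _ in range(rng.integers(1, 5)):
                        records.append(((p, w, s, "T1", False), tuple(rng.normal(size=2))))
        table = _cells_table(records)
        wells = aggregate_profiles(table, "well")
        for _, row in wells.data.iterrows():
            sites = {}
            for (meta, feat) in records:
                if meta[0] == row["Metadata_Plate"] and meta[1] == row["Metadata_Well"]:
                    sites.setdefault(meta[2], []).append(feat)
            expected = np.mean([np.median(v, axis=0) for v in sites.values()], axis=0)
            np.testing.assert_allclose(row[wells.feature_columns].to_numpy(dtype=float), expected)

    def test_na_wells_dropped_before_treatment_level(self):
        t = _cells_table([
            (("P1", "A01", 1, "T1", False), (2, 2)),
            (("P2", "A01", 1, "T1", False), (4, 4)),
        ])
        wells = aggregate_profiles(t, "well")
        wells.data.loc[0, wells.feature_columns[0]] = np.nan
        with pytest.warns(UserWarning, match="NA"):
            tr = aggregate_profiles(wells, "treatment")
        np.testing.assert_allclose(tr.features, [[4.0, 4.0]])


class TestSphering:
    def test_one_dimensional_hand_computation(self):
        X = np.array([[-1.0], [1.0]])
        assert fit_sphering(X, lam=0.0).Q[0, 0] == pytest.approx(1.0)
        assert fit_sphering(X, lam=3.0).Q[0, 0] == pytest.approx(0.5)

    def test_identity_covariance_gives_identity_Q(self, rng):
        # controls with exactly identity sample covariance (n in denominator)
        n, d = 200, 4
        X = rng.normal(size=(n, d))
        X -= X.mean(axis=0)
        cov = X.T @ X / n
        X = X @ np.linalg.inv(np.linalg.cholesky(cov)).T
        T = fit_sphering(X, lam=0.0)
        np.testing.assert_allclose(T.Q, np.eye(d), atol=1e-8)

    def test_whitening_property(self, rng):
        n, d = 120, 6
        A = rng.normal(size=(d, d))
        X = rng.normal(size=(n, d)) @ A
        T = fit_sphering(X, lam=0.0)
        corrected = apply_sphering(T, X)
        cov = corrected.T @ corrected / n
        np.testing.assert_allclose(cov, np.eye(d), atol=1e-8)

    def test_regularized_eigenvalue_shrinkage(self, rng):
        n, d = 100, 5
        X = rng.normal(size=(n, d)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.1])
        Xc = X - X.mean(axis=0)
        evals = np.linalg.eigvalsh(Xc.T @ Xc / n)
        lam = 0.3
        corrected = apply_sphering(fit_sphering(X, lam=lam), X)
        got = np.sort(np.linalg.eigvalsh(corrected.T @ corrected / n))
        expected = np.sort(evals / (evals + lam))
        np.testing.assert_allclose(got, expected, atol=1e-8)
        assert ((got > 0) & (got < 1)).all()

    def test_monotone_in_lambda(self, rng):
        X = rng.normal(size=(50, 3))
        prev = None
        for lam in (0.01, 0.1, 1.0, 10.0):
            corrected = apply_sphering(fit_sphering(X, lam=lam), X)
            evs = np.sort(np.linalg.eigvalsh(corrected.T @ corrected / len(X)))
            if prev is not None:
                assert (evs <= prev + 1e-12).all()
            prev = evs

    def test_large_lambda_limit_uniform_shrinkage(self, rng):
        X = rng.normal(size=(40, 4))
        Xc = X - X.mean(axis=0)
        lam = 1e6 * np.linalg.eigvalsh(Xc.T @ Xc / len(X)).max()
        T = fit_sphering(X, lam=lam)
        np.testing.assert_allclose(
            T.Q, lam**-0.5 * np.eye(4), rtol=1e-5, atol=1e-6 * lam**-0.5
        )

    def test_identity_transform_is_noop(self):
        from morphoprof import SpheringTransform

        T = SpheringTransform(Q=np.eye(3), lam=0.0, mu=np.zeros(3), n_controls=5)
        X = np.arange(12, dtype=float).reshape(4, 3)
        np.testing.assert_allclose(apply_sphering(T, X), X)

    def test_uncentered_mode_matches_literal_formula(self, rng):
        X = rng.normal(loc=2.0, size=(30, 3))
        T = fit_sphering(X, lam=0.1, center=False)
        np.testing.assert_allclose(T.mu, 0.0)
        sigma = X.T @ X / len(X)
        evals, evecs = np.linalg.eigh(sigma)
        Q = (evecs * (evals + 0.1) ** -0.5) @ evecs.T
        np.testing.assert_allclose(T.Q, Q, atol=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError, match=">= 2 control"):
            fit_sphering(np.zeros((1, 3)))
        with pytest.raises(ValueError, match="lambda > 0"):
            fit_sphering(np.random.default_rng(0).normal(size=(3, 5)), lam=0.0)
        T = fit_sphering(np.random.default_rng(0).normal(size=(10, 3)), lam=0.1)
        with pytest.raises(ValueError, match="dimensionality"):
            apply_sphering(T, np.zeros((2, 5)))

    def test_Q_symmetric_positive_definite(self, rng):
        X = rng.normal(size=(20, 4))
        T = fit_sphering(X, lam=0.5)
        assert np.abs(T.Q - T.Q.T).max() < 1e-8
        assert (np.linalg.eigvalsh(T.Q) > 0).all()

    def test_persistence_round_trip(self, rng, tmp_path):
        from morphoprof import load_sphering, save_sphering

        T = fit_sphering(rng.normal(size=(15, 4)), lam=0.2)
        save_sphering(T, tmp_path / "sphering.npz")
        back = load_sphering(tmp_path / "sphering.npz")
        np.testing.assert_array_equal(back.Q, T.Q)
        np.testing.assert_array_equal(back.mu, T.mu)
        assert back.lam == T.lam and back.n_controls == T.n_controls


class TestCosine:
    def test_self_similarity_is_one(self):
        assert cosine_similarity([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_scale_invariance(self):
        assert cosine_similarity([1, 1], [2, 2]) == pytest.approx(1.0)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_similarity([0, 0], [1, 1])


def _well_table(rows):
    df = pd.DataFrame(rows, columns=["Metadata_Plate", "Metadata_Well", "Treatment", "Control", "f0000", "f0001"])
    return ProfileTable(data=df, level="well")


class TestEffectScores:
    def test_hand_built_z_score(self):
        """Controls at distances {1, 1, 3, 3} from their median profile
        (mean 2, sd 1); a treated well at distance 5 scores Z = 3."""
        rows = [
            ("P1", "C1", "DMSO", True, 1.0, 0.0),
            ("P1", "C2", "DMSO", True, -1.0, 0.0),
            ("P1", "C3", "DMSO", True, 3.0, 0.0),
            ("P1", "C4", "DMSO", True, -3.0, 0.0),
            ("P1", "T", "T1", False, 5.0, 0.0),
        ]
        # median control profile = (0, 0); control distances {1, 1, 3, 3}
        scores = effect_scores(_well_table(rows))
        assert scores.set_index("Treatment").loc["T1", "score"] == pytest.approx(3.0)
        wells = scores.attrs["wells"]
        assert sorted(wells[wells["Control"]]["distance"]) == [1.0, 1.0, 3.0, 3.0]

    def test_mean_across_replicates_and_plate_skipping(self):
        rows = [
            ("P1", "C1", "DMSO", True, 0.0, 1.0),
            ("P1", "C2", "DMSO", True, 0.0, -1.0),
            ("P1", "C3", "DMSO", True, 0.0, 3.0),
            ("P1", "T", "T1", False, 4.0, 0.0),
            ("P2", "C1", "DMSO", True, 0.0, 0.0),  # lone control: plate skipped
            ("P2", "T", "T1", False, 9.0, 0.0),
        ]
        with pytest.warns(UserWarning, match="P2"):
            scores = effect_scores(_well_table(rows))
        assert len(scores) == 1
        assert (scores.attrs["wells"]["Metadata_Plate"] == "P1").all()

    def test_degenerate_controls_error(self):
        rows = [
            ("P1", "C1", "DMSO", True, 1.0, 0.0),
            ("P1", "C2", "DMSO", True, 1.0, 0.0),
            ("P1", "T", "T1", False, 4.0, 0.0),
        ]
        with pytest.raises(ValueError, match="degenerate"):
            effect_scores(_well_table(rows))


class TestEffectBands:
    @pytest.mark.parametrize("n,expected", [(205, 41), (995, 199), (1550, 310)])
    def test_band_sizes_match_screen_counts(self, n, expected):
        scores = pd.DataFrame(
            {"Treatment": [f"T{i:05d}" for i in range(n)],
             "score": np.linspace(0, 10, n)}
        )
        for band in ("weak", "median", "strong"):
            assert len(select_effect_band(scores, band)) == expected

    def test_band_contents_and_disjointness(self):
        scores = pd.DataFrame({"Treatment": list("ABCDE"), "score": [5, 1, 3, 2, 4]})
        assert select_effect_band(scores, "weak") == ["B"]
        assert select_effect_band(scores, "strong") == ["A"]
        assert select_effect_band(scores, "median") == ["C"]
        n = 30
        scores = pd.DataFrame(
            {"Treatment": [f"T{i}" for i in range(n)], "score": np.arange(n)[::-1]}
        )
        bands = [set(select_effect_band(scores, b)) for b in ("weak", "median", "strong")]
        assert not (bands[0] & bands[1] or bands[0] & bands[2] or bands[1] & bands[2])

    def test_invalid_frac_errors(self):
        scores = pd.DataFrame({"Treatment": ["A", "B"], "score": [1, 2]})
        with pytest.raises(ValueError):
            select_effect_band(scores, "weak", frac=0.0)
        with pytest.raises(ValueError):
            select_effect_band(scores, "middle")
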