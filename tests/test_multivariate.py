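import numpy as np
import pytest

from triotrace import pca, permutation_validate, plsda_fit

from conftest import make_table


def separated_table(n_per_group=8, n_noise=4, seed=0):
    """One analyte with disjoint group ranges plus log-normal noise rows."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    data = rng.lognormal(1.5, 0.3, (n_noise + 1, n))
    data[0, :n_per_group] = rng.normal(10, 0.1, n_per_group)
    data[0, n_per_group:] = rng.normal(2, 0.1, n_per_group)
    return make_table(data, ["W"] * n_per_group + ["T"] * n_per_group)


class TestPca:
    def test_rank_one_data_fully_explained_by_pc1(self):
        direction = np.array([1.0, 2.0, 3.0, 4.0])
        data = np.outer(direction, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        table = make_table(data, ["W"] * 3 + ["T"] * 3)
        model = pca(table, n_components=3, scaling="center")
        assert model.explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_reconstruction_matches_svd(self, noise_table):
        model = pca(noise_table, n_components=16)
        reconstructed = model.scores @ model.loadings.T
        assert np.abs(reconstructed - model._context["scaled"]).max() < 1e-10

    def test_duplicated_sample_has_identical_scores(self):
        rng = np.random.default_rng(2)
        data = rng.lognormal(0, 0.4, (10, 5))
        data = np.column_stack([data, data[:, 0]])  # duplicate first sample
        table = make_table(data, ["W"] * 3 + ["T"] * 3)
        model = pca(table, n_components=2, scaling="center")
        assert np.allclose(model.scores[0], model.scores[-1], atol=1e-10)

    def test_constant_analyte_excluded_with_warning(self, noise_table):
        table = noise_table
        table.values.loc["a0"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            model = pca(table, n_components=2)
        assert "a0" not in model.analyte_ids


class TestPlsda:
    def test_separated_groups_top_vip_and_high_q2(self):
        model = plsda_fit(separated_table(), ("W", "T"), n_components=2, cv_folds=7)
        assert model.analyte_ids[int(np.argmax(model.vip))] == "a0"
        assert model.q2 > 0.9

    def test_vip_normalization(self, noise_table):
        model = plsda_fit(noise_table, ("A", "B"), n_components=2, cv_folds=4)
        assert float((model.vip**2).mean()) == pytest.approx(1.0, abs=1e-8)

    def test_q2_bounded_by_r2(self):
        for seed in range(5):
            model = plsda_fit(separated_table(seed=seed), ("W", "T"), n_components=2)
            assert model.q2 <= model.r2y + 1e-9

    def test_pure_noise_median_q2_nonpositive(self):
        q2s = []
        for seed in range(15):
            rng = np.random.default_rng(100 + seed)
            table = make_table(rng.lognormal(0, 0.3, (15, 12)), ["A"] * 6 + ["B"] * 6)
            q2s.append(plsda_fit(table, ("A", "B"), n_components=1, cv_folds=3).q2)
        assert float(np.median(q2s)) <= 0.0

    def test_predictions_match_sklearn(self):
        # independent oracle for the NIPALS core
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        from triotrace.multivariate import _pls1, _pls_predict

        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        Xc, yc = X - X.mean(0), y - y.mean()
        for ncomp in (1, 2, 3):
            W, T, P, q = _pls1(Xc, yc, ncomp)
            mine = _pls_predict(Xc, W, P, q)
            ref = sklearn.PLSRegression(n_components=ncomp, scale=False).fit(Xc, yc)
            assert np.abs(mine - ref.predict(Xc).ravel()).max() < 1e-10

    def test_single_label_design_rejected(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.lognormal(0, 0.2, (5, 6)), ["W"] * 6)
        with pytest.raises(ValueError):
            plsda_fit(table, ("W", "T"))

    def test_informative_analyte_recovered_among_noise(self):
        # 1 informative of 50 at a 5-SD group shift: top-1 VIP nearly always
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            data = rng.lognormal(2.0, 0.25, (50, 16))
            shift = data[0].std()
            data[0, 8:] = data[0, 8:] + 5 * shift
            table = make_table(data, ["W"] * 8 + ["T"] * 8)
            model = plsda_fit(table, ("W", "T"), n_components=1, cv_folds=4)
            hits += model.analyte_ids[int(np.argmax(model.vip))] == "a0"
        assert hits >= 38


class TestPermutation:
    def test_separated_groups_beat_all_permutations(self):
        model = plsda_fit(separated_table(), ("W", "T"), n_components=1)
        p = permutation_validate(model, n_perm=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_seed_determinism(self, noise_table):
        model = plsda_fit(noise_table, ("A", "B"), n_components=1, cv_folds=4)
        p1 = permutation_validate(model, n_perm=50, seed=7)
        p2 = permutation_validate(model, n_perm=50, seed=7)
        assert p1 == p2

    def test_low_n_perm_warns(self, noise_table):
        model = plsda_fit(noise_table, ("A", "B"), n_components=1, cv_folds=4)
        with pytest.warns(UserWarning):
            permutation_validate(model, n_perm=10, seed=0)
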