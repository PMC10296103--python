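import numpy as np
import pytest

from cortexmicro import atlas, bpls, synthdata
from cortexmicro.bpls import (
    brain_scores,
    correlation_table,
    cross_block,
    decompose,
    permutation_test,
    run_bpls,
    stable_roi_table,
    zscore_columns,
)


def _null_blocks(rng, n_per_group=15, n_cols=20, n_groups=3):
    n = n_per_group * n_groups
    X = zscore_columns(rng.normal(size=(n, n_cols)))
    Y = rng.normal(size=(n, 3))
    return X, Y, (n_per_group,) * n_groups


class TestZscoreColumns:
    def test_hand_zscores_on_toy(self):
        raw = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 60.0]])
        z = zscore_columns(raw)
        np.testing.assert_allclose(z[:, 0], [-1, 0, 1])
        col = np.array([10.0, 20, 60])
        np.testing.assert_allclose(z[:, 1], (col - 30) / col.std(ddof=1))

    def test_constant_shift_invariance(self, rng):
        raw = rng.normal(size=(10, 4))
        np.testing.assert_allclose(zscore_columns(raw),
                                   zscore_columns(raw + 123.4), atol=1e-10)

    def test_column_moments(self, rng):
        z = zscore_columns(rng.normal(size=(30, 6)))
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_zero_variance_column_named(self):
        raw = np.ones((5, 2))
        raw[:, 0] = [1, 2, 3, 4, 5]
        with pytest.raises(ValueError, match="roiB"):
            zscore_columns(raw, columns=["roiA", "roiB"])


class TestCrossBlock:
    def test_behavior_duplicated_as_brain_column_gives_unit_entry(self, rng):
        n = 12
        Y = rng.normal(size=(n, 3))
        X = np.column_stack([Y[:, 0], rng.normal(size=(n, 3))])
        R = cross_block(X, Y, (n,))
        assert R[0, 0] == pytest.approx(1.0)

    def test_entries_bounded_and_shaped(self, rng):
        X, Y, sizes = _null_blocks(rng)
        R = cross_block(X, Y, sizes)
        assert R.shape == (9, 20)
        assert np.all(np.abs(R) <= 1.0 + 1e-12)

    def test_independent_noise_entries_near_zero(self, rng):
        n = 2000
        X = zscore_columns(rng.normal(size=(n, 50)))
        Y = rng.normal(size=(n, 3))
        R = cross_block(X, Y, (n,))
        assert np.abs(R).max() < 0.1

    def test_within_group_permutation_invariance(self, rng):
        X, Y, sizes = _null_blocks(rng)
        perm = np.concatenate([np.arange(15)[rng.permutation(15)] + 15 * g
                               for g in range(3)])
        R1 = cross_block(X, Y, sizes)
        R2 = cross_block(X[perm], Y[perm], sizes)
        np.testing.assert_allclose(R1, R2, atol=1e-12)

    def test_group_major_stacking_order(self, rng):
        # make group 2's first behavior perfectly track brain column 0
        n = 10
        X = rng.normal(size=(3 * n, 4))
        Y = rng.normal(size=(3 * n, 3))
        Y[n:2 * n, 0] = X[n:2 * n, 0]
        R = cross_block(zscore_columns(X), Y, (n, n, n))
        assert R[3, 0] == pytest.approx(1.0)  # row 3 = group 2, behavior 1

    def test_zero_variance_behavior_rejected(self, rng):
        X = rng.normal(size=(9, 4))
        Y = rng.normal(size=(9, 3))
        Y[:, 1] = 5.0
        with pytest.raises(ValueError, match="behavior"):
            cross_block(X, Y, (9,))


class TestDecompose:
    def test_rank_one_concentrates_covariance(self, rng):
        R = np.outer(rng.normal(size=9), rng.normal(size=30))
        _, s, _, pct = decompose(R)
        assert pct[0] == pytest.approx(100.0)
        assert np.all(pct[1:] < 1e-8)

    def test_reconstruction_and_orthonormality(self, rng):
        R = rng.normal(size=(9, 40))
        u, s, v, pct = decompose(R)
        np.testing.assert_allclose(v @ np.diag(s) @ u.T, R, atol=1e-10)
        np.testing.assert_allclose(u.T @ u, np.eye(9), atol=1e-10)
        np.testing.assert_allclose(v.T @ v, np.eye(9), atol=1e-10)
        assert pct.sum() == pytest.approx(100.0)

    def test_singular_values_match_eigen_oracle(self):
        R = np.array([[3.0, 1.0, 1.0], [-1.0, 3.0, 1.0]])
        _, s, _, _ = decompose(R)
        # oracle: sqrt of eigenvalues of R R^T via the characteristic polynomial
        evals = np.linalg.eigvalsh(R @ R.T)
        np.testing.assert_allclose(np.sort(s**2), np.sort(evals), atol=1e-10)

    def test_covariance_conservation(self, rng):
        R = rng.normal(size=(9, 152))
        _, s, _, _ = decompose(R)
        assert (s**2).sum() == pytest.approx((R**2).sum(), abs=1e-10)

    def test_sign_convention_pivot_positive(self, rng):
        R = rng.normal(size=(9, 12))
        _, _, v, _ = decompose(R)
        for col in v.T:
            assert col[np.argmax(np.abs(col))] > 0

    def test_permutation_equivariance(self, rng):
        R = rng.normal(size=(6, 10))
        u, s, v, _ = decompose(R)
        pr = rng.permutation(6)
        pc = rng.permutation(10)
        u2, s2, v2, _ = decompose(R[pr][:, pc])
        np.testing.assert_allclose(s, s2, atol=1e-10)
        np.testing.assert_allclose(np.abs(u2), np.abs(u[pc]), atol=1e-8)
        np.testing.assert_allclose(np.abs(v2), np.abs(v[pr]), atol=1e-8)


class TestBrainScores:
    def test_unit_salience_selects_column(self, rng):
        X = rng.normal(size=(7, 5))
        u = np.zeros((5, 2))
        u[3, 0] = 1.0
        u[1, 1] = 1.0
        S = brain_scores(X, u)
        np.testing.assert_allclose(S[:, 0], X[:, 3])
        np.testing.assert_allclose(S[:, 1], X[:, 1])

    def test_linearity(self, rng):
        X = rng.normal(size=(7, 5))
        u = rng.normal(size=(5, 3))
        np.testing.assert_allclose(brain_scores(2 * X, u),
                                   2 * brain_scores(X, u))

    def test_score_covariance_identity(self, rng):
        X = rng.normal(size=(200, 6))
        u, _, _, _ = decompose(rng.normal(size=(3, 6)))
        S = brain_scores(X, u)
        sigma = np.cov(X, rowvar=False)
        np.testing.assert_allclose(np.cov(S, rowvar=False), u.T @ sigma @ u,
                                   atol=1e-10)


class TestPermutationTest:
    def test_planted_effect_reaches_floor_p(self, rng):
        n = 30
        y = rng.normal(size=(3 * n, 3))
        w = rng.normal(size=40)
        X = zscore_columns(np.outer(y[:, 0], w) + 0.05 * rng.normal(size=(3 * n, 40)))
        p = permutation_test(X, y, (n, n, n), n_perm=199, rng=rng)
        assert p[0] == pytest.approx(1 / 200)

    def test_seeded_reproducibility(self, rng):
        X, Y, sizes = _null_blocks(rng)
        p1 = permutation_test(X, Y, sizes, n_perm=150, rng=42)
        p2 = permutation_test(X, Y, sizes, n_perm=150, rng=42)
        np.testing.assert_array_equal(p1, p2)

    def test_small_n_perm_warns(self, rng, caplog):
        X, Y, sizes = _null_blocks(rng, n_per_group=5, n_cols=4)
        with caplog.at_level("WARNING"):
            permutation_test(X, Y, sizes, n_perm=50, rng=1)
        assert any("n_perm" in r.message for r in caplog.records)

    def test_within_group_scheme_also_valid(self, rng):
        X, Y, sizes = _null_blocks(rng)
        p = permutation_test(X, Y, sizes, n_perm=150, rng=7,
                             scheme="within_group")
        assert np.all((p > 0) & (p <= 1))


@pytest.fixture(scope="module")
def planted_result(planted_dataset):
    _, ing = planted_dataset
    return run_bpls(ing["X_raw"], ing["Y"], ing["group_sizes"],
                    n_perm=300, n_boot=300, seed=99,
                    column_names=ing["columns"],
                    group_labels=("cis_boy", "gd_afab", "cis_girl"))


class TestBootstrapAndResult:
    def test_boot_ratio_sign_matches_salience_sign(self, planted_result):
        res = planted_result
        stable = res.stable_mask[:, 0]
        assert np.all(np.sign(res.boot_ratio[stable, 0])
                      == np.sign(res.u[stable, 0]))

    def test_fixed_seed_reproduces_mask(self, planted_dataset):
        _, ing = planted_dataset
        r1 = run_bpls(ing["X_raw"], ing["Y"], ing["group_sizes"],
                      n_perm=100, n_boot=100, seed=5)
        r2 = run_bpls(ing["X_raw"], ing["Y"], ing["group_sizes"],
                      n_perm=100, n_boot=100, seed=5)
        np.testing.assert_array_equal(r1.stable_mask, r2.stable_mask)
        np.testing.assert_array_equal(r1.perm_p, r2.perm_p)

    def test_planted_columns_stable_null_columns_not(self, planted_result):
        support = synthdata.default_effect_support() != 0
        stable = planted_result.stable_mask[:, 0]
        assert stable[support].mean() >= 0.8
        assert stable[~support].mean() <= 0.1

    def test_affected_groups_show_stable_correlations(self, planted_result):
        tab = correlation_table(planted_result)
        by_group = tab.groupby("group")["stable"].all()
        assert bool(by_group["cis_boy"]) and bool(by_group["gd_afab"])
        assert not tab[tab["group"] == "cis_girl"]["stable"].any()

    def test_perm_p_display_renders_floor(self, planted_result):
        assert planted_result.perm_p_display(0).startswith("<")

    def test_stable_roi_table_layout(self, planted_result):
        tab = stable_roi_table(planted_result)
        assert set(tab.columns) >= {"name", "hemisphere", "lobe", "T1", "MD"}
        assert ((tab["T1"] == "x") | (tab["MD"] == "x")).all()
        assert len(tab) <= atlas.N_ROIS

    def test_roi_table_round_trips_csv(self, planted_result, tmp_path):
        import pandas as pd

        tab = stable_roi_table(planted_result)
        path = tmp_path / "stable.csv"
        tab.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(
            back[["label", "name", "hemisphere", "T1", "MD"]],
            tab[["label", "name", "hemisphere", "T1", "MD"]],
        )
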