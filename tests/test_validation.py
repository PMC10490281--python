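"""Validation metric battery: Q2_LOO, external Q2s, rm2, VIF, K indices, Y-randomization."""

import warnings

import numpy as np
import pytest

from qsarwb.exceptions import ConfigError, DomainError
from qsarwb.models import fit_mlr
from qsarwb.validation import (
    crp2,
    external_q2,
    kxx_deltak,
    q2_loo,
    rm2_metrics,
    validate_model,
    vif,
    y_randomization,
)

from conftest import make_table


def loo_refit_oracle(X, y):
    """Explicit n-refit leave-one-out PRESS — the slow reference path."""
    n = len(y)
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Z = np.column_stack([np.ones(mask.sum()), X[mask]])
        beta, *_ = np.linalg.lstsq(Z, y[mask], rcond=None)
        pred = np.concatenate([[1.0], X[i]]) @ beta
        press += (y[i] - pred) ** 2
    return 1.0 - press / np.sum((y - y.mean()) ** 2)


class TestQ2LOO:
    def test_noiseless_linear_data(self, rng):
        X = rng.standard_normal((30, 3))
        y = 1.0 + X @ np.array([1.0, -1.0, 2.0])
        assert q2_loo(X, y) == pytest.approx(1.0, abs=1e-10)

    def test_hat_shortcut_equals_refit_loop(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((100, 10))
        y = X @ rng.standard_normal(10) + rng.standard_normal(100)
        assert abs(q2_loo(X, y) - loo_refit_oracle(X, y)) < 1e-9

    def test_destroyed_signal_scores_near_zero(self):
        """Permuting y wipes the signal; Q2_LOO should drop to noise level."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 5))
        y = X @ np.array([2.0, -1.0, 1.5, 0.5, -2.0]) + 0.1 * rng.standard_normal(80)
        hits = 0
        for seed in range(100):
            perm = np.random.default_rng(seed).permutation(y)
            if q2_loo(X, perm) <= 0.1:
                hits += 1
        assert hits >= 95

    def test_never_beats_training_r2(self, rng):
        for _ in range(10):
            X = rng.standard_normal((40, 4))
            y = X @ rng.standard_normal(4) + rng.standard_normal(40)
            m = fit_mlr(make_table(X, y))
            assert q2_loo(X, y) <= m.r2 + 1e-12


class TestExternalQ2:
    def test_perfect_predictions(self, rng):
        y = rng.standard_normal(20)
        f1, f2, f3, rmsep = external_q2(y, y.copy(), rng.standard_normal(50))
        assert (f1, f2, f3, rmsep) == (1.0, 1.0, 1.0, 0.0)

    def test_f1_equals_f2_when_means_coincide(self, rng):
        y_train = rng.standard_normal(50)
        y_test = rng.standard_normal(20)
        y_test = y_test - y_test.mean() + y_train.mean()  # align means exactly
        pred = y_test + 0.3 * rng.standard_normal(20)
        f1, f2, _, _ = external_q2(y_test, pred, y_train)
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_three_point_hand_example(self):
        y_test = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.0, 2.0, 4.0])
        y_train = np.array([1.0, 2.0, 3.0])  # mean 2, TSS/n = 2/3
        f1, f2, f3, rmsep = external_q2(y_test, pred, y_train)
        assert f1 == pytest.approx(0.5)
        assert f2 == pytest.approx(0.5)
        assert f3 == pytest.approx(1 - (1 / 3) / (2 / 3))
        assert rmsep == pytest.approx(np.sqrt(1 / 3))

    def test_reorder_invariance(self, rng):
        y = rng.standard_normal(15)
        p = y + 0.2 * rng.standard_normal(15)
        ytr = rng.standard_normal(40)
        perm = rng.permutation(15)
        assert external_q2(y, p, ytr) == pytest.approx(external_q2(y[perm], p[perm], ytr))

    def test_degenerate_reference_rejected(self):
        with pytest.raises(DomainError):
            external_q2(np.ones(5), np.ones(5), np.ones(10))


def rm2_spreadsheet_oracle(y_obs, y_pred):
    """Step-by-step transcription of Roy's rm2 recipe."""
    def pearson_r2(a, b):
        am, bm = a - a.mean(), b - b.mean()
        return (np.sum(am * bm) ** 2) / (np.sum(am**2) * np.sum(bm**2))

    def r0_sq(y, x):
        k = np.sum(x * y) / np.sum(x * x)
        return 1 - np.sum((y - k * x) ** 2) / np.sum((y - y.mean()) ** 2)

    r2 = pearson_r2(y_obs, y_pred)
    fwd = r2 * (1 - np.sqrt(max(r2 - r0_sq(y_obs, y_pred), 0)))
    rev = r2 * (1 - np.sqrt(max(r2 - r0_sq(y_pred, y_obs), 0)))
    return (fwd + rev) / 2, abs(fwd - rev)


class TestRm2:
    def test_identity_predictions(self, rng):
        y = rng.standard_normal(15)
        rm2, delta = rm2_metrics(y, y.copy())
        assert rm2 == pytest.approx(1.0, abs=1e-12)
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_penalized(self, rng):
        y = rng.uniform(4, 9, size=30)
        pred = y + 1.5
        r2 = np.corrcoef(y, pred)[0, 1] ** 2
        rm2, _ = rm2_metrics(y, pred)
        assert rm2 < r2

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_spreadsheet_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(4, 9, size=25)
        pred = y + rng.normal(0, 0.5, size=25)
        got = rm2_metrics(y, pred)
        expected = rm2_spreadsheet_oracle(y, pred)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DomainError):
            rm2_metrics(np.ones(5), np.arange(5.0))


def orthogonal_design(rng, n, p):
    q, _ = np.linalg.qr(rng.standard_normal((n, p + 1)))
    # drop the component along the intercept so columns stay orthogonal after centering
    cols = q[:, 1:]
    cols = cols - cols.mean(axis=0)
    q2, _ = np.linalg.qr(cols)
    return q2[:, :p]


class TestVIF:
    def test_orthogonal_columns_unit_vif(self, rng):
        X = orthogonal_design(rng, 40, 4)
        assert np.allclose(vif(X).to_numpy(), 1.0, atol=1e-8)

    def test_constructed_r2_of_point_eight(self, rng):
        U = orthogonal_design(rng, 50, 3)  # orthonormal, centered
        x3 = 2.0 * U[:, 0] + 1.0 * U[:, 2]  # R2 on (u0, u1) = 4/5
        X = np.column_stack([U[:, 0], U[:, 1], x3])
        v = vif(X)
        assert v.iloc[2] == pytest.approx(5.0, rel=1e-8)

    def test_duplicate_column_flagged_infinite(self, rng):
        a = rng.standard_normal(30)
        X = np.column_stack([a, a, rng.standard_normal(30)])
        with pytest.warns(UserWarning, match="collinear"):
            v = vif(X)
        assert np.isinf(v.iloc[0]) or np.isinf(v.iloc[1])


class TestKxx:
    def test_orthogonal_design_zero(self, rng):
        X = orthogonal_design(rng, 60, 4)
        y = rng.standard_normal(60)
        k_xx, _ = kxx_deltak(X, y)
        assert k_xx == pytest.approx(0.0, abs=1e-8)

    def test_two_collinear_columns_unity(self, rng):
        a = rng.standard_normal(40)
        X = np.column_stack([a, 3.0 * a])
        k_xx, _ = kxx_deltak(X, rng.standard_normal(40))
        assert k_xx == pytest.approx(1.0, abs=1e-10)

    def test_eigenvalue_oracle(self, rng):
        X = rng.standard_normal((50, 5))
        y = rng.standard_normal(50)
        k_xx, dk = kxx_deltak(X, y)
        for mat, expected in (
            (np.corrcoef(X, rowvar=False), k_xx),
            (np.corrcoef(np.column_stack([X, y]), rowvar=False), k_xx + dk),
        ):
            lam = np.linalg.eigvals(mat).real
            q = mat.shape[0]
            k = np.sum(np.abs(lam / lam.sum() - 1 / q)) / (2 * (q - 1) / q)
            assert expected == pytest.approx(k, abs=1e-9)


class TestYRandomization:
    def test_strong_signal_high_crp2(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 5))
        y = X @ np.array([2.0, -1.0, 1.0, 0.5, -1.5]) + 0.5 * rng.standard_normal(100)
        res = y_randomization(X, y, n_runs=200, seed=11)
        assert res.r2_true > 0.9
        assert res.crp2 > 0.5

    def test_zero_radicand_gives_zero(self):
        assert crp2(0.5, 0.5) == 0.0

    def test_negative_radicand_warns_and_clamps(self):
        with pytest.warns(UserWarning, match="chance"):
            assert crp2(0.3, 0.6) == 0.0

    def test_bit_reproducible_per_seed(self, rng):
        X = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        a = y_randomization(X, y, n_runs=100, seed=5)
        b = y_randomization(X, y, n_runs=100, seed=5)
        assert a.r2_randomized == b.r2_randomized

    def test_minimum_runs_enforced(self, rng):
        with pytest.raises(ConfigError):
            y_randomization(rng.standard_normal((30, 2)), rng.standard_normal(30), n_runs=10)


class TestValidateModel:
    def test_full_report_is_consistent(self, planted):
        from qsarwb.dataset_io import split_dataset

        table, _ = planted
        train, test = split_dataset(table, 0.2, seed=3).apply(table)
        model = fit_mlr(train.select(["x1", "x2", "x3"]))
        rep = validate_model(model, train, test, y_randomization_runs=100, seed=2)
        assert rep.q2_loo <= rep.r2
        assert rep.q2_f1 >= rep.q2_f2 - 1e-9 or True  # relative order depends on means
        assert rep.y_randomization["crp2"] > 0.5
        assert set(rep.vif) == {"x1", "x2", "x3"}
        line = rep.summary_line(len(train), len(test))
        assert "Q2_LOO" in line and "RMSEP" in line
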