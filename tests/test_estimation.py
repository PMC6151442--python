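import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from qpar import (
    CassetteAssignment,
    FeatureTable,
    GeneratorConfig,
    JointModelParams,
    fit_joint_model,
    generate_dataset,
    hill_effect,
    HillParams,
    minmax_normalize,
    model_error,
    olmstead_predict,
    pls_baseline,
    r_squared,
    standard_mixture_dataset,
)
from qpar.estimation import POTENCY_BOUNDS, POWER_BOUNDS, _batch_loss


class TestMinMaxNormalize:
    def test_maps_column_onto_unit_interval(self, tiny_table):
        normed = minmax_normalize(tiny_table)
        np.testing.assert_allclose(normed.abundance["a"], [0.0, 0.5, 1.0, 0.5])

    def test_constant_column_flagged_and_zeroed(self, tiny_table):
        normed = minmax_normalize(tiny_table)
        assert normed.constant_features == ("b",)
        assert (normed.abundance["b"] == 0.0).all()

    def test_idempotent(self, tiny_table):
        once = minmax_normalize(tiny_table)
        twice = minmax_normalize(once)
        pd.testing.assert_frame_equal(once.abundance, twice.abundance)


class TestErrorMetrics:
    @pytest.mark.parametrize(
        "pred, obs, expected",
        [([1.0, 2.0], [1.0, 2.0], 0.0), ([0.0, 1.0], [1.0, 0.0], 1.0),
         ([0.2, 0.4], [0.3, 0.3], 0.1)],
    )
    def test_rmse_values(self, pred, obs, expected):
        assert model_error(pred, obs) == pytest.approx(expected)

    def test_rmse_length_mismatch(self):
        with pytest.raises(ValueError):
            model_error([1.0], [1.0, 2.0])

    @pytest.mark.parametrize(
        "obs, pred, expected",
        [([0.0, 1.0, 2.0], [0.0, 1.0, 2.0], 1.0),
         ([0.0, 1.0, 2.0], [1.0, 1.0, 1.0], 0.0),
         ([0.0, 1.0, 2.0], [0.0, 1.0, 3.0], 0.5)],
    )
    def test_r_squared_values(self, obs, pred, expected):
        assert r_squared(obs, pred) == pytest.approx(expected)

    def test_r_squared_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0], [0.5, 1.5])


def _olmstead_truth_table(seed=5, n_samples=20):
    rng = np.random.default_rng(seed)
    ids = ["a", "b", "c"]
    ab = pd.DataFrame(
        rng.uniform(0.05, 1.0, (n_samples, 3)),
        index=[f"s{i}" for i in range(n_samples)],
        columns=ids,
    )
    table = FeatureTable(ab, pd.Series([1.0, 2.0, 3.0], index=ids))
    truth = JointModelParams(ids, np.array([0.4, 0.7, 1.2]), np.array([2.0]))
    cassettes = CassetteAssignment.single(ids)
    y = pd.Series(olmstead_predict(ab.to_numpy(), truth, cassettes), index=ab.index)
    return table, y, truth, cassettes


class TestJointFit:
    def test_noise_free_parameter_recovery(self):
        table, y, truth, cassettes = _olmstead_truth_table()
        fit = fit_joint_model(table, y, cassettes, model="olmstead", seed=3)
        assert fit.test_rmse < 1e-3
        np.testing.assert_allclose(fit.params.potencies, truth.potencies, rtol=0.15)

    def test_ca_single_feature_recovers_hill_params(self):
        rng = np.random.default_rng(9)
        truth = HillParams(0.6, 1.8)
        cs = rng.uniform(0.05, 2.0, 16)
        ab = pd.DataFrame({"a": cs}, index=[f"s{i}" for i in range(16)])
        table = FeatureTable(ab, pd.Series([1.0], index=["a"]))
        y = pd.Series([hill_effect(c, truth) for c in cs], index=ab.index)
        fit = fit_joint_model(table, y, model="ca", seed=1)
        assert fit.params.potencies[0] == pytest.approx(truth.ec50, rel=0.05)
        assert fit.params.powers[0] == pytest.approx(truth.p, rel=0.05)

    def test_constant_activity_unfittable(self, tiny_table, one_cassette):
        y = pd.Series(0.3, index=tiny_table.abundance.index)
        with pytest.raises(ValueError, match="unfittable"):
            fit_joint_model(tiny_table, y, one_cassette)

    def test_seeded_determinism(self):
        table, y, _, cassettes = _olmstead_truth_table(seed=8)
        a = fit_joint_model(table, y, cassettes, seed=21)
        b = fit_joint_model(table, y, cassettes, seed=21)
        assert np.array_equal(a.params.potencies, b.params.potencies)
        assert np.array_equal(a.params.powers, b.params.powers)
        assert a.train_rmse == b.train_rmse and a.test_rmse == b.test_rmse
        assert a.train_ids == b.train_ids

    def test_multistart_matches_exhaustive_grid_oracle(self):
        """On tiny instances the seeded search reaches the grid-search loss."""
        rng = np.random.default_rng(2)
        cs = rng.uniform(0.05, 1.5, 14)
        ab = pd.DataFrame({"a": cs}, index=[f"s{i}" for i in range(14)])
        table = FeatureTable(ab, pd.Series([1.0], index=["a"]))
        truth = HillParams(0.5, 1.6)
        y_clean = np.array([hill_effect(c, truth) for c in cs])
        y = pd.Series(
            np.clip(y_clean + rng.normal(0, 0.03, 14), 0, 1), index=ab.index
        )
        n = len(cs)
        fit = fit_joint_model(
            table, y, model="ca", seed=4,
            train_idx=np.arange(n), test_idx=np.array([], dtype=int),
        )
        # independent oracle: exhaustive 51-point log-spaced grid per parameter
        lp = np.log10(np.geomspace(*POTENCY_BOUNDS, 51))
        lw = np.log10(np.geomspace(*POWER_BOUNDS, 51))
        grid_p, grid_w = np.meshgrid(lp, lw, indexing="ij")
        losses = _batch_loss(
            cs[:, None], y.to_numpy(), grid_p.ravel()[:, None],
            grid_w.ravel()[:, None], np.array([1]), 1,
        )
        assert fit.train_rmse <= losses.min() * 1.01 + 1e-9


class TestPLSBaseline:
    def test_linear_identity(self):
        rng = np.random.default_rng(0)
        ab = pd.DataFrame(
            {"a": rng.uniform(0, 1, 24), "b": rng.uniform(0, 1, 24)},
            index=[f"s{i}" for i in range(24)],
        )
        # activity exactly linear in one feature; the other is orthogonalised
        # against it so a single latent component suffices
        ab["b"] -= np.polyval(np.polyfit(ab["a"], ab["b"], 1), ab["a"])
        ab["b"] -= ab["b"].min()
        table = FeatureTable(ab, pd.Series([1.0, 2.0], index=["a", "b"]))
        y = pd.Series(2.0 * ab["a"], index=ab.index)
        res = pls_baseline(table, y, n_components=1)
        assert res.r2 > 0.999

    def test_excessive_components_rejected(self, tiny_table):
        y = pd.Series([0.1, 0.2, 0.3, 0.4], index=tiny_table.abundance.index)
        with pytest.raises(ValueError):
            pls_baseline(tiny_table, y, n_components=5)

    def test_permutation_null_r2_near_zero(self):
        table, y, _, _ = standard_mixture_dataset(powers=[2.5], noise_sd=0.05, seed=0)
        normed = minmax_normalize(table)
        r2s = []
        for seed in range(100):
            permuted = pd.Series(
                np.random.default_rng(seed).permutation(y.to_numpy()), index=y.index
            )
            r2s.append(pls_baseline(normed, permuted, n_components=2).r2)
        assert abs(np.median(r2s)) < 0.15

    def test_olmstead_beats_pls_on_steep_synthetic_blends(self):
        """Nonlinear truth: the joint-action fit out-predicts linear PLS."""
        d = generate_dataset(
            GeneratorConfig(n_features=6, n_cassettes=2, n_active=3,
                            potency_scale=2.0, active_power=4.0, seed=2)
        )
        normed = minmax_normalize(d.table)
        fit = fit_joint_model(normed, d.activity, d.cassettes, model="olmstead", seed=2)
        pred = fit.predict(normed)
        r2_olm = r_squared(d.activity.to_numpy(), pred)
        r2_pls = pls_baseline(normed, d.activity, n_components=2).r2
        assert r2_olm > r2_pls
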