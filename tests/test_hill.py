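import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpar import (
    DoseResponsePoint,
    HillParams,
    STANDARD_EC_TABLES,
    ec_x,
    fit_curve,
    fit_two_point,
    hill_effect,
    standard_ec_table,
)
from qpar.hill import EC_LEVELS


class TestHillEffect:
    def test_half_maximal_at_ec50(self):
        for params in (HillParams(1.0, 1.0), HillParams(77.06, 1.71), HillParams(0.3, 5)):
            assert hill_effect(params.ec50, params) == pytest.approx(0.5)

    def test_zero_concentration_gives_zero_effect(self):
        assert hill_effect(0.0, HillParams(10, 2)) == 0.0

    def test_published_baohuoside_ec10_point(self):
        params = standard_ec_table("baohuoside I").fit()
        assert hill_effect(21.32, params) == pytest.approx(0.10, abs=0.005)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill_effect(-1.0, HillParams(1, 1))

    @given(st.floats(0.01, 1e4), st.floats(0.1, 5), st.floats(1.01, 3))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, c, p, step):
        params = HillParams(10.0, p)
        assert hill_effect(c * step, params) > hill_effect(c, params)

    def test_vectorised_matches_scalar(self):
        params = HillParams(3.0, 1.4)
        cs = np.array([0.0, 0.5, 3.0, 50.0])
        np.testing.assert_allclose(
            hill_effect(cs, params), [hill_effect(c, params) for c in cs]
        )


class TestEcx:
    def test_ec50_identity(self):
        assert ec_x(HillParams(42.0, 0.7), 0.5) == pytest.approx(42.0)

    @pytest.mark.parametrize(
        "standard, x, expected",
        [
            ("baohuoside I", 0.20, 34.26),
            ("icartin", 0.10, 4.73),
        ],
    )
    def test_published_intermediate_ec_values(self, standard, x, expected):
        params = standard_ec_table(standard).fit()
        assert ec_x(params, x) == pytest.approx(expected, rel=0.01)

    @pytest.mark.parametrize("x", [0.0, 1.0, -0.2, 1.5])
    def test_boundary_levels_rejected(self, x):
        with pytest.raises(ValueError):
            ec_x(HillParams(1, 1), x)

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.9))
    @settings(max_examples=50, deadline=None)
    def test_increasing_in_level(self, x, dx):
        params = HillParams(5.0, 1.3)
        hi = min(0.99, x + dx)
        assert ec_x(params, hi) >= ec_x(params, x)

    @given(st.floats(0.01, 100.0), st.floats(0.3, 4.0), st.floats(-4.0, 4.0))
    @settings(max_examples=100, deadline=None)
    def test_inversion_roundtrip(self, ec50, p, log_ratio):
        # effect kept within (1e-5, 1 - 1e-5): closer to full saturation the
        # logit is no longer representable at 1e-10 relative precision
        params = HillParams(ec50, p)
        c = ec50 * 10.0 ** (log_ratio / p)
        assert ec_x(params, hill_effect(c, params)) == pytest.approx(c, rel=1e-10)


class TestTwoPointFit:
    def test_closed_form_slope_from_baohuoside_endpoints(self):
        params = fit_two_point(
            DoseResponsePoint(13.77, 0.05), DoseResponsePoint(77.06, 0.50)
        )
        assert params.p == pytest.approx(1.710, abs=0.001)
        assert params.ec50 == pytest.approx(77.06, rel=1e-9)

    def test_roundtrip_recovers_generating_params(self):
        truth = HillParams(12.0, 2.3)
        c = 4.0
        pts = [
            DoseResponsePoint(c, hill_effect(c, truth)),
            DoseResponsePoint(2 * c, hill_effect(2 * c, truth)),
        ]
        fitted = fit_two_point(*pts)
        assert fitted.ec50 == pytest.approx(truth.ec50, rel=1e-12)
        assert fitted.p == pytest.approx(truth.p, rel=1e-12)

    def test_epimedin_b_ec30_prediction(self):
        params = fit_two_point(
            DoseResponsePoint(7.14, 0.05), DoseResponsePoint(402.92, 0.50)
        )
        assert ec_x(params, 0.30) == pytest.approx(126.22, rel=0.01)

    @pytest.mark.parametrize(
        "p1, p2",
        [
            ((5.0, 0.2), (5.0, 0.4)),  # same concentration
            ((5.0, 0.2), (9.0, 0.2)),  # same effect
            ((5.0, 0.0), (9.0, 0.5)),  # boundary effect
        ],
    )
    def test_degenerate_pairs_rejected(self, p1, p2):
        with pytest.raises(ValueError):
            fit_two_point(DoseResponsePoint(*p1), DoseResponsePoint(*p2))


class TestCurveFit:
    def test_noise_free_identity(self):
        truth = HillParams(77.06, 1.71)
        cs = np.geomspace(5, 500, 7)
        pts = [DoseResponsePoint(c, hill_effect(c, truth)) for c in cs]
        fitted = fit_curve(pts)
        assert fitted.ec50 == pytest.approx(truth.ec50, rel=1e-6)
        assert fitted.p == pytest.approx(truth.p, rel=1e-6)

    def test_two_points_fall_back_to_closed_form(self):
        pts = [DoseResponsePoint(10.0, 0.2), DoseResponsePoint(40.0, 0.6)]
        assert fit_curve(pts) == fit_two_point(*pts)

    def test_degenerate_curves_rejected(self):
        flat = [DoseResponsePoint(c, 0.0) for c in (1.0, 2.0, 4.0)]
        with pytest.raises(ValueError):
            fit_curve(flat)

    def test_noisy_ec50_recovery_within_ten_percent(self):
        truth = HillParams(20.0, 1.5)
        cs = np.geomspace(2, 200, 7)
        clean = np.array([hill_effect(c, truth) for c in cs])
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = np.clip(clean + rng.normal(0, 0.02, size=7), 1e-4, 1 - 1e-4)
            pts = [DoseResponsePoint(c, e) for c, e in zip(cs, noisy)]
            fitted = fit_curve(pts, seed=seed, n_starts=4)
            errors.append(abs(fitted.ec50 - truth.ec50) / truth.ec50)
        assert np.median(errors) < 0.10


class TestStandardTables:
    def test_ec_columns_increase_with_level(self):
        for table in STANDARD_EC_TABLES:
            concs = [table.ec(x) for x in EC_LEVELS]
            assert all(b > a for a, b in zip(concs, concs[1:]))

    def test_two_point_fit_reproduces_intermediate_levels(self):
        # epimedin C's tabulated EC5 of 0.02 is heavily rounded, so its
        # intermediate levels are reproduced more loosely.
        for table in STANDARD_EC_TABLES:
            tol = 0.05 if table.name == "epimedin C" else 0.02
            params = table.fit()
            for x in (0.10, 0.20, 0.30, 0.40):
                assert ec_x(params, x) == pytest.approx(table.ec(x), rel=tol), table.name

    def test_nonmonotone_table_rejected(self):
        from qpar import ECTable

        with pytest.raises(ValueError):
            ECTable(name="bad", values={0.05: 5.0, 0.10: 4.0, 0.50: 10.0})
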