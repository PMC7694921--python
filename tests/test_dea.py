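"""Envelopment LP, slacks and adjustment targets against enumeration oracles."""

import numpy as np
import pytest

import hera
from hera.dea_efficiency import (
    DeaModelSpec,
    adjustment_table,
    build_matrices,
    efficiency_table,
    max_slacks,
    solve_envelopment,
)


def crs_ratio_oracle(X, Y):
    """Closed form for 1-input/1-output CRS: theta_j = (y_j/x_j) / max_k (y_k/x_k)."""
    ratios = Y[:, 0] / X[:, 0]
    return ratios / ratios.max()


def single_in_out(*pairs):
    X = np.array([[x] for x, _ in pairs], float)
    Y = np.array([[y] for _, y in pairs], float)
    return X, Y


class TestEnvelopment:
    def test_single_dmu_is_self_efficient(self):
        X, Y = single_in_out((3.0, 2.0))
        for rts in ("CRS", "VRS"):
            theta, lam = solve_envelopment(0, X, Y, rts)
            assert theta == pytest.approx(1.0, abs=1e-9)

    def test_three_dmu_frontier_enumeration(self):
        """A(2,4) spans the CRS ray; VRS hull additionally keeps C(1,1) efficient."""
        X, Y = single_in_out((2.0, 4.0), (4.0, 4.0), (1.0, 1.0))
        crs = [solve_envelopment(j, X, Y, "CRS")[0] for j in range(3)]
        vrs = [solve_envelopment(j, X, Y, "VRS")[0] for j in range(3)]
        assert crs == pytest.approx([1.0, 0.5, 0.5], abs=1e-9)
        assert vrs == pytest.approx([1.0, 0.5, 1.0], abs=1e-9)

    def test_units_invariance(self, rng):
        X = rng.uniform(1, 10, (6, 3))
        Y = rng.uniform(1, 10, (6, 2))
        X2 = X * np.array([1000.0, 1.0, 0.01])
        Y2 = Y * np.array([5.0, 500.0])
        for j in range(6):
            for rts in ("CRS", "VRS"):
                t1, _ = solve_envelopment(j, X, Y, rts)
                t2, _ = solve_envelopment(j, X2, Y2, rts)
                assert t1 == pytest.approx(t2, abs=1e-9)

    def test_crs_matches_ratio_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 7))
            X = rng.uniform(0.5, 10, (n, 1))
            Y = rng.uniform(0.5, 10, (n, 1))
            want = crs_ratio_oracle(X, Y)
            got = [solve_envelopment(j, X, Y, "CRS")[0] for j in range(n)]
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_lambda_feasibility(self, rng):
        X = rng.uniform(1, 10, (5, 2))
        Y = rng.uniform(1, 10, (5, 2))
        for j in range(5):
            theta, lam = solve_envelopment(j, X, Y, "VRS")
            assert np.all(lam >= -1e-9)
            assert lam.sum() == pytest.approx(1.0, abs=1e-7)
            assert np.all(lam @ X <= theta * X[j] + 1e-7)
            assert np.all(lam @ Y >= Y[j] - 1e-7)


class TestSlacks:
    def test_efficient_dmu_has_zero_slacks(self):
        X, Y = single_in_out((2.0, 4.0), (4.0, 4.0), (1.0, 1.0))
        s_in, s_out, _ = max_slacks(0, 1.0, X, Y, "VRS")
        assert np.all(s_in <= 1e-9) and np.all(s_out <= 1e-9)

    def test_radially_efficient_but_mix_inefficient_dmu(self):
        """C uses 1 more of input 2 than A at the same output: theta_VRS = 1
        with a positive slack on input 2."""
        X = np.array([[1.0, 2.0], [2.0, 1.0], [1.0, 3.0]])
        Y = np.array([[1.0], [1.0], [1.0]])
        theta, _ = solve_envelopment(2, X, Y, "VRS")
        assert theta == pytest.approx(1.0, abs=1e-9)
        s_in, s_out, _ = max_slacks(2, theta, X, Y, "VRS")
        assert s_in[0] == pytest.approx(0.0, abs=1e-9)
        assert s_in[1] == pytest.approx(1.0, abs=1e-9)

    def test_slack_solution_replays_constraints(self, rng):
        X = rng.uniform(1, 10, (6, 3))
        Y = rng.uniform(1, 10, (6, 2))
        for j in range(6):
            theta, _ = solve_envelopment(j, X, Y, "VRS")
            s_in, s_out, lam = max_slacks(j, theta, X, Y, "VRS")
            np.testing.assert_allclose(lam @ X + s_in, theta * X[j], atol=1e-6)
            np.testing.assert_allclose(lam @ Y - s_out, Y[j], atol=1e-6)
            assert np.all(s_in >= 0) and np.all(s_out >= 0)


class TestEfficiencyTable:
    def test_te_pte_se_decomposition(self, default_panel):
        scores = efficiency_table(default_panel, 2014)
        assert any(s.theta_vrs >= 1 - 1e-9 for s in scores)  # someone spans the frontier
        for s in scores:
            assert s.theta_crs <= s.theta_vrs + 1e-9
            assert s.scale_eff * s.theta_vrs == pytest.approx(s.theta_crs, abs=1e-9)
            assert 0 < s.theta_crs <= 1 and 0 < s.theta_vrs <= 1

    def test_identical_dmus_are_all_efficient(self):
        recs = [
            hera.CityYearRecord(city=f"C{i}", year=2014, region="r", population=10.0,
                                area=5.0, beds=20.0, outpatient_volume=7.0)
            for i in range(4)
        ]
        panel = hera.ResourcePanel(recs)
        spec = DeaModelSpec(input_fields=("beds",), output_fields=("outpatient_volume",),
                            per_capita_fields=())
        for s in efficiency_table(panel, 2014, spec):
            assert s.theta_crs == pytest.approx(1.0, abs=1e-9)
            assert s.theta_vrs == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_dmu_leaves_scores_unchanged(self, rng):
        X = rng.uniform(1, 10, (5, 2))
        Y = rng.uniform(1, 10, (5, 2))
        X2 = np.vstack([X, X[2]])
        Y2 = np.vstack([Y, Y[2]])
        for j in range(5):
            for rts in ("CRS", "VRS"):
                assert solve_envelopment(j, X, Y, rts)[0] == pytest.approx(
                    solve_envelopment(j, X2, Y2, rts)[0], abs=1e-9
                )

    def test_worsening_an_input_never_raises_theta(self, rng):
        X = rng.uniform(1, 10, (6, 2))
        Y = rng.uniform(1, 10, (6, 2))
        j = int(np.argmin([solve_envelopment(k, X, Y, "CRS")[0] for k in range(6)]))
        base = solve_envelopment(j, X, Y, "CRS")[0]
        X2 = X.copy()
        X2[j, 0] *= 1.5
        worse = solve_envelopment(j, X2, Y, "CRS")[0]
        assert worse <= base + 1e-9

    def test_recovers_generator_truth_rmse(self):
        """theta_VRS estimated on synthetic frontier data tracks the drawn
        inefficiencies to within 0.02 RMSE of the upward DEA bias envelope."""
        fc = hera.FrontierGenConfig(seed=7, sigma_u=0.15)
        panel, truth = hera.generate_frontier_panel(fc)
        spec = DeaModelSpec(input_fields=fc.input_fields, output_fields=fc.output_fields,
                            per_capita_fields=())
        year = panel.years[0]
        scores = efficiency_table(panel, year, spec)
        tr = truth.frame.query("year == @year").set_index("city")["efficiency"]
        est = np.array([s.theta_vrs for s in scores])
        tru = np.array([tr[s.dmu] for s in scores])
        assert est.mean() >= tru.mean() - 0.01  # finite-sample upward bias
        assert np.sqrt(np.mean((est - np.minimum(1.0, tru / tru.max())) ** 2)) < 0.15


class TestAdjustments:
    def test_efficient_city_gets_all_zero_row(self, default_panel):
        spec = DeaModelSpec()
        scores = efficiency_table(default_panel, 2014, spec)
        _, X, Y = build_matrices(default_panel, 2014, spec)
        rows = {r.dmu: r for r in adjustment_table(scores, X, Y)}
        for s in scores:
            r = rows[s.dmu]
            zero = np.all(r.input_variations == 0) and np.all(r.output_variations == 0)
            needs_nothing = s.efficient_vrs and np.all(s.input_slacks == 0) and np.all(
                s.output_slacks == 0)
            assert zero == needs_nothing
            assert np.all(r.input_variations <= 0)
            assert np.all(r.output_variations >= 0)

    def test_radial_variation_formula(self):
        """theta = 0.9, x = (10, 20), zero slacks -> variations (-1, -2)."""
        sc = hera.DmuScore(dmu="A", theta_crs=0.9, theta_vrs=0.9, scale_eff=1.0,
                           lambdas=np.array([1.0]), input_slacks=np.zeros(2),
                           output_slacks=np.zeros(1), peers=("B",))
        row = adjustment_table([sc], np.array([[10.0, 20.0]]), np.array([[1.0]]))[0]
        np.testing.assert_allclose(row.input_variations, [-1.0, -2.0], atol=1e-9)
        np.testing.assert_allclose(row.output_variations, [0.0])

    def test_projected_point_is_efficient(self, rng):
        X = rng.uniform(1, 10, (7, 2))
        Y = rng.uniform(1, 10, (7, 2))
        j = int(np.argmin([solve_envelopment(k, X, Y, "VRS")[0] for k in range(7)]))
        theta, _ = solve_envelopment(j, X, Y, "VRS")
        s_in, s_out, _ = max_slacks(j, theta, X, Y, "VRS")
        x_proj = theta * X[j] - s_in
        y_proj = Y[j] + s_out
        t2, _ = solve_envelopment(0, X, Y, "VRS", point=(x_proj, y_proj))
        assert t2 == pytest.approx(1.0, abs=1e-6)
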