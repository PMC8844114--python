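"""Soil sampling design, variogram fitting and ordinary kriging."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

import traitscape as tc
from traitscape.soil import SoilSamples, VariogramModel, empirical_variogram


def _samples(coords, values, plot=(100.0, 100.0), name="v"):
    df = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], name: values})
    return SoilSamples(df, plot_width=plot[0], plot_height=plot[1])


class TestDesignSoilGrid:
    def test_20ha_plot_has_238_nodes_714_points(self):
        layout = tc.design_soil_grid((500.0, 400.0), rng=np.random.default_rng(0))
        assert (layout["kind"] == "grid").sum() == 238
        assert len(layout) == 714

    def test_offset_points_at_exact_distances(self):
        rng = np.random.default_rng(1)
        layout = tc.design_soil_grid((500.0, 400.0), rng=rng)
        nodes = layout[layout["kind"] == "grid"].set_index("parent")
        offs = layout[layout["kind"] == "offset"]
        # interior nodes only: boundary clipping may shorten the distance
        for _, row in offs.iterrows():
            node = nodes.loc[row["parent"]]
            if 15 <= node["x"] <= 485 and 15 <= node["y"] <= 385:
                d = np.hypot(row["x"] - node["x"], row["y"] - node["y"])
                assert min(abs(d - o) for o in (2.0, 5.0, 15.0)) < 1e-9

    def test_seeded_layout_reproducible(self):
        a = tc.design_soil_grid((200.0, 200.0), rng=np.random.default_rng(7))
        b = tc.design_soil_grid((200.0, 200.0), rng=np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)


class TestFitVariogram:
    def _simulate_exponential(self, nugget, psill, range_, n, seed):
        """Draw one Gaussian field realization with exponential covariance."""
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 300, size=(n, 2))
        d = cdist(coords, coords)
        cov = psill * np.exp(-3.0 * d / range_) + nugget * np.eye(n)
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
        values = chol @ rng.standard_normal(n)
        return _samples(coords, values, plot=(300.0, 300.0))

    def test_recovers_known_exponential_parameters(self):
        true = dict(nugget=0.2, psill=1.0, range_=100.0)
        # average over a few independent realizations: a single field's
        # empirical variogram fluctuates, the estimator should not be biased
        fits = []
        for seed in (0, 1, 2):
            s = self._simulate_exponential(n=500, seed=seed, **true)
            fits.append(tc.fit_variogram(s, "v", model="exponential"))
        sill_hat = np.mean([f.sill for f in fits])
        range_hat = np.mean([f.range_ for f in fits])
        assert sill_hat == pytest.approx(true["nugget"] + true["psill"], rel=0.25)
        assert range_hat == pytest.approx(true["range_"], rel=0.25)

    def test_pure_nugget_data_fits_flat_variogram(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 100, size=(400, 2))
        values = rng.standard_normal(400)
        s = _samples(coords, values)
        fit = tc.fit_variogram(s, "v")
        var = values.var(ddof=1)
        assert fit.sill == pytest.approx(var, rel=0.2)
        # the model should already be near the sill at the first lag
        emp = empirical_variogram(s.coords, values)
        assert fit(np.array([emp["lag"].iloc[0]]))[0] == pytest.approx(var, rel=0.3)

    def test_constant_variable_rejected(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 100, size=(50, 2))
        with pytest.raises(ValueError, match="zero variance"):
            tc.fit_variogram(_samples(coords, np.ones(50)), "v")


class TestKrige:
    def test_constant_samples_give_constant_field(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 100, size=(40, 2))
        s = _samples(coords, np.full(40, 7.25))
        grid = tc.QuadratGrid(scale=20.0, n_x=5, n_y=5)
        vm = VariogramModel("spherical", nugget=0.1, psill=1.0, range_=50.0)
        field = tc.krige(s, "v", grid, vm)
        assert np.allclose(field.values, 7.25, atol=1e-8)

    def test_zero_nugget_exact_at_sample_locations(self):
        grid = tc.QuadratGrid(scale=20.0, n_x=4, n_y=4)
        coords = grid.centers()
        rng = np.random.default_rng(6)
        values = rng.normal(size=len(coords))
        s = _samples(coords, values)
        vm = VariogramModel("spherical", nugget=0.0, psill=1.0, range_=60.0)
        field = tc.krige(s, "v", grid, vm)
        assert np.allclose(field.values, values, atol=1e-8)

    def test_five_point_configuration_matches_direct_solve(self):
        coords = np.array([[10.0, 10.0], [80.0, 15.0], [50.0, 50.0], [20.0, 85.0], [90.0, 90.0]])
        values = np.array([1.0, 3.0, -2.0, 0.5, 4.0])
        s = _samples(coords, values)
        vm = VariogramModel("exponential", nugget=0.1, psill=2.0, range_=70.0)
        grid = tc.QuadratGrid(scale=50.0, n_x=2, n_y=2)
        field = tc.krige(s, "v", grid, vm)
        # independent oracle: assemble and solve the OK system per point
        for q, target in enumerate(grid.centers()):
            n = len(values)
            a = np.zeros((n + 1, n + 1))
            a[:n, :n] = vm(cdist(coords, coords))
            np.fill_diagonal(a[:n, :n], 0.0)
            a[:n, n] = a[n, :n] = 1.0
            b = np.append(vm(cdist(coords, target[None, :])).ravel(), 1.0)
            w = np.linalg.solve(a, b)
            assert field.values[q] == pytest.approx(w[:n] @ values, abs=1e-8)
            assert w[:n].sum() == pytest.approx(1.0, abs=1e-10)

    def test_prediction_linear_in_sample_values(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 100, size=(30, 2))
        v = rng.normal(size=30)
        grid = tc.QuadratGrid(scale=25.0, n_x=4, n_y=4)
        vm = VariogramModel("spherical", nugget=0.2, psill=1.0, range_=40.0)
        base = tc.krige(_samples(coords, v), "v", grid, vm).values
        scaled = tc.krige(_samples(coords, 2.5 * v - 3.0), "v", grid, vm).values
        assert np.allclose(scaled, 2.5 * base - 3.0, atol=1e-8)

    def test_duplicate_coordinates_handled(self):
        coords = np.vstack([np.full((2, 2), 50.0), np.random.default_rng(9).uniform(0, 100, (20, 2))])
        values = np.random.default_rng(10).normal(size=22)
        grid = tc.QuadratGrid(scale=50.0, n_x=2, n_y=2)
        vm = VariogramModel("spherical", nugget=0.1, psill=1.0, range_=40.0)
        field = tc.krige(_samples(coords, values), "v", grid, vm)
        assert np.all(np.isfinite(field.values))


class TestSoilSummary:
    def test_constant_field_sd_zero(self):
        grid = tc.QuadratGrid(scale=10.0, n_x=3, n_y=3)
        fields = {("v", 10.0): tc.GridField(grid, "v", np.full(9, 2.0))}
        table = tc.soil_summary(fields)
        assert table["sd"].iloc[0] == 0.0
        assert table["mean"].iloc[0] == 2.0

    def test_matches_direct_recompute(self):
        rng = np.random.default_rng(11)
        grid = tc.QuadratGrid(scale=10.0, n_x=4, n_y=3)
        vals = rng.normal(size=12)
        table = tc.soil_summary({("v", 10.0): tc.GridField(grid, "v", vals)})
        assert table["mean"].iloc[0] == pytest.approx(vals.mean())
        assert table["sd"].iloc[0] == pytest.approx(vals.std(ddof=1))

    def test_means_nearly_scale_invariant_for_smooth_field(self, mini_study):
        # kriged means should barely move across scales on a smooth surface
        grids = {s: tc.make_grid(mini_study.census, s).grid for s in (5.0, 10.0, 20.0)}
        fields, _ = tc.krige_all(mini_study.soil_samples, grids)
        table = tc.soil_summary(fields)
        for var in ("AP", "AK", "AN"):
            means = table[table["variable"] == var]["mean"].to_numpy()
            assert np.ptp(means) < 0.05 * abs(means.mean())

    def test_fine_scale_field_aggregates_to_coarse(self, mini_study):
        # the 50 m prediction tracks the mean of its nested 5 m predictions
        grids = {5.0: tc.QuadratGrid(5.0, 20, 20), 50.0: tc.QuadratGrid(50.0, 2, 2)}
        fields, _ = tc.krige_all(mini_study.soil_samples, grids)
        f5 = grids[5.0].as_matrix(fields[("AK", 5.0)].values)
        agg = f5.reshape(2, 10, 2, 10).mean(axis=(1, 3)).ravel()
        coarse = fields[("AK", 50.0)].values
        assert np.corrcoef(agg, coarse)[0, 1] > 0.9
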