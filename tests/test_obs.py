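"""Observation binning, skill statistics, and synthetic observations."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from feiso.grid import VerticalGrid
from feiso.obs import bin_obs, extract_model, read_obs_csv, skill, synth_obs


def make_dataset(n_levels=31, delta_span=(-1.0, 1.0), dfe_level=0.5e-6):
    """Synthetic model field: delta varies smoothly with depth and month."""
    grid = VerticalGrid.default(n_levels)
    months = np.arange(1, 13)
    z = grid.center
    base = np.linspace(delta_span[0], delta_span[1], n_levels)
    delta = base[None, :] + 0.05 * np.cos(2 * np.pi * (months[:, None] - 7) / 12.0)
    dfe = dfe_level * (0.3 + z[None, :] / z.max()) * np.ones((12, 1))
    return xr.Dataset(
        {
            "dfe": (("month", "z"), dfe),
            "delta_dfe": (("month", "z"), delta),
        },
        coords={"month": months, "z": z},
        attrs={"reference_ratio": 15.67},
    ), grid


def record(lat=10.2, lon=-20.7, depth=55.0, month=3, dfe=0.5, delta=0.1):
    return {
        "lat": lat, "lon": lon, "depth_m": depth, "month": month,
        "dfe_umol_m3": dfe, "delta56_permil": delta, "uncert_permil": 0.05,
    }


class TestBinObs:
    def test_single_record_maps_to_bin_center(self):
        out = bin_obs(pd.DataFrame([record()]))
        assert len(out) == 1
        assert out["lat"][0] == 10.5 and out["lon"][0] == -20.5
        assert out["depth_m"][0] == 55.0          # level 50-60 m center
        assert out["delta56_permil"][0] == 0.1

    def test_duplicates_averaged(self):
        out = bin_obs(pd.DataFrame([record(delta=-0.2), record(delta=-0.4)]))
        assert len(out) == 1
        assert out["delta56_permil"][0] == pytest.approx(-0.3)

    def test_distinct_months_not_merged(self):
        out = bin_obs(pd.DataFrame([record(month=3), record(month=4)]))
        assert len(out) == 2

    def test_display_mode_pairs_upper_levels(self):
        # 190 m lies in the 16th layer (169-197 m); display mode pairs it
        # with the 15th (150-169 m) into one 150-197 m bin
        out = bin_obs(pd.DataFrame([record(depth=190.0)]), section_display=True)
        assert out["depth_m"][0] == pytest.approx(0.5 * (150.0 + 197.0))

    def test_display_mode_below_197m_unpaired(self):
        out = bin_obs(pd.DataFrame([record(depth=500.0)]), section_display=True)
        assert out["depth_m"][0] == pytest.approx(0.5 * (430.0 + 612.0))

    def test_idempotent(self, rng):
        records = pd.DataFrame(
            [record(lat=rng.uniform(-60, 60), lon=rng.uniform(-180, 180),
                    depth=rng.uniform(0, 5400), month=int(rng.integers(1, 13)),
                    dfe=rng.uniform(0.1, 1.0), delta=rng.uniform(-1, 1))
             for _ in range(200)]
        )
        once = bin_obs(records)
        twice = bin_obs(once)
        once_sorted = once.sort_values(["lat", "lon", "depth_m", "month"]).reset_index(drop=True)
        twice_sorted = twice.sort_values(["lat", "lon", "depth_m", "month"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(once_sorted, twice_sorted, check_like=True)

    def test_invalid_coordinates_dropped(self, caplog):
        out = bin_obs(pd.DataFrame([record(lat=95.0), record()]))
        assert len(out) == 1


class TestSkill:
    def test_perfect_agreement(self):
        ds, grid = make_dataset()
        obs = synth_obs(ds, n_stations=5, noise_sd=0.0, dfe_noise_sd=0.0, seed=1, grid=grid)
        paired = extract_model(ds, obs, grid)
        rep = skill(paired, "delta56")
        assert rep.r == pytest.approx(1.0)
        assert rep.rmse == pytest.approx(0.0, abs=1e-12)
        assert rep.slope == pytest.approx(1.0, abs=1e-10)
        assert rep.intercept == pytest.approx(0.0, abs=1e-10)

    def test_constant_offset(self):
        ds, grid = make_dataset()
        obs = synth_obs(ds, n_stations=5, noise_sd=0.0, dfe_noise_sd=0.0, seed=1, grid=grid)
        obs["delta56_permil"] = obs["delta56_permil"] - 0.1   # model = obs + 0.1
        paired = extract_model(ds, obs, grid)
        rep = skill(paired, "delta56")
        assert rep.r == pytest.approx(1.0)
        assert rep.rmse == pytest.approx(0.1, abs=1e-10)
        assert rep.slope == pytest.approx(1.0, abs=1e-10)
        assert rep.intercept == pytest.approx(0.1, abs=1e-10)

    def test_against_normal_equations_oracle(self, rng):
        obs = rng.normal(0.0, 0.5, 20)
        mod = obs * 0.7 + 0.1 + rng.normal(0.0, 0.1, 20)
        paired = pd.DataFrame({"delta56_permil": obs, "model_delta56_permil": mod})
        rep = skill(paired, "delta56")
        # independent closed-form least squares of model on obs
        x = np.column_stack([np.ones(20), obs])
        beta = np.linalg.solve(x.T @ x, x.T @ mod)
        assert rep.intercept == pytest.approx(beta[0], abs=1e-8)
        assert rep.slope == pytest.approx(beta[1], abs=1e-8)
        assert rep.r == pytest.approx(np.corrcoef(obs, mod)[0, 1], abs=1e-12)
        assert rep.rmse == pytest.approx(np.sqrt(np.mean((mod - obs) ** 2)), abs=1e-12)

    def test_orientation_flag(self, rng):
        obs = rng.normal(0.0, 0.5, 50)
        mod = obs * 0.5
        paired = pd.DataFrame({"delta56_permil": obs, "model_delta56_permil": mod})
        assert skill(paired, "delta56").slope == pytest.approx(0.5, abs=1e-10)
        assert skill(paired, "delta56", regress_obs_on_model=True).slope == pytest.approx(
            2.0, abs=1e-10)

    def test_dfe_log_transform(self):
        ds, grid = make_dataset()
        obs = synth_obs(ds, n_stations=5, noise_sd=0.0, dfe_noise_sd=0.0, seed=1, grid=grid)
        paired = extract_model(ds, obs, grid)
        rep = skill(paired, "dfe", log_dfe=True)
        assert rep.rmse == pytest.approx(0.0, abs=1e-10)
        assert abs(rep.mean_obs) < 2.0      # log10 of sub-micromolar values

    def test_too_few_pairs(self):
        paired = pd.DataFrame({"delta56_permil": [0.1, 0.2],
                               "model_delta56_permil": [0.1, 0.2]})
        with pytest.raises(ValueError, match="at least 3"):
            skill(paired, "delta56")


class TestSynthObs:
    def test_zero_noise_equals_model(self):
        ds, grid = make_dataset()
        obs = synth_obs(ds, n_stations=3, noise_sd=0.0, dfe_noise_sd=0.0, seed=0, grid=grid)
        paired = extract_model(ds, obs, grid)
        np.testing.assert_allclose(
            paired["delta56_permil"], paired["model_delta56_permil"], atol=1e-12)

    def test_deterministic_per_seed(self):
        ds, grid = make_dataset()
        a = synth_obs(ds, n_stations=4, seed=9, grid=grid)
        b = synth_obs(ds, n_stations=4, seed=9, grid=grid)
        pd.testing.assert_frame_equal(a, b)
        c = synth_obs(ds, n_stations=4, seed=10, grid=grid)
        assert not a.equals(c)

    def test_surface_uncertainty_multiplier(self):
        ds, grid = make_dataset()
        obs = synth_obs(ds, n_stations=10, noise_sd=0.05, seed=3, grid=grid)
        surf = obs[obs["depth_m"] < 100.0]["uncert_permil"]
        deep = obs[obs["depth_m"] >= 100.0]["uncert_permil"]
        assert np.allclose(surf, 0.1) and np.allclose(deep, 0.05)

    def test_parameter_recovery_at_n500(self):
        """Regressing the model against 500 synthetic observations with
        0.05 permil analytical noise recovers slope 1 within 0.05."""
        ds, grid = make_dataset()
        obs = synth_obs(ds, n_stations=20, samples_per_station=25,
                        noise_sd=0.05, seed=42, grid=grid)
        assert len(obs) == 500
        paired = extract_model(ds, obs, grid)
        rep = skill(paired, "delta56")
        assert abs(rep.slope - 1.0) < 0.05
        assert abs(rep.intercept) < 0.05
        # residual scatter reflects the injected analytical noise
        assert rep.rmse == pytest.approx(0.05, rel=0.35)


def test_read_obs_csv_roundtrip(tmp_path):
    df = pd.DataFrame([record(), record(depth=500.0, month=7)])
    path = tmp_path / "obs.csv"
    df.to_csv(path, index=False)
    back = read_obs_csv(path)
    pd.testing.assert_frame_equal(back, df)
    bad = pd.DataFrame({"lat": [1.0], "lon": [2.0]})
    bad_path = tmp_path / "bad.csv"
    bad.to_csv(bad_path, index=False)
    with pytest.raises(ValueError):
        read_obs_csv(bad_path)
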