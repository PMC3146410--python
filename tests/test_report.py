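import json

import numpy as np
import pandas as pd
import pytest

from accessineq import (
    AccessResult,
    CSRConfig,
    InputError,
    RunConfig,
    assign_nearest,
    inequality_summary,
    load_config,
    mean_access_time,
    run_analysis,
    simulate_expected_D,
    travel_time_summary,
    weighted_quantile,
)
from accessineq.io import (
    write_blocks_csv,
    write_facilities_csv,
    write_network_csv,
    write_region_geojson,
)
from accessineq.synthetic import ScenarioSpec, make_scenario


def _access(times, pops):
    frame = pd.DataFrame(
        {
            "block_id": [f"B{i}" for i in range(len(times))],
            "facility_id": "F0",
            "distance_km": np.asarray(times, dtype=float),
            "time_min": np.asarray(times, dtype=float),
            "population": pops,
        }
    )
    return AccessResult(frame=frame)


class TestWeightedQuantile:
    def test_matches_numpy_on_exploded_sample(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            n = int(rng.integers(2, 25))
            x = rng.uniform(0, 50, n)
            w = rng.integers(1, 8, n)
            q = rng.uniform(0, 1, 5)
            exploded = np.repeat(x, w)
            got = weighted_quantile(x, w.astype(float), q)
            assert got == pytest.approx(np.quantile(exploded, q), abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            weighted_quantile(np.array([]), np.array([]), 0.5)


class TestTravelTimeSummary:
    def test_constant_times_collapse_with_no_outliers(self):
        s = travel_time_summary(_access([3.0] * 8, [2] * 8))
        assert s.median == s.q1 == s.q3 == s.whisker_lo == s.whisker_hi == 3.0
        assert s.outliers.size == 0

    def test_uniform_1_to_100(self):
        vals = list(range(1, 101))
        s = travel_time_summary(_access(vals, [1] * 100))
        assert s.median == 50.5
        assert s.q1 == pytest.approx(np.quantile(vals, 0.25))
        assert s.q3 == pytest.approx(np.quantile(vals, 0.75))
        assert s.outliers.size == 0

    def test_heavily_weighted_tail_dominates_median(self):
        s = travel_time_summary(_access([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 97]))
        assert s.median == 4.0

    def test_outliers_beyond_whiskers(self):
        vals = [1.0] * 20 + [1.2] * 20 + [50.0]
        s = travel_time_summary(_access(vals, [1] * 41))
        assert 50.0 in s.outliers
        assert s.whisker_hi < 50.0


@pytest.fixture(scope="module")
def scenario_files(tmp_path_factory):
    root = tmp_path_factory.mktemp("scenario")
    sc = make_scenario(
        ScenarioSpec(arrangement="clustered", n_blocks=40, n_facilities=4,
                     grid_nx=9, grid_ny=9, seed=17)
    )
    write_blocks_csv(sc.blocks, root / "blocks.csv")
    write_facilities_csv(sc.facilities, root / "facilities.csv")
    write_network_csv(sc.network, root / "network.csv")
    write_region_geojson(sc.region, root / "region.geojson")
    return root, sc


class TestRunAnalysis:
    def _config(self, root, out):
        return RunConfig(
            blocks=str(root / "blocks.csv"),
            facilities=str(root / "facilities.csv"),
            regions=str(root / "region.geojson"),
            network=str(root / "network.csv"),
            out_dir=str(out),
            n_reps=11,
            seed=5,
        )

    def test_summary_matches_hand_composed_modules(self, scenario_files, tmp_path):
        root, sc = scenario_files
        cfg = self._config(root, tmp_path / "out")
        summary, access, sidecar = run_analysis(cfg)
        row = summary[summary.region_id == sc.region.region_id].iloc[0]

        direct = simulate_expected_D(
            sc.network, sc.blocks, sc.facilities, sc.region,
            config=CSRConfig(n_reps=11, seed=5),
        )
        assert row.D == pytest.approx(direct.d_observed, abs=1e-12)
        assert row.D_bar == pytest.approx(direct.d_bar, abs=1e-12)
        assert row.ratio == pytest.approx(direct.ratio, abs=1e-12)

        reg_access = assign_nearest(sc.network, sc.blocks, sc.facilities)
        assert row.mean_time_min == pytest.approx(mean_access_time(reg_access), abs=1e-12)
        assert row.population == sum(b.population for b in sc.blocks)
        assert row.n_facilities == 4
        assert row.pop_per_facility == pytest.approx(row.population / 4)
        assert row.area_km2 == pytest.approx(sc.region.area_km2)

        total = summary[summary.region_id == "TOTAL"].iloc[0]
        pooled = inequality_summary(access.sample())
        assert total.D == pytest.approx(pooled.D, abs=1e-12)

    def test_rerun_is_byte_identical(self, scenario_files, tmp_path):
        root, _ = scenario_files
        out1, out2 = tmp_path / "a", tmp_path / "b"
        run_analysis(self._config(root, out1))
        run_analysis(self._config(root, out2))
        for name in ("summary.csv", "access.csv", "sidecar.json"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_sidecar_carries_simulated_vectors(self, scenario_files, tmp_path):
        root, sc = scenario_files
        run_analysis(self._config(root, tmp_path / "out"))
        sidecar = json.loads((tmp_path / "out" / "sidecar.json").read_text())
        region = sidecar["regions"][0]
        assert len(region["simulated"]) == 11
        assert region["seed"] == 5


class TestConfigFile:
    def test_parse_roundtrip(self, scenario_files, tmp_path):
        root, _ = scenario_files
        cfg_path = tmp_path / "run.cfg"
        cfg_path.write_text(
            "# pipeline settings\n"
            f"blocks = {root / 'blocks.csv'}\n"
            f"facilities = {root / 'facilities.csv'}\n"
            f"regions = {root / 'region.geojson'}\n"
            f"network = {root / 'network.csv'}\n"
            "n_reps = 7\nseed = 3\nweight = distance\n"
            "speed.toll = 100\n"
        )
        cfg = load_config(cfg_path)
        assert cfg.n_reps == 7 and cfg.seed == 3
        assert cfg.speeds.speed("toll") == 100.0
        assert cfg.speeds.speed("other") == 40.0

    def test_unknown_key_rejected(self, scenario_files, tmp_path):
        root, _ = scenario_files
        cfg_path = tmp_path / "run.cfg"
        cfg_path.write_text(
            f"blocks = {root / 'blocks.csv'}\n"
            f"facilities = {root / 'facilities.csv'}\n"
            f"regions = {root / 'region.geojson'}\n"
            "frobnicate = yes\n"
        )
        with pytest.raises(InputError):
            load_config(cfg_path)

    def test_missing_input_file_rejected(self):
        with pytest.raises(InputError):
            RunConfig(blocks="nope.csv", facilities="nope.csv", regions="nope.geojson",
                      metric="euclidean")
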