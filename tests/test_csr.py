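import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare
from shapely.geometry import Polygon, box

from accessineq import (
    CSRConfig,
    DegenerateRegionError,
    InputError,
    Region,
    SpeedTable,
    rank_regions,
    rank_table,
    sample_csr_points,
    simulate_expected_D,
    standardized_ratio,
)
from accessineq.csr import CSRResult
from accessineq.synthetic import ScenarioSpec, make_scenario

# Published per-area values the standardization is checked against:
# observed D, its CSR expectation, the printed ratio and both rank orders.
AREA_TABLE = pd.DataFrame(
    {
        "region_id": ["Chubu", "Hohi", "Hokubu", "Nambu", "Seibu", "Tobu"],
        "D": [1.081, 0.930, 1.077, 1.147, 1.083, 1.337],
        "D_bar": [0.456, 0.340, 0.341, 0.257, 0.367, 0.732],
        "ratio": [2.370, 2.736, 3.159, 4.464, 2.950, 1.827],
        "rank_D": [3, 1, 2, 5, 4, 6],
        "rank_ratio": [2, 3, 5, 6, 4, 1],
    }
)


class TestSampleCSRPoints:
    def test_zero_points(self):
        region = Region("r", box(0, 0, 1, 1))
        pts = sample_csr_points(region, 0, np.random.default_rng(0))
        assert pts.shape == (0, 2)

    def test_unit_square_uniformity_quadrat_chi_square(self):
        region = Region("sq", box(0, 0, 1, 1))
        pts = sample_csr_points(region, 10_000, np.random.default_rng(2024))
        assert np.all((pts >= 0) & (pts <= 1))
        # 4x4 equal-area quadrats; CSR should not be rejected at alpha=0.001
        ix = np.minimum((pts[:, 0] * 4).astype(int), 3)
        iy = np.minimum((pts[:, 1] * 4).astype(int), 3)
        counts = np.bincount(ix * 4 + iy, minlength=16)
        p = chisquare(counts).pvalue
        assert p > 0.001

    def test_l_shaped_polygon_excluded_quadrant_empty(self):
        l_shape = Polygon([(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)])
        region = Region("L", l_shape)
        pts = sample_csr_points(region, 3000, np.random.default_rng(7))
        in_excluded = (pts[:, 0] > 1) & (pts[:, 1] > 1)
        assert in_excluded.sum() == 0

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(DegenerateRegionError):
            Region("line", Polygon([(0, 0), (1, 0), (2, 0)]))


class TestStandardizedRatio:
    @pytest.mark.parametrize(
        "d,dbar,expected",
        [(1.077, 0.341, 3.159), (1.337, 0.732, 1.827)],
    )
    def test_printed_area_values(self, d, dbar, expected):
        # within one unit in the 3rd decimal: the published ratios were
        # computed from unrounded D and D_bar
        assert standardized_ratio(d, dbar) == pytest.approx(expected, abs=1.1e-3)

    def test_identity(self):
        assert standardized_ratio(0.87, 0.87) == 1.0

    def test_requires_positive_dbar(self):
        with pytest.raises(InputError):
            standardized_ratio(1.0, 0.0)
        with pytest.raises(InputError):
            standardized_ratio(1.0, -0.2)


@pytest.fixture(scope="module")
def small_scenario():
    spec = ScenarioSpec(
        arrangement="clustered",
        n_blocks=50,
        n_facilities=5,
        grid_nx=12,
        grid_ny=12,
        seed=21,
    )
    return make_scenario(spec)


class TestSimulateExpectedD:
    def test_result_structure_and_pooled_mean(self, small_scenario):
        sc = small_scenario
        cfg = CSRConfig(n_reps=19, seed=4, metric="euclidean")
        res = simulate_expected_D(None, sc.blocks, sc.facilities, sc.region, config=cfg)
        assert res.simulated.shape == (19,)
        # D_bar pools the simulated values WITH the observed case
        pooled = np.mean(np.append(res.simulated, res.d_observed))
        assert res.d_bar == pytest.approx(pooled, abs=1e-15)
        assert res.ratio == pytest.approx(res.d_observed / res.d_bar)
        assert res.meta["n_inside"] == 5

    def test_same_seed_is_bit_identical(self, small_scenario):
        sc = small_scenario
        cfg = CSRConfig(n_reps=15, seed=9, metric="network")
        r1 = simulate_expected_D(sc.network, sc.blocks, sc.facilities, sc.region, config=cfg)
        r2 = simulate_expected_D(sc.network, sc.blocks, sc.facilities, sc.region, config=cfg)
        assert r1.d_observed == r2.d_observed
        assert np.array_equal(r1.simulated, r2.simulated)
        assert r1.ratio == r2.ratio

    def test_speed_scaling_leaves_everything_unchanged(self, small_scenario):
        # distance-based nearest assignment is speed-free and D is scale
        # invariant, so doubling every speed must not move a single bit
        sc = small_scenario
        cfg = CSRConfig(n_reps=15, seed=9, metric="network", weight="distance")
        r1 = simulate_expected_D(
            sc.network, sc.blocks, sc.facilities, sc.region, SpeedTable(), cfg
        )
        r2 = simulate_expected_D(
            sc.network, sc.blocks, sc.facilities, sc.region, SpeedTable().scaled(2.0), cfg
        )
        assert r1.d_observed == r2.d_observed
        assert np.array_equal(r1.simulated, r2.simulated)
        assert r1.ratio == r2.ratio

    def test_region_without_facilities_rejected(self, small_scenario):
        sc = small_scenario
        far = Region("far", box(1e6, 1e6, 2e6, 2e6))
        with pytest.raises(InputError):
            simulate_expected_D(None, sc.blocks, sc.facilities, far,
                                config=CSRConfig(n_reps=3, metric="euclidean"))

    def test_outside_facilities_stay_candidates(self):
        # one facility inside a small region, one just outside but closer
        # to a boundary block: the outside one must win assignments
        from conftest import make_blocks, make_facilities

        region = Region("west", box(0, 0, 1000, 1000))
        blocks = make_blocks([(900.0, 500.0), (100.0, 500.0)], pops=[1, 1])
        facs = make_facilities([(50.0, 500.0), (1100.0, 500.0)])
        cfg = CSRConfig(n_reps=5, seed=1, metric="euclidean")
        res = simulate_expected_D(None, blocks, facs, region, config=cfg)
        assert res.meta["n_inside"] == 1 and res.meta["n_outside"] == 1
        # observed: block at x=900 is served by the outside facility at 1100
        assert res.d_observed == pytest.approx(
            _d_two_blocks(d1=200.0, d2=50.0), abs=1e-12
        )


def _d_two_blocks(d1: float, d2: float) -> float:
    mean = (d1 + d2) / 2.0
    return (2 * abs(d1 - d2) / 4.0) / mean


class TestRanking:
    def test_single_region(self):
        res = CSRResult("only", 1.0, np.array([0.5]), 0.75, 4.0 / 3.0, 1, 0)
        table = rank_regions([res])
        assert list(table.rank_D) == [1] and list(table.rank_ratio) == [1]

    def test_published_tables_show_rank_reversal(self):
        ranked = rank_table(AREA_TABLE[["region_id", "D", "ratio"]])
        merged = ranked.merge(AREA_TABLE, on="region_id", suffixes=("", "_pub"))
        assert list(merged.rank_D) == list(merged.rank_D_pub)
        assert list(merged.rank_ratio) == list(merged.rank_ratio_pub)
        # the most unequal area by raw D is the least unequal by R
        worst_by_d = merged.loc[merged.rank_D.idxmax(), "region_id"]
        assert merged.loc[merged.region_id == worst_by_d, "rank_ratio"].item() == 1

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(
            {
                "region_id": [f"r{i}" for i in range(8)],
                "D": rng.uniform(0.5, 1.5, 8),
                "ratio": rng.uniform(1.0, 5.0, 8),
            }
        )
        ranked = rank_table(df)
        order = df.ratio.to_numpy().argsort()
        expected = np.empty(8, dtype=int)
        expected[order] = np.arange(1, 9)
        assert list(ranked.rank_ratio) == list(expected)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            rank_regions([])
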