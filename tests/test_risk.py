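"""Distance statistics, Welch t-test, risk edges and county percentages."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import LineString, Point, box

from invnet import (
    Lake,
    RegionUnit,
    Superhighway,
    county_risk_pct,
    cumulative_distance_curve,
    distance_to_superhighway,
    high_risk_edges,
    movement_medians,
    welch_t,
)
from invnet.risk import movement_risk_fraction


def _lake(lake_id, x, y, invaded=()):
    lk = Lake(lake_id, Point(x, y).buffer(0.1), area_ha=1.0)
    lk.invaded_by.update(invaded)
    return lk


def _edges(rows):
    return pd.DataFrame(
        rows, columns=["origin", "dest", "weight", "n_movements", "length_km"]
    )


class TestDistance:
    SH = Superhighway(
        segments=[LineString([(0, 0), (100, 0)])], retained_mask=np.ones((1, 1), bool)
    )

    def test_point_on_line_and_perpendicular(self):
        lakes = [_lake("on", 50, 0), _lake("off", 50, 10)]
        d = distance_to_superhighway(lakes, self.SH)
        assert d["on"] == pytest.approx(0.0, abs=1e-9)
        assert d["off"] == pytest.approx(10.0)

    def test_empty_superhighway_raises(self):
        empty = Superhighway(segments=[], retained_mask=np.zeros((1, 1), bool))
        with pytest.raises(ValueError):
            distance_to_superhighway([_lake("a", 0, 0)], empty)

    def test_matches_point_to_segment_bruteforce(self):
        def seg_dist(px, py, ax, ay, bx, by):
            # classic projection formula, clamped to the segment
            vx, vy = bx - ax, by - ay
            t = np.clip(((px - ax) * vx + (py - ay) * vy) / (vx**2 + vy**2), 0, 1)
            return np.hypot(px - (ax + t * vx), py - (ay + t * vy))

        rng = np.random.default_rng(23)
        verts = [(0, 0), (40, 15), (90, 5)]
        seg = LineString(verts)
        sh = Superhighway(segments=[seg], retained_mask=np.ones((1, 1), bool))
        lakes = [_lake(f"L{i}", *rng.uniform(0, 100, 2)) for i in range(1000)]
        got = distance_to_superhighway(lakes, sh)
        for lk in lakes:
            brute = min(
                seg_dist(lk.midpoint.x, lk.midpoint.y, *a, *b)
                for a, b in zip(verts, verts[1:])
            )
            assert got[lk.lake_id] == pytest.approx(brute, abs=1e-6)


class TestWelch:
    def test_identical_samples(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # means 2 and 5, both variances 1: t = -3/sqrt(2/3), df = 4
        r = welch_t([1, 2, 3], [4, 5, 6])
        assert r.t == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-4)
        assert r.t == pytest.approx(-3.6742, abs=1e-4)
        assert r.df == pytest.approx(4.0)

    def test_antisymmetry(self):
        r1 = welch_t([1, 2, 3], [4, 5, 7])
        r2 = welch_t([4, 5, 7], [1, 2, 3])
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(5, 60))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(5, 60))
            ours = welch_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)
            assert ours.df == pytest.approx(ref.df, abs=1e-10)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestCumulativeCurve:
    def test_point_values(self):
        curve = cumulative_distance_curve([1.0, 2.0, 3.0], [0.5, 2.0, 10.0])
        assert list(curve["proportion"]) == [0.0, pytest.approx(2 / 3), 1.0]

    def test_monotone_on_any_grid(self):
        rng = np.random.default_rng(4)
        d = rng.exponential(10, 500)
        grid = np.sort(rng.uniform(0, 60, 77))
        curve = cumulative_distance_curve(d, grid)
        assert (np.diff(curve["proportion"]) >= 0).all()
        assert curve["proportion"].iloc[-1] <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cumulative_distance_curve([], [1.0])


class TestHighRisk:
    LAKES = [
        _lake("I", 0, 0, invaded=("dreissena",)),
        _lake("U", 1, 0),
        _lake("I2", 2, 0, invaded=("myriophyllum",)),
    ]

    def test_invaded_to_uninvaded_retained_only(self):
        e = _edges(
            [
                ("I", "U", 1.0, 1, 1.0),  # invaded -> uninvaded: kept
                ("I", "I2", 1.0, 1, 1.0),  # invaded -> invaded: dropped
                ("U", "U", 1.0, 1, 1.0),  # uninvaded origin: dropped
            ]
        )
        hr = high_risk_edges(e, self.LAKES, {"dreissena", "myriophyllum"})
        assert list(zip(hr["origin"], hr["dest"])) == [("I", "U")]

    def test_taxon_scoping(self):
        e = _edges([("I2", "U", 1.0, 1, 1.0)])
        assert high_risk_edges(e, self.LAKES, {"dreissena"}).empty
        assert len(high_risk_edges(e, self.LAKES, {"myriophyllum"})) == 1

    def test_risk_fraction_reports_both_denominators(self):
        e = _edges([("I", "U", 2.0, 1, 1.0), ("U", "I", 1.0, 1, 1.0)])
        frac = movement_risk_fraction(e, self.LAKES, {"dreissena"})
        assert frac["count_fraction"] == pytest.approx(0.5)
        assert frac["weight_fraction"] == pytest.approx(2.0 / 3.0)


class TestCountyRisk:
    COUNTIES = [
        RegionUnit("west", box(0, 0, 10, 10)),
        RegionUnit("east", box(10, 0, 20, 10)),
    ]
    LAKES = [
        _lake("I", 2, 5, invaded=("dreissena",)),
        _lake("U", 5, 5),
        _lake("E", 15, 5),
    ]

    def test_percentage_and_no_data(self):
        e = _edges(
            [
                ("I", "U", 2.0, 1, 1.0),
                ("E", "U", 6.0, 1, 1.0),
            ]
        )
        hr = high_risk_edges(e, self.LAKES, {"dreissena"})
        table = county_risk_pct(e, hr, self.LAKES, self.COUNTIES).set_index("region_id")
        assert table.loc["west", "pct_high_risk"] == pytest.approx(25.0)  # 2 of 8
        assert bool(table.loc["east", "no_data"])
        assert np.isnan(table.loc["east", "pct_high_risk"])

    def test_high_risk_weight_conserved_across_counties(self, small_bundle):
        t = small_bundle.county_table
        assert t["high_risk_in_weight"].sum() == pytest.approx(
            small_bundle.high_risk["weight"].sum(), rel=1e-9
        )
        assert ((t["pct_high_risk"].dropna() >= 0) & (t["pct_high_risk"].dropna() <= 100)).all()


class TestMovementMedians:
    def test_simple_and_interpolated(self):
        m = pd.DataFrame(
            {
                "user_id": ["u"] * 3,
                "origin": ["A"] * 3,
                "dest": ["B"] * 3,
                "day_gap": [1, 7, 30],
                "length_km": [10.0, 20.0, 30.0],
                "weight": [1.0] * 3,
            }
        )
        assert movement_medians(m) == (7.0, 20.0)
        assert movement_medians(m.iloc[:2]) == (4.0, 15.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            movement_medians(pd.DataFrame(columns=["day_gap", "length_km"]))
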