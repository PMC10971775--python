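"""City grids, the above-threshold presence rule, and turnover accounting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from urbanshift.grids import FUTURE_SCENARIOS, SCENARIOS
from urbanshift.maxent import FeatureSpec, MaxEntResults
from urbanshift.occurrences import CityQuadrat
from urbanshift.projection import (
    build_city_grid,
    city_presence,
    compute_turnover,
)


class TestBuildCityGrid:
    def test_exactly_100_points_inside_with_2km_spacing(self):
        q = CityQuadrat("c", (150.0, 90.0))
        grid = build_city_grid(q)
        pts = grid.points
        assert len(pts) == 100
        assert q.contains(pts["x"].to_numpy(), pts["y"].to_numpy()).all()
        xy = pts[["x", "y"]].to_numpy()
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(2.0)

    def test_one_point_per_subcell(self):
        q = CityQuadrat("c", (0.0, 0.0))
        pts = build_city_grid(q).points
        cells = {(int(np.floor((x + 10) / 2)), int(np.floor((y + 10) / 2)))
                 for x, y in zip(pts["x"], pts["y"])}
        assert len(cells) == 100


def _flat_model(value_eta, threshold):
    """A 1-variable model whose logistic output is constant by construction."""
    res = MaxEntResults(
        spec=FeatureSpec("L"), var_names=["MAT"],
        variable_ranges={"MAT": (0.0, 1.0)}, params=np.array([0.0]),
        feature_names=["L(MAT)"], offset=-value_eta, entropy=0.0,
        threshold=threshold,
    )
    return res


class TestCityPresence:
    def test_boundary_mean_equal_threshold_is_absent(self, historic):
        # constant logistic score s: eta=0, offset=-v, H=0 -> s = e^v/(1+e^v)
        q = CityQuadrat("c", (120.0, 120.0))
        grid = build_city_grid(q)
        res = _flat_model(0.0, threshold=0.5)  # score exactly 0.5 everywhere
        mean_s, present = city_presence(res, historic, grid)
        assert mean_s == pytest.approx(0.5)
        assert present is False  # strictly "above" the threshold

    def test_dominant_suitability_is_present(self, historic):
        q = CityQuadrat("c", (120.0, 120.0))
        res = _flat_model(5.0, threshold=0.3)
        mean_s, present = city_presence(res, historic, build_city_grid(q))
        assert present is True

    def test_mostly_ocean_city_is_missing_and_absent(self, historic):
        # quadrat centered in the masked margin corner
        q = CityQuadrat("c", (5.0, 5.0), half_width=4.0)
        res = _flat_model(5.0, threshold=0.3)
        mean_s, present = city_presence(res, historic, build_city_grid(q))
        assert np.isnan(mean_s) and present is False

    def test_unthresholded_model_rejected(self, historic):
        res = _flat_model(0.0, threshold=None)
        res.threshold = None
        q = CityQuadrat("c", (120.0, 120.0))
        with pytest.raises(ValueError):
            city_presence(res, historic, build_city_grid(q))


def _matrix_from(presence: dict) -> pd.DataFrame:
    rows = []
    for (sp, city, sc), pres in presence.items():
        rows.append({"species_id": sp, "city": city, "scenario": sc,
                     "mean_suitability": 0.5 if pres else 0.1, "present": pres})
    return pd.DataFrame(rows)


class TestComputeTurnover:
    def _full(self, spp, cities, fill):
        return {(s, c, sc): fill(s, c, sc)
                for s in spp for c in cities for sc in SCENARIOS}

    def test_identity_future_means_zero_turnover(self):
        mat = _matrix_from(self._full(["s1", "s2"], ["c1"], lambda s, c, sc: s == "s1"))
        t = compute_turnover(mat)
        t.check_conservation()
        assert (t.city_table[["gained", "lost", "net"]] == 0).all().all()

    def test_hand_built_three_species_two_city_toy(self):
        """Transitions specified by hand; tallies must match enumeration."""
        pres = {}
        # s1: present everywhere historically, extirpated everywhere in SSP5-85
        # s2: absent historically, gains both cities in every future
        # s3: keeps c1, loses c2 in SSP3-70 and SSP5-85 only
        for sc in SCENARIOS:
            fut = sc != "historic"
            pres[("s1", "c1", sc)] = (sc != "SSP5-85")
            pres[("s1", "c2", sc)] = (sc != "SSP5-85")
            pres[("s2", "c1", sc)] = fut
            pres[("s2", "c2", sc)] = fut
            pres[("s3", "c1", sc)] = True
            pres[("s3", "c2", sc)] = sc in ("historic", "SSP1-26")
        t = compute_turnover(_matrix_from(pres),
                             taxon_labels={"s1": "bird", "s2": "bird", "s3": "frog"})
        t.check_conservation()
        ct = t.city_table.set_index(["city", "scenario"])
        assert ct.loc[("c1", "SSP1-26"), "gained"] == 1        # s2
        assert ct.loc[("c1", "SSP1-26"), "lost"] == 0
        assert ct.loc[("c2", "SSP3-70"), "lost"] == 1          # s3
        assert ct.loc[("c1", "SSP5-85"), "lost"] == 1          # s1
        assert ct.loc[("c1", "SSP5-85"), "unaffected_present"] == 1  # s3
        st = t.species_table.set_index(["species_id", "scenario"])
        assert st.loc[("s1", "SSP5-85"), "fully_extirpated"]
        assert not st.loc[("s1", "SSP1-26"), "fully_extirpated"]
        assert st.loc[("s2", "SSP1-26"), "n_new_cities"] == 2
        assert st.loc[("s3", "SSP3-70"), "net_cities"] == -1
        tx = t.taxon_table.set_index(["taxon_label", "scenario"])
        # birds in SSP5-85: s1 net -2, s2 net +2 -> mean 0
        assert tx.loc[("bird", "SSP5-85"), "mean_net_cities"] == 0.0
        assert tx.loc[("frog", "SSP5-85"), "mean_net_cities"] == -1.0

    def test_single_historic_city_lost_everywhere_is_full_extirpation(self):
        pres = {("s1", "c1", sc): sc == "historic" for sc in SCENARIOS}
        pres.update({("s1", "c2", sc): False for sc in SCENARIOS})
        t = compute_turnover(_matrix_from(pres))
        assert t.species_table["fully_extirpated"].all()

    def test_conservation_identities_on_randomized_matrices(self):
        """net = gained - lost = future - historic richness, and the
        species-wise and city-wise transition totals cross-tabulate."""
        rng = np.random.default_rng(9)
        spp = [f"s{i}" for i in range(6)]
        cities = ["c1", "c2", "c3"]
        for _ in range(200):
            pres = {(s, c, sc): bool(rng.integers(0, 2))
                    for s in spp for c in cities for sc in SCENARIOS}
            t = compute_turnover(_matrix_from(pres))
            t.check_conservation()
            ct, st = t.city_table, t.species_table
            for sc in FUTURE_SCENARIOS:
                a = ct[ct["scenario"] == sc]
                b = st[st["scenario"] == sc]
                assert a["gained"].sum() == b["n_new_cities"].sum()
                assert a["lost"].sum() == b["n_extirpated_cities"].sum()
                assert a["unaffected_present"].sum() == b["n_unchanged_cities"].sum()

    def test_threshold_monotonicity(self, historic):
        """Raising every species' threshold never increases any richness."""
        q = CityQuadrat("c", (120.0, 120.0))
        grid = build_city_grid(q)
        rows = []
        for thr in (0.3, 0.6):
            res = _flat_model(0.41, threshold=thr)  # score sigmoid(0.41)=0.60
            _, present = city_presence(res, historic, grid)
            rows.append(present)
        assert rows[0] >= rows[1]
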