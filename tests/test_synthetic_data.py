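"""The synthetic city: determinism, planted structure, annotator noise."""

import hashlib
import os

import numpy as np
import pytest

from foodscape.crowd_annotation import majority_vote
from foodscape.spatial_smoothing import fit_variogram
from foodscape.synthetic_data import (
    SCENARIOS,
    CityConfig,
    generate_city,
    plant_scenario,
    write_city,
)


def _dir_hash(path):
    h = hashlib.sha256()
    for name in sorted(os.listdir(path)):
        with open(os.path.join(path, name), "rb") as fh:
            h.update(name.encode())
            h.update(fh.read())
    return h.hexdigest()


def test_same_seed_byte_identical_files(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    write_city(generate_city(CityConfig(seed=0, grid=(4, 4))), str(a))
    write_city(generate_city(CityConfig(seed=0, grid=(4, 4))), str(b))
    assert _dir_hash(a) == _dir_hash(b)
    c = tmp_path / "c"
    write_city(generate_city(CityConfig(seed=1, grid=(4, 4))), str(c))
    assert _dir_hash(a) != _dir_hash(c)


def test_zero_annotator_error_recovers_truth_exactly(city_small):
    city = generate_city(CityConfig(seed=3, grid=(3, 3), annotator_error_rate=0.0))
    by_name = {}
    for r in city.responses:
        by_name.setdefault(r.canonical_name, []).append(r)
    for name, resp in by_name.items():
        cons = majority_vote(resp)
        assert cons.consensus_answers == city.true_chain_answers[name]


def test_majority_vote_recovery_rate_matches_binomial_tail():
    """With 5 annotators and per-answer error 0.2, a question's majority is
    correct when at most 2 annotators err: P(Bin(5, 0.2) <= 2) ~ 0.942."""
    correct = total = 0
    for seed in range(30):
        city = generate_city(
            CityConfig(seed=seed, grid=(3, 3), annotator_error_rate=0.2)
        )
        by_name = {}
        for r in city.responses:
            by_name.setdefault(r.canonical_name, []).append(r)
        for name, resp in by_name.items():
            cons = majority_vote(resp)
            for got, want in zip(cons.consensus_answers, city.true_chain_answers[name]):
                total += 1
                correct += got == want
    assert total >= 2000
    assert correct / total == pytest.approx(0.9421, abs=0.02)


@pytest.mark.parametrize("seed", [0, 1, 5])
def test_generated_shares_respect_bounds(seed):
    city = generate_city(CityConfig(seed=seed, grid=(4, 4)))
    for t in city.tracts:
        assert 0.0 <= t.far_share <= 1.0
        assert 0.0 <= t.poverty_rate <= 1.0
        assert 0 <= t.far_count <= t.population


def test_deprivation_field_variogram_consistent_with_configured_range():
    """Fitting the variogram of the planted deprivation field recovers the
    configured spatial range within +-30% (>= 400 tracts)."""
    cfg = CityConfig(seed=2, grid=(21, 21), search_radius_km=0.5, deprivation_range_km=4.0)
    city = generate_city(cfg)
    lonlat = np.array([city.centroids[t.tract_id] for t in city.tracts])
    z = np.array([city.deprivation[t.tract_id] for t in city.tracts])
    vg = fit_variogram(lonlat, z)
    assert 0.7 * 4.0 <= vg.range_km <= 1.3 * 4.0


def test_estimates_cover_both_modes_once():
    city = generate_city(CityConfig(seed=0, grid=(3, 3)))
    seen = set()
    for e in city.estimates:
        key = (e.origin_id, e.retailer_id, e.mode)
        assert key not in seen
        seen.add(key)
        assert e.duration >= 0


def test_healthy_retailers_decrease_with_deprivation(city_default):
    """The planted retail gradient: deprived tracts see fewer healthy and
    more less-healthy retailers (rank correlation over tracts)."""
    from scipy.stats import spearmanr

    city = city_default
    by_tract_h = {t.tract_id: 0 for t in city.tracts}
    by_tract_u = {t.tract_id: 0 for t in city.tracts}
    for r in city.retailers:
        for t in city.tracts:
            if t.polygon.covers(__import__("shapely").geometry.Point(r.lon, r.lat)):
                if city.true_health[r.retailer_id] == "healthy":
                    by_tract_h[t.tract_id] += 1
                elif city.true_health[r.retailer_id] == "less_healthy":
                    by_tract_u[t.tract_id] += 1
                break
    dep = [city.deprivation[t.tract_id] for t in city.tracts]
    rho_h = spearmanr(dep, [by_tract_h[t.tract_id] for t in city.tracts]).statistic
    rho_u = spearmanr(dep, [by_tract_u[t.tract_id] for t in city.tracts]).statistic
    assert rho_h < 0 < rho_u


class TestScenarios:
    def test_unknown_scenario_errors(self, city_small):
        with pytest.raises(ValueError, match="unknown scenario"):
            plant_scenario(city_small, "nope")

    def test_supermarket_planted_within_500ft_of_desert_tract(self, city_small):
        city = plant_scenario(city_small, "new_supermarket_near_desert")
        planted = next(r for r in city.retailers if r.retailer_id == "R_PLANTED_SUPERMARKET")
        assert planted.health_class == "healthy"
        desert_id = sorted(t for t, lab in city.ground_truth_labels.items() if lab)[0]
        tract = next(t for t in city.tracts if t.tract_id == desert_id)
        from foodscape.geodata_io import haversine_km
        from shapely.geometry import Point

        boundary_deg = tract.polygon.exterior.distance(Point(planted.lon, planted.lat))
        assert boundary_deg * 110.574 <= 0.1524 + 1e-6  # within 500 ft of the boundary

    def test_corridor_adds_fast_food_strip(self, city_small):
        city = plant_scenario(city_small, "unhealthy_corridor")
        planted = [r for r in city.retailers if r.retailer_id.startswith("R_PLANTED_FF")]
        assert len(planted) == 12
        assert len({r.lat for r in planted}) == 1  # all on one latitude
        assert all(r.health_class == "less_healthy" for r in planted)

    def test_route_pair_equal_eta_disjoint_midsections(self, city_small):
        city = plant_scenario(city_small, "equal_eta_route_pair")
        assert {r.route_id for r in city.routes} == {"corridor", "bypass"}
        a, b = city.routes
        assert a.eta == b.eta
        assert a.polyline[0] == b.polyline[0]
        assert a.polyline[-1] == b.polyline[-1]
        assert set(a.polyline[1:-1]).isdisjoint(b.polyline[1:-1])

    def test_original_city_not_mutated(self, city_small):
        n_before = len(city_small.retailers)
        plant_scenario(city_small, "unhealthy_corridor")
        assert len(city_small.retailers) == n_before

    def test_all_scenarios_apply(self, city_small):
        for sc in SCENARIOS:
            plant_scenario(city_small, sc)
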