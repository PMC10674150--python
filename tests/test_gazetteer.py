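"""Gazetteer loading, radius queries, and keyword classification."""

import json
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from geotrigger.gazetteer import (
    Classification,
    Gazetteer,
    GazetteerParseError,
    KeywordDictionary,
    Place,
    active_dictionary,
    classify_places,
    load_gazetteer,
)
from geotrigger.geo import haversine_m


def _feature(pid, name, cats, lat, lon):
    return {
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [lon, lat]},
        "properties": {"place_id": pid, "name": name, "categories": cats},
    }


class TestLoading:
    def test_geojson_count_preserved(self, tmp_path):
        doc = {
            "type": "FeatureCollection",
            "features": [
                _feature("a", "General Hospital", ["hospital"], 45.0, -93.0),
                _feature("b", "FitLife Gym", ["gym", "health"], 45.1, -93.0),
                _feature("c", "Corner Cafe", ["restaurant"], 45.2, -93.0),
            ],
        }
        p = tmp_path / "gaz.geojson"
        p.write_text(json.dumps(doc))
        gaz = load_gazetteer(p)
        assert len(gaz) == 3

    def test_empty_collection_classifies_other(self, tmp_path, include_dict):
        p = tmp_path / "gaz.geojson"
        p.write_text(json.dumps({"type": "FeatureCollection", "features": []}))
        gaz = load_gazetteer(p)
        assert len(gaz) == 0
        res = gaz.query_classified(45.0, -93.0, include_dict)
        assert res.classification is Classification.OTHER

    def test_invalid_latitude_raises_parse_error(self, tmp_path):
        doc = {"type": "FeatureCollection", "features": [_feature("bad", "X", ["y"], 95.0, 0.0)]}
        p = tmp_path / "gaz.geojson"
        p.write_text(json.dumps(doc))
        with pytest.raises(GazetteerParseError, match="bad"):
            load_gazetteer(p)

    def test_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "gaz.tsv"
        p.write_text(
            "place_id\tname\tcategories\tlat\tlon\n"
            "h1\tGeneral Hospital\thospital,health\t45.0\t-93.0\n"
        )
        gaz = load_gazetteer(p)
        assert len(gaz) == 1
        assert gaz.places[0].categories == frozenset({"hospital", "health"})


class TestQuery:
    def test_exact_coordinate_hits_first(self, small_gazetteer):
        hits = small_gazetteer.query(45.000, -93.000, radius_m=300)
        assert hits and hits[0].place_id == "hosp-a"

    def test_far_point_returns_empty(self, small_gazetteer):
        assert small_gazetteer.query(46.0, -93.0, radius_m=300) == []

    def test_equal_distance_tie_broken_by_place_id(self):
        gaz = Gazetteer(
            [
                Place("zzz", "North Clinic", frozenset({"health"}), 45.001, -93.0),
                Place("aaa", "South Clinic", frozenset({"health"}), 44.999, -93.0),
            ]
        )
        hits = gaz.query(45.0, -93.0, radius_m=500)
        assert [p.place_id for p in hits] == ["aaa", "zzz"]

    def test_distances_match_direct_haversine(self):
        # independent spherical law-of-cosines style computation
        import random

        rng = random.Random(42)
        R = 6_371_008.8
        for _ in range(50):
            lat1, lon1 = rng.uniform(-80, 80), rng.uniform(-179, 179)
            lat2, lon2 = lat1 + rng.uniform(-0.5, 0.5), lon1 + rng.uniform(-0.5, 0.5)
            p1, l1, p2, l2 = map(math.radians, (lat1, lon1, lat2, lon2))
            expected = R * math.acos(
                min(1.0, math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(l2 - l1))
            )
            assert haversine_m(lat1, lon1, lat2, lon2) == pytest.approx(expected, abs=1.0)


class TestClassification:
    def test_direct_hospital_match(self, include_dict):
        places = [Place("h", "General Hospital", frozenset({"hospital"}), 45, -93)]
        assert classify_places(places, include_dict) is Classification.HOSPITAL

    def test_gym_tagged_health_is_false_alert_without_exclusions(self, include_dict):
        # a gym carrying a "health" category matches the include list
        places = [Place("g", "FitLife Gym", frozenset({"health"}), 45, -93)]
        assert classify_places(places, include_dict) is Classification.HOSPITAL

    def test_gym_suppressed_by_exclusion_dictionary(self, exclude_dict):
        places = [Place("g", "FitLife Gym", frozenset({"health"}), 45, -93)]
        assert classify_places(places, exclude_dict) is Classification.HEALTH_NONHOSPITAL

    def test_empty_array_is_other(self, include_dict):
        assert classify_places([], include_dict) is Classification.OTHER

    def test_matching_is_case_insensitive_substring(self, include_dict):
        places = [Place("h", "ST. MARY MEDICAL CENTER WEST", frozenset({"clinic"}), 45, -93)]
        assert classify_places(places, include_dict) is Classification.HOSPITAL

    def test_per_place_scope_keeps_colocated_hospital(self, exclude_dict):
        places = [
            Place("h", "General Hospital", frozenset({"hospital"}), 45, -93),
            Place("g", "FitLife Gym", frozenset({"gym", "health"}), 45, -93),
        ]
        assert classify_places(places, exclude_dict, exclusion_scope="array") is Classification.HEALTH_NONHOSPITAL
        assert classify_places(places, exclude_dict, exclusion_scope="place") is Classification.HOSPITAL


_names = st.sampled_from(
    ["General Hospital", "FitLife Gym", "CityCare Pharmacy", "Corner Restaurant", "Medical Center East", "Dentist Office"]
)
_cats = st.frozensets(st.sampled_from(["hospital", "health", "gym", "pharmacy", "restaurant", "dentist"]), min_size=1, max_size=3)
_places = st.lists(
    st.builds(lambda n, c: Place(f"p{abs(hash((n, c))) % 10_000}", n, c, 45.0, -93.0), _names, _cats),
    max_size=5,
)
_terms = st.frozensets(st.sampled_from(["hospital", "medical", "health", "gym", "pharm", "dent", "fitness"]), max_size=4)


class TestClassificationProperties:
    @given(places=_places, include=_terms, extra_exclude=_terms)
    def test_exclusions_never_create_hospital(self, places, include, extra_exclude):
        """Growing the exclusion list is monotone: it can only demote HOSPITAL."""
        include = include - extra_exclude or frozenset({"hospital"})
        base = KeywordDictionary("a", 0, include, frozenset())
        grown = KeywordDictionary("b", 0, include, extra_exclude - include)
        before = classify_places(places, base)
        after = classify_places(places, grown)
        if after is Classification.HOSPITAL:
            assert before is Classification.HOSPITAL
        if before is Classification.OTHER:
            assert after is Classification.OTHER

    @given(places=_places, include=_terms, exclude=_terms)
    def test_matches_brute_force_oracle(self, places, include, exclude):
        """Classification equals an exhaustive scan over all (place, term) pairs."""
        include = include - exclude or frozenset({"hospital"})
        exclude = exclude - include
        kdict = KeywordDictionary("v", 0, include, exclude)

        def hit(place, terms):
            texts = [place.name.lower()] + [c.lower() for c in place.categories]
            return any(term in text for term in terms for text in texts)

        any_inc = any(hit(p, include) for p in places)
        any_exc = any(hit(p, exclude) for p in places)
        if not any_inc:
            expected = Classification.OTHER
        elif any_exc:
            expected = Classification.HEALTH_NONHOSPITAL
        else:
            expected = Classification.HOSPITAL
        assert classify_places(places, kdict) is expected


class TestActiveDictionary:
    def _versions(self):
        inc = frozenset({"hospital"})
        return [
            KeywordDictionary("v0", 0, inc, frozenset()),
            KeywordDictionary("v1", 210, inc, frozenset({"gym"})),
            KeywordDictionary("v2", 365, inc, frozenset({"gym", "spa"})),
        ]

    @pytest.mark.parametrize("day,expected", [(200, "v0"), (210, "v1"), (364, "v1"), (365, "v2"), (0, "v0")])
    def test_version_selection(self, day, expected):
        assert active_dictionary(self._versions(), day).version_id == expected

    def test_day_before_first_version_errors(self):
        with pytest.raises(ValueError):
            active_dictionary(self._versions(), -1)

    def test_include_exclude_overlap_rejected(self):
        with pytest.raises(ValueError):
            KeywordDictionary("v", 0, frozenset({"gym"}), frozenset({"gym"}))
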