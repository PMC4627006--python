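"""Graph-structure indices of corridor networks."""

import math

import pytest

from greennet.network import (
    EcoNetwork,
    Link,
    alpha_index,
    beta_classification,
    beta_index,
    corridor_density,
    cost_ratio,
    gamma_index,
    network_report,
    read_network_geojson,
    round_half_up,
    write_network_geojson,
)
from greennet.synthetic import REFERENCE_COUNTS, reference_networks


def simple_net(n_nodes, edges, length_km=2.0):
    nodes = {i: (float(i) * 1000, 0.0) for i in range(n_nodes)}
    links = [Link(source=a, target=b, length_km=length_km) for a, b in edges]
    return EcoNetwork(nodes=nodes, links=links)


class TestIndices:
    def test_triangle_has_maximal_circuitry(self):
        net = simple_net(3, [(0, 1), (1, 2), (0, 2)])
        assert alpha_index(net) == pytest.approx(1.0)
        assert gamma_index(net) == pytest.approx(1.0)
        assert beta_index(net) == pytest.approx(1.0)

    def test_tree_has_no_loops(self):
        net = simple_net(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        assert alpha_index(net) == 0.0

    def test_star_is_dendroid(self):
        net = simple_net(4, [(0, 1), (0, 2), (0, 3)])
        b = beta_index(net)
        assert b == pytest.approx(0.75)
        assert beta_classification(b) == "dendroid"

    def test_cycle_is_single_loop(self):
        net = simple_net(5, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)])
        b = beta_index(net)
        assert b == pytest.approx(1.0)
        assert beta_classification(b) == "single-loop"

    def test_maximal_planar_gamma(self):
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3), (0, 4), (1, 4), (2, 4)]
        net = simple_net(5, edges)
        assert gamma_index(net) == pytest.approx(1.0)

    def test_edgeless_graph_gamma_zero(self):
        net = simple_net(4, [])
        assert gamma_index(net) == 0.0

    def test_small_networks_are_undefined(self):
        net = simple_net(2, [(0, 1)])
        with pytest.raises(ValueError):
            alpha_index(net)
        with pytest.raises(ValueError):
            gamma_index(net)

    def test_cost_ratio_basic(self):
        net = simple_net(11, [(i, i + 1) for i in range(10)], length_km=2.0)
        # l = 10, d = 20 km
        assert cost_ratio(net) == pytest.approx(0.5)

    def test_cost_ratio_negative_warns(self):
        net = simple_net(3, [(0, 1), (1, 2)], length_km=0.5)  # d = 1 km < l
        with pytest.warns(UserWarning):
            assert cost_ratio(net) == pytest.approx(1 - 2 / 1.0)

    def test_cost_ratio_requires_length(self):
        net = simple_net(3, [])
        with pytest.raises(ValueError):
            cost_ratio(net)

    def test_corridor_density(self):
        net = simple_net(3, [(0, 1), (1, 2)], length_km=5.0)
        net.landscape_area_km2 = 10.0
        assert corridor_density(net) == pytest.approx(1.0)
        net.landscape_area_km2 = None
        with pytest.raises(ValueError):
            corridor_density(net)


class TestInvariants:
    def test_adding_a_link_increases_all_indices(self):
        base = simple_net(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)])
        more = simple_net(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5)])
        assert alpha_index(more) > alpha_index(base)
        assert beta_index(more) > beta_index(base)
        assert gamma_index(more) > gamma_index(base)

    def test_indices_invariant_under_relabeling_and_translation(self):
        edges = [(0, 1), (1, 2), (2, 0), (2, 3)]
        net = simple_net(4, edges)
        relabeled = EcoNetwork(
            nodes={f"n{k}": (x + 500.0, y - 200.0) for k, (x, y) in net.nodes.items()},
            links=[
                Link(f"n{l.source}", f"n{l.target}", length_km=l.length_km)
                for l in net.links
            ],
        )
        for fn in (alpha_index, beta_index, gamma_index, cost_ratio):
            assert fn(relabeled) == pytest.approx(fn(net))


class TestValidation:
    def test_duplicate_corridor_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            simple_net(3, [(0, 1), (1, 0)])

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            simple_net(3, [(1, 1)])

    def test_missing_endpoint_rejected(self):
        with pytest.raises(ValueError, match="missing node"):
            simple_net(2, [(0, 5)])

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            simple_net(3, [(0, 1)], length_km=0.0)


class TestReferenceNetworks:
    """The two district fixtures reproduce the published index table rows."""

    def test_changnan_row(self):
        net = reference_networks()["Changnan"]
        assert (net.v, net.l) == (74, 109)
        assert net.total_length_km == pytest.approx(197.15)
        rec = network_report(net)
        assert rec["display"]["alpha"] == 0.25
        assert rec["display"]["beta"] == 1.47
        assert rec["display"]["gamma"] == 0.50
        assert rec["display"]["cost_ratio"] == 0.45

    def test_changbei_cost_ratio(self):
        net = reference_networks()["Changbei"]
        assert (net.v, net.l) == (44, 56)
        assert net.total_length_km == pytest.approx(100.45)
        assert network_report(net)["display"]["cost_ratio"] == 0.44

    def test_fixtures_are_stable(self):
        a = reference_networks()
        b = reference_networks()
        for name in REFERENCE_COUNTS:
            assert a[name].nodes == b[name].nodes
            assert [(l.source, l.target, l.length_km) for l in a[name].links] == [
                (l.source, l.target, l.length_km) for l in b[name].links
            ]


class TestIO:
    def test_geojson_round_trip(self, tmp_path):
        net = simple_net(4, [(0, 1), (1, 2), (2, 3)], length_km=1.5)
        write_network_geojson(net, tmp_path / "n.geojson", tmp_path / "l.geojson")
        back = read_network_geojson(tmp_path / "n.geojson", tmp_path / "l.geojson")
        assert back.v == net.v and back.l == net.l
        assert back.total_length_km == pytest.approx(net.total_length_km)

    def test_arc_length_used_without_explicit_length(self, tmp_path):
        import json

        nodes = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "geometry": {"type": "Point", "coordinates": [0, 0]},
                 "properties": {"id": 0}},
                {"type": "Feature", "geometry": {"type": "Point", "coordinates": [3000, 0]},
                 "properties": {"id": 1}},
            ],
        }
        # corridor detours through (1500, 2000): arc length 5 km > 3 km chord
        links = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature",
                 "geometry": {"type": "LineString",
                              "coordinates": [[0, 0], [1500, 2000], [3000, 0]]},
                 "properties": {"source": 0, "target": 1}},
            ],
        }
        (tmp_path / "n.geojson").write_text(json.dumps(nodes))
        (tmp_path / "l.geojson").write_text(json.dumps(links))
        net = read_network_geojson(tmp_path / "n.geojson", tmp_path / "l.geojson")
        assert net.links[0].length_km == pytest.approx(5.0)

    def test_schema_violation_names_feature(self, tmp_path):
        import json

        (tmp_path / "n.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": [
                {"type": "Feature", "geometry": {"type": "Point", "coordinates": [0, 0]},
                 "properties": {}}]})
        )
        (tmp_path / "l.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": []})
        )
        with pytest.raises(ValueError, match="feature 0"):
            read_network_geojson(tmp_path / "n.geojson", tmp_path / "l.geojson")


def test_round_half_up_matches_table_convention():
    assert round_half_up(0.445) == 0.45
    assert round_half_up(0.4449) == 0.44
    assert round_half_up(1.005) == 1.01  # naive round() would give 1.0
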