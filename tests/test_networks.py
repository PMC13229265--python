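"""Graph aggregation, strength, Gini selectivity, CDFs, KS, group matrices."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crewnet import io, networks


def _roster(rows):
    return io.validate_roster(pd.DataFrame(rows, columns=list(io.ROSTER_COLUMNS)))


@pytest.fixture
def small_roster():
    return _roster(
        [
            ("A", "person", "IT", None, 0, 13),
            ("B", "person", "IT", None, 0, 13),
            ("C", "person", "FR", None, 0, 13),
            ("lounge", "room", None, "shared", 0, 13),
        ]
    )


def _graph(edges, roster, label="M1"):
    w = io.DeploymentWindow(label, 0, 14)
    rows = []
    for (i, j, seconds) in edges:
        rows += [(k * 10, i, j) for k in range(seconds // 10)]
    contacts = io.canonicalize_contacts(pd.DataFrame(rows, columns=["t", "i", "j"]))
    return networks.aggregate_graph(contacts, w, roster)


class TestAggregate:
    def test_edge_weight_sums_durations(self, small_roster):
        G = _graph([("A", "B", 60)], small_roster)
        assert G["A"]["B"]["weight"] == 60.0

    def test_missing_pair_has_no_edge(self, small_roster):
        G = _graph([("A", "B", 60)], small_roster)
        assert not G.has_edge("A", "C")

    def test_handshake_identity(self, small_roster):
        G = _graph([("A", "B", 3600), ("A", "C", 3600), ("B", "C", 3600)], small_roster)
        total_edge = sum(d["weight"] for _, _, d in G.edges(data=True))
        total_strength = sum(networks.strength(G, n) for n in G.nodes)
        assert total_edge == 3 * 3600
        assert total_strength * 3600 == pytest.approx(2 * total_edge)


class TestStrength:
    def test_room_edges_toggle(self, small_roster):
        G = _graph([("A", "B", 3600), ("A", "lounge", 1800)], small_roster)
        assert networks.strength(G, "A", include_rooms=True) == pytest.approx(1.5)
        assert networks.strength(G, "A", include_rooms=False) == pytest.approx(1.0)

    def test_isolated_node_zero(self, small_roster):
        G = _graph([("A", "B", 3600)], small_roster)
        assert networks.strength(G, "C") == 0.0

    def test_unknown_node_errors(self, small_roster):
        G = _graph([("A", "B", 10)], small_roster)
        with pytest.raises(KeyError):
            networks.strength(G, "Z")


def gini_oracle(weights):
    """Direct pairwise-difference evaluation of the population Gini."""
    w = np.asarray(weights, dtype=float)
    n = len(w)
    return sum(abs(a - b) for a, b in itertools.product(w, w)) / (2 * n * n * w.mean())


class TestGini:
    @pytest.mark.parametrize(
        "weights,expected",
        [([1.0, 1.0, 1.0, 1.0], 0.0), ([1.0, 0.0], 0.5), ([1.0, 0.0, 0.0, 0.0], 0.75)],
    )
    def test_reference_values(self, weights, expected):
        assert networks.gini(weights) == pytest.approx(expected)

    def test_matches_pairwise_oracle_on_grid(self):
        grid = [0.0, 1.0, 2.0, 5.0]
        for n in (2, 3, 4, 5, 6):
            for weights in itertools.product(grid, repeat=n):
                if sum(weights) == 0:
                    continue
                assert networks.gini(weights) == pytest.approx(
                    gini_oracle(weights), abs=1e-12
                )

    @given(
        st.lists(st.floats(0, 100), min_size=2, max_size=8).filter(lambda w: sum(w) > 0),
        st.floats(0.01, 50),
    )
    def test_scale_invariance(self, weights, c):
        assert networks.gini(np.asarray(weights) * c) == pytest.approx(
            networks.gini(weights), abs=1e-9
        )

    def test_zero_total_weight_flagged(self):
        with pytest.raises(ValueError, match="zero total"):
            networks.gini([0.0, 0.0])

    def test_node_gini_includes_silent_partners(self, small_roster):
        # A talks only to B; C is a silent possible partner -> weights (w, 0)
        G = _graph([("A", "B", 3600)], small_roster)
        assert networks.node_gini(G, "A") == pytest.approx(0.5)


class TestDailyStrength:
    @pytest.fixture
    def windows(self):
        return [io.DeploymentWindow("M1", 0, 3)]

    def test_single_contact_day(self, small_roster, windows):
        contacts = io.canonicalize_contacts(
            pd.DataFrame({"t": [86400 + k * 10 for k in range(720)], "i": "A", "j": "lounge"})
        )
        daily = networks.daily_strength(contacts, small_roster, windows)
        a = daily[(daily["sensor_id"] == "A") & (daily["day"] == 1)]
        assert a["strength_hours"].item() == pytest.approx(2.0)

    def test_present_but_silent_day_is_zero(self, small_roster, windows):
        daily = networks.daily_strength(
            io.canonicalize_contacts(pd.DataFrame({"t": [0], "i": ["A"], "j": ["B"]})),
            small_roster,
            windows,
        )
        b_day2 = daily[(daily["sensor_id"] == "B") & (daily["day"] == 2)]
        assert b_day2["present"].item() and b_day2["strength_hours"].item() == 0.0

    def test_absent_day_marked_unavailable(self, windows):
        roster = _roster(
            [("A", "person", "IT", None, 0, 13), ("B", "person", "IT", None, 1, 13)]
        )
        daily = networks.daily_strength(
            io.canonicalize_contacts(pd.DataFrame({"t": [86400], "i": ["A"], "j": ["B"]})),
            roster,
            windows,
        )
        b0 = daily[(daily["sensor_id"] == "B") & (daily["day"] == 0)]
        assert not b0["present"].item() and np.isnan(b0["strength_hours"].item())


class TestCdfAndZeroDays:
    def _daily(self, values, kind="person"):
        return pd.DataFrame(
            {
                "sensor_id": "X",
                "kind": kind,
                "deployment": "M1",
                "day": range(len(values)),
                "present": True,
                "strength_hours": values,
            }
        )

    def test_cdf_step_values(self):
        cdf = networks.strength_cdf(self._daily([0, 0, 5, 5, 10]), "person")
        assert cdf(0) == pytest.approx(0.4)
        assert cdf(5) == pytest.approx(0.8)
        assert cdf(10) == pytest.approx(1.0)
        assert cdf(-1) == 0.0

    def test_all_zero_days(self):
        cdf = networks.strength_cdf(self._daily([0, 0, 0]), "person")
        assert cdf(0) == 1.0

    def test_cdf_at_zero_equals_zero_day_fraction(self):
        daily = self._daily([0, 0, 1, 2, 3, 0, 4, 0, 0, 1])
        assert networks.strength_cdf(daily, "person")(0) == pytest.approx(
            networks.zero_day_fraction(daily, "person")
        )

    def test_zero_day_fraction_examples(self):
        assert networks.zero_day_fraction(
            self._daily([0, 0, 0, 0, 1, 1, 1, 1, 1, 1]), "person"
        ) == pytest.approx(0.4)
        assert networks.zero_day_fraction(self._daily([1, 2]), "person") == 0.0

    def test_all_absent_errors(self):
        daily = self._daily([1.0])
        daily["present"] = False
        with pytest.raises(ValueError):
            networks.zero_day_fraction(daily, "person")


class TestKs:
    def test_identical_samples(self):
        d, p = networks.compare_deployments_ks([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = networks.compare_deployments_ks([0, 0, 0, 0], [1, 1, 1, 1])
        assert d == 1.0

    def test_matches_ecdf_sweep_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 40), rng.normal(0.4, 1.3, 55)
        pooled = np.concatenate([a, b])
        d_oracle = max(
            abs((a <= x).mean() - (b <= x).mean()) for x in pooled
        )
        d, _ = networks.compare_deployments_ks(a, b)
        assert d == pytest.approx(d_oracle, abs=1e-12)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            networks.compare_deployments_ks([1.0], [1.0, 2.0])


class TestGroupMatrix:
    def test_pair_divisors(self):
        rows = [(f"I{k}", "person", "IT", None, 0, 13) for k in range(7)]
        rows += [(f"F{k}", "person", "FR", None, 0, 13) for k in range(5)]
        roster = _roster(rows)
        G = _graph([("I0", "F0", 7200)], roster)
        m = networks.group_contact_matrix(G)
        assert m.rescaled.loc["IT", "FR"] == pytest.approx(2.0 / 35)
        assert m.raw_hours.loc["IT", "FR"] == pytest.approx(2.0)
        assert m.raw_hours.loc["IT", "IT"] == 0.0
        # divisors: C(7,2)=21, C(5,2)=10
        G2 = _graph([("I0", "I1", 3600), ("F0", "F1", 3600)], roster)
        m2 = networks.group_contact_matrix(G2)
        assert m2.rescaled.loc["IT", "IT"] == pytest.approx(1.0 / 21)
        assert m2.rescaled.loc["FR", "FR"] == pytest.approx(1.0 / 10)

    def test_singleton_group_diagonal_missing(self):
        roster = _roster(
            [
                ("A", "person", "IT", None, 0, 13),
                ("B", "person", "IT", None, 0, 13),
                ("L", "person", "ESA-MD", None, 0, 13),
            ]
        )
        G = _graph([("A", "B", 3600)], roster)
        m = networks.group_contact_matrix(G)
        assert np.isnan(m.rescaled.loc["ESA-MD", "ESA-MD"])

    def test_raw_total_matches_person_hours(self, m1_graph):
        m = networks.group_contact_matrix(m1_graph)
        person_seconds = sum(
            d["weight"]
            for a, b, d in m1_graph.edges(data=True)
            if m1_graph.nodes[a]["kind"] == "person" and m1_graph.nodes[b]["kind"] == "person"
        )
        upper = np.triu(m.raw_hours.to_numpy())
        assert upper.sum() == pytest.approx(person_seconds / 3600)


class TestGroupedNetwork:
    def test_category_edges_and_conservation(self, small_roster):
        G = _graph([("A", "C", 3600), ("B", "C", 3600), ("A", "B", 1800)], small_roster)
        H = networks.grouped_network(G)
        assert H["IT"]["FR"]["weight"] == pytest.approx(7200)
        assert H.has_edge("IT", "IT") and H["IT"]["IT"]["weight"] == pytest.approx(1800)
        assert sum(d["weight"] for _, _, d in H.edges(data=True)) == pytest.approx(
            sum(d["weight"] for _, _, d in G.edges(data=True))
        )

    def test_unmapped_node_errors(self):
        G = nx.Graph()
        G.add_node("X", kind="person")
        with pytest.raises(ValueError):
            networks.grouped_network(G)
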