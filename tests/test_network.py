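"""MCC validation metric and per-cancer hub networks."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef

from oncopocketome.network import (
    build_network,
    compute_mcc,
    export_cytoscape_csv,
    export_graphml,
    hub_table,
    observed_contact_residues,
)
from oncopocketome.structures import AtomRecord, Structure

UNIVERSE = frozenset(("A", i, "") for i in range(20))


def subset(indices):
    return frozenset(("A", i, "") for i in indices)


class TestMCC:
    def test_perfect_prediction_is_plus_one(self):
        observed = subset(range(5))
        comp = compute_mcc(observed, observed, UNIVERSE)
        assert comp.mcc == pytest.approx(1.0)
        assert not comp.degenerate

    def test_complete_disagreement_is_minus_one(self):
        observed = subset(range(5))
        predicted = frozenset(UNIVERSE) - observed
        comp = compute_mcc(predicted, observed, UNIVERSE)
        assert comp.mcc == pytest.approx(-1.0)

    def test_balanced_confusion_matrix_is_zero(self):
        # tp=fp=fn=tn=5 on a 20-residue universe
        predicted = subset(range(10))          # 0-4 tp, 5-9 fp
        observed = subset(list(range(5)) + list(range(10, 15)))
        comp = compute_mcc(predicted, observed, UNIVERSE)
        assert (comp.tp, comp.fp, comp.fn, comp.tn) == (5, 5, 5, 5)
        assert comp.mcc == 0.0

    def test_zero_denominator_flagged(self):
        comp = compute_mcc(frozenset(), subset(range(5)), UNIVERSE)
        assert comp.degenerate and comp.mcc == 0.0

    def test_counts_partition_universe(self):
        comp = compute_mcc(subset(range(8)), subset(range(4, 12)), UNIVERSE)
        assert comp.tp + comp.fp + comp.fn + comp.tn == len(UNIVERSE)

    def test_subset_violation_errors(self):
        with pytest.raises(ValueError):
            compute_mcc(frozenset({("B", 99, "")}), frozenset(), UNIVERSE)
        with pytest.raises(ValueError):
            compute_mcc(frozenset(), frozenset(), frozenset())

    def test_matches_sklearn_on_random_triples(self, rng):
        """Formula agrees with an independent confusion-matrix oracle."""
        universe = list(range(30))
        for _ in range(1000):
            pred = set(rng.choice(universe, size=rng.integers(0, 30),
                                  replace=False).tolist())
            obs = set(rng.choice(universe, size=rng.integers(0, 30),
                                 replace=False).tolist())
            comp = compute_mcc(pred, obs, universe)
            y_true = [i in obs for i in universe]
            y_pred = [i in pred for i in universe]
            if comp.degenerate:
                # sklearn also returns 0 for degenerate margins
                assert matthews_corrcoef(y_true, y_pred) == pytest.approx(0.0)
            else:
                assert comp.mcc == pytest.approx(
                    matthews_corrcoef(y_true, y_pred), abs=1e-12)


class TestObservedContacts:
    def _structure(self):
        atoms = [AtomRecord(i + 1, "CA", "C", (float(i * 4), 0.0, 0.0),
                            "ALA", "A", i + 1) for i in range(10)]
        return Structure(atoms)

    def _binder(self, x):
        return Structure([AtomRecord(1, "C1", "C", (x, 0.0, 0.0), "LIG",
                                     "B", 1, het=True)])

    def test_far_binder_no_contacts(self):
        contacts = observed_contact_residues(
            self._structure(), self._binder(500.0), 5.0)
        assert contacts == frozenset()

    def test_cutoff_controls_membership(self):
        st = self._structure()
        binder = self._binder(2.0)  # residue CAs sit at x = 0, 4, 8, ...
        near = observed_contact_residues(st, binder, 2.5)
        far = observed_contact_residues(st, binder, 6.5)
        assert near <= far
        assert ("A", 1, "") in near and ("A", 2, "") in near
        assert ("A", 3, "") in far - near

    def test_empty_binder_errors(self):
        with pytest.raises(ValueError):
            observed_contact_residues(self._structure(), Structure([]), 5.0)

    def test_dimer_cavity_contacts_are_rim(self, interface_bundle):
        contacts = observed_contact_residues(
            interface_bundle["part_a"], interface_bundle["part_b"], 5.0)
        pocket = interface_bundle["pockets_a"][0]
        assert contacts & pocket.lining_residues


def interactions(rows):
    return pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "cancer_types"])


class TestBuildNetwork:
    def test_hub_rule_degree_two(self):
        g = build_network(
            interactions([("HUB", "X", "LUSC"), ("HUB", "Y", "LUSC"),
                          ("X", "Y", "LUSC"), ("LONE", "Z", "LUSC")]),
            None, "LUSC")
        assert g.nodes["HUB"]["hub"] and g.nodes["X"]["hub"]
        assert not g.nodes["LONE"]["hub"] and not g.nodes["Z"]["hub"]

    def test_homodimer_counts_as_one_partner(self):
        g = build_network(
            interactions([("SELF", "SELF", "THCA")]), None, "THCA")
        assert g.nodes["SELF"]["degree"] == 1
        assert not g.nodes["SELF"]["hub"]

    def test_homodimer_plus_partner_makes_hub(self):
        g = build_network(
            interactions([("SELF", "SELF", "THCA"), ("SELF", "P", "THCA")]),
            None, "THCA")
        assert g.nodes["SELF"]["degree"] == 2
        assert g.nodes["SELF"]["hub"]

    def test_empty_table_empty_network(self):
        g = build_network(interactions([]), None, "BRCA")
        assert len(g) == 0

    def test_duplicate_rows_collapsed_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            g = build_network(
                interactions([("A", "B", "LUSC"), ("B", "A", "LUSC")]),
                None, "LUSC")
        assert g.number_of_edges() == 1

    def test_row_shuffle_invariance(self, rng):
        rows = [("P1", "P2", "LUSC"), ("P2", "P3", "LUSC"),
                ("P3", "P4", "LUSC"), ("P1", "P4", "LUSC")]
        g1 = build_network(interactions(rows), None, "LUSC")
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        g2 = build_network(interactions(shuffled), None, "LUSC")
        assert set(g1.nodes) == set(g2.nodes)
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))

    def test_adding_edges_never_removes_hubs(self):
        rows = [("A", "B", "LUSC"), ("A", "C", "LUSC")]
        g1 = build_network(interactions(rows), None, "LUSC")
        g2 = build_network(
            interactions(rows + [("B", "C", "LUSC"), ("D", "A", "LUSC")]),
            None, "LUSC")
        hubs1 = {n for n in g1.nodes if g1.nodes[n]["hub"]}
        hubs2 = {n for n in g2.nodes if g2.nodes[n]["hub"]}
        assert hubs1 <= hubs2

    def test_pocket_counts_attached_and_zero_filled(self):
        summary = pd.DataFrame(
            [{"protein": "A", "n_interface_pockets": 2,
              "n_allosteric_pockets": 3}])
        g = build_network(interactions([("A", "B", "KIRC")]), summary, "KIRC")
        assert g.nodes["A"]["n_total_pockets"] == 5
        assert g.nodes["B"]["n_total_pockets"] == 0


class TestHubTable:
    def test_per_cancer_vs_cross_cancer_degree(self):
        table = interactions(
            [("P", "X", "LUSC"), ("P", "Y", "LUSC"), ("P", "Z", "BRCA")])
        networks = {c: build_network(table, None, c) for c in ("LUSC", "BRCA")}
        df = hub_table(networks)
        lusc = df[(df.protein == "P") & (df.cancer == "LUSC")].iloc[0]
        brca = df[(df.protein == "P") & (df.cancer == "BRCA")].iloc[0]
        assert lusc.degree == 2 and bool(lusc.hub)
        assert brca.degree == 1 and not bool(brca.hub)
        assert lusc.cross_cancer_degree == 3

    def test_all_singletons_no_hubs(self):
        table = interactions([("A", "B", "STAD"), ("C", "D", "STAD")])
        df = hub_table({"STAD": build_network(table, None, "STAD")})
        assert not df.hub.any()

    def test_degree_is_symmetric(self):
        table = interactions([("A", "B", "STAD")])
        df = hub_table({"STAD": build_network(table, None, "STAD")})
        assert set(df.degree) == {1}


class TestExports:
    def test_graphml_and_cytoscape_round_trip(self, tmp_path):
        import networkx as nx

        g = build_network(
            interactions([("A", "B", "LUSC"), ("A", "C", "LUSC")]),
            None, "LUSC")
        gml = tmp_path / "net.graphml"
        export_graphml(g, str(gml))
        back = nx.read_graphml(gml)
        assert set(back.nodes) == set(g.nodes)
        edges = tmp_path / "edges.csv"
        nodes = tmp_path / "nodes.csv"
        export_cytoscape_csv(g, str(edges), str(nodes))
        ndf = pd.read_csv(nodes)
        assert set(ndf.protein) == {"A", "B", "C"}
        assert bool(ndf.set_index("protein").loc["A", "hub"])
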