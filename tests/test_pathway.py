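"""Path ranking, minimax optimality and surface exposure."""

import itertools

import networkx as nx
import numpy as np
import pytest

from protonwire._geom import fibonacci_sphere
from protonwire.hbond import HBondGraph, build_graph, detect_hbonds
from protonwire.pathway import (
    PathQuery,
    Pathway,
    SourceNotFoundError,
    compare_pathways,
    find_pathways,
    surface_exposure,
)
from conftest import assemble, make_residue, make_water


def abstract_graph(n_nodes, edges):
    """An HBondGraph over n abstract side-chain nodes with given weights."""
    residues = [
        make_residue(
            "SER", [("CB", "C", (3.0 * i, 0, 1.43)), ("OG", "O", (3.0 * i, 0, 0))],
            number=i + 1,
        )
        for i in range(n_nodes)
    ]
    structure = assemble(chains={"A": residues})
    g = nx.Graph()
    hb = HBondGraph(graph=g)
    for i, res in enumerate(residues):
        node = f"A:SER{i + 1}:sc"
        g.add_node(node, kind="sidechain")
        hb.residues[node] = res
    for i, j, w in edges:
        g.add_edge(
            f"A:SER{i + 1}:sc", f"A:SER{j + 1}:sc",
            d_ha=float(w), d_da=float(w) + 1.0, kind="hbond", hbond=None,
        )
    return hb, structure, residues


def brute_force_minimax(n_nodes, edges, src, dst):
    """Minimum over all simple paths of the maximum edge weight."""
    adj = {}
    for i, j, w in edges:
        adj.setdefault(i, []).append((j, w))
        adj.setdefault(j, []).append((i, w))
    best = [None]

    def dfs(node, visited, worst):
        if node == dst:
            if best[0] is None or worst < best[0]:
                best[0] = worst
            return
        for nbr, w in adj.get(node, ()):
            if nbr not in visited:
                dfs(nbr, visited | {nbr}, max(worst, w))

    dfs(src, {src}, 0.0)
    return best[0]


class TestRanking:
    def test_lower_bottleneck_wins(self):
        a = Pathway(["x", "y"], [1.9], 1.9, 1.9)
        b = Pathway(["x", "z"], [2.1], 2.1, 2.1)
        assert compare_pathways(a, b) == -1
        assert compare_pathways(b, a) == 1

    def test_equal_bottleneck_total_length_breaks_tie(self):
        a = Pathway(["x", "y", "z"], [2.0, 1.5], 2.0, 3.5)
        b = Pathway(["x", "w", "z"], [2.0, 2.0], 2.0, 4.0)
        assert compare_pathways(a, b) == -1

    def test_fully_equal_metrics_fall_back_to_node_ids(self):
        a = Pathway(["a", "m"], [2.0], 2.0, 2.0)
        b = Pathway(["a", "n"], [2.0], 2.0, 2.0)
        assert compare_pathways(a, b) == -1
        assert compare_pathways(a, a) == 0

    def test_order_is_transitive_and_antisymmetric(self):
        paths = [
            Pathway(["a"], [], 0.0, 0.0),
            Pathway(["a", "b"], [1.8], 1.8, 1.8),
            Pathway(["a", "c"], [1.8], 1.8, 1.8),
            Pathway(["a", "b", "c"], [1.5, 2.0], 2.0, 3.5),
        ]
        for x, y in itertools.permutations(paths, 2):
            assert compare_pathways(x, y) == -compare_pathways(y, x)
        import functools

        ranked = sorted(paths, key=functools.cmp_to_key(compare_pathways))
        assert ranked[0].nodes == ["a"]


class TestMinimaxOptimality:
    def test_top_path_bottleneck_equals_brute_force(self):
        rng = np.random.default_rng(2024)
        tested = 0
        while tested < 30:
            n = int(rng.integers(4, 12))
            edges = [
                (i, j, float(np.round(rng.uniform(1.0, 3.0), 3)))
                for i in range(n) for j in range(i + 1, n)
                if rng.random() < 0.45
            ]
            expected = brute_force_minimax(n, edges, 0, n - 1)
            if expected is None:
                continue
            hb, structure, residues = abstract_graph(n, edges)
            paths = find_pathways(
                hb, structure,
                PathQuery(source="A:1", sinks=[residues[n - 1]],
                          strong_only=False, max_path_length=12),
            )
            assert paths, f"no path found for n={n}"
            assert paths[0].bottleneck == pytest.approx(expected)
            tested += 1

    def test_trivial_source_equals_sink(self):
        hb, structure, residues = abstract_graph(3, [(0, 1, 2.0), (1, 2, 2.0)])
        paths = find_pathways(
            hb, structure, PathQuery(source="A:1", sinks=[residues[0]], strong_only=False)
        )
        assert paths[0].nodes == ["A:SER1:sc"]
        assert paths[0].bottleneck == 0.0

    def test_no_path_returns_empty_list(self):
        hb, structure, residues = abstract_graph(4, [(0, 1, 2.0)])  # 3 disconnected
        paths = find_pathways(
            hb, structure, PathQuery(source="A:1", sinks=[residues[3]], strong_only=False)
        )
        assert paths == []

    def test_unknown_source_names_available_metals(self, wire_factory):
        structure, _ = wire_factory(n_nodes=4, seed=1)
        g = build_graph(detect_hbonds(structure), structure)
        with pytest.raises(SourceNotFoundError, match="M:NI:9001"):
            find_pathways(g, structure, PathQuery(source="ZN"))

    def test_ranking_independent_of_insertion_order(self):
        edges = [(0, 1, 1.8), (1, 2, 1.9), (0, 3, 1.7), (3, 2, 2.1), (0, 2, 2.5)]
        outputs = []
        for order in (edges, edges[::-1]):
            hb, structure, residues = abstract_graph(4, order)
            paths = find_pathways(
                hb, structure,
                PathQuery(source="A:1", sinks=[residues[2]], strong_only=False),
            )
            outputs.append([p.nodes for p in paths])
        assert outputs[0] == outputs[1]


class TestPlantedWireRecovery:
    @pytest.mark.parametrize("seed", range(8))
    def test_wire_ranked_first_with_noise_and_decoys(self, wire_factory, seed):
        structure, truth = wire_factory(
            n_nodes=6, seed=seed, angular_noise=6.0, n_decoys=5, occluder_shell=True
        )
        g = build_graph(detect_hbonds(structure), structure)
        paths = find_pathways(
            g, structure, PathQuery(source="NI", sinks=[truth.sink_spec])
        )
        assert paths and paths[0].nodes == truth.all_nodes


class TestSurfaceExposure:
    def test_isolated_residue_is_exposed(self):
        ser = make_residue("SER", [("CB", "C", (0, 0, 1.43)), ("OG", "O", (0, 0, 0))])
        s = assemble(chains={"A": [ser]})
        for method in ("sasa", "neighbour_count"):
            (result,) = surface_exposure(s, method=method)
            assert result.exposed, method
        (result,) = surface_exposure(s, method="sasa")
        assert result.relative_accessibility > 0.5

    def test_residue_in_dense_cluster_is_buried(self):
        ser = make_residue("SER", [("CB", "C", (0, 0, 1.43)), ("OG", "O", (0, 0, 0))])
        shell = make_residue(
            "DUM",
            [(f"C{i}", "C", tuple(4.0 * p)) for i, p in enumerate(fibonacci_sphere(160))],
            chain="X", number=900, hetero=True,
        )
        s = assemble(chains={"A": [ser]})
        s.hetero.append(shell)
        for method in ("sasa", "neighbour_count"):
            results = surface_exposure(s, method=method)
            ours = next(r for r in results if r.residue is ser)
            assert not ours.exposed, method

    def test_unknown_method_rejected(self, tiny_structure):
        with pytest.raises(ValueError, match="unknown exposure method"):
            surface_exposure(tiny_structure, method="magic")

    def test_auto_sinks_terminate_at_exposed_terminus(self, wire_factory):
        """With the wire interior buried by an occluder shell, auto sink
        selection must pick the exposed terminal residue."""
        structure, truth = wire_factory(n_nodes=7, seed=4, occluder_shell=True)
        g = build_graph(detect_hbonds(structure), structure)
        paths = find_pathways(
            g, structure,
            PathQuery(source="NI", sinks=None, exposure_method="neighbour_count"),
        )
        assert paths
        assert paths[0].nodes[-1] in truth.wire_nodes
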