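"""All-pairs evaluation, significance gating, determinism, export formats."""

import numpy as np
import networkx as nx
import pytest

from lsanet.core import LagWindow, lsa_pair
from lsanet.network import all_pairs_lsa, export_network, significant_graph
from lsanet.preprocess import TimeSeriesMatrix, standardize
from lsanet.synthetic import SyntheticSpec, lagged_pair, null_matrix

from conftest import standardize_vector


def _standardized(matrix):
    return standardize(matrix)


@pytest.fixture
def null_series():
    mat = null_matrix(SyntheticSpec(m=20, n=60, distribution="standard_normal", seed=5))
    return standardize(mat)


def test_two_identical_series_form_one_significant_edge(rng):
    v = rng.standard_normal(100)
    a = standardize_vector(v, "a")
    b = standardize_vector(v, "b")
    table = all_pairs_lsa([a, b], LagWindow(0), alpha=0.001)
    assert len(table.edges) == 1
    row = table.edges.iloc[0]
    assert row.statistic == pytest.approx(1.0, abs=1e-9)
    assert bool(row.significant)
    assert row.p_bound < 1e-6


def test_pair_count_and_canonical_order(null_series):
    m = len(null_series)
    table = all_pairs_lsa(null_series, LagWindow(1), alpha=0.05)
    assert len(table.edges) == m * (m - 1) // 2
    assert (table.edges["label_a"] < table.edges["label_b"]).all()
    # one row per unordered pair
    pairs = set(map(tuple, table.edges[["label_a", "label_b"]].itertuples(index=False)))
    assert len(pairs) == len(table.edges)


def test_rows_match_single_pair_route(null_series):
    table = all_pairs_lsa(null_series[:6], LagWindow(2), alpha=0.05)
    by_label = {s.label: s for s in null_series[:6]}
    for row in table.edges.itertuples(index=False):
        ref = lsa_pair(by_label[row.label_a], by_label[row.label_b], LagWindow(2))
        assert row.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert row.best_lag == ref.best_lag


def test_workers_do_not_change_output(tmp_path):
    mat = null_matrix(SyntheticSpec(m=60, n=40, distribution="standard_normal", seed=8))
    series = standardize(mat)
    outputs = {}
    for workers in (1, 4, 16):
        table = all_pairs_lsa(series, LagWindow(2), alpha=0.05, workers=workers)
        path = tmp_path / f"w{workers}.tsv"
        export_network(table, "edge_attr_tsv", path, all_edges=True)
        outputs[workers] = path.read_bytes()
    assert outputs[1] == outputs[4] == outputs[16]


def test_planted_lagged_pair_is_top_edge():
    n = 50
    rng = np.random.default_rng(17)
    a, b = lagged_pair(n, lag=2, coupling=1.0, noise_sd=0.05, seed=1)
    rows = [a, b] + [rng.standard_normal(n) for _ in range(3)]
    mat = TimeSeriesMatrix(
        values=np.asarray(rows),
        row_labels=("s1", "s2", "u3", "u4", "u5"),
        col_labels=tuple(f"t{j}" for j in range(n)),
    )
    table = all_pairs_lsa(standardize(mat), LagWindow(3), alpha=0.001)
    top = table.edges.loc[table.edges["statistic"].abs().idxmax()]
    assert {top.label_a, top.label_b} == {"s1", "s2"}
    assert abs(top.best_lag) == 2


def test_perm_column_present_and_reproducible(null_series):
    t1 = all_pairs_lsa(null_series[:4], LagWindow(1), alpha=0.05, perms=49, seed=3)
    t2 = all_pairs_lsa(null_series[:4], LagWindow(1), alpha=0.05, perms=49, seed=3)
    assert "p_perm" in t1.edges
    assert t1.edges["p_perm"].tolist() == t2.edges["p_perm"].tolist()
    assert ((t1.edges["p_perm"] > 0) & (t1.edges["p_perm"] <= 1)).all()


def test_validation():
    a = standardize_vector(np.arange(10.0), "a")
    short = standardize_vector(np.arange(8.0), "s")
    with pytest.raises(ValueError, match="equal length"):
        all_pairs_lsa([a, short], LagWindow(1))
    with pytest.raises(ValueError, match="at least 2"):
        all_pairs_lsa([a], LagWindow(1))
    with pytest.raises(ValueError, match="correction"):
        all_pairs_lsa([a, a], LagWindow(1), correction="fdr")


class TestExport:
    @pytest.fixture
    def table(self, rng):
        v = rng.standard_normal(80)
        a = standardize_vector(v, "A")
        b = standardize_vector(v + 0.01 * rng.standard_normal(80), "B")
        c = standardize_vector(-v + 0.01 * rng.standard_normal(80), "C")
        d = standardize_vector(rng.standard_normal(80), "D")
        return all_pairs_lsa([a, b, c, d], LagWindow(0), alpha=0.001)

    def test_sif_sign_coding(self, table, tmp_path):
        path = export_network(table, "sif", tmp_path / "net.sif")
        lines = path.read_text().splitlines()
        assert "A\t+ls\tB" in lines
        assert "A\t-ls\tC" in lines
        assert all(len(l.split("\t")) == 3 for l in lines)

    def test_empty_significant_set_yields_valid_documents(self, null_series, tmp_path):
        table = all_pairs_lsa(null_series, LagWindow(0), alpha=1e-9)
        assert table.meta["num_significant"] == 0
        assert export_network(table, "sif", tmp_path / "e.sif").read_text() == ""
        tsv = export_network(table, "edge_attr_tsv", tmp_path / "e.tsv")
        assert tsv.read_text().startswith("label_a\tlabel_b")
        g = nx.read_graphml(export_network(table, "graphml", tmp_path / "e.graphml"))
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == len(null_series)

    def test_graphml_round_trip(self, table, tmp_path):
        path = export_network(table, "graphml", tmp_path / "net.graphml")
        g = nx.read_graphml(path)
        assert g.number_of_edges() == int(table.edges["significant"].sum())
        edge = g.edges["A", "B"]
        assert edge["statistic"] == pytest.approx(1.0, abs=0.01)

    def test_unknown_format(self, table, tmp_path):
        with pytest.raises(ValueError, match="unknown export format"):
            export_network(table, "dot", tmp_path / "x")

    def test_significant_graph_matches_table(self, table):
        g = significant_graph(table)
        assert g.number_of_edges() == table.meta["num_significant"]
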