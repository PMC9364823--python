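"""Ligand-receptor screen, edge construction, strengths, condition network."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_normalized_adata
from rili_scomm.errors import FormatError, RiliError
from rili_scomm.lr_network import (
    communication_strength,
    condition_upregulated_network,
    export_circos_links,
    load_lr_pairs,
    overexpression_screen,
    significant_interactions,
)
from rili_scomm.qc import normalize_lognorm
from rili_scomm.simulate import (
    SimConfig,
    build_lr_table,
    generate_dataset,
    plan_lr_edges,
)


# --- database loading -----------------------------------------------------

def test_load_pairs_and_collapse_duplicates(tmp_path):
    p = tmp_path / "pairs.tsv"
    p.write_text("ligand\treceptor\nA\tB\nC\tD\nE\tF\n")
    assert len(load_lr_pairs(p)) == 3
    p.write_text("ligand\treceptor\nA\tB\nA\tB\nC\tD\n")
    with pytest.warns(UserWarning, match="duplicate"):
        db = load_lr_pairs(p)
    assert len(db) == 2


@pytest.mark.parametrize(
    "content,match",
    [
        ("ligand\treceptor\nA\t\n", "empty ligand/receptor"),
        ("ligand\tother\nA\tB\n", "lacks column"),
        ("ligand\treceptor\n", "no pairs"),
        ("", "empty"),
    ],
)
def test_load_pairs_format_errors(tmp_path, content, match):
    p = tmp_path / "pairs.tsv"
    p.write_text(content)
    with pytest.raises(FormatError, match=match):
        load_lr_pairs(p)


def test_packaged_lr_fixture_loads():
    import importlib.resources

    source = importlib.resources.files("rili_scomm.data") / "lr_pairs.tsv"
    with importlib.resources.as_file(source) as p:
        db = load_lr_pairs(p)
    assert {"Cxcl16", "Ccl8"} <= set(db["ligand"])
    assert "Cxcr6" in set(db["receptor"])


# --- overexpression screen ------------------------------------------------

def test_worked_screen_case_is_not_significant_at_strict_alpha():
    """Cluster {3,4,5} vs rest {0,1,2}: exact one-sided p = 0.05 exactly."""
    X = np.array([[3.0], [4.0], [5.0], [0.0], [1.0], [2.0]])
    adata = make_normalized_adata(X, clusters=["A"] * 3 + ["B"] * 3)
    screen = overexpression_screen(adata, ["g0"], correction=None)
    row = screen.set_index("cluster").loc["A"]
    assert row["p_value"] == pytest.approx(0.05, abs=1e-15)
    assert not row["significant"]


def test_constant_gene_has_p_one_and_a_rate():
    X = np.full((30, 1), 2.0)
    adata = make_normalized_adata(X, clusters=["A"] * 10 + ["B"] * 20)
    screen = overexpression_screen(adata, ["g0"], correction=None)
    assert (screen["p_value"] == 1.0).all()
    assert (screen["rate"] == 1.0).all()
    assert not screen["significant"].any()


def test_planted_gene_significant_only_in_sender(lr_dataset):
    ds, norm, planted, _ = lr_dataset
    edge = planted[0]
    screen = overexpression_screen(norm, [edge.ligand])
    by_cluster = screen.set_index("cluster")
    assert by_cluster.loc[edge.sender, "significant"]
    others = by_cluster.drop(index=edge.sender)
    assert not others["significant"].any()
    assert by_cluster.loc[edge.sender, "rate"] > others["rate"].max()


def test_screen_excludes_absent_genes_and_small_clusters(lr_dataset):
    _, norm, planted, _ = lr_dataset
    with pytest.warns(UserWarning, match="absent"):
        screen = overexpression_screen(norm, ["nosuchgene", planted[0].ligand])
    assert set(screen["gene"]) == {planted[0].ligand}
    c1 = np.flatnonzero((norm.obs["cluster"] == "C1").values)[:2]
    c2 = np.flatnonzero((norm.obs["cluster"] == "C2").values)
    sub = norm[np.concatenate([c1, c2])].copy()
    with pytest.warns(UserWarning, match="below min_cells"):
        small = overexpression_screen(sub, [planted[0].ligand], min_cells=3)
    assert set(small["cluster"]) == {"C2"}


# --- edge construction ----------------------------------------------------

def _screen_frame(records):
    return pd.DataFrame(
        records,
        columns=["gene", "cluster", "p_value", "adj_p", "rate", "mean_expr",
                 "significant"],
    )


def test_edge_built_from_both_ends_with_intensity():
    screen = _screen_frame([
        ("L", "A", 1e-4, 1e-3, 0.8, 1.0, True),
        ("R", "B", 1e-5, 1e-4, 0.6, 1.0, True),
    ])
    db = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
    edges = significant_interactions(screen, db)
    assert len(edges) == 1
    e = edges.iloc[0]
    assert (e["sender"], e["receiver"]) == ("A", "B")
    assert e["intensity"] == pytest.approx(1.4)


def test_edge_cross_product_and_self_edges():
    screen = _screen_frame([
        ("L", "A", 1e-4, 1e-3, 0.5, 1.0, True),
        ("L", "B", 1e-4, 1e-3, 0.4, 1.0, True),
        ("R", "A", 1e-4, 1e-3, 0.3, 1.0, True),
    ])
    db = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
    edges = significant_interactions(screen, db)
    assert len(edges) == 2  # A->A (autocrine) and B->A
    no_self = significant_interactions(screen, db, include_self=False)
    assert len(no_self) == 1
    assert no_self.iloc[0]["sender"] == "B"


def test_no_significant_records_gives_empty_edges():
    screen = _screen_frame([("L", "A", 0.5, 1.0, 0.5, 1.0, False)])
    db = pd.DataFrame({"ligand": ["L"], "receptor": ["L"]})
    assert significant_interactions(screen, db).empty


def test_edge_count_identity(lr_dataset):
    _, norm, planted, decoys = lr_dataset
    db = build_lr_table(planted, decoys)
    genes = list(dict.fromkeys(list(db["ligand"]) + list(db["receptor"])))
    screen = overexpression_screen(norm, genes)
    edges = significant_interactions(screen, db)
    sig = screen[screen["significant"]]
    n_sig = sig.groupby("gene").size()
    expected = sum(
        int(n_sig.get(p.ligand, 0)) * int(n_sig.get(p.receptor, 0))
        for p in db.itertuples()
    )
    assert len(edges) == expected


def test_alpha_monotonicity_of_edge_set(lr_dataset):
    _, norm, planted, decoys = lr_dataset
    db = build_lr_table(planted, decoys)
    genes = list(dict.fromkeys(list(db["ligand"]) + list(db["receptor"])))
    screen = overexpression_screen(norm, genes, correction=None)
    previous = set()
    for alpha in (1e-6, 1e-3, 0.05, 0.5):
        scr = screen.assign(significant=screen["adj_p"] < alpha)
        edges = significant_interactions(scr, db)
        current = {tuple(r) for r in edges[
            ["sender", "receiver", "ligand", "receptor"]
        ].itertuples(index=False)}
        assert previous <= current
        previous = current


# --- communication strength ----------------------------------------------

def test_strength_counts_directed_and_undirected():
    edges = pd.DataFrame({
        "sender": ["A", "A", "A", "B"],
        "receiver": ["B", "B", "B", "A"],
        "ligand": list("wxyz"), "receptor": list("wxyz"),
        "ligand_p": 0.0, "receptor_p": 0.0,
        "ligand_rate": 0.5, "receptor_rate": 0.5, "intensity": 1.0,
    })
    cm = communication_strength(edges)
    assert cm.directed.loc["A", "B"] == 3
    assert cm.directed.loc["B", "A"] == 1
    assert cm.undirected.loc["A", "B"] == 4
    assert cm.total == 4


def test_strength_total_equals_edge_count_random():
    rng = np.random.default_rng(0)
    clusters = list("ABCDE")
    n = 40
    edges = pd.DataFrame({
        "sender": rng.choice(clusters, n),
        "receiver": rng.choice(clusters, n),
        "ligand": [f"L{i}" for i in range(n)],
        "receptor": [f"R{i}" for i in range(n)],
        "ligand_p": 0.0, "receptor_p": 0.0,
        "ligand_rate": 0.5, "receptor_rate": 0.5, "intensity": 1.0,
    })
    cm = communication_strength(edges)
    assert cm.total == n


def test_empty_edges_give_zero_matrix():
    cm = communication_strength(pd.DataFrame(
        columns=["sender", "receiver", "ligand", "receptor", "ligand_p",
                 "receptor_p", "ligand_rate", "receptor_rate", "intensity"]
    ), clusters=["A", "B"])
    assert cm.total == 0
    assert (cm.directed.values == 0).all()


# --- condition-upregulated network ----------------------------------------

def test_identical_conditions_give_empty_network():
    rng = np.random.default_rng(1)
    X = rng.poisson(1.0, (80, 6)).astype(float)
    adata = make_normalized_adata(
        X, clusters=["A"] * 40 + ["B"] * 40,
        conditions=["pre", "post"] * 40,
    )
    db = pd.DataFrame({"ligand": ["g0", "g2"], "receptor": ["g1", "g3"]})
    edges = condition_upregulated_network(adata, db)
    assert edges.empty


def test_ligand_up_but_receptor_flat_gives_no_edge():
    n = 40
    pre_post = ["pre"] * (n // 2) + ["post"] * (n // 2)
    X = np.ones((n, 2)) * 0.2
    X[n // 2:, 0] = 3.0  # ligand strongly up post; receptor flat
    adata = make_normalized_adata(X, clusters=["A"] * n, conditions=pre_post)
    db = pd.DataFrame({"ligand": ["g0"], "receptor": ["g1"]})
    assert condition_upregulated_network(adata, db).empty


def test_condition_network_recovers_post_only_edges():
    base = SimConfig(n_clusters=4, cells_per_cluster_pre=150,
                     depletion_factor=1.0, n_genes=200, cycling_fraction=0.0,
                     seed=6)
    post_only = plan_lr_edges(base, 2, 0.6)
    baseline = plan_lr_edges(base, 2, 0.6, gene_offset=2)
    cfg = SimConfig(**{**base.__dict__,
                       "planted_lr_edges": baseline,
                       "planted_condition_lr_edges": post_only})
    ds = generate_dataset(cfg)
    norm = normalize_lognorm(ds.adata)
    norm.obs["cluster"] = norm.obs["true_cluster"]
    db = build_lr_table(post_only + baseline)
    edges = condition_upregulated_network(norm, db)
    found = {tuple(r) for r in edges[
        ["sender", "receiver", "ligand", "receptor"]].itertuples(index=False)}
    assert {e.key() for e in post_only} <= found
    assert not found & {e.key() for e in baseline}


def test_condition_absent_everywhere_rejected():
    adata = make_normalized_adata(np.ones((10, 2)), clusters=["A"] * 10,
                                  conditions=["pre"] * 10)
    db = pd.DataFrame({"ligand": ["g0"], "receptor": ["g1"]})
    with pytest.raises(RiliError, match="absent"):
        condition_upregulated_network(adata, db)


# --- export ----------------------------------------------------------------

def test_circos_export_round_trip(tmp_path):
    edges = pd.DataFrame({
        "sender": ["A", "A", "B"], "receiver": ["B", "B", "A"],
        "ligand": ["l1", "l2", "l3"], "receptor": ["r1", "r2", "r3"],
        "ligand_p": 0.001, "receptor_p": 0.001,
        "ligand_rate": 0.7, "receptor_rate": 0.5, "intensity": 1.2,
    })
    cm = communication_strength(edges)
    out = tmp_path / "links.tsv"
    export_circos_links(edges, cm, out)
    links = pd.read_csv(out, sep="\t")
    assert links.set_index(["sender", "receiver"]).loc[("A", "B"), "weight"] == 2
    assert links["weight"].sum() == len(edges)
    long_form = pd.read_csv(tmp_path / "links.tsv.edges.tsv", sep="\t")
    assert len(long_form) == len(edges)


def test_circos_export_empty_guard(tmp_path):
    empty = pd.DataFrame(columns=["sender", "receiver", "ligand", "receptor",
                                  "ligand_p", "receptor_p", "ligand_rate",
                                  "receptor_rate", "intensity"])
    cm = communication_strength(empty)
    with pytest.raises(ValueError, match="allow_empty"):
        export_circos_links(empty, cm, tmp_path / "x.tsv")
    export_circos_links(empty, cm, tmp_path / "x.tsv", allow_empty=True)
    assert (tmp_path / "x.tsv").exists()
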