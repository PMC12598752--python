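"""Classification metrics, composite score, GOGO, colocalization, nulls."""

import itertools

import networkx as nx
import numpy as np
import pytest

from cofracnet.labels import ComplexCatalog
from cofracnet.metrics import (
    GoDag,
    bootstrap_null,
    classification_metrics,
    colocalization_score,
    composite_score,
    gogo_cluster_score,
    gogo_gene_sim,
    gogo_term_sim,
    jaccard,
    overlap_score,
    representation_separation,
)

# ---------------------------------------------------------------------------
# classification


def test_perfect_separation_gives_ones():
    m = classification_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
    assert m["sensitivity"] == m["specificity"] == m["auc"] == 1.0
    assert m["mcc"] == pytest.approx(1.0)


def test_worked_confusion_example():
    # TP=3, FP=1, FN=2, TN=4
    y = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
    s = [0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.4, 0.3, 0.2, 0.1]
    m = classification_metrics(y, s)
    assert m["sensitivity"] == pytest.approx(0.6)
    assert m["specificity"] == pytest.approx(0.8)
    assert m["mcc"] == pytest.approx(10 / np.sqrt(600))


def test_score_exactly_at_threshold_is_negative():
    m = classification_metrics([1, 0], [0.5, 0.1])
    assert m["sensitivity"] == 0.0  # the 0.5-scored positive counts as FN


def test_mcc_zero_denominator_warns_zero():
    with pytest.warns(UserWarning, match="MCC"):
        m = classification_metrics([1, 1, 0], [0.9, 0.8, 0.7])
    assert m["mcc"] == 0.0


def test_single_class_auc_undefined():
    with pytest.raises(ValueError, match="class"):
        classification_metrics([1, 1], [0.2, 0.9])


def rank_auc_oracle(y, s):
    """Mann-Whitney statistic with half credit for ties."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    u = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    )
    return u / (len(pos) * len(neg))


def test_auc_equals_rank_oracle_with_ties():
    rng = np.random.default_rng(0)
    for _ in range(20):
        y = rng.integers(0, 2, size=60)
        if len(np.unique(y)) < 2:
            continue
        s = np.round(rng.random(60), 1)  # coarse scores force ties
        m = classification_metrics(y, s)
        assert m["auc"] == pytest.approx(rank_auc_oracle(y, s), abs=1e-12)


# ---------------------------------------------------------------------------
# overlap / jaccard


def test_identity_sets_score_one():
    assert overlap_score({"a", "b"}, {"a", "b"}) == 1.0
    assert jaccard({"a", "b"}, {"a", "b"}) == 1.0


def test_empty_set_rejected():
    with pytest.raises(ValueError):
        overlap_score(set(), {"a"})
    with pytest.raises(ValueError):
        jaccard({"a"}, set())


@pytest.mark.parametrize(
    "n_ref, n_clu, n_common, coverage, purity, expected_j",
    [
        (16, 14, 10, 62.50, 71.43, 0.500),  # Mediator-like replicate 1
        (23, 25, 19, 82.61, 76.00, 0.655),  # Mediator-like replicate 2
        (12, 15, 12, 100.00, 80.00, 0.800),  # large ribosomal subunit-like
    ],
)
def test_jaccard_from_coverage_and_purity(
    n_ref, n_clu, n_common, coverage, purity, expected_j
):
    """Coverage and purity percentages determine the Jaccard index."""
    ref = {f"r{i}" for i in range(n_ref)}
    clu = {f"r{i}" for i in range(n_common)} | {
        f"c{i}" for i in range(n_clu - n_common)
    }
    assert round(100 * len(ref & clu) / len(ref), 2) == coverage
    assert round(100 * len(ref & clu) / len(clu), 2) == purity
    assert round(jaccard(ref, clu), 3) == expected_j


# ---------------------------------------------------------------------------
# composite score


def test_perfect_recovery_composite_three():
    ref = ComplexCatalog({"C1": {"a", "b", "c"}, "C2": {"d", "e", "f"}})
    m = composite_score([{"a", "b", "c"}, {"d", "e", "f"}], ref)
    for key in ("overlap_frac", "sn", "ppv", "accuracy", "mmr"):
        assert m[key] == pytest.approx(1.0)
    assert m["composite"] == pytest.approx(3.0)


def test_overlap_fraction_strictly_greater_than_quarter():
    ref = ComplexCatalog({"C1": {"a", "b", "c", "d"}})
    m = composite_score([{"a", "b", "e", "f"}], ref)  # overlap 4/16 = 0.25
    assert m["overlap_frac"] == 0.0


def mmr_oracle(ref_sets, clusters):
    """Exhaustive maximum-weight one-to-one matching."""
    ov = [
        [len(b & c) ** 2 / (len(b) * len(c)) for c in clusters] for b in ref_sets
    ]
    n, m = len(ref_sets), len(clusters)
    k = min(n, m)
    best = 0.0
    if n <= m:
        for cols in itertools.permutations(range(m), k):
            best = max(best, sum(ov[i][cols[i]] for i in range(n)))
    else:
        for rows in itertools.permutations(range(n), k):
            best = max(best, sum(ov[rows[j]][j] for j in range(m)))
    return best / n


def test_mmr_matches_exhaustive_enumeration():
    rng = np.random.default_rng(1)
    pool = [f"p{i}" for i in range(20)]
    for _ in range(40):
        n_ref = rng.integers(1, 6)
        n_clu = rng.integers(1, 6)
        ref = {
            f"R{i}": set(rng.choice(pool, size=rng.integers(3, 7), replace=False))
            for i in range(n_ref)
        }
        clusters = [
            set(rng.choice(pool, size=rng.integers(3, 7), replace=False))
            for _ in range(n_clu)
        ]
        m = composite_score(clusters, ref)
        assert m["mmr"] == pytest.approx(
            mmr_oracle([frozenset(v) for v in ref.values()], clusters), abs=1e-12
        )


def test_composite_invariant_to_input_order():
    rng = np.random.default_rng(2)
    pool = [f"p{i}" for i in range(15)]
    ref = {
        f"R{i}": set(rng.choice(pool, size=4, replace=False)) for i in range(3)
    }
    clusters = [set(rng.choice(pool, size=4, replace=False)) for _ in range(4)]
    a = composite_score(clusters, ref)
    b = composite_score(clusters[::-1], dict(reversed(list(ref.items()))))
    assert a == pytest.approx(b)


# ---------------------------------------------------------------------------
# GOGO

W_IS_A = 1.0 / (0.67 + 2) + 0.4  # edge weight under a 2-child ancestor


def test_three_node_hand_computation(toy_dag_is_a):
    expected = (2 * W_IS_A) / (2 * (1 + W_IS_A))
    assert gogo_term_sim("T1", "T2", toy_dag_is_a) == pytest.approx(
        expected, abs=1e-12
    )
    assert expected == pytest.approx(0.4365, abs=5e-4)


def test_part_of_similarity_lower_than_is_a(toy_dag_is_a, toy_dag_part_of):
    assert gogo_term_sim("T1", "T2", toy_dag_part_of) < gogo_term_sim(
        "T1", "T2", toy_dag_is_a
    )


def test_self_similarity_is_one_everywhere():
    from cofracnet.simulate import make_toy_godag

    dag = make_toy_godag(4, 3, seed=3)
    rng = np.random.default_rng(0)
    terms = list(dag.graph.nodes)
    for t in rng.choice(terms, size=100):
        assert gogo_term_sim(t, t, dag) == pytest.approx(1.0, abs=1e-12)


def test_term_similarity_symmetric():
    from cofracnet.simulate import make_toy_godag

    dag = make_toy_godag(4, 3, seed=4)
    rng = np.random.default_rng(1)
    terms = list(dag.graph.nodes)
    for _ in range(50):
        t, k = rng.choice(terms, size=2)
        assert gogo_term_sim(t, k, dag) == pytest.approx(
            gogo_term_sim(k, t, dag), abs=1e-12
        )


def test_gene_similarity_reductions(toy_dag_is_a):
    toy_dag_is_a.annotations = {
        "g1": {"BP": {"T1"}},
        "g2": {"BP": {"T2"}},
        "g3": {"BP": {"T1"}},
    }
    s12 = gogo_gene_sim("g1", "g2", toy_dag_is_a)
    assert s12 == pytest.approx(gogo_term_sim("T1", "T2", toy_dag_is_a))
    assert gogo_gene_sim("g1", "g3", toy_dag_is_a) == pytest.approx(1.0)
    cluster = gogo_cluster_score({"g1", "g2", "g3"}, toy_dag_is_a)
    assert cluster == pytest.approx((s12 + s12 + 1.0) / 3)


def test_unannotated_genes_handled(toy_dag_is_a):
    toy_dag_is_a.annotations = {"g1": {"BP": {"T1"}}}
    with pytest.raises(ValueError):
        gogo_gene_sim("g1", "gX", toy_dag_is_a)
    with pytest.warns(UserWarning):
        assert gogo_cluster_score({"g1", "gX", "gY"}, toy_dag_is_a) is None


def test_cyclic_graph_rejected():
    g = nx.DiGraph()
    g.add_edge("A", "B", type="is_a")
    g.add_edge("B", "A", type="is_a")
    with pytest.raises(ValueError, match="acyclic"):
        GoDag(g)


# ---------------------------------------------------------------------------
# colocalization


def test_colocalization_cases():
    loc = {"a": "nucleus", "b": "nucleus", "c": "cytosol", "d": "mitochondrion"}
    assert colocalization_score({"a", "b"}, loc) == 1.0
    assert colocalization_score({"a", "b", "c", "d"}, loc) == 0.5
    # unannotated member excluded from the denominator
    assert colocalization_score({"a", "b", "zz"}, loc) == 1.0
    assert colocalization_score({"zz"}, loc) is None


# ---------------------------------------------------------------------------
# representation separation


def test_separation_identical_rows_limit():
    rng = np.random.default_rng(0)
    base = rng.uniform(0.1, 1, size=(3, 8))
    X = np.vstack([np.tile(base[i], (4, 1)) for i in range(3)])
    ids = [f"P{i}" for i in range(12)]
    cat = ComplexCatalog(
        {f"C{i}": set(ids[4 * i: 4 * i + 4]) for i in range(3)}
    )
    out = representation_separation(X, ids, cat)
    assert np.allclose(out["intra_distances"], 0.0, atol=1e-12)
    assert out["test_p"] < 1e-6


def test_separation_null_calibrated():
    """Shuffled complex assignment rejects at roughly the nominal rate."""
    rng = np.random.default_rng(42)
    ids = [f"P{i}" for i in range(24)]
    rejections = 0
    n_rep = 300
    for _ in range(n_rep):
        X = rng.normal(size=(24, 6))
        perm = rng.permutation(ids)
        cat = ComplexCatalog(
            {f"C{i}": set(perm[4 * i: 4 * i + 4]) for i in range(6)}
        )
        if representation_separation(X, ids, cat)["test_p"] < 0.05:
            rejections += 1
    assert 0.01 <= rejections / n_rep <= 0.10


def test_separation_contract_errors():
    ids = ["a", "b", "c", "d"]
    X = np.ones((4, 3))
    single = ComplexCatalog({"C1": {"a", "b", "c", "d"}})
    with pytest.raises(ValueError, match="2 complexes"):
        representation_separation(X, ids, single)
    with pytest.raises(ValueError, match="zero"):
        representation_separation(
            np.zeros((4, 3)), ids, ComplexCatalog({"C1": {"a", "b"}, "C2": {"c", "d"}})
        )


# ---------------------------------------------------------------------------
# bootstrap null


def test_bootstrap_shifted_scores_reject():
    rng = np.random.default_rng(0)
    pool = {s: list(rng.normal(0.5, 0.1, size=20)) for s in range(3, 8)}
    sizes = [3, 4, 5, 6, 7] * 3
    observed = [pool[s][0] + 0.5 for s in sizes]
    out = bootstrap_null(observed, sizes, pool, n_boot=2000, seed=1)
    assert out["p_value"] < 0.01
    assert out["observed_mean"] > out["null_mean"]


def test_bootstrap_missing_size_rejected():
    with pytest.raises(ValueError, match="sizes"):
        bootstrap_null([0.5], [9], {3: [0.1, 0.2]}, n_boot=10, seed=0)


def test_bootstrap_seeded_reproducible():
    rng = np.random.default_rng(3)
    pool = {s: list(rng.normal(0.5, 0.1, size=20)) for s in (3, 4)}
    a = bootstrap_null([0.4, 0.6], [3, 4], pool, n_boot=500, seed=7)
    b = bootstrap_null([0.4, 0.6], [3, 4], pool, n_boot=500, seed=7)
    assert a == b
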