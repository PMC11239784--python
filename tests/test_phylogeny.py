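import math

import numpy as np
import pytest

from gh13tools.csr import CsrColumnMap
from gh13tools.phylogeny import (
    DistanceMatrix,
    Tree,
    TreeNode,
    bootstrap_support,
    neighbor_joining,
    pairwise_distance,
    trim_to_barrel,
)
from gh13tools.sequence_io import Alignment, SequenceRecord


def random_additive_case(rng, n_taxa):
    """A random unrooted binary tree and its (additive) leaf distance matrix,
    computed by an independent path-walk over the generated branch lengths."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # store per-node leaf->distance maps while joining randomly
    items = [({lab: 0.0}, frozenset([lab])) for lab in labels]
    dist = {}
    while len(items) > 2:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (da, _sa), (db, _sb) = items[i], items[j]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        for x, dx in da.items():
            for y, dy in db.items():
                dist[frozenset((x, y))] = dx + la + dy + lb
        merged = {x: d + la for x, d in da.items()}
        merged.update({y: d + lb for y, d in db.items()})
        items = [it for k, it in enumerate(items) if k not in (i, j)]
        items.append((merged, _sa | _sb))
    (da, _), (db, _) = items
    l = rng.uniform(0.1, 1.0)
    for x, dx in da.items():
        for y, dy in db.items():
            dist[frozenset((x, y))] = dx + dy + l
    D = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            D[a, b] = D[b, a] = dist[frozenset((labels[a], labels[b]))]
    return DistanceMatrix(labels, D)


def test_two_taxa_single_edge():
    D = DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
    tree = neighbor_joining(D)
    names, d = tree.path_length_matrix()
    assert d[names.index("a"), names.index("b")] == pytest.approx(0.4)


def test_three_taxa_closed_form():
    d_ab, d_ac, d_bc = 0.6, 0.8, 1.0
    D = DistanceMatrix(
        ["a", "b", "c"],
        np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]], float),
    )
    tree = neighbor_joining(D)
    by_label = {c.label: c.length for c in tree.root.children}
    assert by_label["a"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
    assert by_label["b"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
    assert by_label["c"] == pytest.approx((d_ac + d_bc - d_ab) / 2)


@pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
def test_nj_exact_on_additive_matrices(n_taxa):
    rng = np.random.default_rng(100 + n_taxa)
    for _ in range(5):
        D = random_additive_case(rng, n_taxa)
        tree = neighbor_joining(D)
        names, d = tree.path_length_matrix()
        order = [names.index(t) for t in D.ids]
        assert np.abs(d[np.ix_(order, order)] - D.d).max() < 1e-9


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


def _alignment(rows):
    return Alignment([SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)])


def test_p_distance_and_poisson():
    aln = _alignment(["AAAA", "AACC"])
    p = pairwise_distance(aln, model="p")
    assert p.d[0, 1] == pytest.approx(0.5)
    poisson = pairwise_distance(aln, model="poisson")
    assert poisson.d[0, 1] == pytest.approx(-math.log(0.5), abs=1e-6)


def test_identical_rows_zero_distance():
    aln = _alignment(["ACDE", "ACDE"])
    assert pairwise_distance(aln, "p").d[0, 1] == 0.0


def test_gap_pairwise_deletion_and_x_mismatch():
    aln = _alignment(["AC-E", "ACDE"])
    # denominator 3 comparable columns, zero mismatches
    assert pairwise_distance(aln, "p").d[0, 1] == 0.0
    aln2 = _alignment(["ACXE", "ACXE"])
    # X is comparable but never matches, even itself: 1 mismatch / 4
    assert pairwise_distance(aln2, "p").d[0, 1] == pytest.approx(0.25)


def test_zero_overlap_pair_rejected():
    aln = _alignment(["AC--", "--DE"])
    with pytest.raises(ValueError, match="comparable"):
        pairwise_distance(aln, "p")


def test_poisson_capped_at_095():
    aln = _alignment(["AAAA", "CCCC"])
    d = pairwise_distance(aln, "poisson").d[0, 1]
    assert d == pytest.approx(-math.log(1 - 0.95), abs=1e-6)


def test_trim_to_barrel():
    rows = ["MKDAELTDVW", "MKDAELTDVF"]
    aln = _alignment(rows)
    cmap = CsrColumnMap({1: 2, 52: 7})
    trimmed = trim_to_barrel(aln, cmap)
    assert trimmed.records[0].residues == rows[0][2:8]
    # idempotent once re-anchored at the new ends
    again = trim_to_barrel(trimmed, CsrColumnMap({1: 0, 52: trimmed.n_columns - 1}))
    assert again.records[0].residues == trimmed.records[0].residues
    with pytest.raises(ValueError):
        trim_to_barrel(aln, CsrColumnMap({1: 2}))


def test_perfectly_separating_columns_full_support():
    rows = ["AAAA", "AAAA", "CCCC", "CCCC"]
    aln = _alignment(rows)
    tree = bootstrap_support(aln, n_replicates=50, seed=1, model="p")
    assert tree.has_clade({"s0", "s1"})
    assert tree.support_of({"s0", "s1"}) == 100


def test_bootstrap_deterministic_under_seed(small_benchmark):
    aln = Alignment(small_benchmark.alignment.records[:30])
    t1 = bootstrap_support(aln, n_replicates=20, seed=9)
    t2 = bootstrap_support(aln, n_replicates=20, seed=9)
    assert t1.to_newick() == t2.to_newick()


def test_four_clade_synthetic_supports(benchmark_config):
    """On 4-class synthetic data every class splits out with strong support,
    mirroring the display threshold used for the real trees (>70%)."""
    from gh13tools import csr, synth
    from gh13tools.pipeline import clade_supports

    bench = synth.make_benchmark(
        list(benchmark_config["specs"].values()),
        {"GH13_48": 12, "GH13_49": 8, "GH13_38": 4, "intermediary": 4},
        seed=17,
    )
    aln = bench.alignment
    cmap = csr.anchor_csr_columns(aln, aln.records[0].id, bench.refmap)
    trimmed = trim_to_barrel(aln, cmap)
    tree = bootstrap_support(trimmed, n_replicates=100, seed=17)
    supports = clade_supports(tree, bench.truth)
    assert all(v is not None for v in supports.values())
    assert supports["GH13_48"] >= 70 and supports["GH13_49"] >= 70
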