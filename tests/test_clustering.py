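"""Stratified Hamming-distance clustering, networks, metrics, overlap."""

import math
import random

import numpy as np
import pandas as pd
import pytest

from tcrclust.clustering import (
    ClonotypeEntry,
    build_network,
    cluster_metrics,
    cluster_summary,
    collapse_clonotypes,
    hamming,
    repertoire_overlap,
    stratified_clusters,
    subcluster_complete_linkage,
)


def _entry(junction, v="TRAV1", j="TRAJ4", n_cells=1, subjects=("D1",),
           subsets=None):
    return ClonotypeEntry(
        chain="TRA", v_gene=v, j_gene=j, junction_aa=junction, n_cells=n_cells,
        subjects=frozenset(subjects), subset_counts=subsets or {"C0": n_cells},
    )


@pytest.mark.parametrize(
    "a, b, d",
    [("CALA", "CALA", 0), ("CALSD", "CALTD", 1), ("CALS", "CALSD", math.inf),
     ("CALSD", "CTLTD", 2)],
)
def test_hamming(a, b, d):
    assert hamming(a, b) == d


def test_single_vs_complete_linkage_chain():
    """HD(A,B)=1, HD(B,C)=1, HD(A,C)=2: single merges all, complete splits."""
    entries = [_entry("CALAD"), _entry("CALBD"), _entry("CALBE")]
    single = stratified_clusters(entries, "single")
    assert len(single) == 1 and single[0].cluster_id == 1
    complete = stratified_clusters(entries, "complete")
    sizes = sorted(len(c.members) for c in complete)
    assert sizes == [1, 2]
    for c in complete:  # every pair within a complete cluster is at HD <= 1
        for a in c.members:
            for b in c.members:
                assert hamming(a.junction_aa, b.junction_aa) <= 1


def test_stratification_separates_v_subgroups_and_lengths():
    entries = [
        _entry("CALSD", v="TRAV9-11"),
        _entry("CALSD", v="TRAV43-1"),  # same junction, other V subgroup
        _entry("CALSDD", v="TRAV9-11"),  # other length
    ]
    clusters = stratified_clusters(entries, "single")
    assert len(clusters) == 3  # never co-clustered across subgroup or length
    # same subgroup, different member genes DO co-cluster at HD 0
    together = stratified_clusters(
        [_entry("CALSD", v="TRAV9-11"), _entry("CALSD", v="TRAV9-6")], "single"
    )
    assert len(together) == 1


def test_singleton_is_its_own_numbered_cluster():
    (c,) = stratified_clusters([_entry("CALSD")], "single")
    cluster_metrics(c)
    assert c.cluster_id == 1 and c.n_clonotypes == 1
    assert c.density == 0.0 and c.max_degree == 0


def test_network_shapes_and_metrics():
    # 3-member chain -> path graph: 2 edges, density 2/3, max degree 2
    (path,) = stratified_clusters(
        [_entry("CALAD"), _entry("CALBD"), _entry("CALBE")], "single"
    )
    g = build_network(path)
    assert g.number_of_edges() == 2
    cluster_metrics(path, g)
    assert path.density == pytest.approx(2 / 3)
    assert path.max_degree == 2
    hub = max(g.degree, key=lambda kv: kv[1])[0]
    assert path.centrality_ranks[hub] == 1
    # star: hub CALAA plus k=3 spokes each at HD 1 from hub, HD 2 pairwise
    star_members = [_entry("CALAA"), _entry("CBLAA"), _entry("CALBA"), _entry("CALAB")]
    (star,) = stratified_clusters(star_members, "single")
    sg = build_network(star)
    assert sg.number_of_edges() == 3
    # clique of 4 (all differ at one shared position): density 1
    (clique,) = stratified_clusters(
        [_entry("CALAD"), _entry("CALBD"), _entry("CALCD"), _entry("CALDD")], "single"
    )
    cluster_metrics(clique)
    assert clique.density == 1.0


def test_publicity_and_subset_composition():
    entries = [
        _entry("CALAD", subjects=("D1", "D2"), n_cells=3,
               subsets={"C0": 2, "C1": 1}),
        _entry("CALBD", subjects=("D3",), n_cells=1, subsets={"C0": 1}),
    ]
    (c,) = stratified_clusters(entries, "single")
    cluster_metrics(c)
    assert c.publicity == 3
    assert c.subset_composition == {"C0": 0.75, "C1": 0.25}
    assert sum(c.subset_composition.values()) == pytest.approx(1.0)


def test_subclusters_confine_variation_to_one_position():
    entries = [_entry("CALSD"), _entry("CALTD"), _entry("CBLTE")]
    (c,) = stratified_clusters(entries[:2], "single")
    subs = subcluster_complete_linkage(c)
    assert subs[0]["variable_positions"] == [4]
    assert subs[0]["rank"] == 1


def test_summary_publicity_fraction():
    entries = [
        _entry("CALAD", subjects=("D1", "D2")),
        _entry("CAHHH", subjects=("D1",)),
    ]
    clusters = stratified_clusters(entries, "single")
    for c in clusters:
        cluster_metrics(c)
    summary = cluster_summary(clusters, n_subjects=2)
    assert summary["n_clusters"] == 2
    assert summary["frac_full_publicity"] == pytest.approx(0.5)
    # all-private repertoires have zero full-publicity clusters
    private = stratified_clusters([_entry("CALAD"), _entry("CAHHH")], "single")
    for c in private:
        cluster_metrics(c)
    assert cluster_summary(private, 2)["frac_full_publicity"] == 0.0


def test_collapse_clonotypes_counts():
    cells = pd.DataFrame(
        [
            ("D1", "b0", "C0", "TRA", "TRAV1", "TRAJ4", "CAVRGNKLVF"),
            ("D1", "b1", "C1", "TRA", "TRAV1", "TRAJ4", "CAVRGNKLVF"),
            ("D2", "b0", "C0", "TRA", "TRAV1", "TRAJ4", "CAVRGNKLVF"),
            ("D1", "b2", "C0", "TRA", "TRAV2", "TRAJ4", "CAVRGNKLVF"),
        ],
        columns=["subject_id", "barcode", "subset_label", "chain", "v_gene",
                 "j_gene", "junction_aa"],
    )
    entries = collapse_clonotypes(cells, "TRA")
    assert len(entries) == 2  # same junction but different V gene stays separate
    big = next(e for e in entries if e.v_gene == "TRAV1")
    assert big.n_cells == 3
    assert big.subjects == frozenset({"D1", "D2"})
    assert big.subset_counts == {"C0": 2, "C1": 1}


def test_overlap_jaccard_and_morisita():
    entries = [
        _entry("CAAAA", subsets={"X": 1, "Y": 1}),
        _entry("CBBBB", subsets={"X": 1, "Y": 1}),
        _entry("CCCCC", subsets={"X": 1, "Y": 1}),
    ]
    mat = repertoire_overlap(entries, "jaccard")
    assert mat.loc["X", "Y"] == pytest.approx(1.0)
    disjoint = [_entry("CAAAA", subsets={"X": 1}), _entry("CBBBB", subsets={"Y": 1})]
    assert repertoire_overlap(disjoint, "jaccard").loc["X", "Y"] == 0.0
    # {a,b,c} vs {b,c,d} -> 2/4
    abc_bcd = [
        _entry("CAAAA", subsets={"X": 1}),
        _entry("CBBBB", subsets={"X": 1, "Y": 1}),
        _entry("CCCCC", subsets={"X": 1, "Y": 1}),
        _entry("CDDDD", subsets={"Y": 1}),
    ]
    assert repertoire_overlap(abc_bcd, "jaccard").loc["X", "Y"] == pytest.approx(0.5)
    mh = repertoire_overlap(entries, "morisita")
    assert mh.loc["X", "Y"] == pytest.approx(1.0)
    assert (np.diag(repertoire_overlap(abc_bcd, "jaccard")) == 1.0).all()


def test_deterministic_under_input_order():
    rng = random.Random(3)
    juncs = ["CAL" + a + b for a in "ASDF" for b in "ASDF"]
    entries = [_entry(j) for j in juncs]
    base = stratified_clusters(entries, "single")
    for c in base:
        cluster_metrics(c)
    shuffled = entries[:]
    rng.shuffle(shuffled)
    again = stratified_clusters(shuffled, "single")
    for c in again:
        cluster_metrics(c)
    key = lambda cs: [(c.cluster_id, c.stratum, sorted(e.key for e in c.members),
                       c.density, c.publicity) for c in cs]
    assert key(base) == key(again)
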