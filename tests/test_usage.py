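"""Junction lengths, gene usage, pairing, PWMs and germline attribution."""

import numpy as np
import pandas as pd
import pytest

from tcrclust.io import GermlineDB
from tcrclust.profiles import build_cell_profiles
from tcrclust.usage import (
    dominance_flags,
    gene_usage,
    germline_attribution,
    junction_length_distribution,
    position_weight_matrix,
    single_pair_cells,
    vj_pairing,
)


def _cells(rows):
    return pd.DataFrame(
        rows,
        columns=["subject_id", "barcode", "subset_label", "chain", "v_gene",
                 "j_gene", "junction_aa"],
    ).assign(length=lambda d: d["junction_aa"].str.len())


def test_length_median_and_skew_flag():
    rows = [("D1", f"b{i}", "X", "TRA", "TRAV1", "TRAJ4", "C" * L)
            for i, L in enumerate([14, 14, 15])]
    dist = junction_length_distribution(_cells(rows), "TRA")
    assert dist.attrs["medians"]["X"] == 14
    assert dist.groupby("subset_label")["percent"].sum().eq(100.0).all()
    # a subset with a >=50% modal length is flagged skewed
    assert dist.attrs["skewed"] == {"X": 14}


def test_usage_fractions_and_column_sums():
    rows = [("D1", f"b{i}", "X", "TRA", v, "TRAJ4", "CAVRGNKLVF")
            for i, v in enumerate(["TRAV1", "TRAV1", "TRAV1", "TRAV2"])]
    table = gene_usage(_cells(rows), "TRA", "V")
    assert table.loc["TRAV1", "X"] == pytest.approx(0.75)
    assert table.loc["TRAV2", "X"] == pytest.approx(0.25)
    assert table.sum(axis=0).eq(1.0).all()


def test_pairing_fractions_and_marginal_consistency():
    rows = [
        ("D1", "b0", "X", "TRA", "TRAV1", "TRAJ4", "CAVRGNKLVF"),
        ("D1", "b1", "X", "TRA", "TRAV1", "TRAJ4", "CAVRGNKLVF"),
        ("D1", "b2", "X", "TRA", "TRAV1", "TRAJ4", "CAVRGNKLVF"),
        ("D1", "b3", "X", "TRA", "TRAV1", "TRAJ9", "CAVRTGGFKTIF"),
    ]
    cells = _cells(rows)
    mat = vj_pairing(cells, "TRA", "X")
    assert mat.loc["TRAV1", "TRAJ4"] == pytest.approx(0.75)
    assert mat.loc["TRAV1", "TRAJ9"] == pytest.approx(0.25)
    ranked = mat.attrs["ranked_pairs"]
    assert tuple(ranked.iloc[0][["v_gene", "j_gene"]]) == ("TRAV1", "TRAJ4")
    # pairing marginals reproduce usage tables exactly
    v_usage = gene_usage(cells, "TRA", "V")["X"]
    j_usage = gene_usage(cells, "TRA", "J")["X"]
    assert np.allclose(mat.sum(axis=1), v_usage.reindex(mat.index))
    assert np.allclose(mat.sum(axis=0), j_usage.reindex(mat.columns))


def test_pairing_marginals_on_cohort(small_cohort):
    prof = build_cell_profiles(small_cohort.contigs, small_cohort.annotations)
    cells = single_pair_cells(small_cohort.contigs, prof)
    mat = vj_pairing(cells, "TRA", "C13")
    v_usage = gene_usage(cells, "TRA", "V")["C13"]
    assert np.allclose(mat.sum(axis=1), v_usage.reindex(mat.index))
    # genes absent from the pairing matrix are unused in that subset
    assert v_usage.drop(mat.index).eq(0).all()


def test_dominance_rule_arithmetic():
    usage = pd.DataFrame(
        {"A": [0.825, 0.05], "B": [0.05, 0.05], "C": [0.04, 0.05], "D": [0.06, 0.05]},
        index=["geneX", "geneY"],
    )
    flags = dominance_flags(usage)
    assert list(flags["gene"]) == ["geneX"] and list(flags["subset_label"]) == ["A"]
    # fold 2 < 3 is not flagged even above min_frac
    usage2 = pd.DataFrame({"A": [0.30], "B": [0.15], "C": [0.15]}, index=["g"])
    assert dominance_flags(usage2).empty
    uniform = pd.DataFrame({"A": [0.5, 0.5], "B": [0.5, 0.5]}, index=["g1", "g2"])
    assert dominance_flags(uniform).empty


def test_pwm_hand_count_and_one_hot():
    pwm = position_weight_matrix(["CAT", "CAT", "CAG"])
    assert pwm.matrix.loc[3, "T"] == pytest.approx(2 / 3)
    assert pwm.matrix.loc[3, "G"] == pytest.approx(1 / 3)
    assert pwm.consensus == "CA?"
    assert pwm.variable_positions == [3]
    assert np.allclose(pwm.matrix.sum(axis=1), 1.0)

    single = position_weight_matrix(["CALSD"])
    assert (single.matrix.to_numpy().max(axis=1) == 1.0).all()
    assert single.variable_positions == []
    assert single.consensus == "CALSD"

    with pytest.raises(ValueError, match="stratify"):
        position_weight_matrix(["CAT", "CATS"])


def test_germline_attribution_invariant_motif(germline):
    """16-aa invariant junction: 4 V-encoded, 2 added, 10 J-encoded."""
    att = germline_attribution("CALSDRYSGVGSQLTF", "TRAV9-11", "TRAJ28", germline)
    assert (att.n_v, att.n_added, att.n_j) == (4, 2, 10)
    assert att.length == 16


def test_germline_attribution_edge_cases(germline):
    # junction that is exactly V-prefix + J-suffix: nothing added
    att = germline_attribution("CALS" + "YSGVGSQLTF", "TRAV9-11", "TRAJ28", germline)
    assert att.n_added == 0
    # junction sharing nothing with either germline region
    att = germline_attribution("WWWWWWWWWW", "TRAV9-11", "TRAJ28", germline)
    assert (att.n_v, att.n_added, att.n_j) == (0, 10, 0)
    from tcrclust.io import MissingGeneError

    with pytest.raises(MissingGeneError):
        germline_attribution("CALSDRYSGVGSQLTF", "TRAV99", "TRAJ28", germline)


def _attribution_oracle(junction, gv, gj):
    """Enumerate all (prefix, suffix) splits; maximise matched positions, then n_v."""
    L = len(junction)
    best = (0, 0)  # (n_v, n_j) maximising n_v + n_j then n_v
    for i in range(0, min(L, len(gv)) + 1):
        if junction[:i] != gv[:i]:
            continue
        for j in range(0, min(L - i, len(gj)) + 1):
            if j and junction[L - j:] != gj[len(gj) - j:]:
                continue
            if (i + j, i) > (best[0] + best[1], best[0]):
                best = (i, j)
    return best


def test_attribution_matches_split_enumeration_oracle(germline):
    rng = np.random.default_rng(5)
    genes_v = [g for g in germline.as_dict() if "V" in g]
    genes_j = [g for g in germline.as_dict() if "J" in g]
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(300):
        v = genes_v[rng.integers(len(genes_v))]
        j = genes_j[rng.integers(len(genes_j))]
        gv, gj = germline.get(v), germline.get(j)
        n_insert = int(rng.integers(0, 6))
        insert = "".join(aa[i] for i in rng.integers(0, 20, n_insert))
        keep_j = int(rng.integers(1, len(gj) + 1))
        junction = gv + insert + gj[len(gj) - keep_j:]
        att = germline_attribution(junction, v, j, germline)
        n_v, n_j = _attribution_oracle(junction, gv, gj)
        assert (att.n_v, att.n_j) == (n_v, n_j)
        assert att.n_v + att.n_added + att.n_j == len(junction)
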