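"""Junction lengths, V/J gene usage and pairing, motifs and germline attribution.

All statistics in this module are computed on cells carrying exactly one
productive TRA and one productive TRB rearrangement (pattern "1-1"), so
that each cell contributes exactly one rearrangement per chain and dual-TCR
cells cannot double-count.  Junction lengths use the anchored convention
(conserved C and F included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ContigRecord, GermlineDB

AA_ORDER = list("ACDEFGHIKLMNPQRSTVWY")


def single_pair_cells(
    contigs: list[ContigRecord], profiles: pd.DataFrame
) -> pd.DataFrame:
    """Long table of rearrangements for pattern "1-1" cells.

    One row per cell per chain: subject_id, barcode, subset_label, chain,
    v_gene, j_gene, junction_aa, length.
    """
    keep = profiles.loc[profiles["pattern"] == "1-1"]
    subset_of = {
        (r.subject_id, r.barcode): r.subset_label for r in keep.itertuples()
    }
    seen: set[tuple] = set()
    rows = []
    for c in contigs:
        key = (c.subject_id, c.barcode)
        if key not in subset_of or not c.productive:
            continue
        ident = (c.subject_id, c.barcode, c.chain, c.v_gene, c.j_gene, c.junction_aa)
        if ident in seen:  # duplicate contig rows for the same rearrangement
            continue
        seen.add(ident)
        rows.append(
            {
                "subject_id": c.subject_id,
                "barcode": c.barcode,
                "subset_label": subset_of[key],
                "chain": c.chain,
                "v_gene": c.v_gene,
                "j_gene": c.j_gene,
                "junction_aa": c.junction_aa,
                "length": len(c.junction_aa),
            }
        )
    return pd.DataFrame(rows)


def junction_length_distribution(
    cells: pd.DataFrame, chain: str, dominance_frac: float = 0.5
) -> pd.DataFrame:
    """Per-subset junction-length histogram with medians and skew flags.

    Returns a long frame (subset_label, length, n_cells, percent) with
    attrs ``medians`` (per subset), ``global_median`` and ``skewed``
    (subsets whose modal length holds >= ``dominance_frac`` of cells).
    """
    df = cells.loc[cells["chain"] == chain]
    if df.empty:
        raise ValueError(f"no {chain} rearrangements among single-pair cells")
    counts = (
        df.groupby(["subset_label", "length"]).size().rename("n_cells").reset_index()
    )
    totals = counts.groupby("subset_label")["n_cells"].transform("sum")
    counts["percent"] = 100.0 * counts["n_cells"] / totals
    medians = df.groupby("subset_label")["length"].median()
    modal = counts.loc[counts.groupby("subset_label")["percent"].idxmax()]
    skewed = {
        r.subset_label: int(r.length)
        for r in modal.itertuples()
        if r.percent >= 100.0 * dominance_frac
    }
    counts.attrs["medians"] = medians
    counts.attrs["global_median"] = float(df["length"].median())
    counts.attrs["skewed"] = skewed
    return counts


def gene_usage(
    cells: pd.DataFrame, chain: str, segment: str, top_k: int = 20
) -> pd.DataFrame:
    """Usage fractions per subset: rows = gene, columns = subset.

    Column sums are 1 over the genes observed in each subset.  The global
    top-``top_k`` ranking (by mean fraction across subsets) is stored in
    ``attrs["top_genes"]``.
    """
    if segment not in ("V", "J"):
        raise ValueError("segment must be 'V' or 'J'")
    col = "v_gene" if segment == "V" else "j_gene"
    df = cells.loc[cells["chain"] == chain]
    counts = df.groupby(["subset_label", col]).size().unstack(fill_value=0).T
    usage = counts / counts.sum(axis=0)
    usage = usage.sort_index()
    ranking = usage.mean(axis=1).sort_values(ascending=False)
    usage.attrs["top_genes"] = list(ranking.index[:top_k])
    return usage


def vj_pairing(cells: pd.DataFrame, chain: str, subset: str) -> pd.DataFrame:
    """V x J cell-fraction matrix for one subset.

    ``attrs["ranked_pairs"]`` holds (v_gene, j_gene, fraction) sorted by
    fraction descending, ties broken lexicographically.
    """
    df = cells.loc[(cells["chain"] == chain) & (cells["subset_label"] == subset)]
    if df.empty:
        raise ValueError(f"no {chain} rearrangements in subset {subset!r}")
    counts = df.groupby(["v_gene", "j_gene"]).size().unstack(fill_value=0)
    mat = counts / counts.to_numpy().sum()
    pairs = (
        mat.stack().rename("fraction").reset_index().query("fraction > 0")
        .sort_values(["fraction", "v_gene", "j_gene"], ascending=[False, True, True])
        .reset_index(drop=True)
    )
    mat.attrs["ranked_pairs"] = pairs
    return mat


def pairing_edge_list(mat: pd.DataFrame) -> pd.DataFrame:
    """Flatten a pairing matrix to a (v_gene, j_gene, weight) edge list."""
    edges = mat.stack().rename("weight").reset_index()
    return edges.loc[edges["weight"] > 0].reset_index(drop=True)


def dominance_flags(
    usage: pd.DataFrame, min_frac: float = 0.25, min_fold: float = 3.0
) -> pd.DataFrame:
    """Flag (gene, subset) pairs with outlier usage.

    A gene is flagged in a subset when its within-subset fraction is at
    least ``min_frac`` and at least ``min_fold`` times the median fraction
    of that gene across subsets.
    """
    if usage.shape[1] < 2:
        raise ValueError("dominance flags need usage over at least 2 subsets")
    medians = usage.median(axis=1)
    rows = []
    for gene in usage.index:
        med = medians[gene]
        for subset in usage.columns:
            frac = usage.at[gene, subset]
            if frac >= min_frac and frac >= min_fold * med:
                rows.append(
                    {"gene": gene, "subset_label": subset, "fraction": frac,
                     "median_fraction": med}
                )
    return pd.DataFrame(rows, columns=["gene", "subset_label", "fraction", "median_fraction"])


@dataclass
class PositionWeightMatrix:
    """Length-stratified per-position amino-acid frequencies."""

    length: int
    matrix: pd.DataFrame  # positions (1-based index) x 20 amino acids
    n_sequences: int
    consensus: str  # '?' marks variable positions
    variable_positions: list[int] = field(default_factory=list)  # 1-based


def position_weight_matrix(junctions: list[str]) -> PositionWeightMatrix:
    """PWM of equal-length junctions; raises on mixed lengths."""
    if not junctions:
        raise ValueError("need at least one junction sequence")
    lengths = {len(j) for j in junctions}
    if len(lengths) > 1:
        raise ValueError(
            f"mixed junction lengths {sorted(lengths)}: stratify by length first"
        )
    L = lengths.pop()
    mat = np.zeros((L, len(AA_ORDER)))
    aa_idx = {aa: i for i, aa in enumerate(AA_ORDER)}
    for j in junctions:
        for pos, aa in enumerate(j):
            mat[pos, aa_idx[aa]] += 1
    mat /= len(junctions)
    df = pd.DataFrame(mat, index=range(1, L + 1), columns=AA_ORDER)
    consensus = []
    variable = []
    for pos in range(L):
        top = mat[pos].argmax()
        if mat[pos, top] == 1.0:
            consensus.append(AA_ORDER[top])
        else:
            consensus.append("?")
            variable.append(pos + 1)
    return PositionWeightMatrix(
        length=L, matrix=df, n_sequences=len(junctions),
        consensus="".join(consensus), variable_positions=variable,
    )


@dataclass(frozen=True)
class GermlineAttribution:
    """Split of junction positions into V-encoded, added, and J-encoded."""

    n_v: int
    n_added: int
    n_j: int

    @property
    def length(self) -> int:
        return self.n_v + self.n_added + self.n_j


def germline_attribution(
    junction_aa: str, v_gene: str, j_gene: str, germline: GermlineDB
) -> GermlineAttribution:
    """Attribute junction positions to germline V, germline J, or additions.

    The V junction region is anchored at the junction start (conserved C),
    the J region at the junction end (conserved F): n_v is the longest
    junction prefix matching the V region prefix, n_j the longest junction
    suffix matching the J region suffix (trimming removes the 5' end of J).
    When the two matches overlap, the J match is truncated so that n_v is
    maximised first.
    """
    gv = germline.get(v_gene)
    gj = germline.get(j_gene)
    L = len(junction_aa)
    n_v = 0
    for k in range(1, min(L, len(gv)) + 1):
        if junction_aa[:k] == gv[:k]:
            n_v = k
        else:
            break
    n_j = 0
    for k in range(1, min(L, len(gj)) + 1):
        if junction_aa[L - k:] == gj[len(gj) - k:]:
            n_j = k
        else:
            break
    n_j = min(n_j, L - n_v)
    return GermlineAttribution(n_v=n_v, n_added=L - n_v - n_j, n_j=n_j)
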