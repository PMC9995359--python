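"""Per-cell rearrangement patterns and detection rates.

A cell's pattern is ``"x-y"`` where x and y are the numbers of *distinct
productive* TRA and TRB rearrangements detected for that cell; a
rearrangement is a distinct (chain, V gene, J gene, junction-aa) tuple, so
duplicate contig rows supporting the same rearrangement collapse to one.
Annotated cells without any contig get pattern "0-0" so that
detection-rate denominators are the QC-passing cell universe, not the
contig-bearing one.
"""

from __future__ import annotations

import logging

import pandas as pd

from .io import CellAnnotation, ContigRecord

logger = logging.getLogger(__name__)


def build_cell_profiles(
    contigs: list[ContigRecord], annotations: list[CellAnnotation]
) -> pd.DataFrame:
    """One row per annotated cell: subject_id, barcode, subset_label, n_tra, n_trb, pattern."""
    ann_index = {(a.subject_id, a.barcode): a for a in annotations}
    rearr: dict[tuple[str, str], set[tuple]] = {key: set() for key in ann_index}
    n_orphans = 0
    for c in contigs:
        key = (c.subject_id, c.barcode)
        if key not in ann_index:
            n_orphans += 1
            continue
        if not c.productive:
            continue
        rearr[key].add((c.chain, c.v_gene, c.j_gene, c.junction_aa))
    if n_orphans:
        logger.warning("dropped %d contigs whose cell is not annotated", n_orphans)
    rows = []
    for key, ann in ann_index.items():
        tuples = rearr[key]
        n_tra = sum(1 for t in tuples if t[0] == "TRA")
        n_trb = sum(1 for t in tuples if t[0] == "TRB")
        rows.append(
            {
                "subject_id": ann.subject_id,
                "barcode": ann.barcode,
                "subset_label": ann.subset_label,
                "n_tra": n_tra,
                "n_trb": n_trb,
                "pattern": f"{n_tra}-{n_trb}",
            }
        )
    return pd.DataFrame(rows)


def pattern_frequencies(
    profiles: pd.DataFrame, by_subset: bool = True
) -> pd.DataFrame:
    """Pattern counts and percentages per group (subset or global).

    Returns a long frame (group, pattern, n_cells, percent); percents sum
    to 100 within each group.  A ``median_percent`` per pattern across
    groups is attached as frame attribute ``pattern_medians`` and is also
    available from :func:`pattern_percent_matrix`.
    """
    if profiles.empty:
        raise ValueError("no cell profiles")
    df = profiles.copy()
    df["group"] = df["subset_label"] if by_subset else "all"
    counts = (
        df.groupby(["group", "pattern"], sort=True).size().rename("n_cells").reset_index()
    )
    totals = counts.groupby("group")["n_cells"].transform("sum")
    counts["percent"] = 100.0 * counts["n_cells"] / totals
    mat = counts.pivot(index="pattern", columns="group", values="percent").fillna(0.0)
    counts.attrs["pattern_medians"] = mat.median(axis=1)
    return counts


def pattern_percent_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Wide table: rows = pattern, columns = subset, values = percent of cells."""
    freq = pattern_frequencies(profiles, by_subset=True)
    mat = freq.pivot(index="pattern", columns="group", values="percent").fillna(0.0)
    mat["median"] = mat.median(axis=1)
    return mat


def detection_rate(
    profiles: pd.DataFrame, threshold: float = 75.0
) -> tuple[pd.DataFrame, float, int]:
    """Percent of cells per subset with at least one rearrangement.

    Returns ``(per_subset, median_percent, n_subsets_above_threshold)``.
    """
    df = profiles.copy()
    df["detected"] = (df["n_tra"] + df["n_trb"]) >= 1
    per = (
        df.groupby("subset_label")["detected"]
        .agg(n_cells="size", n_detected="sum")
        .reset_index()
    )
    per["percent_detected"] = 100.0 * per["n_detected"] / per["n_cells"]
    median = float(per["percent_detected"].median())
    n_above = int((per["percent_detected"] >= threshold).sum())
    return per, median, n_above
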