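"""Virtual CD4/CD8A gating and lineage-group classification of subsets.

Cells are gated on detection of the two lineage markers in the expression
matrix: double-positive (dp) if both reach the positivity threshold,
single-positive (CD4_sp / CD8A_sp) if exactly one does, double-negative
(dn) otherwise.  Transcriptome subsets are then classified from their gate
composition *after excluding dn cells*: a subset is CD4-dominant when at
least 66% of non-dn cells are CD4_sp and fewer than 25% are CD8A_sp; the
mirrored rule defines CD8A-dominant; everything else is mixed.

The positivity rule is detection-above-zero by default (threshold 1 UMI on
raw counts); marker drop-out is why dn cells are excluded from composition
denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellAnnotation

GATES = ("CD4_sp", "CD8A_sp", "dp", "dn")

CD4_DOMINANT = "CD4_dominant"
CD8A_DOMINANT = "CD8A_dominant"
MIXED = "mixed"


@dataclass(frozen=True)
class GateCall:
    barcode: str
    subject_id: str
    gate: str


def gate_cells(expression: pd.DataFrame, threshold: int = 1) -> list[GateCall]:
    """Assign one gate per cell from CD4/CD8A counts.

    ``expression`` is indexed by (subject_id, barcode) with integer columns
    ``CD4`` and ``CD8A`` (see :func:`tcrclust.io.read_expression_extract`).
    """
    if threshold < 1:
        raise ValueError("threshold must be a positive integer")
    cd4 = expression["CD4"].to_numpy()
    cd8a = expression["CD8A"].to_numpy()
    if (cd4 < 0).any() or (cd8a < 0).any():
        raise ValueError("negative marker counts")
    cd4_pos = cd4 >= threshold
    cd8a_pos = cd8a >= threshold
    gate = np.where(
        cd4_pos & cd8a_pos, "dp",
        np.where(cd4_pos, "CD4_sp", np.where(cd8a_pos, "CD8A_sp", "dn")),
    )
    return [
        GateCall(barcode=bc, subject_id=subj, gate=g)
        for (subj, bc), g in zip(expression.index, gate)
    ]


def cluster_composition(
    gates: list[GateCall], annotations: list[CellAnnotation]
) -> pd.DataFrame:
    """Per-subset gate composition over non-dn cells.

    Returns a frame indexed by subset_label with columns ``n_cells_total``,
    ``n_dn``, ``frac_cd4_sp``, ``frac_cd8a_sp``, ``frac_dp`` and a boolean
    ``all_dn`` flag; fractions are NaN for all-dn subsets.
    """
    ann = {(a.subject_id, a.barcode): a.subset_label for a in annotations}
    rows = []
    for g in gates:
        key = (g.subject_id, g.barcode)
        if key not in ann:
            raise ValueError(f"gated cell {key} has no annotation")
        rows.append({"subset_label": ann[key], "gate": g.gate})
    df = pd.DataFrame(rows)
    out = []
    for subset, grp in df.groupby("subset_label", sort=True):
        n_total = len(grp)
        counts = grp["gate"].value_counts()
        n_dn = int(counts.get("dn", 0))
        n_pos = n_total - n_dn
        rec = {
            "subset_label": subset,
            "n_cells_total": n_total,
            "n_dn": n_dn,
            "all_dn": n_pos == 0,
        }
        for gate, col in (("CD4_sp", "frac_cd4_sp"), ("CD8A_sp", "frac_cd8a_sp"), ("dp", "frac_dp")):
            rec[col] = float(counts.get(gate, 0)) / n_pos if n_pos else float("nan")
        out.append(rec)
    return pd.DataFrame(out).set_index("subset_label")


def assign_lineage_group(
    frac_cd4_sp: float,
    frac_cd8a_sp: float,
    dominant_min: float = 0.66,
    other_max: float = 0.25,
) -> str:
    """Classify one subset composition into CD4-dominant / CD8A-dominant / mixed."""
    if np.isnan(frac_cd4_sp) or np.isnan(frac_cd8a_sp):
        raise ValueError("composition undefined (all-dn subset)")
    if frac_cd4_sp >= dominant_min and frac_cd8a_sp < other_max:
        return CD4_DOMINANT
    if frac_cd8a_sp >= dominant_min and frac_cd4_sp < other_max:
        return CD8A_DOMINANT
    return MIXED


def classify_clusters(composition: pd.DataFrame, **kwargs) -> pd.Series:
    """Vectorised :func:`assign_lineage_group` over a composition table."""
    return pd.Series(
        {
            subset: (
                assign_lineage_group(row.frac_cd4_sp, row.frac_cd8a_sp, **kwargs)
                if not row.all_dn
                else "undefined"
            )
            for subset, row in composition.iterrows()
        },
        name="lineage_group",
    )
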