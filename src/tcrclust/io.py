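"""Reading, validation and writing of repertoire tables.

Supported inputs are the two contig-table dialects commonly produced by
single-cell V(D)J pipelines (the 10x ``filtered_contig_annotations.csv``
layout and the AIRR Rearrangement TSV), a cell metadata table mapping
barcodes to subjects and transcriptome subsets, a two-gene (CD4/CD8A)
expression extract, and a germline junction-region FASTA.

Conventions
-----------
* Gene names are normalised by stripping the allele suffix (``TRAV9-11*01``
  -> ``TRAV9-11``); the gene-member suffix is kept.  :func:`subgroup`
  additionally strips the member suffix (``TRAV9-11`` -> ``TRAV9``) for
  stratified clustering.
* Junctions follow the anchored IMGT convention: the conserved cysteine and
  phenylalanine are included in ``junction_aa`` and in every reported
  length.
* Cells are identified by ``(subject_id, barcode)`` so that merged
  multi-subject cohorts cannot collide on barcode alone.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

_ALLELE_RE = re.compile(r"\*\d+$")
_MEMBER_RE = re.compile(r"-\d+$")


class SchemaError(ValueError):
    """An input table is missing a required column or violates its schema."""


class MissingGeneError(KeyError):
    """A queried V/J gene is absent from the germline reference."""


def normalize_gene(name: str) -> str:
    """Strip the allele suffix (``*NN``) from a gene name. Idempotent."""
    return _ALLELE_RE.sub("", name.strip())


def subgroup(gene: str) -> str:
    """Gene subgroup: strip the member suffix (``TRAV9-11`` -> ``TRAV9``)."""
    return _MEMBER_RE.sub("", normalize_gene(gene))


@dataclass(frozen=True)
class ContigRecord:
    """One V(D)J contig call for one cell."""

    barcode: str
    subject_id: str
    chain: str  # "TRA" | "TRB"
    v_gene: str
    j_gene: str
    junction_aa: str
    junction_nt: str | None = None
    productive: bool = True
    umis: int = 0

    def validate(self) -> None:
        if self.chain not in ("TRA", "TRB"):
            raise ValueError(f"unknown chain {self.chain!r}")
        if self.umis < 0:
            raise ValueError("umis must be non-negative")
        if self.productive and len(self.junction_aa) < 5:
            raise ValueError(
                f"productive junction {self.junction_aa!r} shorter than 5 aa"
            )
        if self.junction_nt and self.junction_aa:
            if len(self.junction_nt) != 3 * len(self.junction_aa):
                raise ValueError(
                    "junction_nt length must be 3x junction_aa length"
                )
        if self.v_gene and not self.v_gene.startswith(self.chain + "V"):
            raise ValueError(
                f"v_gene {self.v_gene!r} does not match chain {self.chain}"
            )


@dataclass(frozen=True)
class CellAnnotation:
    """Barcode -> subject and transcriptome subset assignment."""

    barcode: str
    subject_id: str
    subset_label: str
    lineage_group: str | None = None


class GermlineDB:
    """Map from gene name to the germline junction-region amino acids.

    For V genes the stored region starts at the conserved cysteine; for J
    genes it ends at the conserved phenylalanine.  Lookup uses normalised
    gene names and raises :class:`MissingGeneError` for absent genes.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            key = normalize_gene(name)
            seq = seq.upper()
            bad = set(seq) - AA_ALPHABET
            if bad:
                raise ValueError(
                    f"germline {name!r} contains non-amino-acid characters {sorted(bad)}"
                )
            if key in self._seqs:
                raise ValueError(f"duplicate germline gene {key!r}")
            self._seqs[key] = seq

    def get(self, gene: str) -> str:
        key = normalize_gene(gene)
        try:
            return self._seqs[key]
        except KeyError:
            raise MissingGeneError(f"gene {gene!r} not in germline reference") from None

    def __contains__(self, gene: str) -> bool:
        return normalize_gene(gene) in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def as_dict(self) -> dict[str, str]:
        return dict(self._seqs)


_TENX_COLUMNS = ["barcode", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt", "productive", "umis"]
_AIRR_COLUMNS = ["cell_id", "locus", "v_call", "j_call", "junction_aa", "junction", "productive", "duplicate_count"]

_TRUTHY = {"true", "t", "1", "yes"}
_FALSY = {"false", "f", "0", "no", "none", ""}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot interpret productive flag {value!r}")


def read_contig_table(
    path: str | Path,
    dialect: str,
    subject_id: str | None = None,
    rejects: list | None = None,
) -> list[ContigRecord]:
    """Read a contig annotation table into :class:`ContigRecord` objects.

    Parameters
    ----------
    dialect
        ``"tenx_csv"`` or ``"airr_tsv"``.
    subject_id
        Subject to assign when the table has no ``subject_id`` column
        (single-subject exports).
    rejects
        Optional list; records with an unknown chain value are appended to
        it as ``(row_index, reason)`` instead of raising.
    """
    path = Path(path)
    if dialect == "tenx_csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required, colmap = _TENX_COLUMNS, {
            "barcode": "barcode", "chain": "chain", "v_gene": "v_gene",
            "j_gene": "j_gene", "cdr3": "junction_aa", "cdr3_nt": "junction_nt",
            "productive": "productive", "umis": "umis",
        }
    elif dialect == "airr_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required, colmap = _AIRR_COLUMNS, {
            "cell_id": "barcode", "locus": "chain", "v_call": "v_gene",
            "j_call": "j_gene", "junction_aa": "junction_aa",
            "junction": "junction_nt", "productive": "productive",
            "duplicate_count": "umis",
        }
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{dialect} table {path.name} is missing column {col!r}")

    records: list[ContigRecord] = []
    n_empty = 0
    for idx, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        junction_aa = row_d[next(k for k, v in colmap.items() if v == "junction_aa")].strip()
        if not junction_aa:
            n_empty += 1
            continue
        chain = row_d[next(k for k, v in colmap.items() if v == "chain")].strip()
        if chain not in ("TRA", "TRB"):
            if rejects is not None:
                rejects.append((idx, f"unknown chain {chain!r}"))
                continue
            raise ValueError(f"row {idx}: unknown chain {chain!r}")
        subj = row_d.get("subject_id", "") or (subject_id or "")
        nt = row_d[next(k for k, v in colmap.items() if v == "junction_nt")].strip() or None
        rec = ContigRecord(
            barcode=row_d[next(k for k, v in colmap.items() if v == "barcode")].strip(),
            subject_id=subj,
            chain=chain,
            v_gene=normalize_gene(row_d[next(k for k, v in colmap.items() if v == "v_gene")]),
            j_gene=normalize_gene(row_d[next(k for k, v in colmap.items() if v == "j_gene")]),
            junction_aa=junction_aa,
            junction_nt=nt,
            productive=_parse_bool(row_d[next(k for k, v in colmap.items() if v == "productive")]),
            umis=int(row_d[next(k for k, v in colmap.items() if v == "umis")] or 0),
        )
        records.append(rec)
    if n_empty:
        logger.warning("%s: dropped %d contig rows with empty junction", path.name, n_empty)
    if not records:
        logger.warning("%s: no contig records read", path.name)
    return records


def read_cell_metadata(path: str | Path) -> list[CellAnnotation]:
    """Read the barcode -> (subject, subset) table; duplicates are an error."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    for col in ("barcode", "subject_id", "subset_label"):
        if col not in df.columns:
            raise SchemaError(f"cell metadata {path.name} is missing column {col!r}")
    dup = df.duplicated(subset=["barcode", "subject_id"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["subject_id", "barcode"]].drop_duplicates()
        raise ValueError(
            "duplicate (barcode, subject) pairs in cell metadata: "
            + "; ".join(f"{r.subject_id}/{r.barcode}" for r in offenders.itertuples())
        )
    return [
        CellAnnotation(
            barcode=r.barcode,
            subject_id=r.subject_id,
            subset_label=r.subset_label,
            lineage_group=getattr(r, "lineage_group", None) or None,
        )
        for r in df.itertuples(index=False)
    ]


def read_germline_reference(path: str | Path) -> GermlineDB:
    """Read a germline junction-region FASTA (headers are gene names)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if normalize_gene(name) in seqs:
            raise ValueError(f"duplicate FASTA header {name!r}")
        seqs[normalize_gene(name)] = str(rec.seq)
    return GermlineDB(seqs)


def read_expression_extract(path: str | Path) -> pd.DataFrame:
    """Read a CD4/CD8A expression extract.

    Dense TSV layout: columns ``subject_id, barcode, CD4, CD8A``.  MTX
    layout: ``<stem>.mtx`` (genes x cells) with ``<stem>.genes.txt`` and
    ``<stem>.cells.txt`` (cells as ``subject_id<TAB>barcode``).
    Returns a frame indexed by (subject_id, barcode) with integer columns
    CD4 and CD8A.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(str(path)).toarray()
        genes = Path(str(path)[: -len(".mtx")] + ".genes.txt").read_text().split()
        cells = [
            tuple(line.split("\t"))
            for line in Path(str(path)[: -len(".mtx")] + ".cells.txt").read_text().splitlines()
        ]
        df = pd.DataFrame(mat.T, columns=genes)
        df.index = pd.MultiIndex.from_tuples(cells, names=["subject_id", "barcode"])
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.set_index(["subject_id", "barcode"])
    for gene in ("CD4", "CD8A"):
        if gene not in df.columns:
            raise SchemaError(f"expression extract is missing gene column {gene!r}")
    out = df[["CD4", "CD8A"]].astype(int)
    if (out < 0).any().any():
        raise ValueError("expression extract contains negative counts")
    return out


# ---------------------------------------------------------------------------
# Writers


def contigs_to_frame(contigs: Iterable[ContigRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "barcode": c.barcode, "subject_id": c.subject_id, "chain": c.chain,
                "v_gene": c.v_gene, "j_gene": c.j_gene, "junction_aa": c.junction_aa,
                "junction_nt": c.junction_nt or "", "productive": c.productive,
                "umis": c.umis,
            }
            for c in contigs
        ]
    )


def write_contigs_tenx(contigs: Iterable[ContigRecord], path: str | Path) -> None:
    df = contigs_to_frame(contigs)
    out = pd.DataFrame(
        {
            "barcode": df["barcode"], "subject_id": df["subject_id"],
            "chain": df["chain"], "v_gene": df["v_gene"], "j_gene": df["j_gene"],
            "cdr3": df["junction_aa"], "cdr3_nt": df["junction_nt"],
            "productive": df["productive"].map({True: "True", False: "False"}),
            "umis": df["umis"],
        }
    )
    out.to_csv(path, index=False)


def write_contigs_airr(contigs: Iterable[ContigRecord], path: str | Path) -> None:
    df = contigs_to_frame(contigs)
    out = pd.DataFrame(
        {
            "cell_id": df["barcode"], "subject_id": df["subject_id"],
            "locus": df["chain"], "v_call": df["v_gene"], "j_call": df["j_gene"],
            "junction_aa": df["junction_aa"], "junction": df["junction_nt"],
            "productive": df["productive"].map({True: "T", False: "F"}),
            "duplicate_count": df["umis"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_cell_metadata(annotations: Iterable[CellAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"barcode": a.barcode, "subject_id": a.subject_id, "subset_label": a.subset_label}
            for a in annotations
        ]
    ).to_csv(path, sep="\t", index=False)


def write_expression_extract(expr: pd.DataFrame, path: str | Path) -> None:
    expr.reset_index().to_csv(path, sep="\t", index=False)


def write_germline_fasta(db: GermlineDB, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(db.as_dict().items())
    ]
    SeqIO.write(records, str(path), "fasta")


def write_table(df: pd.DataFrame, path: str | Path, params: Mapping | None = None,
                index: bool = False) -> None:
    """Write a result TSV with generating parameters in ``#`` header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (params or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)
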