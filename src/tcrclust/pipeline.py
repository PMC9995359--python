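"""End-to-end repertoire analysis runner.

:func:`run_pipeline` chains every analysis stage over one cohort -- gating,
rearrangement patterns, junction lengths, V/J usage and pairing, dominance
flags, invariant-motif PWMs with germline attribution, and V/J-stratified
clonotype superclustering with network metrics -- and writes one TSV per
result plus a JSON run manifest (package version, parameters, input
checksums) so a run can be reproduced exactly.  Inputs come either from
files (:class:`RunConfig`) or from an in-memory simulated cohort.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import clustering, gating, profiles, usage
from .io import (
    CellAnnotation,
    ContigRecord,
    GermlineDB,
    read_cell_metadata,
    read_contig_table,
    read_expression_extract,
    read_germline_reference,
    write_table,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """File-based pipeline configuration (paths must exist at validation)."""

    contig_path: str
    metadata_path: str
    output_dir: str
    dialect: str = "airr_tsv"
    expression_path: str | None = None
    germline_path: str | None = None
    gating_threshold: int = 1
    v_level: str = "subgroup"
    j_level: str = "gene"
    hd_cutoff: int = 1
    dominance_min_frac: float = 0.25
    dominance_min_fold: float = 3.0
    overlap_metric: str = "jaccard"
    top_clusters_detail: int = 5

    def validate(self) -> None:
        for label, path in (
            ("contig table", self.contig_path),
            ("cell metadata", self.metadata_path),
            ("expression extract", self.expression_path),
            ("germline reference", self.germline_path),
        ):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label} not found: {path}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class ReportBundle:
    """All stage outputs of one pipeline run."""

    profiles: pd.DataFrame
    pattern_matrix: pd.DataFrame
    detection: pd.DataFrame
    detection_median: float
    single_pair: pd.DataFrame
    lengths: dict  # chain -> length-distribution frame
    usage_tables: dict  # (chain, segment) -> usage frame
    dominance: pd.DataFrame
    gate_composition: pd.DataFrame | None
    lineage_groups: pd.Series | None
    clusters: dict  # chain -> list[ClonotypeCluster]
    summaries: dict  # chain -> summary dict
    overlap: dict  # chain -> overlap matrix
    motifs: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapper

    return deco


def analyse(
    contigs: list[ContigRecord],
    annotations: list[CellAnnotation],
    expression: pd.DataFrame | None = None,
    germline: GermlineDB | None = None,
    *,
    gating_threshold: int = 1,
    v_level: str = "subgroup",
    j_level: str = "gene",
    hd_cutoff: int = 1,
    dominance_min_frac: float = 0.25,
    dominance_min_fold: float = 3.0,
    overlap_metric: str = "jaccard",
) -> ReportBundle:
    """Run every analysis stage on in-memory inputs."""
    prof = _stage("profiles")(profiles.build_cell_profiles)(contigs, annotations)
    pattern_matrix = _stage("patterns")(profiles.pattern_percent_matrix)(prof)
    detection, det_median, _ = _stage("detection")(profiles.detection_rate)(prof)
    pairs = _stage("single_pair")(usage.single_pair_cells)(contigs, prof)

    lengths = {}
    usage_tables = {}
    for chain in ("TRA", "TRB"):
        lengths[chain] = _stage("lengths")(usage.junction_length_distribution)(pairs, chain)
        for segment in ("V", "J"):
            usage_tables[(chain, segment)] = _stage("usage")(usage.gene_usage)(
                pairs, chain, segment
            )
    flag_frames = [
        _stage("dominance")(usage.dominance_flags)(
            tbl, dominance_min_frac, dominance_min_fold
        )
        for tbl in usage_tables.values()
    ]
    flag_frames = [f for f in flag_frames if not f.empty]
    dominance = (
        pd.concat(flag_frames, ignore_index=True)
        if flag_frames
        else pd.DataFrame(columns=["gene", "subset_label", "fraction", "median_fraction"])
    )

    gate_comp = lineage = None
    if expression is not None:
        gates = _stage("gating")(gating.gate_cells)(expression, gating_threshold)
        gate_comp = _stage("gating")(gating.cluster_composition)(gates, annotations)
        lineage = _stage("gating")(gating.classify_clusters)(gate_comp)

    clusters = {}
    summaries = {}
    overlap = {}
    n_subjects = len({a.subject_id for a in annotations})
    for chain in ("TRA", "TRB"):
        entries = _stage("clustering")(clustering.collapse_clonotypes)(pairs, chain)
        chain_clusters = _stage("clustering")(clustering.stratified_clusters)(
            entries, "single", hd_cutoff, v_level, j_level
        )
        for c in chain_clusters:
            clustering.cluster_metrics(c)
        clusters[chain] = chain_clusters
        summaries[chain] = _stage("summary")(clustering.cluster_summary)(
            chain_clusters, n_subjects
        )
        overlap[chain] = _stage("overlap")(clustering.repertoire_overlap)(
            entries, overlap_metric
        )

    motifs = []
    if germline is not None:
        motifs = _stage("motifs")(_invariant_motifs)(clusters, germline)

    return ReportBundle(
        profiles=prof, pattern_matrix=pattern_matrix, detection=detection,
        detection_median=det_median, single_pair=pairs, lengths=lengths,
        usage_tables=usage_tables, dominance=dominance,
        gate_composition=gate_comp, lineage_groups=lineage,
        clusters=clusters, summaries=summaries, overlap=overlap, motifs=motifs,
    )


def _invariant_motifs(clusters: dict, germline: GermlineDB, top_n: int = 3) -> list[dict]:
    """PWMs and germline attribution for the largest clusters of each chain.

    For each of the ``top_n`` clusters by clonotype count, the junction PWM
    is computed over member clonotypes, complete-linkage sub-clusters are
    ranked, and the consensus junction of the largest member clonotype is
    attributed to germline V / additions / germline J.
    """
    out = []
    for chain, chain_clusters in clusters.items():
        ranked = sorted(chain_clusters, key=lambda c: (-c.n_clonotypes, c.cluster_id))
        for cluster in ranked[:top_n]:
            if cluster.n_clonotypes < 2:
                continue
            pwm = usage.position_weight_matrix(
                [e.junction_aa for e in cluster.members]
            )
            # attribute the modal (consensus-filled) junction of the cluster
            modal = "".join(pwm.matrix.iloc[pos].idxmax() for pos in range(pwm.length))
            top_entry = max(cluster.members, key=lambda e: (e.n_cells, e.junction_aa))
            attribution = usage.germline_attribution(
                modal, top_entry.v_gene, top_entry.j_gene, germline
            )
            subclusters = clustering.subcluster_complete_linkage(cluster)
            out.append(
                {
                    "chain": chain,
                    "cluster_id": cluster.cluster_id,
                    "stratum": cluster.stratum,
                    "pwm": pwm,
                    "variable_positions": pwm.variable_positions,
                    "consensus": pwm.consensus,
                    "attribution": attribution,
                    "n_subclusters": len(subclusters),
                    "top_subcluster_variable_positions": [
                        s["variable_positions"] for s in subclusters[:8]
                    ],
                }
            )
    return out


def write_bundle(bundle: ReportBundle, output_dir: str | Path, params: dict) -> dict:
    """Write all bundle tables as TSV under ``output_dir``; returns path->sha256."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        write_table(df, path, params=params, index=index)
        written[name] = _sha256(path)

    emit(bundle.profiles, "cell_profiles.tsv")
    emit(bundle.pattern_matrix, "pattern_percent_matrix.tsv", index=True)
    emit(bundle.detection, "detection_rate.tsv")
    for chain, df in bundle.lengths.items():
        emit(df, f"junction_lengths_{chain}.tsv")
    for (chain, segment), df in bundle.usage_tables.items():
        emit(df, f"usage_{chain}{segment}.tsv", index=True)
    emit(bundle.dominance, "dominance_flags.tsv")
    if bundle.gate_composition is not None:
        comp = bundle.gate_composition.copy()
        comp["lineage_group"] = bundle.lineage_groups
        emit(comp, "gate_composition.tsv", index=True)
    for chain, chain_clusters in bundle.clusters.items():
        emit(clustering.clusters_to_frame(chain_clusters), f"clusters_{chain}.tsv")
        top = sorted(chain_clusters, key=lambda c: (-c.n_clonotypes, c.cluster_id))[:3]
        edges = [
            clustering.network_edge_table(c, clustering.build_network(c)) for c in top
        ]
        if edges:
            emit(pd.concat(edges, ignore_index=True), f"network_edges_{chain}.tsv")
        emit(bundle.overlap[chain], f"overlap_{chain}.tsv", index=True)
    for motif in bundle.motifs:
        name = f"pwm_{motif['chain']}_cluster{motif['cluster_id']}.tsv"
        emit(motif["pwm"].matrix, name, index=True)
    return written


def run_pipeline(config: RunConfig) -> ReportBundle:
    """File-to-file pipeline run with a reproducibility manifest."""
    config.validate()
    contigs = read_contig_table(config.contig_path, config.dialect)
    annotations = read_cell_metadata(config.metadata_path)
    expression = (
        read_expression_extract(config.expression_path)
        if config.expression_path
        else None
    )
    germline = (
        read_germline_reference(config.germline_path) if config.germline_path else None
    )
    bundle = analyse(
        contigs, annotations, expression, germline,
        gating_threshold=config.gating_threshold,
        v_level=config.v_level, j_level=config.j_level,
        hd_cutoff=config.hd_cutoff,
        dominance_min_frac=config.dominance_min_frac,
        dominance_min_fold=config.dominance_min_fold,
        overlap_metric=config.overlap_metric,
    )
    params = {
        k: v for k, v in vars(config).items() if k not in ("output_dir",)
    }
    written = write_bundle(bundle, config.output_dir, params)
    manifest = {
        "tcrclust_version": __version__,
        "python": platform.python_version(),
        "parameters": params,
        "input_checksums": {
            name: _sha256(path)
            for name, path in (
                ("contigs", config.contig_path),
                ("metadata", config.metadata_path),
                ("expression", config.expression_path),
                ("germline", config.germline_path),
            )
            if path
        },
        "output_checksums": written,
    }
    bundle.manifest = manifest
    (Path(config.output_dir) / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return bundle
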