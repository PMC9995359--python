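# Methods

This note documents the models, conventions and numerical choices behind
`tcrclust`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Conventions

* **Junction.** The anchored IMGT junction: the conserved cysteine and
  phenylalanine are included in `junction_aa` and in all reported lengths.
  Reported lengths of 12–16 aa therefore include both anchors.
* **Gene names.** The allele suffix (`*01`) is always stripped; the
  gene-member suffix (`-11`) is kept. `subgroup()` additionally strips the
  member suffix (`TRAV9-11` → `TRAV9`) and is the default V-stratification
  level for clustering (J genes are stratified at gene level). Both levels
  are configurable.
* **Cell identity.** Cells are keyed by `(subject_id, barcode)` so merged
  multi-subject cohorts cannot collide on barcode alone.
* **Input dialects.** Both the 10x `filtered_contig_annotations.csv`
  layout and the AIRR Rearrangement TSV are accepted; which export feeds a
  given analysis is an explicit parameter, and the two are treated as
  equivalent views of the same records (verified by round-trip tests).

## Rearrangement profiling

A rearrangement is a distinct productive `(chain, V, J, junction_aa)`
tuple within a cell; duplicate contig rows supporting the same
rearrangement collapse to one. Cells with three or more rearrangements per
chain keep their true count (patterns such as `3-1` are reported, not
bucketed). The denominator for pattern percentages and detection rates is
the full annotated (QC-passing) cell set, so chain-negative cells appear
as `0-0` rather than silently vanishing.

## Virtual gating

Positivity is detection above zero by default (count ≥ 1 on raw counts;
the threshold and a normalised matrix are both supported, raw is the
default since marker drop-out — not expression level — is the dominant
signal at single-cell depth). Composition fractions are computed over
non-double-negative cells only. The CD4-dominant rule (≥ 66% CD4-sp and
< 25% CD8A-sp) is mirrored symmetrically for CD8A-dominant classification;
the CD4 bound is inclusive and the opposing bound strict, and the rule is
symmetric under swapping the two markers (property-tested).

## Usage, motifs, germline attribution

All §-level statistics (lengths, usage, pairing, PWMs, attribution) are
restricted to cells with exactly one productive rearrangement per chain,
so every cell contributes exactly once per chain and dual-TCR cells cannot
double-count. Pairing-matrix marginals reproduce the usage tables exactly
(tested as an identity).

Dominance flagging operationalises "outlier usage": a gene is flagged in a
subset when its within-subset fraction is ≥ `min_frac` (default 0.25) and
≥ `min_fold` (default 3) times the cross-subset median for that gene.

Germline attribution works at the amino-acid level against a
junction-region reference: the V region starts at the conserved C, the J
region ends at the conserved F. `n_v` is the longest junction prefix
matching the V-region prefix; `n_j` the longest junction suffix matching
the J-region suffix (right-anchored, since exonucleolytic trimming removes
the 5' end of the J segment); overlaps are resolved by truncating the J
match, i.e. ties maximise `n_v` first (configurable in principle; the
greedy rule is provably equivalent to exhaustive split enumeration with
that tie-break, and is tested against an enumeration oracle).
Nucleotide-level N/P-region inference is out of scope.

## Clonotype superclustering

* Strata are `(V subgroup, J gene, junction length)`. Hamming distance is
  undefined across lengths and treated as infinite, so unequal-length
  junctions never co-cluster; within a stratum, identical junctions on
  different member genes of the same V subgroup sit at HD 0 and always
  co-cluster.
* Single linkage at cutoff 1 is computed as connected components of the
  1-HD graph (networkx); complete linkage via
  `scipy.cluster.hierarchy.linkage(..., "complete")` cut at the cutoff.
  Both are validated against brute-force all-pairs oracles in the test
  suite.
* Cluster numbering is deterministic: strata sorted lexicographically,
  clusters within a stratum by descending clonotype count, ties by the
  lexicographically smallest junction. Numbers are an artifact convention
  and carry no meaning beyond identity.
* Metrics: density = observed 1-HD edges over `n(n-1)/2` (0 for
  singletons); node centrality is degree, ranked descending with
  competition ranking; the cluster-level centrality reduction is reported
  as max degree with mean degree alongside (the field uses several
  conventions; max degree is the hub-oriented one). Publicity is the
  number of distinct subjects over member cells. Complete-linkage
  sub-clusters are ranked by clonotype count (ties lexicographic) and each
  carries a PWM; only pairwise HD ≤ 1 is guaranteed within a sub-cluster,
  not a shared variable position set.
* Repertoire overlap defaults to the Jaccard index on clonotype identity
  sets per subset; Morisita–Horn on cell counts is available where
  abundance weighting is wanted.

## The synthetic cohort

The generator emulates the statistical structure of a four-subject
peripheral-blood TCRαβ cohort with 22 transcriptome subsets. Key defaults
(all configurable via `SimulationConfig` / YAML):

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 4 | cohort size |
| `cells_per_subject` | 7,500 | ~30,000 cells total |
| `dropout_tra` / `dropout_trb` | 0.24 / 0.115 | per-cell chain detection failure |
| baseline dual rates | 0.045 TRA / 0.022 TRB | second productive rearrangement |
| iNKT-like dual-TRA | 0.266 | elevated dual receptor rate |
| MAIT invariant pair rate | 0.821 | fraction of subset cells on TRAV9-11/TRAJ28 |
| `n_invariant_clonotypes` | 160 | distinct invariant junctions shared by all subjects |
| `public_rate` / `public_pool_size` | 0.05 / 25 | background clonotype sharing |
| `clone_geom_p` | 0.75 | clone sizes ~ geometric(p) |
| junction length models | TRA median 14 aa, TRB 15 aa | MAIT fixed 16, iNKT mode 13 |

These values were chosen once so that the closed-form pattern expectations
(`expected_pattern_probs`) give a `1-1` majority near 62%, TRB-only near
21% and TRA-only near 9%, and the invariant populations match the
magnitudes above. Junctions are assembled as germline-V prefix +
untemplated insert + germline-J suffix from a bundled **synthetic**
germline junction-region set (the gene names follow TR nomenclature, but
the sequences are invented, not curated references), so every
rearrangement carries exact germline-attribution truth. The invariant
junction is `CAL` + [S/T, 70:30] + two residues from a 12-letter alphabet
+ `YSGVGSQLTF`.

**Deliberate simplifications.** Background junctions are rejection-sampled
to be pairwise HD ≥ 2 within each stratum, so clonal-network structure in
the output is attributable to the designed invariant population; real
repertoires also contain chance near-neighbour pairs and
germline-convergent clusters, which this generator does not emulate (its
cluster counts are therefore close to its clonotype counts, unlike real
data). Chain drop-out removes a whole chain at once (no per-rearrangement
loss), detection rates do not vary across subsets, there is no sequencing
error model, no transcriptome simulation beyond the two gating markers,
and public sharing applies whole rearrangements within a lineage group.
Passing recovery tests therefore demonstrates correctness of the
measurement pipeline under this model, not robustness to every property of
real data.

Random streams are split per (subject, subset) from the master seed, so
resizing one subset leaves the others' draws unchanged.

## Test calibration and problem sizes

Parameter-recovery tests run at 10,000 cells and compare observed
statistics against configured values using binomial intervals with 95%
*family-wise* coverage (Šidák-adjusted across the nine interval checks);
where cells are correlated through clones, the variance is inflated by the
design effect `E[S²]/E[S]` of the geometric clone-size distribution.
Clustering correctness is checked on 100 random strata of up to 500
clonotypes against brute-force oracles; germline attribution on 1,000
constructed junctions against split enumeration. The acceptance script
uses the full ~30,000-cell default cohort. These sizes keep the whole
suite fast on a single CPU while leaving every estimate's sampling error
well inside the tested tolerances.

## Known limitations

* TRA↔TRB paired-receptor (whole-cell) clonotype clustering is not
  implemented; chains are clustered independently.
* Doublet deconvolution is out of scope: dual-pattern cells are reported,
  not resolved.
* Germline junction-region boundaries are taken from the input FASTA as
  given; the package does not curate references.
* Supercluster density compares clusters of very different sizes on one
  scale; small complete clusters trivially reach density 1, so density is
  best read together with clonotype count.
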