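# tcrclust

Single-cell TCRαβ repertoire analysis for multi-subject cohorts: per-cell
TRA/TRB rearrangement profiling, virtual CD4/CD8A gating, V/J usage and
pairing statistics, CDR3 motif and germline-attribution analysis, and
V/J-stratified Hamming-distance clonotype superclustering with clonal
network metrics. A bundled synthetic repertoire generator with full ground
truth makes every stage testable end to end without any data download.

## Who this is for

Immunologists and computational biologists analysing paired-chain
single-cell V(D)J data (10x `filtered_contig_annotations.csv` or AIRR
Rearrangement TSV) together with a transcriptome clustering of the same
cells. Typical questions: which transcriptome subsets carry invariant
(MAIT-like / iNKT-like) receptors, how V/J usage and junction lengths vary
across subsets, which clonotypes are public across subjects, and how
repertoires overlap between subsets.

## The method

**Rearrangement patterns.** Each cell is summarised as a pattern `x-y`,
the number of *distinct productive* TRA and TRB rearrangements detected
(a rearrangement is a distinct chain/V/J/junction tuple, so duplicate
contigs collapse). Annotated cells without contigs count as `0-0`, making
detection rates interpretable over the full QC-passing cell universe.

**Virtual gating.** Cells are gated on CD4/CD8A detection (dp, CD4-sp,
CD8A-sp, dn at a UMI threshold, default 1). After excluding dn cells, a
subset is *CD4-dominant* when ≥ 66% of cells are CD4-sp and < 25% are
CD8A-sp; the mirrored rule defines *CD8A-dominant*; the rest are *mixed*.

**Usage and motifs.** On cells with exactly one productive rearrangement
per chain (`1-1`), the package computes junction-length distributions
(anchored IMGT junction, conserved C and F included), V/J usage and V×J
pairing tables, and flags outlier gene usage (fraction ≥ 0.25 and ≥ 3× the
cross-subset median). Equal-length junction sets yield position weight
matrices (PWMs); each junction can be split into germline-V prefix,
untemplated additions, and germline-J suffix against a junction-region
reference (n_v + n_added + n_j = L).

**Clonotype superclustering.** Clonotypes (chain, V, J, junction) are
stratified by V-gene subgroup, J gene and junction length, then clustered
at a Hamming-distance cutoff of 1: single linkage (connected components of
the 1-HD graph) defines superclusters; complete linkage (pairwise HD ≤ 1)
dissects them into tight sub-clusters. Per cluster the package reports
cells, clonotypes, network density `edges / (n(n-1)/2)`, degree centrality
ranks, publicity (distinct subjects), and subset composition, plus
pairwise subset repertoire overlap (Jaccard, or Morisita–Horn on
abundances).

**Synthetic cohort.** `tcrclust.simulate.default_study_config()` describes
a 4-subject, 22-subset cohort: a diverse conventional background (TRA/TRB
junction medians 14/15 aa), a MAIT-like subset whose cells carry a
semi-invariant TRAV9-11/TRAJ28 16-aa junction `CAL???YSGVGSQLTF` variable
only at positions 4–6 and shared by all subjects, an iNKT-like subset
(13-aa junctions, two dominant V genes, 26.6% dual-TRA rate), a
dual-TRB-prone subset, chain drop-out, clonal expansion, public
clonotypes, and CD4/CD8A counts for gating.

## Worked example

```sh
python analysis/01_simulate_cohort.py --cells-per-subject 2500   # 10,000 cells
python analysis/02_virtual_gating.py
python analysis/03_rearrangement_patterns.py
python analysis/04_usage_and_motifs.py
python analysis/05_clonotype_clustering.py
```

Output (seed 1, abridged):

```
gated 10000 cells at threshold 1
CD4_dominant     11
CD8A_dominant     8
mixed             3

global rearrangement patterns (% of cells):
1-1    61.8
0-1    20.1
1-0     8.2

TRA: global median junction length 14 aa; skewed subsets: {'C13': 16, 'C19': 13}
dominance outliers (TRAJ):
TRAJ28          C13     0.796            0.048
C13: top TRA pair TRAV9-11/TRAJ28 in 78.2% of cells
invariant motif: CAL???YSGVGSQLTF (n=223), variable positions [4, 5, 6]
germline attribution of modal junction: 4 V-encoded, 2 added, 10 J-encoded

TRA: 4808 clonotypes in 4714 clusters; ...
  top cluster #4327 ('TRAV9', 'TRAJ28', 16): 95 clonotypes, 223 cells,
  density 0.085, max degree 16, publicity 4
```

Reading this: the 22 simulated subsets classify into 11 CD4-dominant, 8
CD8A-dominant and 3 mixed groups; 61.8% of cells carry exactly one
productive TRA and TRB; the MAIT-like subset C13 is dominated by a single
TRAV9-11→TRAJ28 rearrangement whose 16-aa junction varies only at
positions 4–6, with 4 positions encoded by the V gene, 2 untemplated and
10 by the J gene; and those clonotypes form the largest, densest TRA
supercluster, shared by all 4 subjects (publicity 4). All result tables
are written as TSV under `results/`.

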