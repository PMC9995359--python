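"""Synthetic paired-chain single-cell TCR repertoire generator with ground truth.

The generator emulates the statistical structure of a four-subject
peripheral-blood TCRab cohort: ~20 transcriptome subsets spanning
CD4-dominant, CD8A-dominant and mixed lineages; a diverse conventional
background repertoire with TRA/TRB junction lengths centred at 14/15 aa;
a MAIT-like subset with a semi-invariant TRA (one dominant V/J pair, fixed
16-aa junction variable only at positions 4-6, shared across subjects); an
iNKT-like subset with 13-aa-dominant junctions, two dominant V genes and an
elevated dual-TRA rate; one subset with frequent dual TRB; chain-level
detection drop-out; clonal expansion; and CD4/CD8A marker counts for
virtual gating.

Junctions are assembled as germline-V prefix + untemplated insert +
germline-J suffix from a bundled *synthetic* germline set, so germline
attribution has known truth.  Background junctions are rejection-sampled to
be pairwise Hamming distance >= 2 within each (V subgroup, J, length)
stratum: clonal network structure in the output is therefore attributable
to the designed invariant populations rather than to chance near-neighbour
collisions (a deliberate simplification relative to real repertoires).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import CellAnnotation, ContigRecord, GermlineDB, subgroup

# ---------------------------------------------------------------------------
# Bundled synthetic germline junction regions (not curated canine genes).
# V regions start at the conserved cysteine; J regions end at the conserved
# phenylalanine.  TRAV9-11 / TRAJ28 carry the invariant-motif regions.

GERMLINE_SEQS: dict[str, str] = {
    # TRA V
    "TRAV1": "CAVR", "TRAV2": "CAVS", "TRAV3": "CAMT", "TRAV4": "CAGD",
    "TRAV5": "CAES", "TRAV6": "CALN", "TRAV8-1": "CAVE", "TRAV9-6": "CALG",
    "TRAV9-11": "CALS", "TRAV12": "CAMR", "TRAV13": "CAAH", "TRAV16": "CATD",
    "TRAV17": "CAGQ", "TRAV22": "CAYE", "TRAV24": "CAFM", "TRAV26": "CIVN",
    "TRAV38": "CAWK", "TRAV41": "CAVQ", "TRAV43-1": "CAYG", "TRAV43-4": "CAYR",
    # TRA J
    "TRAJ4": "GNKLVF", "TRAJ9": "TGGFKTIF", "TRAJ12": "DSSYKLIF",
    "TRAJ16": "SGGYNKLIF", "TRAJ20": "SNDYKLSF", "TRAJ22": "GSARQLTF",
    "TRAJ23": "NQGGKLIF", "TRAJ28": "YSGVGSQLTF", "TRAJ30": "NRDDKIIF",
    "TRAJ33": "DSNYQLIF", "TRAJ37": "GNTGKLIF", "TRAJ40": "TTSGTYKYIF",
    "TRAJ45": "SGGGADGLTF", "TRAJ49": "NTGNQFYF", "TRAJ52": "NAGGTSYGKLTF",
    # TRB V
    "TRBV2": "CASSE", "TRBV3": "CASSQ", "TRBV5": "CASSL", "TRBV6": "CASSY",
    "TRBV7": "CASSF", "TRBV9": "CASSV", "TRBV12": "CASSD", "TRBV15": "CATSR",
    "TRBV16": "CASSP", "TRBV18": "CASSG", "TRBV20": "CSARD", "TRBV25": "CASSM",
    "TRBV26": "CASSI", "TRBV28": "CASSK", "TRBV30": "CAWSA",
    # TRB J
    "TRBJ1-1": "NTEAFF", "TRBJ1-2": "NYGYTF", "TRBJ1-3": "SGNTIYF",
    "TRBJ1-4": "TNEKLFF", "TRBJ1-5": "SNQPQHF", "TRBJ1-6": "SYNSPLHF",
    "TRBJ2-1": "SYNEQFF", "TRBJ2-2": "NTGELFF", "TRBJ2-3": "STDTQYF",
    "TRBJ2-4": "AKNIQYF", "TRBJ2-5": "QETQYF", "TRBJ2-6": "SGANVLTF",
    "TRBJ2-7": "SYEQYF",
}

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "AGT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

INSERT_ALPHABET = list("ADEGHIKLMNPQRSTVWY")  # untemplated additions

# invariant MAIT-like receptor
MAIT_V = "TRAV9-11"
MAIT_J = "TRAJ28"
MAIT_PREFIX = "CAL"  # positions 1-3
MAIT_POS4 = ["S", "T"]
MAIT_POS4_P = [0.7, 0.3]
MAIT_VAR_ALPHABET = list("ADEGHIKLNQRS")  # positions 5-6
MAIT_SUFFIX = "YSGVGSQLTF"  # positions 7-16 (germline TRAJ28)

INKT_V_BOOST = {"TRAV43-1": 0.40, "TRAV24": 0.30}

_TRA_V_DEFAULT = {"TRAV43-1": 0.144, "TRAV9-6": 0.089, "TRAV43-4": 0.083, "TRAV9-11": 0.022}
_TRA_J_DEFAULT = {"TRAJ33": 0.055, "TRAJ52": 0.050, "TRAJ28": 0.045}
_TRB_V_DEFAULT = {"TRBV16": 0.149, "TRBV7": 0.119, "TRBV18": 0.102}
_TRB_J_DEFAULT = {"TRBJ2-1": 0.148, "TRBJ2-6": 0.120, "TRBJ1-2": 0.111}


def _fill_usage(named: dict[str, float], genes: list[str]) -> dict[str, float]:
    """Spread the unassigned mass uniformly over the unnamed genes."""
    rest = [g for g in genes if g not in named]
    remaining = 1.0 - sum(named.values())
    out = dict(named)
    for g in rest:
        out[g] = remaining / len(rest)
    return {g: out[g] for g in genes}


def gene_lists() -> dict[str, list[str]]:
    tra_v = [g for g in GERMLINE_SEQS if g.startswith("TRAV")]
    tra_j = [g for g in GERMLINE_SEQS if g.startswith("TRAJ")]
    trb_v = [g for g in GERMLINE_SEQS if g.startswith("TRBV")]
    trb_j = [g for g in GERMLINE_SEQS if g.startswith("TRBJ")]
    return {"TRA_V": tra_v, "TRA_J": tra_j, "TRB_V": trb_v, "TRB_J": trb_j}


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SubsetSpec:
    """One transcriptome subset of the simulated cohort."""

    label: str
    role: str = "conventional"  # conventional | MAIT_like | iNKT_like
    weight: float = 0.05  # fraction of each subject's cells
    lineage_mix: dict = field(
        default_factory=lambda: {"cd4": 0.97, "cd8a": 0.02, "dp": 0.01}
    )
    marker_detect_p: float = 0.85
    dual_tra_rate: float = 0.045
    dual_trb_rate: float = 0.022
    invariant_pair_rate: float = 0.0  # MAIT_like: fraction of cells on the invariant TRA
    tra_length_probs: dict = field(
        default_factory=lambda: {12: 0.08, 13: 0.20, 14: 0.38, 15: 0.22, 16: 0.12}
    )
    trb_length_probs: dict = field(
        default_factory=lambda: {13: 0.08, 14: 0.22, 15: 0.38, 16: 0.20, 17: 0.12}
    )
    tra_v_probs: dict | None = None  # None -> global defaults
    tra_j_probs: dict | None = None
    trb_v_probs: dict | None = None
    trb_j_probs: dict | None = None
    clone_geom_p: float = 0.75  # clone size ~ geometric(p)


@dataclass
class SimulationConfig:
    """Cohort-level generator parameters."""

    n_subjects: int = 4
    cells_per_subject: int = 7500
    dropout_tra: float = 0.24
    dropout_trb: float = 0.115
    public_rate: float = 0.05  # background rearrangements drawn from a shared pool
    public_pool_size: int = 25
    nonproductive_rate: float = 0.05
    n_invariant_clonotypes: int = 160
    subsets: list[SubsetSpec] = field(default_factory=list)

    def validate(self) -> None:
        if not self.subsets:
            raise ValueError("config needs at least one subset")
        for p in (self.dropout_tra, self.dropout_trb, self.public_rate,
                  self.nonproductive_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        total = sum(s.weight for s in self.subsets)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"subset weights sum to {total}, expected 1")
        genes = gene_lists()
        for s in self.subsets:
            for p in (s.dual_tra_rate, s.dual_trb_rate, s.invariant_pair_rate,
                      s.marker_detect_p):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{s.label}: probability {p} outside [0, 1]")
            if abs(sum(s.lineage_mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"{s.label}: lineage_mix must sum to 1")
            for name, dist in (
                ("tra_length_probs", s.tra_length_probs),
                ("trb_length_probs", s.trb_length_probs),
            ):
                if abs(sum(dist.values()) - 1.0) > 1e-6:
                    raise ValueError(f"{s.label}: {name} must sum to 1")
            for name, dist, pool in (
                ("tra_v_probs", s.tra_v_probs, genes["TRA_V"]),
                ("tra_j_probs", s.tra_j_probs, genes["TRA_J"]),
                ("trb_v_probs", s.trb_v_probs, genes["TRB_V"]),
                ("trb_j_probs", s.trb_j_probs, genes["TRB_J"]),
            ):
                if dist is None:
                    continue
                if abs(sum(dist.values()) - 1.0) > 1e-6:
                    raise ValueError(f"{s.label}: {name} must sum to 1")
                unknown = set(dist) - set(pool)
                if unknown:
                    raise ValueError(f"{s.label}: unknown genes {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["subsets"] = [SubsetSpec(**s) for s in data.get("subsets", [])]
        return cls(**data)


def _biased(base: dict[str, float], boost: dict[str, float]) -> dict[str, float]:
    """Give ``boost`` genes their stated mass, scale the rest proportionally."""
    rest_mass = 1.0 - sum(boost.values())
    rest = {g: p for g, p in base.items() if g not in boost}
    scale = rest_mass / sum(rest.values())
    out = {g: p * scale for g, p in rest.items()}
    out.update(boost)
    return {g: out[g] for g in base}


def default_study_config(cells_per_subject: int = 7500) -> SimulationConfig:
    """The study-scale default: 4 subjects, 22 subsets, invariant populations.

    Weights and rates reproduce the cohort-level magnitudes the generator is
    meant to emulate: a ~62% "1-1" pattern majority, ~21% TRB-only and ~9%
    TRA-only cells, a MAIT-like subset (C13) with an 82% invariant
    TRAV9-11/TRAJ28 16-aa junction, an iNKT-like subset (C19) with 13-aa
    junctions, two dominant V genes and a 26.6% dual-TRA rate, and a
    dual-TRB-prone subset (C15).
    """
    genes = gene_lists()
    cd4 = {"cd4": 0.965, "cd8a": 0.025, "dp": 0.01}
    cd8 = {"cd4": 0.02, "cd8a": 0.97, "dp": 0.01}
    mixed = {"cd4": 0.60, "cd8a": 0.38, "dp": 0.02}
    tra_v = _fill_usage(_TRA_V_DEFAULT, genes["TRA_V"])

    weights = {
        # CD4-dominant
        "C0": 0.115, "C1": 0.095, "C2": 0.085, "C3": 0.075, "C4": 0.065,
        "C5": 0.055, "C6": 0.050, "C8": 0.045, "C9": 0.040, "C10": 0.035,
        "C15": 0.030,
        # CD8A-dominant
        "C7": 0.055, "C12": 0.045, "C13": 0.043, "C14": 0.030, "C16": 0.025,
        "C17": 0.025, "C18": 0.022, "C19": 0.020,
        # mixed
        "C11": 0.020, "C20": 0.015, "C21": 0.010,
    }
    cd8_labels = {"C7", "C12", "C13", "C14", "C16", "C17", "C18", "C19"}
    mixed_labels = {"C11", "C20", "C21"}

    subsets = []
    for label in sorted(weights, key=lambda l: int(l[1:])):
        mix = cd8 if label in cd8_labels else (mixed if label in mixed_labels else cd4)
        spec = SubsetSpec(label=label, weight=weights[label], lineage_mix=dict(mix))
        if label == "C13":
            spec.role = "MAIT_like"
            spec.invariant_pair_rate = 0.821
            spec.trb_v_probs = _biased(
                _fill_usage(_TRB_V_DEFAULT, genes["TRB_V"]),
                {"TRBV28": 0.307, "TRBV25": 0.302},
            )
        elif label == "C19":
            spec.role = "iNKT_like"
            spec.dual_tra_rate = 0.266
            spec.tra_length_probs = {12: 0.15, 13: 0.60, 14: 0.25}
            spec.tra_v_probs = _biased(tra_v, INKT_V_BOOST)
            spec.trb_v_probs = _biased(
                _fill_usage(_TRB_V_DEFAULT, genes["TRB_V"]), {"TRBV26": 0.279}
            )
            spec.clone_geom_p = 0.55
        elif label == "C15":  # dual-TCR-prone subset
            spec.dual_tra_rate = 0.31
            spec.dual_trb_rate = 0.45
        elif label == "C17":
            spec.tra_v_probs = _biased(tra_v, {"TRAV9-11": 0.282})
        elif label == "C18":
            spec.tra_v_probs = _biased(tra_v, {"TRAV9-11": 0.354})
        subsets.append(spec)
    return SimulationConfig(cells_per_subject=cells_per_subject, subsets=subsets)


def expected_pattern_probs(config: SimulationConfig, subset: str | None = None) -> dict[str, float]:
    """Closed-form pattern probabilities implied by the configuration.

    Chain drop-out removes all rearrangements of a chain at once, so with
    TRA drop-out a, TRB drop-out b and dual rates dA, dB the pattern
    probabilities factorise; ``subset=None`` returns the weight-averaged
    cohort expectation.  Coincidental collapse of a dual rearrangement onto
    its sibling is ignored (negligible).
    """
    a, b = config.dropout_tra, config.dropout_trb

    def one(spec: SubsetSpec) -> dict[str, float]:
        dA, dB = spec.dual_tra_rate, spec.dual_trb_rate
        p_tra = {0: a, 1: (1 - a) * (1 - dA), 2: (1 - a) * dA}
        p_trb = {0: b, 1: (1 - b) * (1 - dB), 2: (1 - b) * dB}
        return {
            f"{x}-{y}": p_tra[x] * p_trb[y] for x in (0, 1, 2) for y in (0, 1, 2)
        }

    if subset is not None:
        spec = next(s for s in config.subsets if s.label == subset)
        return one(spec)
    acc: dict[str, float] = {}
    for spec in config.subsets:
        for pat, p in one(spec).items():
            acc[pat] = acc.get(pat, 0.0) + spec.weight * p
    return acc


# ---------------------------------------------------------------------------
# Generation


def _pool_group(spec: SubsetSpec) -> str:
    """Lineage group sharing one public-clonotype pool."""
    mix = spec.lineage_mix
    if mix.get("cd4", 0) >= 0.66:
        return "CD4"
    if mix.get("cd8a", 0) >= 0.66:
        return "CD8A"
    return "mixed"


class _StratumRegistry:
    """Tracks junctions per (V subgroup, J, length) stratum.

    Background junctions are admitted only at Hamming distance >= 2 from
    every junction already in their stratum; invariant-pool junctions are
    registered unconditionally (their mutual 1-HD relatedness is designed).
    """

    def __init__(self):
        self._strata: dict[tuple, list[np.ndarray]] = {}

    @staticmethod
    def _key(v: str, j: str, junction: str) -> tuple:
        return (subgroup(v), j, len(junction))

    def admissible(self, v: str, j: str, junction: str) -> bool:
        arrs = self._strata.get(self._key(v, j, junction))
        if not arrs:
            return True
        q = np.frombuffer(junction.encode(), dtype=np.uint8)
        mat = np.stack(arrs)
        return int((mat != q).sum(axis=1).min()) >= 2

    def add(self, v: str, j: str, junction: str) -> None:
        key = self._key(v, j, junction)
        self._strata.setdefault(key, []).append(
            np.frombuffer(junction.encode(), dtype=np.uint8)
        )


@dataclass
class Rearrangement:
    chain: str
    v_gene: str
    j_gene: str
    junction_aa: str
    n_v: int  # germline-attribution truth
    n_added: int
    n_j: int

    @property
    def key(self) -> tuple:
        return (self.chain, self.v_gene, self.j_gene, self.junction_aa)


def _nt(junction_aa: str) -> str:
    return "".join(_CODON[aa] for aa in junction_aa)


class _BackgroundSampler:
    """Draws background rearrangements honouring per-subset usage and length."""

    MIN_INSERT = 3
    MIN_J = 3

    def __init__(self, germ: GermlineDB, registry: _StratumRegistry):
        self.germ = germ
        self.registry = registry
        self.genes = gene_lists()
        g = self.genes
        self.defaults = {
            "TRA": (
                _fill_usage(_TRA_V_DEFAULT, g["TRA_V"]),
                _fill_usage(_TRA_J_DEFAULT, g["TRA_J"]),
            ),
            "TRB": (
                _fill_usage(_TRB_V_DEFAULT, g["TRB_V"]),
                _fill_usage(_TRB_J_DEFAULT, g["TRB_J"]),
            ),
        }

    def sample(
        self,
        rng: np.random.Generator,
        chain: str,
        spec: SubsetSpec,
        register: bool = True,
        max_tries: int = 200,
    ) -> Rearrangement:
        if chain == "TRA":
            vp = spec.tra_v_probs or self.defaults["TRA"][0]
            jp = spec.tra_j_probs or self.defaults["TRA"][1]
            lp = spec.tra_length_probs
        else:
            vp = spec.trb_v_probs or self.defaults["TRB"][0]
            jp = spec.trb_j_probs or self.defaults["TRB"][1]
            lp = spec.trb_length_probs
        v_genes, v_probs = zip(*sorted(vp.items()))
        j_genes, j_probs = zip(*sorted(jp.items()))
        lengths, l_probs = zip(*sorted(lp.items()))
        for _ in range(max_tries):
            v = v_genes[rng.choice(len(v_genes), p=np.asarray(v_probs))]
            j = j_genes[rng.choice(len(j_genes), p=np.asarray(j_probs))]
            L = int(lengths[rng.choice(len(lengths), p=np.asarray(l_probs))])
            gv, gj = self.germ.get(v), self.germ.get(j)
            slack = L - len(gv) - self.MIN_INSERT
            if slack < self.MIN_J:
                continue
            j_keep = min(len(gj), slack)
            if j_keep > self.MIN_J and rng.random() < 0.3:
                j_keep -= 1
            insert_len = L - len(gv) - j_keep
            insert = "".join(
                INSERT_ALPHABET[i]
                for i in rng.integers(0, len(INSERT_ALPHABET), insert_len)
            )
            # keep attribution truth exact: the insert must not extend either match
            if j_keep < len(gj) and insert[-1] == gj[len(gj) - j_keep - 1]:
                continue
            junction = gv + insert + gj[len(gj) - j_keep:]
            if register:
                if not self.registry.admissible(v, j, junction):
                    continue
                self.registry.add(v, j, junction)
            return Rearrangement(
                chain=chain, v_gene=v, j_gene=j, junction_aa=junction,
                n_v=len(gv), n_added=insert_len, n_j=j_keep,
            )
        raise RuntimeError(f"could not sample an admissible {chain} junction")


@dataclass
class GroundTruth:
    """Per-cell truth and configured rates for parameter-recovery tests."""

    cells: pd.DataFrame  # one row per cell, incl. pre/post-dropout rearrangements
    config: SimulationConfig
    invariant_junctions: list[str]

    def observed_clonotypes(self, chain: str) -> set[tuple]:
        """Distinct (chain, V, J, junction) among observed single-pair cells."""
        col = "tra_obs" if chain == "TRA" else "trb_obs"
        keys: set[tuple] = set()
        for _, row in self.cells.iterrows():
            if len(row["tra_obs"]) == 1 and len(row["trb_obs"]) == 1:
                keys.update(r.key for r in row[col])
        return keys


@dataclass
class SimulatedRepertoire:
    contigs: list[ContigRecord]
    annotations: list[CellAnnotation]
    expression: pd.DataFrame
    germline: GermlineDB
    truth: GroundTruth
    config: SimulationConfig


def _make_invariant_pool(rng: np.random.Generator, n: int) -> list[Rearrangement]:
    """Distinct MAIT-like clonotypes: CAL + [S/T] + 2 variable + germline J."""
    n_grid = len(MAIT_POS4) * len(MAIT_VAR_ALPHABET) ** 2
    n = min(n, n_grid)
    picks = rng.choice(n_grid, size=n, replace=False)
    pool = []
    for code in picks:
        i4, rem = divmod(int(code), len(MAIT_VAR_ALPHABET) ** 2)
        i5, i6 = divmod(rem, len(MAIT_VAR_ALPHABET))
        junction = (
            MAIT_PREFIX + MAIT_POS4[i4] + MAIT_VAR_ALPHABET[i5]
            + MAIT_VAR_ALPHABET[i6] + MAIT_SUFFIX
        )
        pool.append(
            Rearrangement(
                chain="TRA", v_gene=MAIT_V, j_gene=MAIT_J, junction_aa=junction,
                n_v=4 if MAIT_POS4[i4] == "S" else 3,
                n_added=2 if MAIT_POS4[i4] == "S" else 3,
                n_j=len(MAIT_SUFFIX),
            )
        )
    return pool


def generate(config: SimulationConfig, seed: int) -> SimulatedRepertoire:
    """Generate the cohort; byte-identical outputs for identical (config, seed)."""
    config.validate()
    germ = GermlineDB(GERMLINE_SEQS)
    registry = _StratumRegistry()
    sampler = _BackgroundSampler(germ, registry)

    root = np.random.SeedSequence(seed)
    pool_rng = np.random.default_rng(root.spawn(1)[0])
    pool = _make_invariant_pool(pool_rng, config.n_invariant_clonotypes)
    for r in pool:
        registry.add(r.v_gene, r.j_gene, r.junction_aa)
    # clonal-expansion weights, biased toward the dominant position-4 serine
    pool_weights = pool_rng.dirichlet(np.full(len(pool), 1.2))
    pos4_bias = np.array(
        [dict(zip(MAIT_POS4, MAIT_POS4_P))[r.junction_aa[3]] for r in pool]
    )
    pool_weights = pool_weights * pos4_bias
    pool_weights /= pool_weights.sum()

    # shared public rearrangement pools per (lineage group, chain): public
    # clonotypes recur across subjects and across subsets of the same group
    public_pools: dict[tuple[str, str], list[Rearrangement]] = {}
    shared_rng = np.random.default_rng(root.spawn(2)[1])
    for spec in config.subsets:
        group = _pool_group(spec)
        for chain in ("TRA", "TRB"):
            if (group, chain) not in public_pools:
                public_pools[(group, chain)] = [
                    sampler.sample(shared_rng, chain, spec)
                    for _ in range(config.public_pool_size)
                ]

    subjects = [f"DOG{i + 1}" for i in range(config.n_subjects)]
    subset_rngs = {
        (subj, spec.label): np.random.default_rng(child)
        for (subj, spec), child in zip(
            [(s, sp) for s in subjects for sp in config.subsets],
            np.random.SeedSequence((seed, 7)).spawn(len(subjects) * len(config.subsets)),
        )
    }

    contigs: list[ContigRecord] = []
    annotations: list[CellAnnotation] = []
    expr_rows = []
    truth_rows = []

    for subj in subjects:
        cell_counter = 0
        # largest subset absorbs the rounding remainder
        n_per_subset = {
            s.label: int(round(s.weight * config.cells_per_subject))
            for s in config.subsets
        }
        biggest = max(config.subsets, key=lambda s: s.weight).label
        n_per_subset[biggest] += config.cells_per_subject - sum(n_per_subset.values())

        for spec in config.subsets:
            rng = subset_rngs[(subj, spec.label)]
            n_cells = n_per_subset[spec.label]
            if n_cells <= 0:
                continue

            # ---- clone assembly -------------------------------------------------
            clones: list[tuple[Rearrangement, Rearrangement, int, str]] = []
            n_inv = (
                int(rng.binomial(n_cells, spec.invariant_pair_rate))
                if spec.role == "MAIT_like"
                else 0
            )
            if n_inv:
                idx, counts = np.unique(
                    rng.choice(len(pool), size=n_inv, p=pool_weights),
                    return_counts=True,
                )
                for i, k in zip(idx, counts):
                    trb = self_or_public(sampler, rng, "TRB", spec, public_pools, config)
                    clones.append((pool[int(i)], trb, int(k), f"inv{int(i)}"))
            remaining = n_cells - n_inv
            c_id = 0
            while remaining > 0:
                size = min(int(rng.geometric(spec.clone_geom_p)), remaining, 50)
                tra = self_or_public(sampler, rng, "TRA", spec, public_pools, config)
                trb = self_or_public(sampler, rng, "TRB", spec, public_pools, config)
                clones.append((tra, trb, size, f"bg{c_id}"))
                c_id += 1
                remaining -= size

            # ---- cells ----------------------------------------------------------
            for tra, trb, size, clone_tag in clones:
                for _ in range(size):
                    cell_counter += 1
                    barcode = f"CELL{cell_counter:06d}"
                    tra_true = [tra]
                    trb_true = [trb]
                    if rng.random() < spec.dual_tra_rate:
                        tra_true.append(
                            sampler.sample(rng, "TRA", spec, register=False)
                        )
                    if rng.random() < spec.dual_trb_rate:
                        trb_true.append(
                            sampler.sample(rng, "TRB", spec, register=False)
                        )
                    tra_drop = bool(rng.random() < config.dropout_tra)
                    trb_drop = bool(rng.random() < config.dropout_trb)
                    tra_obs = [] if tra_drop else tra_true
                    trb_obs = [] if trb_drop else trb_true
                    for r in tra_obs + trb_obs:
                        contigs.append(
                            ContigRecord(
                                barcode=barcode, subject_id=subj, chain=r.chain,
                                v_gene=r.v_gene, j_gene=r.j_gene,
                                junction_aa=r.junction_aa,
                                junction_nt=_nt(r.junction_aa),
                                productive=True,
                                umis=int(rng.poisson(8.0)) + 1,
                            )
                        )
                    if rng.random() < config.nonproductive_rate:
                        r = sampler.sample(rng, "TRA", spec, register=False)
                        contigs.append(
                            ContigRecord(
                                barcode=barcode, subject_id=subj, chain="TRA",
                                v_gene=r.v_gene, j_gene=r.j_gene,
                                junction_aa=r.junction_aa,
                                junction_nt=_nt(r.junction_aa),
                                productive=False,
                                umis=int(rng.poisson(2.0)) + 1,
                            )
                        )
                    annotations.append(
                        CellAnnotation(
                            barcode=barcode, subject_id=subj, subset_label=spec.label
                        )
                    )
                    # CD4/CD8A marker counts
                    lineages = ["cd4", "cd8a", "dp"]
                    mix = np.array([spec.lineage_mix[l] for l in lineages])
                    lineage = lineages[rng.choice(3, p=mix / mix.sum())]
                    cd4 = cd8a = 0
                    if lineage in ("cd4", "dp") and rng.random() < spec.marker_detect_p:
                        cd4 = int(rng.poisson(1.5)) + 1
                    if lineage in ("cd8a", "dp") and rng.random() < spec.marker_detect_p:
                        cd8a = int(rng.poisson(1.5)) + 1
                    if lineage == "cd4" and rng.random() < 0.01:
                        cd8a = 1
                    if lineage == "cd8a" and rng.random() < 0.01:
                        cd4 = 1
                    expr_rows.append(
                        {"subject_id": subj, "barcode": barcode, "CD4": cd4, "CD8A": cd8a}
                    )
                    truth_rows.append(
                        {
                            "subject_id": subj, "barcode": barcode,
                            "subset_label": spec.label, "role": spec.role,
                            "clone_id": f"{subj}:{spec.label}:{clone_tag}",
                            "invariant": clone_tag.startswith("inv"),
                            "true_lineage": lineage,
                            "n_tra_true": len(tra_true), "n_trb_true": len(trb_true),
                            "tra_dropped": tra_drop, "trb_dropped": trb_drop,
                            "tra_obs": tra_obs, "trb_obs": trb_obs,
                        }
                    )

    expression = (
        pd.DataFrame(expr_rows).set_index(["subject_id", "barcode"]).sort_index()
    )
    truth = GroundTruth(
        cells=pd.DataFrame(truth_rows),
        config=config,
        invariant_junctions=[r.junction_aa for r in pool],
    )
    return SimulatedRepertoire(
        contigs=contigs, annotations=annotations, expression=expression,
        germline=germ, truth=truth, config=config,
    )


def self_or_public(
    sampler: _BackgroundSampler,
    rng: np.random.Generator,
    chain: str,
    spec: SubsetSpec,
    public_pools: dict,
    config: SimulationConfig,
) -> Rearrangement:
    """A clone's rearrangement: shared public pool item or a fresh private one."""
    pool = public_pools[(_pool_group(spec), chain)]
    if pool and rng.random() < config.public_rate:
        return pool[int(rng.integers(0, len(pool)))]
    return sampler.sample(rng, chain, spec)
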