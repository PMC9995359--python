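"""Synthetic repertoire generator: determinism, config handling, ground truth."""

import numpy as np
import pytest

from tcrclust.profiles import build_cell_profiles
from tcrclust.usage import single_pair_cells
from tcrclust.clustering import collapse_clonotypes
from tcrclust.simulate import (
    SimulationConfig,
    SubsetSpec,
    default_study_config,
    expected_pattern_probs,
    generate,
)


def _tiny_config(**kwargs):
    defaults = dict(n_subjects=2, cells_per_subject=300)
    defaults.update(kwargs)
    return SimulationConfig(
        subsets=[SubsetSpec(label="S0", weight=0.6), SubsetSpec(label="S1", weight=0.4)],
        **defaults,
    )


def test_same_seed_gives_identical_output():
    cfg = _tiny_config()
    a = generate(cfg, seed=3)
    b = generate(cfg, seed=3)
    assert a.contigs == b.contigs
    assert a.annotations == b.annotations
    assert a.expression.equals(b.expression)
    c = generate(cfg, seed=4)
    assert c.contigs != a.contigs


def test_invalid_config_rejected_before_sampling():
    with pytest.raises(ValueError, match="weights"):
        SimulationConfig(subsets=[SubsetSpec(label="S", weight=0.5)]).validate()
    with pytest.raises(ValueError, match="sum to 1"):
        SimulationConfig(
            subsets=[SubsetSpec(label="S", weight=1.0,
                                tra_length_probs={14: 0.5, 15: 0.4})]
        ).validate()
    with pytest.raises(ValueError, match="at least one subset"):
        SimulationConfig(subsets=[]).validate()
    with pytest.raises(ValueError, match="unknown genes"):
        SimulationConfig(
            subsets=[SubsetSpec(label="S", weight=1.0, tra_v_probs={"TRAV999": 1.0})]
        ).validate()


def test_no_dropout_means_no_missing_chains():
    cfg = _tiny_config(dropout_tra=0.0, dropout_trb=0.0, nonproductive_rate=0.0)
    rep = generate(cfg, seed=5)
    prof = build_cell_profiles(rep.contigs, rep.annotations)
    assert (prof["n_tra"] >= 1).all()
    assert (prof["n_trb"] >= 1).all()


def test_yaml_config_round_trip(tmp_path):
    cfg = default_study_config(cells_per_subject=100)
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    back = SimulationConfig.from_yaml(path)
    assert back == cfg


def test_ground_truth_matches_emitted_tables(small_cohort):
    rep = small_cohort
    # every emitted cell is annotated and tracked in the truth table
    assert len(rep.truth.cells) == len(rep.annotations)
    prof = build_cell_profiles(rep.contigs, rep.annotations)
    truth = rep.truth.cells.set_index(["subject_id", "barcode"])
    obs = prof.set_index(["subject_id", "barcode"])
    # observed pattern equals the truth's post-dropout rearrangement counts
    n_tra_truth = truth["tra_obs"].map(len)
    assert obs["n_tra"].eq(n_tra_truth.reindex(obs.index)).all()
    # pipeline clonotype collapse equals the generator's own bookkeeping
    cells = single_pair_cells(rep.contigs, prof)
    entries = collapse_clonotypes(cells, "TRA")
    assert {e.key for e in entries} == rep.truth.observed_clonotypes("TRA")


def test_subset_sizes_and_mait_fraction_recovered(small_cohort):
    rep = small_cohort
    labels = rep.truth.cells["subset_label"]
    per_subject = rep.truth.cells.groupby("subject_id").size()
    assert (per_subject == rep.config.cells_per_subject).all()
    c13 = next(s for s in rep.config.subsets if s.label == "C13")
    n13 = (labels == "C13").sum()
    expected = c13.weight * len(labels)
    assert abs(n13 - expected) <= 4 * np.sqrt(expected)
    # configured invariant fraction within binomial error
    inv = rep.truth.cells.loc[labels == "C13", "invariant"]
    se = np.sqrt(0.821 * 0.179 / len(inv))
    assert inv.mean() == pytest.approx(0.821, abs=4 * se)


def test_expected_pattern_probs_are_a_distribution():
    cfg = default_study_config(cells_per_subject=100)
    probs = expected_pattern_probs(cfg)
    assert sum(probs.values()) == pytest.approx(1.0)
    assert probs["1-1"] == pytest.approx(0.62, abs=0.03)
    inkt = expected_pattern_probs(cfg, subset="C19")
    assert inkt["2-1"] > probs["2-1"]


def test_invariant_junctions_are_16mers_with_fixed_flanks(small_cohort):
    for junction in small_cohort.truth.invariant_junctions:
        assert len(junction) == 16
        assert junction.startswith("CAL")
        assert junction.endswith("YSGVGSQLTF")
        assert junction[3] in "ST"
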