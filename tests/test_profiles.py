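"""Rearrangement-pattern profiling and detection rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcrclust.io import CellAnnotation, ContigRecord
from tcrclust.profiles import build_cell_profiles, detection_rate, pattern_frequencies
from tcrclust.simulate import SubsetSpec, SimulationConfig, generate


def _contig(bc, chain, junction, v="1", j="4", productive=True):
    prefix = chain + "V", chain + "J"
    return ContigRecord(bc, "D1", chain, f"{prefix[0][:4]}{v}", f"{prefix[1][:4]}{j}",
                        junction, productive=productive)


ANN = [CellAnnotation(f"b{i}", "D1", "C0") for i in range(4)]


def test_patterns_from_contigs():
    contigs = [
        _contig("b0", "TRA", "CAVRGNKLVF"),
        _contig("b0", "TRB", "CASSENTEAFF"),
        # two distinct TRA + one TRB
        _contig("b1", "TRA", "CAVRGNKLVF"),
        _contig("b1", "TRA", "CAVSGNKLVF"),
        _contig("b1", "TRB", "CASSENTEAFF"),
        # non-productive only
        _contig("b2", "TRA", "CAVRGNKLVF", productive=False),
    ]
    prof = build_cell_profiles(contigs, ANN).set_index("barcode")
    assert prof.loc["b0", "pattern"] == "1-1"
    assert prof.loc["b1", "pattern"] == "2-1"
    assert prof.loc["b2", "pattern"] == "0-0"
    assert prof.loc["b3", "pattern"] == "0-0"  # annotated, no contigs at all
    assert len(prof) == len(ANN)


def test_duplicate_contigs_collapse_and_orphans_dropped(caplog):
    contigs = [
        _contig("b0", "TRA", "CAVRGNKLVF"),
        _contig("b0", "TRA", "CAVRGNKLVF"),  # duplicate row, same rearrangement
        _contig("ghost", "TRA", "CAVRGNKLVF"),  # not annotated
    ]
    prof = build_cell_profiles(contigs, ANN).set_index("barcode")
    assert prof.loc["b0", "pattern"] == "1-0"
    assert "ghost" not in prof.index


@given(st.permutations(range(5)))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_profiles_invariant_under_contig_order(order):
    contigs = [
        _contig("b0", "TRA", "CAVRGNKLVF"),
        _contig("b0", "TRB", "CASSENTEAFF"),
        _contig("b1", "TRA", "CAVRGNKLVF"),
        _contig("b1", "TRA", "CAVSGNKLVF"),
        _contig("b2", "TRB", "CASSENTEAFF"),
    ]
    shuffled = [contigs[i] for i in order]
    a = build_cell_profiles(contigs, ANN).set_index("barcode").sort_index()
    b = build_cell_profiles(shuffled, ANN).set_index("barcode").sort_index()
    assert a.equals(b)


def test_pattern_frequencies_sum_to_100():
    ann = [CellAnnotation(f"b{i}", "D1", "C0") for i in range(10)]
    contigs = []
    for i in range(6):  # 6 of 10 cells are 1-1
        contigs.append(_contig(f"b{i}", "TRA", "CAVRGNKLVF"))
        contigs.append(_contig(f"b{i}", "TRB", "CASSENTEAFF"))
    prof = build_cell_profiles(contigs, ann)
    freq = pattern_frequencies(prof, by_subset=False)
    f = freq.set_index("pattern")
    assert f.loc["1-1", "percent"] == pytest.approx(60.0)
    assert freq.groupby("group")["percent"].sum().eq(100.0).all()


def test_detection_rate_counts_zero_cells():
    ann = [CellAnnotation(f"b{i}", "D1", "C0") for i in range(4)]
    contigs = [_contig(f"b{i}", "TRA", "CAVRGNKLVF") for i in range(3)]
    per, median, n_above = detection_rate(build_cell_profiles(contigs, ann))
    assert per.loc[0, "percent_detected"] == pytest.approx(75.0)
    assert median == pytest.approx(75.0)
    assert n_above == 1
    per0, median0, _ = detection_rate(build_cell_profiles([], ann))
    assert median0 == 0.0


def test_configured_dual_rate_recovered_without_dropout():
    """With zero drop-out, a 0.25 dual-TRA subset shows ~25% '2-1' cells."""
    config = SimulationConfig(
        n_subjects=2, cells_per_subject=1500, dropout_tra=0.0, dropout_trb=0.0,
        nonproductive_rate=0.0,
        subsets=[SubsetSpec(label="S", weight=1.0, dual_tra_rate=0.25,
                            dual_trb_rate=0.0)],
    )
    rep = generate(config, seed=11)
    prof = build_cell_profiles(rep.contigs, rep.annotations)
    # no drop-out: every cell has at least 1 TRA and 1 TRB
    assert (prof["n_tra"] >= 1).all() and (prof["n_trb"] >= 1).all()
    freq = pattern_frequencies(prof, by_subset=False).set_index("pattern")
    n = len(prof)
    se = 100 * np.sqrt(0.25 * 0.75 / n)
    assert freq.loc["2-1", "percent"] == pytest.approx(25.0, abs=3 * se)
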