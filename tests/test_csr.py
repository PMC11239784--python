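import math

import numpy as np
import pytest

from gh13tools import synth
from gh13tools.csr import (
    CsrColumnMap,
    CsrMatrix,
    CsrScheme,
    Fingerprint,
    anchor_csr_columns,
    conservation_count,
    evaluate_fingerprint,
    extract_csr_block,
    make_logo_table,
    position_frequencies,
)
from gh13tools.sequence_io import Alignment, SequenceRecord


def test_scheme_regions_cover_1_to_52():
    scheme = CsrScheme()
    assert scheme.region_of(25) == "CSR-II"
    assert scheme.region_of(34) == "CSR-III"
    assert scheme.region_of(43) == "CSR-IV"
    assert scheme.region_of(1) == "CSR-VI" and scheme.region_of(52) == "CSR-VII"
    with pytest.raises(ValueError):
        CsrScheme(regions={"CSR-I": (1, 52), "CSR-II": (10, 20)})


def _reference_alignment(gap_before_column=None):
    """Small alignment whose reference carries D/E/D at chosen logo anchors."""
    #          0123456789...
    ref_seq = "MKDAELTDVWAAY"
    rows = [
        SequenceRecord("ref", ref_seq),
        SequenceRecord("x", "MKDAELTDVWAAY".replace("W", "F")),
    ]
    if gap_before_column is not None:
        rows = [
            SequenceRecord(
                r.id,
                r.residues[:gap_before_column] + "-" + r.residues[gap_before_column:],
            )
            for r in rows
        ]
    return Alignment(rows)


def test_anchor_identity_on_gapless_alignment():
    aln = _reference_alignment()
    refmap = {16: 1, 25: 2, 34: 4, 43: 7, 52: 10}
    cmap = anchor_csr_columns(aln, "ref", refmap)
    for logo, idx in refmap.items():
        assert cmap[logo] == idx
    assert cmap["preCSRV"] == 0  # residue immediately before logo 16


def test_anchor_shifts_with_inserted_gap_column():
    refmap = {16: 1, 25: 2, 34: 4, 43: 7, 52: 10}
    plain = anchor_csr_columns(_reference_alignment(), "ref", refmap)
    shifted = anchor_csr_columns(_reference_alignment(gap_before_column=4), "ref", refmap)
    # positions anchored before the insertion keep their columns
    assert shifted[16] == plain[16] and shifted[25] == plain[25]
    # positions at/after the insertion shift by one column
    assert shifted[34] == plain[34] + 1
    assert shifted[43] == plain[43] + 1
    assert shifted[52] == plain[52] + 1


def test_gap_column_insertion_leaves_block_unchanged():
    refmap = {16: 1, 25: 2, 34: 4, 43: 7, 52: 10}
    aln0 = _reference_alignment()
    aln1 = _reference_alignment(gap_before_column=6)
    m0 = extract_csr_block(aln0, anchor_csr_columns(aln0, "ref", refmap))
    m1 = extract_csr_block(aln1, anchor_csr_columns(aln1, "ref", refmap))
    assert m0.rows == m1.rows


def test_catalytic_validation():
    aln = _reference_alignment()
    bad = {16: 1, 25: 3, 34: 4, 43: 7}  # residue at index 3 is 'A', not D
    with pytest.raises(ValueError, match="nucleophile"):
        anchor_csr_columns(aln, "ref", bad)
    anchor_csr_columns(aln, "ref", bad, allow_aberrant=True)  # override allowed


def test_missing_reference_rejected():
    with pytest.raises(KeyError):
        anchor_csr_columns(_reference_alignment(), "nope", {25: 2})


def test_extract_block_reads_ded_at_catalytic(small_benchmark, small_matrix):
    ref = small_benchmark.alignment.records[0].id
    assert small_matrix.char(ref, 25) == "D"
    assert small_matrix.char(ref, 34) == "E"
    assert small_matrix.char(ref, 43) == "D"
    width = len(small_matrix.positions)
    assert all(len(row) == width for row in small_matrix.rows.values())


def _toy_matrix():
    rows = {
        "a": "CD",
        "b": "CD",
        "c": "C-",
        "d": "AD",
    }
    return CsrMatrix([24, 25], rows)


def test_conservation_count_and_semantics():
    m = _toy_matrix()
    full = conservation_count(m, {24: {"C"}})
    assert (full.count, full.total) == (3, 4)
    both = conservation_count(m, {24: {"C"}, 25: {"D"}})
    assert both.count == 2  # 'c' fails at 25 (gap), 'd' at 24
    with pytest.raises(KeyError):
        conservation_count(m, {99: {"C"}})


def test_conservation_and_monotonicity(small_matrix, small_benchmark):
    ids48 = [s for s, l in small_benchmark.truth.items() if l == "GH13_48"]
    s1 = conservation_count(small_matrix, {19: {"L"}}, ids48)
    s2 = conservation_count(small_matrix, {20: {"D", "N"}}, ids48)
    s12 = conservation_count(small_matrix, {19: {"L"}, 20: {"D", "N"}}, ids48)
    assert s12.count <= min(s1.count, s2.count)


def test_position_frequencies_gap_excluded():
    m = CsrMatrix([1], {f"s{i}": ("C" if i < 5 else "-") for i in range(10)})
    pft = position_frequencies(m)
    assert pft.frequencies[0, 1] == 1.0  # C fully conserved among non-gaps
    assert pft.gap_fraction[0] == 0.5
    assert pft.n_sequences == 10


def test_frequency_rows_sum_to_one(small_matrix):
    pft = position_frequencies(small_matrix)
    sums = pft.frequencies.sum(axis=1)
    nonzero = pft.counts.sum(axis=1) > 0
    assert np.allclose(sums[nonzero], 1.0, atol=1e-9)


def test_logo_information_content():
    m = CsrMatrix([1, 2, 3], {
        **{f"a{i}": "CCA" for i in range(5)},
        **{f"b{i}": "C-C" for i in range(5)},
    })
    # position 1: pure C; position 3: half C half A (with 5 gaps at pos 2)
    table = make_logo_table(position_frequencies(m))
    ic = dict(zip(table["position"], table["information_bits"]))
    assert ic["1"] == pytest.approx(math.log2(20))
    assert ic["3"] == pytest.approx(math.log2(20) - 1.0)
    row3 = table[table["position"] == "3"].iloc[0]
    assert row3["C"] == pytest.approx((math.log2(20) - 1.0) / 2, abs=1e-9)
    assert row3["A"] == pytest.approx(1.6609, abs=1e-3)


def test_logo_uniform_column_zero_bits():
    from gh13tools.sequence_io import AA20

    m = CsrMatrix([1], {f"s{i}": AA20[i] for i in range(20)})
    table = make_logo_table(position_frequencies(m))
    assert table["information_bits"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_all_gap_position_ic_zero():
    m = CsrMatrix([1], {"a": "-", "b": "-"})
    table = make_logo_table(position_frequencies(m))
    assert table["information_bits"].iloc[0] == 0.0


def test_evaluate_fingerprint(benchmark_config, small_matrix, small_benchmark):
    fp48 = benchmark_config["fingerprints"]["GH13_48"][0]  # L-[DN]
    fp49 = next(
        fp for fp in benchmark_config["fingerprints"]["GH13_49"]
        if fp.label == "csr2_WYGA"
    )
    # consensus rows straight from the observed per-class frequencies
    ids48 = [s for s, l in small_benchmark.truth.items() if l == "GH13_48"]
    ids49 = [s for s, l in small_benchmark.truth.items() if l == "GH13_49"]
    cons48 = position_frequencies(small_matrix, ids48).consensus()
    cons49 = position_frequencies(small_matrix, ids49).consensus()
    m = CsrMatrix(small_matrix.positions, {"c48": cons48, "c49": cons49})
    assert evaluate_fingerprint(m, "c48", fp48).fraction == 1.0
    assert evaluate_fingerprint(m, "c49", fp49).fraction == 1.0
    # the 48-consensus must fail the 49 fingerprint at the [WY] position
    rep = evaluate_fingerprint(m, "c48", fp49)
    assert rep.matches[28] is False


def test_fingerprint_gap_fails():
    fp = Fingerprint("toy", [(24, frozenset("C"), "")])
    m = CsrMatrix([24], {"a": "-"})
    assert evaluate_fingerprint(m, "a", fp).matches[24] is False


def test_synthetic_conservation_matches_parameter(benchmark_config):
    """Observed fingerprint conservation converges to the generating c
    within 3 binomial standard errors."""
    specs = benchmark_config["specs"]
    bench = synth.make_benchmark(
        list(specs.values()),
        {"GH13_48": 800, "GH13_49": 800, "GH13_38": 2, "intermediary": 2},
        seed=29,
    )
    aln = bench.alignment
    cmap = anchor_csr_columns(aln, aln.records[0].id, bench.refmap)
    matrix = extract_csr_block(aln, cmap)
    ids49 = [s for s, l in bench.truth.items() if l == "GH13_49"]
    c = specs["GH13_49"].positions[33].c
    stat = conservation_count(matrix, {33: {"D"}}, ids49)
    se = math.sqrt(c * (1 - c) / len(ids49))
    assert abs(stat.fraction - c) <= 3 * se
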