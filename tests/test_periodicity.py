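"""Alignment tallies, LOR profiles, window statistics, expression bins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from codonramp import (
    OrfRecord,
    align_and_count,
    codon_window_stat,
    compute_background,
    lor_profile,
    partition_by_expression,
    yeast_orf_background,
)
from codonramp.periodicity import (
    BackgroundFrequencies,
    codon_position,
    g2_mean_from_counts,
    window_base_matrix,
)


def brute_force_tally(records, anchor, positions, region):
    """Independent per-position tally by direct string slicing."""
    counts = {p: {b: 0 for b in "ACGT"} for p in positions}
    for r in records:
        if anchor == "stop_codon" and not r.complete_cds:
            continue
        full = r.utr5 + r.cds + r.utr3
        a0 = len(r.utr5) if anchor == "start_codon" else len(r.utr5) + len(r.cds)
        lo, hi = {
            "utr5": (0, len(r.utr5)),
            "cds": (len(r.utr5), len(r.utr5) + len(r.cds)),
            "utr3": (len(r.utr5) + len(r.cds), len(full)),
            "spanning": (0, len(full)),
        }[region]
        for p in positions:
            k = a0 + p - 1 if p > 0 else a0 + p
            if lo <= k < hi and full[k] in counts[p]:
                counts[p][full[k]] += 1
    return counts


def test_identical_records_start_anchor(quad_orfs):
    pfm = align_and_count(quad_orfs, "start_codon", range(1, 10), "cds")
    assert pfm.counts.loc[4].to_dict() == {"A": 0, "C": 0, "G": 4, "T": 0}
    assert (pfm.n_contributing == 4).all()


def test_identical_records_stop_anchor(quad_orfs):
    pfm = align_and_count(quad_orfs, "stop_codon", range(-3, 0), "cds")
    assert pfm.counts.loc[-3, "T"] == 4  # stop codon starts with T
    assert pfm.counts.loc[-2, "A"] == 4
    assert pfm.counts.loc[-1, "A"] == 4


@pytest.mark.parametrize("region", ["cds", "utr5", "utr3", "spanning"])
@pytest.mark.parametrize("anchor", ["start_codon", "stop_codon"])
def test_align_matches_brute_force_oracle(mixed_orfs, anchor, region):
    positions = [p for p in range(-8, 9) if p != 0]
    pfm = align_and_count(mixed_orfs, anchor, positions, region)
    oracle = brute_force_tally(mixed_orfs, anchor, positions, region)
    for p in positions:
        assert pfm.counts.loc[p].to_dict() == oracle[p], f"position {p}"


def test_align_matches_oracle_on_random_records():
    rng = np.random.default_rng(5)
    records = []
    for i in range(20):
        n_codons = rng.integers(3, 12)
        body = "".join(rng.choice(list("ACGT"), 3 * (n_codons - 2)))
        cds = "ATG" + body + "TAA"
        utr5 = "".join(rng.choice(list("ACGTN"), rng.integers(0, 10)))
        records.append(OrfRecord.from_raw(f"r{i}", utr5, cds, ""))
    positions = [p for p in range(-6, 16) if p != 0]
    pfm = align_and_count(records, "start_codon", positions, "spanning")
    oracle = brute_force_tally(records, "start_codon", positions, "spanning")
    for p in positions:
        assert pfm.counts.loc[p].to_dict() == oracle[p]
    # shorter records drop out at distant offsets
    assert pfm.n_contributing.loc[15] <= pfm.n_contributing.loc[4]


def test_n_excluded_at_n_positions_only():
    records = [
        OrfRecord.from_raw("a", "", "ATGNCTTAA", ""),
        OrfRecord.from_raw("b", "", "ATGGCTTAA", ""),
    ]
    pfm = align_and_count(records, "start_codon", range(1, 10), "cds")
    assert pfm.n_contributing.loc[4] == 1  # N excluded here only
    assert pfm.n_contributing.loc[5] == 2


def test_background_computed_and_fixed():
    allA = compute_background([OrfRecord.from_raw("a", "", "AAAA", "")])
    assert allA.freq.to_dict() == {"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0}
    bg = compute_background([OrfRecord.from_raw("a", "", "ACGT", "")])
    assert bg.freq.to_dict() == {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    assert bg.source == "computed"
    fixed = yeast_orf_background()
    assert fixed.freq.to_dict() == {"A": 0.326, "C": 0.192, "G": 0.204, "T": 0.278}
    assert fixed.source == "yeast_orf_default"


def test_lor_zero_when_observed_equals_background(quad_orfs):
    bg = BackgroundFrequencies(pd.Series({"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}))
    records = [OrfRecord.from_raw(f"g{i}", "", "ATG" + b * 4 + "TAA", "")
               for i, b in enumerate("ACGT")]
    prof = lor_profile(
        align_and_count(records, "start_codon", [4], "cds"), bg, pseudocount=0
    )
    assert prof.lor.loc[4].abs().max() < 1e-12


def test_lor_log2_values(quad_orfs):
    pfm = align_and_count(quad_orfs, "start_codon", range(1, 10), "cds")
    prof = lor_profile(pfm, yeast_orf_background(), pseudocount=0)
    # all four records have G at position 4: freq 1 vs background 0.204
    assert prof.lor.loc[4, "G"] == pytest.approx(np.log2(1 / 0.204))
    # zero counts with pseudocount 0 become -inf sentinels, flagged
    assert np.isneginf(prof.lor.loc[4, "A"])
    assert prof.has_infinite


def test_lor_stored_formula_with_pseudocount(quad_orfs):
    pfm = align_and_count(quad_orfs, "start_codon", [4], "cds")
    a = 0.5
    prof = lor_profile(pfm, yeast_orf_background(), pseudocount=a)
    expected = np.log2(((4 + a) / (4 + 4 * a)) / 0.204)
    assert prof.lor.loc[4, "G"] == pytest.approx(expected)
    assert np.isfinite(prof.lor.loc[4].to_numpy()).all()


def test_lor_consistency_identity(mixed_orfs):
    """With pseudocount 0, sum_b bg[b] * 2**lor[p][b] = 1 wherever n > 0."""
    pfm = align_and_count(mixed_orfs, "start_codon", range(1, 10), "cds")
    bg = yeast_orf_background()
    prof = lor_profile(pfm, bg, pseudocount=0)
    for p in prof.lor.index:
        if pfm.n_contributing.loc[p] > 0:
            total = float((bg.freq * np.power(2.0, prof.lor.loc[p])).sum())
            assert total == pytest.approx(1.0)


def test_codon_position_classes():
    assert [codon_position(p) for p in (1, 2, 3, 4, 7, 22)] == [1, 2, 3, 1, 1, 1]
    sites2 = [p for p in range(7, 23) if codon_position(p) == 2]
    assert sites2 == [8, 11, 14, 17, 20]


def test_window_stat_on_synthetic_profile(quad_orfs):
    pfm = align_and_count(quad_orfs * 3, "start_codon", range(1, 23), "cds")
    prof = lor_profile(pfm, yeast_orf_background())
    # hand-build a profile with G LOR -1 at exactly the position-2 sites
    prof.lor.loc[:, "G"] = 0.0
    prof.lor.loc[[8, 11, 14, 17, 20], "G"] = -1.0
    prof.n_contributing[:] = 12
    stat = codon_window_stat(prof, (7, 22))
    assert stat.g2_mean == pytest.approx(-1.0)
    assert stat.positions_by_class[2] == (8, 11, 14, 17, 20)
    assert stat.g2_mean == stat.per_codon_position.loc[2, "G"]


def test_window_stat_all_zero_profile(quad_orfs):
    pfm = align_and_count(quad_orfs, "start_codon", range(1, 23), "cds")
    prof = lor_profile(pfm, yeast_orf_background())
    prof.lor.loc[:, :] = 0.0
    stat = codon_window_stat(prof, (7, 22))
    assert (stat.per_codon_position.to_numpy() == 0).all()
    assert stat.g2_mean == 0.0


def test_window_outside_profile_raises(quad_orfs):
    pfm = align_and_count(quad_orfs, "start_codon", range(1, 9), "cds")
    prof = lor_profile(pfm, yeast_orf_background())
    with pytest.raises(ValueError, match="outside"):
        codon_window_stat(prof, (7, 22))


def _expressed(n):
    return [
        OrfRecord.from_raw(f"g{i:03d}", "", "ATGGCTTAA", "", expression=float(i + 1))
        for i in range(n)
    ]


def test_partition_even_and_remainder():
    bins = partition_by_expression(_expressed(100), 10)
    assert [len(b) for b in bins] == [10] * 10
    bins = partition_by_expression(_expressed(101), 10)
    assert [len(b) for b in bins] == [11] + [10] * 9
    # bin 1 holds the top expressers
    assert min(r.expression for r in bins[0]) > max(r.expression for r in bins[1])


def test_partition_tie_break_deterministic():
    records = [
        OrfRecord.from_raw(g, "", "ATGGCTTAA", "", expression=5.0)
        for g in ("b", "a", "d", "c")
    ]
    bins = partition_by_expression(records, 2)
    assert [r.gene_id for r in bins[0]] == ["a", "b"]
    assert [r.gene_id for r in bins[1]] == ["c", "d"]


def test_partition_errors():
    with pytest.raises(ValueError, match="bins"):
        partition_by_expression(_expressed(5), 6)
    bad = [OrfRecord.from_raw("x", "", "ATGGCTTAA", "", expression=0.0)]
    with pytest.raises(ValueError, match="> 0"):
        partition_by_expression(bad, 1)


def test_window_matrix_reproduces_pooled_counts(mixed_orfs):
    M, positions = window_base_matrix(mixed_orfs, (7, 22))
    pooled = M.sum(axis=0)
    pfm = align_and_count(mixed_orfs, "start_codon", positions, "cds")
    assert (pooled == pfm.counts.to_numpy()).all()
    g2 = g2_mean_from_counts(pooled, positions, yeast_orf_background(), 0.5)
    prof = lor_profile(pfm, yeast_orf_background(), 0.5)
    assert g2 == pytest.approx(codon_window_stat(prof, (7, 22)).g2_mean)


@given(st.integers(1, 200))
def test_codon_position_partitions_all_positions(p):
    assert codon_position(p) in (1, 2, 3)
    assert codon_position(p) == (p - 1) % 3 + 1
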