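"""Positional nucleotide statistics for anchored ORF alignments.

The central quantity is the per-position log2 odds ratio (LOR)

    LOR[p][b] = log2( freq_obs[p][b] / freq_background[b] )

computed after aligning a gene collection at an anchor (annotated start
codon, stop codon, or an alternative AUG).  A 3-nt periodicity shows up as
positive LOR for G at codon position 1 (G1) and C at codon position 2
(C2), and negative LOR for G at codon position 2 (G2, the "G2 depression").
The signature summary statistic is the mean G2 LOR over a ramp window of
nucleotides, default 7-22 (codon-position-2 sites 8, 11, 14, 17, 20).

Positions are 1-based; there is no position 0.  Start-anchored coordinates
run 1, 2, 3, ... into the CDS and -1, -2, ... into the 5'UTR;
stop-anchored coordinates place the stop codon at -3, -2, -1 with the
3'UTR at 1, 2, ...
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import NUCLEOTIDES, OrfRecord

log = logging.getLogger(__name__)

#: Nucleotide frequencies of all annotated S. cerevisiae ORFs, the default
#: background for LOR profiles.
YEAST_ORF_BACKGROUND = {"A": 0.326, "C": 0.192, "G": 0.204, "T": 0.278}

DEFAULT_WINDOW = (7, 22)
DEFAULT_PSEUDOCOUNT = 0.5

_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


@dataclass
class BackgroundFrequencies:
    """A strictly positive nucleotide frequency vector summing to 1."""

    freq: pd.Series
    source: str = "computed"

    def __post_init__(self) -> None:
        self.freq = pd.Series(self.freq, dtype=float).reindex(list(NUCLEOTIDES))
        if self.freq.isna().any() or (self.freq < 0).any() or (self.freq > 1).any():
            raise ValueError("background frequencies must lie in [0, 1]")
        if abs(float(self.freq.sum()) - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {self.freq.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return self.freq.to_numpy()


def yeast_orf_background() -> BackgroundFrequencies:
    """The fixed yeast-ORF background (A .326, C .192, G .204, T .278)."""
    return BackgroundFrequencies(pd.Series(YEAST_ORF_BACKGROUND), source="yeast_orf_default")


def compute_background(records: Iterable[OrfRecord]) -> BackgroundFrequencies:
    """Pooled nucleotide frequencies over all CDS nucleotides (N excluded)."""
    counts = dict.fromkeys(NUCLEOTIDES, 0)
    for rec in records:
        for b in rec.cds:
            if b in counts:
                counts[b] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no CDS nucleotides to compute a background from")
    return BackgroundFrequencies(
        pd.Series({b: c / total for b, c in counts.items()}), source="computed"
    )


def codon_position(p: int) -> int:
    """Codon-position class (1, 2 or 3) of start-anchored nucleotide p >= 1."""
    if p < 1:
        raise ValueError(f"codon_position needs a CDS position >= 1, got {p}")
    return (p - 1) % 3 + 1


@dataclass
class PositionFrequencyMatrix:
    """Per-alignment-position nucleotide counts for an anchored collection.

    ``n_contributing`` varies by position: records too short to reach a
    position (or with N there) simply do not contribute to it.
    """

    anchor: str
    positions: tuple[int, ...]
    counts: pd.DataFrame  # index = positions, columns = A,C,G,T
    n_contributing: pd.Series
    n_records: int

    def __post_init__(self) -> None:
        row_sums = self.counts.sum(axis=1)
        if not (row_sums.to_numpy() == self.n_contributing.to_numpy()).all():
            raise ValueError("counts at each position must sum to n_contributing")
        if (self.n_contributing > self.n_records).any():
            raise ValueError("n_contributing cannot exceed the number of records")

    def frequencies(self) -> pd.DataFrame:
        """Observed per-position frequencies (NaN where nothing contributes)."""
        n = self.n_contributing.replace(0, np.nan)
        return self.counts.div(n, axis=0)


def _anchor_index(rec: OrfRecord, anchor: str) -> int:
    # 0-based index in rec.spanning of the base at coordinate 1
    if anchor == "start_codon":
        return len(rec.utr5)
    if anchor == "stop_codon":
        return len(rec.utr5) + len(rec.cds)
    raise ValueError(f"unknown anchor: {anchor!r}")

def _region_bounds(rec: OrfRecord, region: str) -> tuple[int, int]:
    a, b, c = len(rec.utr5), len(rec.cds), len(rec.utr3)
    bounds = {
        "utr5": (0, a),
        "cds": (a, a + b),
        "utr3": (a + b, a + b + c),
        "spanning": (0, a + b + c),
    }
    try:
        return bounds[region]
    except KeyError:
        raise ValueError(f"unknown region: {region!r}") from None

def _offset_index(anchor_idx: int, offset: int) -> int:
    # coordinates are 1-based in both directions; -1 and 1 are adjacent
    if offset == 0:
        raise ValueError("coordinates are 1-based; there is no position 0")
    return anchor_idx + offset - 1 if offset > 0 else anchor_idx + offset


def _validate_positions(positions: Sequence[int]) -> tuple[int, ...]:
    positions = tuple(int(p) for p in positions)
    if not positions:
        raise ValueError("empty position range")
    if 0 in positions:
        raise ValueError("coordinates are 1-based; there is no position 0")
    return positions


def _tally(
    items: Iterable[tuple[str, int, int, int]],
    positions: tuple[int, ...],
) -> tuple[np.ndarray, np.ndarray]:
    """Tally bases at offsets for (sequence, anchor_idx, lo, hi) items."""
    counts = np.zeros((len(positions), 4), dtype=np.int64)
    for seq, anchor_idx, lo, hi in items:
        for j, p in enumerate(positions):
            k = _offset_index(anchor_idx, p)
            if lo <= k < hi:
                i = _BASE_INDEX.get(seq[k])
                if i is not None:  # N excluded at this position only
                    counts[j, i] += 1
    return counts, counts.sum(axis=1)


def _pfm_from_counts(
    anchor: str, positions: tuple[int, ...], counts: np.ndarray, n_records: int
) -> PositionFrequencyMatrix:
    df = pd.DataFrame(counts, index=list(positions), columns=list(NUCLEOTIDES))
    return PositionFrequencyMatrix(
        anchor=anchor,
        positions=positions,
        counts=df,
        n_contributing=df.sum(axis=1),
        n_records=n_records,
    )


def align_and_count(
    records: Iterable[OrfRecord],
    anchor: str = "start_codon",
    positions: Sequence[int] = (),
    region: str = "cds",
) -> PositionFrequencyMatrix:
    """Align records at an anchor and tally nucleotides at each offset.

    ``region`` restricts which part of each gene may contribute (e.g. the
    UTR panels of a start/stop-anchored profile); ``spanning`` lets windows
    run across region boundaries.  Stop-anchored alignments use only
    complete CDSs.
    """
    positions = _validate_positions(positions)
    recs = list(records)
    if not recs:
        raise ValueError("empty record collection")
    if anchor == "stop_codon":
        kept = [r for r in recs if r.complete_cds]
        if len(kept) < len(recs):
            log.info(
                "stop-anchored alignment: excluded %d incomplete CDS records",
                len(recs) - len(kept),
            )
        recs = kept
        if not recs:
            raise ValueError("no complete-CDS records for stop-anchored alignment")
    items = [
        (r.spanning, _anchor_index(r, anchor), *_region_bounds(r, region)) for r in recs
    ]
    counts, _ = _tally(items, positions)
    return _pfm_from_counts(anchor, positions, counts, len(recs))


@dataclass
class LorProfile:
    """Per-position, per-base log2 odds ratios against a background.

    With pseudocount a, lor[p][b] = log2((counts+a) / (n+4a) / background[b]).
    Positions where nothing contributes are emitted as missing (NaN).
    """

    positions: tuple[int, ...]
    lor: pd.DataFrame
    background: BackgroundFrequencies
    pseudocount: float
    n_contributing: pd.Series

    @property
    def has_infinite(self) -> bool:
        """True when a zero count met pseudocount 0 (a -inf sentinel)."""
        return bool(np.isinf(self.lor.to_numpy()).any())


def lor_profile(
    pfm: PositionFrequencyMatrix,
    background: BackgroundFrequencies | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> LorProfile:
    """Compute the LOR profile of a position-frequency matrix."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    bg = background if background is not None else yeast_orf_background()
    if (bg.freq <= 0).any():
        raise ValueError("LOR requires a strictly positive background")
    lor = pd.DataFrame(
        lor_from_counts(
            pfm.counts.to_numpy(float),
            pfm.n_contributing.to_numpy(float),
            bg.as_array(),
            pseudocount,
        ),
        index=pfm.counts.index,
        columns=pfm.counts.columns,
    )
    profile = LorProfile(
        positions=pfm.positions,
        lor=lor,
        background=bg,
        pseudocount=float(pseudocount),
        n_contributing=pfm.n_contributing,
    )
    if profile.has_infinite:
        log.warning("LOR profile contains -inf (zero count with pseudocount 0)")
    return profile


def lor_from_counts(
    counts: np.ndarray, n: np.ndarray, background: np.ndarray, pseudocount: float
) -> np.ndarray:
    """Vectorized LOR kernel shared by profiles and resampling statistics."""
    n = np.asarray(n, dtype=float)
    denom = n[..., None] + 4.0 * pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = (np.asarray(counts, dtype=float) + pseudocount) / denom
        lor = np.log2(freq / background)
    lor[n == 0] = np.nan  # no contributing records: missing, not 0.25/bg
    return lor


@dataclass
class CodonWindowStat:
    """Superimposed-codon means of a LOR profile over a nucleotide window.

    Window positions are classed by codon position ((p-1) mod 3 + 1) and
    the LOR values of each class are averaged per base.  ``g2_mean`` (mean
    LOR of G at codon position 2) is the headline periodicity statistic.
    """

    window: tuple[int, int]
    per_codon_position: pd.DataFrame  # index = 1,2,3; columns = A,C,G,T
    g2_mean: float
    positions_by_class: dict[int, tuple[int, ...]] = field(default_factory=dict)


def codon_window_stat(
    profile: LorProfile, window: tuple[int, int] = DEFAULT_WINDOW
) -> CodonWindowStat:
    """Average a start-anchored LOR profile over superimposed codons."""
    lo, hi = int(window[0]), int(window[1])
    if lo > hi or lo < 1:
        raise ValueError(f"bad window {window}; needs 1 <= lo <= hi")
    wanted = list(range(lo, hi + 1))
    missing = [p for p in wanted if p not in profile.lor.index]
    if missing:
        raise ValueError(f"window positions outside profile: {missing}")
    by_class: dict[int, list[int]] = {1: [], 2: [], 3: []}
    for p in wanted:
        by_class[codon_position(p)].append(p)
    rows = {
        c: profile.lor.loc[ps].mean(axis=0, skipna=True) for c, ps in by_class.items()
    }
    per = pd.DataFrame(rows).T
    per.index.name = "codon_position"
    return CodonWindowStat(
        window=(lo, hi),
        per_codon_position=per,
        g2_mean=float(per.loc[2, "G"]),
        positions_by_class={c: tuple(ps) for c, ps in by_class.items()},
    )


def partition_by_expression(
    records: Iterable[OrfRecord], n_bins: int
) -> list[list[OrfRecord]]:
    """Split records into expression bins, bin 1 = highest expressers.

    Records are sorted by expression descending (ties broken by gene_id so
    the partition is deterministic) and cut into near-equal bins; when the
    count does not divide evenly the earlier bins take one extra record
    each.  Every record must carry a positive expression value.
    """
    recs = list(records)
    for r in recs:
        if r.expression is None:
            raise ValueError(f"{r.gene_id}: missing expression")
        if r.expression <= 0:
            raise ValueError(f"{r.gene_id}: expression must be > 0 for partitioning")
    if n_bins < 1 or n_bins > len(recs):
        raise ValueError(f"cannot split {len(recs)} records into {n_bins} bins")
    recs.sort(key=lambda r: (-r.expression, r.gene_id))
    base, rem = divmod(len(recs), n_bins)
    bins: list[list[OrfRecord]] = []
    start = 0
    for i in range(n_bins):
        size = base + (1 if i < rem else 0)
        bins.append(recs[start : start + size])
        start += size
    return bins


def window_base_matrix(
    records: Iterable[OrfRecord],
    window: tuple[int, int] = DEFAULT_WINDOW,
    anchor: str = "start_codon",
    region: str = "cds",
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Per-record base-indicator tensor over a window, for resampling.

    Returns ``(M, positions)`` where ``M[i, j, b]`` is 1 iff record i
    contributes base b at window position j.  Summing M over a subset of
    records gives exactly the pooled counts ``align_and_count`` would
    produce for that subset, so window statistics of arbitrary subsets can
    be recomputed cheaply inside bootstrap loops.
    """
    lo, hi = int(window[0]), int(window[1])
    positions = tuple(range(lo, hi + 1))
    recs = list(records)
    M = np.zeros((len(recs), len(positions), 4), dtype=np.uint8)
    for i, r in enumerate(recs):
        seq = r.spanning
        a0 = _anchor_index(r, anchor)
        blo, bhi = _region_bounds(r, region)
        for j, p in enumerate(positions):
            k = _offset_index(a0, p)
            if blo <= k < bhi:
                b = _BASE_INDEX.get(seq[k])
                if b is not None:
                    M[i, j, b] = 1
    return M, positions


def g2_mean_from_counts(
    counts: np.ndarray,
    positions: tuple[int, ...],
    background: BackgroundFrequencies,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Mean G LOR at codon-position-2 sites of pooled window counts."""
    n = counts.sum(axis=1)
    lor = lor_from_counts(counts, n, background.as_array(), pseudocount)
    sites = [j for j, p in enumerate(positions) if codon_position(p) == 2]
    vals = lor[sites, _BASE_INDEX["G"]]
    return float(np.nanmean(vals))
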