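"""G1+C2 analysis of ramp-reporter nine-mer libraries.

Large sorted reporter libraries measure expression of constructs that vary
a three-codon (nine-mer) ramp insert.  Each nine-mer is scored by how many
of its codons carry G at codon position 1 or C at codon position 2 — the
G1+C2 count, 0..6 for three codons (7 groups) or 0..4 for a two-codon
subset (5 groups) — and per-group expression histograms and cumulative
frequency curves are compared.  The qualitative signature: at low
expression more G1/C2 is beneficial, at high expression detrimental, so
per-group cumulative curves cross.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import NineMerRecord


def g1c2_count(sequence: str, codon_subset: Sequence[int] = (1, 2, 3)) -> int:
    """Number of selected codons with G at position 1, plus those with C at 2.

    ``codon_subset`` indexes codons within the nine-mer (1-based); the count
    never depends on codon position 3 (the N of GCN).
    """
    if len(sequence) != 9:
        raise ValueError(f"expected a nine-mer, got {len(sequence)} nt")
    subset = tuple(codon_subset)
    if not subset:
        raise ValueError("codon_subset must be non-empty")
    if not set(subset) <= {1, 2, 3}:
        raise ValueError(f"codon_subset must be within {{1,2,3}}, got {subset}")
    count = 0
    for i in subset:
        codon = sequence[3 * (i - 1) : 3 * i]
        count += (codon[0] == "G") + (codon[1] == "C")
    return count


class ExpressionBinScheme:
    """A named, ordered expression-bin scheme with an assignment rule."""

    def __init__(self, name: str, labels: Sequence[str], assign: Callable[[object], str]):
        self.name = name
        self.labels = tuple(labels)
        self._assign = assign

    def assign(self, x) -> str:
        label = self._assign(x)
        assert label in self.labels
        return label

    def ordinal(self, label: str) -> int:
        """1-based rank of a bin label (used as a numeric stand-in)."""
        return self.labels.index(label) + 1

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionBinScheme({self.name!r}, {len(self.labels)} bins)"


def _verma9_assign(x) -> str:
    x = float(x)
    if not (1.0 <= x <= 5.0):
        raise ValueError(f"expression {x} outside [1, 5]")
    if x == 5.0:
        return "5"
    edge = 1.0 + np.floor((x - 1.0) * 2.0) / 2.0
    return f"{edge:g}"


#: Nine half-open width-0.5 bins on [1, 5), labeled by lower edge, plus the
#: singleton bin at exactly 5.
VERMA9 = ExpressionBinScheme(
    "verma9", ("1", "1.5", "2", "2.5", "3", "3.5", "4", "4.5", "5"), _verma9_assign
)

_THREE_LABELS = ("low", "intermediate", "high")


def _three_bin_assign(x) -> str:
    if isinstance(x, str):
        label = x.strip().lower()
        if label in _THREE_LABELS:
            return label
        raise ValueError(f"unknown bin label {x!r}")
    i = int(round(float(x)))
    if i not in (1, 2, 3) or abs(float(x) - i) > 1e-9:
        raise ValueError(f"numeric three-bin expression must be 1, 2 or 3; got {x}")
    return _THREE_LABELS[i - 1]


#: Coarse three-bin scheme of the yeast-style library (labels or 1/2/3).
THREE_BIN = ExpressionBinScheme("low/intermediate/high", _THREE_LABELS, _three_bin_assign)

BIN_SCHEMES = {"verma9": VERMA9, "three": THREE_BIN}


def assign_expression_bin(x, scheme: ExpressionBinScheme = VERMA9) -> str:
    """Bin label for one expression value under a scheme (default verma9)."""
    return scheme.assign(x)


def weighted_expression(bin_fractions: Sequence[float]) -> float:
    """Weighted expression on [1, 5] from a variant's 5-bin read fractions.

    The score is sum_i i * f_i for bins i = 1..5; a variant entirely in bin
    i scores exactly i.
    """
    fr = [float(f) for f in bin_fractions]
    if len(fr) != 5:
        raise ValueError("need exactly 5 bin fractions")
    if any(f < 0 for f in fr):
        raise ValueError("bin fractions must be nonnegative")
    if abs(sum(fr) - 1.0) > 1e-9:
        raise ValueError(f"bin fractions sum to {sum(fr)}, not 1")
    return float(sum(i * f for i, f in zip(range(1, 6), fr)))


def _numeric_expression(rec: NineMerRecord, scheme: ExpressionBinScheme) -> float:
    if isinstance(rec.expression, float):
        return rec.expression
    return float(scheme.ordinal(scheme.assign(rec.expression)))


@dataclass
class GroupedExpressionHistogram:
    """Per-G1+C2-group expression frequencies and cumulative frequencies.

    Groups are the literal integer counts 0 .. 2*|codon_subset| (empty
    groups kept with n = 0 and all-zero frequency rows).
    """

    codon_subset: tuple[int, ...]
    scheme: ExpressionBinScheme
    groups: tuple[int, ...]
    freq: pd.DataFrame  # index = group, columns = bin labels
    cumfreq: pd.DataFrame
    n_per_group: pd.Series
    mean_expression: pd.Series  # numeric (ordinal for label-binned data)
    n_excluded_structured: int = 0

    def nonempty_groups(self) -> list[int]:
        return [g for g in self.groups if self.n_per_group[g] > 0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: group, bin, n, freq, cumfreq."""
        rows = []
        counts = self.freq.mul(self.n_per_group, axis=0)
        for g in self.groups:
            for label in self.scheme.labels:
                rows.append(
                    {
                        "group": g,
                        "bin": label,
                        "n": int(round(counts.loc[g, label])),
                        "freq": self.freq.loc[g, label],
                        "cumfreq": self.cumfreq.loc[g, label],
                    }
                )
        return pd.DataFrame(rows)


def group_histograms(
    records: Iterable[NineMerRecord],
    codon_subset: Sequence[int] = (1, 2, 3),
    exclude_structured: bool = False,
    scheme: ExpressionBinScheme = VERMA9,
) -> GroupedExpressionHistogram:
    """Group nine-mers by G1+C2 count and bin their expression.

    ``exclude_structured`` drops variants flagged as having potential RNA
    secondary structure before grouping (the count dropped is reported on
    the result).
    """
    recs = list(records)
    n_before = len(recs)
    if exclude_structured:
        recs = [r for r in recs if not r.structured]
    n_excluded = n_before - len(recs)
    subset = tuple(codon_subset)
    groups = tuple(range(0, 2 * len(subset) + 1))
    labels = list(scheme.labels)
    counts = pd.DataFrame(0, index=list(groups), columns=labels, dtype=float)
    sums = pd.Series(0.0, index=list(groups))
    ns = pd.Series(0, index=list(groups), dtype=int)
    for r in recs:
        g = g1c2_count(r.sequence, subset)
        label = scheme.assign(r.expression)
        counts.loc[g, label] += 1
        sums[g] += _numeric_expression(r, scheme)
        ns[g] += 1
    with np.errstate(invalid="ignore"):
        freq = counts.div(ns.replace(0, np.nan), axis=0).fillna(0.0)
    cumfreq = freq.cumsum(axis=1)
    mean_expr = sums / ns.replace(0, np.nan)
    return GroupedExpressionHistogram(
        codon_subset=subset,
        scheme=scheme,
        groups=groups,
        freq=freq,
        cumfreq=cumfreq,
        n_per_group=ns,
        mean_expression=mean_expr,
        n_excluded_structured=n_excluded,
    )


@dataclass
class AdjacencyContrast:
    """Histograms and scalar effects for several 2-codon subsets.

    ``effects[pair]`` is the difference in mean expression between the
    highest and lowest non-empty G1+C2 groups of that pair — larger for
    codon pairs whose G1/C2 content matters more (adjacent pairs, if codon
    adjacency amplifies the effect).
    """

    histograms: dict[tuple[int, ...], GroupedExpressionHistogram]
    effects: dict[tuple[int, ...], float]


def adjacency_contrast(
    records: Iterable[NineMerRecord],
    subset_pairs: Sequence[Sequence[int]] = ((1, 2), (2, 3), (1, 3)),
    exclude_structured: bool = False,
    scheme: ExpressionBinScheme = VERMA9,
) -> AdjacencyContrast:
    """Per-pair grouped histograms plus top-minus-bottom mean-expression effects."""
    recs = list(records)
    histograms: dict[tuple[int, ...], GroupedExpressionHistogram] = {}
    effects: dict[tuple[int, ...], float] = {}
    for pair in subset_pairs:
        pair = tuple(pair)
        if not set(pair) <= {1, 2, 3}:
            raise ValueError(f"codon pair {pair} not within {{1,2,3}}")
        hist = group_histograms(recs, pair, exclude_structured, scheme)
        histograms[pair] = hist
        present = hist.nonempty_groups()
        if len(present) < 2:
            effects[pair] = float("nan")
        else:
            effects[pair] = float(
                hist.mean_expression[present[-1]] - hist.mean_expression[present[0]]
            )
    return AdjacencyContrast(histograms=histograms, effects=effects)
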