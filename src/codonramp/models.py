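"""Model/Results front-ends over the profiling and reporter analyses.

Two statsmodels-style entry points:

* :class:`CodonPeriodicityModel` — built from an ORF record collection;
  ``fit()`` aligns the genes at an anchor, computes the LOR profile and the
  superimposed-codon window statistic, and returns a results object that
  can additionally run the resampling test of G2 depression for a focal
  subset.

* :class:`RampReporterModel` — built from a nine-mer library; ``fit()``
  groups variants by G1+C2 count, bins expression, and returns per-group
  histograms, cumulative curves and effect summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from . import bootstrap as _bootstrap
from . import periodicity as _per
from . import reporter as _rep
from .seqio import NineMerRecord, OrfRecord


class CodonPeriodicityModel:
    """Positional-periodicity analysis of an anchored ORF collection.

    Parameters
    ----------
    records : iterable of OrfRecord
        The gene collection (also the background population for tests).
    background : BackgroundFrequencies, optional
        LOR background; defaults to the fixed yeast-ORF vector.
    pseudocount : float
        Added to every base count per position (default 0.5); set to 0 for
        large collections if exact zero-count sentinels are wanted.
    """

    def __init__(
        self,
        records: Iterable[OrfRecord],
        background: _per.BackgroundFrequencies | None = None,
        pseudocount: float = _per.DEFAULT_PSEUDOCOUNT,
    ):
        self.records = list(records)
        self.background = (
            background if background is not None else _per.yeast_orf_background()
        )
        self.pseudocount = float(pseudocount)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CodonPeriodicityModel":
        """Build from a DataFrame with gene_id/utr5/cds/utr3 (+ optional
        expression, msms_detected) columns."""
        from .seqio import _records_from_frame

        return cls(_records_from_frame(df.astype(str).replace("nan", "")), **kwargs)

    def fit(
        self,
        anchor: str = "start_codon",
        positions: Sequence[int] | None = None,
        region: str = "cds",
        window: tuple[int, int] = _per.DEFAULT_WINDOW,
    ) -> "CodonPeriodicityResults":
        """Align, profile, and summarize the window codon statistic."""
        if positions is None:
            positions = (
                range(1, 61) if anchor == "start_codon" else range(-60, 0)
            )
        pfm = _per.align_and_count(self.records, anchor, positions, region)
        profile = _per.lor_profile(pfm, self.background, self.pseudocount)
        stat = (
            _per.codon_window_stat(profile, window)
            if anchor == "start_codon" and all(p > 0 for p in pfm.positions)
            and set(range(window[0], window[1] + 1)) <= set(pfm.positions)
            else None
        )
        return CodonPeriodicityResults(self, pfm, profile, stat, window)


@dataclass
class CodonPeriodicityResults:
    """Fitted profile plus window summaries and resampling tests."""

    model: CodonPeriodicityModel
    pfm: _per.PositionFrequencyMatrix
    profile: _per.LorProfile
    window_stat: _per.CodonWindowStat | None
    window: tuple[int, int]

    @property
    def g2_mean(self) -> float:
        if self.window_stat is None:
            raise ValueError("no window statistic for this anchor/position range")
        return self.window_stat.g2_mean

    def test_g2_depression(
        self,
        focal: Iterable[OrfRecord],
        B: int = 10_000,
        seed: int = 0,
        alternative: str = "less",
    ) -> _bootstrap.BootstrapResult:
        """Resampling test of the focal subset's G2 window mean against the
        model's full collection."""
        return _bootstrap.g2_depression_test(
            focal,
            self.model.records,
            window=self.window,
            background=self.model.background,
            pseudocount=self.model.pseudocount,
            B=B,
            seed=seed,
            alternative=alternative,
        )

    def summary(self) -> str:
        lines = [
            "Codon periodicity profile",
            "=" * 58,
            f"records: {self.pfm.n_records}    anchor: {self.pfm.anchor}"
            f"    pseudocount: {self.model.pseudocount}",
            f"background ({self.model.background.source}): "
            + "  ".join(
                f"{b}={v:.3f}" for b, v in self.model.background.freq.items()
            ),
        ]
        if self.window_stat is not None:
            per = self.window_stat.per_codon_position
            lines.append(
                f"window {self.window[0]}-{self.window[1]} mean LOR by codon position:"
            )
            header = "  pos " + "".join(f"{b:>9}" for b in per.columns)
            lines.append(header)
            for c in per.index:
                lines.append(
                    f"  {c:>3} " + "".join(f"{per.loc[c, b]:>9.4f}" for b in per.columns)
                )
            lines.append(f"G2 depression (mean LOR of G at codon position 2): "
                         f"{self.window_stat.g2_mean:.4f}")
        return "\n".join(lines)

    def plot(self, ax=None, bases: str = "ACGT"):
        from .plotting import plot_lor_profile

        return plot_lor_profile(self.profile, ax=ax, bases=bases)


class RampReporterModel:
    """G1+C2 grouping analysis of a nine-mer reporter library."""

    def __init__(
        self,
        records: Iterable[NineMerRecord],
        scheme: _rep.ExpressionBinScheme | str = _rep.VERMA9,
    ):
        self.records = list(records)
        self.scheme = (
            _rep.BIN_SCHEMES[scheme] if isinstance(scheme, str) else scheme
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "RampReporterModel":
        records = [
            NineMerRecord.from_raw(row.sequence, row.expression,
                                   getattr(row, "structured", False))
            for row in df.itertuples(index=False)
        ]
        return cls(records, **kwargs)

    def fit(
        self,
        codon_subset: Sequence[int] = (1, 2, 3),
        exclude_structured: bool = False,
    ) -> "RampReporterResults":
        hist = _rep.group_histograms(
            self.records, codon_subset, exclude_structured, self.scheme
        )
        return RampReporterResults(self, hist)


@dataclass
class RampReporterResults:
    """Grouped expression histograms plus scalar effect summaries."""

    model: RampReporterModel
    histogram: _rep.GroupedExpressionHistogram

    @property
    def group_effect(self) -> float:
        """Mean-expression difference, highest minus lowest non-empty group."""
        present = self.histogram.nonempty_groups()
        if len(present) < 2:
            return float("nan")
        me = self.histogram.mean_expression
        return float(me[present[-1]] - me[present[0]])

    def adjacency(
        self, subset_pairs: Sequence[Sequence[int]] = ((1, 2), (2, 3), (1, 3))
    ) -> _rep.AdjacencyContrast:
        return _rep.adjacency_contrast(
            self.model.records, subset_pairs, scheme=self.model.scheme
        )

    def summary(self) -> str:
        h = self.histogram
        lines = [
            "Ramp reporter G1+C2 analysis",
            "=" * 58,
            f"variants: {int(h.n_per_group.sum())}"
            f"    codon subset: {h.codon_subset}"
            f"    bins: {h.scheme.name}",
            f"structured variants excluded: {h.n_excluded_structured}",
            "  group        n   mean expression",
        ]
        for g in h.groups:
            n = int(h.n_per_group[g])
            me = h.mean_expression[g]
            me_s = f"{me:.4f}" if n else "   -  "
            lines.append(f"  {g:>5} {n:>8}   {me_s}")
        lines.append(f"top-vs-bottom group effect: {self.group_effect:.4f}")
        return "\n".join(lines)

    def plot_cumulative(self, ax=None):
        from .plotting import plot_group_cumulative

        return plot_group_cumulative(self.histogram, ax=ax)
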