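"""Empirical significance of window statistics by resampling a background.

A focal gene (or AUG-site) subset is compared with B subsets of the same
size drawn uniformly without replacement from the background collection — a
randomization-style null in which the focal labels carry no information.
The one-sided empirical p-value uses the plus-one rule with ties counted as
consistent, so the smallest attainable p is 1/(B+1) and p = 0 is never
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from . import periodicity
from .periodicity import BackgroundFrequencies, DEFAULT_PSEUDOCOUNT, DEFAULT_WINDOW
from .seqio import OrfRecord

log = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    """Observed statistic, resampled null, and empirical one-sided p-value."""

    observed: float
    null_values: np.ndarray
    p_value: float
    B: int
    subset_size: int
    seed: int
    alternative: str
    n_redraws: int = 0

    def summary(self) -> str:
        lines = [
            "Resampling test",
            f"  observed statistic : {self.observed: .6f}",
            f"  null mean (sd)     : {self.null_values.mean(): .6f} ({self.null_values.std(ddof=1):.6f})",
            f"  alternative        : {self.alternative}",
            f"  B / subset / seed  : {self.B} / {self.subset_size} / {self.seed}",
            f"  p-value            : {self.p_value:.6g}",
        ]
        return "\n".join(lines)


def bootstrap_pvalue(
    focal: Sequence,
    background: Sequence,
    stat: Callable[[Sequence], float],
    B: int = 10_000,
    seed: int = 0,
    alternative: str = "less",
    replace: bool = False,
    max_redraws: int = 100,
) -> BootstrapResult:
    """One-sided empirical p-value of ``stat(focal)`` against resampled nulls.

    ``focal`` and ``background`` are arbitrary item sequences (records,
    sites, or rows of a precomputed matrix); ``stat`` maps a sequence of
    items to a real number.  Resamples for which the statistic is undefined
    (NaN or a raised ValueError) are redrawn and counted.
    """
    if alternative not in {"less", "greater"}:
        raise ValueError(f"alternative must be 'less' or 'greater', got {alternative!r}")
    if B < 1:
        raise ValueError("B must be >= 1")
    k = len(focal)
    n_bg = len(background)
    if k > n_bg and not replace:
        raise ValueError(f"focal size {k} exceeds background size {n_bg}")
    observed = float(stat(focal))
    rng = np.random.default_rng(seed)
    bg_is_array = isinstance(background, np.ndarray)
    nulls = np.empty(B, dtype=float)
    n_redraws = 0
    for b in range(B):
        for _ in range(max_redraws + 1):
            idx = rng.choice(n_bg, size=k, replace=replace)
            sub = background[idx] if bg_is_array else [background[i] for i in idx]
            try:
                v = float(stat(sub))
            except ValueError:
                v = float("nan")
            if v == v:
                break
            n_redraws += 1
        else:
            raise RuntimeError(f"statistic undefined on {max_redraws} consecutive resamples")
        nulls[b] = v
    if n_redraws:
        log.info("redrew %d resamples with undefined statistic", n_redraws)
    if alternative == "less":
        consistent = int((nulls <= observed).sum())
    else:
        consistent = int((nulls >= observed).sum())
    p = (1 + consistent) / (B + 1)
    return BootstrapResult(
        observed=observed,
        null_values=nulls,
        p_value=p,
        B=B,
        subset_size=k,
        seed=seed,
        alternative=alternative,
        n_redraws=n_redraws,
    )


def g2_depression_test(
    focal: Iterable[OrfRecord],
    background_records: Iterable[OrfRecord],
    window: tuple[int, int] = DEFAULT_WINDOW,
    background: BackgroundFrequencies | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    anchor: str = "start_codon",
    region: str = "cds",
    B: int = 10_000,
    seed: int = 0,
    alternative: str = "less",
) -> BootstrapResult:
    """Test whether a gene subset's window G2 mean is unusually depressed.

    The statistic is the mean G LOR at codon-position-2 sites of the window
    (default 7-22), recomputed per resample from pooled counts via a
    precomputed per-record indicator tensor so large B is cheap.
    """
    bg_freq = background if background is not None else periodicity.yeast_orf_background()
    M_focal, positions = periodicity.window_base_matrix(focal, window, anchor, region)
    M_bg, _ = periodicity.window_base_matrix(background_records, window, anchor, region)

    def stat(rows) -> float:
        pooled = np.asarray(rows, dtype=np.int64).sum(axis=0)
        return periodicity.g2_mean_from_counts(pooled, positions, bg_freq, pseudocount)

    return bootstrap_pvalue(
        M_focal, M_bg, stat, B=B, seed=seed, alternative=alternative
    )
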