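"""Synthetic ORF collections and reporter libraries with known ground truth.

The generators emulate the statistical structure the analyses assume so the
whole pipeline is testable without genome downloads:

* ORF sets: UTRs are i.i.d. background (no periodicity); CDS codons are
  drawn from a stop-free codon distribution whose positional marginals
  carry injected log2-odds effects — G1 and C2 enrichment and G2 depression
  — inside a ramp codon range, with effect sizes scaled by each gene's
  expression stratum.  Effects are parameterized in log2-odds so ground
  truth is directly comparable to estimated LOR profiles.

* Reporter libraries: nine-mers uniform over stop-free codon triplets,
  expression a noisy piecewise-linear function of the G1+C2 count whose
  slope switches sign between the low- and high-baseline regimes (the
  accelerator/brake pattern).

Effects are injected as exact target marginals (f_G = bg_G * 2**offset,
remaining bases renormalized proportionally) and codon distributions are
fitted to those marginals by iterative proportional fitting over the 61
stop-free codons, so the realized positional frequencies match the targets
despite stop exclusion and the injected offset is recoverable as-is from a
LOR profile.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .periodicity import BackgroundFrequencies, yeast_orf_background
from .seqio import NUCLEOTIDES, OrfRecord, NineMerRecord, STOP_CODONS

ALL_CODONS = tuple("".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3))
NONSTOP_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
_STOP_TUPLE = ("TAA", "TAG", "TGA")


@dataclass
class OrfSimParams:
    """Study conditions for a synthetic ORF collection.

    ``g1_boost`` / ``c2_boost`` / ``g2_depress`` are log2-odds offsets (in
    LOR units) applied to the positional marginals of codons in
    ``ramp_codons`` (1-based, inclusive).  ``stratum_gradient`` scales the
    offsets by expression stratum: genes are ranked into ``n_strata``
    equal bins by expression and a stratum with center quantile q gets
    multiplier 1 + gradient * (q - 0.5), so at gradient 2 the top decile
    carries 1.9x the nominal effect and the bottom decile 0.1x.  MS/MS
    detection is Bernoulli with probability quantile**detection_exponent,
    concentrating detection in high expressers.
    """

    n_genes: int = 5791
    cds_codons: int = 60
    utr5_len: int = 50
    utr3_len: int = 50
    background: BackgroundFrequencies | None = None
    g1_boost: float = 0.3
    c2_boost: float = 0.3
    g2_depress: float = 0.3
    ramp_codons: tuple[int, int] = (3, 8)
    stratum_gradient: float = 2.0
    n_strata: int = 10
    detection_exponent: float = 4.0
    expression_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        lo, hi = self.ramp_codons
        if not (2 <= lo <= hi <= self.cds_codons - 1):
            raise ValueError(
                f"ramp_codons {self.ramp_codons} must fit between codon 2 and the stop"
            )
        if self.utr5_len < 0 or self.utr3_len < 0 or self.cds_codons < 3:
            raise ValueError("invalid sequence lengths")


@dataclass
class ReporterSimParams:
    """Study conditions for a synthetic sorted-reporter nine-mer library.

    Baseline expression per variant is 1 + 4*Beta(alpha, beta) on [1, 5];
    the G1+C2 count adds ``effect_low`` per unit when the baseline is below
    ``regime_threshold`` and ``effect_high`` per unit above it (typically
    opposite signs), plus Gaussian noise; results are clamped to [1, 5].
    """

    n_variants: int = 215_414
    codon_offset: int = 3
    effect_low: float = 0.2
    effect_high: float = -0.2
    regime_threshold: float = 3.0
    baseline_alpha: float = 2.0
    baseline_beta: float = 2.0
    noise_sd: float = 0.4
    p_structured: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be positive")
        if not (0.0 <= self.p_structured <= 1.0):
            raise ValueError("p_structured must be in [0, 1]")


def target_marginals(
    background: BackgroundFrequencies,
    g1_boost: float = 0.0,
    c2_boost: float = 0.0,
    g2_depress: float = 0.0,
) -> np.ndarray:
    """Per-codon-position target base frequencies (3 x 4, base order ACGT).

    At codon position 1, G's frequency is set to bg_G * 2**g1_boost and the
    other bases are scaled proportionally; at position 2, C and G are set to
    bg_C * 2**c2_boost and bg_G * 2**(-g2_depress) and the remainder is
    shared by A and T proportionally to background; position 3 is pure
    background.  The set frequencies must leave positive mass for the rest.
    """
    bg = background.as_array()  # A C G T
    m = np.tile(bg, (3, 1)).astype(float)
    # position 1: pin G
    fg = bg[2] * 2.0**g1_boost
    if fg >= 1.0:
        raise ValueError("g1_boost drives G frequency to >= 1")
    scale = (1.0 - fg) / (1.0 - bg[2])
    m[0] = bg * scale
    m[0, 2] = fg
    # position 2: pin C and G
    fc = bg[1] * 2.0**c2_boost
    fg2 = bg[2] * 2.0 ** (-g2_depress)
    rest = 1.0 - fc - fg2
    if rest <= 0.0:
        raise ValueError("position-2 offsets leave no probability for A/T")
    at_scale = rest / (bg[0] + bg[3])
    m[1] = bg * at_scale
    m[1, 1] = fc
    m[1, 2] = fg2
    assert np.allclose(m.sum(axis=1), 1.0)
    return m


def stopfree_codon_distribution(
    marginals: np.ndarray, tol: float = 1e-12, max_iter: int = 500
) -> np.ndarray:
    """Stop-free 64-codon distribution with prescribed positional marginals.

    Starts from the product of the per-position marginals with the three
    stop codons zeroed and applies iterative proportional fitting until the
    realized marginals match the targets.  Returns a length-64 probability
    vector (stop entries exactly 0) in ACGT lexicographic codon order.
    """
    m = np.asarray(marginals, dtype=float)
    W = m[0][:, None, None] * m[1][None, :, None] * m[2][None, None, :]
    # zero TAA, TAG, TGA (A=0, C=1, G=2, T=3)
    W[3, 0, 0] = W[3, 0, 2] = W[3, 2, 0] = 0.0
    axes = [(1, 2), (0, 2), (0, 1)]
    for _ in range(max_iter):
        worst = 0.0
        for ax, other in enumerate(axes):
            cur = W.sum(axis=other)
            worst = max(worst, float(np.abs(cur - m[ax]).max()))
            ratio = np.where(cur > 0, m[ax] / np.where(cur > 0, cur, 1.0), 0.0)
            shape = [1, 1, 1]
            shape[ax] = 4
            W *= ratio.reshape(shape)
        if worst < tol:
            break
    else:  # pragma: no cover
        raise RuntimeError("IPF failed to converge")
    W /= W.sum()
    return W.reshape(64)


@dataclass
class OrfSimTruth:
    """Ground truth accompanying a simulated ORF collection."""

    params: OrfSimParams
    genes: pd.DataFrame  # gene_id, expression, quantile, stratum, multiplier, msms_detected
    stratum_multipliers: np.ndarray


def _draw_strings(rng, probs: np.ndarray, n: int, length: int) -> list[str]:
    if length == 0:
        return [""] * n
    bases = np.array(list(NUCLEOTIDES))
    draws = rng.choice(4, size=(n, length), p=probs)
    return ["".join(row) for row in bases[draws]]


def simulate_orf_set(params: OrfSimParams) -> tuple[list[OrfRecord], OrfSimTruth]:
    """Generate an ORF collection with injected ramp periodicity.

    Returns the records and an :class:`OrfSimTruth` carrying the per-gene
    expression strata and effect multipliers.  Reproducible: the same
    params (including seed) give byte-identical collections.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    bg = p.background if p.background is not None else yeast_orf_background()
    bgv = bg.as_array()
    n = p.n_genes

    expression = rng.lognormal(mean=0.0, sigma=p.expression_sigma, size=n)
    order = np.argsort(np.argsort(-expression))  # 0 = highest expresser
    quantile = 1.0 - (order + 0.5) / n  # in (0, 1), ~1 = top
    stratum = np.minimum((order * p.n_strata) // n, p.n_strata - 1)  # 0 = top
    centers = 1.0 - (np.arange(p.n_strata) + 0.5) / p.n_strata
    multipliers = 1.0 + p.stratum_gradient * (centers - 0.5)
    if (multipliers < 0).any():
        raise ValueError("stratum_gradient produces a negative effect multiplier")
    msms = rng.random(n) < quantile**p.detection_exponent

    base_dist = stopfree_codon_distribution(target_marginals(bg))
    codon_strs = np.array(ALL_CODONS)
    lo, hi = p.ramp_codons
    ramp_slots = list(range(lo, hi + 1))
    body_slots = [c for c in range(2, p.cds_codons) if c not in ramp_slots]

    codons = np.empty((n, p.cds_codons), dtype=np.int64)
    codons[:, 0] = ALL_CODONS.index("ATG")
    stop_idx = np.array([ALL_CODONS.index(c) for c in _STOP_TUPLE])
    codons[:, -1] = stop_idx[rng.integers(0, 3, size=n)]
    if body_slots:
        body = rng.choice(64, size=(n, len(body_slots)), p=base_dist)
        codons[:, np.array(body_slots) - 1] = body
    for s in range(p.n_strata):
        mask = stratum == s
        k = int(mask.sum())
        if k == 0:
            continue
        mult = multipliers[s]
        dist = stopfree_codon_distribution(
            target_marginals(
                bg, p.g1_boost * mult, p.c2_boost * mult, p.g2_depress * mult
            )
        )
        ramp = rng.choice(64, size=(k, len(ramp_slots)), p=dist)
        codons[np.ix_(mask, np.array(ramp_slots) - 1)] = ramp

    utr5s = _draw_strings(rng, bgv, n, p.utr5_len)
    utr3s = _draw_strings(rng, bgv, n, p.utr3_len)
    gene_ids = [f"g{i:05d}" for i in range(n)]
    records = []
    for i in range(n):
        cds = "".join(codon_strs[codons[i]])
        records.append(
            OrfRecord(
                gene_id=gene_ids[i],
                utr5=utr5s[i],
                cds=cds,
                utr3=utr3s[i],
                expression=float(expression[i]),
                msms_detected=bool(msms[i]),
                complete_cds=True,
            )
        )
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "expression": expression,
            "quantile": quantile,
            "stratum": stratum + 1,  # 1 = top stratum, matching bin numbering
            "multiplier": multipliers[stratum],
            "msms_detected": msms,
        }
    )
    truth = OrfSimTruth(params=p, genes=genes, stratum_multipliers=multipliers)
    return records, truth


@dataclass
class ReporterSimTruth:
    """Ground truth accompanying a simulated reporter library."""

    params: ReporterSimParams
    variants: pd.DataFrame  # baseline, g1c2_count, regime, expression, structured


# per-codon G1/C2 contribution for the uniform stop-free composition
_G1C2_CONTRIB = np.array(
    [(c[0] == "G") + (c[1] == "C") for c in NONSTOP_CODONS], dtype=np.int64
)


def stopfree_group_probabilities(codon_subset_size: int = 3) -> np.ndarray:
    """Analytic G1+C2 group probabilities under uniform stop-free codons.

    Per codon, of the 61 stop-free codons 4 contribute 2 (GCN), 24
    contribute 1 and 33 contribute 0; the group distribution over k codons
    is the k-fold convolution.
    """
    per = np.bincount(_G1C2_CONTRIB, minlength=3) / len(NONSTOP_CODONS)
    dist = np.array([1.0])
    for _ in range(codon_subset_size):
        dist = np.convolve(dist, per)
    return dist


def simulate_reporter(
    params: ReporterSimParams,
) -> tuple[list[NineMerRecord], ReporterSimTruth]:
    """Generate a nine-mer reporter library with a two-regime G1+C2 effect."""
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_variants
    idx = rng.integers(0, len(NONSTOP_CODONS), size=(n, 3))
    counts = _G1C2_CONTRIB[idx].sum(axis=1)
    codon_arr = np.array(NONSTOP_CODONS)
    seqs = ["".join(row) for row in codon_arr[idx]]
    baseline = 1.0 + 4.0 * rng.beta(p.baseline_alpha, p.baseline_beta, size=n)
    low = baseline < p.regime_threshold
    slope = np.where(low, p.effect_low, p.effect_high)
    expr = np.clip(baseline + slope * counts + rng.normal(0.0, p.noise_sd, size=n), 1.0, 5.0)
    structured = rng.random(n) < p.p_structured
    records = [
        NineMerRecord(
            sequence=seqs[i],
            expression=float(expr[i]),
            structured=bool(structured[i]),
            codon_offset=p.codon_offset,
        )
        for i in range(n)
    ]
    variants = pd.DataFrame(
        {
            "baseline": baseline,
            "g1c2_count": counts,
            "regime": np.where(low, "low", "high"),
            "expression": expr,
            "structured": structured,
        }
    )
    return records, ReporterSimTruth(params=p, variants=variants)
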