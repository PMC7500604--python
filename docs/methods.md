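# Methods

## The model

Protein-coding sequences carry a 3-nucleotide compositional periodicity:
relative to the pooled nucleotide frequencies of ORFs, G is overrepresented
at codon position 1 (G1), C at codon position 2 (C2), and G is
underrepresented at codon position 2 (the "G2 depression").  The pattern is
strongest in the first few codons of the ORF — the translation-initiation
ramp — and its strength scales with protein expression.  `codonramp`
quantifies the pattern with positional log2 odds ratios.

Genes are aligned at an anchor (the annotated start AUG, the stop codon, or
an alternative AUG), positions are 1-based in both directions with no
position 0, and at each aligned position p the profile is

    LOR[p][b] = log2( (count[p][b] + a) / (n[p] + 4a) / background[b] ),

where `n[p]` is the number of genes contributing at p (genes too short to
reach p, or with an N there, drop out at that position only), `a` is a
pseudocount and `background` is a fixed frequency vector over {A,C,G,T}.
The default background is the pooled composition of all annotated yeast
ORFs (A 0.326, C 0.192, G 0.204, T 0.278); `compute_background` derives the
analogous vector for any input collection.

The ramp summary statistic averages the profile over a nucleotide window,
default 7–22 inclusive, after classing each position by codon position
`((p-1) mod 3) + 1`.  The headline quantity `g2_mean` is the mean LOR of G
over the window's codon-position-2 sites {8, 11, 14, 17, 20}.  The window
is a nucleotide range rather than a codon range; because the codon classes
are computed per nucleotide, a window stated as "codons 3–7/8" and one
stated as "nucleotides 7–22" give the identical G2 statistic, so the two
conventions are interchangeable here.  Both ends are configurable.

## Significance by resampling

A focal subset (MS/MS-detected genes, an expression decile, a set of
alternative-AUG anchors) is compared against its parent collection by
drawing B subsets of the same size uniformly **without replacement** from
the parent and recomputing the window statistic on each — a
randomization-style null in which membership in the focal subset is
uninformative.  The one-sided empirical p-value uses the plus-one rule with
ties counted as consistent,

    p = (1 + #{null consistent with the alternative}) / (B + 1),

so p = 0 is never reported and the smallest attainable p is 1/(B+1).
Defaults: B = 10,000, alternative = "less" (depression).  With-replacement
resampling is available behind a flag.  Resamples on which the statistic is
undefined are redrawn and counted.  For large B the statistic is evaluated
from pooled counts of a precomputed per-record indicator tensor
(`window_base_matrix`), which is exactly equivalent to re-running the
alignment tally on each resample.

Calibration note: because the focal subset and the resamples are
exchangeable under the null, P(p <= k/(B+1)) = k/(B+1) up to ties, which the
type-I-error suite verifies empirically.

## Alternative start sites

`find_augs` scans for ATG triplets upstream (anywhere in the 5'UTR, with
triplets allowed to run across the UTR/CDS junction, since a uORF may
overlap the main ORF) or downstream (CDS positions 2–100 by default,
inclusive).  Frames are classed relative to the annotated start: frame 1 is
the annotated frame, frames 2 and 3 are +1 and +2 nt shifts; for a site
whose A sits at 0-based distance d from the annotated A, frame =
(d mod 3) + 1.  Frame-3 sites are detected and labeled but excluded from
default reports, which concentrate on frames 1 and 2.  `align_at_augs`
re-anchors profiles at each site's A (= position 1), so a downstream window
fed to the codon statistic is read in the alternative AUG's own frame.
`sample_random_augs` draws matched comparison sets for the resampling test;
matching by frame and location is achieved by sampling within the
caller-filtered site list.

## Reporter libraries

Nine-mer (three-codon) ramp variants are scored by `g1c2_count`: the number
of selected codons with G at position 1 plus the number with C at position
2 — 0..6 over three codons (7 groups), 0..4 over a codon pair (5 groups).
Counts never depend on the wobble position.  Expression is binned by a
pluggable scheme: `verma9` (nine half-open width-0.5 bins on [1, 5) labeled
by lower edge, plus a singleton bin at exactly 5) for the continuous-scale
library, or a coarse low/intermediate/high scheme for label-binned data.
`weighted_expression` converts a variant's five sorted-bin read fractions
to the 1–5 scale as sum(i * f_i).  Variants flagged as potentially
structured can be excluded before grouping; variants with an in-frame stop
codon are rejected at load time with counts reported.  The adjacency
contrast recomputes the grouped histograms for codon pairs and summarizes
each pair by the mean-expression difference between its highest and lowest
non-empty groups.

## Synthetic data

The generators produce data with the statistical structure the analyses
assume, plus ground truth, so every stage is testable end to end.

**ORF sets.**  UTRs are i.i.d. background (no periodicity).  CDS codons are
drawn from a stop-free codon distribution; inside the ramp (codons 3–8 by
default) the positional marginals carry injected log2-odds offsets for G1,
C2 and G2.  Two numerical choices matter:

* Offsets are injected as *exact target marginals*: the affected base is
  pinned at `background * 2**offset` and the remaining bases are rescaled
  proportionally.  Naively multiplying by `2**offset` and renormalizing
  would shift the realized LOR by `-log2(Z)` (about 0.15 at an offset of
  1), breaking the correspondence between injected and estimated effects.
* Internal stop codons are never generated (the final codon is uniform over
  TAA/TAG/TGA).  Simply rejecting stops would bias the realized position-2
  G frequency by another ~0.04 in LOR units, so each codon distribution is
  fitted by iterative proportional fitting over the 61 stop-free codons to
  match the target marginals exactly.  The result: an injected G2
  depression of d is recovered by the estimator as -d up to sampling noise,
  making parameter recovery a sharp test.

Expression is lognormal(0, 1).  Genes are ranked into ten strata and a
stratum at quantile q scales all ramp offsets by `1 + gradient*(q - 0.5)`;
the default gradient 2.0 gives the top decile 1.9x the nominal effect and
the bottom decile 0.1x.  Detection flags are Bernoulli(quantile^4),
concentrating detection in high expressers (expected detected fraction
1/5).  The default effect sizes (g1_boost = c2_boost = g2_depress = 0.3)
were chosen so that, combined with the gradient, the genome-wide ramp G2
depression is about -0.3 and the detected subset's about -0.45 — the scale
of the reported yeast profiles.  These defaults are the package's study
conditions; experiments that need a clean single-effect configuration
(e.g. parameter recovery) set the other offsets and the gradient to zero
explicitly.

**Reporter libraries.**  Nine-mers are uniform over stop-free codon
triplets (per codon: 4/61 contribute 2 to the G1+C2 count, 24/61 contribute
1, 33/61 contribute 0, so group sizes follow the 3-fold convolution).
Baseline expression is 1 + 4*Beta(2, 2); the G1+C2 count adds +0.2 per unit
below baseline 3 and -0.2 per unit above it, plus N(0, 0.4) noise, clamped
to [1, 5].  This two-regime ("accelerator/brake") structure makes the
per-group cumulative expression curves cross, the qualitative pattern the
grouped-histogram analysis is designed to reveal.  The generator does not
attempt to match real codon-usage, tRNA-pool or expression distributions,
so passing tests demonstrate correctness of the estimators under the
assumed structure, not biological fidelity of any particular dataset.

## Defaults and numerical choices

| parameter | default | rationale |
|---|---|---|
| background | yeast-ORF vector | fixed published composition; `computed` available |
| pseudocount a | 0.5 per base/position | Jeffreys-style; keeps small-fixture LOR finite; 0 allowed for large collections (zero counts then yield -inf sentinels, flagged) |
| window | nucleotides 7–22 | ramp codons 3–8; position-2 sites 8,11,14,17,20 |
| B | 10,000 | smallest attainable p 1e-4, below the 0.001 reporting level |
| expression bins | 10 (bin 1 = top) | decile partition; earlier bins absorb the remainder, ties broken by gene_id for determinism |
| downstream AUG scan | 2–100 | inclusive; excludes the annotated start |

Degenerate inputs: empty record collections and windows outside the profile
raise; positions nobody reaches are emitted as missing (NaN), not zero; a
computed background may contain zeros but LOR profiling then refuses it.

## Problem sizes used in the checks

The automated checks run at desk scale on one CPU: genome-scale collections
are emulated at n = 5,791 genes of 60 codons; parameter recovery uses 2,000
genes (±0.1 tolerance at an injected depression of 1.0); type-I-error
calibration uses 1,000 replications at B = 999 on a 500-gene null
collection (expected 5% ± 2%); the reporter pattern uses the full default
library size.  Real-data analyses of whole transcriptomes are I/O-bound but
use the same code paths.

## Known limitations

* The generator's per-codon independence ignores codon-pair and amino-acid
  constraints of real ORFs; the stratum model is a step function of
  expression rank rather than a smooth dose-response.
* Structure-exclusion flags are consumed, never predicted; no RNA folding
  is performed.
* Upstream-AUG analyses apply no maximal-distance filter and do not treat
  terminated uORFs specially; callers can pre-filter the site list.
* No multiple-testing correction across windows or subsets: the resampling
  test reports single-window p-values.
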