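# codonramp

Tools for quantifying the 3-nucleotide **GCN periodicity** of protein-coding
sequences — the enrichment of G at codon position 1 (G1) and C at codon
position 2 (C2), and the depression of G at codon position 2 (G2) — with a
focus on the translation-initiation **ramp** (roughly codons 3–8), where the
pattern is strongest and tracks protein expression.  Intended for
computational biologists analyzing ORF composition, alternative start-codon
usage, and large sorted reporter-library screens.

## What it computes

Genes are aligned at an anchor (start codon, stop codon, or any alternative
AUG) and each aligned position gets a log2 odds ratio against a background
frequency vector:

    LOR[p][b] = log2( freq_obs[p][b] / freq_background[b] )

The default background is the pooled composition of annotated yeast ORFs
(A 0.326, C 0.192, G 0.204, T 0.278).  Ramp periodicity is summarized by the
mean LOR per codon position over a nucleotide window (default 7–22); the
headline statistic `g2_mean` is the mean G LOR at the window's
codon-position-2 sites {8, 11, 14, 17, 20}.  Significance of a focal gene
subset (e.g. genes detected by MS/MS, or a top expression decile) is
assessed by resampling same-size subsets from the full collection
(one-sided empirical p with the plus-one rule).

The package also scans and frame-classifies upstream/downstream AUGs
(uORFs, leaky-scanning starts) and re-anchors profiles in the alternative
frame; partitions nine-mer reporter libraries into G1+C2 groups (7 groups
over three codons, 5 over a pair) with binned expression histograms and
cumulative curves; and generates synthetic ORF collections and reporter
libraries with known injected effects, in LOR units, for end-to-end
validation.  See `docs/methods.md` for the model, defaults and numerical
choices.

## Worked example

```python
import codonramp as cr

# a synthetic collection under the default study conditions:
# ramp G1/C2 enrichment and G2 depression scaling with expression
records, truth = cr.simulate_orf_set(cr.OrfSimParams(n_genes=1000, seed=42))

res = cr.CodonPeriodicityModel(records).fit()
print(res.summary())
```

```
Codon periodicity profile
==========================================================
records: 1000    anchor: start_codon    pseudocount: 0.5
background (yeast_orf_default): A=0.326  C=0.192  G=0.204  T=0.278
window 7-22 mean LOR by codon position:
  pos         A        C        G        T
    1   -0.1017  -0.0723   0.2719  -0.0630
    2   -0.0446   0.3242  -0.3209   0.0082
    3   -0.0630  -0.0325   0.0702   0.0382
G2 depression (mean LOR of G at codon position 2): -0.3209
```

Codon position 1 is G-enriched (+0.27), position 2 is C-enriched (+0.32)
and G-depressed (−0.32): the GCN signature.  Is the depression stronger in
the detected (high-expression) genes than expected for a random subset of
the same size?

```python
detected = [r for r in records if r.msms_detected]
test = res.test_g2_depression(detected, B=9999, seed=0)
print(test.summary())
```

```
Resampling test
  observed statistic : -0.599661
  null mean (sd)     : -0.330698 (0.096783)
  alternative        : less
  B / subset / seed  : 9999 / 188 / 0
  p-value            : 0.0046
```

The 188 detected genes have a window G2 mean of −0.60 versus −0.33 for
random subsets — depressed well beyond resampling noise (p ≈ 0.005; at
genome scale, n ≈ 5,800, the same contrast reaches p < 0.001).

The same stages are available from the shell:

```sh
codonramp simulate orfs --n 1000 --seed 42 --out run/
codonramp profile --input run/orfs.tsv --range 1:60 --out run/
codonramp bootstrap --input run/orfs.tsv --focal msms --B 9999 --seed 0 --out run/
```

Reporter libraries follow the same pattern with `RampReporterModel` /
`codonramp reporter` (G1+C2 grouping, expression binning, adjacency
contrasts).

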