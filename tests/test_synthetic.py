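"""Ground-truth recovery and distributional checks for the generators."""

import numpy as np
import pytest
from scipy import stats

from codonramp import (
    CodonPeriodicityModel,
    OrfSimParams,
    ReporterSimParams,
    g2_depression_test,
    simulate_orf_set,
    simulate_reporter,
    yeast_orf_background,
)
from codonramp.reporter import adjacency_contrast, group_histograms
from codonramp.synthetic import (
    NONSTOP_CODONS,
    stopfree_codon_distribution,
    stopfree_group_probabilities,
    target_marginals,
)


def test_same_seed_reproducible():
    params = OrfSimParams(n_genes=30, seed=123)
    recs1, truth1 = simulate_orf_set(params)
    recs2, truth2 = simulate_orf_set(params)
    assert recs1 == recs2
    assert truth1.genes.equals(truth2.genes)
    rparams = ReporterSimParams(n_variants=200, seed=5)
    nm1, _ = simulate_reporter(rparams)
    nm2, _ = simulate_reporter(rparams)
    assert nm1 == nm2


def test_orf_records_are_well_formed():
    records, truth = simulate_orf_set(OrfSimParams(n_genes=25, seed=0))
    assert len(records) == 25
    for r in records:
        assert r.complete_cds
        assert len(r.cds) == 60 * 3
        # no internal stop codons by construction
        internal = [r.cds[i : i + 3] for i in range(3, len(r.cds) - 3, 3)]
        assert not set(internal) & {"TAA", "TAG", "TGA"}
    assert truth.genes.shape[0] == 25


def test_stopfree_distribution_matches_marginals():
    bg = yeast_orf_background()
    m = target_marginals(bg, g1_boost=0.4, c2_boost=0.3, g2_depress=1.0)
    dist = stopfree_codon_distribution(m).reshape(4, 4, 4)
    # prescribed positional marginals are realized exactly
    assert np.allclose(dist.sum(axis=(1, 2)), m[0], atol=1e-9)
    assert np.allclose(dist.sum(axis=(0, 2)), m[1], atol=1e-9)
    assert np.allclose(dist.sum(axis=(0, 1)), m[2], atol=1e-9)
    # stop codons carry zero mass
    assert dist[3, 0, 0] == dist[3, 0, 2] == dist[3, 2, 0] == 0.0
    # injected offsets are readable straight off the marginals
    assert np.log2(m[1][2] / bg.freq["G"]) == pytest.approx(-1.0)
    assert np.log2(m[1][1] / bg.freq["C"]) == pytest.approx(0.3)


def test_null_simulation_has_flat_profile():
    params = OrfSimParams(
        n_genes=800, g1_boost=0, c2_boost=0, g2_depress=0,
        stratum_gradient=0, seed=42,
    )
    records, _ = simulate_orf_set(params)
    res = CodonPeriodicityModel(records).fit()
    # |g2_mean| within ~3 SE of 0 at this sample size
    assert abs(res.g2_mean) < 0.1


def test_injected_depression_recovered():
    params = OrfSimParams(
        n_genes=2000, g1_boost=0, c2_boost=0, g2_depress=1.0,
        stratum_gradient=0, seed=7,
    )
    records, _ = simulate_orf_set(params)
    res = CodonPeriodicityModel(records).fit()
    assert res.g2_mean == pytest.approx(-1.0, abs=0.1)


def test_cds_composition_matches_analytic_distribution():
    """Chi-square goodness of fit of generated ramp codons against the
    offset-adjusted stop-free codon distribution (non-rejection at 1%)."""
    params = OrfSimParams(
        n_genes=400, g1_boost=0.3, c2_boost=0.3, g2_depress=0.3,
        stratum_gradient=0, seed=13,
    )
    records, _ = simulate_orf_set(params)
    expected_dist = stopfree_codon_distribution(
        target_marginals(yeast_orf_background(), 0.3, 0.3, 0.3)
    )
    from codonramp.synthetic import ALL_CODONS

    codon_index = {c: i for i, c in enumerate(ALL_CODONS)}
    counts = np.zeros(64)
    lo, hi = params.ramp_codons
    for r in records:
        for c in range(lo, hi + 1):
            counts[codon_index[r.cds[3 * (c - 1) : 3 * c]]] += 1
    keep = expected_dist > 0
    _, p = stats.chisquare(counts[keep], counts.sum() * expected_dist[keep])
    assert p > 0.01


def test_pipeline_power_and_calibration():
    """The composed simulate -> profile -> resample pipeline detects an
    injected depression (high power) and a null focal subset does not score
    spuriously small p across a handful of replications."""
    null_recs, _ = simulate_orf_set(
        OrfSimParams(n_genes=500, g1_boost=0, c2_boost=0, g2_depress=0,
                     stratum_gradient=0, seed=31)
    )
    hits = 0
    for i in range(10):
        hit_recs, _ = simulate_orf_set(
            OrfSimParams(n_genes=100, g1_boost=0, c2_boost=0, g2_depress=1.0,
                         stratum_gradient=0, seed=1000 + i)
        )
        hit_recs = [
            type(r)("hit_" + r.gene_id, r.utr5, r.cds, r.utr3, r.expression,
                    r.msms_detected, r.complete_cds)
            for r in hit_recs
        ]
        res = g2_depression_test(hit_recs, null_recs + hit_recs, B=199, seed=i)
        hits += res.p_value <= 0.05
    assert hits >= 9  # power > 0.9 at this effect size


def test_reporter_null_case_flat():
    params = ReporterSimParams(
        n_variants=3000, effect_low=0, effect_high=0, noise_sd=0, seed=3
    )
    records, truth = simulate_reporter(params)
    # without any G1+C2 effect, group means differ only by sampling noise;
    # compare well-populated groups (rare high-count groups are too small)
    hist = group_histograms(records)
    big = [g for g in hist.nonempty_groups() if hist.n_per_group[g] >= 200]
    assert len(big) >= 4
    spread = hist.mean_expression[big].max() - hist.mean_expression[big].min()
    assert spread < 0.2


def test_reporter_group_sizes_multinomial():
    params = ReporterSimParams(n_variants=20_000, seed=11)
    records, truth = simulate_reporter(params)
    observed = np.bincount(truth.variants["g1c2_count"], minlength=7)
    expected = stopfree_group_probabilities(3) * params.n_variants
    _, p = stats.chisquare(observed, expected)
    assert p > 0.01
    # analytic composition: per codon 4/61 score 2, 24/61 score 1, 33/61 score 0
    assert stopfree_group_probabilities(1) == pytest.approx(
        np.array([33, 24, 4]) / 61
    )


def test_reporter_two_regime_effect_signs():
    records, truth = simulate_reporter(ReporterSimParams(n_variants=30_000, seed=2))
    df = truth.variants
    low = df[df.regime == "low"]
    high = df[df.regime == "high"]
    slope_low = np.polyfit(low.g1c2_count, low.expression, 1)[0]
    slope_high = np.polyfit(high.g1c2_count, high.expression, 1)[0]
    assert slope_low > 0
    assert slope_high < 0


def test_reporter_structured_flags_rate():
    records, _ = simulate_reporter(
        ReporterSimParams(n_variants=5000, p_structured=0.3, seed=8)
    )
    rate = np.mean([r.structured for r in records])
    assert rate == pytest.approx(0.3, abs=0.03)
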