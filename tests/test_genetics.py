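"""Variant filters, linear scan, LD clumping and polygenic scoring."""

import numpy as np
import pandas as pd
import pytest

from cardiomass import genetics as gen
from cardiomass.errors import AlleleMismatchError, ConfigurationError, ValidationError
from cardiomass.simulate import (
    GenoSimSpec,
    LDBlock,
    generate_genotypes,
    simulate_quantitative_phenotype,
)


@pytest.fixture(scope="module")
def panel():
    return generate_genotypes(GenoSimSpec(n_subjects=800, n_variants=60, seed=1))


# ---------------------------------------------------------------------------
# filters


def test_filter_thresholds_are_inclusive(panel):
    p = generate_genotypes(GenoSimSpec(n_subjects=50, n_variants=10, seed=2))
    p.variants.loc[0, "maf"] = 0.005   # below
    p.variants.loc[1, "maf"] = 0.01    # exactly at -> retained
    p.variants.loc[2, "info"] = 0.29   # below
    p.variants.loc[3, "info"] = 0.30   # exactly at -> retained
    kept = gen.filter_variants(p)
    ids = set(kept.variants["variant_id"])
    assert p.variants["variant_id"][0] not in ids
    assert p.variants["variant_id"][1] in ids
    assert p.variants["variant_id"][2] not in ids
    assert p.variants["variant_id"][3] in ids
    assert kept.n_variants == 8


def test_filter_count_oracle():
    p = generate_genotypes(GenoSimSpec(n_subjects=30, n_variants=100, seed=3))
    fail = np.random.default_rng(4).choice(100, size=7, replace=False)
    p.variants.loc[fail, "info"] = 0.1
    assert gen.filter_variants(p).n_variants == 93


# ---------------------------------------------------------------------------
# linear scan


def test_scan_matches_statsmodels(panel):
    import statsmodels.api as sm

    rng = np.random.default_rng(5)
    y = rng.normal(size=panel.n_subjects)
    covs = rng.normal(size=(panel.n_subjects, 2))
    stats = gen.linear_scan(panel, y, covs)
    for j in (0, 17, 59):
        X = sm.add_constant(np.column_stack([covs, panel.dosages[:, j]]))
        res = sm.OLS(y, X).fit()
        assert stats["beta"][j] == pytest.approx(res.params[-1], abs=1e-10)
        assert stats["se"][j] == pytest.approx(res.bse[-1], abs=1e-10)
        assert stats["p_value"][j] == pytest.approx(res.pvalues[-1], abs=1e-10)


def test_covariate_free_beta_matches_closed_form():
    p = generate_genotypes(GenoSimSpec(n_subjects=10_000, n_variants=5, seed=6))
    y = simulate_quantitative_phenotype(p, noise_sd=1.0, seed=7)
    stats = gen.linear_scan(p, y)
    for j in range(5):
        g = p.dosages[:, j]
        closed = np.cov(g, y, ddof=1)[0, 1] / np.var(g, ddof=1)
        assert stats["beta"][j] == pytest.approx(closed, abs=1e-6)


def test_injected_effect_recovered_within_three_se():
    spec = GenoSimSpec(
        n_subjects=5000, n_variants=50, maf_range=(0.2, 0.2),
        causal_betas={7: 0.3}, seed=8,
    )
    p = generate_genotypes(spec)
    y = simulate_quantitative_phenotype(p, noise_sd=1.0, seed=9)
    stats = gen.linear_scan(p, y)
    assert abs(stats["beta"][7] - 0.3) < 3 * stats["se"][7]


def test_constant_dosage_reported_undefined(panel):
    p = generate_genotypes(GenoSimSpec(n_subjects=100, n_variants=5, seed=10))
    p.dosages[:, 2] = 1.0
    y = np.random.default_rng(11).normal(size=100)
    stats = gen.linear_scan(p, y)
    assert np.isnan(stats["beta"][2]) and np.isnan(stats["p_value"][2])
    assert np.isfinite(stats["beta"].drop(2)).all()


def test_covariate_explaining_phenotype_nulls_all_betas(panel):
    rng = np.random.default_rng(12)
    c = rng.normal(size=panel.n_subjects)
    y = 3.0 * c  # fully explained by the covariate
    stats = gen.linear_scan(panel, y, c[:, None])
    assert np.nanmax(np.abs(stats["beta"])) < 1e-8


# ---------------------------------------------------------------------------
# clumping


def _stats(rows):
    return pd.DataFrame(rows, columns=["variant_id", "chr", "pos", "p_value"]).assign(
        ref="A", alt="G", beta=0.1, se=0.01, n=100
    )


def test_no_significant_variants_gives_empty_list():
    stats = _stats([("a", 1, 100_000, 1e-4)])
    assert gen.clump(stats, lambda x, y: 0.0) == []


def test_close_correlated_pair_keeps_smaller_p():
    stats = _stats([("a", 1, 100_000, 1e-9), ("b", 1, 200_000, 1e-10)])
    leads = gen.clump(stats, lambda x, y: 0.9)
    assert leads == ["b"]


def test_distant_pair_both_lead_regardless_of_ld():
    stats = _stats([("a", 1, 100_000, 1e-10), ("b", 1, 700_000, 1e-9)])
    leads = gen.clump(stats, lambda x, y: 0.99)
    assert sorted(leads) == ["a", "b"]


def test_same_position_different_chromosome_independent():
    stats = _stats([("a", 1, 100_000, 1e-10), ("b", 2, 100_000, 1e-9)])
    assert sorted(gen.clump(stats, lambda x, y: 0.99)) == ["a", "b"]


def test_low_ld_neighbours_both_lead():
    stats = _stats([("a", 1, 100_000, 1e-10), ("b", 1, 150_000, 1e-9)])
    assert sorted(gen.clump(stats, lambda x, y: 0.5)) == ["a", "b"]


def test_missing_ld_entry_is_configuration_error():
    stats = _stats([("a", 1, 100_000, 1e-10), ("b", 1, 150_000, 1e-9)])
    with pytest.raises(ConfigurationError, match="a"):
        gen.clump(stats, {})


def test_clump_input_order_invariance():
    rng = np.random.default_rng(13)
    rows = [(f"v{i}", int(rng.integers(1, 3)), int(rng.integers(1, 2_000_000)),
             float(10.0 ** rng.uniform(-12, -7))) for i in range(40)]
    stats = _stats(rows)
    pair_r2 = {}

    def ld(a, b):
        key = (a, b) if a < b else (b, a)
        if key not in pair_r2:
            pair_r2[key] = float(np.random.default_rng(hash(key) % 2**31).random())
        return pair_r2[key]

    leads = gen.clump(stats, ld)
    shuffled = stats.sample(frac=1.0, random_state=14)
    assert gen.clump(shuffled, ld) == leads


# ---------------------------------------------------------------------------
# PRS


def _weights(panel, alleles, w):
    return pd.DataFrame(
        {"variant_id": panel.variants["variant_id"][: len(w)],
         "effect_allele": alleles, "weight": w}
    )


def test_zero_weights_zero_scores(panel):
    w = _weights(panel, panel.variants["alt"][:5], [0.0] * 5)
    assert (gen.prs_score(panel, w) == 0).all()


def test_single_variant_arithmetic():
    p = generate_genotypes(GenoSimSpec(n_subjects=10, n_variants=3, seed=15))
    p.dosages[:, 0] = 2.0
    w = pd.DataFrame({"variant_id": [p.variants["variant_id"][0]],
                      "effect_allele": [p.variants["alt"][0]], "weight": [0.5]})
    assert (gen.prs_score(p, w) == 1.0).all()


def test_scores_match_double_loop_oracle(panel):
    rng = np.random.default_rng(16)
    use_alt = rng.random(20) < 0.5
    alleles = np.where(use_alt, panel.variants["alt"][:20], panel.variants["ref"][:20])
    w = _weights(panel, alleles, rng.normal(size=20))
    scores = gen.prs_score(panel, w).to_numpy()
    oracle = np.zeros(panel.n_subjects)
    for i in range(panel.n_subjects):
        for j in range(20):
            sign = 1.0 if alleles[j] == panel.variants["alt"][j] else -1.0
            oracle[i] += sign * w["weight"][j] * panel.dosages[i, j]
    assert np.max(np.abs(scores - oracle)) < 1e-12


def test_prs_is_linear_in_weights(panel):
    rng = np.random.default_rng(17)
    alleles = panel.variants["alt"][:10]
    w1 = _weights(panel, alleles, rng.normal(size=10))
    w2 = _weights(panel, alleles, rng.normal(size=10))
    w12 = w1.copy()
    w12["weight"] = w1["weight"] + w2["weight"]
    lhs = gen.prs_score(panel, w12).to_numpy()
    rhs = gen.prs_score(panel, w1).to_numpy() + gen.prs_score(panel, w2).to_numpy()
    # float distributivity: (w1+w2)*d vs w1*d + w2*d round differently
    assert np.max(np.abs(lhs - rhs)) < 1e-12


def test_allele_flip_with_negated_weight_identical(panel):
    rng = np.random.default_rng(18)
    w = _weights(panel, panel.variants["alt"][:8], rng.normal(size=8))
    flipped = w.copy()
    flipped["effect_allele"] = panel.variants["ref"][:8]
    flipped["weight"] = -flipped["weight"]
    assert np.array_equal(gen.prs_score(panel, w).to_numpy(),
                          gen.prs_score(panel, flipped).to_numpy())


def test_unmatched_effect_allele_raises(panel):
    w = pd.DataFrame({"variant_id": [panel.variants["variant_id"][0]],
                      "effect_allele": ["Z"], "weight": [1.0]})
    with pytest.raises(AlleleMismatchError):
        gen.prs_score(panel, w)


def test_duplicate_weight_ids_rejected(panel):
    vid = panel.variants["variant_id"][0]
    w = pd.DataFrame({"variant_id": [vid, vid],
                      "effect_allele": [panel.variants["alt"][0]] * 2, "weight": [1.0, 2.0]})
    with pytest.raises(ValidationError):
        gen.prs_score(panel, w)


def test_absent_weight_variant_skipped(panel):
    w = pd.DataFrame({"variant_id": ["rs_not_here"], "effect_allele": ["A"], "weight": [1.0]})
    assert (gen.prs_score(panel, w) == 0).all()


def test_top_decile_flags_exactly_ten_percent():
    scores = pd.Series(np.random.default_rng(19).normal(size=1000))
    assert gen.prs_quantile_flag(scores, 90.0).sum() == 100
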