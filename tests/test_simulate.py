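import numpy as np
import pandas as pd
import pytest

from snpcnv import association as assoc
from snpcnv.io import ValidationError, VariantCatalogEntry
from snpcnv.simulate import (CallerProfile, CnvLocus, SimulationDesign,
                             blur_to_probabilities, default_caller_profiles,
                             default_design, genetic_component_variance,
                             simulate_cnv_calls, simulate_cohort,
                             simulate_covariates, simulate_genotypes,
                             simulate_phenotypes, simulate_proxy,
                             solve_variance_scaling)


def _design(freq, n=10_000, beta=0.1):
    cat = [VariantCatalogEntry("rs1", "chr1", 100, "A", "G", beta, freq)]
    return SimulationDesign(n_subjects=n, catalog=cat)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def test_hwe_moments_at_half():
    gs = simulate_genotypes(_design(0.5), seed=1)
    d = gs.dosage.ravel()
    n = d.size
    se_mean = np.sqrt(0.5 / n)           # var of dosage = 2 f (1-f) = 0.5
    assert abs(d.mean() - 1.0) < 3 * se_mean
    for g, p in zip((0, 1, 2), (0.25, 0.5, 0.25)):
        prop = (d == g).mean()
        assert abs(prop - p) < 3 * np.sqrt(p * (1 - p) / n)


def test_degenerate_frequencies():
    eps = 1e-12
    assert (simulate_genotypes(_design(eps, n=200), seed=2).dosage == 0).all()
    assert (simulate_genotypes(_design(1 - eps, n=200), seed=2).dosage == 2).all()


def test_empty_catalog_rejected():
    with pytest.raises(ValidationError):
        simulate_genotypes(SimulationDesign(n_subjects=10, catalog=[]), seed=0)


# ---------------------------------------------------------------------------
# Imputation blur
# ---------------------------------------------------------------------------

def test_blur_quality_one_is_degenerate():
    gs = simulate_genotypes(_design(0.3, n=500), seed=3)
    b = blur_to_probabilities(gs, quality=1.0, seed=4)
    het = gs.dosage == 1
    assert np.all(b.probs[het.nonzero()[0], 0] == np.array([0.0, 1.0, 0.0]))
    assert np.array_equal(b.dosage, gs.dosage)


def test_blur_achieves_target_info():
    gs = simulate_genotypes(_design(0.3), seed=5)
    b = blur_to_probabilities(gs, quality=0.8, seed=6)
    f = np.nanmean(gs.dosage) / 2
    info = np.nanvar(b.dosage) / (2 * f * (1 - f))
    assert 0.75 <= info <= 0.85


def test_blur_triples_sum_to_one():
    gs = simulate_genotypes(_design(0.4, n=300), seed=7)
    b = blur_to_probabilities(gs, quality=0.85, seed=8)
    assert np.allclose(np.nansum(b.probs, axis=2), 1.0, atol=1e-12)


def test_blur_rejects_bad_quality():
    gs = simulate_genotypes(_design(0.4, n=10), seed=7)
    for bad in (0.0, -0.5, 1.5):
        with pytest.raises(ValidationError):
            blur_to_probabilities(gs, quality=bad, seed=1)


# ---------------------------------------------------------------------------
# Proxy markers
# ---------------------------------------------------------------------------

def test_proxy_r2_one_is_identity():
    gs = simulate_genotypes(_design(0.5, n=500), seed=9)
    p = simulate_proxy(gs, r2=1.0, seed=10)
    assert np.array_equal(p.dosage, gs.dosage)


def test_proxy_r2_calibration():
    gs = simulate_genotypes(_design(0.5, n=20_000), seed=11)
    p = simulate_proxy(gs, r2=0.8, seed=12)
    r = np.corrcoef(gs.dosage.ravel(), p.dosage.ravel())[0, 1]
    assert 0.77 <= r**2 <= 0.83


def test_proxy_full_flip_is_independent():
    gs = simulate_genotypes(_design(0.5, n=20_000), seed=13)
    p = simulate_proxy(gs, r2=0.5, seed=14, flip_probability=0.5)
    r = np.corrcoef(gs.dosage.ravel(), p.dosage.ravel())[0, 1]
    assert abs(r) < 3 / np.sqrt(gs.n_samples)


def test_proxy_rejects_bad_r2():
    gs = simulate_genotypes(_design(0.5, n=10), seed=13)
    with pytest.raises(ValidationError):
        simulate_proxy(gs, r2=0.0, seed=1)


# ---------------------------------------------------------------------------
# CNV callers
# ---------------------------------------------------------------------------

def _perfect_profiles(k=3):
    return [CallerProfile(f"c{i}", sensitivity=1.0, boundary_jitter_sd=0.0,
                          false_call_rate=0.0) for i in range(k)]


def test_noise_free_callers_reproduce_truth(small_design):
    calls, carriers = simulate_cnv_calls(small_design, _perfect_profiles(),
                                         seed=15)
    expected = int(carriers.to_numpy().sum())
    for plist in calls.values():
        assert len(plist) == expected
        observed = {(c.sample, c.chrom, c.start, c.end, c.state) for c in plist}
        truth = set()
        for locus in small_design.cnv_loci:
            for sample in carriers.index[carriers[locus.region]]:
                truth.add((sample, locus.chrom, locus.start, locus.end, locus.state))
        assert observed == truth


def test_planted_frequency_recovered():
    locus = CnvLocus("del16", "chr16", 21_500_000, 21_521_000, "DEL", freq=0.169)
    design = SimulationDesign(n_subjects=2348,
                              catalog=[VariantCatalogEntry("rs1", "chr1", 1, "A",
                                                           "G", 0.1, 0.5)],
                              cnv_loci=[locus])
    _, carriers = simulate_cnv_calls(design, _perfect_profiles(2), seed=16)
    count = int(carriers["del16"].sum())
    exp = 2348 * 0.169
    se = np.sqrt(2348 * 0.169 * (1 - 0.169))
    assert abs(count - exp) < 3 * se


def test_zero_sensitivity_yields_only_spurious_calls(small_design):
    eps = 1e-12
    profiles = [CallerProfile(f"c{i}", sensitivity=eps, boundary_jitter_sd=0.0,
                              false_call_rate=0.5) for i in range(2)]
    calls, _ = simulate_cnv_calls(small_design, profiles, seed=17)
    loci = small_design.cnv_loci
    for plist in calls.values():
        assert plist  # rate 0.5 over 400 subjects: spurious calls exist
        for c in plist:
            assert not any(l.chrom == c.chrom and min(l.end, c.end) > max(l.start, c.start)
                           for l in loci)


# ---------------------------------------------------------------------------
# Phenotypes and variance calibration
# ---------------------------------------------------------------------------

def test_single_snp_noise_variance_closed_form():
    # one SNP, f = 0.5, beta = 1, target fraction 0.5, no covariates/CNV:
    # raw genetic variance 2*0.5*0.5 = 0.5 anchors the scale, so the noise
    # variance solves to 0.5 as well
    cat = [VariantCatalogEntry("rs1", "chr1", 1, "A", "G", 1.0, 0.5)]
    design = SimulationDesign(
        n_subjects=100, catalog=cat,
        variance_fractions={"covariates": 0.0, "grss": 0.5, "cnv": 0.0})
    scaling = solve_variance_scaling(design)
    assert scaling["raw_variances"]["grss"] == pytest.approx(0.5)
    assert scaling["noise_sd"] ** 2 == pytest.approx(0.5)
    assert scaling["scale_grss"] == 1.0


def test_mean_bmi_matches_intercept(cohort_2348):
    ph = cohort_2348.phenotypes
    bmi = ph["weight"] / ph["height"] ** 2
    assert abs(bmi.mean() - 27.63) < 0.5


def test_null_grss_fraction_gives_null_association(full_catalog):
    design = SimulationDesign(
        n_subjects=2348, catalog=full_catalog,
        variance_fractions={"covariates": 0.083, "grss": 0.0, "cnv": 0.0})
    r2s = []
    betas = np.array([e.beta for e in full_catalog])
    for s in range(50):
        gs = simulate_genotypes(design, seed=1000 + s)
        cov = simulate_covariates(design, seed=2000 + s)
        carriers = pd.DataFrame(index=cov["subject_id"])
        ph, _ = simulate_phenotypes(design, gs, carriers, cov, seed=3000 + s)
        bmi = (ph["weight"] / ph["height"] ** 2).to_numpy()
        score = gs.dosage @ betas
        r2s.append(assoc.fit_linear(bmi, pd.DataFrame({"g": score})).r2)
    assert np.mean(r2s) < 0.002


def test_variance_calibration_on_large_cohort(full_catalog):
    """Each component's empirical variance share matches its target within
    0.005 on a 1e5-subject cohort."""
    design = default_design(n_subjects=100_000, catalog=full_catalog)
    c = simulate_cohort(design, seed=55)
    ph = c.phenotypes
    bmi = (ph["weight"] / ph["height"] ** 2).to_numpy()
    total = bmi.var()

    betas = np.array([e.beta for e in design.catalog])
    g = c.genotypes.dosage @ betas * c.truth["scale_grss"]
    b = design.covariates.coeffs
    l = sum(b[k] * ph[k] for k in b) * c.truth["scale_covariates"]
    effects = np.array([x.effect for x in design.cnv_loci])
    cn = c.carriers.to_numpy(float) @ effects * c.truth["scale_cnv"]
    for comp, target in ((g, 0.031), (l.to_numpy(), 0.083), (cn, 0.001)):
        assert abs(comp.var() / total - target) < 0.005


def test_cohort_determinism(small_design):
    a = simulate_cohort(small_design, seed=77)
    b = simulate_cohort(small_design, seed=77)
    assert np.array_equal(a.genotypes.dosage, b.genotypes.dosage)
    assert np.array_equal(a.probabilities.probs, b.probabilities.probs)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    assert a.caller_calls == b.caller_calls
    c = simulate_cohort(small_design, seed=78)
    assert not np.array_equal(a.genotypes.dosage, c.genotypes.dosage)


def test_infeasible_fractions_rejected(small_catalog):
    with pytest.raises(ValidationError):
        SimulationDesign(n_subjects=10, catalog=small_catalog,
                         variance_fractions={"covariates": 0.6, "grss": 0.5})
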