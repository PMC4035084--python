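"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without access-restricted genotype data:

* biallelic SNP genotypes under Hardy-Weinberg equilibrium at catalog
  frequencies, with loci in linkage equilibrium;
* imputation-probability triples of configurable quality (a Dirichlet
  perturbation around the true genotype, calibrated against the imputation
  info statistic var(dosage)/2f(1-f));
* proxy markers at a configurable squared allelic correlation with the true
  loci (independent per-haplotype allele flips);
* three noisy CNV callers over planted common/rare loci, with per-caller
  sensitivity, boundary jitter, Log Bayes Factor draws and spurious calls;
* BMI from a linear model whose covariate, SNP-score and CNV components are
  scaled analytically to prescribed fractions of phenotypic variance.

Variance calibration is exact in expectation.  When the SNP-score fraction
is positive the genetic component keeps its natural scale (catalog betas in
kg/m^2 per allele, raw variance sum 2 f (1-f) beta^2), which fixes the total
phenotypic variance as V_g / fraction and solves the noise variance from the
remaining share; when the score fraction is zero, the ``residual_sd`` field
anchors the scale instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import (CnvCall, CnvRegionCatalogEntry, GenotypeSet, ValidationError,
                 VariantCatalogEntry)

logger = logging.getLogger("snpcnv")

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]  # non-ambiguous


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnvLocus:
    """A planted CNV locus: interval, state, carrier frequency, BMI effect."""

    region: str
    chrom: str
    start: int
    end: int
    state: str
    freq: float
    effect: float = 0.0  # kg/m^2 per carrier before variance scaling

    def __post_init__(self):
        if not 0.0 < self.freq < 1.0:
            raise ValidationError(f"locus {self.region}: frequency outside (0, 1)")

    def catalog_entry(self) -> CnvRegionCatalogEntry:
        return CnvRegionCatalogEntry(
            region=self.region, chrom=self.chrom, start=self.start, end=self.end,
            state=self.state, source="synthetic", reported_freq=self.freq)


@dataclass
class CallerProfile:
    """Error model of one CNV caller."""

    name: str
    sensitivity: float = 0.95
    boundary_jitter_sd: float = 200.0    # bp
    false_call_rate: float = 0.3         # expected spurious calls per subject
    has_lbf: bool = True
    lbf_true: tuple[float, float] = (35.0, 12.0)      # mean, sd of true-call LBF
    lbf_spurious: tuple[float, float] = (12.0, 6.0)

    def __post_init__(self):
        if not 0.0 < self.sensitivity <= 1.0:
            raise ValidationError("sensitivity must be in (0, 1]")
        if self.boundary_jitter_sd < 0:
            raise ValidationError("boundary jitter SD must be >= 0")


def default_caller_profiles() -> list[CallerProfile]:
    """Three array-CNV callers; the first emits no confidence metric."""
    return [
        CallerProfile("callerA", sensitivity=0.92, boundary_jitter_sd=300.0,
                      false_call_rate=0.30, has_lbf=False),
        CallerProfile("callerB", sensitivity=0.95, boundary_jitter_sd=150.0,
                      false_call_rate=0.25),
        CallerProfile("callerC", sensitivity=0.93, boundary_jitter_sd=200.0,
                      false_call_rate=0.35),
    ]


@dataclass
class CovariateModel:
    """Marginals and effects of the non-genetic covariates.

    Sex is Bernoulli (1 = female); age Normal; alcohol (AD) and nicotine (ND)
    dependence are Bernoulli with sex-dependent rates; ancestry is a
    two-level label on a fixed split, loading on PC1; PC4 and PC8 are
    standard-normal ancestry-unrelated axes.  Defaults mirror a
    substance-use-ascertained adult cohort.
    """

    p_female: float = 1337 / 2348
    age_mean: float = 39.9
    age_sd: float = 9.0
    ad_rate_male: float = 0.664
    ad_rate_female: float = 0.314
    nd_rate_male: float = 0.525
    nd_rate_female: float = 0.462
    p_aa: float = 498 / 2348            # two-level ancestry split
    pc1_noise_sd: float = 0.25
    coeffs: dict = field(default_factory=lambda: {
        "sex": -1.0, "age": 0.04, "AD": -0.2, "ND": -0.06,
        "PC1": -1.0, "PC4": 0.2, "PC8": -0.3,
    })

    def predictor_variance(self) -> float:
        """Analytic variance of the covariate linear predictor.

        Accounts for the sex/AD, sex/ND and AD/ND covariances induced by the
        sex-dependent dependence rates; PCs are unit-variance by
        construction and independent of the rest.
        """
        b = self.coeffs
        p = self.p_female
        dbar = (1 - p) * self.ad_rate_male + p * self.ad_rate_female
        nbar = (1 - p) * self.nd_rate_male + p * self.nd_rate_female
        var = (b["sex"] ** 2 * p * (1 - p)
               + b["age"] ** 2 * self.age_sd ** 2
               + b["AD"] ** 2 * dbar * (1 - dbar)
               + b["ND"] ** 2 * nbar * (1 - nbar)
               + b["PC1"] ** 2 + b["PC4"] ** 2 + b["PC8"] ** 2)
        d_gap = self.ad_rate_female - self.ad_rate_male
        n_gap = self.nd_rate_female - self.nd_rate_male
        pq = p * (1 - p)
        var += 2 * (b["sex"] * b["AD"] * pq * d_gap
                    + b["sex"] * b["ND"] * pq * n_gap
                    + b["AD"] * b["ND"] * pq * d_gap * n_gap)
        return var

    def predictor_mean(self) -> float:
        b = self.coeffs
        p = self.p_female
        dbar = (1 - p) * self.ad_rate_male + p * self.ad_rate_female
        nbar = (1 - p) * self.nd_rate_male + p * self.nd_rate_female
        return (b["sex"] * p + b["age"] * self.age_mean
                + b["AD"] * dbar + b["ND"] * nbar)


@dataclass
class SimulationDesign:
    """Full specification of one synthetic cohort."""

    n_subjects: int = 2348
    catalog: list[VariantCatalogEntry] = field(default_factory=list)
    cnv_loci: list[CnvLocus] = field(default_factory=list)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    variance_fractions: dict = field(default_factory=lambda: {
        "covariates": 0.083, "grss": 0.031, "cnv": 0.001})
    intercept: float = 27.63
    residual_sd: float = 5.3            # scale anchor when the grss fraction is 0
    imputation_quality: float = 0.95
    proxy_r2: float = 0.8
    ancestry_af_shift: float = 0.0      # allele-frequency offset for the AA stratum

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        if sum(self.variance_fractions.values()) >= 1.0:
            raise ValidationError("variance fractions must sum below 1")
        for k, v in self.variance_fractions.items():
            if v < 0:
                raise ValidationError(f"variance fraction {k!r} negative")


def default_variant_catalog(n_snps: int = 32, seed: int = 20140514
                            ) -> list[VariantCatalogEntry]:
    """A synthetic risk-SNP catalog.

    Effect sizes are uniform on the published per-allele range
    [0.06, 0.39] kg/m^2; risk-allele frequencies uniform on (0.1, 0.9)
    (the real per-SNP frequencies are not in the main text).  One SNP is
    flagged as having no adequate proxy marker, so proxy-based scores cover
    n_snps - 1 loci.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_snps):
        risk, other = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
        if rng.random() < 0.5:
            risk, other = other, risk
        entries.append(VariantCatalogEntry(
            snp_id=f"rs{900000 + i}",
            chrom=f"chr{(i % 22) + 1}",
            pos=int(1_000_000 + 37_000 * i + rng.integers(0, 10_000)),
            risk_allele=risk, other_allele=other,
            beta=float(rng.uniform(0.06, 0.39)),
            freq=float(rng.uniform(0.1, 0.9)),
            proxy_r2=float("nan") if i == n_snps - 1 else 0.8,
        ))
    return entries


def default_cnv_loci(n_regions: int = 84, seed: int = 20140514) -> list[CnvLocus]:
    """A synthetic literature catalog of BMI/obesity CNV regions.

    Three common loci mirror the published frequencies — a 21-kb deletion at
    16.9%, a 66-kb duplication at 1.2% and a 1635-kb deletion at 7.7% — with
    only the 21-kb deletion given a BMI effect.  The remaining loci are rare
    (frequency 0.05-0.8%), effect-free, and spread over the genome.
    """
    rng = np.random.default_rng(seed)
    loci = [
        CnvLocus("del16p12.3", "chr16", 21_500_000, 21_521_000, "DEL",
                 freq=0.169, effect=-1.0),
        CnvLocus("dup1p36.1", "chr1", 16_800_000, 16_866_400, "DUP", freq=0.012),
        CnvLocus("del5q13.2", "chr5", 68_900_000, 70_535_000, "DEL", freq=0.077),
    ]
    for i in range(n_regions - len(loci)):
        chrom = f"chr{(i % 22) + 1}"
        while True:  # rejection: planted loci must not overlap each other
            length = int(np.exp(rng.uniform(np.log(20_000), np.log(1_000_000))))
            start = int(rng.uniform(5e6, 100e6))
            end = start + length
            if not any(l.chrom == chrom and min(l.end, end) > max(l.start, start)
                       for l in loci):
                break
        loci.append(CnvLocus(
            region=f"r{i + 4:02d}", chrom=chrom, start=start, end=end,
            state="DEL" if rng.random() < 0.6 else "DUP",
            freq=float(rng.uniform(0.0005, 0.008)),
        ))
    return loci


def default_design(n_subjects: int = 2348, **overrides) -> SimulationDesign:
    design = SimulationDesign(
        n_subjects=n_subjects,
        catalog=default_variant_catalog(),
        cnv_loci=default_cnv_loci(),
    )
    return replace(design, **overrides) if overrides else design


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(design: SimulationDesign, seed: int,
                       ancestry: np.ndarray | None = None) -> GenotypeSet:
    """Hard-call genotypes under HWE at catalog frequencies, loci independent.

    The VCF orientation is ALT = risk allele, so the ALT dosage is the
    risk-allele count.  ``ancestry`` (0/1 per subject) shifts allele
    frequencies by ``design.ancestry_af_shift`` in stratum 1 when requested.
    """
    if not design.catalog:
        raise ValidationError("catalog must be non-empty")
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    freqs = np.array([e.freq for e in design.catalog])
    f = np.tile(freqs, (n, 1))
    if ancestry is not None and design.ancestry_af_shift != 0.0:
        f[ancestry == 1] = np.clip(freqs + design.ancestry_af_shift, 0.01, 0.99)
    dosage = rng.binomial(2, f).astype(float)
    return GenotypeSet(
        samples=[f"S{i:05d}" for i in range(n)],
        snp_ids=[e.snp_id for e in design.catalog],
        chrom=np.array([e.chrom for e in design.catalog]),
        pos=np.array([e.pos for e in design.catalog]),
        ref=[e.other_allele for e in design.catalog],
        alt=[e.risk_allele for e in design.catalog],
        dosage=dosage, mode="hard",
    )


# ---------------------------------------------------------------------------
# Imputation-probability blur
# ---------------------------------------------------------------------------

def _analytic_info(w: float, f: float, concentration: float) -> float:
    """Info statistic var(dosage)/2f(1-f) of the Dirichlet blur model.

    Triples are Dirichlet with mean m(g) = (1-w) e_g + w pi, pi the HWE
    genotype distribution, concentration kappa; the statistic decomposes as
    (1-w)^2 + E_g[within-triple dosage variance]/(kappa+1)/V.
    """
    pi = np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
    v = 2 * f * (1 - f)
    within = 0.0
    for g in range(3):
        e = np.zeros(3)
        e[g] = 1.0
        m = (1 - w) * e + w * pi
        s1 = m[1] + 2 * m[2]
        s2 = m[1] + 4 * m[2]
        within += pi[g] * (s2 - s1 ** 2)
    return ((1 - w) ** 2 * v + within / (concentration + 1)) / v


def _solve_blur_weight(quality: float, f: float, concentration: float) -> float:
    floor = _analytic_info(1.0, f, concentration)
    if quality <= floor:
        raise ValidationError(
            f"imputation quality {quality} unreachable below {floor:.3g} "
            f"at concentration {concentration}")
    return brentq(lambda w: _analytic_info(w, f, concentration) - quality, 0.0, 1.0,
                  xtol=1e-10)


def blur_to_probabilities(hard_calls: GenotypeSet, quality: float, seed: int,
                          concentration: float = 50.0) -> GenotypeSet:
    """Replace hard calls by genotype-probability triples of target info.

    quality = 1 yields exactly degenerate (0/1) triples; otherwise triples
    are Dirichlet draws centered on a mixture of the true-genotype vertex
    and the HWE prior, with the mixture weight root-found so the analytic
    info statistic equals ``quality``.
    """
    if not 0.0 < quality <= 1.0:
        raise ValidationError("imputation quality must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n, m = hard_calls.dosage.shape
    probs = np.full((n, m, 3), np.nan)
    freqs = hard_calls.sample_alt_freq()
    for j in range(m):
        col = hard_calls.dosage[:, j]
        f = float(freqs[j])
        observed = ~np.isnan(col)
        if quality == 1.0 or not 0.0 < f < 1.0:
            for g in range(3):
                probs[observed & (col == g), j, :] = np.eye(3)[g]
            continue
        w = _solve_blur_weight(quality, f, concentration)
        pi = np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
        for g in range(3):
            idx = np.flatnonzero(observed & (col == g))
            if idx.size == 0:
                continue
            alpha = concentration * ((1 - w) * np.eye(3)[g] + w * pi)
            draws = rng.standard_gamma(np.broadcast_to(alpha, (idx.size, 3)))
            probs[idx, j, :] = draws / draws.sum(axis=1, keepdims=True)
    dosage = probs[:, :, 1] + 2.0 * probs[:, :, 2]
    return GenotypeSet(
        samples=hard_calls.samples, snp_ids=hard_calls.snp_ids,
        chrom=hard_calls.chrom, pos=hard_calls.pos,
        ref=hard_calls.ref, alt=hard_calls.alt,
        dosage=dosage, probs=probs, mode="probability",
    )


# ---------------------------------------------------------------------------
# Proxy markers
# ---------------------------------------------------------------------------

def _allelic_corr(eps: float, f: float) -> float:
    mu = f + eps * (1 - 2 * f)
    cov = f * (1 - eps) - f * mu
    denom = np.sqrt(f * (1 - f) * mu * (1 - mu))
    return cov / denom


def simulate_proxy(hard_calls: GenotypeSet, r2: float, seed: int,
                   flip_probability: float | None = None) -> GenotypeSet:
    """Proxy markers: per-haplotype allele copies with a calibrated flip rate.

    Each of the two haplotype alleles is copied from the true locus and
    flipped independently with probability eps, root-found so the squared
    allelic correlation equals ``r2`` in expectation.  r2 = 1 reproduces the
    original dosages exactly.  ``flip_probability`` overrides the calibration
    (eps = 0.5 gives an independent marker at f = 0.5).
    """
    if flip_probability is None and not 0.0 < r2 <= 1.0:
        raise ValidationError("proxy r2 must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n, m = hard_calls.dosage.shape
    freqs = hard_calls.sample_alt_freq()
    out = np.full((n, m), np.nan)
    for j in range(m):
        col = hard_calls.dosage[:, j]
        observed = ~np.isnan(col)
        f = float(freqs[j])
        if flip_probability is not None:
            eps = flip_probability
        elif r2 == 1.0 or not 0.0 < f < 1.0:
            eps = 0.0
        else:
            eps = brentq(lambda e: _allelic_corr(e, f) ** 2 - r2, 0.0, 0.5 - 1e-12,
                         xtol=1e-12)
        g = col[observed].astype(int)
        a1 = (g >= 1).astype(int)   # decompose dosage into two haplotype alleles
        a2 = (g == 2).astype(int)
        if eps > 0:
            flip1 = rng.random(g.size) < eps
            flip2 = rng.random(g.size) < eps
            a1 = np.where(flip1, 1 - a1, a1)
            a2 = np.where(flip2, 1 - a2, a2)
        out[observed, j] = a1 + a2
    return GenotypeSet(
        samples=hard_calls.samples, snp_ids=hard_calls.snp_ids,
        chrom=hard_calls.chrom, pos=hard_calls.pos,
        ref=hard_calls.ref, alt=hard_calls.alt,
        dosage=out, mode="hard",
    )


# ---------------------------------------------------------------------------
# CNV callers
# ---------------------------------------------------------------------------

_GENOME = {f"chr{i}": 120_000_000 for i in range(1, 23)}


def simulate_cnv_calls(design: SimulationDesign,
                       profiles: list[CallerProfile],
                       seed: int,
                       samples: list[str] | None = None
                       ) -> tuple[dict[str, list[CnvCall]], pd.DataFrame]:
    """Per-caller CNV call lists over planted loci, plus the true carrier table.

    Each subject carries each planted locus independently at its frequency.
    A caller detects a carried event with its sensitivity, jitters both
    boundaries with Gaussian noise, and draws an LBF when it emits one;
    spurious calls arrive Poisson per subject and are placed uniformly
    outside the planted loci.
    """
    if len(profiles) < 2:
        raise ValidationError("need >= 2 caller profiles")
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    if samples is None:
        samples = [f"S{i:05d}" for i in range(n)]
    loci = design.cnv_loci
    carrier = rng.random((n, len(loci))) < np.array([l.freq for l in loci])
    carriers = pd.DataFrame(carrier, index=pd.Index(samples, name="subject_id"),
                            columns=[l.region for l in loci])

    chrom_names = list(_GENOME)
    chrom_lengths = np.array([_GENOME[c] for c in chrom_names])

    def spurious_interval():
        for _ in range(20):
            ci = int(rng.integers(len(chrom_names)))
            length = int(np.exp(rng.normal(np.log(50_000), 0.6)))
            start = int(rng.integers(0, max(1, chrom_lengths[ci] - length)))
            iv = (chrom_names[ci], start, start + length)
            if not any(l.chrom == iv[0] and min(l.end, iv[2]) > max(l.start, iv[1])
                       for l in loci):
                return iv
        return None

    calls: dict[str, list[CnvCall]] = {}
    for prof in profiles:
        plist: list[CnvCall] = []
        for li, locus in enumerate(loci):
            cn = 1 if locus.state == "DEL" else 3
            for si in np.flatnonzero(carrier[:, li]):
                if rng.random() >= prof.sensitivity:
                    continue
                js, je = 0.0, 0.0
                if prof.boundary_jitter_sd > 0:
                    js, je = rng.normal(0, prof.boundary_jitter_sd, 2)
                start = int(round(locus.start + js))
                end = max(start + 1, int(round(locus.end + je)))
                lbf = None
                if prof.has_lbf:
                    lbf = float(max(0.0, rng.normal(*prof.lbf_true)))
                plist.append(CnvCall(sample=samples[si], chrom=locus.chrom,
                                     start=start, end=end, state=locus.state,
                                     copy_number=cn, lbf=lbf, caller=prof.name))
        if prof.false_call_rate > 0:
            counts = rng.poisson(prof.false_call_rate, n)
            for si in np.flatnonzero(counts):
                for _ in range(counts[si]):
                    iv = spurious_interval()
                    if iv is None:
                        continue
                    state = "DEL" if rng.random() < 0.5 else "DUP"
                    lbf = None
                    if prof.has_lbf:
                        lbf = float(max(0.0, rng.normal(*prof.lbf_spurious)))
                    plist.append(CnvCall(
                        sample=samples[si], chrom=iv[0], start=iv[1], end=iv[2],
                        state=state, copy_number=1 if state == "DEL" else 3,
                        lbf=lbf, caller=prof.name))
        calls[prof.name] = plist
        logger.info("caller %s: %d calls simulated", prof.name, len(plist))
    return calls, carriers


# ---------------------------------------------------------------------------
# Covariates and phenotypes
# ---------------------------------------------------------------------------

def simulate_covariates(design: SimulationDesign, seed: int,
                        samples: list[str] | None = None) -> pd.DataFrame:
    """Covariate table: sex, age, AD, ND, ancestry, PC1/PC4/PC8.

    Ancestry is a fixed two-level split (round(n * p_aa) subjects in the
    second stratum, randomly placed); PC1 is the standardized ancestry
    indicator plus Gaussian noise, so it is the stratification axis.
    """
    cov = design.covariates
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    if samples is None:
        samples = [f"S{i:05d}" for i in range(n)]
    sex = (rng.random(n) < cov.p_female).astype(int)   # 1 = female
    age = rng.normal(cov.age_mean, cov.age_sd, n)
    ad = (rng.random(n) < np.where(sex == 1, cov.ad_rate_female, cov.ad_rate_male)
          ).astype(int)
    nd = (rng.random(n) < np.where(sex == 1, cov.nd_rate_female, cov.nd_rate_male)
          ).astype(int)
    n_aa = int(round(n * cov.p_aa))
    anc = np.zeros(n, dtype=int)
    anc[rng.permutation(n)[:n_aa]] = 1
    pc1 = ((anc - cov.p_aa) + rng.normal(0, cov.pc1_noise_sd, n)) \
        / np.sqrt(cov.p_aa * (1 - cov.p_aa) + cov.pc1_noise_sd ** 2)
    return pd.DataFrame({
        "subject_id": samples, "sex": sex, "age": age, "AD": ad, "ND": nd,
        "ancestry": np.where(anc == 1, "AA", "EA"),
        "PC1": pc1, "PC4": rng.normal(0, 1, n), "PC8": rng.normal(0, 1, n),
    })


def genetic_component_variance(catalog) -> float:
    """Raw variance of the additive genetic value under HWE/LE:
    sum_i 2 f_i (1 - f_i) beta_i^2."""
    return float(sum(2 * e.freq * (1 - e.freq) * e.beta ** 2 for e in catalog))


def solve_variance_scaling(design: SimulationDesign) -> dict:
    """Analytic component scalings for the phenotype model.

    Returns total variance, per-component multipliers and the noise SD; each
    component's share of total variance equals its target fraction exactly
    in expectation.
    """
    fr = design.variance_fractions
    f_cov = fr.get("covariates", 0.0)
    f_g = fr.get("grss", 0.0)
    f_c = fr.get("cnv", 0.0)
    v_g = genetic_component_variance(design.catalog)
    v_cov = design.covariates.predictor_variance()
    v_cnv = float(sum(l.effect ** 2 * l.freq * (1 - l.freq) for l in design.cnv_loci))

    if f_g > 0 and v_g > 0:
        total = v_g / f_g           # genetic component anchors the scale
        scale_g = 1.0
    else:
        total = design.residual_sd ** 2 / (1.0 - f_cov - f_g - f_c)
        scale_g = 0.0 if v_g == 0 else np.sqrt(f_g * total / v_g)
    scale_cov = 0.0 if (f_cov == 0 or v_cov == 0) else np.sqrt(f_cov * total / v_cov)
    scale_cnv = 0.0 if (f_c == 0 or v_cnv == 0) else np.sqrt(f_c * total / v_cnv)
    noise_var = total * (1.0 - f_cov - f_g - f_c)
    return {
        "total_variance": total, "noise_sd": float(np.sqrt(noise_var)),
        "scale_covariates": float(scale_cov), "scale_grss": float(scale_g),
        "scale_cnv": float(scale_cnv),
        "raw_variances": {"grss": v_g, "covariates": v_cov, "cnv": v_cnv},
    }


def simulate_phenotypes(design: SimulationDesign, genotypes: GenotypeSet,
                        carriers: pd.DataFrame, covariates: pd.DataFrame,
                        seed: int) -> tuple[pd.DataFrame, dict]:
    """BMI from the calibrated linear model; height/weight back-synthesised.

    BMI = intercept + covariate predictor + genetic value + CNV term +
    Gaussian noise, each component mean-centered analytically and scaled to
    its target variance fraction.  Returns (phenotype table, truth record).
    """
    rng = np.random.default_rng(seed)
    cov = design.covariates
    scaling = solve_variance_scaling(design)
    n = design.n_subjects

    betas = np.array([e.beta for e in design.catalog])
    g_value = np.nan_to_num(genotypes.dosage) @ betas
    g_mean = float(sum(2 * e.freq * e.beta for e in design.catalog))

    b = cov.coeffs
    l_value = (b["sex"] * covariates["sex"] + b["age"] * covariates["age"]
               + b["AD"] * covariates["AD"] + b["ND"] * covariates["ND"]
               + b["PC1"] * covariates["PC1"] + b["PC4"] * covariates["PC4"]
               + b["PC8"] * covariates["PC8"]).to_numpy()
    l_mean = cov.predictor_mean()

    effects = np.array([l.effect for l in design.cnv_loci])
    c_value = carriers.to_numpy(dtype=float) @ effects
    c_mean = float(sum(l.effect * l.freq for l in design.cnv_loci))

    bmi = (design.intercept
           + scaling["scale_covariates"] * (l_value - l_mean)
           + scaling["scale_grss"] * (g_value - g_mean)
           + scaling["scale_cnv"] * (c_value - c_mean)
           + rng.normal(0, scaling["noise_sd"], n))

    sex = covariates["sex"].to_numpy()
    height = np.where(sex == 1, rng.normal(1.64, 0.065, n), rng.normal(1.78, 0.07, n))
    height = np.clip(height, 1.45, 1.99)
    weight = bmi * height ** 2

    pheno = covariates.copy()
    pheno["height"] = height
    pheno["weight"] = weight
    truth = {
        "intercept": design.intercept,
        "variance_fractions": dict(design.variance_fractions),
        **scaling,
        "genetic_mean": g_mean,
    }
    return pheno, truth


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    design: SimulationDesign
    seed: int
    genotypes: GenotypeSet               # true hard calls (ALT = risk allele)
    probabilities: GenotypeSet           # blurred probability triples
    proxies: GenotypeSet                 # proxy hard calls
    caller_calls: dict
    carriers: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: dict


def simulate_cohort(design: SimulationDesign, seed: int,
                    profiles: list[CallerProfile] | None = None) -> SimulatedCohort:
    """Generate one full cohort; identical (design, seed) -> identical cohort."""
    if profiles is None:
        profiles = default_caller_profiles()
    ss = np.random.SeedSequence(seed).spawn(6)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    genotypes = simulate_genotypes(design, sub[0])
    probabilities = blur_to_probabilities(genotypes, design.imputation_quality, sub[1])
    proxies = simulate_proxy(genotypes, design.proxy_r2, sub[2])
    covariates = simulate_covariates(design, sub[3], samples=genotypes.samples)
    caller_calls, carriers = simulate_cnv_calls(design, profiles, sub[4],
                                                samples=genotypes.samples)
    phenotypes, truth = simulate_phenotypes(design, genotypes, carriers,
                                            covariates, sub[5])
    truth["seed"] = seed
    return SimulatedCohort(design=design, seed=seed, genotypes=genotypes,
                           probabilities=probabilities, proxies=proxies,
                           caller_calls=caller_calls, carriers=carriers,
                           phenotypes=phenotypes, truth=truth)
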