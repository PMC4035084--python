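"""SNP genetic risk sum scores (GRSS).

Six score constructions are supported, crossing count vs weighted with three
genotype sources: proxy hard calls, imputed hard calls, and imputed genotype
probabilities.  A score is

    score_s = sum_i beta_i * p_si / D

where p_si is the expected risk-allele count (dosage) of subject s at SNP i
(0..2, fractional for probability-based dosages), beta_i = 1 for count
scores or the published per-allele effect size for weighted scores, and D is
a normalising denominator: 2n (per counted allele) for the hard-call
methods, n (per SNP) for the probability methods.  Downstream association
statistics are invariant to D (and to any common rescaling of the betas).

Missing genotypes are imputed as the expected dosage 2f from the sample
allele frequency of the analysis cohort, mirroring the allelic-scoring
convention of standard tooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeSet, ValidationError, VariantCatalogEntry

logger = logging.getLogger("snpcnv")

SCORE_METHODS = (
    "proxy_count", "proxy_weighted",
    "imputed_count", "imputed_weighted",
    "prob_count", "prob_weighted",
)

# strand-ambiguous allele pairs: indistinguishable under strand flips
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


@dataclass
class ScoreSpec:
    """Specification of one GRSS construction."""

    method: str
    weights: np.ndarray                      # beta_i; all ones for count scores
    denominator: str = "per_allele"          # 'per_allele' (2n) or 'per_snp' (n)
    missing_policy: str = "impute_sample_freq"

    def __post_init__(self):
        if self.method not in SCORE_METHODS:
            raise ValidationError(f"unknown GRSS method {self.method!r}")
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("GRSS weights must be finite")
        if self.denominator not in ("per_allele", "per_snp"):
            raise ValidationError(f"unknown denominator convention {self.denominator!r}")


@dataclass
class EffectEstimate:
    """Regression effect of a GRSS on BMI: estimate and standard error."""

    es: float
    se: float

    def __post_init__(self):
        if not self.se > 0:
            raise ValidationError("standard error must be > 0")


# ---------------------------------------------------------------------------
# Per-genotype risk dosages
# ---------------------------------------------------------------------------

def risk_dosage_from_hardcall(genotype: Sequence[str] | None,
                              risk_allele: str, other_allele: str) -> float:
    """Count risk alleles in an allele pair; NaN for a missing genotype.

    An allele outside {risk, other} indicates a strand/orientation fault and
    raises.
    """
    if genotype is None:
        return float("nan")
    count = 0
    for a in genotype:
        if a == risk_allele:
            count += 1
        elif a != other_allele:
            raise ValidationError(
                f"allele {a!r} matches neither risk ({risk_allele}) nor other "
                f"({other_allele}) allele — possible strand fault")
    return float(count)


def risk_dosage_from_probabilities(triple: Sequence[float]) -> float:
    """Expected risk-allele count from a probability triple ordered 0/1/2."""
    t = np.asarray(triple, dtype=float)
    if t.shape != (3,) or np.any(t < 0) or abs(t.sum() - 1.0) > 1e-6:
        raise ValidationError(f"malformed genotype probability triple {triple}")
    return float(t[1] + 2.0 * t[2])


def impute_missing_dosage(freq: float) -> float:
    """Expected dosage 2f for a missing genotype, f = sample risk-allele frequency."""
    if not 0.0 < freq < 1.0:
        raise ValidationError(f"allele frequency {freq} outside (0, 1)")
    return 2.0 * freq


# ---------------------------------------------------------------------------
# Catalog/VCF allele harmonization
# ---------------------------------------------------------------------------

def _is_ambiguous(a: str, b: str) -> bool:
    return {a, b} in _AMBIGUOUS


def harmonize(gs: GenotypeSet, catalog: Sequence[VariantCatalogEntry],
              allow_ambiguous: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Orient VCF ALT dosages to catalog risk alleles.

    Returns (risk_dosage matrix, keep mask over catalog SNPs).  A/T and C/G
    SNPs are strand-ambiguous; they are flagged and dropped unless
    ``allow_ambiguous`` is set.
    """
    idx = {s: j for j, s in enumerate(gs.snp_ids)}
    n = gs.n_samples
    cols, keep = [], []
    for entry in catalog:
        j = idx.get(entry.snp_id)
        if j is None:
            keep.append(False)
            continue
        if _is_ambiguous(entry.risk_allele, entry.other_allele) and not allow_ambiguous:
            logger.warning("SNP %s: strand-ambiguous alleles %s/%s — excluded",
                           entry.snp_id, entry.risk_allele, entry.other_allele)
            keep.append(False)
            continue
        ref, alt = gs.ref[j], gs.alt[j]
        if (entry.risk_allele, entry.other_allele) == (alt, ref):
            cols.append(gs.dosage[:, j])
        elif (entry.risk_allele, entry.other_allele) == (ref, alt):
            cols.append(2.0 - gs.dosage[:, j])
        else:
            raise ValidationError(
                f"SNP {entry.snp_id}: catalog alleles {entry.risk_allele}/"
                f"{entry.other_allele} do not match VCF {ref}/{alt}")
        keep.append(True)
    mat = np.column_stack(cols) if cols else np.empty((n, 0))
    return mat, np.asarray(keep, dtype=bool)


# ---------------------------------------------------------------------------
# Score computation
# ---------------------------------------------------------------------------

def compute_grss(dosages: np.ndarray, spec: ScoreSpec) -> np.ndarray:
    """Per-subject GRSS from a subjects x SNPs risk-dosage matrix.

    NaN dosages are imputed at 2f using the sample allele frequency of the
    non-missing subjects; a subject missing every SNP gets a NaN score.
    """
    d = np.asarray(dosages, dtype=float).copy()
    if d.ndim != 2 or d.shape[1] != len(spec.weights):
        raise ValidationError("dosage matrix does not match spec weights")
    n_snps = d.shape[1]
    all_missing = np.all(np.isnan(d), axis=1)
    if np.isnan(d).any():
        freqs = np.nanmean(d, axis=0) / 2.0
        for j in range(n_snps):
            miss = np.isnan(d[:, j])
            if miss.any():
                d[miss, j] = impute_missing_dosage(float(freqs[j]))
    denom = 2.0 * n_snps if spec.denominator == "per_allele" else float(n_snps)
    scores = d @ spec.weights / denom
    scores[all_missing] = np.nan
    return scores


def default_score_specs(catalog: Sequence[VariantCatalogEntry]) -> dict[str, ScoreSpec]:
    """The six standard score specs for a catalog.

    Proxy scores cover only SNPs with a usable proxy marker; imputed and
    probability scores cover the full catalog.  Hard-call methods use the
    per-allele denominator, probability methods the per-SNP denominator.
    """
    betas = np.array([e.beta for e in catalog])
    ones = np.ones(len(catalog))
    proxy_mask = np.array([e.has_proxy for e in catalog])
    return {
        "proxy_count": ScoreSpec("proxy_count", ones[proxy_mask], "per_allele"),
        "proxy_weighted": ScoreSpec("proxy_weighted", betas[proxy_mask], "per_allele"),
        "imputed_count": ScoreSpec("imputed_count", ones, "per_allele"),
        "imputed_weighted": ScoreSpec("imputed_weighted", betas, "per_allele"),
        "prob_count": ScoreSpec("prob_count", ones, "per_snp"),
        "prob_weighted": ScoreSpec("prob_weighted", betas, "per_snp"),
    }


def compute_all_scores(catalog: Sequence[VariantCatalogEntry],
                       proxy: GenotypeSet | None,
                       imputed: GenotypeSet | None,
                       probability: GenotypeSet | None,
                       allow_ambiguous: bool = False) -> pd.DataFrame:
    """Compute every constructible GRSS; one column per method.

    ``probability`` must carry genotype-probability triples; its dosages are
    the probability-weighted expected risk-allele counts.
    """
    specs = default_score_specs(catalog)
    proxy_catalog = [e for e in catalog if e.has_proxy]
    out: dict[str, np.ndarray] = {}
    samples = None
    sources = {
        "proxy": (proxy, proxy_catalog, ("proxy_count", "proxy_weighted")),
        "imputed": (imputed, list(catalog), ("imputed_count", "imputed_weighted")),
        "prob": (probability, list(catalog), ("prob_count", "prob_weighted")),
    }
    for label, (gs, cat, methods) in sources.items():
        if gs is None:
            continue
        samples = gs.samples if samples is None else samples
        dosages, keep = harmonize(gs, cat, allow_ambiguous=allow_ambiguous)
        kept_cat = [e for e, k in zip(cat, keep) if k]
        for m in methods:
            spec = specs[m]
            # restrict spec weights to the SNPs actually available/kept
            if label == "proxy":
                base = [e for e in catalog if e.has_proxy]
            else:
                base = list(catalog)
            w = np.array([spec.weights[i] for i, e in enumerate(base)
                          if e in kept_cat])
            sub = ScoreSpec(m, w, spec.denominator)
            out[m] = compute_grss(dosages, sub)
    df = pd.DataFrame(out)
    df.insert(0, "subject_id", samples)
    return df


def score_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and missingness per score method."""
    rows = []
    for col in scores.columns:
        if col == "subject_id":
            continue
        v = scores[col].to_numpy(dtype=float)
        rows.append({"method": col, "mean": np.nanmean(v), "sd": np.nanstd(v, ddof=1),
                     "n_missing": int(np.isnan(v).sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Effect-size comparison between score methods
# ---------------------------------------------------------------------------

def compare_effect_sizes(a: EffectEstimate, b: EffectEstimate) -> tuple[float, float]:
    """z-test for a difference between two GRSS effect sizes.

    z = (ES_a - ES_b) / sqrt(SE_a^2 + SE_b^2), two-sided p from the standard
    normal.
    """
    z = (a.es - b.es) / np.hypot(a.se, b.se)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
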