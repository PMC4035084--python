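"""Readers and writers for the external formats of the pipeline.

All genomic intervals are 0-based, half-open, both in memory and in the
BED/TSV files this package writes.  VCF positions (1-based) are converted on
read and on write.  Tabular formats are plain TSV with a header row so that
every intermediate artifact stays diff-able and text-only.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("snpcnv")

VALID_CNV_STATES = ("DEL", "DUP")


class FormatError(ValueError):
    """A file does not conform to the expected dialect (missing column, bad token)."""


class ValidationError(ValueError):
    """A well-formed value violates a domain constraint (range, ordering)."""


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger; filtering stages log counts in/out."""
    logging.basicConfig(format="%(asctime)s %(name)s %(levelname)s %(message)s")
    logger.setLevel(getattr(logging, level.upper()))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class Thresholds:
    """Analysis thresholds; defaults are the study's published choices."""

    reciprocal_overlap: float = 0.5   # consensus rule: >=50% reciprocal overlap
    catalog_overlap: float = 0.4      # literature-region match: >=40% overlap
    lbf_min: float = 10.0             # calls with Log Bayes Factor < 10 removed
    common_freq: float = 0.01         # carrier frequency >= 1% -> common
    large_cnv_bp: int = 100_000       # ">=100 kb" score restriction
    interaction_alpha: float = 0.002  # Bonferroni level for interaction scan

    def validate(self) -> None:
        for name in ("reciprocal_overlap", "catalog_overlap", "lbf_min",
                     "common_freq", "large_cnv_bp", "interaction_alpha"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name!r} must be strictly positive")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    The seed is recorded in every output artifact so that re-running with the
    same config reproduces all stochastic outputs exactly.
    """

    seed: int = 0
    cohort_size: int = 2348
    variance_fractions: dict = field(
        default_factory=lambda: {"covariates": 0.083, "grss": 0.031, "cnv": 0.001}
    )
    variant_catalog: str | None = None
    genotypes: str | None = None
    cnv_calls: list = field(default_factory=list)
    cnv_region_catalog: str | None = None
    exclusion_bed: str | None = None
    phenotypes: str | None = None
    genome_build: str = "synthetic"   # annotation only; intervals are taken verbatim
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        fracs = self.variance_fractions
        for k, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"variance fraction {k!r}={v} outside [0, 1]")
        if sum(fracs.values()) > 1.0:
            raise ValidationError("variance fractions sum above 1")
        if self.cohort_size < 2:
            raise ValidationError("cohort_size must be >= 2")
        self.thresholds.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}},)
        cfg.thresholds = thr
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Risk-variant catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantCatalogEntry:
    """One risk SNP: risk allele, per-allele effect size (kg/m^2) and frequency."""

    snp_id: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    beta: float
    freq: float
    proxy_r2: float = float("nan")  # NaN -> no adequate proxy marker exists

    @property
    def has_proxy(self) -> bool:
        return not math.isnan(self.proxy_r2)


_CATALOG_COLUMNS = ("snp_id", "chrom", "pos", "risk_allele", "other_allele", "beta", "freq")


def read_variant_catalog(path: str | Path) -> list[VariantCatalogEntry]:
    """Read the risk-SNP catalog TSV, in file order.

    Required columns: snp_id, chrom, pos, risk_allele, other_allele, beta,
    freq.  An optional proxy_r2 column flags SNPs with a usable proxy marker
    (empty cell = none).  Duplicate snp_id or freq outside (0, 1) is rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in _CATALOG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"variant catalog missing required column {col!r}")
    if df["snp_id"].duplicated().any():
        dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValidationError(f"duplicate snp_id in catalog: {dups}")
    entries = []
    for row in df.itertuples(index=False):
        freq = float(row.freq)
        if not 0.0 < freq < 1.0:
            raise ValidationError(f"{row.snp_id}: freq={freq} outside (0, 1)")
        proxy_r2 = float(getattr(row, "proxy_r2", float("nan")))
        entries.append(
            VariantCatalogEntry(
                snp_id=str(row.snp_id), chrom=str(row.chrom), pos=int(row.pos),
                risk_allele=str(row.risk_allele), other_allele=str(row.other_allele),
                beta=float(row.beta), freq=freq, proxy_r2=proxy_r2,
            )
        )
    logger.info("variant catalog: %d entries read from %s", len(entries), path)
    return entries


def write_variant_catalog(entries: Sequence[VariantCatalogEntry], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(e) for e in entries])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Genotypes (VCF)
# ---------------------------------------------------------------------------

@dataclass
class GenotypeSet:
    """Subjects x variants genotype container.

    ``dosage`` counts copies of the ALT allele (0..2, fractional when derived
    from probabilities); NaN flags a missing genotype — missingness is never
    silently zeroed.  ``probs`` (optional) holds genotype-probability triples
    ordered by ALT-allele count (0, 1, 2 copies).
    """

    samples: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: list[str]
    alt: list[str]
    dosage: np.ndarray               # (n_samples, n_snps), float, NaN = missing
    probs: np.ndarray | None = None  # (n_samples, n_snps, 3) or None
    mode: str = "hard"

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def sample_alt_freq(self) -> np.ndarray:
        """Per-SNP ALT-allele frequency over non-missing subjects."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0


def read_genotypes(path: str | Path, mode: str = "hard") -> GenotypeSet:
    """Read genotypes from VCF; ``mode`` selects GT (hard), DS (dosage) or GP.

    GP triples are renormalized to sum to 1; a triple whose raw sum lies
    outside [0.99, 1.01] is rejected.  Missing entries are flagged with NaN.
    """
    from cyvcf2 import VCF

    if mode not in ("hard", "dosage", "probability"):
        raise ValidationError(f"unknown genotype mode {mode!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chroms, poss, refs, alts = [], [], [], [], []
    dosage_cols: list[np.ndarray] = []
    prob_cols: list[np.ndarray] = []
    for v in vcf:
        snp_ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)  # VCF is 1-based; internal coordinates 0-based
        refs.append(v.REF)
        alts.append(v.ALT[0] if v.ALT else ".")
        if mode == "hard":
            col = np.full(len(samples), np.nan)
            for i, g in enumerate(v.genotypes):
                a = [x for x in g[:2]]
                if -1 in a:
                    continue
                col[i] = float(a[0] + a[1])
            dosage_cols.append(col)
        elif mode == "dosage":
            try:
                ds = v.format("DS")
            except KeyError:
                ds = None
            if ds is None:
                raise FormatError("requested DS field absent from VCF")
            col = ds.astype(float).reshape(-1)
            col[col < 0] = np.nan
            dosage_cols.append(col)
        else:
            try:
                gp = v.format("GP")
            except KeyError:
                gp = None
            if gp is None:
                raise FormatError("requested GP field absent from VCF")
            gp = gp.astype(float)
            sums = gp.sum(axis=1)
            ok = ~np.isnan(sums)
            bad = ok & ((sums < 0.99) | (sums > 1.01))
            if bad.any():
                raise ValidationError(
                    f"GP triple at {v.ID or v.POS} sums outside [0.99, 1.01]"
                )
            gp[ok] = gp[ok] / sums[ok, None]
            prob_cols.append(gp)
            dosage_cols.append(gp[:, 1] + 2.0 * gp[:, 2])
    dosage = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    probs = np.stack(prob_cols, axis=1) if prob_cols else None
    gs = GenotypeSet(
        samples=samples, snp_ids=snp_ids, chrom=np.array(chroms), pos=np.array(poss),
        ref=refs, alt=alts, dosage=dosage, probs=probs, mode=mode,
    )
    logger.info("genotypes: %d samples x %d variants (%s) from %s",
                gs.n_samples, gs.n_snps, mode, path)
    return gs


def write_vcf(gs: GenotypeSet, path: str | Path) -> None:
    """Write a GenotypeSet as an uncompressed VCF with GT, DS and GP fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(str(c) for c in gs.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n')
        fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gs.samples) + "\n")
        for j in range(gs.n_snps):
            fields = [str(gs.chrom[j]), str(int(gs.pos[j]) + 1), gs.snp_ids[j],
                      gs.ref[j], gs.alt[j], ".", "PASS", ".", "GT:DS:GP"]
            cells = []
            for i in range(gs.n_samples):
                d = gs.dosage[i, j]
                if np.isnan(d):
                    cells.append("./.:.:.")
                    continue
                if gs.probs is not None:
                    p = gs.probs[i, j]
                else:
                    p = np.zeros(3)
                    p[int(round(d))] = 1.0
                hard = int(round(float(p[1] + 2 * p[2])))
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[min(2, max(0, hard))]
                cells.append(f"{gt}:{d:.6g}:{p[0]:.6g},{p[1]:.6g},{p[2]:.6g}")
            fh.write("\t".join(fields + cells) + "\n")


# ---------------------------------------------------------------------------
# CNV calls, exclusion regions, literature catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnvCall:
    """One caller's CNV interval call for one subject (0-based half-open)."""

    sample: str
    chrom: str
    start: int
    end: int
    state: str               # DEL | DUP
    copy_number: int
    lbf: float | None        # Log Bayes Factor; None for callers without one
    caller: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"CNV call {self.chrom}:{self.start}-{self.end}: start >= end")
        if self.state not in VALID_CNV_STATES:
            raise FormatError(f"unknown CNV state token {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def read_cnv_calls(path: str | Path) -> list[CnvCall]:
    """Read a per-caller CNV call table (TSV).

    Columns: sample, chrom, start, end, state, copy_number, lbf, caller.
    An empty lbf cell means the caller emits no confidence metric.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = ("sample", "chrom", "start", "end", "state", "copy_number", "lbf", "caller")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"CNV call table missing required column {col!r}")
    calls = []
    for row in df.itertuples(index=False):
        lbf = None if pd.isna(row.lbf) else float(row.lbf)
        calls.append(CnvCall(
            sample=str(row.sample), chrom=str(row.chrom),
            start=int(row.start), end=int(row.end), state=str(row.state),
            copy_number=int(row.copy_number), lbf=lbf, caller=str(row.caller),
        ))
    logger.info("CNV calls: %d read from %s", len(calls), path)
    return calls


def write_cnv_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    rows = [
        {"sample": c.sample, "chrom": c.chrom, "start": c.start, "end": c.end,
         "state": c.state, "copy_number": c.copy_number,
         "lbf": "" if c.lbf is None else c.lbf, "caller": c.caller}
        for c in calls
    ]
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "state",
                                "copy_number", "lbf", "caller"]).to_csv(
        path, sep="\t", index=False)


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals (first three columns; 0-based half-open)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValidationError(f"BED interval {chrom}:{start}-{end}: start >= end")
            regions.append((chrom, start, end))
    return regions


def write_bed(regions: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


@dataclass(frozen=True)
class CnvRegionCatalogEntry:
    """A literature-reported BMI/obesity CNV region."""

    region: str              # cytoband-style label, e.g. 16p12.3
    chrom: str
    start: int
    end: int
    state: str
    source: str = "literature"
    reported_freq: float = float("nan")

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(f"catalog region {self.region}: start >= end")
        if self.state not in VALID_CNV_STATES:
            raise FormatError(f"unknown CNV state token {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def read_cnv_region_catalog(path: str | Path) -> list[CnvRegionCatalogEntry]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ("region", "chrom", "start", "end", "state")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"CNV region catalog missing required column {col!r}")
    entries = []
    for row in df.itertuples(index=False):
        entries.append(CnvRegionCatalogEntry(
            region=str(row.region), chrom=str(row.chrom), start=int(row.start),
            end=int(row.end), state=str(row.state),
            source=str(getattr(row, "source", "literature")),
            reported_freq=float(getattr(row, "reported_freq", float("nan"))),
        ))
    logger.info("CNV region catalog: %d regions from %s", len(entries), path)
    return entries


def write_cnv_region_catalog(entries: Sequence[CnvRegionCatalogEntry], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(e) for e in entries]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotype / covariate tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise FormatError("phenotype table missing required column 'subject_id'")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
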