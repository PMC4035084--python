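"""CNV consensus integration, filtering, catalog matching and aggregate scores.

Multi-caller call sets are integrated into consensus events (an event must be
supported by at least two distinct callers under a >=50% reciprocal-overlap
rule), filtered by caller confidence (Log Bayes Factor) and against an
exclusion BED of artifact-prone regions, matched to a literature catalog of
BMI/obesity-associated CNV regions at >=40% reciprocal overlap, classified as
common (carrier frequency >= 1%) or rare, and summarised into per-subject
aggregate scores: per-class catalog-region counts (CNV-GRSS), a >=100-kb
restricted variant of those, and the genome-wide rare-event burden.

All intervals are 0-based half-open.  The consensus interval is the
intersection of the supporting calls (conservative); the boundary envelope is
their union and is what the >=100-kb length filter measures.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CnvCall, CnvRegionCatalogEntry, ValidationError

logger = logging.getLogger("snpcnv")


@dataclass(frozen=True)
class ConsensusCnv:
    """A CNV event supported by >= 2 distinct callers."""

    sample: str
    chrom: str
    start: int               # intersection of supporters
    end: int
    state: str
    callers: frozenset
    envelope_start: int      # union of supporters
    envelope_end: int

    def __post_init__(self):
        if len(self.callers) < 2:
            raise ValidationError("consensus event requires >= 2 supporting callers")
        if not (self.envelope_start <= self.start < self.end <= self.envelope_end):
            raise ValidationError("consensus interval must lie within its envelope")

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def envelope_length(self) -> int:
        return self.envelope_end - self.envelope_start


# ---------------------------------------------------------------------------
# Confidence filter
# ---------------------------------------------------------------------------

def filter_calls_by_confidence(calls: list[CnvCall], lbf_min: float = 10.0
                               ) -> list[CnvCall]:
    """Drop calls with Log Bayes Factor below ``lbf_min``.

    Calls from callers that emit no LBF metric (lbf is None) are retained and
    flagged in the log — the filter only applies where the metric exists.
    """
    kept, no_metric = [], 0
    for c in calls:
        if c.lbf is None:
            no_metric += 1
            kept.append(c)
        elif c.lbf >= lbf_min:
            kept.append(c)
    logger.info("LBF filter (>= %g): %d in, %d retained (%d without metric)",
                lbf_min, len(calls), len(kept), no_metric)
    return kept


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def overlap_bp(a: tuple[str, int, int], b: tuple[str, int, int]) -> int:
    """Shared length of two half-open intervals; 0 if different chromosomes."""
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]))


def reciprocal_overlap(a: tuple[str, int, int], b: tuple[str, int, int]
                       ) -> tuple[float, float]:
    """Overlap as a fraction of each interval's own length; (0, 0) when disjoint."""
    shared = overlap_bp(a, b)
    return shared / (a[2] - a[1]), shared / (b[2] - b[1])


# ---------------------------------------------------------------------------
# Consensus merging
# ---------------------------------------------------------------------------

def merge_consensus(per_caller_calls: dict[str, list[CnvCall]],
                    threshold: float = 0.5) -> list[ConsensusCnv]:
    """Integrate per-caller call lists into consensus events.

    Within each (sample, chromosome, state) group, calls whose pairwise
    reciprocal overlaps both reach ``threshold`` are linked; connected
    components of that relation with calls from >= 2 distinct callers emit
    one consensus event (interval = intersection of supporters, envelope =
    union).  The result is independent of caller and call order.
    """
    if len(per_caller_calls) < 2:
        raise ValidationError("consensus requires call lists from >= 2 callers")
    groups: dict[tuple, list[CnvCall]] = defaultdict(list)
    for calls in per_caller_calls.values():
        for c in calls:
            groups[(c.sample, c.chrom, c.state)].append(c)

    events: list[ConsensusCnv] = []
    for (sample, chrom, state), calls in groups.items():
        calls = sorted(calls, key=lambda c: (c.start, c.end, c.caller))
        n = len(calls)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(n), 2):
            fa, fb = reciprocal_overlap(calls[i].interval, calls[j].interval)
            if fa >= threshold and fb >= threshold:
                parent[find(i)] = find(j)

        components: dict[int, list[CnvCall]] = defaultdict(list)
        for i in range(n):
            components[find(i)].append(calls[i])
        for comp in components.values():
            callers = frozenset(c.caller for c in comp)
            if len(callers) < 2:
                continue
            start = max(c.start for c in comp)
            end = min(c.end for c in comp)
            if start >= end:  # chained pairs with empty joint intersection
                logger.warning("consensus component at %s:%s has empty intersection; skipped",
                               chrom, sample)
                continue
            events.append(ConsensusCnv(
                sample=sample, chrom=chrom, start=start, end=end, state=state,
                callers=callers,
                envelope_start=min(c.start for c in comp),
                envelope_end=max(c.end for c in comp),
            ))
    events.sort(key=lambda e: (e.sample, e.chrom, e.start, e.end, e.state))
    logger.info("consensus merge: %d calls -> %d events (>= 2 callers, RO >= %g)",
                sum(len(v) for v in per_caller_calls.values()), len(events), threshold)
    return events


def remove_excluded_regions(events: list[ConsensusCnv],
                            exclusion_regions: list[tuple[str, int, int]]
                            ) -> list[ConsensusCnv]:
    """Drop events overlapping an excluded region by >= 1 bp (any-overlap rule)."""
    kept = [e for e in events
            if not any(overlap_bp(e.interval, r) > 0 for r in exclusion_regions)]
    logger.info("exclusion regions (%d regions): %d events in, %d retained",
                len(exclusion_regions), len(events), len(kept))
    return kept


# ---------------------------------------------------------------------------
# Literature-catalog matching
# ---------------------------------------------------------------------------

def match_catalog(events: list[ConsensusCnv],
                  catalog: list[CnvRegionCatalogEntry],
                  threshold: float = 0.4) -> pd.DataFrame:
    """Assign consensus events to literature catalog regions.

    The match rule is reciprocal: the shared length must be >= ``threshold``
    of BOTH the event and the catalog interval, and states must agree.
    One-way-only matches are logged.  An event matches at most one region:
    best overlap (the smaller of the two fractions) wins; ties break to the
    smaller catalog interval, then to the lexicographically first label.

    Returns a table with columns sample, region, state, event coordinates and
    envelope length.
    """
    rows = []
    one_way = 0
    for e in events:
        best = None
        for entry in catalog:
            if entry.state != e.state:
                continue
            fe, fc = reciprocal_overlap(e.interval, entry.interval)
            if (fe >= threshold) != (fc >= threshold) and max(fe, fc) > 0:
                one_way += 1
            if fe >= threshold and fc >= threshold:
                key = (-min(fe, fc), entry.length, entry.region)
                if best is None or key < best[0]:
                    best = (key, entry)
        if best is not None:
            entry = best[1]
            rows.append({
                "sample": e.sample, "region": entry.region, "state": e.state,
                "chrom": e.chrom, "start": e.start, "end": e.end,
                "envelope_length": e.envelope_length,
            })
    if one_way:
        logger.info("catalog match: %d event/region pairs passed one-way only", one_way)
    df = pd.DataFrame(rows, columns=["sample", "region", "state", "chrom",
                                     "start", "end", "envelope_length"])
    logger.info("catalog match (RO >= %g): %d events, %d assigned",
                threshold, len(events), len(df))
    return df


def region_carrier_matrix(assignments: pd.DataFrame, samples: list[str],
                          regions: list[str]) -> pd.DataFrame:
    """Binary subjects x regions carrier matrix (>= 1 event in a region -> 1)."""
    mat = pd.DataFrame(0, index=pd.Index(samples, name="subject_id"),
                       columns=regions, dtype=int)
    for row in assignments.itertuples(index=False):
        if row.sample in mat.index and row.region in mat.columns:
            mat.at[row.sample, row.region] = 1
    return mat


def classify_frequency(carrier_counts: dict[str, int], n_subjects: int,
                       common_freq: float = 0.01) -> dict[str, str]:
    """Classify each region common (carrier frequency >= threshold) or rare.

    A region with zero carriers is rare and flagged absent in the log.
    """
    out = {}
    for region, count in carrier_counts.items():
        if count > n_subjects:
            raise ValidationError(f"region {region}: carriers exceed cohort size")
        if count == 0:
            logger.info("region %s: absent from cohort (0 carriers)", region)
        out[region] = "common" if count / n_subjects >= common_freq else "rare"
    return out


# ---------------------------------------------------------------------------
# Aggregate scores
# ---------------------------------------------------------------------------

def build_cnv_scores(assignments: pd.DataFrame, classification: dict[str, str],
                     samples: list[str], classes: set[str] = frozenset({"rare"}),
                     min_length: int | None = None) -> pd.Series:
    """Per-subject count of catalog-region events in the given frequency class.

    ``min_length`` (bp) optionally restricts to events whose boundary
    envelope is at least that long (the >=100-kb score variant).
    """
    counts = pd.Series(0, index=pd.Index(samples, name="subject_id"), dtype=int)
    for row in assignments.itertuples(index=False):
        if classification.get(row.region) not in classes:
            continue
        if min_length is not None and row.envelope_length < min_length:
            continue
        if row.sample in counts.index:
            counts[row.sample] += 1
    return counts


def compute_burden(events: list[ConsensusCnv], n_subjects: int,
                   samples: list[str], common_freq: float = 0.01,
                   cluster_threshold: float = 0.5) -> pd.Series:
    """Genome-wide rare-CNV burden: per-subject count of rare consensus events.

    Event frequency is defined genome-wide, not only at catalog regions:
    events across subjects are clustered into loci by the same
    reciprocal-overlap connected-component rule used for consensus merging,
    and a locus is rare when its distinct-carrier frequency is below
    ``common_freq``.
    """
    by_group: dict[tuple, list[ConsensusCnv]] = defaultdict(list)
    for e in events:
        by_group[(e.chrom, e.state)].append(e)

    burden = pd.Series(0, index=pd.Index(samples, name="subject_id"), dtype=int)
    for group in by_group.values():
        group = sorted(group, key=lambda e: (e.start, e.end, e.sample))
        n = len(group)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        # group sizes are small at cohort scale, so the quadratic pass is fine
        for i, j in itertools.combinations(range(n), 2):
            fa, fb = reciprocal_overlap(group[i].interval, group[j].interval)
            if fa >= cluster_threshold and fb >= cluster_threshold:
                parent[find(i)] = find(j)
        clusters: dict[int, list[ConsensusCnv]] = defaultdict(list)
        for i in range(n):
            clusters[find(i)].append(group[i])
        for cluster in clusters.values():
            carriers = {e.sample for e in cluster}
            if len(carriers) / n_subjects < common_freq:
                for e in cluster:
                    if e.sample in burden.index:
                        burden[e.sample] += 1
    return burden
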