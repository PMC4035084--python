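import itertools

import numpy as np
import pandas as pd
import pytest

from snpcnv.cnv import (ConsensusCnv, build_cnv_scores, classify_frequency,
                        compute_burden, filter_calls_by_confidence,
                        match_catalog, merge_consensus, region_carrier_matrix,
                        remove_excluded_regions, reciprocal_overlap)
from snpcnv.io import CnvCall, CnvRegionCatalogEntry, ValidationError
from snpcnv.simulate import (CallerProfile, SimulationDesign,
                             simulate_cnv_calls)


def _call(caller, start, end, sample="S1", state="DEL", lbf=20.0, chrom="chr1"):
    return CnvCall(sample=sample, chrom=chrom, start=start, end=end,
                   state=state, copy_number=1 if state == "DEL" else 3,
                   lbf=lbf, caller=caller)


# ---------------------------------------------------------------------------
# Confidence filter
# ---------------------------------------------------------------------------

def test_lbf_filter_boundary_is_strict():
    calls = [_call("a", 0, 10, lbf=9.99), _call("a", 0, 10, lbf=10.0)]
    kept = filter_calls_by_confidence(calls, 10.0)
    assert [c.lbf for c in kept] == [10.0]


def test_lbf_filter_keeps_callers_without_metric():
    calls = [_call("a", 0, 10, lbf=None), _call("a", 0, 10, lbf=2.0)]
    kept = filter_calls_by_confidence(calls, 10.0)
    assert len(kept) == 1 and kept[0].lbf is None


def test_lbf_filter_counts():
    assert filter_calls_by_confidence([], 10.0) == []
    calls = [_call("a", 0, 10, lbf=v) for v in (5, 9, 10, 15, 30)]
    assert len(filter_calls_by_confidence(calls, 10.0)) == 3


# ---------------------------------------------------------------------------
# Reciprocal overlap
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a,b,expected", [
    (("chr1", 100, 200), ("chr1", 100, 200), (1.0, 1.0)),
    (("chr1", 100, 200), ("chr1", 300, 400), (0.0, 0.0)),
    (("chr1", 100, 200), ("chr2", 100, 200), (0.0, 0.0)),
    (("chr1", 100, 200), ("chr1", 150, 250), (0.5, 0.5)),
    (("chr1", 0, 1000), ("chr1", 400, 500), (0.1, 1.0)),
])
def test_reciprocal_overlap(a, b, expected):
    assert reciprocal_overlap(a, b) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Consensus merging
# ---------------------------------------------------------------------------

def test_two_of_three_callers_make_consensus():
    calls = {"a": [_call("a", 1000, 2000)], "b": [_call("b", 1000, 2000)],
             "c": []}
    events = merge_consensus(calls)
    assert len(events) == 1
    assert events[0].callers == frozenset({"a", "b"})


def test_single_caller_never_emits_consensus():
    events = merge_consensus({"a": [_call("a", 1000, 2000)], "b": []})
    assert events == []


def test_consensus_interval_intersection_envelope_union():
    calls = {"a": [_call("a", 1000, 2000)], "b": [_call("b", 1100, 2100)],
             "c": [_call("c", 950, 1900)]}
    # pairwise reciprocal overlaps all >= 0.5 (checked by brute force)
    for x, y in itertools.combinations([c[0] for c in calls.values()], 2):
        fa, fb = reciprocal_overlap(x.interval, y.interval)
        assert fa >= 0.5 and fb >= 0.5
    events = merge_consensus(calls)
    assert len(events) == 1
    e = events[0]
    assert (e.start, e.end) == (1100, 1900)
    assert (e.envelope_start, e.envelope_end) == (950, 2100)


def test_consensus_requires_state_match():
    calls = {"a": [_call("a", 1000, 2000, state="DEL")],
             "b": [_call("b", 1000, 2000, state="DUP")]}
    assert merge_consensus(calls) == []


def test_consensus_invariant_to_caller_order():
    base = {"a": [_call("a", 1000, 2000), _call("a", 9000, 9500, sample="S2")],
            "b": [_call("b", 1050, 2050)],
            "c": [_call("c", 950, 1950), _call("c", 9100, 9600, sample="S2")]}
    ref = merge_consensus(base)
    for perm in itertools.permutations(base):
        shuffled = {k: list(reversed(base[k])) for k in perm}
        assert merge_consensus(shuffled) == ref


def test_removing_a_caller_never_grows_consensus():
    rng = np.random.default_rng(21)
    callers = {}
    for name in ("a", "b", "c"):
        calls = []
        for _ in range(15):
            start = int(rng.integers(0, 50_000))
            calls.append(_call(name, start, start + int(rng.integers(500, 5000))))
        callers[name] = calls
    full = merge_consensus(callers)
    for drop in ("a", "b", "c"):
        reduced = merge_consensus({k: v for k, v in callers.items() if k != drop})
        assert len(reduced) <= len(full)


def test_consensus_fields_validated():
    with pytest.raises(ValidationError):
        ConsensusCnv("S1", "chr1", 100, 200, "DEL", frozenset({"a"}), 100, 200)
    with pytest.raises(ValidationError):
        ConsensusCnv("S1", "chr1", 100, 200, "DEL", frozenset({"a", "b"}), 150, 200)


# ---------------------------------------------------------------------------
# Exclusion regions
# ---------------------------------------------------------------------------

def _event(start, end, sample="S1", state="DEL", chrom="chr1"):
    return ConsensusCnv(sample, chrom, start, end, state,
                        frozenset({"a", "b"}), start, end)


def test_exclusion_any_overlap_rule():
    events = [_event(100, 200), _event(999, 1200), _event(1500, 1600)]
    kept = remove_excluded_regions(events, [("chr1", 0, 1000)])
    # 1-bp overlap removes; abutting (half-open) retains
    assert [(e.start, e.end) for e in kept] == [(1500, 1600)]
    kept2 = remove_excluded_regions([_event(1000, 1100)], [("chr1", 0, 1000)])
    assert len(kept2) == 1


# ---------------------------------------------------------------------------
# Catalog matching and frequency classes
# ---------------------------------------------------------------------------

CATALOG = [
    CnvRegionCatalogEntry("delA", "chr1", 1000, 2000, "DEL"),
    CnvRegionCatalogEntry("dupB", "chr1", 5000, 6000, "DUP"),
]


def test_match_identical_interval():
    df = match_catalog([_event(1000, 2000)], CATALOG)
    assert df["region"].tolist() == ["delA"]


def test_match_rejects_state_mismatch():
    df = match_catalog([_event(5000, 6000, state="DEL")], CATALOG)
    assert df.empty


def test_match_at_45_percent_reciprocal():
    # event shares 450/1000 = 45% with the catalog region and vice versa
    df = match_catalog([_event(1550, 2550)], CATALOG, threshold=0.4)
    assert df["region"].tolist() == ["delA"]
    df2 = match_catalog([_event(1650, 2650)], CATALOG, threshold=0.4)  # 35%
    assert df2.empty


def test_classify_frequency_one_percent_boundary():
    cls = classify_frequency({"a": 24, "b": 23, "c": 0}, 2348)
    assert cls == {"a": "common", "b": "rare", "c": "rare"}


def test_carrier_matrix_binary_even_with_two_events():
    df = match_catalog([_event(1000, 2000), _event(1010, 1990)], CATALOG)
    mat = region_carrier_matrix(df, ["S1", "S2"], ["delA", "dupB"])
    assert mat.loc["S1", "delA"] == 1
    assert mat.loc["S2"].sum() == 0


def test_cnv_scores_and_length_filter():
    events = [_event(1000, 2000), _event(5000, 6000, state="DUP")]
    df = match_catalog(events, CATALOG)
    cls = {"delA": "rare", "dupB": "rare"}
    scores = build_cnv_scores(df, cls, ["S1"], {"rare"})
    assert scores["S1"] == 2
    big = build_cnv_scores(df, cls, ["S1"], {"rare"}, min_length=100_000)
    assert big["S1"] == 0  # both events are far below 100 kb
    assert build_cnv_scores(df.iloc[:0], cls, ["S1"], {"rare"})["S1"] == 0


# ---------------------------------------------------------------------------
# Genome-wide burden
# ---------------------------------------------------------------------------

def test_burden_counts_rare_events_only():
    n = 200
    events = []
    # a common locus: 10 carriers (5%) at the same interval
    for i in range(10):
        events.append(_event(1000, 2000, sample=f"S{i}"))
    # rare singleton events elsewhere (1/200 = 0.5% < 1%)
    events.append(_event(50_000, 60_000, sample="S0"))
    events.append(_event(80_000, 95_000, sample="S0"))
    samples = [f"S{i}" for i in range(n)]
    burden = compute_burden(events, n, samples, common_freq=0.01)
    assert burden["S0"] == 2      # the 5%-frequency locus does not count
    assert burden["S1"] == 0


def test_burden_mean_matches_planted_rate(small_catalog):
    """With spurious-only callers the per-subject burden is Poisson-thinned;
    perfect planted rare loci give mean burden = sum of rare locus rates."""
    from snpcnv.simulate import CnvLocus
    loci = [CnvLocus(f"L{i}", f"chr{i+1}", 1_000_000, 1_050_000, "DEL",
                     freq=0.005) for i in range(8)]
    design = SimulationDesign(n_subjects=2000, catalog=small_catalog,
                              cnv_loci=loci)
    profiles = [CallerProfile(f"c{i}", sensitivity=1.0, boundary_jitter_sd=0.0,
                              false_call_rate=0.0) for i in range(2)]
    calls, carriers = simulate_cnv_calls(design, profiles, seed=31)
    events = merge_consensus(calls)
    burden = compute_burden(events, 2000, list(carriers.index), common_freq=0.01)
    lam = 8 * 0.005
    se = np.sqrt(lam / 2000)      # Poisson-binomial SE of the mean
    assert abs(burden.mean() - lam) < 3 * se


def test_noise_free_pipeline_recovers_planted_truth(small_design):
    profiles = [CallerProfile(f"c{i}", sensitivity=1.0, boundary_jitter_sd=0.0,
                              false_call_rate=0.0) for i in range(3)]
    calls, carriers = simulate_cnv_calls(small_design, profiles, seed=41)
    events = merge_consensus(calls)
    catalog = [l.catalog_entry() for l in small_design.cnv_loci]
    df = match_catalog(events, catalog)
    mat = region_carrier_matrix(df, list(carriers.index),
                                [c.region for c in catalog])
    pd.testing.assert_frame_equal(mat.astype(bool), carriers,
                                  check_names=False)
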