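"""Benchmark matching, metrics and breakpoint statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svrefine.evaluator import (PRESETS, CallRecord, MatchParams, eligible,
                                breakpoint_context, from_locus, match_calls,
                                relative_rate, sv_breakpoints)
from svrefine.io_formats import AnnotationTrack, GenomeSequence, SVLocus

from conftest import make_rng, random_seq


def rec(chrom, start, size, svtype="DEL"):
    if svtype == "INS":
        return CallRecord(chrom, start, start, 0, size, "INS")
    return CallRecord(chrom, start, start + size, size,
                      size if svtype == "INV" else 0, svtype)


def test_identical_sets_perfect_strict():
    calls = [rec("c", 100, 80), rec("c", 1000, 200, "INS"),
             rec("c", 3000, 500, "INV")]
    res = match_calls(calls, list(calls), PRESETS["strict"])
    assert (res.precision, res.recall, res.f1) == (1.0, 1.0, 1.0)


def test_shifted_call_strict_vs_relaxed():
    truth = [rec("c", 1000, 300)]
    calls = [rec("c", 1010, 300)]
    strict = match_calls(calls, truth, PRESETS["strict"])
    relaxed = match_calls(calls, truth, PRESETS["relaxed"])
    assert strict.tp == 0 and relaxed.tp == 1


def test_metric_arithmetic_fixture():
    """tp=2, fp=1, fn=3: P=2/3, R=2/5, F1 = 2*(2/3)(2/5)/((2/3)+(2/5)) = 0.5."""
    truth = [rec("c", i * 10_000, 100) for i in range(5)]
    calls = [rec("c", 0, 100), rec("c", 10_000, 100),
             rec("c", 90_000, 100)]  # third call matches nothing
    res = match_calls(calls, truth, PRESETS["strict"])
    assert (res.tp, res.fp, res.fn) == (2, 1, 3)
    assert res.precision == pytest.approx(2 / 3)
    assert res.recall == pytest.approx(2 / 5)
    assert res.f1 == pytest.approx(0.5)


def _exhaustive_max_tp(calls, truth, params):
    """Oracle: maximum one-to-one matching by brute force over injections."""
    elig = [[eligible(c, t, params) for t in truth] for c in calls]
    best = 0
    n, m = len(calls), len(truth)
    small = min(n, m)
    for k in range(small, 0, -1):
        for cs in itertools.combinations(range(n), k):
            for ts in itertools.permutations(range(m), k):
                if all(elig[c][t] for c, t in zip(cs, ts)):
                    return k
    return best


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_matching_equals_exhaustive_oracle(seed):
    rng = make_rng(100 + seed)
    truth = [rec("c", int(p), int(s), ["DEL", "INS"][int(rng.integers(2))])
             for p, s in zip(rng.integers(0, 50_000, 8),
                             rng.integers(60, 400, 8))]
    calls = []
    for t in truth[:6]:
        jitter = int(rng.integers(-60, 60))
        calls.append(rec("c", t.ref_start + jitter, max(t.ref_len, t.qry_len),
                         t.svtype))
    calls += [rec("c", int(rng.integers(0, 50_000)), 100) for _ in range(3)]
    for params in (PRESETS["strict"], PRESETS["relaxed"]):
        got = match_calls(calls, truth, params)
        assert got.tp == _exhaustive_max_tp(calls, truth, params)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.lists(st.tuples(st.integers(0, 30_000), st.integers(60, 400),
                          st.sampled_from(["DEL", "INS"])),
                min_size=1, max_size=8))
def test_strict_subset_of_relaxed(raw):
    truth = [rec("c", i * 3000 + 100, 150) for i in range(6)]
    calls = [rec("c", p, s, t) for p, s, t in raw]
    strict = match_calls(calls, truth, PRESETS["strict"])
    relaxed = match_calls(calls, truth, PRESETS["relaxed"])
    # every strict-eligible pair is relaxed-eligible, so TP can only grow
    assert strict.tp <= relaxed.tp
    for c, t in strict.match_pairs:
        assert eligible(c, t, PRESETS["relaxed"])


def test_sub_matches_ins_and_del_sides():
    sub = CallRecord("c", 1000, 1003, 3, 504, "SUB")
    ins_truth = CallRecord("c", 1000, 1000, 0, 504, "INS")
    del_truth = CallRecord("c", 1000, 1003, 3, 0, "DEL")
    relaxed = PRESETS["relaxed"]
    assert eligible(sub, ins_truth, relaxed)
    assert not eligible(sub, ins_truth, relaxed, sub_flex=False)
    # the 3-bp reference side cannot satisfy sizemin-like rules vs DEL of 3
    assert eligible(sub, del_truth, MatchParams(refdist=50, pctsize=0.9,
                                                pctovl=0.9))


def test_from_locus_adapter():
    dup = SVLocus("x", "c", 100, 100, "DUP", 250)
    adapted = from_locus(dup)
    assert adapted.svtype == "INS" and adapted.qry_len == 250


# ---------------------------------------------------------------------------
# statistics

def _track():
    return AnnotationTrack(
        {"genic": {"c": [(0, 1000)]},
         "regulatory": {"c": [(1000, 4000)]},
         "intergenic": {"c": [(4000, 10_000)]}},
        {"genic": 1000, "regulatory": 3000, "intergenic": 6000})


def test_relative_rate_hand_computed():
    track = _track()
    bps = ([("c", 500)] * 2 + [("c", 2000)] * 6 + [("c", 5000)] * 2)
    rates = relative_rate(bps, track)
    assert rates["genic"] == pytest.approx(2.0)
    assert rates["regulatory"] == pytest.approx(2.0)
    assert rates["intergenic"] == pytest.approx(1 / 3)


def test_relative_rate_uniform_null():
    """Uniformly scattered breakpoints: every enrichment is 1 within three
    binomial standard errors."""
    rng = make_rng(101)
    track = _track()
    n = 1000
    bps = [("c", int(p)) for p in rng.integers(0, 10_000, n)]
    rates = relative_rate(bps, track)
    for cls, frac in (("genic", 0.1), ("regulatory", 0.3),
                      ("intergenic", 0.6)):
        sigma = np.sqrt(frac * (1 - frac) / n) / frac
        assert abs(rates[cls] - 1.0) <= 3 * sigma


def test_relative_rate_degenerate_cases():
    track = _track()
    rates = relative_rate([("c", 500)] * 7, track)
    assert rates["genic"] == pytest.approx(10.0)
    assert rates["regulatory"] == 0.0 and rates["intergenic"] == 0.0
    empty = AnnotationTrack({"genic": {}, "regulatory": {}, "intergenic": {}},
                            {"genic": 0, "regulatory": 3000,
                             "intergenic": 6000})
    assert relative_rate([("c", 1)], empty)["genic"] is None


def test_breakpoint_context_extremes():
    g = GenomeSequence.from_raw("c", "AT" * 200 + "GC" * 200)
    at = breakpoint_context([("c", 100)], [g], window=50)
    gc = breakpoint_context([("c", 500)], [g], window=50)
    assert at["per_breakpoint"][0] == 1.0
    assert gc["per_breakpoint"][0] == 0.0


def test_breakpoint_context_background():
    rng = make_rng(102)
    g = GenomeSequence.from_raw("c", random_seq(rng, 100_000, gc=0.4))
    pts = [("c", int(p)) for p in rng.integers(100, 99_900, 200)]
    ctx = breakpoint_context(pts, [g], window=50)
    n_bases = 200 * 100
    sigma = np.sqrt(0.6 * 0.4 / n_bases)
    assert abs(ctx["mean_at_fraction"] - 0.6) <= 4 * sigma + 0.01
    assert abs(ctx["background_at_fraction"] - 0.6) <= 0.01


def test_breakpoint_context_truncation_flagged():
    g = GenomeSequence.from_raw("c", "ACGT" * 30)
    ctx = breakpoint_context([("c", 3)], [g], window=50)
    assert ctx["truncated"] == 1


def test_sv_breakpoints_extraction(curation):
    bps = sv_breakpoints(curation.svs)
    spans = sum(1 for sv in curation.svs if sv.ref_end != sv.ref_start)
    points = len(curation.svs) - spans
    assert len(bps) == 2 * spans + points
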