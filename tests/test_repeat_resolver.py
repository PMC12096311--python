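"""Copy catalog, tandem detection, optimal pairing and breakpoint placement."""

import itertools

import numpy as np
import pytest

from svrefine.repeat_resolver import (CopyCatalog, _exhaustive_assignment,
                                      apply_events, assign_pattern,
                                      decompose_segments, detect_tandem_unit,
                                      match_copies, place_breakpoints,
                                      resolve_pair)
from svrefine.seqs import revcomp

from conftest import make_rng, random_seq


# ---------------------------------------------------------------------------
# tandem detection

def brute_force_period(seq, max_mismatch_frac=0.1):
    """Oracle: smallest period whose shifted self-agreement tolerates the
    mismatch budget, by direct scanning."""
    n = len(seq)
    for p in range(2, n // 2 + 1):
        mism = sum(1 for i in range(n - p) if seq[i] != seq[i + p])
        if mism <= max_mismatch_frac * (n - p):
            return (p, n // p)
    return None


def test_tandem_exact():
    assert detect_tandem_unit("ACGTT" * 8) == (5, 8)


def test_tandem_with_snp_vs_oracle():
    s = list("ACGTT" * 8)
    s[7] = "A"
    s = "".join(s)
    assert detect_tandem_unit(s) == brute_force_period(s) == (5, 8)


def test_tandem_random_none():
    rng = make_rng(20)
    assert detect_tandem_unit(random_seq(rng, 200)) is None


# ---------------------------------------------------------------------------
# copy matching

def test_exhaustive_assignment_counterexample():
    """The greedy choice (r1,q2)=0.92 path fails; the optimal assignment
    pairs (r1,q1),(r2,q2) — verified against the 2-permutation oracle."""
    sim = [[0.99, 0.92], [0.93, 0.98]]
    got = _exhaustive_assignment(sim, 2, 2)
    best = max(itertools.permutations(range(2)),
               key=lambda p: sum(sim[i][p[i]] for i in range(2)))
    assert sorted(got) == sorted(enumerate(best)) == [(0, 0), (1, 1)]


@pytest.mark.parametrize("n,m", [(2, 3), (3, 3), (4, 2), (4, 4)])
def test_assignment_matches_oracle(n, m):
    rng = make_rng(21)
    for _ in range(20):
        sim = rng.random((n, m)).tolist()
        got = _exhaustive_assignment(sim, n, m)
        small = min(n, m)
        best = -1
        for combo in itertools.permutations(range(m), small) if n <= m else \
                itertools.permutations(range(n), small):
            if n <= m:
                sc = sum(sim[i][j] for i, j in enumerate(combo))
            else:
                sc = sum(sim[i][j] for j, i in enumerate(combo))
            best = max(best, sc)
        assert sum(sim[i][j] for i, j in got) == pytest.approx(best)


def test_tie_break_leftmost():
    """One reference copy, two identical query copies: the leftmost query
    copy pairs, the rightmost is variant material."""
    from svrefine.repeat_resolver import Copy, SegmentFamily
    rng = make_rng(22)
    copy = random_seq(rng, 300)
    R = random_seq(rng, 200) + copy + random_seq(rng, 200)
    Q = random_seq(rng, 200) + copy + random_seq(rng, 150) + copy
    fam = SegmentFamily(0, [Copy("ref", (200, 500)),
                            Copy("qry", (200, 500)),
                            Copy("qry", (650, 950))])
    catalog = CopyCatalog(R, Q, [fam])
    pairing = match_copies(catalog)
    qry_copies = sorted((c for c in fam.copies if c.genome == "qry"),
                        key=lambda c: c.interval)
    paired_qry = {id(q) for _, q in pairing.pairs}
    assert id(qry_copies[0]) in paired_qry       # leftmost paired
    assert any(id(c) == id(qry_copies[-1]) for c in pairing.unpaired_qry)


# ---------------------------------------------------------------------------
# catalog

def test_dispersed_copies_one_family():
    rng = make_rng(23)
    unit = random_seq(rng, 500)
    R = (random_seq(rng, 600) + unit + random_seq(rng, 600) + unit +
         random_seq(rng, 600))
    Q = (random_seq(rng, 500) + unit + random_seq(rng, 400) + unit +
         random_seq(rng, 400) + unit + random_seq(rng, 500))
    catalog = decompose_segments(R, Q)
    fams = [f for f in catalog.families if f.is_repeat]
    assert len(fams) == 1
    assert fams[0].count("ref") == 2 and fams[0].count("qry") == 3


def test_no_self_similarity_unique_context():
    rng = make_rng(24)
    R = random_seq(rng, 3000)
    Q = R[:1400] + R[1600:]
    catalog = decompose_segments(R, Q)
    assert catalog.is_unique_context


def test_subsegment_containment_recorded():
    """A short segment with an extra standalone copy inside a larger
    repeat's copies is recorded as contained and collapsed."""
    rng = make_rng(25)
    small = random_seq(rng, 200)
    big = random_seq(rng, 300) + small + random_seq(rng, 300)
    R = (random_seq(rng, 500) + big + random_seq(rng, 400) + big +
         random_seq(rng, 400) + small + random_seq(rng, 500))
    Q = R
    catalog = decompose_segments(R, Q)
    assert catalog.containments
    contained = {id(a) for a, _ in catalog.containments}
    assert all(a.collapsed for a, _ in catalog.containments)
    assert contained


# ---------------------------------------------------------------------------
# resolution

def test_unique_deletion_single_placement():
    rng = make_rng(26)
    R = random_seq(rng, 2000)
    Q = R[:900] + R[1100:]
    (ev,) = resolve_pair(R, Q)
    assert (ev.kind, ev.r_start, ev.r_end) == ("del", 900, 1100)
    assert ev.amb_len == 1


def test_tandem_deletion_ambiguity_enumeration():
    """Removing two units from a perfect five-unit array: the equivalent
    placements span the array; oracle enumerates them directly."""
    rng = make_rng(27)
    unit = random_seq(rng, 100)
    R = random_seq(rng, 700) + unit * 5 + random_seq(rng, 700)
    Q = R[:700] + unit * 3 + R[1200:]
    (ev,) = resolve_pair(R, Q)
    placements = [x for x in range(len(R) - 200 + 1)
                  if R[:x] + R[x + 200:] == Q]
    assert ev.amb == (placements[0], placements[-1] + 1)
    assert ev.amb_len == 301
    assert ev.r_start == placements[0]  # canonical leftmost


def test_left_shift_normalization_property():
    """The canonical placement cannot be shifted one base left while still
    reconstructing the query."""
    rng = make_rng(28)
    for trial in range(5):
        R = random_seq(rng, 1500) + random_seq(rng, 80) * 3 + random_seq(rng, 1500)
        cut = int(rng.integers(500, 3000))
        ln = int(rng.integers(60, 200))
        Q = R[:cut] + R[cut + ln:]
        for ev in resolve_pair(R, Q):
            if ev.kind != "del":
                continue
            x = ev.r_start - 1
            if x >= 0:
                assert R[:x] + R[x + ev.ref_len:] != Q


def test_reconstruction_random_edit_scripts():
    rng = make_rng(29)
    for trial in range(8):
        R = random_seq(rng, 6000)
        edits = sorted(rng.choice(np.arange(500, 5500, 700), 3, replace=False))
        Q = R
        for pos in reversed(edits):
            kind = int(rng.integers(3))
            if kind == 0:
                Q = Q[:pos] + Q[pos + int(rng.integers(60, 300)):]
            elif kind == 1:
                Q = Q[:pos] + random_seq(rng, int(rng.integers(60, 300))) + Q[pos:]
            else:
                Q = Q[:pos] + random_seq(rng, 120) + Q[pos + 100:]
        events = resolve_pair(R, Q)
        assert apply_events(R, events) == Q


def test_sub_vs_ins_distinction():
    rng = make_rng(30)
    R = random_seq(rng, 3000)
    # 3-bp-vs-504-bp substitution: both alleles non-empty and unalignable
    Q = R[:1500] + random_seq(rng, 504) + R[1503:]
    events = [e for e in resolve_pair(R, Q) if max(e.ref_len, e.qry_len) > 50]
    assert len(events) == 1 and events[0].kind == "sub"


def test_inversion_candidate_detected():
    rng = make_rng(31)
    R = random_seq(rng, 6000)
    Q = R[:2000] + revcomp(R[2000:4000]) + R[4000:]
    events = resolve_pair(R, Q)
    kinds = [e.kind for e in events]
    assert kinds == ["inv_candidate"]


def test_place_breakpoints_complex_escalation():
    """Copies whose similarity-optimal pairing crosses the positional order
    escalate the region instead of emitting calls."""
    rng = make_rng(32)
    u = random_seq(rng, 600)

    def mut(seq, rate):
        arr = list(seq)
        for i in rng.choice(len(arr), int(rate * len(arr)), replace=False):
            arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
        return "".join(arr)

    r1, r2 = mut(u, 0.05), mut(u, 0.05)
    R = random_seq(rng, 2000) + r1 + random_seq(rng, 1500) + r2 + random_seq(rng, 2000)
    Q = R[:2000] + mut(r2, 0.003) + R[2600:4100] + mut(r1, 0.003) + R[4700:]
    catalog = decompose_segments(R, Q)
    pairing = match_copies(catalog)
    assert pairing.crossing
    calls, status = place_breakpoints(catalog, pairing)
    assert status == "complex" and calls == []


def test_pattern_labels_match_generator(suite, curation, strict_eval):
    """On the noiseless suite the resolver-inferred repeat pattern equals the
    generator's label for every recovered SV."""
    for call, truth in strict_eval.match_pairs:
        assert call.pattern == truth.pattern
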