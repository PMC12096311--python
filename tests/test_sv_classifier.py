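"""SV typing rules, inversion criteria and benchmark summaries."""

import pytest

from svrefine.repeat_resolver import RawEvent, resolve_pair
from svrefine.seqs import revcomp
from svrefine.sv_classifier import (ResolvedSV, check_inversion, classify,
                                    summarize)

from conftest import make_rng, random_seq


def test_classify_residual_rules():
    rng = make_rng(40)
    qry = random_seq(rng, 504)
    assert classify("", qry) == "INS"
    assert classify(qry, "") == "DEL"
    assert classify("", "") is None
    assert classify("", random_seq(rng, 30)) is None      # below size floor
    # both residuals non-empty, mutually unalignable -> SUB even though one
    # side is only 3 bp (the floor applies to the longer side)
    assert classify(random_seq(rng, 3), qry) == "SUB"
    # residuals that still align must be decomposed, not typed
    a = random_seq(rng, 300)
    b = list(a)
    b[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[10]]
    assert classify(a, "".join(b)) == "DECOMPOSE"


def test_classify_inversion_path():
    rng = make_rng(41)
    a = random_seq(rng, 2000)
    assert classify(a, revcomp(a), orientation_evidence=True) == "INV"
    assert classify(a, revcomp(a), orientation_evidence=True,
                    gap_mask=(True, False)) != "INV"


def _inv_setup(rng, div_rev=0.0):
    R = random_seq(rng, 8000)
    inv = revcomp(R[3000:5000])
    Q = R[:3000] + inv + R[5000:]
    return R, Q


def test_check_inversion_clean_true():
    rng = make_rng(42)
    R, Q = _inv_setup(rng)
    (ev,) = resolve_pair(R, Q)
    assert ev.kind == "inv_candidate"
    assert check_inversion(R, Q, ev)


def test_check_inversion_gap_false():
    rng = make_rng(43)
    R, Q = _inv_setup(rng)
    (ev,) = resolve_pair(R, Q)
    assert not check_inversion(R, Q, ev, ref_gap=True)
    assert not check_inversion(R, Q, ev, qry_gap=True)
    assert not check_inversion(R, Q, ev, flanks_forward=False)


def test_check_inversion_forward_alternative_wins():
    """A reverse-orientation match at 90% is rejected when a forward copy
    of the same interval aligns at 99% elsewhere in the window."""
    rng = make_rng(44)
    x = random_seq(rng, 1000)

    def mut(seq, rate):
        arr = list(seq)
        for i in rng.choice(len(arr), int(rate * len(arr)), replace=False):
            arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
        return "".join(arr)

    R = random_seq(rng, 1500) + x + random_seq(rng, 1500)
    # query: candidate interval is a 10%-diverged reverse copy, but a 1%-
    # diverged forward copy sits nearby
    Q = (random_seq(rng, 500) + revcomp(mut(x, 0.10)) + random_seq(rng, 500)
         + mut(x, 0.01) + random_seq(rng, 500))
    ev = RawEvent(1500, 2500, 500, 1500, Q[500:1500], "inv_candidate")
    assert not check_inversion(R, Q, ev)


def test_summary_partition_identity(curation):
    s = summarize(curation.svs)
    assert s["total"] == sum(s["by_type"].values())
    assert s["total"] == sum(s["by_pattern"].values())


def test_no_inv_intersects_gap(suite, curation):
    ref_by = {g.name: g for g in suite.ref_genomes}
    qry_by = {g.name: g for g in suite.qry_genomes}
    for sv in curation.svs:
        if sv.svtype != "INV":
            continue
        assert not ref_by[sv.chrom].gap_in(sv.ref_start, sv.ref_end)
        assert not qry_by[sv.qry_chrom].gap_in(sv.qry_start, sv.qry_end)


def test_swap_symmetry_on_region_pairs():
    """Swapping reference and query exchanges INS and DEL, maps SUB to SUB
    with allele sides exchanged, and keeps INV an INV."""
    rng = make_rng(45)
    R = random_seq(rng, 4000)
    cases = {
        "del": R[:1500] + R[1700:],
        "ins": R[:1500] + random_seq(rng, 200) + R[1500:],
        "sub": R[:1500] + random_seq(rng, 300) + R[1900:],
        "inv": R[:1500] + revcomp(R[1500:2600]) + R[2600:],
    }
    flipped = {"del": "ins", "ins": "del", "sub": "sub",
               "inv": "inv_candidate"}
    for kind, Q in cases.items():
        fwd = [e.kind for e in resolve_pair(R, Q)
               if max(e.ref_len, e.qry_len) > 50]
        rev = [e.kind for e in resolve_pair(Q, R)
               if max(e.ref_len, e.qry_len) > 50]
        expect = "inv_candidate" if kind == "inv" else kind
        assert fwd == [expect]
        assert rev == [flipped[expect] if expect != "inv_candidate"
                       else "inv_candidate"]


def test_dup_label_never_emitted(curation):
    assert all(sv.svtype in ("INS", "DEL", "INV", "SUB")
               for sv in curation.svs)


def test_insertion_source_recorded(curation):
    """Repeat-context insertions carry their source copy when identifiable."""
    repeat_ins = [sv for sv in curation.svs
                  if sv.svtype == "INS" and sv.pattern != "unique"]
    assert repeat_ins
    assert any(sv.source for sv in repeat_ins)


def test_resolved_sv_size_floor_invariants(curation):
    for sv in curation.svs:
        if sv.svtype == "INS":
            assert sv.ref_len == 0 and sv.qry_len > 50
        elif sv.svtype == "DEL":
            assert sv.qry_len == 0 and sv.ref_len > 50
        elif sv.svtype == "SUB":
            assert sv.ref_len >= 1 and sv.qry_len >= 1
            assert max(sv.ref_len, sv.qry_len) > 50
        else:
            assert sv.ref_len == sv.qry_len
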