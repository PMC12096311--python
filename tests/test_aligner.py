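"""Seeding, chaining and identity against independent oracles."""

import numpy as np
import pytest
from Bio import Align

from svrefine.aligner import (align_pair, chain_and_extend, copy_similarity,
                              oriented_similarity, seed_anchors, self_align)
from svrefine.seqs import revcomp

from conftest import make_rng, random_seq


def brute_force_maximal_matches(a, b, k):
    """Quadratic-scan oracle: merge matching k-mer pairs into maximal runs,
    independent of the index-based implementation."""
    pairs = {(i, j) for i in range(len(a) - k + 1)
             for j in range(len(b) - k + 1)
             if a[i:i + k] == b[j:j + k] and "N" not in a[i:i + k]}
    maximal = set()
    for i, j in pairs:
        if (i - 1, j - 1) in pairs:
            continue
        ln = k
        while (i + ln - k + 1, j + ln - k + 1) in pairs:
            ln += 1
        maximal.add((i, j, ln))
    return maximal


@pytest.mark.parametrize("seq_builder", [
    lambda rng: "A" * 50,
    lambda rng: random_seq(rng, 120) + random_seq(rng, 40) * 2,
])
def test_seed_anchors_match_quadratic_oracle(seq_builder):
    rng = make_rng(3)
    a = seq_builder(rng)
    got = {(x.q_pos, x.t_pos, x.length) for x in seed_anchors(a, a, 15)
           if x.strand == "+"}
    assert got == brute_force_maximal_matches(a, a, 15)


def test_self_identity_and_revcomp_strand():
    rng = make_rng(0)
    a = random_seq(rng, 1000)
    segs = align_pair(a, a)
    assert segs[0].identity == 1.0
    assert (segs[0].q_start, segs[0].q_end) == (0, 1000)

    rev = align_pair(a, revcomp(a))
    assert all(s.strand == "-" for s in rev)
    assert (rev[0].t_start, rev[0].t_end) == (0, 1000)
    # strand symmetry: coordinates map through the revcomp involution
    assert (rev[0].q_start, rev[0].q_end) == (0, 1000)


def test_single_snp_pair_one_segment():
    rng = make_rng(1)
    a = random_seq(rng, 1000)
    b = a[:500] + ("A" if a[500] != "A" else "C") + a[501:]
    segs = align_pair(a, b)
    assert len(segs) == 1
    assert segs[0].identity >= 0.999


def test_deletion_span_balance_vs_dp_oracle():
    """A 100-bp central deletion: segment spans account for exactly 100 bp,
    and identity agrees with a full dynamic-programming alignment."""
    rng = make_rng(2)
    a = random_seq(rng, 1000)
    b = a[:450] + a[550:]
    segs = align_pair(a, b)
    assert 1 <= len(segs) <= 2
    q_span = sum(s.q_end - s.q_start for s in segs)
    t_span = sum(s.t_end - s.t_start for s in segs)
    assert q_span - t_span == 100

    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=-2, open_gap_score=-4,
                                    extend_gap_score=-1)
    aln = aligner.align(a, b)[0]
    cols = aln.length
    matches = sum(x == y for x, y in zip(aln[0], aln[1]))
    oracle_identity = matches / cols
    ours = sum(s.matches for s in segs) / sum(s.block_len for s in segs)
    assert abs(ours - oracle_identity) <= 0.01


def test_unrelated_sequences_no_segment():
    rng = make_rng(4)
    a, b = random_seq(rng, 1000), random_seq(rng, 1000)
    assert align_pair(a, b) == []
    assert self_align(a) == []


def test_self_align_tandem_offsets_dotplot_oracle():
    rng = make_rng(5)
    unit = random_seq(rng, 100)
    arr = random_seq(rng, 300) + unit * 3 + random_seq(rng, 300)
    segs = self_align(arr)
    offsets = {s.t_start - s.q_start for s in segs if s.strand == "+"}
    assert offsets == {100, 200}


def test_self_align_palindrome_foldback():
    rng = make_rng(6)
    s = random_seq(rng, 400)
    pal = random_seq(rng, 200) + s + revcomp(s) + random_seq(rng, 200)
    segs = self_align(pal)
    assert any(g.strand == "-" for g in segs)


def test_copy_similarity_values():
    rng = make_rng(7)
    unit = random_seq(rng, 100)
    assert copy_similarity(unit, unit) == 1.0
    mutated = list(unit)
    for i in (5, 25, 45, 65, 85):
        mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
    assert copy_similarity(unit, "".join(mutated)) == pytest.approx(0.95)


def test_orientation_preference():
    """A forward near-identical copy beats a more diverged reverse one."""
    rng = make_rng(8)
    x = random_seq(rng, 500)
    fwd_copy = list(x)
    for i in rng.choice(500, 5, replace=False):
        fwd_copy[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[fwd_copy[i]]
    fwd, rev = oriented_similarity(x, "".join(fwd_copy))
    assert fwd > 0.98 > rev


def test_determinism():
    rng = make_rng(9)
    a = random_seq(rng, 800) + random_seq(rng, 100) * 2
    s1 = self_align(a)
    s2 = self_align(a)
    assert s1 == s2


def test_k_too_small_rejected():
    with pytest.raises(ValueError):
        seed_anchors("ACGTACGTACGT", "ACGTACGTACGT", k=4)


def test_n_kmers_never_seed():
    a = "ACGTACGTACGTACG" + "N" * 20 + "ACGTACGTACGTACG"
    anchors = seed_anchors(a, a, 15)
    for x in anchors:
        assert "N" not in a[x.q_pos:x.q_pos + x.length]
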