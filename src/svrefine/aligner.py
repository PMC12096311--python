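"""Desk-scale pairwise and self alignment.

Exact-match seeding, colinear chaining and gapped refinement between two
sequences (or a sequence against itself).  This is the alignment substrate
the rest of the toolkit runs on: flank anchoring, repeat-copy discovery and
copy-similarity scoring all go through the functions here.  Gapped alignment
and identity computation are delegated to edlib (infix and global modes with
extended CIGAR); the seeding, maximal-match merging and chaining logic is
local.

Identity is always matches / alignment columns, with gap columns counted in
the denominator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from .seqs import revcomp

DEFAULT_K = 15
DEFAULT_MIN_LEN = 45
DEFAULT_MIN_IDENTITY = 0.8
#: maximum per-side gap bridged when joining anchors into one chain
DEFAULT_MAX_GAP = 500

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class Anchor:
    """Maximal exact match: q[q_pos:q_pos+length] equals t[t_pos:t_pos+length]
    (forward) or its reverse complement (reverse)."""

    q_pos: int
    t_pos: int
    length: int
    strand: str  # '+' or '-'


@dataclass
class AlignmentSegment:
    """One gapped local alignment between intervals of two sequences."""

    q_name: str
    t_name: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    matches: int
    block_len: int
    identity: float

    @property
    def q_interval(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def t_interval(self) -> tuple[int, int]:
        return (self.t_start, self.t_end)


@dataclass
class AnchorChain:
    anchors: list[Anchor] = field(default_factory=list)
    score: float = 0.0


class KmerIndex:
    """Hash of every N-free k-mer of a target sequence to its positions."""

    def __init__(self, seq: str, k: int = DEFAULT_K):
        if k < 8:
            raise ValueError("k must be >= 8")
        self.seq = seq
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append(i)
        self._index = index

    def get(self, kmer: str) -> list[int]:
        return self._index.get(kmer, ())


def _merge_diagonal_runs(hits: list[tuple[int, int]], k: int, strand: str) -> list[Anchor]:
    """Merge k-mer hit pairs into maximal exact matches.

    Forward hits extend along the diagonal (q+1, t+1); reverse hits along the
    anti-diagonal (q+1, t-1).
    """
    anchors = []
    if strand == "+":
        hits.sort(key=lambda h: (h[0] - h[1], h[0]))
        run_start = None
        prev = None
        for q, t in hits:
            d = q - t
            if prev is not None and d == prev[0] - prev[1] and q == prev[0] + 1:
                prev = (q, t)
                continue
            if run_start is not None:
                anchors.append(Anchor(run_start[0], run_start[1],
                                      prev[0] - run_start[0] + k, "+"))
            run_start = (q, t)
            prev = (q, t)
        if run_start is not None:
            anchors.append(Anchor(run_start[0], run_start[1],
                                  prev[0] - run_start[0] + k, "+"))
    else:
        # anti-diagonal c = q + t is constant along a reverse run
        hits.sort(key=lambda h: (h[0] + h[1], h[0]))
        run_start = None
        prev = None
        for q, t in hits:
            c = q + t
            if prev is not None and c == prev[0] + prev[1] and q == prev[0] + 1:
                prev = (q, t)
                continue
            if run_start is not None:
                length = prev[0] - run_start[0] + k
                anchors.append(Anchor(run_start[0], prev[1], length, "-"))
            run_start = (q, t)
            prev = (q, t)
        if run_start is not None:
            length = prev[0] - run_start[0] + k
            anchors.append(Anchor(run_start[0], prev[1], length, "-"))
    return anchors


def seed_anchors(seq_a: str, seq_b: str, k: int = DEFAULT_K,
                 index: KmerIndex | None = None) -> list[Anchor]:
    """All maximal exact matches of length >= k between seq_a and seq_b,
    on both strands.  N-containing k-mers never seed."""
    if index is None:
        index = KmerIndex(seq_b, k)
    elif index.k != k:
        raise ValueError("index built with a different k")
    fwd_hits: list[tuple[int, int]] = []
    rev_hits: list[tuple[int, int]] = []
    for i in range(len(seq_a) - k + 1):
        kmer = seq_a[i:i + k]
        if "N" in kmer:
            continue
        for j in index.get(kmer):
            fwd_hits.append((i, j))
        for j in index.get(revcomp(kmer)):
            rev_hits.append((i, j))
    anchors = _merge_diagonal_runs(fwd_hits, k, "+")
    anchors += _merge_diagonal_runs(rev_hits, k, "-")
    return anchors


def cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, alignment columns) from an extended CIGAR string."""
    matches = 0
    cols = 0
    for n, op in _CIG_RE.findall(cigar):
        n = int(n)
        cols += n
        if op == "=":
            matches += n
    return matches, cols


def edlib_identity(a: str, b: str, mode: str = "NW") -> tuple[int, int, str, tuple[int, int] | None]:
    """Align with edlib; return (matches, columns, cigar, target_locations)."""
    res = edlib.align(a, b, mode=mode, task="path")
    cigar = res["cigar"] or ""
    matches, cols = cigar_stats(cigar)
    loc = None
    if res["locations"]:
        s, e = res["locations"][0]
        loc = (s if s is not None else 0, e + 1)
    return matches, cols, cigar, loc


def copy_similarity(seq_a: str, seq_b: str) -> float:
    """End-to-end (global) identity between two copies, in [0, 1].

    Identity is matches over alignment columns of the best global alignment;
    grossly different lengths therefore score low because the unmatched
    excess costs gap columns.
    """
    if not seq_a or not seq_b:
        return 0.0
    matches, cols, _, _ = edlib_identity(seq_a, seq_b, mode="NW")
    return matches / cols if cols else 0.0


def oriented_similarity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(forward, reverse-complement) end-to-end identity of two copies."""
    return copy_similarity(seq_a, seq_b), copy_similarity(seq_a, revcomp(seq_b))


def _gap_cost(dq: int, dt: int, gap_open: float, gap_extend: float) -> float:
    return gap_open + gap_extend * abs(dq - dt) + 0.05 * min(dq, dt)


def chain_and_extend(anchors: list[Anchor], seq_a: str, seq_b: str, *,
                     q_name: str = "q", t_name: str = "t",
                     min_len: int = DEFAULT_MIN_LEN,
                     min_identity: float = DEFAULT_MIN_IDENTITY,
                     max_gap: int = DEFAULT_MAX_GAP,
                     gap_open: float = 4.0, gap_extend: float = 1.0,
                     match: float = 1.0) -> list[AlignmentSegment]:
    """Chain colinear anchors and refine each chain into a gapped segment.

    Chaining is scored as anchor length times ``match`` minus an affine gap
    cost; anchors more than ``max_gap`` apart on either sequence never join,
    so distinct repeat copies stay distinct segments.  Each chain span is
    re-aligned globally with edlib to obtain matches/columns identity.
    Segments shorter than ``min_len`` columns or below ``min_identity`` are
    dropped.  Output is deterministic: ties resolve by coordinates.
    """
    segments: list[AlignmentSegment] = []
    for strand in ("+", "-"):
        sub = [a for a in anchors if a.strand == strand]
        if not sub:
            continue
        if strand == "+":
            sub.sort(key=lambda a: (a.q_pos, a.t_pos))
        else:
            # in (a, revcomp(b)) space a reverse anchor occupies
            # t' = len(b) - (t_pos + length); chain there
            sub.sort(key=lambda a: (a.q_pos, -a.t_pos))
        n = len(sub)
        score = [a.length * match for a in sub]
        back = [-1] * n
        for i in range(n):
            ai = sub[i]
            for j in range(i - 1, -1, -1):
                aj = sub[j]
                dq = ai.q_pos - (aj.q_pos + aj.length)
                # coincidental 1-2 bp anchor extensions around an indel make
                # neighbouring anchors overlap slightly; tolerate that
                if dq < -20:
                    continue
                if dq > max_gap:
                    continue
                if strand == "+":
                    dt = ai.t_pos - (aj.t_pos + aj.length)
                else:
                    dt = aj.t_pos - (ai.t_pos + ai.length)
                if dt < -20 or dt > max_gap:
                    continue
                cand = score[j] + ai.length * match - _gap_cost(dq, dt, gap_open, gap_extend)
                if cand > score[i]:
                    score[i] = cand
                    back[i] = j
        used = [False] * n
        order = sorted(range(n), key=lambda i: (-score[i], sub[i].q_pos, sub[i].t_pos))
        for i in order:
            if used[i]:
                continue
            chain = []
            cur = i
            broken = False
            while cur != -1:
                if used[cur]:
                    broken = True
                    break
                chain.append(cur)
                cur = back[cur]
            if broken and not chain:
                continue
            for c in chain:
                used[c] = True
            chain.reverse()
            members = [sub[c] for c in chain]
            # a link bridging substantial sequence on both sides must be a
            # real alignment, not two repeat copies joined across unrelated
            # spacers; split the chain at links whose gap fails identity
            pieces: list[list[Anchor]] = [[members[0]]]
            for prev, cur in zip(members, members[1:]):
                dq = cur.q_pos - (prev.q_pos + prev.length)
                if strand == "+":
                    dt = cur.t_pos - (prev.t_pos + prev.length)
                    gap_t = seq_b[prev.t_pos + prev.length:cur.t_pos]
                else:
                    dt = prev.t_pos - (cur.t_pos + cur.length)
                    gap_t = revcomp(seq_b[cur.t_pos + cur.length:prev.t_pos])
                if min(dq, dt) >= 40:
                    gap_q = seq_a[prev.q_pos + prev.length:cur.q_pos]
                    m, cols, _, _ = edlib_identity(gap_q, gap_t, mode="NW")
                    # random DNA aligns globally at ~0.55 identity; diverged
                    # homologous gaps sit well above this floor
                    if cols and m / cols < 0.65:
                        pieces.append([cur])
                        continue
                pieces[-1].append(cur)
            for members in pieces:
                _emit_segment(members, seq_a, seq_b, strand, q_name, t_name,
                              min_len, min_identity, segments)
    segments.sort(key=lambda s: (s.q_start, s.t_start, s.strand))
    return segments


def _emit_segment(members, seq_a, seq_b, strand, q_name, t_name,
                  min_len, min_identity, segments):
    q0 = members[0].q_pos
    q1 = members[-1].q_pos + members[-1].length
    if strand == "+":
        t0 = members[0].t_pos
        t1 = members[-1].t_pos + members[-1].length
    else:
        t0 = members[-1].t_pos
        t1 = members[0].t_pos + members[0].length
    sa = seq_a[q0:q1]
    st = seq_b[t0:t1] if strand == "+" else revcomp(seq_b[t0:t1])
    m, cols, _, _ = edlib_identity(sa, st, mode="NW")
    if cols < min_len:
        return
    ident = m / cols if cols else 0.0
    if ident < min_identity:
        return
    segments.append(AlignmentSegment(q_name, t_name, q0, q1, t0, t1,
                                     strand, m, cols, ident))


def align_pair(seq_a: str, seq_b: str, *, k: int = DEFAULT_K,
               q_name: str = "q", t_name: str = "t",
               index: KmerIndex | None = None,
               **chain_kwargs) -> list[AlignmentSegment]:
    """Seed + chain + refine in one call."""
    anchors = seed_anchors(seq_a, seq_b, k, index=index)
    return chain_and_extend(anchors, seq_a, seq_b, q_name=q_name,
                            t_name=t_name, **chain_kwargs)


def self_align(seq: str, *, k: int = DEFAULT_K, name: str = "seq",
               **chain_kwargs) -> list[AlignmentSegment]:
    """Off-diagonal self-alignment (dot-plot style).

    The trivial full-length main diagonal is excluded and symmetric
    duplicates are reduced to q_start <= t_start.
    """
    anchors = [a for a in seed_anchors(seq, seq, k)
               if not (a.strand == "+" and a.q_pos == a.t_pos)]
    anchors = [a for a in anchors if a.q_pos <= a.t_pos]
    segs = chain_and_extend(anchors, seq, seq, q_name=name, t_name=name,
                            **chain_kwargs)
    return [s for s in segs if not (s.strand == "+" and s.q_start == s.t_start)]
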