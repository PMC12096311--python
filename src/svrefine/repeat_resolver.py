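"""Repeat-copy decomposition and base-pair breakpoint placement.

Given the anchored region sequences of both genomes, this module

* catalogues repeat segments and their copies from self- and
  cross-alignment (`decompose_segments`),
* detects tandem periodicity (`detect_tandem_unit`),
* pairs orthologous copies by similarity with an optimal assignment
  (`match_copies`), and
* places breakpoints at base-pair resolution (`place_breakpoints`),
  reporting for every call the interval of equivalent placements
  (breakpoints inside repeats can usually be shifted through identical
  bases) and one of four repeat-context patterns:

  - ``unique``  — no repeat involvement;
  - ``cat1``    — a single-segment copy present once in one genome and
                  more than once in the other (copies joined directly or
                  through unique sequence);
  - ``cat2``    — a multi-segment copy present once in one genome and
                  multiply in the other;
  - ``cat3``    — multiple distinct copies in both genomes (typically
                  tandem arrays).

The canonical breakpoint is always the leftmost equivalent placement.

The base diff between the two region sequences is computed from a global
alignment (edlib, extended CIGAR): non-match runs separated by fewer than
``join`` matching columns are merged into one block, shift-equivalent
same-type blocks are coalesced into single events, and every event is then
left-normalized with its equivalent placements enumerated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .aligner import (_CIG_RE, align_pair, copy_similarity, edlib_identity,
                      oriented_similarity, seed_anchors, self_align)
from .seqs import reciprocal_overlap, revcomp, trim_common

PATTERNS = ("unique", "cat1", "cat2", "cat3")

DEFAULT_JOIN = 10
FAMILY_RECIP_OVERLAP = 0.8
SUBSEGMENT_CONTAINMENT = 0.95
TANDEM_MIN_IDENTITY = 0.9
INV_MIN_IDENTITY = 0.9
ALIGNED_RESIDUAL_IDENTITY = 0.8
#: a substitution must remain unaligned even with its flanks attached; a
#: block whose context aligns this well is a small-variant cluster instead
SUB_CONTEXT_ALIGNED = 0.85


# ---------------------------------------------------------------------------
# catalog types

@dataclass
class Copy:
    genome: str          # 'ref' or 'qry'
    interval: tuple[int, int]
    strand: str = "+"
    collapsed: bool = False  # redundant fully-contained copy

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class SegmentFamily:
    fam_id: int
    copies: list[Copy] = field(default_factory=list)

    @property
    def is_repeat(self) -> bool:
        """A 1:1 cross-genome family is just orthologous sequence, not a
        repeat."""
        nr = sum(1 for c in self.copies if c.genome == "ref")
        nq = sum(1 for c in self.copies if c.genome == "qry")
        return max(nr, nq) >= 2

    def count(self, genome: str) -> int:
        return sum(1 for c in self.copies if c.genome == genome)


@dataclass
class CopyCatalog:
    ref_seq: str
    qry_seq: str
    families: list[SegmentFamily] = field(default_factory=list)
    containments: list[tuple[Copy, Copy]] = field(default_factory=list)
    tandem_units: dict[int, tuple[int, int]] = field(default_factory=dict)
    _sim_cache: dict = field(default_factory=dict, repr=False)

    def copy_seq(self, c: Copy) -> str:
        seq = self.ref_seq if c.genome == "ref" else self.qry_seq
        s = seq[c.interval[0]:c.interval[1]]
        return s if c.strand == "+" else revcomp(s)

    def similarity(self, a: Copy, b: Copy) -> float:
        key = (id(a), id(b)) if id(a) < id(b) else (id(b), id(a))
        if key not in self._sim_cache:
            self._sim_cache[key] = copy_similarity(self.copy_seq(a), self.copy_seq(b))
        return self._sim_cache[key]

    @property
    def is_unique_context(self) -> bool:
        return not any(f.is_repeat for f in self.families)


@dataclass
class Pairing:
    pairs: list[tuple[Copy, Copy]] = field(default_factory=list)
    unpaired_ref: list[Copy] = field(default_factory=list)
    unpaired_qry: list[Copy] = field(default_factory=list)
    crossing: bool = False        # similarity-optimal order crosses
    crossing_margin: float = 0.0  # by how much it beats positional order


@dataclass
class RawEvent:
    """One difference block between the region sequences (region-local,
    0-based half-open; canonical leftmost placement after normalization)."""

    r_start: int
    r_end: int
    q_start: int
    q_end: int
    q_seq: str                    # material present in the query at the locus
    kind: str                     # ins / del / sub / inv_candidate / aligned
    amb: tuple[int, int] = (0, 0)  # interval of equivalent placement starts

    @property
    def ref_len(self) -> int:
        return self.r_end - self.r_start

    @property
    def qry_len(self) -> int:
        return self.q_end - self.q_start

    @property
    def amb_len(self) -> int:
        return self.amb[1] - self.amb[0]


@dataclass
class BreakpointCall:
    ref_pos: int
    qry_pos: int
    ambiguity: tuple[int, int]
    pattern: str
    event: RawEvent

    @property
    def ambiguity_len(self) -> int:
        return self.ambiguity[1] - self.ambiguity[0]


# ---------------------------------------------------------------------------
# segment/copy catalog

def _cluster_copies(occs: list[tuple[str, tuple[int, int], str]],
                    recip: float) -> tuple[list[Copy], list[int]]:
    """Merge occurrence intervals into copies; returns copies and the copy
    index of each occurrence."""
    copies: list[Copy] = []
    assignment: list[int] = []
    for genome, iv, strand in occs:
        hit = -1
        for ci, c in enumerate(copies):
            if c.genome == genome and reciprocal_overlap(c.interval, iv) >= recip:
                hit = ci
                break
        if hit == -1:
            copies.append(Copy(genome, iv, strand))
            assignment.append(len(copies) - 1)
        else:
            c = copies[hit]
            # keep the longer occurrence as representative; unioning here
            # lets chained merges bloat a copy far past any real occurrence
            if iv[1] - iv[0] > c.length:
                c.interval = iv
            assignment.append(hit)
    return copies, assignment


def decompose_segments(ref_seq: str, qry_seq: str, *,
                       k: int = 15, min_len: int = 45,
                       min_identity: float = 0.8,
                       recip: float = FAMILY_RECIP_OVERLAP) -> CopyCatalog:
    """Catalog repeat segments and copies of an anchored region pair.

    Self-alignment of each genome's region plus cross-alignment between them
    yields alignment segments; their end intervals are clustered into copies
    (reciprocal overlap >= ``recip``) and copies linked by a segment form a
    family.  Copies fully contained (>= 95%) in a copy of a larger family
    are recorded as sub-segments and collapsed (ignored for pairing) to
    minimize redundant repeat evidence.
    """
    kwargs = dict(min_len=min_len, min_identity=min_identity)
    segs = []
    for s in self_align(ref_seq, k=k, **kwargs):
        segs.append((("ref", s.q_interval, "+"), ("ref", s.t_interval, s.strand)))
    for s in self_align(qry_seq, k=k, **kwargs):
        segs.append((("qry", s.q_interval, "+"), ("qry", s.t_interval, s.strand)))
    for s in align_pair(ref_seq, qry_seq, k=k, **kwargs):
        segs.append((("ref", s.q_interval, "+"), ("qry", s.t_interval, s.strand)))

    occs = [o for pair in segs for o in pair]
    copies, assign = _cluster_copies(occs, recip)

    parent = list(range(len(copies)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(0, len(assign), 2):
        union(assign[i], assign[i + 1])

    groups: dict[int, list[Copy]] = {}
    for ci, c in enumerate(copies):
        groups.setdefault(find(ci), []).append(c)
    families = [SegmentFamily(i, sorted(g, key=lambda c: (c.genome, c.interval)))
                for i, g in enumerate(groups.values())]
    families.sort(key=lambda f: min(c.interval for c in f.copies))

    catalog = CopyCatalog(ref_seq, qry_seq, families)

    # sub-segment containment across repeat families; containment inside the
    # 1:1 orthologous backbone is not redundancy and must not collapse copies
    for fa, fb in itertools.permutations(families, 2):
        if not fb.is_repeat:
            continue
        for ca in fa.copies:
            la = ca.length
            for cb in fb.copies:
                if cb.genome != ca.genome or cb.length <= la:
                    continue
                ov = max(0, min(ca.interval[1], cb.interval[1]) -
                         max(ca.interval[0], cb.interval[0]))
                if la and ov / la >= SUBSEGMENT_CONTAINMENT:
                    catalog.containments.append((ca, cb))
                    ca.collapsed = True
    for fam in families:
        w = detect_tandem_unit(ref_seq[slice(*fam.copies[0].interval)])
        if w:
            catalog.tandem_units[fam.fam_id] = w
    return catalog


def detect_tandem_unit(seq: str, min_identity: float = TANDEM_MIN_IDENTITY,
                       min_period: int = 2) -> tuple[int, int] | None:
    """Smallest period with >=2 approximate copies, or None.

    A period p qualifies when the sequence agrees with itself shifted by p
    at >= ``min_identity`` of positions (substitution-level divergence).
    Returns (unit_len, copy_count).
    """
    n = len(seq)
    if n < 2 * min_period:
        return None
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for p in range(min_period, n // 2 + 1):
        frac = float(np.mean(arr[:-p] == arr[p:]))
        if frac >= min_identity:
            return (p, n // p)
    return None


# ---------------------------------------------------------------------------
# orthologous copy pairing

def match_copies(catalog: CopyCatalog, *, exhaustive_limit: int = 6,
                 margin: float = 0.02) -> Pairing:
    """One-to-one pairing of ref copies to qry copies per family, maximizing
    total similarity.

    Exhaustive over permutations up to ``exhaustive_limit`` copies per side
    (first-found maximum in lexicographic order implements the
    leftmost-to-leftmost tie-break); Hungarian assignment beyond that.
    Unpaired copies are the variant material.  ``crossing`` is set when the
    optimal pairing deviates from positional order by more than ``margin``
    total similarity.
    """
    pairing = Pairing()
    for fam in catalog.families:
        ref_c = sorted((c for c in fam.copies if c.genome == "ref" and not c.collapsed),
                       key=lambda c: c.interval)
        qry_c = sorted((c for c in fam.copies if c.genome == "qry" and not c.collapsed),
                       key=lambda c: c.interval)
        if not ref_c or not qry_c:
            pairing.unpaired_ref += ref_c
            pairing.unpaired_qry += qry_c
            continue
        n, m = len(ref_c), len(qry_c)
        sim = [[catalog.similarity(r, q) for q in qry_c] for r in ref_c]
        if max(n, m) <= exhaustive_limit:
            pairs_idx = _exhaustive_assignment(sim, n, m)
        else:
            pairs_idx = _hungarian_assignment(sim, n, m)
        paired_r = {i for i, _ in pairs_idx}
        paired_q = {j for _, j in pairs_idx}
        fam_pairs = [(ref_c[i], qry_c[j]) for i, j in pairs_idx]
        pairing.pairs += fam_pairs
        pairing.unpaired_ref += [ref_c[i] for i in range(n) if i not in paired_r]
        pairing.unpaired_qry += [qry_c[j] for j in range(m) if j not in paired_q]
        # crossing check against the positional pairing
        if n == m and n >= 2:
            opt = sum(sim[i][j] for i, j in pairs_idx)
            pos = sum(sim[i][i] for i in range(n))
            if sorted(pairs_idx) != [(i, i) for i in range(n)] and opt > pos + margin:
                pairing.crossing = True
                pairing.crossing_margin = max(pairing.crossing_margin, opt - pos)
    return pairing


def _exhaustive_assignment(sim, n, m) -> list[tuple[int, int]]:
    small, large = (n, m) if n <= m else (m, n)
    best = None
    best_score = -1.0
    for combo in itertools.combinations(range(large), small):
        for perm in itertools.permutations(combo):
            if n <= m:
                idx = list(zip(range(small), perm))
            else:
                idx = [(i, j) for j, i in zip(range(small), perm)]
            score = sum(sim[i][j] for i, j in idx)
            if score > best_score + 1e-12:
                best_score = score
                best = idx
    return best or []


def _hungarian_assignment(sim, n, m) -> list[tuple[int, int]]:
    size = max(n, m)
    cost = np.zeros((size, size))
    for i in range(n):
        for j in range(m):
            # tiny diagonal bonus implements the leftmost tie-break
            cost[i, j] = -(sim[i][j] + 1e-9 * (size - abs(i - j)))
    rows, cols = linear_sum_assignment(cost)
    return [(i, j) for i, j in zip(rows, cols) if i < n and j < m]


# ---------------------------------------------------------------------------
# diff engine

def _cigar_blocks(cigar: str, join: int) -> list[tuple[int, int, int, int]]:
    """Merge non-match CIGAR runs into blocks (r_s, r_e, q_s, q_e); '=' runs
    shorter than ``join`` do not break a block."""
    blocks = []
    r = q = 0
    cur = None  # [r_s, r_e, q_s, q_e]
    pend_eq = 0
    for n_s, op in _CIG_RE.findall(cigar):
        n = int(n_s)
        if op == "=":
            if cur is not None:
                pend_eq += n
                if pend_eq >= join:
                    blocks.append(tuple(cur))
                    cur = None
                    pend_eq = 0
            r += n
            q += n
            continue
        dr = n if op in ("X", "I") else 0
        dq = n if op in ("X", "D") else 0
        if cur is None:
            cur = [r, r + dr, q, q + dq]
        else:
            # reabsorb the pending short match run
            cur[1] = r + dr
            cur[3] = q + dq
        pend_eq = 0
        r += dr
        q += dq
    if cur is not None:
        blocks.append(tuple(cur))
    return blocks


def _events_from_blocks(blocks, R, Q, join, depth=0):
    events: list[RawEvent] = []
    for (rs, re_, qs, qe) in blocks:
        rlen, qlen = re_ - rs, qe - qs
        if rlen and not qlen:
            events.append(RawEvent(rs, re_, qs, qe, "", "del"))
        elif qlen and not rlen:
            events.append(RawEvent(rs, re_, qs, qe, Q[qs:qe], "ins"))
        else:
            rb, qb = R[rs:re_], Q[qs:qe]
            fwd, rev = oriented_similarity(rb, qb)
            ratio = min(rlen, qlen) / max(rlen, qlen)
            if rev >= INV_MIN_IDENTITY and rev > fwd and ratio >= 0.9:
                events.append(RawEvent(rs, re_, qs, qe, qb, "inv_candidate"))
            elif max(fwd, rev) < ALIGNED_RESIDUAL_IDENTITY:
                ctx = min(100, max(rlen, qlen) // 2)
                ctx_id = copy_similarity(R[max(0, rs - ctx):re_ + ctx],
                                         Q[max(0, qs - ctx):qe + ctx])
                if ctx_id >= SUB_CONTEXT_ALIGNED:
                    # a dense local substitution cluster inside otherwise
                    # well-aligned sequence, not an unalignable segment
                    events.append(RawEvent(rs, re_, qs, qe, qb, "aligned"))
                else:
                    events.append(RawEvent(rs, re_, qs, qe, qb, "sub"))
            elif depth == 0:
                # residuals still align: decompose into constituent runs
                _, _, cigar, _ = edlib_identity(rb, qb, mode="NW")
                sub_blocks = [(rs + a, rs + b, qs + c, qs + d)
                              for a, b, c, d in _cigar_blocks(cigar, join=1)]
                events += _events_from_blocks(sub_blocks, R, Q, join, depth + 1)
            else:
                events.append(RawEvent(rs, re_, qs, qe, qb, "aligned"))
    return events


def _merge_across_gaps(events: list[RawEvent], R: str, Q: str,
                       join: int) -> list[RawEvent]:
    """Rejoin events separated only by N runs.

    N positions match each other in the alignment even when the surrounding
    context disagrees, so an event spanning an assembly gap (e.g. an
    inverted segment containing an N run) is otherwise split in two.
    """
    changed = True
    while changed and len(events) > 1:
        changed = False
        for i in range(len(events) - 1):
            e1, e2 = events[i], events[i + 1]
            gap_r = R[e1.r_end:e2.r_start]
            gap_q = Q[e1.q_end:e2.q_start]
            # the separation must be an assembly gap: an N run on both
            # sides, with at most a few coincidentally matching bases
            def _is_gap(s):
                return "N" * 10 in s and len(s) - s.count("N") <= 20
            if gap_r and _is_gap(gap_r) and _is_gap(gap_q):
                merged = _events_from_blocks(
                    [(e1.r_start, e2.r_end, e1.q_start, e2.q_end)],
                    R, Q, join, depth=1)
                events[i:i + 2] = merged
                changed = True
                break
    return events


def _coalesce(events: list[RawEvent], R: str, Q: str) -> list[RawEvent]:
    """Merge shift-equivalent same-type pure indels into single events.

    Global alignment may split one repeat-mediated indel into several runs;
    two neighbouring runs are merged whenever one contiguous indel of the
    combined length reproduces the query exactly.
    """
    changed = True
    while changed:
        changed = False
        for i in range(len(events) - 1):
            e1, e2 = events[i], events[i + 1]
            if e1.kind == e2.kind == "del":
                L = e1.ref_len + e2.ref_len
                target = R[:e1.r_start] + R[e1.r_end:e2.r_start] + R[e2.r_end:]
                for x in range(e1.r_start, e2.r_end - L + 1):
                    if R[:x] + R[x + L:] == target:
                        off = e1.q_start - e1.r_start
                        merged = RawEvent(x, x + L, x + off, x + off, "", "del")
                        events[i:i + 2] = [merged]
                        changed = True
                        break
            elif e1.kind == e2.kind == "ins":
                L = e1.qry_len + e2.qry_len
                target = Q[:e1.q_start] + Q[e1.q_end:e2.q_start] + Q[e2.q_end:]
                for y in range(e1.q_start, e2.q_end - L + 1):
                    if Q[:y] + Q[y + L:] == target:
                        off = e1.q_start - e1.r_start
                        merged = RawEvent(y - off, y - off, y, y + L,
                                          Q[y:y + L], "ins")
                        events[i:i + 2] = [merged]
                        changed = True
                        break
            if changed:
                break
    return events


def _normalize_events(events: list[RawEvent], R: str, Q: str) -> list[RawEvent]:
    """Left-shift each indel to its leftmost equivalent placement and record
    the interval of equivalent placement starts."""
    out: list[RawEvent] = []
    for idx, ev in enumerate(events):
        prev_end = out[-1].r_end if out else 0
        next_start = events[idx + 1].r_start if idx + 1 < len(events) else len(R)
        if ev.kind == "del":
            s, e = ev.r_start, ev.r_end
            L = e - s
            smin = s
            while smin > prev_end and R[smin - 1] == R[smin + L - 1]:
                smin -= 1
            smax, emax = s, e
            while emax < next_start and emax < len(R) and R[emax] == R[smax]:
                smax += 1
                emax += 1
            off = ev.q_start - ev.r_start
            out.append(RawEvent(smin, smin + L, smin + off, smin + off, "",
                                "del", amb=(smin, smax + 1)))
        elif ev.kind == "ins":
            s = ev.r_start
            T = ev.q_seq
            smin, Tmin = s, T
            while smin > prev_end and Tmin and Tmin[-1] == R[smin - 1]:
                Tmin = R[smin - 1] + Tmin[:-1]
                smin -= 1
            smax, Tmax = s, T
            while smax < next_start and smax < len(R) and Tmax and Tmax[0] == R[smax]:
                Tmax = Tmax[1:] + R[smax]
                smax += 1
            off = ev.q_start - ev.r_start
            out.append(RawEvent(smin, smin, smin + off, smin + off + len(T),
                                Tmin, "ins", amb=(smin, smax + 1)))
        else:
            out.append(RawEvent(ev.r_start, ev.r_end, ev.q_start, ev.q_end,
                                ev.q_seq, ev.kind,
                                amb=(ev.r_start, ev.r_start + 1)))
    return out


def apply_events(R: str, events: list[RawEvent]) -> str:
    """Splice query material into the reference at the resolved breakpoints."""
    parts = []
    cur = 0
    for ev in sorted(events, key=lambda e: e.r_start):
        parts.append(R[cur:ev.r_start])
        parts.append(ev.q_seq)
        cur = ev.r_end
    parts.append(R[cur:])
    return "".join(parts)


MIN_SPLIT_ANCHOR = 25


def _best_chain(anchors):
    """Highest-scoring colinear forward chain of anchors (no overlaps)."""
    sub = sorted((a for a in anchors if a.strand == "+"),
                 key=lambda a: (a.q_pos, a.t_pos))
    if not sub:
        return []
    n = len(sub)
    score = [a.length * 1.0 for a in sub]
    back = [-1] * n
    for i in range(n):
        ai = sub[i]
        for j in range(i):
            aj = sub[j]
            dq = ai.q_pos - (aj.q_pos + aj.length)
            dt = ai.t_pos - (aj.t_pos + aj.length)
            if dq < -20 or dt < -20:
                continue
            cand = score[j] + ai.length - (4.0 + abs(dq - dt) * 0.05
                                           + 0.01 * max(min(dq, dt), 0))
            if cand > score[i]:
                score[i] = cand
                back[i] = j
    best = max(range(n), key=lambda i: score[i])
    chain = []
    cur = best
    while cur != -1:
        chain.append(sub[cur])
        cur = back[cur]
    chain.reverse()
    return chain


def _diff_blocks(R: str, Q: str, rs: int, re_: int, qs: int, qe: int,
                 blocks: list) -> None:
    """Recursive anchored diff of R[rs:re_] vs Q[qs:qe] into leaf blocks.

    Long exact matches are chained into a skeleton so that the minimal-edit
    path cannot smear two nearby indels into one mismatch region; gaps
    between skeleton anchors recurse until anchor-free, then become one
    block each.
    """
    r, q = R[rs:re_], Q[qs:qe]
    p, s = trim_common(r, q)
    rs, re_, qs, qe = rs + p, re_ - s, qs + p, qe - s
    r, q = R[rs:re_], Q[qs:qe]
    if not r and not q:
        return
    if not r or not q:
        blocks.append((rs, re_, qs, qe))
        return
    anchors = [a for a in seed_anchors(r, q)
               if a.strand == "+" and a.length >= MIN_SPLIT_ANCHOR]
    chain = _best_chain(anchors)
    # a chain spanning the whole core provides no split
    if not chain or (len(chain) == 1 and chain[0].length >= len(r) and
                     chain[0].length >= len(q)):
        blocks.append((rs, re_, qs, qe))
        return
    cr, cq = 0, 0
    for a in chain:
        # anchors may slightly overlap the previous one; trim both
        # coordinates together so the exact correspondence is kept
        trim = max(cr - a.q_pos, cq - a.t_pos, 0)
        aq, at_, ln = a.q_pos + trim, a.t_pos + trim, a.length - trim
        if ln <= 0:
            continue
        _diff_blocks(R, Q, rs + cr, rs + aq, qs + cq, qs + at_, blocks)
        cr, cq = aq + ln, at_ + ln
    _diff_blocks(R, Q, rs + cr, re_, qs + cq, qe, blocks)


def resolve_pair(R: str, Q: str, join: int = DEFAULT_JOIN) -> list[RawEvent]:
    """Full diff of an anchored region pair into normalized events."""
    blocks: list[tuple[int, int, int, int]] = []
    _diff_blocks(R, Q, 0, len(R), 0, len(Q), blocks)
    # refine each anchor-free leaf with a global alignment
    refined = []
    for (brs, bre, bqs, bqe) in blocks:
        if brs == bre or bqs == bqe:
            refined.append((brs, bre, bqs, bqe))
            continue
        _, _, cigar, _ = edlib_identity(R[brs:bre], Q[bqs:bqe], mode="NW")
        refined += [(brs + a, brs + b, bqs + c, bqs + d)
                    for a, b, c, d in _cigar_blocks(cigar, join)]
    events = _events_from_blocks(refined, R, Q, join)
    events.sort(key=lambda e: (e.r_start, e.q_start))
    events = _merge_across_gaps(events, R, Q, join)
    events = _coalesce(events, R, Q)
    events = _normalize_events(events, R, Q)
    return events


# ---------------------------------------------------------------------------
# pattern assignment

def _positional_identity(a: str, b: str) -> float:
    if len(a) != len(b) or not a:
        return 0.0
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return float(np.mean(xa == xb))


def _count_unit_copies(seq: str, junction: int, unit: str,
                       min_identity: float = TANDEM_MIN_IDENTITY) -> int:
    """Adjacent in-phase copies of ``unit`` around ``junction`` in ``seq``."""
    p = len(unit)
    n = 0
    pos = junction
    while pos + p <= len(seq) and _positional_identity(seq[pos:pos + p], unit) >= min_identity:
        n += 1
        pos += p
    pos = junction
    while pos - p >= 0 and _positional_identity(seq[pos - p:pos], unit) >= min_identity:
        n += 1
        pos -= p
    return n


def assign_pattern(ev: RawEvent, catalog: CopyCatalog) -> str:
    """Infer the repeat-context pattern of one event from the catalog."""
    R, Q = catalog.ref_seq, catalog.qry_seq
    # ---- tandem route
    if ev.kind in ("del", "ins"):
        if ev.kind == "del":
            side_seq, start = R, ev.r_start
            other_seq, junction = Q, ev.q_start
            L = ev.ref_len
        else:
            side_seq, start = Q, ev.q_start
            other_seq, junction = R, ev.r_start
            L = ev.qry_len
        span = (ev.amb_len - 1) + L
        window = side_seq[start:start + span]
        det = detect_tandem_unit(window) if span >= 4 else None
        if det:
            p, c = det
            unit = window[:p]
            n_other = _count_unit_copies(other_seq, junction, unit)
            if min(c, n_other) >= 2:
                return "cat3"
            if _multisegment_evidence(catalog, ev, start, span, p):
                return "cat2"
            return "cat1"
    # ---- family route
    fams = _overlapping_repeat_families(catalog, ev)
    if not fams:
        return "unique"
    primary = max(fams, key=lambda f: _family_overlap(f, ev))
    nr, nq = primary.count("ref"), primary.count("qry")
    if min(nr, nq) >= 2:
        return "cat3"
    if len(fams) >= 2:
        return "cat2"
    return "cat1"


def _event_material_interval(ev: RawEvent, genome: str) -> tuple[int, int] | None:
    """Interval of variant material on one genome side; None when that side
    carries no material (a copy merely touching an insertion point is not
    repeat involvement)."""
    if genome == "ref":
        if ev.ref_len == 0:
            return None
        return (ev.amb[0], ev.amb[1] - 1 + ev.ref_len)
    if ev.qry_len == 0:
        return None
    return (ev.q_start, ev.q_end)


def _overlapping_repeat_families(catalog: CopyCatalog, ev: RawEvent):
    out = []
    for fam in catalog.families:
        if not fam.is_repeat:
            continue
        if _family_overlap(fam, ev) > 0:
            out.append(fam)
    return out


def _family_overlap(fam: SegmentFamily, ev: RawEvent) -> int:
    total = 0
    for c in fam.copies:
        iv = _event_material_interval(ev, c.genome)
        if iv is None:
            continue
        ov = max(0, min(iv[1], c.interval[1]) - max(iv[0], c.interval[0]))
        if ov >= 0.5 * min(c.length, iv[1] - iv[0]):
            total += ov
    return total


def _multisegment_evidence(catalog: CopyCatalog, ev: RawEvent,
                           start: int, span: int, period: int) -> bool:
    """A tandem unit built from several catalogued segments (sub-segments
    with copies both inside the unit and elsewhere) marks a multi-segment
    copy."""
    genome = "del" == ev.kind and "ref" or "qry"
    window = (start, start + span)
    for fam in catalog.families:
        inside = outside = False
        for c in fam.copies:
            if c.length > 0.8 * period:
                continue
            if c.genome == genome and c.interval[0] >= window[0] and c.interval[1] <= window[1]:
                inside = True
            elif (max(0, min(c.interval[1], window[1]) - max(c.interval[0], window[0]))
                  < 0.5 * c.length):
                outside = True
        if inside and outside:
            return True
    return False


# ---------------------------------------------------------------------------
# breakpoint placement

def place_breakpoints(catalog: CopyCatalog, pairing: Pairing,
                      join: int = DEFAULT_JOIN
                      ) -> tuple[list[BreakpointCall], str]:
    """Resolve the anchored region pair into breakpoint calls.

    Returns (calls, status); status is 'ok' or 'complex'.  A pairing whose
    similarity-optimal order crosses the positional order (implying a
    rearrangement the event model cannot express) escalates the region and
    emits nothing, as does a diff that fails the splice-reconstruction
    check.
    """
    if pairing is not None and pairing.crossing:
        return [], "complex"
    R, Q = catalog.ref_seq, catalog.qry_seq
    events = resolve_pair(R, Q, join=join)
    if apply_events(R, events) != Q:
        return [], "complex"
    calls = []
    for ev in events:
        calls.append(BreakpointCall(ev.r_start, ev.q_start, ev.amb,
                                    assign_pattern(ev, catalog), ev))
    return calls, "ok"
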