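"""Uniquely-aligned-sequence (UAS) anchoring of SV regions.

SV boundaries in repeat-dense regions cannot be trusted from caller output;
instead, flanks of the region are extended step by step until they align to
exactly one confident location in the other genome.  The inner edges of the
two anchored flanks then pin the region in both genomes.  Complex container
regions are split at internal UAS stretches into separately resolvable
sub-regions.

Uniqueness of a flank is defined on its genome-wide hit list: a single
candidate hit, or a best hit that beats the runner-up by ``min_margin``
identity while itself exceeding ``min_identity``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from .aligner import KmerIndex, align_pair, edlib_identity
from .io_formats import GenomeSequence
from .region_builder import SVRegion
from .seqs import revcomp

log = logging.getLogger(__name__)

DEFAULT_STEP = 5000
DEFAULT_MAX_EXTEND = 30000
MIN_IDENTITY = 0.95
MIN_MARGIN = 0.05
CANDIDATE_FLOOR = 0.80
MIN_INTERNAL_UAS = 1000


@dataclass
class Hit:
    """One candidate location of a flank in the other genome."""

    chrom: str
    start: int
    end: int
    strand: str
    identity: float


@dataclass
class UASAnchor:
    genome_side: str                  # 'reference' (the flank lives there)
    flank: str                        # 'upstream' or 'downstream'
    interval: tuple[int, int]         # flank interval on the reference
    mate_chrom: str | None = None
    mate_interval: tuple[int, int] | None = None
    identity: float = 0.0
    margin: float = 1.0
    multiplicity: int = 0
    strand: str = "+"
    truncated: bool = False
    extension: int = 0                # flank length actually used


@dataclass
class AnchoredRegion:
    """A region with UAS-pinned windows in both genomes.

    The windows include the anchoring flanks themselves (they are trimmed
    away again during resolution), so their ends are homologous by
    construction.
    """

    region: SVRegion
    status: str                       # ok / unanchorable / inverted_context
    up: UASAnchor | None = None
    down: UASAnchor | None = None
    qry_chrom: str | None = None
    qry_interval: tuple[int, int] | None = None   # between the mate inner edges
    ref_window: tuple[int, int] | None = None
    qry_window: tuple[int, int] | None = None
    flank_hits: list[list[Hit]] = field(default_factory=list)


def is_unique(hits: list[Hit], min_identity: float = MIN_IDENTITY,
              min_margin: float = MIN_MARGIN,
              candidate_floor: float = CANDIDATE_FLOOR) -> bool:
    """Uniqueness of a flank's genome-wide hit list."""
    cands = sorted((h for h in hits if h.identity >= candidate_floor),
                   key=lambda h: -h.identity)
    if not cands:
        return False
    if len(cands) == 1:
        return True
    margin = cands[0].identity - cands[1].identity
    return margin >= min_margin and cands[0].identity >= min_identity


def locate(flank_seq: str, genomes: list[GenomeSequence],
           indices: dict[str, KmerIndex], *, min_len: int = 45,
           gather_identity: float = 0.5) -> list[Hit]:
    """Candidate locations of a flank across a genome, refined with an
    infix alignment per locus; sorted by identity, best first."""
    hits: list[Hit] = []
    flank_len = len(flank_seq)
    for g in genomes:
        segs = align_pair(flank_seq, g.seq, index=indices[g.name],
                          min_len=min_len, min_identity=gather_identity)
        # cluster segments into loci per strand; the gap tolerance bridges
        # segments split by an indel inside one locus without fusing
        # genuinely distinct candidate loci
        cluster_gap = max(500, flank_len // 5)
        for strand in ("+", "-"):
            ivs = sorted(s.t_interval for s in segs if s.strand == strand)
            loci: list[list[int]] = []
            for s, e in ivs:
                if loci and s - loci[-1][1] <= cluster_gap:
                    loci[-1][1] = max(loci[-1][1], e)
                else:
                    loci.append([s, e])
            for s, e in loci:
                # window must contain the locus plus room for the full flank
                pad = max(100, flank_len - (e - s) + 100)
                ws = max(0, s - pad)
                we = min(len(g.seq), e + pad)
                window = g.seq[ws:we]
                target = window if strand == "+" else revcomp(window)
                m, cols, _, loc = edlib_identity(flank_seq, target, mode="HW")
                if not cols or loc is None:
                    continue
                ident = m / cols
                # every well-separated optimal placement is its own hit:
                # inside a tandem array a flank has many equivalent homes,
                # and that multiplicity must not be hidden by the clustering
                res = edlib.align(flank_seq, target, mode="HW",
                                  task="locations")
                placements: list[tuple[int, int]] = []
                for ls, le in res["locations"] or [loc]:
                    ls = ls or 0
                    if placements and ls - placements[-1][0] <= 20:
                        continue
                    placements.append((ls, le + 1))
                for ls, le in placements[:10]:
                    if strand == "+":
                        hs, he = ws + ls, ws + le
                    else:
                        hs, he = we - le, we - ls
                    hits.append(Hit(g.name, hs, he, strand, ident))
    hits.sort(key=lambda h: (-h.identity, h.chrom, h.start))
    return hits


def _find_flank(side: str, region: SVRegion, ref: GenomeSequence,
                qry_genomes: list[GenomeSequence],
                indices: dict[str, KmerIndex], step: int, max_extend: int,
                uniq_kwargs: dict) -> tuple[UASAnchor | None, list[Hit]]:
    ext = step
    last_hits: list[Hit] = []
    while ext <= max_extend:
        if side == "upstream":
            fs, fe = max(0, region.start - ext), region.start
            truncated = region.start - ext < 0
        else:
            fs, fe = region.end, min(len(ref), region.end + ext)
            truncated = region.end + ext > len(ref)
        flank_seq = ref.seq[fs:fe]
        if not flank_seq:
            return None, last_hits
        hits = locate(flank_seq, qry_genomes, indices)
        last_hits = hits
        if is_unique(hits, **uniq_kwargs):
            best = hits[0]
            cands = [h for h in hits if h.identity >= uniq_kwargs.get(
                "candidate_floor", CANDIDATE_FLOOR)]
            margin = (cands[0].identity - cands[1].identity
                      if len(cands) >= 2 else 1.0)
            return UASAnchor("reference", side, (fs, fe), best.chrom,
                             (best.start, best.end), best.identity, margin,
                             len(cands), best.strand, truncated, fe - fs), hits
        if truncated:
            break
        ext += step
    return None, last_hits


def find_uas(region: SVRegion, ref: GenomeSequence,
             qry_genomes: list[GenomeSequence],
             indices: dict[str, KmerIndex] | None = None, *,
             step: int = DEFAULT_STEP, max_extend: int = DEFAULT_MAX_EXTEND,
             min_identity: float = MIN_IDENTITY, min_margin: float = MIN_MARGIN,
             candidate_floor: float = CANDIDATE_FLOOR) -> AnchoredRegion:
    """Anchor a region with unique flanks in both genomes.

    Flanks grow independently per side in ``step`` increments until unique
    (so the two extensions may differ).  Returns status 'unanchorable' when
    no unique flank exists within ``max_extend``, and 'inverted_context'
    when the only unique mates are reverse-oriented (such regions go to
    inversion assessment rather than failing).
    """
    if indices is None:
        indices = {g.name: KmerIndex(g.seq) for g in qry_genomes}
    uniq = dict(min_identity=min_identity, min_margin=min_margin,
                candidate_floor=candidate_floor)
    up, up_hits = _find_flank("upstream", region, ref, qry_genomes, indices,
                              step, max_extend, uniq)
    down, down_hits = _find_flank("downstream", region, ref, qry_genomes,
                                  indices, step, max_extend, uniq)
    ar = AnchoredRegion(region, "ok", up, down,
                        flank_hits=[up_hits, down_hits])
    if up is None or down is None:
        ar.status = "unanchorable"
        return ar
    if up.strand == "-" or down.strand == "-":
        ar.status = "inverted_context"
        return ar
    if up.mate_chrom != down.mate_chrom or up.mate_interval[1] > down.mate_interval[0]:
        ar.status = "unanchorable"
        return ar
    ar.qry_chrom = up.mate_chrom
    ar.qry_interval = (up.mate_interval[1], down.mate_interval[0])
    ar.ref_window = (up.interval[0], down.interval[1])
    ar.qry_window = (up.mate_interval[0], down.mate_interval[1])
    region.qry_chrom = ar.qry_chrom
    region.qry_interval = ar.qry_interval
    return ar


def split_complex_region(container: SVRegion, ref: GenomeSequence,
                         qry_genomes: list[GenomeSequence],
                         indices: dict[str, KmerIndex] | None = None, *,
                         min_internal_uas: int = MIN_INTERNAL_UAS,
                         window: int = 1000, stride: int = 500,
                         internal_min_identity: float = 0.99,
                         **uas_kwargs) -> list[AnchoredRegion]:
    """Partition a container region at internal UAS stretches.

    Windows across the container that are unique in the other genome are
    merged into maximal UAS stretches (>= ``min_internal_uas``); the
    intervals between consecutive stretches become candidate sub-regions,
    each anchored by the adjacent stretches.  Partitions with no
    inter-genome difference are discarded.
    """
    if indices is None:
        indices = {g.name: KmerIndex(g.seq) for g in qry_genomes}
    outer = find_uas(container, ref, qry_genomes, indices, **uas_kwargs)
    if outer.status != "ok":
        return [outer]
    qry = next(g for g in qry_genomes if g.name == outer.qry_chrom)

    # unique internal windows with forward mates
    marks: list[tuple[int, int, int, int]] = []  # (ref_s, ref_e, qry_s, qry_e)
    pos = container.start
    while pos + window <= container.end:
        wseq = ref.seq[pos:pos + window]
        hits = locate(wseq, qry_genomes, indices)
        # an internal UAS stretch must be unique AND essentially identical
        # to its mate; a window overlapping a real variant (identity dips)
        # must not extend a stretch, or the partition mates go inconsistent
        if hits and hits[0].strand == "+" and hits[0].chrom == outer.qry_chrom \
                and hits[0].identity >= internal_min_identity and is_unique(hits):
            marks.append((pos, pos + window, hits[0].start, hits[0].end))
        pos += stride
    # merge overlapping/adjacent marks into stretches, but only while the
    # ref->qry offset stays constant — a jump means a variant sits between
    # two windows and must not be bridged
    stretches: list[list[int]] = []
    last_mark: tuple[int, int] | None = None
    for rs, re_, qs, qe in marks:
        consistent = (stretches and rs <= stretches[-1][1]
                      and last_mark is not None
                      and abs((qs - last_mark[1]) - (rs - last_mark[0])) <= 20)
        if consistent:
            stretches[-1][1] = max(stretches[-1][1], re_)
            stretches[-1][3] = max(stretches[-1][3], qe)
        else:
            stretches.append([rs, re_, qs, qe])
        last_mark = (rs, qs)
    stretches = [s for s in stretches if s[1] - s[0] >= min_internal_uas]
    # monotone in the query
    filtered = []
    for s in stretches:
        if not filtered or s[2] >= filtered[-1][3]:
            filtered.append(s)
    stretches = filtered

    # cut points: container outer anchors + internal stretches
    cuts = [(outer.up.interval[0], container.start,
             outer.up.mate_interval[0], outer.qry_interval[0])]
    for rs, re_, qs, qe in stretches:
        cuts.append((rs, re_, qs, qe))
    cuts.append((container.end, outer.down.interval[1],
                 outer.qry_interval[1], outer.down.mate_interval[1]))

    out: list[AnchoredRegion] = []
    for (r0s, r0e, q0s, q0e), (r1s, r1e, q1s, q1e) in zip(cuts, cuts[1:]):
        sub_ref = (r0e, r1s)
        sub_qry = (q0e, q1s)
        if sub_ref[1] <= sub_ref[0] and sub_qry[1] <= sub_qry[0]:
            continue
        if ref.seq[sub_ref[0]:sub_ref[1]] == qry.seq[sub_qry[0]:sub_qry[1]]:
            continue  # no inter-genome difference
        members = [lo for lo in container.member_loci
                   if lo.start < sub_ref[1] + 500 and lo.end > sub_ref[0] - 500]
        sub = SVRegion(container.chrom, sub_ref[0], max(sub_ref[1], sub_ref[0]),
                       members or container.member_loci,
                       qry_chrom=outer.qry_chrom, qry_interval=sub_qry)
        up = UASAnchor("reference", "upstream", (r0s, r0e), outer.qry_chrom,
                       (q0s, q0e), 1.0, 1.0, 1)
        down = UASAnchor("reference", "downstream", (r1s, r1e),
                         outer.qry_chrom, (q1s, q1e), 1.0, 1.0, 1)
        out.append(AnchoredRegion(sub, "ok", up, down, outer.qry_chrom,
                                  sub_qry, (r0s, r1e), (q0s, q1e),
                                  flank_hits=outer.flank_hits))
    return out
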