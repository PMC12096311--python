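"""SV typing: INS, DEL, INV and SUB.

Types are assigned from the resolved residual material of each event, not
from caller labels:

* INS / DEL — sequence present in only one genome at the locus (the >50 bp
  size floor applies to the present side);
* SUB — both genomes carry non-empty residuals that remain unalignable in
  either orientation (identity < ``sub_max_identity``); the size floor
  applies to the longer side, so a 3 bp vs 504 bp substitution qualifies;
* INV — equal-sized residuals aligning in reverse orientation, subject to
  three criteria: forward-aligned flanking UAS, reciprocal-best reverse
  match (no forward alternative with higher identity), and no assembly gap
  inside the inverted interval in either genome.

Caller DUP/CNV labels are never emitted: duplicated material is an INS whose
source copy, when identifiable, is recorded in a SOURCE field.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .aligner import align_pair, oriented_similarity
from .io_formats import GenomeSequence, write_benchmark_vcf
from .repeat_resolver import (INV_MIN_IDENTITY, CopyCatalog, RawEvent,
                              assign_pattern)
from .seqs import revcomp

SUB_MAX_IDENTITY = 0.8
SIZE_FLOOR = 50
INV_SIZE_RATIO = 0.9


@dataclass
class ResolvedSV:
    """A base-pair-resolved structural variant in both genomes."""

    chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    svtype: str
    pattern: str = "unique"
    ambiguity_len: int = 1
    uas_up: tuple[tuple[int, int], tuple[int, int]] | None = None
    uas_down: tuple[tuple[int, int], tuple[int, int]] | None = None
    alt_seq: str | None = None
    source: str | None = None
    filter: str = "PASS"

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_len(self) -> int:
        return self.qry_end - self.qry_start

    @property
    def size(self) -> int:
        return max(self.ref_len, self.qry_len)


def classify(ref_residual: str, qry_residual: str,
             orientation_evidence: bool = False,
             gap_mask: tuple[bool, bool] = (False, False),
             sub_max_identity: float = SUB_MAX_IDENTITY,
             size_floor: int = SIZE_FLOOR) -> str | None:
    """Type a residual pair; None when no event qualifies.

    Returns 'DECOMPOSE' when both residuals still align forward above the
    substitution threshold — such material must be split further rather
    than typed.
    """
    if not ref_residual and not qry_residual:
        return None
    if not ref_residual:
        return "INS" if len(qry_residual) > size_floor else None
    if not qry_residual:
        return "DEL" if len(ref_residual) > size_floor else None
    fwd, rev = oriented_similarity(ref_residual, qry_residual)
    ratio = min(len(ref_residual), len(qry_residual)) / max(len(ref_residual),
                                                            len(qry_residual))
    if (orientation_evidence and rev >= INV_MIN_IDENTITY and rev > fwd
            and ratio >= INV_SIZE_RATIO and not any(gap_mask)):
        return "INV"
    if max(fwd, rev) < sub_max_identity:
        if max(len(ref_residual), len(qry_residual)) > size_floor:
            return "SUB"
        return None
    return "DECOMPOSE"


def check_inversion(ref_window: str, qry_window: str, ev: RawEvent,
                    flanks_forward: bool = True,
                    ref_gap: bool = False, qry_gap: bool = False) -> bool:
    """The three inversion criteria for a reverse-aligning candidate.

    (1) flanking UAS forward-aligned; (2) the reverse alignment is the
    reciprocal best match — no forward alternative of either interval
    anywhere in the other window has higher identity; (3) no assembly gap
    intersects the interval in either genome.
    """
    if not flanks_forward or ref_gap or qry_gap:
        return False
    rb = ref_window[ev.r_start:ev.r_end]
    qb = qry_window[ev.q_start:ev.q_end]
    if not rb or not qb:
        return False
    fwd, rev = oriented_similarity(rb, qb)
    if rev < INV_MIN_IDENTITY or rev <= fwd:
        return False
    best_fwd = 0.0
    for s in align_pair(rb, qry_window, min_identity=0.5):
        if s.strand == "+":
            best_fwd = max(best_fwd, s.identity)
    for s in align_pair(qb, ref_window, min_identity=0.5):
        if s.strand == "+":
            best_fwd = max(best_fwd, s.identity)
    return rev > best_fwd


def _find_source(ev: RawEvent, catalog: CopyCatalog,
                 chrom: str, window_start: int) -> str | None:
    """Reference-genome copy matching inserted material, if one exists."""
    for fam in catalog.families:
        if not fam.is_repeat:
            continue
        for c in fam.copies:
            if c.genome != "ref":
                continue
            ov = max(0, min(c.interval[1], ev.r_start + 1) - max(c.interval[0], ev.amb[0] - c.length))
            if ov > 0 or (abs(c.interval[0] - ev.r_start) <= c.length):
                return f"{chrom}:{window_start + c.interval[0] + 1}-{window_start + c.interval[1]}"
    return None


def classify_events(anchored, events: list[RawEvent], catalog: CopyCatalog,
                    ref: GenomeSequence, qry: GenomeSequence, *,
                    sub_max_identity: float = SUB_MAX_IDENTITY,
                    size_floor: int = SIZE_FLOOR) -> list[ResolvedSV]:
    """Turn resolved region events into typed, genome-coordinate SVs."""
    rs = anchored.ref_window[0]
    qs = anchored.qry_window[0]
    Rwin = ref.seq[anchored.ref_window[0]:anchored.ref_window[1]]
    Qwin = qry.seq[anchored.qry_window[0]:anchored.qry_window[1]]
    chrom = anchored.region.chrom
    qchrom = anchored.qry_chrom
    out: list[ResolvedSV] = []
    for ev in events:
        g_ref = (rs + ev.r_start, rs + ev.r_end)
        g_qry = (qs + ev.q_start, qs + ev.q_end)
        pattern = assign_pattern(ev, catalog)
        base = dict(chrom=chrom, ref_start=g_ref[0], ref_end=g_ref[1],
                    qry_chrom=qchrom, qry_start=g_qry[0], qry_end=g_qry[1],
                    pattern=pattern,
                    ambiguity_len=ev.amb_len,
                    uas_up=_uas_tuple(anchored, "up"),
                    uas_down=_uas_tuple(anchored, "down"))
        if ev.kind == "del" and ev.ref_len > size_floor:
            out.append(ResolvedSV(svtype="DEL", alt_seq="", **base))
        elif ev.kind == "ins" and ev.qry_len > size_floor:
            sv = ResolvedSV(svtype="INS", alt_seq=ev.q_seq, **base)
            if pattern != "unique":
                sv.source = _find_source(ev, catalog, chrom, rs)
            out.append(sv)
        elif ev.kind == "sub":
            if max(ev.ref_len, ev.qry_len) > size_floor:
                out.append(ResolvedSV(svtype="SUB", alt_seq=ev.q_seq, **base))
        elif ev.kind == "inv_candidate":
            ok = check_inversion(
                Rwin, Qwin, ev,
                flanks_forward=(anchored.status == "ok"),
                ref_gap=ref.gap_in(*g_ref),
                qry_gap=qry.gap_in(*g_qry))
            if ok and min(ev.ref_len, ev.qry_len) > size_floor:
                out.append(ResolvedSV(svtype="INV", alt_seq=None, **base))
            # failed candidates are excluded, not re-typed: their residuals
            # align (in reverse), so they are not substitutions either
    return out


def _uas_tuple(anchored, which):
    a = anchored.up if which == "up" else anchored.down
    if a is None or a.mate_interval is None:
        return None
    return (a.interval, a.mate_interval)


def summarize(svs: list[ResolvedSV]) -> dict:
    """Per-type and per-pattern counts; total equals the sum of the four
    type counts."""
    types = Counter(sv.svtype for sv in svs)
    patterns = Counter(sv.pattern for sv in svs)
    return {
        "total": len(svs),
        "by_type": {t: types.get(t, 0) for t in ("INS", "DEL", "INV", "SUB")},
        "by_pattern": {p: patterns.get(p, 0)
                       for p in ("unique", "cat1", "cat2", "cat3")},
    }


def emit_benchmark(svs: list[ResolvedSV], genomes: list[GenomeSequence],
                   path=None, uas_seq_len: int = 500) -> dict:
    """Write the benchmark VCF (if ``path``) and return summary counts."""
    if path is not None:
        write_benchmark_vcf(svs, genomes, path)
    return summarize(svs)
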