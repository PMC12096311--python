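"""Benchmark evaluation and breakpoint statistics.

`match_calls` scores a call set against a truth set under a parameterized
matching rule (breakpoint distance, size ratio, reciprocal overlap) with a
one-to-one assignment maximizing the number of true positives; ties resolve
by smallest breakpoint distance, then leftmost call.  The two presets
mirror a strict (exact) and a relaxed (50-bp, 90%) comparison; a third
preset allows 1-kb deviation.

`relative_rate` and `breakpoint_context` compute the regional enrichment of
SV breakpoints (share of breakpoints in a class over share of the genome in
that class) and the AT content of the +/-50 bp breakpoint context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_formats import AnnotationTrack, GenomeSequence


@dataclass(frozen=True)
class MatchParams:
    refdist: int
    pctsize: float
    pctovl: float
    pctseq: float = 0.0      # sequence comparison disabled throughout
    sizemin: int = 1
    sizemax: int = 30_000_000


PRESETS = {
    "strict": MatchParams(refdist=0, pctsize=1.0, pctovl=1.0),
    "relaxed": MatchParams(refdist=50, pctsize=0.9, pctovl=0.9),
    "relaxed1k": MatchParams(refdist=1000, pctsize=0.9, pctovl=0.9),
}


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    match_pairs: list = field(default_factory=list)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _size(sv) -> int:
    return max(sv.ref_len, sv.qry_len)


def _distance(a, b) -> int:
    ds = abs(a.ref_start - b.ref_start)
    de = abs(a.ref_end - b.ref_end)
    return max(ds, de)


def _type_class(t: str) -> str:
    return t


def eligible(call, truth, params: MatchParams, sub_flex: bool = True) -> bool:
    """Can this call/truth pair count as a match under ``params``?

    With ``sub_flex`` a SUB may match an INS or DEL (and vice versa) using
    the length of the corresponding allele side — the same locus can
    legitimately be typed either way depending on which genomes are
    compared.
    """
    if call.chrom != truth.chrom:
        return False
    tc, tt = call.svtype, truth.svtype
    if tc == tt:
        size_c, size_t = _size(call), _size(truth)
    elif sub_flex and {tc, tt} in ({"SUB", "INS"}, {"SUB", "DEL"}):
        side = "qry_len" if "INS" in (tc, tt) else "ref_len"
        size_c, size_t = getattr(call, side), getattr(truth, side)
    else:
        return False
    if _distance(call, truth) > params.refdist:
        return False
    if size_c == 0 or size_t == 0:
        return False
    if min(size_c, size_t) / max(size_c, size_t) < params.pctsize:
        return False
    # reciprocal overlap applies to span events only
    if tc != "INS" and tt != "INS" and params.pctovl > 0:
        if call.ref_len > 0 and truth.ref_len > 0:
            ov = max(0, min(call.ref_end, truth.ref_end) -
                     max(call.ref_start, truth.ref_start))
            if (ov / call.ref_len < params.pctovl or
                    ov / truth.ref_len < params.pctovl):
                return False
    return True


def match_calls(calls: list, truth: list, params: MatchParams,
                sub_flex: bool = True) -> EvalResult:
    """One-to-one matching maximizing the TP count.

    Candidate pairs must satisfy `eligible`; among maximum-cardinality
    matchings the one with smallest total breakpoint distance (then leftmost
    calls) wins.  Size bounds [sizemin, sizemax] filter both sets up front;
    unmatched calls are FPs and unmatched truths FNs.
    """
    calls = [c for c in calls if params.sizemin <= _size(c) <= params.sizemax]
    truth = [t for t in truth if params.sizemin <= _size(t) <= params.sizemax]
    n, m = len(calls), len(truth)
    if n == 0 or m == 0:
        return EvalResult(0, n, m)
    big = 1e9
    reward = np.zeros((n, m))
    for i, c in enumerate(calls):
        for j, t in enumerate(truth):
            if eligible(c, t, params, sub_flex):
                reward[i, j] = big - _distance(c, t) - 1e-6 * i
    rows, cols = linear_sum_assignment(reward, maximize=True)
    pairs = [(calls[i], truth[j]) for i, j in zip(rows, cols)
             if reward[i, j] > 0]
    tp = len(pairs)
    return EvalResult(tp, n - tp, m - tp, pairs)


@dataclass
class CallRecord:
    """Minimal record for matching (adapter for raw caller loci)."""

    chrom: str
    ref_start: int
    ref_end: int
    ref_len: int
    qry_len: int
    svtype: str


def from_locus(lo) -> CallRecord:
    """Adapt a raw caller locus to the matching interface.

    DUP labels are treated as insertions of the duplicated material; BND
    records carry no interval and match nothing under size rules.
    """
    t = lo.svtype_raw
    if t == "DUP":
        t = "INS"
    if t == "INS":
        return CallRecord(lo.chrom, lo.start, lo.start, 0, lo.svlen, "INS")
    if t == "DEL":
        return CallRecord(lo.chrom, lo.start, lo.end, lo.svlen, 0, "DEL")
    if t == "INV":
        return CallRecord(lo.chrom, lo.start, lo.end, lo.svlen, lo.svlen, "INV")
    qlen = len(lo.alt_seq) if lo.alt_seq else lo.svlen
    return CallRecord(lo.chrom, lo.start, lo.end, lo.end - lo.start, qlen, t)


# ---------------------------------------------------------------------------
# breakpoint statistics

def sv_breakpoints(svs) -> list[tuple[str, int]]:
    """Reference-genome breakpoint positions of a set of SVs (both edges of
    span events, single point for insertions)."""
    out = []
    for sv in svs:
        out.append((sv.chrom, sv.ref_start))
        if sv.ref_end != sv.ref_start:
            out.append((sv.chrom, sv.ref_end))
    return out


def relative_rate(breakpoints: list[tuple[str, int]],
                  annotation: AnnotationTrack) -> dict[str, float | None]:
    """Regional enrichment of breakpoints.

    rate(class) = (breakpoints in class / all breakpoints) /
    (class bp / genome bp); classes with zero genomic span report None.
    """
    genome_bp = sum(annotation.total_bp.values())
    counts = {c: 0 for c in AnnotationTrack.CLASSES}
    total = 0
    for chrom, pos in breakpoints:
        cls = annotation.class_of(chrom, pos)
        if cls is None:
            continue
        counts[cls] += 1
        total += 1
    rates: dict[str, float | None] = {}
    for cls in AnnotationTrack.CLASSES:
        class_bp = annotation.total_bp.get(cls, 0)
        if class_bp == 0 or genome_bp == 0:
            rates[cls] = None
        elif total == 0:
            rates[cls] = 0.0
        else:
            rates[cls] = (counts[cls] / total) / (class_bp / genome_bp)
    return rates


def breakpoint_context(breakpoints: list[tuple[str, int]],
                       genomes: list[GenomeSequence],
                       window: int = 50) -> dict:
    """AT fraction of the +/-``window`` bp context of each breakpoint.

    Returns per-breakpoint fractions, the genome-background AT fraction and
    their ratio; contexts truncated at contig ends are flagged.  Context
    sequences can feed external motif tools via `context_fasta`.
    """
    by_name = {g.name: g for g in genomes}
    fractions = []
    truncated = 0
    seqs = []
    for chrom, pos in breakpoints:
        g = by_name[chrom]
        s, e = pos - window, pos + window
        if s < 0 or e > len(g):
            truncated += 1
            s, e = max(0, s), min(len(g), e)
        ctx = g.seq[s:e]
        seqs.append((f"{chrom}:{s + 1}-{e}", ctx))
        at = sum(1 for b in ctx if b in "AT")
        denom = sum(1 for b in ctx if b in "ACGT")
        fractions.append(at / denom if denom else float("nan"))
    bg_at = bg_all = 0
    for g in genomes:
        bg_at += sum(1 for b in g.seq if b in "AT")
        bg_all += sum(1 for b in g.seq if b in "ACGT")
    background = bg_at / bg_all if bg_all else float("nan")
    mean = float(np.nanmean(fractions)) if fractions else float("nan")
    return {
        "per_breakpoint": fractions,
        "mean_at_fraction": mean,
        "background_at_fraction": background,
        "ratio": mean / background if background else float("nan"),
        "truncated": truncated,
        "contexts": seqs,
    }


def context_fasta(context: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in context["contexts"]:
            fh.write(f">{name}\n{seq}\n")
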