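"""Filtering, consolidation and boundary-scenario diagnosis of caller loci.

Raw caller calls are kept only when quality-flagged (PASS/PRECISE, where the
caller has flag discipline) and longer than 50 bp, then single-linkage
clustered into SV regions with a 500-bp gap tolerance.  Loci above 20 kb are
held out of clustering as their own container regions, since such calls
frequently span several real events.

Each region is then diagnosed against the three repeat-driven boundary
failure scenarios (copy-number discrepancy, reverse-orientation artifact,
copy misalignment) or labelled simple/combined.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .io_formats import SVLocus

log = logging.getLogger(__name__)

MERGE_GAP = 500
UNMERGE_LEN = 20_000
MIN_SVLEN = 50  # kept only when strictly exceeded

SCENARIOS = ("simple", "copy_number_discrepancy", "reverse_artifact",
             "copy_misalignment", "combined", "unlocatable")


@dataclass
class SVRegion:
    """A merged cluster of caller loci on the reference."""

    chrom: str
    start: int
    end: int
    member_loci: list[SVLocus] = field(default_factory=list)
    scenario: str | None = None
    qry_chrom: str | None = None
    qry_interval: tuple[int, int] | None = None
    is_container: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def filter_loci(loci: list[SVLocus],
                flagged_callers: set[str] | None = None,
                min_svlen: int = MIN_SVLEN) -> list[SVLocus]:
    """Keep loci with svlen strictly above ``min_svlen`` and, for callers
    with FILTER discipline, a PASS or PRECISE flag.

    ``flagged_callers`` limits the flag rule to the named callers; None means
    the rule applies to every locus that carries any filter flags at all
    (assembly-style outputs without flags bypass it).
    """
    kept: list[SVLocus] = []
    dropped = Counter()
    for lo in loci:
        if lo.svlen <= min_svlen:
            dropped[lo.caller] += 1
            continue
        apply_flag_rule = (lo.caller in flagged_callers) if flagged_callers is not None \
            else bool(lo.filter_flags)
        if apply_flag_rule and not (lo.filter_flags & {"PASS", "PRECISE"}):
            dropped[lo.caller] += 1
            continue
        kept.append(lo)
    for caller, n in sorted(dropped.items()):
        log.info("filter_loci: dropped %d loci from %s", n, caller)
    return kept


def merge_loci(loci: list[SVLocus], merge_gap: int = MERGE_GAP,
               unmerge_len: int = UNMERGE_LEN) -> list[SVRegion]:
    """Single-linkage clustering of loci into SV regions.

    Loci whose gap is <= ``merge_gap`` join one region (per chromosome).
    Any locus longer than ``unmerge_len`` is excluded from clustering and
    emitted as its own container region; loci lying inside it still cluster
    among themselves.  The region interval is the union of member intervals.
    """
    regions: list[SVRegion] = []
    big = [lo for lo in loci if lo.svlen > unmerge_len]
    small = [lo for lo in loci if lo.svlen <= unmerge_len]
    for lo in big:
        regions.append(SVRegion(lo.chrom, lo.start, max(lo.end, lo.start + lo.svlen),
                                [lo], is_container=True))
    by_chrom: dict[str, list[SVLocus]] = {}
    for lo in small:
        by_chrom.setdefault(lo.chrom, []).append(lo)
    for chrom in sorted(by_chrom):
        chrom_loci = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur: list[SVLocus] = []
        cur_end = None
        for lo in chrom_loci:
            if cur and lo.start - cur_end > merge_gap:
                regions.append(SVRegion(chrom, min(x.start for x in cur),
                                        max(x.end for x in cur), cur))
                cur = []
                cur_end = None
            cur.append(lo)
            cur_end = max(cur_end, lo.end) if cur_end is not None else lo.end
        if cur:
            regions.append(SVRegion(chrom, min(x.start for x in cur),
                                    max(x.end for x in cur), cur))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end, not r.is_container))
    return regions


# ---------------------------------------------------------------------------
# scenario diagnosis

def diagnose_scenario(region: SVRegion, catalog, pairing,
                      flank_hits: list | None = None,
                      hit_multiplicity: int = 5,
                      margin: float = 0.02) -> str:
    """Label a region with its boundary-determination scenario.

    Uses the repeat-copy catalog and orthologous pairing of the region plus
    the genome-wide hit lists of its flanks:

    * ``copy_number_discrepancy`` — >=2 copies in one genome strictly prefer
      (by more than ``margin`` identity) the same single copy in the other.
    * ``reverse_artifact`` — flank sequences hit >= ``hit_multiplicity``
      dispersed reverse-orientation locations although their best hit is
      forward.
    * ``copy_misalignment`` — the similarity-optimal copy pairing differs
      from the positional (order-preserving) pairing when copy counts agree.
    * ``combined`` when two or more fire; ``simple`` otherwise;
      ``unlocatable`` when the region has no query anchor.
    """
    if region.qry_interval is None:
        return "unlocatable"
    flags = set()
    if catalog is not None:
        if _copy_number_discrepancy(catalog, margin):
            flags.add("copy_number_discrepancy")
        if pairing is not None and _copy_misalignment(catalog, pairing, margin):
            flags.add("copy_misalignment")
    if flank_hits and _reverse_artifact(flank_hits, hit_multiplicity):
        flags.add("reverse_artifact")
    if len(flags) >= 2:
        return "combined"
    if flags:
        return flags.pop()
    return "simple"


def _copy_number_discrepancy(catalog, margin: float) -> bool:
    for fam in catalog.families:
        for side, other in (("ref", "qry"), ("qry", "ref")):
            mine = [c for c in fam.copies if c.genome == side]
            theirs = [c for c in fam.copies if c.genome == other]
            if len(mine) < 2 or len(theirs) < 2:
                continue
            best_targets = []
            for c in mine:
                sims = [(catalog.similarity(c, t), t) for t in theirs]
                sims.sort(key=lambda x: -x[0])
                if len(sims) >= 2 and sims[0][0] - sims[1][0] > margin:
                    best_targets.append(id(sims[0][1]))
                else:
                    best_targets.append(None)  # no strict preference
            counts = Counter(t for t in best_targets if t is not None)
            if counts and counts.most_common(1)[0][1] >= 2:
                return True
    return False


def _copy_misalignment(catalog, pairing, margin: float) -> bool:
    """Optimal pairing beats the positional pairing by a real margin."""
    for fam in catalog.families:
        ref_copies = sorted((c for c in fam.copies if c.genome == "ref"),
                            key=lambda c: c.interval)
        qry_copies = sorted((c for c in fam.copies if c.genome == "qry"),
                            key=lambda c: c.interval)
        if len(ref_copies) != len(qry_copies) or len(ref_copies) < 2:
            continue
        fam_pairs = [(r, q) for (r, q) in pairing.pairs
                     if r in fam.copies and q in fam.copies]
        if len(fam_pairs) != len(ref_copies):
            continue
        opt = sum(catalog.similarity(r, q) for r, q in fam_pairs)
        pos = sum(catalog.similarity(r, q) for r, q in zip(ref_copies, qry_copies))
        positional = {(id(r), id(q)) for r, q in zip(ref_copies, qry_copies)}
        actual = {(id(r), id(q)) for r, q in fam_pairs}
        if actual != positional and opt > pos + margin:
            return True
    return False


def _reverse_artifact(flank_hits, hit_multiplicity: int) -> bool:
    for hits in flank_hits:
        if not hits:
            continue
        best = max(hits, key=lambda h: h.identity)
        n_rev = sum(1 for h in hits if h.strand == "-")
        if best.strand == "+" and n_rev >= hit_multiplicity:
            return True
    return False
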