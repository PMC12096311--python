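"""On-disk formats and coordinate conventions.

Internal coordinates are 0-based half-open everywhere; 1-based inclusive
conventions (VCF, printed coordinates) are converted at the I/O boundary
only.  FASTA goes through Bio.SeqIO, VCF through pysam.VariantFile, PAF and
BED/GFF3 are simple tab tables.

Caller VCF dialects differ in where the event type, length and end live;
they are declared in a small registry (`DIALECTS`) rather than sniffed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pysam
from Bio import SeqIO

from .aligner import AlignmentSegment
from .seqs import DEFAULT_GAP_MIN_N, find_gap_runs, normalize

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types

@dataclass
class GenomeSequence:
    """A named nucleotide sequence with an assembly-gap (N-run) mask."""

    name: str
    seq: str
    gap_runs: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_raw(cls, name: str, seq: str,
                 gap_min_n: int = DEFAULT_GAP_MIN_N) -> "GenomeSequence":
        s = normalize(seq)
        if not s:
            raise ValueError(f"empty sequence for {name!r}")
        return cls(name, s, find_gap_runs(s, gap_min_n))

    def __len__(self) -> int:
        return len(self.seq)

    def gap_in(self, start: int, end: int) -> bool:
        """True if any gap run intersects the half-open interval."""
        return any(gs < end and ge > start for gs, ge in self.gap_runs)


@dataclass
class SVLocus:
    """One raw caller call, normalized to 0-based half-open coordinates.

    Insertions are point-anchored: start == end at the post-base position.
    """

    caller: str
    chrom: str
    start: int
    end: int
    svtype_raw: str
    svlen: int
    filter_flags: set[str] = field(default_factory=set)
    alt_seq: str | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start > end")
        if self.svlen < 0:
            raise ValueError("negative svlen")


@dataclass
class AnnotationTrack:
    """Genic / regulatory / intergenic partition of annotated chromosomes.

    Overlaps are resolved with precedence genic > regulatory > intergenic, so
    the three classes partition every chromosome they cover.
    """

    intervals: dict[str, dict[str, list[tuple[int, int]]]]
    total_bp: dict[str, int]

    CLASSES = ("genic", "regulatory", "intergenic")

    def class_of(self, chrom: str, pos: int) -> str | None:
        for cls in self.CLASSES:
            for s, e in self.intervals.get(cls, {}).get(chrom, ()):
                if s <= pos < e:
                    return cls
        return None


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path,
               gap_min_n: int = DEFAULT_GAP_MIN_N) -> list[GenomeSequence]:
    """Read a FASTA file into GenomeSequence records (uppercased, gap runs
    computed)."""
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Bio raises ValueError on malformed records
        raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [GenomeSequence.from_raw(r.id, str(r.seq), gap_min_n) for r in records]


def write_fasta(genomes: list[GenomeSequence], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# caller VCF dialects

@dataclass(frozen=True)
class VcfDialect:
    """Where a caller keeps type/length/end information.

    ``symbolic_pos_is_first_base``: for symbolic ALT records, POS names the
    first affected base (rather than the padding base before it).
    ``has_filter_discipline``: the caller emits meaningful FILTER flags; if
    False, downstream PASS/PRECISE filtering applies only the length rule.
    """

    name: str
    symbolic_pos_is_first_base: bool = True
    has_filter_discipline: bool = True


DIALECTS: dict[str, VcfDialect] = {
    "standard": VcfDialect("standard"),
    "assembly": VcfDialect("assembly", has_filter_discipline=False),
    "benchmark": VcfDialect("benchmark", has_filter_discipline=False),
}


def read_caller_vcf(path: str | Path, caller_name: str,
                    dialect: str = "standard") -> tuple[list[SVLocus], dict[str, int]]:
    """Read one caller's VCF into SVLocus records.

    Returns (loci, stats); stats counts dropped records by reason
    (unmated BNDs, records without resolvable coordinates) and logged
    SVLEN/END discrepancies.
    """
    if dialect not in DIALECTS:
        raise KeyError(f"unknown VCF dialect {dialect!r}; known: {sorted(DIALECTS)}")
    dia = DIALECTS[dialect]
    stats = {"dropped_unmated_bnd": 0, "dropped_no_coords": 0,
             "svlen_end_discrepancy": 0}

    vf = pysam.VariantFile(str(path))
    records = list(vf)

    # first pass: collect BND ids with mates present
    bnd_ids = {rec.id for rec in records
               if (rec.info.get("SVTYPE") == "BND") and rec.id}
    loci: list[SVLocus] = []
    for rec in records:
        svtype = rec.info.get("SVTYPE")
        alt = rec.alts[0] if rec.alts else None
        symbolic = alt is not None and alt.startswith("<")
        if svtype == "BND" or (alt is not None and ("[" in alt or "]" in alt)):
            mate = rec.info.get("MATEID")
            if isinstance(mate, tuple):
                mate = mate[0] if mate else None
            if not mate or mate not in bnd_ids:
                stats["dropped_unmated_bnd"] += 1
                continue
            # mated BNDs carry no interval; keep as zero-length locus
            start0 = rec.pos - 1
            loci.append(SVLocus(caller_name, rec.chrom, start0, start0,
                                "BND", 0, set(rec.filter.keys())))
            continue

        # pysam hoists INFO/END into rec.stop and recomputes it from SVLEN
        # when both are present; take END verbatim from the record text
        m = re.search(r"(?:^|;)END=(\d+)(?:;|$)", str(rec).split("\t")[7])
        info_end = int(m.group(1)) if m else None
        svlen = rec.info.get("SVLEN")
        if isinstance(svlen, tuple):
            svlen = svlen[0] if svlen else None
        if svlen is not None:
            svlen = abs(int(svlen))

        if symbolic:
            if svtype is None:
                svtype = alt.strip("<>")
            if info_end is None and svlen is None:
                stats["dropped_no_coords"] += 1
                continue
            if dia.symbolic_pos_is_first_base:
                start0 = rec.pos - 1
            else:
                start0 = rec.pos
            if info_end is not None:
                end0 = int(info_end)
                length = end0 - start0
                if svlen is not None and svlen != length and svtype != "INS":
                    stats["svlen_end_discrepancy"] += 1
                    log.warning("%s: SVLEN %d != END-derived length %d at %s:%d"
                                " (keeping END)", caller_name, svlen, length,
                                rec.chrom, rec.pos)
            else:
                length = svlen
                end0 = start0 + (0 if svtype == "INS" else length)
            if svtype == "INS":
                loci.append(SVLocus(caller_name, rec.chrom, start0, start0,
                                    "INS", svlen if svlen is not None else length,
                                    set(rec.filter.keys())))
            else:
                loci.append(SVLocus(caller_name, rec.chrom, start0, end0,
                                    svtype, length, set(rec.filter.keys())))
            continue

        if alt is None or rec.ref is None:
            stats["dropped_no_coords"] += 1
            continue
        # explicit REF/ALT with leading padding base
        ref_len = len(rec.ref) - 1
        alt_len = len(alt) - 1
        start0 = rec.pos  # POS is the 1-based padding base -> event starts at POS (0-based)
        if svtype is None:
            if ref_len == 0 and alt_len > 0:
                svtype = "INS"
            elif alt_len == 0 and ref_len > 0:
                svtype = "DEL"
            else:
                svtype = "SUB"
        if svtype == "INS":
            loci.append(SVLocus(caller_name, rec.chrom, start0, start0, "INS",
                                alt_len, set(rec.filter.keys()), alt_seq=alt[1:]))
        elif svtype == "DEL":
            loci.append(SVLocus(caller_name, rec.chrom, start0, start0 + ref_len,
                                "DEL", ref_len, set(rec.filter.keys())))
        else:
            loci.append(SVLocus(caller_name, rec.chrom, start0, start0 + ref_len,
                                svtype, max(ref_len, alt_len),
                                set(rec.filter.keys()), alt_seq=alt[1:]))
    return loci, stats


# ---------------------------------------------------------------------------
# benchmark VCF output

_VCF_HEADER = """##fileformat=VCFv4.2
##source=svrefine
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type (INS/DEL/INV/SUB)">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="max of reference and query allele lengths">
##INFO=<ID=END,Number=1,Type=Integer,Description="1-based inclusive end on the reference">
##INFO=<ID=QRY_CHROM,Number=1,Type=String,Description="query-genome sequence name">
##INFO=<ID=QRY_START,Number=1,Type=Integer,Description="query interval start, 1-based">
##INFO=<ID=QRY_END,Number=1,Type=Integer,Description="query interval end, 1-based inclusive">
##INFO=<ID=PATTERN,Number=1,Type=String,Description="breakpoint repeat pattern (unique/cat1/cat2/cat3)">
##INFO=<ID=AMBIG,Number=1,Type=Integer,Description="number of equivalent breakpoint placements">
##INFO=<ID=UAS_UP,Number=1,Type=String,Description="upstream unique anchor ref:start-end|qry:start-end (1-based)">
##INFO=<ID=UAS_DOWN,Number=1,Type=String,Description="downstream unique anchor ref:start-end|qry:start-end (1-based)">
##INFO=<ID=SOURCE,Number=1,Type=String,Description="source copy of duplicated insertion material">
##FILTER=<ID=GAP,Description="inversion candidate spanning an assembly gap">
"""


def _fmt_interval(chrom: str, start: int, end: int) -> str:
    """0-based half-open -> chrom:start-end 1-based inclusive."""
    return f"{chrom}:{start + 1}-{end}"


def write_benchmark_vcf(svs, genomes: list[GenomeSequence],
                        path: str | Path) -> None:
    """Write resolved SVs as a VCF 4.2 benchmark file.

    Alleles carry the actual sequences (with the usual leading padding base);
    INV records are symbolic with POS at the first inverted base.  The file
    round-trips through `read_caller_vcf` with the ``benchmark`` dialect.
    """
    by_name = {g.name: g for g in genomes}
    lines = [_VCF_HEADER]
    for g in genomes:
        lines.append(f"##contig=<ID={g.name},length={len(g)}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for i, sv in enumerate(sorted(svs, key=lambda s: (s.chrom, s.ref_start))):
        g = by_name.get(sv.chrom)
        if g is None or sv.ref_end > len(g) or sv.ref_start < 0:
            raise ValueError(f"SV {i} ({sv.chrom}:{sv.ref_start}) outside sequence bounds")
        info = {
            "SVTYPE": sv.svtype,
            "SVLEN": max(sv.ref_len, sv.qry_len),
            "QRY_CHROM": sv.qry_chrom,
            "QRY_START": sv.qry_start + 1,
            "QRY_END": sv.qry_end,
            "PATTERN": sv.pattern,
            "AMBIG": sv.ambiguity_len,
        }
        if sv.uas_up is not None:
            info["UAS_UP"] = "{}|{}".format(
                _fmt_interval(sv.chrom, *sv.uas_up[0]),
                _fmt_interval(sv.qry_chrom, *sv.uas_up[1]))
        if sv.uas_down is not None:
            info["UAS_DOWN"] = "{}|{}".format(
                _fmt_interval(sv.chrom, *sv.uas_down[0]),
                _fmt_interval(sv.qry_chrom, *sv.uas_down[1]))
        if getattr(sv, "source", None):
            info["SOURCE"] = sv.source
        filt = getattr(sv, "filter", None) or "PASS"
        if sv.svtype == "INV":
            pos1 = sv.ref_start + 1  # first inverted base
            ref_allele = g.seq[sv.ref_start]
            alt = "<INV>"
            info["END"] = sv.ref_end
        else:
            s = sv.ref_start
            if s == 0:
                raise ValueError("event at position 0 not representable with "
                                 "leading padding base")
            pos1 = s  # 1-based position of the padding base at 0-based s-1
            pad = g.seq[s - 1]
            ref_allele = pad + g.seq[s:sv.ref_end]
            alt_seq = getattr(sv, "alt_seq", None)
            if alt_seq is None:
                alt_seq = ""
            alt = pad + alt_seq
            info["END"] = s - 1 + len(ref_allele)
        info_s = ";".join(f"{k}={v}" for k, v in info.items())
        lines.append(f"{sv.chrom}\t{pos1}\tsv{i}\t{ref_allele}\t{alt}\t.\t{filt}\t{info_s}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def write_caller_vcf(loci: list[SVLocus], genomes: list[GenomeSequence],
                     path: str | Path, with_filter: bool = True) -> None:
    """Write raw caller-style loci (symbolic ALTs, INFO SVTYPE/SVLEN/END)."""
    by_name = {g.name: g for g in genomes}
    header = ("##fileformat=VCFv4.2\n"
              '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n'
              '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n'
              '##INFO=<ID=END,Number=1,Type=Integer,Description="end, 1-based inclusive">\n'
              '##INFO=<ID=MATEID,Number=1,Type=String,Description="breakend mate">\n'
              '##FILTER=<ID=PASS,Description="ok">\n'
              '##FILTER=<ID=LowQual,Description="low quality">\n'
              '##FILTER=<ID=PRECISE,Description="precise call">\n'
              '##ALT=<ID=INS,Description="insertion">\n'
              '##ALT=<ID=DEL,Description="deletion">\n'
              '##ALT=<ID=INV,Description="inversion">\n'
              '##ALT=<ID=DUP,Description="duplication">\n')
    lines = [header]
    for g in genomes:
        lines.append(f"##contig=<ID={g.name},length={len(g)}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for i, lo in enumerate(sorted(loci, key=lambda x: (x.chrom, x.start))):
        g = by_name[lo.chrom]
        if lo.svtype_raw == "INS" and lo.alt_seq:
            pos1 = lo.start
            pad = g.seq[lo.start - 1]
            line_ref, line_alt = pad, pad + lo.alt_seq
            info = f"SVTYPE=INS;SVLEN={lo.svlen}"
        else:
            pos1 = lo.start + 1  # symbolic: POS is the first affected base
            line_ref = g.seq[lo.start] if lo.start < len(g) else "N"
            line_alt = f"<{lo.svtype_raw}>"
            end1 = lo.end if lo.end > lo.start else lo.start + lo.svlen
            info = f"SVTYPE={lo.svtype_raw};SVLEN={lo.svlen};END={end1}"
        filt = ";".join(sorted(lo.filter_flags)) if (with_filter and lo.filter_flags) else "."
        lines.append(f"{lo.chrom}\t{pos1}\tcall{i}\t{line_ref}\t{line_alt}\t.\t{filt}\t{info}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


# ---------------------------------------------------------------------------
# PAF

def read_paf(path: str | Path) -> list[AlignmentSegment]:
    """Read a >=12 column PAF into alignment segments.

    Identity is residue matches (col 10) over alignment block length (col 11).
    """
    out: list[AlignmentSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"PAF line {lineno}: expected >=12 columns, got {len(cols)}")
            q_name, _, q_start, q_end, strand, t_name, _, t_start, t_end, nmatch, blocklen = (
                cols[0], cols[1], int(cols[2]), int(cols[3]), cols[4], cols[5],
                cols[6], int(cols[7]), int(cols[8]), int(cols[9]), int(cols[10]))
            ident = nmatch / blocklen if blocklen else 0.0
            out.append(AlignmentSegment(q_name, t_name, q_start, q_end,
                                        t_start, t_end, strand, nmatch,
                                        blocklen, ident))
    return out


def write_paf(segments: list[AlignmentSegment], q_len: dict[str, int],
              t_len: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write("\t".join(map(str, [
                s.q_name, q_len.get(s.q_name, 0), s.q_start, s.q_end, s.strand,
                s.t_name, t_len.get(s.t_name, 0), s.t_start, s.t_end,
                s.matches, s.block_len, 60])) + "\n")


# ---------------------------------------------------------------------------
# annotation

def read_annotation(path: str | Path, chrom_sizes: dict[str, int],
                    regulatory_window: int = 3000) -> AnnotationTrack:
    """Build a genic/regulatory/intergenic partition from GFF3 genes or a
    labelled BED.

    For GFF3 input the regulatory class is a fixed window upstream of each
    gene's TSS (strand-aware), truncated at chromosome ends; everything else
    is intergenic.  Overlaps resolve with precedence genic > regulatory.
    """
    path = Path(path)
    genic: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    regulatory: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    explicit_classes = False
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if path.suffix.lower() in (".bed",) or (len(cols) == 4 and not cols[1].isalpha()):
                chrom, s, e, cls = cols[0], int(cols[1]), int(cols[2]), cols[3]
                explicit_classes = True
                if chrom not in chrom_sizes:
                    continue
                if cls == "genic":
                    genic[chrom].append((s, e))
                elif cls == "regulatory":
                    regulatory[chrom].append((s, e))
                # intergenic rows are implied by the remainder
            else:
                if len(cols) < 7 or cols[2] != "gene":
                    continue
                chrom, s1, e1, strand = cols[0], int(cols[3]), int(cols[4]), cols[6]
                if chrom not in chrom_sizes:
                    continue
                s, e = s1 - 1, e1  # GFF3 is 1-based inclusive
                genic[chrom].append((s, e))
                if strand == "-":
                    reg = (e, min(chrom_sizes[chrom], e + regulatory_window))
                else:
                    reg = (max(0, s - regulatory_window), s)
                regulatory[chrom].append(reg)

    from .seqs import merge_intervals
    intervals = {"genic": {}, "regulatory": {}, "intergenic": {}}
    totals = {"genic": 0, "regulatory": 0, "intergenic": 0}
    for chrom, size in chrom_sizes.items():
        gen = merge_intervals(genic[chrom])
        reg_raw = merge_intervals(regulatory[chrom])
        # precedence: regulatory loses to genic
        reg = _subtract(reg_raw, gen)
        inter = _subtract([(0, size)], merge_intervals(gen + reg))
        intervals["genic"][chrom] = gen
        intervals["regulatory"][chrom] = reg
        intervals["intergenic"][chrom] = inter
        totals["genic"] += sum(e - s for s, e in gen)
        totals["regulatory"] += sum(e - s for s, e in reg)
        totals["intergenic"] += sum(e - s for s, e in inter)
    if not explicit_classes and all(not v for v in genic.values()):
        log.warning("no gene features found in %s", path)
    return AnnotationTrack(intervals, totals)


def _subtract(base: list[tuple[int, int]],
              minus: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference of unions of half-open intervals."""
    out = []
    for s, e in base:
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return [iv for iv in out if iv[1] > iv[0]]


def write_regions_bed(regions, path: str | Path) -> None:
    """BED of SV regions with scenario labels and anchoring status."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            name = getattr(r, "scenario", ".") or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")
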