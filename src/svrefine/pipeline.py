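"""End-to-end curation pipeline.

ingest -> filter/merge -> UAS anchoring -> repeat resolution -> typing ->
benchmark emission, as one reproducible run with a serialized config, a
per-region JSON-lines decision log (the automated counterpart of a manual
inspection audit trail) and stage-count reporting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .aligner import KmerIndex
from .io_formats import (GenomeSequence, SVLocus, read_caller_vcf, read_fasta,
                         write_benchmark_vcf, write_regions_bed)
from .region_builder import (SVRegion, diagnose_scenario, filter_loci,
                             merge_loci)
from .repeat_resolver import decompose_segments, match_copies, place_breakpoints
from .sv_classifier import ResolvedSV, classify_events, summarize
from .uas_anchor import AnchoredRegion, find_uas, split_complex_region

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    ref_fasta: str = ""
    qry_fasta: str = ""
    calls: list[dict] = field(default_factory=list)  # {caller, path, dialect}
    out_dir: str = "svrefine_out"
    merge_gap: int = 500
    unmerge_len: int = 20_000
    min_svlen: int = 50
    step: int = 5000
    max_extend: int = 30_000
    min_identity: float = 0.95
    min_margin: float = 0.05
    candidate_floor: float = 0.80
    min_internal_uas: int = 1000
    sub_max_identity: float = 0.8
    truth_vcf: str | None = None


@dataclass
class CurationResult:
    svs: list[ResolvedSV]
    regions: list[SVRegion]
    anchored: list[AnchoredRegion]
    report: dict
    log_rows: list[dict]


def curate_genomes(ref_genomes: list[GenomeSequence],
                   qry_genomes: list[GenomeSequence],
                   loci_by_caller: dict[str, list[SVLocus]],
                   config: RunConfig | None = None) -> CurationResult:
    """Run the full curation on in-memory genomes and caller loci."""
    cfg = config or RunConfig()
    ref_by_name = {g.name: g for g in ref_genomes}
    qry_by_name = {g.name: g for g in qry_genomes}
    indices = {g.name: KmerIndex(g.seq) for g in qry_genomes}

    all_loci = [lo for loci in loci_by_caller.values() for lo in loci]
    filtered = filter_loci(all_loci, min_svlen=cfg.min_svlen)
    regions = merge_loci(filtered, merge_gap=cfg.merge_gap,
                         unmerge_len=cfg.unmerge_len)

    uas_kwargs = dict(step=cfg.step, max_extend=cfg.max_extend,
                      min_identity=cfg.min_identity,
                      min_margin=cfg.min_margin,
                      candidate_floor=cfg.candidate_floor)
    resolved: list[ResolvedSV] = []
    anchored_all: list[AnchoredRegion] = []
    log_rows: list[dict] = []
    scenario_counts: Counter = Counter()
    n_unanchorable = 0
    for region in regions:
        ref = ref_by_name.get(region.chrom)
        if ref is None:
            log_rows.append({"region": _riv(region), "status": "no_ref_chrom"})
            continue
        if region.is_container:
            anchored_list = split_complex_region(
                region, ref, qry_genomes, indices,
                min_internal_uas=cfg.min_internal_uas, **uas_kwargs)
        else:
            anchored_list = [find_uas(region, ref, qry_genomes, indices,
                                      **uas_kwargs)]
        for ar in anchored_list:
            anchored_all.append(ar)
            row = {"region": _riv(ar.region), "status": ar.status,
                   "container": region.is_container}
            if ar.status != "ok":
                if ar.status == "unanchorable":
                    n_unanchorable += 1
                    ar.region.scenario = "unlocatable"
                log_rows.append(row)
                continue
            qry = qry_by_name[ar.qry_chrom]
            Rwin = ref.seq[ar.ref_window[0]:ar.ref_window[1]]
            Qwin = qry.seq[ar.qry_window[0]:ar.qry_window[1]]
            catalog = decompose_segments(Rwin, Qwin)
            pairing = match_copies(catalog)
            scenario = diagnose_scenario(ar.region, catalog, pairing,
                                         ar.flank_hits)
            ar.region.scenario = scenario
            scenario_counts[scenario] += 1
            calls, status = place_breakpoints(catalog, pairing)
            row["scenario"] = scenario
            row["resolution"] = status
            if status != "ok":
                log_rows.append(row)
                continue
            # resolution windows include the 5-30 kb anchoring flanks, which
            # can reach into neighbouring regions; those events belong to
            # (and are resolved by) their own regions
            lo = ar.region.start - cfg.merge_gap
            hi = ar.region.end + cfg.merge_gap
            own = [c.event for c in calls
                   if ar.ref_window[0] + c.event.r_end >= lo
                   and ar.ref_window[0] + c.event.r_start <= hi]
            svs = classify_events(ar, own, catalog, ref, qry,
                                  sub_max_identity=cfg.sub_max_identity,
                                  size_floor=cfg.min_svlen)
            row["n_svs"] = len(svs)
            log_rows.append(row)
            resolved.extend(svs)

    svs = _dedupe(resolved)
    report = {
        "loci_in": len(all_loci),
        "loci_filtered": len(filtered),
        "regions": len(regions),
        "containers": sum(1 for r in regions if r.is_container),
        "anchored_ok": sum(1 for a in anchored_all if a.status == "ok"),
        "unanchorable": n_unanchorable,
        "scenarios": dict(scenario_counts),
        **summarize(svs),
    }
    return CurationResult(svs, regions, anchored_all, report, log_rows)


def _riv(region: SVRegion) -> str:
    return f"{region.chrom}:{region.start}-{region.end}"


def _dedupe(svs: list[ResolvedSV]) -> list[ResolvedSV]:
    """Overlapping resolution windows can re-derive the same event; identical
    canonical calls collapse to one."""
    seen = set()
    out = []
    for sv in sorted(svs, key=lambda s: (s.chrom, s.ref_start, s.ref_end,
                                         s.svtype)):
        key = (sv.chrom, sv.ref_start, sv.ref_end, sv.svtype, sv.qry_len)
        if key in seen:
            continue
        seen.add(key)
        out.append(sv)
    return out


def curate(config: RunConfig) -> CurationResult:
    """File-based pipeline run; writes benchmark.vcf, regions.bed,
    report.tsv, manifest.json and log.jsonl to the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref_genomes = read_fasta(config.ref_fasta)
    qry_genomes = read_fasta(config.qry_fasta)
    loci_by_caller: dict[str, list[SVLocus]] = {}
    for spec in config.calls:
        loci, stats = read_caller_vcf(spec["path"], spec["caller"],
                                      spec.get("dialect", "standard"))
        loci_by_caller[spec["caller"]] = loci
        log.info("read %d loci from %s (%s)", len(loci), spec["caller"], stats)

    result = curate_genomes(ref_genomes, qry_genomes, loci_by_caller, config)

    write_benchmark_vcf(result.svs, ref_genomes, out / "benchmark.vcf")
    write_regions_bed(result.regions, out / "regions.bed")
    with open(out / "report.tsv", "w") as fh:
        for k, v in result.report.items():
            fh.write(f"{k}\t{json.dumps(v) if isinstance(v, dict) else v}\n")
    (out / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2))
    with open(out / "log.jsonl", "w") as fh:
        for row in result.log_rows:
            fh.write(json.dumps(row) + "\n")

    if config.truth_vcf:
        from .evaluator import PRESETS, from_locus, match_calls
        truth, _ = read_caller_vcf(config.truth_vcf, "truth", "benchmark")
        truth_rec = [from_locus(t) for t in truth
                     if not t.filter_flags or t.filter_flags & {"PASS"}]
        call_rec = [_sv_record(sv) for sv in result.svs]
        with open(out / "metrics.tsv", "w") as fh:
            fh.write("preset\ttp\tfp\tfn\tprecision\trecall\tf1\n")
            for preset, params in PRESETS.items():
                ev = match_calls(call_rec, truth_rec, params)
                fh.write(f"{preset}\t{ev.tp}\t{ev.fp}\t{ev.fn}\t"
                         f"{ev.precision:.4f}\t{ev.recall:.4f}\t{ev.f1:.4f}\n")
    return result


def _sv_record(sv: ResolvedSV):
    return sv
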