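"""Seeded reference/query genome pairs with planted SVs.

The generator builds the test substrate for the whole toolkit: background
sequence at a chosen GC content, explicit repeat landscapes (tandem arrays,
dispersed copies, inverted repeats, dense fold-back clusters), N-gap runs,
and planted variants (insertions, deletions, inversions, substitutions) in
unique or repeat context, together with exact truth records.

Truth breakpoints are canonical (leftmost) and their ambiguity intervals
are computed by exhaustive enumeration of equivalent placements — every
position where applying the same edit reproduces the query byte-for-byte.
Applying all truth records to the reference reconstructs the query exactly.

The default scenario suite plants roughly twenty SVs across a dozen
~20-30 kb chromosome pairs, one chromosome per repeat scenario, with
simulated caller output (optionally jittered and with spurious calls) for
end-to-end pipeline tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import GenomeSequence, SVLocus, write_caller_vcf, write_fasta
from .seqs import revcomp, trim_common

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# building blocks

def random_seq(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute a ``rate`` fraction of positions (no indels)."""
    if rate <= 0:
        return seq
    arr = bytearray(seq.encode())
    n_mut = int(round(rate * len(arr)))
    for i in rng.choice(len(arr), size=min(n_mut, len(arr)), replace=False):
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.decode()


@dataclass
class RepeatSpec:
    """One repeat landscape element for `make_reference`."""

    kind: str                 # tandem_array / dispersed_copy / inverted_repeat / foldback_cluster
    unit_len: int
    copy_count: int
    divergence: float = 0.0
    placement: list[int] | tuple[int, int] | None = None

    def __post_init__(self):
        if self.unit_len < 10:
            raise ValueError("unit_len must be >= 10")
        if self.copy_count < 2:
            raise ValueError("copy_count must be >= 2")
        if not 0 <= self.divergence <= 0.2:
            raise ValueError("divergence must be in [0, 0.2]")


def _instantiate_repeat(rng, spec: RepeatSpec, length: int) -> list[tuple[int, str]]:
    """Concrete (position, sequence) pieces for a repeat spec."""
    unit = random_seq(rng, spec.unit_len)
    pieces = []
    if spec.kind == "tandem_array":
        start = spec.placement[0] if spec.placement else int(
            rng.integers(0, length - spec.unit_len * spec.copy_count))
        arr = "".join(mutate(rng, unit, spec.divergence)
                      for _ in range(spec.copy_count))
        pieces.append((start, arr))
    elif spec.kind == "dispersed_copy":
        if isinstance(spec.placement, list):
            positions = spec.placement
        else:
            positions = sorted(rng.choice(
                length - spec.unit_len, size=spec.copy_count, replace=False))
        for p in positions:
            pieces.append((int(p), mutate(rng, unit, spec.divergence)))
    elif spec.kind == "inverted_repeat":
        positions = spec.placement or sorted(rng.choice(
            length - spec.unit_len, size=2, replace=False))
        pieces.append((int(positions[0]), mutate(rng, unit, spec.divergence)))
        pieces.append((int(positions[1]),
                       revcomp(mutate(rng, unit, spec.divergence))))
    elif spec.kind == "foldback_cluster":
        # dense cluster of short fragments and their reverse complements
        s, e = spec.placement
        frag_pool = [random_seq(rng, int(rng.integers(80, spec.unit_len + 1)))
                     for _ in range(max(2, spec.copy_count // 4))]
        parts = []
        total = 0
        while total < (e - s) - spec.unit_len:
            f = frag_pool[int(rng.integers(len(frag_pool)))]
            f = mutate(rng, f, spec.divergence)
            if rng.random() < 0.5:
                f = revcomp(f)
            joint = random_seq(rng, int(rng.integers(20, 60)))
            parts += [f, joint]
            total += len(f) + len(joint)
        pieces.append((s, "".join(parts)[:e - s]))
    else:
        raise ValueError(f"unknown repeat kind {spec.kind!r}")
    return pieces


def make_reference(seed: int, length: int, gc: float = 0.4,
                   repeat_specs: list[RepeatSpec] = (),
                   gap_spec: list[tuple[int, int]] = (),
                   at_rich_blocks: list[tuple[int, int, float]] = (),
                   name: str = "chr1") -> GenomeSequence:
    """Background sequence with instantiated repeats, gaps and AT blocks.

    Same seed, same output — all randomness flows from ``seed``.
    """
    rng = np.random.default_rng(seed)
    if length < 1000:
        raise ValueError("length too small for a usable chromosome")
    seq = bytearray(random_seq(rng, length, gc).encode())
    occupied: list[tuple[int, int]] = []
    for spec in repeat_specs:
        for pos, piece in _instantiate_repeat(rng, spec, length):
            end = pos + len(piece)
            if end > length:
                raise ValueError(
                    f"repeat spec {spec.kind} needs {end} bp, have {length}")
            for s, e in occupied:
                if pos < e and end > s:
                    raise ValueError("repeat specs overlap; adjust placements")
            seq[pos:end] = piece.encode()
            occupied.append((pos, end))
    for pos, ln, at in at_rich_blocks:
        seq[pos:pos + ln] = random_seq(rng, ln, gc=1 - at).encode()
    for pos, ln in gap_spec:
        seq[pos:pos + ln] = b"N" * ln
    return GenomeSequence.from_raw(name, seq.decode())


# ---------------------------------------------------------------------------
# planting

@dataclass
class PlantSpec:
    """One edit to apply to the reference.

    kind 'del' removes ``ref_len`` bases at ``pos``; 'ins' inserts ``seq``
    at ``pos``; 'sub' replaces ``ref_len`` bases with ``seq``; 'inv'
    reverse-complements ``ref_len`` bases in place.
    """

    kind: str
    pos: int
    ref_len: int = 0
    seq: str = ""
    pattern: str = "unique"
    excluded_reason: str | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.pos, self.pos + self.ref_len)


@dataclass
class TruthSV:
    svtype: str
    chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    pattern: str = "unique"
    ambiguity: tuple[int, int] = (0, 0)
    alt_seq: str = ""
    excluded_reason: str | None = None
    uas_up = None
    uas_down = None
    source = None

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_len(self) -> int:
        return self.qry_end - self.qry_start

    @property
    def size(self) -> int:
        return max(self.ref_len, self.qry_len)

    @property
    def ambiguity_len(self) -> int:
        return max(1, self.ambiguity[1] - self.ambiguity[0])

    @property
    def filter(self) -> str:
        return "GAP" if self.excluded_reason else "PASS"


def plant_svs(ref: GenomeSequence, plant_specs: list[PlantSpec],
              qry_name: str | None = None,
              truth_window: int = 1500) -> tuple[GenomeSequence, list[TruthSV]]:
    """Apply edits to the reference and derive exact truth records.

    Edits must not overlap (refused with the conflict list).  For every
    indel the ambiguity interval is found by exhaustively testing each
    placement inside a window around the edit; inversions and substitutions
    are trimmed to their maximal-mismatch core so the recorded breakpoints
    are canonical.
    """
    specs = sorted(plant_specs, key=lambda s: s.pos)
    conflicts = [(a, b) for a, b in zip(specs, specs[1:])
                 if a.interval[1] > b.interval[0]]
    if conflicts:
        raise ValueError("overlapping plants: " + "; ".join(
            f"{a.kind}@{a.pos} vs {b.kind}@{b.pos}" for a, b in conflicts))
    R = ref.seq
    qry_name = qry_name or ref.name
    parts = []
    cur = 0
    deltas = []
    for sp in specs:
        parts.append(R[cur:sp.pos])
        if sp.kind == "del":
            new = ""
        elif sp.kind == "ins":
            new = sp.seq
        elif sp.kind == "sub":
            new = sp.seq
        elif sp.kind == "inv":
            new = revcomp(R[sp.pos:sp.pos + sp.ref_len])
        else:
            raise ValueError(f"unknown plant kind {sp.kind!r}")
        parts.append(new)
        deltas.append(len(new) - sp.ref_len)
        cur = sp.pos + sp.ref_len
    parts.append(R[cur:])
    Q = "".join(parts)

    truths: list[TruthSV] = []
    off = 0
    for i, sp in enumerate(specs):
        prev_end = specs[i - 1].interval[1] if i else 0
        next_start = specs[i + 1].pos if i + 1 < len(specs) else len(R)
        a = max(prev_end, sp.pos - truth_window)
        b = min(next_start, sp.interval[1] + truth_window)
        qa, qb = a + off, b + off + deltas[i]
        R_w, Q_w = R[a:b], Q[qa:qb]
        if sp.kind == "del":
            L = sp.ref_len
            xs = [x for x in range(len(R_w) - L + 1)
                  if R_w[:x] + R_w[x + L:] == Q_w]
            assert xs and xs == list(range(xs[0], xs[-1] + 1))
            truths.append(TruthSV("DEL", ref.name, a + xs[0], a + xs[0] + L,
                                  qry_name, qa + xs[0], qa + xs[0],
                                  sp.pattern, (a + xs[0], a + xs[-1] + 1),
                                  "", sp.excluded_reason))
        elif sp.kind == "ins":
            L = len(sp.seq)
            ys = [y for y in range(len(Q_w) - L + 1)
                  if Q_w[:y] + Q_w[y + L:] == R_w]
            assert ys and ys == list(range(ys[0], ys[-1] + 1))
            truths.append(TruthSV("INS", ref.name, a + ys[0], a + ys[0],
                                  qry_name, qa + ys[0], qa + ys[0] + L,
                                  sp.pattern, (a + ys[0], a + ys[-1] + 1),
                                  Q_w[ys[0]:ys[0] + L], sp.excluded_reason))
        else:
            p, s = trim_common(R_w, Q_w)
            rs_, re_ = a + p, b - s
            qs_, qe_ = qa + p, qb - s
            assert re_ > rs_ and qe_ > qs_, "edit vanished after trimming"
            svtype = "INV" if sp.kind == "inv" else "SUB"
            truths.append(TruthSV(svtype, ref.name, rs_, re_, qry_name,
                                  qs_, qe_, sp.pattern, (rs_, rs_ + 1),
                                  Q[qs_:qe_] if svtype == "SUB" else "",
                                  sp.excluded_reason))
        off += deltas[i]
    qry = GenomeSequence.from_raw(qry_name, Q)
    return qry, truths


def apply_truth(ref_seq: str, truths: list[TruthSV], qry_seqs: dict[str, str]) -> str:
    """Reconstruct the query chromosome from the reference and its truth
    records (the reconstruction identity every generated pair satisfies)."""
    parts = []
    cur = 0
    for t in sorted(truths, key=lambda t: t.ref_start):
        parts.append(ref_seq[cur:t.ref_start])
        if t.svtype == "INV":
            parts.append(revcomp(ref_seq[t.ref_start:t.ref_end]))
        else:
            parts.append(qry_seqs[t.qry_chrom][t.qry_start:t.qry_end])
        cur = t.ref_end
    parts.append(ref_seq[cur:])
    return "".join(parts)


# ---------------------------------------------------------------------------
# simulated callers

@dataclass
class CallerProfile:
    name: str
    dialect: str = "standard"        # emits PASS/PRECISE flags
    detects: float = 1.0             # fraction of truths reported
    dup_confusion: bool = False      # reports repeat-context INS as DUP
    sub_as: str = "INS"              # how substitutions are reported


DEFAULT_CALLERS = [
    CallerProfile("alpha", "standard", 1.0, dup_confusion=False, sub_as="INS"),
    CallerProfile("beta", "assembly", 1.0, dup_confusion=True, sub_as="DEL"),
    CallerProfile("gamma", "standard", 0.8, dup_confusion=False, sub_as="INS"),
]


def simulate_calls(truths: list[TruthSV], genomes: list[GenomeSequence],
                   rng: np.random.Generator,
                   callers: list[CallerProfile] = DEFAULT_CALLERS,
                   jitter_sd: float = 0.0,
                   spurious_per_mb: float = 0.0) -> dict[str, list[SVLocus]]:
    """Caller-style loci derived from the truth set.

    Breakpoint jitter is Gaussian (rounded); spurious calls arrive at a
    Poisson rate per Mb; type confusion follows the caller profile.
    """
    by_name = {g.name: g for g in genomes}
    calls: dict[str, list[SVLocus]] = {c.name: [] for c in callers}
    for prof in callers:
        for t in truths:
            if rng.random() > prof.detects:
                continue
            jit = int(round(rng.normal(0, jitter_sd))) if jitter_sd else 0
            start = max(1, t.ref_start + jit)
            svtype = t.svtype
            if svtype == "SUB":
                svtype = prof.sub_as
            if svtype == "INS" and prof.dup_confusion and t.pattern != "unique":
                svtype = "DUP"
            flags = {"PASS"} if prof.dialect == "standard" else set()
            if svtype == "INS" or (svtype == "DUP") or (t.svtype == "SUB" and svtype == "INS"):
                svlen = t.qry_len
                calls[prof.name].append(SVLocus(prof.name, t.chrom, start,
                                                start, svtype, svlen, flags))
            elif svtype == "DEL":
                svlen = t.ref_len if t.svtype != "SUB" else t.ref_len
                calls[prof.name].append(SVLocus(prof.name, t.chrom, start,
                                                start + svlen, svtype, svlen,
                                                flags))
            else:  # INV
                calls[prof.name].append(SVLocus(prof.name, t.chrom, start,
                                                start + t.ref_len, "INV",
                                                t.ref_len, flags))
        if spurious_per_mb > 0:
            total_bp = sum(len(g) for g in genomes)
            n_spur = rng.poisson(spurious_per_mb * total_bp / 1e6)
            for _ in range(n_spur):
                g = genomes[int(rng.integers(len(genomes)))]
                pos = int(rng.integers(1000, len(g) - 1000))
                ln = int(rng.integers(60, 500))
                svt = ["DEL", "INS"][int(rng.integers(2))]
                flags = {"PASS"} if prof.dialect == "standard" else set()
                end = pos + ln if svt == "DEL" else pos
                calls[prof.name].append(
                    SVLocus(prof.name, g.name, pos, end, svt, ln, flags))
        calls[prof.name].sort(key=lambda lo: (lo.chrom, lo.start))
    return calls


# ---------------------------------------------------------------------------
# scenario suite

@dataclass
class Scenario:
    name: str
    ref: GenomeSequence
    qry: GenomeSequence
    truths: list[TruthSV]
    extra_calls: list[SVLocus] = field(default_factory=list)
    expected_scenario: str | None = None  # diagnosis label, where engineered
    #: query built by plant_svs, so truth records reconstruct it exactly;
    #: False for artifact scenarios whose differences are sub-SV edits
    reconstructable: bool = True


def _sub_seq_distinct(rng, n, first_not, last_not):
    """Random sequence whose first/last bases differ from given bases, so
    trimming cannot eat into the planted substitution."""
    s = random_seq(rng, n)
    first = [b for b in "ACGT" if b != first_not][int(rng.integers(3))]
    last = [b for b in "ACGT" if b != last_not][int(rng.integers(3))]
    return first + s[1:-1] + last


def _scn_unique_indels(rng, name):
    ref = make_reference(int(rng.integers(2**31)), 24000, name=name)
    specs = [PlantSpec("del", 6000, 220),
             PlantSpec("ins", 12000, seq=random_seq(rng, 320)),
             PlantSpec("del", 18000, 150)]
    qry, truths = plant_svs(ref, specs)
    return Scenario(name, ref, qry, truths, expected_scenario="simple")


def _scn_substitution(rng, name):
    ref = make_reference(int(rng.integers(2**31)), 20000, name=name)
    # mirror of the worked 3-bp-vs-504-bp case, plus a similar-length SUB
    sub1 = _sub_seq_distinct(rng, 504, ref.seq[8000], ref.seq[8002])
    sub2 = _sub_seq_distinct(rng, 380, ref.seq[14000], ref.seq[14399])
    specs = [PlantSpec("sub", 8000, 3, sub1),
             PlantSpec("sub", 14000, 400, sub2)]
    qry, truths = plant_svs(ref, specs)
    return Scenario(name, ref, qry, truths, expected_scenario="simple")


def _scn_tandem_cat1(rng, name):
    seed = int(rng.integers(2**31))
    copy = random_seq(rng, 300)
    ref = make_reference(seed, 20000, name=name)
    ref = GenomeSequence.from_raw(name, ref.seq[:8000] + copy + ref.seq[8300:])
    # query gains an adjacent second copy: one copy in ref, two in qry
    qry, truths = plant_svs(ref, [PlantSpec("ins", 8000, seq=copy, pattern="cat1")])
    return Scenario(name, ref, qry, truths, expected_scenario="simple")


def _scn_dispersed_cat1(rng, name):
    seed = int(rng.integers(2**31))
    copy = random_seq(rng, 400)
    spacer = random_seq(rng, 200)
    ref = make_reference(seed, 20000, name=name)
    ref = GenomeSequence.from_raw(name, ref.seq[:9000] + copy + ref.seq[9400:])
    # query: copy + unique spacer + copy
    qry, truths = plant_svs(ref, [PlantSpec("ins", 9000, seq=copy + spacer,
                                            pattern="cat1")])
    return Scenario(name, ref, qry, truths, expected_scenario="simple")


def _scn_tandem_cat3_del(rng, name):
    seed = int(rng.integers(2**31))
    unit = random_seq(rng, 100)
    ref = make_reference(seed, 20000, name=name)
    ref = GenomeSequence.from_raw(name, ref.seq[:9000] + unit * 5 + ref.seq[9500:])
    qry, truths = plant_svs(ref, [PlantSpec("del", 9000, 200, pattern="cat3")])
    return Scenario(name, ref, qry, truths, expected_scenario="simple")


def _scn_tandem_cat3_ins(rng, name):
    seed = int(rng.integers(2**31))
    unit = random_seq(rng, 120)
    ref = make_reference(seed, 20000, name=name)
    ref = GenomeSequence.from_raw(name, ref.seq[:9000] + unit * 3 + ref.seq[9360:])
    qry, truths = plant_svs(ref, [PlantSpec("ins", 9000, seq=unit * 2,
                                            pattern="cat3")])
    return Scenario(name, ref, qry, truths, expected_scenario="simple")


def _scn_multiseg_cat2(rng, name):
    seed = int(rng.integers(2**31))
    a, b, c = (random_seq(rng, 150) for _ in range(3))
    comp = a + b + c
    ref = make_reference(seed, 22000, name=name)
    # composite copy at 8000 and a lone middle segment at 10500
    seq = ref.seq[:8000] + comp + ref.seq[8450:10500] + b + ref.seq[10650:]
    ref = GenomeSequence.from_raw(name, seq)
    qry, truths = plant_svs(ref, [PlantSpec("ins", 8000, seq=comp,
                                            pattern="cat2")])
    return Scenario(name, ref, qry, truths, expected_scenario="simple")


def _scn_inversion_clean(rng, name):
    ref = make_reference(int(rng.integers(2**31)), 22000, name=name)
    specs = [PlantSpec("inv", 8000, 2500),
             PlantSpec("del", 14000, 300),
             PlantSpec("ins", 18000, seq=random_seq(rng, 280))]
    qry, truths = plant_svs(ref, specs)
    return Scenario(name, ref, qry, truths, expected_scenario="simple")


def _scn_inversion_gap(rng, name):
    ref = make_reference(int(rng.integers(2**31)), 20000,
                         gap_spec=[(10000, 50)], name=name)
    qry, truths = plant_svs(ref, [PlantSpec("inv", 9000, 2000,
                                            excluded_reason="gap_inversion")])
    return Scenario(name, ref, qry, truths, expected_scenario="simple")


def _scn_copy_number(rng, name):
    """Two diverged reference copies; both query copies sequence-prefer the
    first — no real SV, but callers report one."""
    seed = int(rng.integers(2**31))
    u = random_seq(rng, 500)
    u_far = mutate(rng, u, 0.08)
    ref = make_reference(seed, 21000, name=name)
    seq = ref.seq[:7000] + u + ref.seq[7500:9000] + u_far + ref.seq[9500:]
    ref = GenomeSequence.from_raw(name, seq)
    # query: second copy drifts toward the first (closer to u than u_far is)
    q_second = mutate(rng, u, 0.02)
    qry = GenomeSequence.from_raw(name, seq[:9000] + q_second + seq[9500:])
    extra = [SVLocus("alpha", name, 9000, 9500, "DEL", 500, {"PASS"})]
    return Scenario(name, ref, qry, [], extra,
                    expected_scenario="copy_number_discrepancy",
                    reconstructable=False)


def _scn_copy_misalignment(rng, name):
    """Equal copy counts but the similarity-optimal pairing crosses the
    positional pairing — pure alignment artifact, no real SV."""
    seed = int(rng.integers(2**31))
    u = random_seq(rng, 600)
    r1 = mutate(rng, u, 0.05)
    r2 = mutate(rng, u, 0.05)
    ref = make_reference(seed, 21000, name=name)
    seq = ref.seq[:7000] + r1 + ref.seq[7600:9200] + r2 + ref.seq[9800:]
    ref = GenomeSequence.from_raw(name, seq)
    q1 = mutate(rng, r2, 0.003)   # first query copy resembles second ref copy
    q2 = mutate(rng, r1, 0.003)
    qry = GenomeSequence.from_raw(name, seq[:7000] + q1 + seq[7600:9200] +
                                  q2 + seq[9800:])
    extra = [SVLocus("alpha", name, 7000, 7600, "DEL", 600, {"PASS"})]
    return Scenario(name, ref, qry, [], extra,
                    expected_scenario="copy_misalignment",
                    reconstructable=False)


def _scn_reverse_artifact(rng, name):
    """A block whose diverged reverse-complement copies are scattered
    genome-wide in both genomes; the real event is a deletion next to it."""
    seed = int(rng.integers(2**31))
    f = random_seq(rng, 800)
    ref = make_reference(seed, 26000, name=name)
    seq = bytearray(ref.seq.encode())
    positions = [2000, 5000, 16000, 18500, 21000, 23500]
    for p in positions:
        seq[p:p + 800] = revcomp(mutate(rng, f, 0.10)).encode()
    seq[9500:10300] = f.encode()
    ref = GenomeSequence.from_raw(name, seq.decode())
    qry, truths = plant_svs(ref, [PlantSpec("del", 10900, 300)])
    extra = [SVLocus("alpha", name, 5000, 5800, "DEL", 800, {"PASS"})]
    return Scenario(name, ref, qry, truths, extra,
                    expected_scenario="reverse_artifact")


def _scn_tyfonas(rng, name):
    """A >20 kb container with dense fold-back repeats and three variant
    islands separated by internal unique stretches."""
    seed = int(rng.integers(2**31))
    ref = make_reference(seed, 33000, name=name)
    seq = bytearray(ref.seq.encode())

    def foldback(span):
        frags = [random_seq(rng, int(rng.integers(80, 253))) for _ in range(5)]
        parts, total = [], 0
        while total < span:
            fr = frags[int(rng.integers(len(frags)))]
            fr = mutate(rng, fr, 0.02)
            if rng.random() < 0.5:
                fr = revcomp(fr)
            joint = random_seq(rng, int(rng.integers(20, 50)))
            parts += [fr, joint]
            total += len(fr) + len(joint)
        return "".join(parts)[:span]

    # cluster [6000, 27000): FB - islet - FB - spacer - FB - islet - FB -
    # spacer - FB - islet - FB   (islets are small unique stretches)
    pieces = [("fb", foldback(2500)), ("islet", random_seq(rng, 800)),
              ("fb", foldback(2500)), ("spacer", random_seq(rng, 1600)),
              ("fb", foldback(2500)), ("islet", random_seq(rng, 800)),
              ("fb", foldback(2500)), ("spacer", random_seq(rng, 1600)),
              ("fb", foldback(2500)), ("islet", random_seq(rng, 800)),
              ("fb", foldback(2500))]
    islets = []
    pos = 6000
    for kind, piece in pieces:
        if kind == "islet":
            islets.append(pos)
        pos += len(piece)
    layout = "".join(p for _, p in pieces)
    assert len(layout) == 20600 and len(islets) == 3
    seq[6000:6000 + len(layout)] = layout.encode()
    ref = GenomeSequence.from_raw(name, seq.decode())
    specs = [PlantSpec("del", islets[0] + 250, 300),
             PlantSpec("ins", islets[1] + 250, seq=random_seq(rng, 250)),
             PlantSpec("del", islets[2] + 250, 400)]
    qry, truths = plant_svs(ref, specs)
    # one caller lumps the whole cluster into a single >20 kb inversion
    extra = [SVLocus("alpha", name, 6000, 26600, "INV", 20600, {"PASS"})]
    return Scenario(name, ref, qry, truths, extra)


SCENARIO_BUILDERS = {
    "unique_indels": _scn_unique_indels,
    "substitution": _scn_substitution,
    "tandem_cat1": _scn_tandem_cat1,
    "dispersed_cat1": _scn_dispersed_cat1,
    "tandem_cat3_del": _scn_tandem_cat3_del,
    "tandem_cat3_ins": _scn_tandem_cat3_ins,
    "multiseg_cat2": _scn_multiseg_cat2,
    "inversion_clean": _scn_inversion_clean,
    "inversion_gap": _scn_inversion_gap,
    "copy_number": _scn_copy_number,
    "copy_misalignment": _scn_copy_misalignment,
    "reverse_artifact": _scn_reverse_artifact,
    "tyfonas": _scn_tyfonas,
}


@dataclass
class Suite:
    scenarios: dict[str, Scenario]
    calls: dict[str, list[SVLocus]]

    @property
    def ref_genomes(self) -> list[GenomeSequence]:
        return [s.ref for s in self.scenarios.values()]

    @property
    def qry_genomes(self) -> list[GenomeSequence]:
        return [s.qry for s in self.scenarios.values()]

    @property
    def truths(self) -> list[TruthSV]:
        return [t for s in self.scenarios.values() for t in s.truths]

    @property
    def valid_truths(self) -> list[TruthSV]:
        return [t for t in self.truths if t.excluded_reason is None]


def scenario_suite(seed: int, names: list[str] | None = None,
                   jitter_sd: float = 0.0, spurious_per_mb: float = 0.0,
                   outdir: str | Path | None = None) -> Suite:
    """Build the full scenario suite (or a named subset), deterministic in
    ``seed``; optionally write FASTA pairs, truth VCF, caller VCFs and a
    manifest to ``outdir``."""
    names = names or list(SCENARIO_BUILDERS)
    scenarios: dict[str, Scenario] = {}
    for i, nm in enumerate(names):
        rng = np.random.default_rng([seed % (2**31), i])
        scenarios[nm] = SCENARIO_BUILDERS[nm](rng, nm)
    rng = np.random.default_rng([seed % (2**31), 10_000])
    truths = [t for s in scenarios.values() for t in s.truths]
    genomes = [s.ref for s in scenarios.values()]
    calls = simulate_calls([t for t in truths if t.excluded_reason is None]
                           + [t for t in truths if t.excluded_reason],
                           genomes, rng, jitter_sd=jitter_sd,
                           spurious_per_mb=spurious_per_mb)
    for s in scenarios.values():
        for lo in s.extra_calls:
            calls.setdefault(lo.caller, []).append(lo)
    for k in calls:
        calls[k].sort(key=lambda lo: (lo.chrom, lo.start))
    suite = Suite(scenarios, calls)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(suite.ref_genomes, outdir / "ref.fa")
        write_fasta(suite.qry_genomes, outdir / "qry.fa")
        from .io_formats import write_benchmark_vcf
        write_benchmark_vcf(suite.truths, suite.ref_genomes,
                            outdir / "truth.vcf")
        for caller, loci in calls.items():
            write_caller_vcf(loci, suite.ref_genomes,
                             outdir / f"calls_{caller}.vcf")
        manifest = {
            "seed": seed, "jitter_sd": jitter_sd,
            "spurious_per_mb": spurious_per_mb,
            "scenarios": {nm: {"chrom_len": len(s.ref),
                               "n_truth": len(s.truths)}
                          for nm, s in scenarios.items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return suite
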