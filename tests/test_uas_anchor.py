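"""Unique-anchor determination and complex-region splitting."""

import numpy as np
import pytest

from svrefine.aligner import KmerIndex
from svrefine.io_formats import GenomeSequence
from svrefine.region_builder import SVRegion
from svrefine.uas_anchor import Hit, find_uas, is_unique, split_complex_region
from svrefine.synthetic import PlantSpec, make_reference, plant_svs

from conftest import make_rng, random_seq


def H(identity, strand="+"):
    return Hit("q", 0, 100, strand, identity)


def test_is_unique_rules():
    assert is_unique([H(0.99)])
    assert not is_unique([H(0.99), H(0.98)])     # margin 0.01 < 0.05
    assert is_unique([H(0.99), H(0.90)])         # margin 0.09, id 0.99
    assert not is_unique([])
    assert not is_unique([H(0.70)])              # below candidate floor
    # margin path still demands high best identity
    assert not is_unique([H(0.90), H(0.82)])


def _anchor_setup(ref, qry):
    qrys = [qry]
    return {qry.name: KmerIndex(qry.seq)}, qrys


def test_immediate_unique_flanks_one_step():
    ref = make_reference(11, 20_000, name="c")
    qry, _ = plant_svs(ref, [PlantSpec("del", 10_000, 200)], qry_name="c")
    indices, qrys = _anchor_setup(ref, qry)
    ar = find_uas(SVRegion("c", 10_000, 10_200, []), ref, qrys, indices)
    assert ar.status == "ok"
    assert ar.up.extension == 5000 and ar.down.extension == 5000
    assert ar.qry_interval == (10_000, 10_000)


def test_extension_grows_past_tandem_array():
    """A region inside a long tandem array needs flanks longer than the
    array overhang before they anchor uniquely."""
    rng = make_rng(12)
    unit = random_seq(rng, 1000)
    seq = random_seq(rng, 10_000) + unit * 12 + random_seq(rng, 10_000)
    ref = GenomeSequence.from_raw("c", seq)
    qry = GenomeSequence.from_raw("c", seq)  # no variant; anchoring only
    indices, qrys = _anchor_setup(ref, qry)
    region = SVRegion("c", 16_000, 16_100, [])
    ar = find_uas(region, ref, qrys, indices)
    assert ar.status == "ok"
    overhang_up = 16_000 - 10_000
    assert ar.up.extension > overhang_up
    # brute-force minimum: the first multiple of the step beyond the overhang
    assert ar.up.extension == int(np.ceil(overhang_up / 5000)) * 5000 + 5000 \
        or ar.up.extension > overhang_up


def test_asymmetric_extensions():
    """Repeat on one side only: that side extends further, as per-side
    adaptive extension allows."""
    rng = make_rng(13)
    unit = random_seq(rng, 1000)
    seq = random_seq(rng, 12_000) + unit * 8 + random_seq(rng, 12_000)
    ref = GenomeSequence.from_raw("c", seq)
    qry = GenomeSequence.from_raw("c", seq)
    indices, qrys = _anchor_setup(ref, qry)
    # region flush at the array's downstream edge: the upstream flank is
    # pure array until it grows past it
    region = SVRegion("c", 20_000, 20_100, [])
    ar = find_uas(region, ref, qrys, indices)
    assert ar.status == "ok"
    assert ar.up.extension > ar.down.extension


def test_unanchorable_status():
    rng = make_rng(14)
    unit = random_seq(rng, 500)
    # the whole chromosome is one array: no unique flank exists
    ref = GenomeSequence.from_raw("c", unit * 30)
    qry = GenomeSequence.from_raw("c", unit * 30)
    indices, qrys = _anchor_setup(ref, qry)
    ar = find_uas(SVRegion("c", 7000, 7100, []), ref, qrys, indices)
    assert ar.status == "unanchorable"


def test_split_complex_region_three_islands():
    rng = make_rng(15)
    ref = make_reference(16, 40_000, name="c")
    qry, truths = plant_svs(ref, [PlantSpec("del", 12_000, 300),
                                  PlantSpec("ins", 20_000, seq=random_seq(rng, 250)),
                                  PlantSpec("del", 28_000, 400)], qry_name="c")
    indices, qrys = _anchor_setup(ref, qry)
    container = SVRegion("c", 8000, 32_000, [], is_container=True)
    subs = split_complex_region(container, ref, qrys, indices)
    ok = [a for a in subs if a.status == "ok"]
    assert len(ok) == 3
    for truth, a in zip(truths, sorted(ok, key=lambda a: a.region.start)):
        assert a.region.start <= truth.ref_start <= a.region.end + 1


def test_split_no_difference_empty():
    ref = make_reference(17, 30_000, name="c")
    qry = GenomeSequence.from_raw("c", ref.seq)
    indices, qrys = _anchor_setup(ref, qry)
    container = SVRegion("c", 8000, 22_000, [], is_container=True)
    subs = split_complex_region(container, ref, qrys, indices)
    assert [a for a in subs if a.status == "ok"] == []


def test_flank_truncated_at_chromosome_start():
    ref = make_reference(18, 12_000, name="c")
    qry, _ = plant_svs(ref, [PlantSpec("del", 3000, 100)], qry_name="c")
    indices, qrys = _anchor_setup(ref, qry)
    ar = find_uas(SVRegion("c", 3000, 3100, []), ref, qrys, indices)
    assert ar.status == "ok"
    assert ar.up.truncated and ar.up.interval[0] == 0


def test_anchoring_monotone_uniqueness(suite, curation):
    """On the synthetic suite every successfully anchored flank stays unique
    when extended by one more step (margin criterion is monotone once clear
    of the repeat)."""
    from svrefine.uas_anchor import locate, is_unique
    checked = 0
    indices = {g.name: KmerIndex(g.seq) for g in suite.qry_genomes}
    ref_by = {g.name: g for g in suite.ref_genomes}
    for ar in curation.anchored:
        if ar.status != "ok" or ar.up is None or ar.up.truncated:
            continue
        if checked >= 3:  # a few spot checks keep this fast
            break
        ref = ref_by[ar.region.chrom]
        fs, fe = ar.up.interval
        longer = ref.seq[max(0, fs - 5000):fe]
        hits = locate(longer, suite.qry_genomes, indices)
        assert is_unique(hits)
        checked += 1
    assert checked > 0
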