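# Methods

This note documents the models, algorithms and numerical choices behind
`svrefine`, and what its synthetic validation does and does not show.

## Coordinate conventions

All internal coordinates are 0-based half-open; 1-based inclusive
conventions (VCF POS/END, printed genomic coordinates) are converted only
at the I/O boundary. Insertions are point-anchored (`start == end` at the
post-base position). An assembly gap is a run of ≥ 10 consecutive Ns
(`gap_min_n`, configurable) — the source material motivating the inversion
gap criterion never defines "gap" quantitatively, so the package pins one.

## Alignment substrate

Desk-scale alignment replaces whole-genome aligners for region-sized
problems (flanks, anchored windows, copy pairs):

* **Seeding** — maximal exact matches ≥ k (default k = 15) on both strands,
  from a k-mer hash; N-containing k-mers never seed.
* **Chaining** — colinear dynamic-programming chains with an affine-style
  gap cost (open 4, extend 1 per unbalanced base, 0.05/base for balanced
  gaps); anchors more than 500 bp apart never join, so distinct repeat
  copies stay distinct segments. Anchors may overlap by up to 20 bp
  (coincidental extensions at indel edges). A chain link bridging ≥ 40 bp
  on both sequences is validated by aligning the two gap sequences: below
  0.65 identity the chain is split. Random DNA aligns globally at ≈ 0.55
  identity, diverged homologs well above 0.75, so 0.65 separates "two
  copies joined across unrelated spacer" from "one diverged alignment".
* **Gapped refinement** — each chain span is re-aligned globally with edlib
  (extended CIGAR); *identity is matches over alignment columns, gap
  columns included in the denominator*. Segments shorter than 45 columns
  (the smallest curated region the method must express) or below 0.8
  identity are dropped.
* `copy_similarity` is the end-to-end (global) identity of two copies; a
  wrong-length pairing pays for its excess in gap columns.

External alignments (PAF, e.g. from minimap2) can replace the internal
aligner for real genomes; the segment interface is identical.

## Region building

Caller loci are kept when svlen > 50 (strict) and, for callers that emit
meaningful FILTER flags, PASS/PRECISE-flagged; flag-free (assembly-style)
callers face only the length rule. Merging is single-linkage with
inter-locus gap ≤ 500 bp, pooled across callers (a per-caller-first mode
was considered and rejected: pooling is what the merged-region count
semantics require). "Within a 500 bp range" is read as gap distance, not
midpoint distance. The > 20 kb unmerge applies to locus length, not region
length, since it exists to stop one bloated call from swallowing real
events inside it; such loci become container regions and their contents
still cluster among themselves.

## UAS anchoring

A flank is *uniquely aligned* when its genome-wide hit list has a single
candidate (identity ≥ 0.80) or the best candidate beats the runner-up by
≥ 0.05 identity while itself exceeding 0.95. The margin default is
motivated by the observation that a 0.99-vs-0.90 contrast is decisive in
practice while 0.99-vs-0.98 is not; all three thresholds are flags.
Within a tandem array a flank has many equivalent optimal placements; the
locator asks the infix aligner for *all* optimal locations and counts the
well-separated ones (> 20 bp apart), so array-internal flanks are never
falsely unique. Flanks grow in 5-kb steps to 30 kb, each side stopping
independently (upstream and downstream extensions routinely differ).
Resolution windows include the anchoring flanks themselves: their outer
ends are homologous by construction and the shared sequence is trimmed
away again during resolution, which makes window-edge placement errors
harmless to breakpoint coordinates.

Container splitting scans 1-kb windows (stride 500) for internal UAS;
a window extends a UAS stretch only if it is unique, essentially identical
to its mate (≥ 0.99), and offset-consistent with the previous window
(|Δqry − Δref| ≤ 20 bp) — an identity dip or offset jump marks a variant
and must not be bridged. Stretches ≥ 1 kb partition the container;
partitions with byte-identical sequence in both genomes are discarded.

## Breakpoint resolution

The anchored region pair is diffed by anchored recursion: maximal exact
matches ≥ 25 bp are chained into a skeleton and the anchor-free leaves are
aligned globally (edlib). The skeleton is essential — a plain
minimum-edit-distance path routinely "smears" two nearby indels into one
mismatch region, because unit-cost edits over random sequence undercut the
biological two-indel path. Non-match runs separated by fewer than 10
matching columns merge into blocks; events separated only by an assembly
gap re-join (N matches N even across unrelated contexts); shift-equivalent
same-type indels coalesce whenever one contiguous indel of the combined
length reproduces the query exactly.

Each indel is then left-normalized and its equivalent placements
enumerated by shifting through identical bases; the canonical breakpoint
is the leftmost placement, and `AMBIG` is the count of placements (301 for
removing two units of a perfect five-by-100-bp array). Both-sided blocks
are typed by orientation and similarity:

* reverse identity ≥ 0.9, above forward, sizes within 10 % → inversion
  candidate;
* both orientations < 0.8 → substitution, **provided** the block also
  fails to align once its flanks are attached (context identity < 0.85,
  context width min(100, block/2) per side) — otherwise it is a dense
  local substitution cluster inside alignable sequence, not an
  "unalignable segment", and is not an SV;
* otherwise the block still aligns and is decomposed further; its
  constituent runs face the 50-bp floor individually.

Repeat-copy bookkeeping: self- and cross-alignment segments are clustered
into copies (reciprocal overlap ≥ 0.8; the representative interval is the
longest occurrence, never an unbounded union) and linked into families;
copies ≥ 95 % contained in a copy of a larger *repeat* family are recorded
as sub-segments and collapsed for pairing (containment in the trivial 1:1
orthologous backbone is not redundancy). Orthologous copies pair by
maximum-total-similarity assignment — exhaustive to 6 copies per side
(first-found maximum in lexicographic order implements the
leftmost-to-leftmost tie-break), Hungarian beyond. Greedy pairing is
provably wrong here (a 0.99/0.92/0.93/0.98 similarity square defeats it).
A pairing whose optimal order crosses the positional order by > 0.02 total
similarity implies a rearrangement the linear event model cannot express;
the region is escalated as `complex` and emits nothing, as does any region
whose resolved events fail the splice-reconstruction identity.

Pattern assignment prefers tandem evidence: the variant-side window
(material plus ambiguity span) is tested for periodicity (smallest period
with ≥ 0.9 shifted self-agreement), unit copies are counted on both sides
of the junction, and min-copy counts decide `cat1`/`cat3`; a tandem unit
containing catalogued sub-segments that also occur outside the array marks
a multi-segment (`cat2`) context. Failing tandem evidence, families
overlapping the variant material (on the side that carries material — a
copy merely touching an insertion point is not involvement) are counted
instead. No qualifying family means `unique`.

## Typing

INS/DEL require the present side > 50 bp; SUB requires the *longer* side
> 50 bp, so a 3-bp-vs-504-bp substitution qualifies. Inversions must pass
three criteria: forward-aligned flanking UAS; reciprocal best match in
reverse orientation (no forward alternative of either interval anywhere in
the other window with higher identity); and no assembly gap inside the
interval — checked in *both* genomes, since a gap on either side makes the
reverse alignment untrustworthy. Failed inversion candidates are excluded
rather than re-typed (their residuals do align, in reverse, so they are
not substitutions either). DUP labels are never emitted; duplicated
material is an insertion whose source copy, when identifiable from the
catalog, is recorded in `SOURCE`.

## Evaluation

Matching is one-to-one, maximizing true-positive count, ties broken by
smallest breakpoint distance then leftmost call (solved as a linear
assignment; an exhaustive search over all injections is the test oracle).
Pair eligibility: same type class, breakpoint distance
max(|Δstart|, |Δend|) ≤ refdist, size ratio ≥ pctsize, and reciprocal
overlap ≥ pctovl for span events. Sequence-similarity comparison is
disabled (pctseq 0) throughout. A substitution may match an insertion or
deletion (and vice versa) through the corresponding allele side — the same
locus is legitimately typed either way depending on which genomes are
compared; `sub_flex=False` disables this. Presets: strict (0 / 1.0 / 1.0),
relaxed (50 bp / 0.9 / 0.9), relaxed1k (1000 bp / 0.9 / 0.9), all with
size bounds [1, 3·10⁷] bp. Tie-breaking inside third-party benchmarking
tools is version-dependent; the rule here is pinned and deterministic.

Relative rate is (breakpoint share in class)/(genomic share of class),
with precedence genic > regulatory > intergenic and the regulatory class
defaulting to a 3-kb window upstream of the TSS (no standard width exists;
it is a flag). Span events contribute both edges as breakpoints,
insertions one.

## Synthetic data

The generator is deliberately simple where simplicity aids testability:
background sequence is i.i.d. at a chosen GC (default 0.40, a typical
plant-genome euchromatin value); repeat realism comes from explicit specs
(tandem arrays, dispersed copies, inverted repeats, fold-back clusters of
80-252-bp fragments and their reverse complements), not from composition
models. Truth ambiguity intervals are computed by exhaustive placement
enumeration (every position where re-applying the edit reproduces the
query byte-for-byte) — independent of the resolver's shift-based
normalization, so their agreement is evidence, not tautology. Caller noise
is Gaussian breakpoint jitter (rounded), Poisson spurious calls per Mb,
and profile-driven type confusion (repeat-context insertions reported as
DUP; substitutions reported as INS by one caller and DEL by another).

The default suite is thirteen chromosome pairs of 20-33 kb (~290 kb
total), one per scenario, with 17 scorable planted SVs plus one
deliberately excluded gap-spanning inversion: unique indels and
substitutions (including a 3-bp/504-bp mirror of the worked case), tandem
copy-number changes (cat1/cat3), a multi-segment copy gain (cat2), clean
and gap-spanning inversions, a > 20-kb fold-back container with three
variant islands, and three artifact-only scenarios engineered to satisfy
exactly one boundary-scenario definition each (copy-number discrepancy,
reverse-orientation artifact, copy misalignment). These sizes keep the
full pipeline run under ten seconds while exercising every code path;
they are scaled-down stand-ins, and passing them shows the machinery is
exact on its model, not that real assemblies — with their polymorphism
density, N-gap abundance, and megabase repeat fields — would be resolved
at the same rates.

## Known limitations

* Inter-chromosomal translocations and nested
  inversions-in-duplications escalate as `complex` rather than resolve.
* The internal aligner is desk-scale; real genome pairs should bring
  minimap2/MUMmer alignments via PAF.
* The copy-misalignment diagnosis requires equal copy counts; unequal
  crossing configurations surface as copy-number discrepancy or stay
  undiagnosed.
* Genotypes are not assigned (assembly-to-assembly comparison is
  haploid-like); BND records are parsed but never emitted.
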