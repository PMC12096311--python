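# svrefine

Base-pair-resolution curation and benchmarking of structural variants (SVs)
between two genome assemblies.

## The problem

SV callers agree well in unique sequence and disagree wildly in repeats:
tandem arrays, dispersed segmental copies, inverted repeats and dense
fold-back ("tyfonas"-like) clusters produce boundary shifts, copy-number
artifacts and outright false calls. Curating a trustworthy SV set between a
reference and a query assembly therefore needs more than merging caller
output — it needs breakpoints pinned at single-base resolution, in both
genomes, with the repeat structure around each event made explicit.

`svrefine` automates that curation as a pipeline:

1. **Filter & merge** — caller loci are kept when PASS/PRECISE-flagged (for
   callers with flag discipline) and longer than 50 bp, then single-linkage
   merged into SV regions with a 500-bp gap tolerance; loci above 20 kb are
   held out as *container* regions that frequently span several real events.
2. **Anchor (UAS)** — each region's flanks are extended in 5-kb steps (up to
   30 kb, independently per side) until they align to exactly one confident
   location in the other genome: a *uniquely aligned sequence* (UAS). A
   flank is unique when it has a single candidate hit, or when its best hit
   beats the runner-up by ≥ 0.05 identity while itself exceeding 0.95.
   Containers are split into sub-regions at internal UAS stretches ≥ 1 kb.
3. **Resolve** — the anchored region pair is decomposed into repeat
   segments and copies (self- plus cross-alignment), orthologous copies are
   paired by an optimal assignment over copy similarities, and the
   remaining material is placed as base-pair breakpoints. Every equivalent
   placement inside a repeat is enumerated; the canonical breakpoint is the
   leftmost, and the ambiguity-interval length is reported (`AMBIG`).
   Each call carries one of four repeat-context patterns: `unique`, `cat1`
   (single-segment copy present once in one genome, more than once in the
   other), `cat2` (multi-segment copy, once vs. multiply), `cat3` (multiple
   distinct copies in both genomes, typically tandem arrays).
4. **Classify** — events are typed from their residual material, never from
   caller labels: **INS**/**DEL** (sequence present in only one genome),
   **SUB** (both residuals non-empty and mutually unalignable, < 0.8
   identity in either orientation — a 3-bp-vs-504-bp substitution is a
   legitimate SV), and **INV**, subject to three criteria: forward-aligned
   flanking UAS, reciprocal-best reverse match, and no assembly gap (N run)
   inside the interval in either genome. DUP/CNV labels are re-expressed as
   INS/DEL of identified copies (with a `SOURCE` field).
5. **Evaluate** — call sets are scored against a benchmark under a
   one-to-one matching rule with presets `strict` (refdist 0, size ratio
   1.0, reciprocal overlap 1.0), `relaxed` (50 bp, 0.9, 0.9) and
   `relaxed1k` (1 kb, 0.9, 0.9), reporting precision, recall and
   F1 = 2PR/(P+R). Regional enrichment of breakpoints
   (rate = breakpoint share / genomic share per genic/regulatory/intergenic
   class) and ±50-bp AT-content context summaries are included.

A seeded synthetic-genome module generates reference/query pairs with
planted SVs in configurable repeat landscapes, exact truth records with
exhaustively enumerated ambiguity intervals, and simulated caller output —
the test substrate for the whole toolkit.

## Worked example

```bash
svrefine simulate --seed 7 --out sim --scenarios unique_indels,tandem_cat3_del,substitution
svrefine run --ref sim/ref.fa --qry sim/qry.fa \
    --calls alpha=sim/calls_alpha.vcf --calls beta=sim/calls_beta.vcf:assembly \
    --out-dir out --truth sim/truth.vcf
```

prints the stage report:

```json
{
  "loci_in": 12,
  "loci_filtered": 11,
  "regions": 6,
  "anchored_ok": 6,
  "total": 6,
  "by_type": {"INS": 1, "DEL": 3, "INV": 0, "SUB": 2},
  "by_pattern": {"unique": 5, "cat1": 0, "cat2": 0, "cat3": 1}
}
```

Twelve raw caller loci (two callers) pass the length/flag filter as eleven,
merge into six regions, and resolve into six SVs — one of them a deletion
inside a five-unit tandem array (`cat3`, reported with a 301-placement
ambiguity interval), two of them substitutions. `out/metrics.tsv` compares
the emitted benchmark against the generator's truth:

```
preset     tp  fp  fn  precision  recall  f1
strict      6   0   0     1.0000  1.0000  1.0000
relaxed     6   0   0     1.0000  1.0000  1.0000
```

Every planted SV is recovered at its exact canonical breakpoint, so even
the zero-tolerance preset scores perfectly. The emitted `out/benchmark.vcf`
carries full allele sequences plus `QRY_CHROM/QRY_START/QRY_END`,
`PATTERN`, `AMBIG` and the anchoring UAS intervals per record.

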