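# Methods

This document records the model implemented by `sinescout`, the default
parameters and why they hold, the scope of the synthetic-genome
generator, and the numerical/design decisions a user should know before
trusting or changing the defaults.

## Model and assumptions

A SINE element is modelled as a head–body–tail architecture:

```
[ TSD ] [ 5' head (host-gene derived, carries the pol III promoter) ]
        [ body ] [ 3' tail (oligo-T or simple tandem repeat) ] [ TSD ]
```

- **Coordinates.** All internal coordinates are 0-based half-open.
  GFF3 output converts to 1-based inclusive; BED output stays 0-based.
- **Alphabet.** Sequences are normalised to upper-case `ACGTN`; any
  other IUPAC letter in input becomes `N`. In *alignment*, `N` matches
  nothing (including another `N`): an uncertain base must not
  contribute evidence of homology. In *motif scanning*, a consensus `N`
  matches any sequence base (including `N`), while a sequence `N`
  matches only a consensus `N`: the model's wildcard is permissive, the
  data's uncertainty is not.
- **Classification** is a decision list: (1) 5S head test — candidate
  head (first 100 nt) vs each 5S reference, call SINE3 if any reference
  reaches ≥ 60% identity over ≥ 60 aligned nt; (2) tRNA head test under
  the same thresholds, call SINE2 with the isotype of the winning
  reference (ties across isotypes → "ambiguous"); (3) type-2 promoter
  fallback, call SINE2 on an A+B box pair. The 5S test runs first
  because a 5S-derived head would otherwise collect a spurious tRNA
  isotype. LINE 3′-UTR similarity is reported as evidence only and
  never changes the call.
- **True-gene filtering.** A candidate aligning to a reference gene at
  ≥ 90% identity over ≥ 90% of the *reference* length is that gene, not
  a derived element, and is discarded; likewise candidates whose
  genomic interval overlaps a provided gene annotation by ≥ 50% of
  their own length.

## Parameters and defaults

| parameter | default | rationale |
| --- | --- | --- |
| alignment scoring | match +2, mismatch −1, gap open −5, gap extend −1 | standard DNA local-alignment weights; a gap of length L costs 5 + L |
| head identity / overlap | 60% / 60 nt over head_len 100 | the published homology rule separating 5S-derived from tRNA-derived elements; on the fixture it isolates exactly the five 5S elements |
| TSD length bounds | 4–20 (planted range 4–14) | insertions produce 4–14 bp duplications; the upper bound leaves headroom for unusually long repeats |
| TSD matching | exact, 0 mismatches | degraded TSDs are evidence of age, i.e. deliberate non-matches; `find_near_miss_tsd` reports them separately |
| tail window | last 50 nt | tails terminate elements; a signal must overlap this window but is reported at its full extent (one fixture element's oligo-T tract ends 49 nt from the 3′ end) |
| oligo-T threshold | ≥ 4 T | shortest run treated as a pol III-style tail |
| tandem repeat | unit 1–6 nt, ≥ 3 copies | covers the observed (ACT)ₙ-style tails |
| type-2 spacer bounds | 10–150 nt between A and B box | generous envelope around observed 30–60 nt spacers |
| terminator | `GCTTTTCG`, 0 mismatches | the canonical pol III termination signal; occurs in exactly 1 of the 5 fixture 5S elements |
| copy mapping | k = 12 seeds, ≥ 80% identity, ≥ 0.8 query coverage, merge gap 50 | for 140–500 nt elements at 10% divergence at least one intact 12-mer survives with high probability; thresholds separate true copies (~90% identity) from background |
| boundary extension | 1,000 nt upstream, 2,000 nt downstream | standard re-annotation margins, taken in element orientation |
| discovery tail search | first tail signal within 600 nt of the A box | 600 nt exceeds the longest catalogued element (493 bp); tandem signals must span ≥ 9 nt so a chance 3-nt homopolymer does not truncate a candidate |

Every run logs its full configuration, and `run_pipeline(..., outdir=...)`
writes it to `run_config.yaml`; reruns byte-reproduce all outputs.

## Numerical choices

- **Aligner.** Gotoh's affine-gap local alignment (three int32 matrices,
  numba-compiled fill, Python traceback). Traceback ties prefer
  diagonal, then up, then left; among equal-scoring cells the earliest
  (row-major) end cell wins, making results deterministic. Identity is
  `matches / aligned_columns` *including gap columns* — a gapped
  alignment is penalised in identity, not just score. Overlap is the
  subject-side span. Scores are validated against an exhaustive
  enumeration oracle (all pairs ≤ 4 nt), a sampled oracle (5–8 nt), and
  Biopython's `PairwiseAligner` across *all* two-letter pairs ≤ 8 nt
  (Biopython's `open_gap_score` equals our `gap_open + gap_extend`).
- **Motif scanning.** IUPAC consensi compile to 4-bit masks; mismatch
  counts come from a vectorised sliding-window comparison. Minus-strand
  hits are found on the reverse complement and mirrored back to forward
  coordinates. Windowed models (type-1 boxes) scan forward-only.
- **Tandem repeats.** The reported run maximises total length, then
  prefers the shortest primitive unit, then the lexicographically
  smallest unit, then the leftmost start — so rotations such as
  ACT/CTA/TAC of the same 21-nt run resolve deterministically to ACT.
- **Oligo-T detection is sense-strand only.** Tails are a property of
  the transcribed strand; elements on the genomic minus strand are
  analysed after reverse-complementing (see `extend_boundaries`).
- **Enrichment.** Per-region locus counts are tested against the
  region's length fraction with a one-sided binomial test
  (`scipy.stats.binomtest`, alternative="greater"); the test suite
  checks it against an explicit tail sum.

## Synthetic-genome generator: scope and limits

`simulate_genome(SimConfig)` plants element copies in i.i.d. background
sequence at a chosen GC content. Each insertion is
`background | TSD | element | TSD | background` with the TSD copied
exactly; copies diverge from the family master by per-site substitution
at the configured rate. Element bodies are rejection-sampled so the
planted tail is the *first* tail-like signal downstream of the B box —
otherwise a chance signal would legitimately truncate discovered
candidates and the ground truth would be wrong, not the discoverer.
`simulate_genome` returns `(genome, truth, families)` where `families`
holds the undiverged masters: at 10% per-copy divergence two copies are
~19% apart, so mapping must query with the master, exactly as a curated
consensus library is used on real genomes.

Limits: background is i.i.d. (the simplest null for false-positive
budgeting; no Markov structure, no pre-existing repeats), divergence is
substitution-only (no indels), and TSDs are planted undegraded. These
match the guarantees the pipeline is tested against, not the full
messiness of real genomes.

## Known limitations

- Exact-LCS flanking-TSD recovery is ~96% at divergence 0 over the
  planted 4–14 bp range: a 4-bp TSD is occasionally displaced by a
  chance ≥ 5-nt common substring within the two 30-nt windows. This is
  inherent to the "longest exact common substring" definition, so the
  ≥ 95% guarantee is tested in aggregate (400 planted copies).
- The degenerate default promoter consensi (with mismatch budgets) are
  calibrated for annotating *candidate elements*; genome-wide de-novo
  discovery should use strict models (see `examples/04_discover_de_novo.py`),
  otherwise chance hits dominate.
- No statistical dating of insertions from TSD decay, no transcription
  or copy-number assays, no workflow-manager integration.
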