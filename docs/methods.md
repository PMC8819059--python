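# Methods

## ORF calling conventions

ORFs are maximal start-codon → stop-codon spans: within one reading frame,
a span runs from the earliest start codon after the previous in-frame stop
to the stop codon that terminates it, with the stop codon included in the
reported interval. Coordinates are 1-based inclusive on the forward
transcript; minus-strand calls (six-frame mode) are converted back to
forward coordinates. A complete ORF of *n* amino acids therefore spans
3(*n* + 1) nt.

**Start codons.** Two modes: `atg` ({ATG}) and the default `near_cognate`
(ATG plus its nine single-substitution neighbours CTG, GTG, TTG, ACG, AAG,
AGG, ATA, ATC, ATT — the conventional near-cognate initiation set). The
peptide is the literal standard-genetic-code translation of the span, so a
near-cognate-initiated peptide begins with that codon's amino acid rather
than an initiator methionine; this keeps translation a single well-defined
primitive and is easy to post-process if initiator-Met semantics are
wanted.

**Filters and defaults.** Minimum peptide length 10 aa; spans without an
in-frame stop are dropped by default (`require_stop`), since the interval
convention above presumes a terminal stop; six frames by default with a
three-frame sense-only switch, as transcripts are single-stranded in
nature. Codons containing N translate to `X`; an ambiguous codon is never
interpreted as a stop, so ORFs are delimited only by unambiguous TAA/TAG/TGA.

**Overlap resolution.** When ORFs overlap, the longest is kept. Overlap is
judged on forward-strand nucleotide intervals across all frames and both
strands — the stricter and simpler reading of "overlapping ORFs on one
transcript". Selection is greedy by descending nt length, with a
deterministic tie-break (smaller start, then `+` before `−`, then smaller
frame); kept intervals are pairwise disjoint. Report ids are
`<transcript_id>_ORF-<k>` with *k* numbered by position.

## Evidence mapping

All mapping happens in transcript coordinates (1-based inclusive in
memory; the on-disk track format is BED-like, 0-based half-open, 6 columns).

- **Ribo-seq**: a record counts for an ORF when overlap/record-length
  ≥ 0.90. The fraction is computed on the record side and the comparison is
  inclusive, matching `bedtools intersect -f 0.90`, which is the instrument
  this rule is modelled on; a `strict_gt` switch gives a literal > reading.
- **TIS**: a position counts anywhere inside the ORF (inclusive ends),
  since mapped initiation sites may mark internal starts; an optional
  `start_window` restricts counting to positions near the ORF start.
- **m6A**: the ORF-relative 3′ UTR is (end, transcript_length]. A site
  counts when it falls strictly downstream of the stop codon; positions are
  deduplicated by (transcript, position) because merged m6A resources
  report the same site more than once. A per-transcript mode instead uses
  the region downstream of the most 3′ selected ORF. The per-ORF
  definition is the default because it is the only one that assigns
  evidence to a specific peptide on multi-ORF transcripts.
- **Pfam**: hits with e-value strictly < 10⁻⁴ are retained (the strict
  inequality is deliberate; a hit at exactly 10⁻⁴ is excluded). Hits come
  from a 3-column TSV or from hmmsearch `--tblout` output.
- **CPAT / CPC2**: per-transcript coding probabilities in [0, 1], consumed
  as input tables; conflicting duplicate rows are an error, an absent
  transcript simply lacks that evidence.

Counters are interval-tree backed, order-invariant, and validated against
naive full-scan loops in the test suite.

## Scoring

The composite peptide-encoding score is the sum of six per-evidence
scores. CPAT and CPC2 probabilities pass through unchanged. Each
count-based kind is normalized by the cohort median of its hit counts, and
Ribo-seq is additionally weighted ×5, reflecting that ribosome occupancy
is the most direct translation evidence:

    S(kind)     = Hits(kind) / Median(kind)
    S(Ribo-seq) = 5 × Hits(Ribo-seq) / Median(Ribo-seq)

Zero hits — or an undefined median — score 0.

Two scoring modes are shipped because normalized-quotient and
presence/absence formulations both have currency: `median_normalized`
(default; fully specified, unbounded above) and `binary` (1 if any record
mapped, else 0). There is no silent clamping; an optional `clamp` caps
normalized scores at 1 for users who want a bounded scale.

**Cohort definition.** The median denominator is taken over all scored
peptides of the same species within the current run. The default
`nonzero_only` policy computes the median over peptides with ≥ 1 hit,
which keeps the denominator positive in sparse tracks; `all_peptides` is
available and leaves the score undefined (hence 0) when the overall median
is 0. The composite is additive to 1e-9: removing one kind lowers the
score by exactly that component.

**Evidence-type counting and HCP rules.** A kind supports a peptide when
hits > 0; CPAT/CPC2 support when probability ≥ 0.5 (each tool's
conventional coding call; configurable). Kinds not assayed for a species
never count and contribute 0 to the composite. High-confidence peptides:
human and mouse require Ribo-seq evidence; *A. thaliana*, *C. elegans*,
fruit fly, rat, yeast, zebrafish require ≥ 4 evidence types; every other
species ≥ 3. Rules are overridable per species via configuration. Whether
coding-tool probabilities count as "pieces of evidence" is a genuine
modelling choice; here they do, under the threshold rule, so the maximum
count is 6.

## Synthetic data generator

`lncorf.simulate` emulates, at desk scale, the statistical shape of a
per-species lncRNA/evidence corpus: transcripts of 300–2000 nt carrying
planted ORFs of 10–200 aa, Poisson-distributed true evidence hits per ORF
(defaults: Ribo-seq 3, m6A 2, TIS 1, Pfam 1 — a lightly evidenced corpus
in which most peptides end up with more than two supporting types), one
background (rule-violating) record per kb per track, and uniform coding
probabilities.

Background sequence interleaves ≤ 6-nt random stretches with the 12-mer
`TTAATTAATTAA`, which contains a TAA stop in all three frames and is its
own reverse complement — so every frame on both strands is interrupted at
least every ~28 nt, and no background region can host a complete ORF of
≥ 10 aa (which needs a 33-nt stop-free span). Planted ORF codons are
resampled until no overlapping foreign-frame ORF reaches the planted
length. Planted ORFs are therefore exactly the calls that survive
longest-ORF selection, by construction, and recall is total rather than
statistical.

True evidence records satisfy each mapping rule by margin (Ribo-seq fully
inside the ORF, fraction 1; TIS inside; m6A strictly downstream; Pfam
e-values ≤ 10⁻⁵) and background records violate it by margin (Ribo-seq at
≤ 50% coverage, TIS/m6A outside every admissible region, Pfam e-values
≥ 1.26 × 10⁻⁴), so mapped counts equal the recorded truth exactly and
tests are not threshold-flaky. All randomness flows through NumPy's
PCG64 (`numpy.random.default_rng`) seeded from the configuration; equal
seeds give byte-identical output files.

What the simulator does **not** model: Ribo-seq three-nucleotide
periodicity and P-site structure, m6A DRACH motif context, realistic
length/GC distributions, sequence-dependent coding probabilities, or
isoform structure. Passing the recovery tests therefore demonstrates that
the mapping/scoring machinery implements its rules exactly — not that the
rules themselves would achieve any particular accuracy on real data.

## Numerical and degenerate-input choices

- Composite additivity tolerance 1e-9 (pure sums of a handful of terms).
- Empty evidence tracks, absent coding probabilities, and transcripts too
  short to host an ORF are all valid inputs yielding zero counts, zero
  scores, or empty reports — never errors. Mixed-transcript inputs to
  per-ORF operations, conflicting duplicate probability rows, non-positive
  e-values, and malformed parameters raise validation errors.
- The pipeline is deterministic end to end for fixed inputs and
  configuration; repeated runs produce byte-identical reports.

## Problem sizes

The test suite and the acceptance script run on simulated corpora of
15–120 transcripts and oracle comparisons of 200–1000 random instances;
these sizes give exact (construction-based) checks and tight stochastic
bounds while keeping the whole suite in the order of seconds.

## Known limitations

- Species labels are free-form run metadata; only the listed species (and
  common aliases) resolve to specific HCP rules, all others fall to the
  ≥ 3-types default.
- Genomic ↔ transcript coordinate lift-over is out of scope; all evidence
  must already be in transcript coordinates.
- CPAT, CPC2 and HMMER are consumed as input tables, not re-implemented;
  an hmmsearch `--tblout` reader is provided for users who run HMMER
  themselves.
- The near-cognate start set and the cross-frame overlap rule are
  conventions; both are configurable, and alternative choices change which
  ORFs are reported.
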