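# Methods

## Scope and data model

`annoweave` operates downstream of alignment and prediction: genomes arrive
soft-masked (lowercase = repeat), transcript models arrive as GFF3 or BED12,
hints arrive as an AUGUSTUS-style GFF dialect (`intron|start|stop` features
with `src=E|P;mult=N`), and dosage genotypes arrive as a TSV matrix. All
coordinates are 0-based half-open internally; GFF3 I/O converts to and from
the 1-based inclusive convention. Minus-strand transcripts store exons in
ascending genomic order and derive transcription order where needed, so
there is exactly one canonical storage form per model.

`interval_length` supports both conventions because printed genome
coordinates ("25,901,374–37,085,204 bp") are 1-based inclusive: a single
base prints as (p, p) and has length 1, which a half-open interval cannot
represent; raw endpoint pairs are accepted for that case.

## ORF detection

The longest ORF of a spliced transcript is the longest ATG→stop run in one
of the three forward frames, stop codon included. Only forward frames are
scanned because full-length Iso-Seq reads are orientation-resolved upstream
by primer/polyA classification. ORFs lacking a stop codon inside the
transcript are not reported — a conservative choice that keeps every
reported ORF re-translatable with no internal stop. Codons containing
ambiguity codes qualify neither as start nor stop. Length ties are broken
by the smallest transcript start, making the result deterministic and
invariant to trailing sequence. Projection to the genome maps transcript
coordinates through the exon chain; on the minus strand transcript position
0 corresponds to the highest genomic base.

## Representative isoform selection

"Overlapping isoforms" is defined as same-strand genomic-span overlap of at
least 1 bp, grouped into connected components — locus granularity rather
than exon-level overlap, since the purpose is one representative per locus.
Components are strand-aware; antisense isoforms form separate loci. The
representative is the member with the longest ORF (ties: smaller span
start, then lexicographic id). The lORF ≥ 300 nt and intron ≤ 10,000 nt
filters run **after** selection, deliberately: the winner of a locus can
fail them even when a shorter-ORF member would have passed, leaving the
locus without a representative. A regression test pins this order.

Alignment identity/coverage attributes are read as fractions; values > 1
are auto-detected as percentages. Thresholds are inclusive (0.95/0.90
survive), while the length filters are strict (299 nt fails, 300 survives;
a 10,000 nt intron survives, 10,001 fails).

## Mask refinement

Only the intersection of masked runs with supported ORF intervals is
unmasked — never whole repeat runs. "A masked region overlapping an ORF"
could mean either the overlap itself or the whole repeat run it belongs to;
the intersection is the minimal, conservative reading and is pinned by
tests. Eligibility — independent protein or RNA-Seq support for the ORF —
reuses the support machinery: an isoform qualifies when at least one of its
introns appears in
the RNA-Seq or protein intron-hint set or, for a single-exon ORF, when both
codon hints match. The operation only changes case, is idempotent, and the
report counts distinct changed bases plus loci whose intervals overlapped
at least one initially masked base; locus attribution is judged against the
original mask so the report is independent of iteration order when ORF
intervals overlap.

## Hint algebra

Hint identity is the exact key (seq_id, kind, start, end, strand) with no
fuzz window — both hint producers emit exact splice coordinates. A `HintSet`
holds one record per (key, source); adding a duplicate sums multiplicities,
which is also how intron tallying from spliced models works. Coverage
filters are inclusive and monotone in the threshold. Intersection is
defined on keys with the pairwise-minimum multiplicity as the conservative
combined weight; merging keeps records from both sources distinguishable.

## Seed combination

Seeds are compared on same-strand CDS genomic spans — untranslated overlap
is irrelevant to a coding-region seed. Inputs must each be internally
nonoverlapping (hard error otherwise). When one Iso-Seq seed overlaps
several predictions, the >50 nt rule is applied against the longest-CDS
opponent; if the Iso-Seq seed wins, every prediction it overlaps is
removed. For Iso-Seq entries the seed extent is the ORF (CDS) span, not the
full transcript span — the alternative (transcript span) would let UTR
overlap evict predictions, which contradicts the coding-seed purpose. The
sequential local rule can, in a rare chain configuration (a prediction
overlapping two Iso-Seq seeds with opposite outcomes), drop a region that
no surviving seed covers; the output no-overlap guarantee always holds.

## Support classification

Levels are assigned per evidence class from literal structural rules (see
README for the full set). Two interpretation choices were genuinely open:

* the tolerance for extra introns of a supporting isoform "in its UTRs" is
  evaluated against the *prediction's* CDS genomic span — extra introns
  strictly outside that span are tolerated, since the isoform's own UTRs
  are only definable relative to coding extent;
* single-exon Iso-Seq support requires exact projected-ORF start/end
  equality (the strictest reading; any fuzz window would need an unstated
  tolerance), and partial Iso-Seq support requires ≥ 1 bp of same-strand
  CDS overlap, exposed as `min_overlap` for users who want a higher floor.

Single-exon transcripts are special-cased so the "all introns supported"
rule is never applied vacuously: RNA-Seq evidence consists solely of intron
hints, so a single-exon transcript can only be RNA-Seq "none". Support is
monotone: adding hints never demotes a level. The category tally satisfies
`fully_supported_any + partial_only + unsupported = total` by construction.

## Annotation statistics

Medians use the midpoint-of-two rule; printed percentages and ratios use
half-up decimal rounding (`proportion`, `ratio`), the convention consistent
with how such values are reported. Protein length in amino acids is
CDS_nt/3 − 1 (stop codon excluded). Mean introns per gene takes each gene's
maximum across isoforms; gene length is the span of the isoform union.
Empty input returns an empty-summary sentinel rather than an error.

## Single-dose marker filter

The three rules run in a fixed order — (a) dosage 0/0/0/1 × 0/0/0/0,
(b) missing fraction strictly below 5%, (c) chi-square goodness-of-fit
against 1:1 presence:absence with p ≥ α — and the audit table records the
first failed rule, so rejection counts partition cleanly. The 1:1 test is a
plain chi-square with one degree of freedom, no continuity correction and
no multiplicity adjustment, the common default for segregation screening;
α is exposed as a flag. Relaxing `max_missing` or lowering `alpha` can only
grow the retained set.

## Synthetic fixtures

The generator emulates the pipeline's inputs at desk scale with exact
ground truth. Defaults: 40 genes on a 200 kb sequence, 1–6 exons of
150–400 bp, introns 60–300 bp with canonical GT–AG dinucleotides, CDS
always ≥ 306 nt (so planted ORFs clear the 300 nt filter), ~30% of the
genome soft-masked in 100–600 bp runs, intergenic gaps of 600–1,000 bp
(wide enough that UTR-extended isoforms of neighbouring genes never
overlap). Iso-Seq isoforms are emitted per gene with probability 0.7,
carry 40–120 bp UTRs, an extra UTR intron with probability 0.2, and
identity/coverage drawn from [0.95, 1] × [0.90, 1] so emitted isoforms pass
the alignment filter by construction. RNA-Seq intron hints are emitted per
intron with probability 0.8 and coverage uniform on [3, 150]; protein
intron/start/stop hints with probabilities 0.7/0.6/0.6.

Two constructions keep the analytic truth exact rather than approximate:
5' UTR sequence is drawn from {C, G, T}, so no upstream ATG can extend the
planted ORF, and each assembled transcript is checked (and its random parts
resampled) until its longest ORF is exactly the planted CDS. The
expected-category table is then a Poisson-binomial: per gene,
P(full Iso-Seq) = p_isoseq, P(full RNA-Seq) = p_rnaseq^k for k introns
(0 for single-exon genes), P(full protein) = p_protein_intron^k or
p_start·p_stop for single-exon genes, with independence across classes for
the any-full expectation.

The marker fixture plants simplex × nulliplex markers segregating
Binomial(n = 119 progeny, 0.5) — the progeny count of a typical F1 mapping
population — with a 2% per-call missing rate, 60% simplex fraction and 10%
of simplex markers distorted to present-probability 0.75. Off-type parental
dosages use tetrasomic bivalent gamete probabilities
(P(absent gamete) = C(4−d, 2)/C(4, 2)).

What the fixtures do **not** emulate: alignment error and soft-clipping
(identity/coverage are sampled, not earned), non-canonical splice sites,
nested/overlapping real gene structures, hint noise at wrong coordinates,
paralogy, and double-reduction or preferential pairing in the tetraploid
model. Passing tests therefore demonstrate the correctness of the decision
rules and their calibration under clean evidence, not robustness to
misaligned evidence.

## Numerical and scale choices

A single integer seed drives one NumPy generator threaded through all
sampling; identical (config, seed) yields byte-identical files. Test and
acceptance runs use deliberately small problem sizes — 40–300 genes,
1,000–2,000 markers — chosen so the whole suite exercises every rule,
including the stochastic calibration checks (3-standard-error bands around
the analytic expectations, and the exact discrete type-I rate of the
chi-square filter at n = 119), in seconds. Determinism fixes all reported
numbers; the 3 SE bands quantify what would vary under reseeding.

## Known limitations

* GFF3 support covers the gene/mRNA/exon/CDS subset used by gene
  predictors, not the full feature ontology; GTF is out of scope.
* The classifier trusts hint coordinates; there is no fuzzy splice-site
  matching.
* The marker module consumes pre-called dosage matrices; variant calling
  and linkage-group ordering live upstream and downstream respectively.
* The headline numbers of a real annotation run (tens of thousands of
  genes) depend on the external predictors and raw data and are not
  reproducible from this package alone; the package reproduces the
  decision layer between those tools.
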