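# Methods

## Scope and data model

The package analyses single-end small RNA-Seq of virus-infected cells.  Its
in-memory model is deliberately small: `ReferenceSequence` (a named
uppercase A/C/G/T/N sequence with a species tag and a role: genome,
transcriptome or pre-miRNA), `Placement` (one full-length ungapped
alignment), `AssignmentRecord` (a collapsed read with category, mismatch
tier and all placements), `PileupTrack`/`BinnedTrack` (5′-end counts), and
`Hotspot`.  Coordinates are 1-based and inclusive everywhere, expressed on
the plus strand; a minus-strand feature's 5′ end is its **largest**
plus-strand coordinate (a species spanning 252..271 on the minus strand has
its 5′ nucleotide at 271).  BED/bedGraph exports convert to 0-based
half-open at the file boundary only.  Ambiguous IUPAC codes are collapsed
to N on input and N never matches any base during alignment, so N behaves
as a guaranteed mismatch rather than a wildcard.

## Preprocessing

The 3′ sequencing adapter (default: the TruSeq small RNA adapter,
`TGGAATTCTCGGGTGCCAAGG`) is located at the leftmost read offset where an
adapter *prefix* of at least `min_overlap = 8` nt matches with at most
`max_mm = 1` mismatch; the read is cut at that offset.  These tolerances
are conventional small-RNA defaults and both are configurable.  Trimming
never lengthens a read and is idempotent.  Reads shorter than 16 nt after
trimming are discarded; the minimum-length filter is applied *after*
trimming because a pre-trim length cutoff would measure adapter content,
not insert content.  Surviving reads are collapsed to unique sequences with
multiplicities (lexicographic order for determinism); every downstream
number is re-expanded by multiplicity, so all reported counts are read
counts, not unique-sequence counts.  Conservation holds by construction:
`n_input = n_discarded_short + Σ collapsed counts`.

A vectorised batch trimmer (`trim_reads`) groups reads by length and
resolves each group with one numpy pass per offset; it is property-tested
element-wise identical to the scalar function.

## Placement enumeration

`enumerate_placements` returns **all** full-length ungapped placements of a
read on both strands of every reference with Hamming distance ≤ `max_mm`
(0, 1 or 2), deterministically ordered by (reference order, start, strand
with + before −).  The implementation is seed-and-verify: for a read of
length L at tier m it uses `m + 1` non-overlapping seeds of length
`k = min(12, L // (m + 1))` looked up in lazily built per-reference k-mer
tables.  By pigeonhole at least one seed of every placement within the
mismatch budget is error-free, so the search is exhaustive; a fixed 12-mer
seed would not be (for a 16-nt read at two mismatches, two substitutions
can intersect every 12-nt window).  k-mers containing N are never indexed
and never seed, consistent with N-never-matches.  The index path is tested
bit-exact — same placements, same order — against a naive per-position
Hamming scan, which also serves as the independent oracle in the
acceptance script.

## Hierarchical assignment

For each tier in the schedule (default `(0,)`, optionally `(0,1)` or
`(0,1,2)`): reads with any host placement at that tier are assigned
`human`, sub-flagged `human_mirna` if any placement lies on a pre-miRNA
reference (regardless of coexisting genome placements); only reads still
unassigned are tested against each viral species independently.  Host
priority is absolute — a read matching host and virus is never counted
viral — which keeps viral calls conservative.  A read matching two or more
viral species at the same tier is flagged cross-species ambiguous and
counted once per species in the per-virus summary columns (the partition
check excludes the double count).  Reads surviving all tiers are
`unknown`.  Adding tiers can only move reads out of `unknown`, so the
unknown count is non-increasing in the schedule; this monotonicity is
asserted on noisy simulations.

All placements of one read form its equivalence group.  The canonical
representative is the minimum by (reference order, 5′ position, + before
−); this tie-break is a package convention chosen for determinism, since
ambiguous repeat reads are legitimately displayed at either end.

## Hotspot calling

Pileups count read 5′ ends at single-nucleotide resolution per reference
and strand, under two weightings: `all_placements` (each placement of the
equivalence group contributes the full read count — the display convention
that assigns ITR reads to either end) and `canonical_only` (each read
counted exactly once; used for species totals, which then equal the sum of
record counts exactly).  Binning sums closed intervals [1..w], [w+1..2w], …
and is sum-preserving; 10-nt and 100-nt widths are the typical display
choices.

A position is a hotspot iff its count **strictly** exceeds the threshold —
a count exactly at the threshold is not called, following the reading of
"above this threshold".  The default absolute threshold is 3,000 reads.  In
relative mode the threshold is `relative_factor` (default 100) times a
background estimate defined as the median of the non-zero position counts
of the track; the source analysis states only "approximately 100-fold above
background" without defining background, so the estimator is a package
decision and is configurable.

Hotspots whose supporting read sets share equivalence groups are linked by
union-find into one group (the mirrored ITR calls); linked hotspots carry
identical counts under `all_placements` weighting — the same reads pile at
every member position — and the group's unique read count is reported once
in species totals.  Length statistics (histogram, mean to one decimal,
median, mode with smallest-on-tie) summarise supporting reads, and the
top-N candidate table ranks all 5′ positions by count (ties by position
ascending, + before −) with a representative sequence (the most abundant
supporting read).

## miRNA fold-change analysis

Raw per-miRNA counts for a sample pair are normalised to CPM over the
≥16-nt library size by default — library depths in the emulated design
differ by up to ~1.5×, so raw-count comparison conflates depth with
regulation — with raw mode available to mirror published scatter plots
literally, since whether those axes were depth-corrected is not
determinable.  The fold change is `(norm_b + 0.5) / (norm_a + 0.5)`; the
0.5 pseudocount handles zero counts, on which the source convention is
silent.  Classification bands on `max(fc, 1/fc)`: ≤2 within 2-fold, (2, 5]
between 2- and 5-fold, >5 beyond 5-fold.  miRNAs with raw counts below the
representativeness floor (100 reads) in **both** samples are
`not_representative` regardless of fold change — the exclusion square of
the published scatter bounds both axes — with an `either`-sample rule
available.  Swapping the samples inverts fold changes and up/down labels
but never changes a band.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
real biology:

- **Host reference**: random decoy "genome" sequences (default 4 × 5 kb)
  plus hairpin pre-miRNAs built as arm + loop + reverse-complemented arm
  (21-nt arms, 15-nt loops), with a catalog of mature arms.  Host reads are
  either a catalog arm (`host_mirna`) or a random genome window of 16–28 nt
  (`host_other`).
- **Viral genome**: `make_itr_genome` builds ITR + core + reverse
  complement of the ITR, where the ITR is P + revcomp(P) + D (62-nt
  palindromic arm P, unique D segment, 145 nt total).  The core's first and
  last bases are pinned so the terminal-repeat relation cannot extend into
  the core.  By construction a read equal to the genome prefix of length
  ≤ |P| also places on the minus strand with 5′ end at 2|P| = 124, and
  every left-ITR read has mirrors in the right ITR — the ambiguity the
  equivalence machinery must resolve.
- **Hotspots**: planted 5′ positions with explicit length distributions
  (mode-21 nt; uniform 16–23 nt; 18–19 nt — the three shapes the analysis
  distinguishes) and abundances acting as multinomial weights; a diffuse
  background is drawn uniformly over genome positions (18–24 nt reads).
  The default background weight is 1% of hotspot mass; benchmark scenarios
  set it so the mean per-position depth is ~30 reads, putting the 3,000-read
  threshold at the intended ~100-fold above background.
- **Read synthesis**: substitution-only errors (default 0.2% per base;
  alignment downstream is ungapped, so indels are out of model) applied to
  insert + adapter, then padding with random bases or truncation to a fixed
  51-nt machine read, so adapter trimming is genuinely exercised on every
  read.  FASTQ qualities are constant 'I'.  Every read gets a truth row
  (source, reference, strand, 5′ position, length).  All randomness flows
  from one seeded generator: identical seeds give byte-identical FASTQ.

The eight-sample study design reproduces the per-sample composition
magnitudes of the emulated experiment (fractions of ≥16-nt reads that are
human, human-miRNA, per-virus and unknown; helper co-infection raising
AAV-assigned reads by ~200×).  The published columns do not sum to 100% of
≥16-nt reads; the unexplained remainder is assigned to the host_other
component so that the simulated categories, which must partition, stay
closest to the printed human/viral/unknown columns.  Junk reads (random
sequence, 10–30 nt) supply both the sub-16-nt discard fraction and the
unknown fraction, split by `junk_short_fraction`.

`hotspot_benchmark` additionally re-rolls its genome seed (deterministically
derived from the user seed) until no genomic window on either strand lies
within one mismatch of the 8-nt adapter-trimming seed and the planted
hotspot sequences have no host placement at ≤2 mismatches and are unique on
the viral genome.  These are generator guarantees that make the zero-error
identity exact for any seed: without them a background read overlapping an
adapter-like motif could be over-trimmed below 16 nt, or a planted viral
read captured by the host-first cascade.

**What the generator does not model** — and what passing tests therefore do
not show about real data: ligation and PCR bias, duplicate structure,
quality-score realism, indels, spliced or multi-locus host structure,
RNA secondary structure, and real miRNA sequence families.  Synthetic
decoys are random sequence, so host multi-mapping is far rarer than in a
real genome; conclusions about repeat-driven ambiguity transfer only to the
ITR construction, which is exact.

## Problem sizes and determinism

The test suite and acceptance script run scaled-down simulations chosen to
exercise every code path at comfortable margins: 200,000 reads for
planted-hotspot recovery (abundances ≈12,000/12,700/3,800 over a ~30-read
background), 60,000 reads for the ITR-equivalence scenario, 40,000 noisy
reads (1% error) for conservation/monotonicity, 200 random reads × three
2-kb references × tiers 0–2 for the aligner/oracle comparison, and a
979-miRNA table for the fold-change analysis.  Every stochastic component
is seeded; hypothesis profiles are derandomised.

## Known limitations

- The aligner is designed for virus-scale references (kb–100 kb) and
  collapsed small-RNA read sets; it is not a substitute for a genome-scale
  mapper on a real human genome.
- Hotspot calling is a single absolute/relative threshold with no
  replicate awareness, peak-shape model or FDR control, faithful to the
  method it implements.
- The fold-change module deliberately performs no statistical testing
  (single libraries per condition; no replicates exist in the design).
- Cross-viral double counting is reported but not resolved; the source
  convention for a read matching two viral species is undefined, so both
  per-species columns include it and the flag preserves the information.
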