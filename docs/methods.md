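# Methods

`gapseq` implements the analytics of a snap-back/S1 palindrome-enrichment
sequencing assay (GAPF coupled to sequencing).  Genomic DNA is denatured and
rapidly reannealed; DNA palindromes fold back on themselves into
double-stranded hairpins and survive digestion with the single-strand-specific
S1 nuclease, while ordinary single-copy DNA is destroyed.  Sequencing the
survivors turns palindromes into localized read pileups on the reference.
Everything in this package follows from that one physical fact.

## The caller

**Coordinates.**  Internal coordinates are 0-based half-open (BED-native);
lengths are `end − start`.  Report output is 1-based inclusive, the
convention of published candidate tables.  The conversion lives only in
`GenomicInterval.to_report_coords`.

**Contigs and the base read ratio.**  Uniquely mapped reads are assembled
into contigs — maximal runs of overlapping reads.  Abutting reads (gap
exactly 0 in half-open coordinates) merge, since a zero-gap union is still
one contiguous region.  Each contig is scored with the base read ratio

    B = Σ read lengths in the contig / contig length .

A lone read has B = 1; pileups have B > 1.  B is scale-free, which is what
makes a fixed threshold usable across platforms.

**Joined contigs and the Rank score.**  Contigs with B ≥ 1.5 lying within
7.5 kb of each other (edge-to-edge, single linkage, so joining is
transitive, order-independent and idempotent) are clustered; clusters need
at least two member contigs.  Each surviving cluster spans from its first
member's start to its last member's end and is scored with

    R = Σ lengths of all reads inside the span / (span length − masked length) ,

where "all reads" includes low-B contigs and singletons between the members
(a read counts, at full length, when its midpoint lies inside the span —
the midpoint rule keeps the accounting unambiguous without double
counting), and "masked length" is the repeat-masked portion of the span.
Subtracting the mask matters because reads cannot map to masked sequence:
without the correction, candidates straddling repeats would be penalized.
Candidates are joined contigs with R > 0.75, sorted by R (ties broken by
position for determinism).  All four thresholds are parameters
(`CallerParams`); the defaults are the published operating point.

As a guard, reads overlapping the mask by more than 50% of their length are
dropped before assembly with a logged count; properly uniquely-mapped input
should contain none.

## Density profiles and the palindrome signature

Shearing during DNA isolation (fragments generally below ~50 kb) and the
distance dependence of intrastrand reannealing make palindrome-derived
coverage *decay with distance from the palindrome center*.  Over a candidate
(± 10-kb flanks) read midpoints are counted in 1-kb bins; a genuine
palindrome shows density rising monotonically toward one edge — the edge
nearest the center.

Two quantities are derived from the profile, both of them this package's
own formalization of what the original analysis judged by eye:

* **signature_score** — the fraction of adjacent bin pairs whose counts are
  non-increasing moving away from the maximum bin (1.0 = perfect monotone
  decay on both sides).  Ties count as non-increasing, so low-count flat
  stretches are not punished; profiles with no coherent gradient score low
  because noise breaks monotonicity in both directions.
* **orientation and center.**  Orientation is the half of the window with
  the larger read sum; halves within 20% (relative) are "ambiguous" — the
  tolerance exists because the original call was visual and a noise-driven
  call is worse than no call.  The center estimate is *not* the midpoint of
  the single maximum bin: at realistic per-bin counts (~20 reads at the
  peak) the argmax wanders under Poisson noise across the several
  near-center bins whose means differ by less than one standard deviation.
  Instead we take the run of bins statistically compatible with the maximum
  (count ≥ max − 2·√max) and report its rising-side edge, which is where
  the decay truly terminates.  At the default study conditions this
  localizes planted centers within 2 kb in 19/20 replicates versus 11/20
  for the raw argmax midpoint.  Ambiguous-orientation profiles fall back to
  the max-bin midpoint.

Bins with masked fraction > 0.5 are flagged but never excluded: masked bins
can be over-represented (fast-reannealing repeats) or under-represented
(reads removed by the masker), and either way the neighboring bins carry
the signal.

## The random-placement null

To measure what pure coverage noise produces, the observed read multiset
(count and lengths preserved exactly) is re-placed uniformly over the
genome; placements touching any masked base are rejected and redrawn, so
null reads live entirely in unique sequence like the real input.  The full
caller then runs on the null reads.

The default null genome is a deliberate scale-down chosen to be computable
in seconds while preserving the only quantity the statistics depend on,
the read density per unique bp: one 50-Mb chromosome, 10% masked in 500-bp
islands, 6% coverage of fixed 279-bp reads (the observed mean read length).
At this density ~4% of null reads fall into contigs with B > 1.5, in
agreement with the full-scale figure, and the agreement is
scale-invariant (a property test checks a 10-Mb genome gives the same
fraction).

**A caveat we consider a finding.**  The claim that the top null joined
contigs all stay below R = 0.75 does *not* survive scrutiny.  Two 2-read
pileups (each B ≥ 1.5 requires start offsets ≤ 93 bp at 279-bp reads)
landing within ~800 bp of each other form a legitimate joined contig with
R up to ~2, and at 6% coverage such pairs occur at a rate of roughly one
per few hundred Mb.  Per 50-Mb replicate the maximum null R exceeds 0.75
in about half of seeds.  The practical consequence: a fixed R > 0.75
cutoff has excellent but not perfect specificity, and rare false
candidates are expected at genome scale — they are recognizable as
few-read, short-span loci.  `empirical_threshold` (a chosen quantile of
pooled top-K null ranks) and the `rank_by="reads"` top-loci mode exist for
users who want a data-driven cutoff or abundance-ranked null loci instead.

## The protocol simulator

The generator emulates the enrichment protocol, not the sequencer: no base
qualities, no platform artifacts, no multi-amplicon rearrangement
structures, and no multicopy (mtDNA-like) contamination.  Its purpose is to
produce read sets whose *spatial statistics* match the assay so the caller
and center predictor can be evaluated against a known truth.

* A random-sequence reference (one chromosome) with repeat-mask islands;
  planted palindromes are recorded as (center, arm length, spacer length,
  orientation, optional insertion/deletion).
* Both palindrome arms are sequence-identical, so both map to the *same*
  reference arm interval — enrichment appears as depth, not as a new
  locus.  Arm-derived read midpoints are drawn at truncated-exponential
  distances `d ~ Exp(decay_tau)` from the center.  Only the monotone decay
  is protocol-backed; the exponential form is a modeling choice, and a
  regression test verifies the realized profile returns `decay_tau` within
  ×1.5.
* Background reads (incomplete S1 digestion, fast-annealing non-palindromic
  DNA) are uniform over unmasked sequence.
* Read lengths are Normal(279, 30) truncated to [40, 50 000] bp; every read
  is redrawn until it lies inside the chromosome and entirely off the mask.

Defaults (the emulated study conditions, fixed once): 10-Mb genome, 10%
masked in 500-bp islands, 6% coverage, 90% background, one palindrome with
a 30-kb arm, 500-bp spacer and `decay_tau` = 10 kb.  These put ~20 reads in
the peak 1-kb bin over a background of ~0.2 reads per bin (roughly a
hundred-fold center enrichment), matching the read budget of the assay they
emulate.  Passing recovery tests therefore demonstrate sensitivity to
*clean exponential pileups on a uniform background* — real genomes add
mapping artifacts, segmental duplications and copy-number structure that
the generator deliberately omits.  Consistent with the null-model analysis
above, palindrome-free control genomes at these conditions yield a false
candidate in roughly one of five replicates (measured 0.2/control over 20
seeds); this is a property of the R > 0.75 operating point itself, not of
the generator.

## Junction tools

All junction arithmetic treats the rearranged molecule as
`arm + spacer + reverse_complement(arm)` (`build_palindrome_sequence`; with
an empty spacer the output is its own reverse complement).

* **Inversion PCR.**  Primers are designed from one reference strand — the
  strand pointing toward the center from the arm side.  An arm primer whose
  5′ start lies d bp from the center occurs again, reverse-complemented, at
  the mirrored position, so it amplifies alone: product = 2d + spacer.  Two
  arm primers give d₁ + d₂ + spacer; a spacer primer at offset u from the
  center-proximal spacer end with an arm primer gives (spacer − u) + d.
  Every product necessarily contains the novel junction.  Right-arm loci
  are handled by reflection through the center, which preserves all product
  lengths.  Distances use the primer's 5′ start because that is what the
  string-level oracle (exhaustive search of primer and reverse-complement
  occurrences in the constructed molecule, enumerating convergent pairs)
  yields; the tests pin the arithmetic to that oracle exactly.
* **Snap-back digests.**  The rearranged molecule mirrors the arm side
  about the spacer, so the nearest arm-side restriction site at distance d
  flanks the palindromic fragment on both sides: native = 2d + spacer, and
  the post-snap-back hairpin is d + spacer/2 — the "half-sized band" that
  confirms a palindrome on a blot.  Sites lying only on the spacer-distal
  side do not exist on the rearranged molecule and raise an error.
* **Microhomology** is the longest exact terminal match (case-insensitive,
  N earns no credit) between the two donors' junction-flanking strings;
  observed junctions show 0–7 bp, the fingerprint of end-joining repair.
* **Spacer bookkeeping** is boundary subtraction (end − start on the
  printed boundaries) plus insertion length minus deletion length.
  Published spacer tables are internally inconsistent at the ±1 level
  (one row's printed size equals the boundary difference plus one); the
  subtraction convention is fixed project-wide and documented rather than
  special-cased.

## qPCR and CNV-breakpoint proximity

Fold depletion is `(1+E)^ΔCt` with efficiency E defaulting to 1.0 (perfect
doubling — the conventional 2^ΔCt), exposed because real assays run below
1.  Relative enrichment of a target versus a single-copy reference is the
ratio of their fold depletions, `(1+E)^(ΔCt_ref − ΔCt_target)`.

Candidate-to-CNVB distance is the minimum over both candidate endpoints of
the distance to the nearest breakpoint ("from either side" read as a
minimum, consistent with an inclusive proximity claim), zero when a
breakpoint falls inside the candidate, null when the chromosome has no
breakpoints; the proximity rule counts distances strictly below 5 kb.
Breakpoint extraction from raw copy-number segmentation is out of scope —
the module consumes positions.

## Numerical and degenerate-input conventions

* All randomness flows from a single integer seed through spawned
  generator streams (mask, sequence, reads are independent streams, so
  skipping sequence generation does not perturb read placement).
* Fully masked joined-contig spans (denominator ≤ 0) are dropped with a
  warning during joining and raise in direct `compute_rank` calls.
* A read midpoint exactly on a bin boundary belongs to the right bin
  (half-open bins); candidate ties in R sort by (chrom, start).
* Unknown chromosomes in mask queries count as unmasked with a one-time
  warning; empty read files produce empty outputs, not errors.
* Pipeline outputs are byte-identical across re-runs of identical inputs
  and configuration (no timestamps, fixed float formatting).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely from generated data:
five 50-Mb null replicates (~10 750 reads each) for the null statistics and
twenty 10-Mb simulator replicates (plus twenty palindrome-free controls)
for recovery — sizes chosen so the whole suite completes in well under a
minute while leaving the per-unique-bp read density, which drives every
statistic above, at the full-scale value.

## Known limitations

* The caller is single-sample; the original analysis also contrasted a
  control cell line, which is left to the user (run both, compare tables).
* No paired-end or mapping-quality logic; input reads are trusted to be
  uniquely mapped.
* The exponential decay is a stand-in for an unknown annealing-efficiency
  curve; only monotone decay should be relied upon.
* The fixed R > 0.75 threshold admits rare few-read false positives (see
  the null-model caveat); use `empirical_threshold` for calibrated
  specificity.
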