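# gapseq

Genome-wide detection of DNA palindromes from snap-back/S1 enrichment
sequencing (GAP-Seq), for genome-instability and cancer-genomics analysts.

A DNA palindrome is a sequence immediately followed — after an optional
spacer — by its reverse complement.  Palindromes fold back on themselves
when denatured DNA is rapidly reannealed (snap-back), so after digestion of
everything single-stranded with S1 nuclease, palindromic loci dominate the
surviving DNA.  Sequencing those survivors turns palindromes into read
pileups on the reference genome.  `gapseq` provides the analytics for that
assay:

* **Candidate calling.**  Uniquely mapped reads (BED) are assembled into
  contigs scored by the base read ratio
  *B* = Σ read lengths / contig length (a lone read has *B* = 1).  Contigs
  with *B* ≥ 1.5 within 7.5 kb of each other are clustered into joined
  contigs scored by the Rank
  *R* = Σ read lengths in the span / (span length − masked length),
  and joined contigs with *R* > 0.75 are the palindrome candidates.
* **Center and orientation prediction** from 1-kb binned read-density
  profiles: protocol physics (shearing plus distance-dependent intrastrand
  reannealing) makes coverage decay away from the palindrome center, so a
  true candidate shows a density gradient pointing at its center.
* **Random-placement null model** quantifying what the B/R thresholds pass
  under pure coverage noise.
* **Protocol simulator** that plants palindromes on a synthetic genome and
  emits reads with exponentially decaying center enrichment plus uniform
  background, with ground truth for end-to-end evaluation.
* **Junction utilities**: in-silico inversion-PCR product sizes (primers
  from one strand amplify across the novel junction), snap-back
  restriction-fragment prediction (the diagnostic "half-sized" band),
  junction microhomology, spacer bookkeeping, TaqMan ΔΔCt
  depletion/enrichment arithmetic, and candidate-to-CNV-breakpoint
  distances.

See `docs/methods.md` for the model, parameter meanings and limitations.

## Worked example

Simulate an assay over a 10-Mb genome carrying one palindrome (30-kb arm,
500-bp spacer, center at 5,000,000), then call candidates:

```sh
gapseq simulate --seed 42 --out demo/sim
# 2151 reads over 1 palindrome(s) written to demo/sim
gapseq call --reads demo/sim/reads.bed --mask demo/sim/mask.bed --out demo/run
# 1 candidate(s) written to demo/run
cat demo/run/candidates.tsv
# #chrom  start    end      n_contigs  n_reads  read_bp  masked_bp  R
# sim1    4978009  5000106  13         211      58667    0          2.65486
cat demo/run/centers.tsv
# #chrom  start    end      R        center_estimate  orientation  signature_score
# sim1    4978009  5000106  2.65486  5000009          right        0.690476
```

Read this as: one candidate was called, a 22-kb span holding 211 reads
(58,667 read bp) for a Rank of 2.65 — well above the 0.75 threshold.  Its
density profile rises toward the right edge ("orientation right"), and the
predicted palindrome center, 5,000,009, lands 9 bp from the planted truth.
Coordinates in the tables are 1-based inclusive; the BED outputs are
0-based half-open.

The same stages are importable as a library (`gapseq.call_candidates`,
`gapseq.predict_center`, ...), and `gapseq nullsim`, `gapseq junctions`,
`gapseq qpcr`, `gapseq cnvb` and `gapseq validate` cover the remaining
operations; `--help` on any subcommand lists the options.

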