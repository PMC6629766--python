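# Methods

locuskit re-creates, at desk scale and with complete ground truth, the
analysis of a targeted long-read study of a single disease gene: a
~114 kb minus-strand locus captured both as sheared genomic DNA and as
full-length cDNA across a 12-sample cohort (4 Parkinson's disease, 4
dementia with Lewy bodies, 4 neurologically normal). Every stage that in
a real study would run on multi-gigabyte instrument output runs here on
a simulated locus whose truth is known exactly, so each algorithm can be
held to recovery of that truth rather than to visual inspection.

## The synthetic locus

The reference contig is 114,000 bp of seeded random sequence with the
following planted architecture (all coordinates fixed; the base sequence
varies with the seed):

- a six-exon gene on the minus strand. Exon coordinates are chosen so
  that all coding exons are codon-aligned: exon 2 carries 90 coding
  bases after a 50-base 5' UTR, exons 3/4/5 are fully coding with
  lengths 126/120/84 (all ≡ 0 mod 3), and exon 6 carries the final
  codon plus stop and a 3' UTR. The canonical product is 141 aa.
  Codon alignment means skipping exon 3 or exon 5 removes whole codons:
  the reading frame and the annotated stop are preserved by
  construction, which is the frame property the ORF caller must report.
- two alternative annotated first exons, plus a novel (unannotated)
  first exon and a novel terminal exon inside the large intron 4.
- four annotated transcript 3' ends giving UTR lengths 300, 1000, 1800
  and 2600 bases.
- canonical GT-AG motifs at every planted junction (one GC-AG donor, so
  the "GT-AG or GC-AG" rule is exercised on both motifs), and one
  deliberately noncanonical AT-AG junction reachable only through a
  decoy isoform.
- a (TTG)16 triplet repeat with non-repeat guard flanks, and a 229-bp
  CT-rich low-complexity region whose sequence is catalogue haplotype 1.
  The catalogue holds four haplotypes of lengths 229/217/241/253 with
  pairwise edit distances ≥ 18. The length gaps (≥ 12) are deliberate:
  single-read indel noise (~1 indel per spanning segment) can never
  bridge two alleles through the ±2-base size-binning chain, so size
  alone separates heterozygous clusters and the similarity pass only has
  to split same-length noise. An earlier catalogue draft with a 4-base
  gap and a distance-12 pair sat exactly on the 5% similarity cutoff and
  was redesigned.

## The cohort truth

Sample-level truth mirrors the study conditions: triplet-repeat
genotypes use alleles of 9, 12 and 15 units with three heterozygous
samples; CT-rich assignments use all four catalogue haplotypes with
haplotype 3 confined to disease samples. A population pool of 282
intronic SNPs and 35 intronic indels (1–3 bp) is drawn once per locus
seed with ≥ 15 bp spacing, clear of exons, splice motifs and repeat
regions; each sample is heterozygous for a pool variant with
probability 0.35 and homozygous-alt with 0.10, giving a median het
spacing near 1.1 kb. Four exonic SNPs are planted at positions chosen to
reproduce the isoform-structure dependence of transcript-level variants:
one in exon 1, one in an alternative first exon (mutually exclusive with
exon 1), one ~950 bases into the 3' UTR (covered only by UTRs ≥ 1 kb),
and one in the novel intron-internal terminal exon. Exonic variants are
substitutions only — the cDNA caller is substitutions-only, and this
keeps full-length alignments free of planted indels so splice junctions
are never displaced. Exonic SNP sites are placed outside homopolymer
context (run ≥ 4 within ±2) so the caller's homopolymer gate never
suppresses a planted site.

The planted isoform repertoire has 13 valid isoforms — eight AllExons
combinations of first exon × UTR length (96% of the mix, the most
abundant single isoform at 30%), one exon-3 skip (0.5%), two exon-5
skips (2%), one novel-start (1%) and one novel-end (0.5%) — plus two
decoys: one with ample support but a noncanonical junction, and one
planted at exactly 19 total full-length reads, one below the retention
threshold.

## Read simulation

Reads are emitted pre-aligned. The simulator applies each haplotype's
variants to the reference, samples ~N(6000, 600) gDNA fragments (or full
transcripts for cDNA), and converts the haplotype placement back to a
reference CIGAR, so repeat contractions/expansions appear as I/D
operations and exonic SNPs as mismatches. Sequencing errors are layered
on top: substitutions at 0.006/base and 1-bp indels at 0.005/base
(~98.9% accuracy), with indel errors applied only strictly inside match
segments — mapping endpoints and splice junctions are exact by
construction, which is what makes endpoint deduplication and
junction-chain collapse exactly checkable against truth. Base qualities
are two-regime: correct calls draw QV uniformly from 30–93, errors from
3–20, so a QV ≥ 13 filter removes ~56% of erroneous bases and
essentially no correct ones; the effective post-filter error rate is
~0.0026/base, comfortably below the 0.005 modelled by the SNP caller's
error row (a conservative choice that costs a little power and buys
specificity).

PCR duplicates are extra copies of a fragment with independently
resampled errors. Which copy of a duplicate group is "the original" is
unobservable downstream, so the truth table labels the group
representative with the same deterministic convention the dedup module
uses (highest mean QV, ties to the lexicographically smallest read id);
fragment endpoints are rejection-sampled to be unique per sample and
strand, since two independent co-terminal fragments would be
indistinguishable from duplicates by any endpoint method. Full-length
read ends jitter by up to ±15 bases; isoform mixes are allocated either
deterministically (largest remainder — the default, used where exact
planted counts matter) or multinomially (used where sampling noise is
the point of the check).

What the simulator does not emulate: chimeric reads, barcode errors,
reference mapping bias, capture-efficiency profiles (probe dropout is
reduced to optional zero-coverage intervals), coverage
inhomogeneity beyond fragment-boundary effects, and homopolymer-
concentrated indel errors. Passing tests therefore demonstrate
correctness of the downstream logic under idealised alignments, not
robustness to alignment artefacts — the alignment step itself is out of
scope by design.

## Analysis stages and numerical choices

**Duplicate marking** groups reads by (sample, contig, start, end,
strand) — exact endpoints, no fuzzy window — and keeps the highest
mean-QV member (ties to smallest read id). Marking is idempotent and
only flags, never removes.

**Pileup genotyping** works per sample on QV ≥ 13 bases: at sites with
filtered depth ≥ 10, alt fraction f < 0.2 → 0/0, f ≤ 0.8 → 0/1, else
1/1. Indels are collected from alignment gaps keyed by (anchor, kind,
length) and genotyped by the same fractions against spanning depth. The
0.2/0.8 band is the standard choice for high-accuracy long reads; both
thresholds are configurable and echoed in the run log. The triplet
repeat and CT-rich region (± 30 bp) are masked — fraction-threshold
pileup genotyping is exactly what fails there, and the repeat haplotyper
owns those intervals.

**Phase-consistency filtering** examines het pairs co-observed on ≥ 8
reads; a call is flagged only when every such partner leaves > 20% of
co-covering reads in minority configurations. This automates the
original study's manual review of variants that "did not phase";
isolated hets are left alone (no evidence either way).

**Read-backed phasing** builds a graph over passing het SNPs: edge
orientation is the majority cis/trans configuration, weight
|cis − trans|, tied edges removed, haplotypes propagated over a maximum
spanning tree per component; components with ≥ 2 sites become blocks.
Block span statistics (total, fraction of region, longest) are simple
sums — blocks cannot overlap because components partition sites and
edges never cross a component boundary; tests assert the sum equals a
brute-force interval union anyway.

**Repeat haplotyping** extracts the query subsequence between aligned
anchors from reads fully spanning the region ± 20 bp, bins by length
(±2 bases, chained), single-links within bins at edit distance ≤
⌈5% of mean length⌉ (edlib), discards clusters under 3 reads, and builds
a consensus per cluster by star alignment against the member closest to
the median length with per-column majority vote (ties to the anchor
base; insertions kept when a strict majority carries them). Star
alignment + majority replaces a full multiple alignment; at CCS-level
accuracy (~1% error) and ≥ 5 reads per allele the consensus is exact,
which the tests assert. Repeat alleles are reported as the longest exact
run of the unit; interrupted repeats count their longest run.
Catalogued regions label each allele with the nearest catalogue entry by
edit distance.

**Isoform collapse** groups spliced reads by exact junction chain, then
clusters transcript 5' ends (tolerance 50) and 3' ends (tolerance 100)
within each chain by greedy mode-seeded assignment; cluster modes become
representative ends. The tolerances absorb the simulated ±15-base end
jitter with wide margin while sitting far below the 300-base minimum
separation of planted UTR classes. Filtering drops isoforms with any
non-GT-AG/GC-AG junction motif (computed strand-aware from the
reference), fewer than 20 total FL reads, or a genomic polyA tract
(≥ 12 A in the 20 transcribed-strand bases downstream of the 3' end —
the internal-priming artefact signature). Splice classes use the
five-label scheme with precedence Skip3 > Skip5 > Alt5 > Alt3 >
AllExons; "skipped" requires the transcript span to bridge the annotated
exon, so a novel-start isoform that simply begins downstream of exon 3
is Alt5, not Skip3 — the grouping that matches how such isoforms are
described. Abundance is the percent of each sample's retained FL reads.
Junction validation labels each junction against a short-read support
table at a threshold of 10 reads; an isoform is confirmed iff all its
novel junctions are supported.

**ORF prediction** translates from the annotated start codon when the
transcript contains it, otherwise from the longest ORF (minimum 50
codons). Status: canonical (annotated stop, full length),
frame_maintained_shorter (annotated stop, shorter — whole in-frame exons
removed), truncated (premature or lost stop, or 3' end before the
annotated stop), none.

**Isoform-level SNP calling** pools QV ≥ 13 substitution counts from
reads assigned to retained isoforms. Positions with pooled coverage
≥ 40 are tested (their count is the Bonferroni m); at each, the top
non-reference base is tested one-sided (enrichment) by Fisher's exact
test against an expected-error row [round(0.005·cov), cov −
round(0.005·cov)] (round half-up, so 0.5 expected reads → 1). A SNP is
called iff p ≤ 0.01/m and the site is not within 1 base of a ≥ 4-run of
identical reference bases; suppressed sites still count toward m. The
2×2 table against an expected-error margin is an interpretation (the
contingency design was not fully specified in the original description);
it is isolated in one function so a per-QV expected-error model could be
swapped in. One-sided is deliberate: depletion relative to the error
rate is not a variant. Genotyping is the 5+/5+ full-length-read rule,
a total function over count pairs. SNP–isoform linkage is exonic
containment; SNP pairs with disjoint covering sets are reported as
unlinkable.

## Problem sizes

Defaults are the study conditions: 12 samples, 114 kb locus, 6 kb mean
fragments, 40-fold mean gDNA coverage (per-sample coverages of 16–71×
are supported via the per-sample coverage map), 2,000 FL reads per
sample (the original FL depth per sample is not stated; 2,000 gives
every planted feature comfortable power on a desk machine). The test
suite and the acceptance script scale some analyses to keep runs brisk:
repeat haplotyping and dedup run the full cohort at 25×, deep genotyping
and phasing run single samples or pairs at 40×, and the cDNA analyses
run the full 12 × 2,000 study. The numbered analysis scripts use 25× and
600 FL reads/sample; at that cDNA depth the SNP on the rare novel
terminal exon falls below the 40-read coverage gate, which the script
reports — the coverage dependence is real behaviour, not a defect.

## Known limitations

- No alignment step: all conclusions are conditional on correct
  alignment; soft-clips, supplementary alignments and mapping ambiguity
  in the repeat regions are not modelled.
- The genotyper does no local reassembly; dense variant clusters within
  one read length are genotyped independently per site.
- Phasing is spanning-tree propagation, not MEC-optimal; with tied or
  conflicting edges it follows the maximum spanning tree.
- The repeat haplotyper assumes at most two true alleles per sample and
  flags (rather than resolves) extra clusters.
- Isoform quantification has no uncertainty model; abundances are raw
  FL-read percentages.
- The cDNA SNP caller's error row uses one global error rate; a
  QV-stratified expected-error model would be strictly better at high
  coverage.
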