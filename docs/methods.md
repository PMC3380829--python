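# Methods

`censat` reimplements a reference-free strategy for identifying and
quantifying the repeat families that build functional centromere domains:
instead of aligning ChIP-seq reads to a genome assembly (which does not
exist for large repeat-rich genomes such as pea), both the ChIP and the
input reads are matched against a set of low-coverage (<<1x) genomic
*reference reads*, and enrichment is measured per cluster of mutually
similar reference reads or per individual reference read.

## The enrichment model

For a unit u (a repeat cluster or a single 100 nt reference read) with c
ChIP reads and i input reads mapped to it, out of C and I high-quality
reads in total, the ChIP enrichment is the ratio of proportions

    E(u) = (c / C) / (i / I).

E is scale-free: multiplying all counts and totals by a constant leaves it
unchanged. Units with i = 0 but c > 0 get E = +inf and are always
selected at any finite threshold; no pseudocount is applied by default
because pseudocounts distort the reported enrichment values (a
`pseudocount` mode exists for sensitivity analyses). C and I are post-QC
read counts, not mapped counts, so unmapped reads dilute both proportions
symmetrically.

A consequence worth stating explicitly: if enriched repeats occupy a
fraction p of the genome at sampling weight f, the realized enrichment is
f / (1 - p + p f), not f. Strong ChIP enrichment of centromeric repeats
therefore pushes every other abundant repeat below E = 1, which is why
most repeat clusters appear ChIP-depleted.

## Pipeline stages

1. **QC** (`censat.qc`). Reads are trimmed at both ends to 31 nt
   (default split 3 bp from the 5' end and 2 bp from the 3' end of a
   36 nt read; the exact split is configurable because only the target
   length is determined) and removed if more than one base has Phred
   quality below 20. Reads containing N are kept; N simply never matches
   during mapping.

2. **Approximate matching** (`censat.mapping`). A query matches a
   reference read if the *full* query aligns to a window of the reference
   with at most 2 difference events, where a mismatch is one event and a
   contiguous indel run of L bases is one event, with at most 4 indel
   bases in total. Both strands are searched. Candidates come from exact
   seeds over a k-mer index of the concatenated reference reads: three
   non-overlapping 10-mers, plus two joint seed pairs (a 7-mer anchored at
   one query end co-occurring, within +/-4 diagonals, with a 6-mer from
   the query middle) that cover the corner case of an insertion run
   straddling a 10-mer boundary — with plain 10-mer seeds alone, two
   insertion runs of two bases each placed on the two seed boundaries
   break all three seeds, so pigeonhole completeness fails. Candidates
   are verified by a banded dynamic program over a bitmask lattice of
   (events, indel bases) states, compiled with numba. The test suite
   checks exact agreement with a brute-force DP oracle on >1,000 random
   and adversarial query/reference pairs.

   Each query yields at most one hit per (reference, strand), carrying
   the minimal (events, indel bases) alignment; the reported reference
   offset is exact for substitution-only alignments and accurate to +/-4
   bases when the best alignment contains an indel. Multi-hit counting
   defaults to `count_all` (every reference hit by a query is
   incremented), which is symmetric between ChIP and input and therefore
   leaves ratios unbiased; a `fractional` mode is available.

3. **Clustering** (`censat.clustering`). Reference reads become nodes of
   a similarity graph; an edge requires a local overlap alignment (either
   strand) covering at least 55% of the shorter read at >= 90% identity.
   Repeat families appear as connected components because reads sampled
   from the same repeat tile its consensus transitively. Candidate pairs
   are pre-filtered by shared exact 13-mers and scored on the best
   ungapped diagonal; this is exact for substitution-divergent repeats
   (the regime the generator produces) and is the documented desk-scale
   simplification of a gapped local alignment. Components are sorted by
   genome proportion (members / total analyzed reads) with ties broken by
   the smallest member read id, making cluster ids deterministic.

   ChIP/input reads are assigned to at most one cluster: the cluster of
   their best hit (fewest events, then fewest indel bases); exact ties
   across clusters go to the cluster with the higher genome
   representation, then the lower cluster id.

4. **Enrichment analyses** (`censat.pipeline`). *Approach A* clusters a
   random sample of reference reads (the study used 2 million; the
   sample size is configurable), keeps the top 1000 clusters by genome
   representation, and computes per-cluster enrichment from assigned
   reads — this resolves all abundant families but misses low-copy
   sequences. *Approach B* computes E for every reference read, selects
   reads with E >= 10 (inclusive), and clusters only those, which
   recovers rare enriched families as well.

5. **Profiling** (`censat.profiling`). Each cluster with at least
   `min_cluster_size` (default 5) reads is characterized:

   - a representative contig is assembled by greedy overlap extension
     (overlap >= 30 bp at >= 85% identity, reads reusable, both
     orientations, capped at 4600 bp so monomers up to ~2200 bp can show
     two full periods). Extensions whose leading bases are corroborated
     by a second read are preferred, so the walk does not wander into
     unique flanking sequence carried by array-junction reads; a walk
     that still stalls early is restarted from other seed reads and the
     longest contig wins;
   - the monomer length is the smallest shift at which the contig's
     self-identity reaches 80% — the fundamental period, so a dimer
     array still reports its monomer; divergence lowers the peak
     identity but not its position, because the generator's divergence
     is substitution-only. The overlap floor for a trusted shift is
     25 bases: when gaps in the read-start phase spectrum cut the walk
     short at about one period plus a read length, the junction-spanning
     overlap still identifies the period, and 0.8 identity over 25 bases
     has a ~1e-8 chance rate per shift;
   - head-to-tail organization (the in-silico analog of outward-facing
     primer PCR) requires two adjacent same-orientation consensus copies
     with inter-copy gap <= 10% of the monomer; the probe consensus is
     taken from the contig's *periodic core* (the widest region actually
     repeating at the estimated period), so flank sequence brought in by
     junction reads cannot masquerade as the monomer. In the pipeline's
     satellite gate, a linear contig that repeats at shift m is itself
     accepted as head-to-tail evidence — such a contig necessarily spans
     a copy junction — because the explicit probe needs a second full
     copy that a gap-limited contig of a long monomer may not contain;
   - the family AT content is measured over all cluster member reads
     rather than the contig: a short-monomer contig is a mosaic that
     reuses a handful of reads, so its composition is a small-sample
     estimate, while the member reads contribute two orders of magnitude
     more bases;
   - classification: *satellite* = periodic AND head-to-tail;
     *ltr_retroelement* = >= 80% identity to a provided reference element
     over >= 50% of the contig (winning over a conflicting satellite
     signal, flagged); otherwise *unclassified*. Replacing the original
     visual graph-shape criterion with the periodicity + tandem-junction
     test makes the classification computable and testable.

   All-to-all dot plots (windowed identity, both strands) expose shared
   monomer fragments between families; such families are *not* force-merged
   or force-split — shared-fragment links simply surface as inter-family
   edges and cross-match blocks, mirroring how the TR-11/TR-19 case can
   only be resolved cytogenetically.

6. **Quantification** (`censat.quantify`). Genome proportion p (percent)
   converts to p/100 x G Mbp with G the haploid genome size (pea default
   4300 Mbp); chromosome size is G x relative length / 100; the
   centromeric segment is the DAPI-density fraction times the chromosome
   size. Mbp values are reported rounded half-up to 2 decimals; raw
   values stay in machine output.

## The synthetic data generator

`censat.simulate` builds truth-annotated genomes: satellite families are
head-to-tail arrays of a family consensus with independent per-base
substitutions (no indels), retroelements are dispersed single copies, and
the background is AT-biased random sequence. Consensus sequences realize
their target AT content exactly up to rounding, and substitutions draw
replacement bases from the sequence's own composition — uniform
replacements would systematically erode the AT richness of satellite
copies (by ~0.014 at 3% divergence), whereas real AT-rich repeats keep
their skewed composition; the residual bias of the composition-preserving
model is below 0.003, so measured AT contents are attributable to the
seeded values. Reference reads are uniform; ChIP reads are sampled
with per-start-position weight equal to the covering family's
fold-enrichment (background 1), input reads uniformly; Phred qualities
come from a clipped normal with a separate low-quality (< Q20) rate.
Truth labels use a majority-base-pair rule with ties going to background.

The canonical "pea-like" fixture carries 13 enriched satellite families
whose monomer lengths (50, 120, 164, 245, 510, 642, 659, 867, 867, 881,
1644, 1813, 2094 bp) and AT contents (0.67-0.77) span the observed
spectrum, plus one dispersed 3 kb CRM-like retroelement, all at 50-fold
enrichment with 3% divergence. Problem sizes are desk-scale stand-ins
chosen once so the study conditions are internally consistent:

- genome ~9.5 Mbp (scale-free proportions; Mbp reporting uses a
  configurable genome size);
- total repeat content ~4.3%, so the realized enrichment is
  50 / (0.957 + 0.043 x 50) ~ 16 — comfortably above the 10-fold
  cutoff for nearly every individual reference read (at the study's
  ~2% repeat content the same arithmetic gives E ~ 25);
- copy numbers >= max(30, 3500/monomer) and reference coverage 0.8x, so
  each family's consensus is tiled at >= ~24x by reference reads: the
  family stays one connected cluster after the 10-fold selection thins
  it (a break needs a 45 bp tiling gap, probability e^(-0.45 x 24) per
  read), and >= 65 bp gaps in the read-start phase spectrum — which
  would stall the contig walk — are vanishingly rare;
- 1e5 ChIP and 1e5 input reads of 36 nt.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: sequencing errors and indels in reads
(divergence is substitution-only, so period estimates are exact and
ungapped overlap scoring is sufficient), higher-order repeat structure,
library-preparation and GC biases, paired-end information, and
inter-family homology except where explicitly constructed. At desk-scale
sequencing depth the per-reference Poisson means are of order 1, so
approach B also selects a halo of background reads with zero input
coverage (E = +inf); these form components below the cluster-size floor
or small unclassified clusters and do not contaminate family calls, but
the *fraction* of enriched reference reads is much larger than the 1.73%
seen at the study's 20-million-read depth.

## Numerical and tie-break choices

- Matcher budgets fit in a 15-bit lattice (3 event levels x 5 indel-base
  levels); looser budgets up to 60 bits fall back to exhaustive window
  verification.
- Cluster ordering, top-N selection, read assignment and report sorting
  all have explicit deterministic tie-breaks; identical seed and config
  give byte-identical outputs.
- Degenerate inputs: reads shorter than the trim target are dropped and
  counted; single-read clusters return the read as a flagged
  low-confidence contig; homopolymers report period 1; all-N sequences
  report undefined AT content; an empty reference set yields empty match
  results, not an error.
- Alignment scoring for `pairwise_identity`: match +1, mismatch -1, gap
  open -2, gap extend -0.5, end gaps free; identity = matches /
  alignment columns between the first and last aligned pair.

## Known limitations

- The ungapped-diagonal similarity scoring in clustering and profiling
  under-detects overlaps containing real indels; on indel-rich data the
  edge test would need the gapped aligner used by `pairwise_identity`.
- The monomer estimator assumes the contig spans at least two periods;
  with the 4600 bp contig cap, monomers above ~2250 bp would be reported
  as aperiodic.
- Approach A's random reference sample makes its cluster inventory (and
  thus which families are reported) sample-dependent, exactly as in the
  original design; approach B is the robust route for rare families.
- With `count_all` multi-hit counting, per-read counts of reads hitting
  many references are correlated across those references; enrichment
  ratios are unbiased but their per-read variances are not independent.
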