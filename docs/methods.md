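# Methods

## Scope and data model

All coordinates inside the package are 0-based, half-open, on named
sequences; GFF3 (1-based, closed) is converted at the I/O boundary and
nowhere else. A splice junction is stored as its *intron* interval — first
intronic base to one past the last — so a junction's start coincides with
the end of the upstream exon and its end with the start of the downstream
exon. This representation is strand-independent and unambiguous, unlike
exon-anchor (BED-block) conventions. Junction lists from multiple samples
are clustered by exact intron coordinates; duplicates merge by summing
read support and keeping the maximum confidence score (support is
evidence and accumulates; the score is a per-call confidence for which
the best call is retained).

## Event detection

Detection runs against a gene model, after two filtering steps:

1. **Score filter.** Only junctions with confidence strictly greater than
   0.5 are used. The boundary itself is excluded; a junction scoring
   exactly 0.5 is discarded.
2. **Partition.** Survivors are split by whether both, one, or neither
   splice site coincides exactly with an annotated exon boundary
   (both-known / half-known / both-novel).

**Cassette exons** are annotated internal exons skipped by a both-known
junction joining the boundaries of non-adjacent exons of one transcript.
Novel cassette exons can only arise after the augmentation step has made
them part of the model — a deliberate two-phase design that keeps the
detector a pure function of the (possibly augmented) annotation.

**Intron retention** requires (i) strictly more than 5x depth at *every*
intronic base, and (ii) inclusion ratio at least 3x a genome-wide baseline
(default 0.017, configurable; on synthetic data it can be recomputed from
all annotated introns). The inclusion ratio `2·Cov(p,q)/(Cov(a,p)+Cov(q,d))`
may exceed 1 and is not clamped — the formula permits it whenever the
intron is deeper than its flanks. A 1e-12 tolerance below the threshold
keeps a ratio exactly at the printed boundary (0.051 = 3 x 0.017) inside
the accepted set despite binary floating point.

**Alternative exon boundaries** come from half-known junctions sharing one
site with an annotated intron. The free end must differ from the annotated
boundary by fewer than 200 nt (strictly; a 200-nt displacement is
rejected) and must not cross the far boundary of the affected exon —
otherwise the junction is a novel-exon candidate instead. Whether the
moved side is the donor or the acceptor is decided in transcription
orientation: the 5' intron end is the donor. The splicing ratio is
minor/major junction support; ties count as 1 and break toward the
annotated site as "major". The boundary-region inclusion ratio is the
support of the junction whose shorter intron leaves the disputed region
inside the exon, over the summed support.

**Alternative terminal exons** are distinct first (last) exons of one gene
whose initial (final) introns splice to the same acceptor (donor) site,
which must belong to an exon present in every transcript of the gene —
the "constitutive" restriction. Within a shared-site group, each
lower-support variant is reported against the top-support one.

Missing junctions contribute support 0 rather than excluding an event, so
ratio extremes (0 and 1) that the binned analyses rely on are observable.
Events are deduplicated per gene by kind and coordinates.

## Gene-model augmentation

"Transcribed islands" are maximal runs of coverage at depth >= 5 (the same
floor as the IR criterion), with gaps <= 10 nt merged and a minimum length
of 50 nt, that do not overlap any exon already in the model. The depth /
length / gap values are package choices, exposed as configuration; they
are conservative defaults, not a reconstruction of any published
boundary-refinement procedure.

A half-known junction whose free end lands in an island contributes a
novel exon spanning from the junction end (exact) to the far island edge
(accurate to within the merge gap); it is attached to the anchoring gene
as a new two-exon transcript. A both-novel junction bridging two islands
in intergenic space (no overlap with any annotated gene span) creates a
novel two-exon gene; single islands never become transcripts on their own.
Annotated features are never modified or deleted; all additions carry
provenance `novel` and the GFF3 source tag `beesplice`; augmentation is
idempotent (re-running with the same inputs adds nothing). When a junction
record carries no strand, orientation is inferred from the GT..AG
dinucleotides in the genome.

## Maximum-entropy splice-site model

Windows follow the common scoring convention: donor 3 exonic + 6 intronic
nt, acceptor 20 intronic + 3 exonic nt, read 5'→3' in transcription
orientation (minus-strand windows are reverse-complemented). The model is
the maximum-entropy distribution over the window subject to empirical
marginal constraints from training sites — by default all introns of the
supplied annotation's non-novel transcripts.

With first-order (positional) constraints only, the solution is exactly
the independence/PWM model; the fitting loop reproduces it to machine
precision. Adding adjacent-pairwise constraints makes the constraint graph
a chain, so the distribution factorizes over neighbouring positions;
fitting uses iterative proportional scaling with one factor updated at a
time (simultaneous updates diverge) and exact marginals from a scaled
forward-backward recursion, normalization included — no enumeration of the
4^23 acceptor space is ever needed. Convergence is declared at a maximum
marginal deviation below 1e-4 (in practice the chain fit is exact after
one sweep). Training-set log-likelihood is non-decreasing in constraint
order, as the order-2 family nests order 1.

Strength is `log2 P_model / P_background` with a 0th-order background
(genome base frequencies; uniform if none is supplied). Motifs containing
a base unseen at some training position score `-inf`, which ranks
correctly in the nonparametric comparisons; no pseudocount is applied by
default so that fitted marginals equal empirical ones exactly.

## CpG and methylation metrics

CpG(o/e) is `P_CpG/(P_C·P_G)` with overlapping dinucleotide counting and
denominator `L-1`; base frequencies use `L`. Counting is done on the plus
strand — a CpG is its own reverse complement, so the statistic is
strand-symmetric (property-tested). Regions without C or G are flagged NA
rather than zero.

The relative CpG score of an AEB event is the absolute o/e difference
between the two boundary variants of the affected exon; a zero
displacement gives 0 identically.

BS-seq region status: a region is *methylated* as soon as one covered CpG
cytosine (either strand; symmetric CpG handling) has a non-zero methylated
count, *unmethylated* if it has covered CpGs and none methylated,
*no_data* otherwise. The default coverage requirement is a single read
(configurable); no stricter depth filter is imposed.

## Binned comparisons and testing

Figure-style analyses bin events by inclusion or splicing ratio (default
edges 0, 0.2, 0.4, 0.6, 0.8, 1; values above the top edge — possible for
IR — fall in the last bin) and compare the lowest against the highest
occupied bin with a two-sided Mann-Whitney-Wilcoxon test: exact null
distribution when the combined n is at most 20 with no ties, tie-corrected
normal approximation otherwise; identical constant groups give p = 1. A
comparison with fewer than two occupied bins reports NA instead of
failing. P-values are raw: no multiple-testing correction is applied
anywhere, so families of bin comparisons should be read accordingly. For
IR methylation, retained-intron CpG(o/e) is additionally compared against
all annotated introns with a two-tailed Welch t-test.

## Synthetic data

The generator lays genes left-to-right on one chromosome with
study-realistic geometry: exons average 320 nt, introns 1,390 nt, cassette
exons 178 nt, 4–7 exons per gene, random strands, AT-rich base composition
(33/17/17/33). Every intron boundary gets canonical GT/AG dinucleotides in
transcription orientation. Exonic coverage is uniform at the configured
read depth (default 100x); intronic/intergenic background is block-Poisson
noise with mean 0.017x the exonic depth, mirroring the genome-wide
baseline intron inclusion ratio; the 25-nt noise block is deliberately
smaller than the island length threshold so noise cannot alias into
spurious islands.

Planted events draw a target ratio (default uniform on a configurable
range) and emit binomial junction supports at the locus depth, so
recomputing the ratio from the emitted files recovers the target up to
binomial error (mean absolute error < 0.02 at 1000x in the tests). IR
introns get uniform coverage at `ratio x depth`. AEB displacements are
planted *into* the intron (the exon extension direction): both directions
satisfy the detection window, and this choice stays geometrically feasible
when large displacements (30–120 nt, used by the coupled plantings so that
motif windows and CpG fills do not collide) would exceed the minimum exon
length. Alternative terminal exons are planted as second annotated
transcripts; novel exons and intergenic transcripts are planted as
coverage islands plus junctions only, never as annotation.

Optional couplings create the effects the figure-level analyses look for:
strong/weak motif pools (sharp versus flat PWMs over the fixed GT/AG) at
event sites keyed to the planted ratio, CpG depletion of "methylated"
exons (each CG retained with the configured probability, default 0.25,
with matching BS-seq records), and CG-rich fills in high-inclusion AEB
boundary regions. With couplings off, the same analyses see pure noise —
the null control. A fixed seed yields a byte-identical file set.

What the generator does *not* emulate: read-level sampling (junction
supports are draws, not alignments), sequencing error, expression
variation between genes, overlapping genes, alternative splicing of more
than one kind per gene, and real splice-site sequence diversity. Passing
tests therefore demonstrate correctness of the formulas, detectors and
statistics under the stated generative assumptions — not performance on
real libraries, where junction calling noise and mappability dominate.

## Numerical and interface choices

* Detection thresholds (score 0.5, depth 5, baseline 0.017, window 200)
  are strict/inclusive exactly as documented above; boundary behavior is
  pinned by tests.
* Denominator-zero cases (all-zero supports, zero flank coverage, C- or
  G-free regions) flag NA (`None`) and keep the event rather than raising.
* All file writers sort deterministically (chromosome, coordinate, id);
  reports are byte-identical across runs for a fixed seed and output path.
* The pipeline copies the input model before augmenting, so callers'
  objects are never mutated.
* Events TSVs use genomic-order coordinate columns `a b p q p2 q2 c d`;
  kind labels are IR, CE, ALT_DONOR, ALT_ACCEPTOR, AFE, ALE.

## Known limitations

* CE inclusion uses the immediate flanking exons' junctions; multi-exon
  skipping events are emitted per skipped exon but share the one skip
  junction's support.
* The ortholog join treats "same number of AS events" on pooled kinds (a
  per-kind breakdown is emitted alongside) and consumes a user-supplied
  table; no orthology inference is performed.
* The maximum-entropy model supports constraint orders 1 and 2 (adjacent
  pairs) only; non-adjacent dependencies are out of scope.
* Single-ended transcripts, overlapping genes and trans-splicing are not
  modelled.
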