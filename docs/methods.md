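# Methods

## Problem setting

Given coordinate-sorted alignments from one or two sequencing platforms and an
indexed reference, the caller reports SNVs and small (1–50 bp) indels with
diploid (or, optionally, arbitrary-ploidy) genotypes. Short reads are accurate
but substitution-error-prone and hard to map in repetitive sequence; accurate
long reads carry low-rate but context-dependent indel errors concentrated in
homopolymers. The architecture and the simulator both reflect these profiles.

## Candidate-site detection

Every covered reference position is examined once per read during a single
alignment walk. A read's allele at position *p* is the replacement string for
a reference span anchored at *p*: the aligned base (SNV/reference), the base
plus following inserted bases (insertion, span 1), or the base with the
following deleted reference bases absorbed into the span (deletion, span
1 + d). Reads whose alignment is ambiguous at *p* — a deletion passing through
*p*, or a deletion truncated by the alignment end — contribute depth but no
allele, and are later routed to a discard pool instead of being forced onto a
candidate.

A position is a *hotspot* when some non-reference allele is spelled by at
least `min_count` reads (default 2) comprising at least `min_fraction` of the
overlapping depth (default 0.12). These defaults are deliberately permissive:
at 15–30× coverage a heterozygous variant is expected in roughly half the
reads, and the binomial lower tail at depth 15 still clears a 12% fraction
with high probability, while isolated sequencing errors (one or two reads) do
not. Both thresholds are configurable. In dual-platform mode, hotspot sets are
computed per platform and unioned by site; the merged record retains each
platform's original counts.

Site extraction caps the non-reference candidate list at the 8
highest-support alleles and each support set at 100 reads (uniform
downsampling from a per-site RNG seeded by the configured seed and the site
position, so results are reproducible run to run). Both caps bound the
genotype event space and the encoding workload at pathological coverage and
are far above anything the desk-scale workflows reach.

## Read encoding

Each supporting read becomes a 150-column × C-channel uint8 matrix, C = 6, or
7 when haplotags are present. The analyzed site is forced to column 75;
alignment columns fill outward until the read ends and the remainder is
zero-padded. Insertions occupy their own columns with the reference channel
padded; deletion columns keep the reference base with the read channel
padded, so one column always represents one alignment event unit.

Channel code points are fixed package constants: bases A/C/G/T → 25/75/125/
175 (other/pad 0), base quality min(q,40)·254/40, mapping quality
min(m,60)·254/60, strand 170/85, site flag 255/0, haplotag none/1/2 →
0/120/240. The specific values are free parameters the network learns around;
what matters is that they are monotone where the underlying quantity is
ordered, well separated, and exactly representable in a byte, making the
encoding a pure, lossless function of its inputs.

## Network

All stages are built from weight-normalized 1-D convolutions (kernel 3,
'same' padding), rectified linear activations, and residual skip connections
over pairs of convolutional layers. Weight normalization (w = g·v/‖v‖ per
filter) is used instead of batch normalization because batch composition here
varies wildly — sites differ in read depth and candidate count — making batch
statistics unreliable; with no running statistics anywhere, evaluation is
exactly deterministic.

The default ("full-size") architecture per stage: stage 1 opens with a
C→16-channel convolution followed by 16→48, then 3 residual pairs at width
48; stage 2 is 3 residual pairs; stage 3 is 3 residual pairs, global average
pooling, and a 2-layer classifier (48→48→1) emitting a single logit through a
sigmoid — a two-way allele status is one Bernoulli, so one logit suffices.
The narrow entry layer makes the cost of the optional haplotag channel
exactly 16·3 = 48 parameters, confirmed by the parameter-count consistency
check; the full-size single-platform models hold 131,314 (6-channel) and
131,362 (7-channel) trainable scalars, counting the weight-norm
parameterization as stored (direction + gain). A reduced spec (width 16, one
residual pair per stage) is provided for desk-scale training.

The hybrid model instantiates one stage-1/2 tower per platform, fuses allele
features and site features with two separate two-layer mixing networks
(concatenate along channels, mix back to one platform's width), and shares a
single comparison head. Candidates seen on only one platform receive a zero
feature map from the other platform's tower rather than being dropped —
evidence asymmetry between platforms is itself informative. The fusion
networks do not share parameters.

The compute engine is implemented in numpy with hand-written backward passes
for every layer; gradient correctness is verified against central finite
differences in the test suite at relative error below 1e-4.

## Genotyping

Per-allele probabilities are clamped to [1e-6, 1−1e-6] before logarithms so
no event has −∞ log-likelihood. The event space Ω_p enumerates all status
tuples with 1..p true alleles; the argmax is taken on the unnormalized
log-likelihood (the Ω_p normalizer is constant and provably cannot change the
argmax — asserted numerically), and the normalized posterior feeds the
genotype quality, GQ = −10·log10(1 − posterior(E*)), capped at 99. Ties break
deterministically: fewer true statuses first, then lexicographic candidate
order. Records are left-aligned and parsimony-trimmed against the reference
before VCF emission; a best event consisting of the reference allele alone
produces no record.

## Truth labeling

Truth VCFs may spell an indel differently from the pileup (left- vs
right-aligned representations of the same haplotype), so labels are assigned
by sequence, not by record comparison. Hotspots within 20 bp of each other
are clustered with all truth variants near the cluster span (the 20 bp
default covers typical realignment ambiguity and is configurable). Unphased
truth genotypes expand over all phase assignments (capped at 64 per cluster;
larger clusters are skipped with a warning), producing candidate haplotype
sequence pairs for the cluster window. Each haplotype sequence is then sought
by a prefix-pruned depth-first search over the tree whose branches pick one
candidate (or the implicit reference) per hotspot with fixed reference
segments between; a candidate is labeled true exactly when some truth
haplotype is spelled by a path through it. The search is validated against a
brute-force oracle that applies every option combination to the reference
window and string-compares. Clusters where no path matches any haplotype
(truth/representation gaps) label everything false and are flagged.

## Simulator

The simulator emulates the study conditions end to end: a uniform-random
reference contig (default 100 kb), SNVs at 1e-3/bp and indels at 2e-4/bp with
truncated-geometric lengths over 1–50 bp, a 2:1 het:hom ratio (human-typical),
phased diploid genotypes, non-overlapping placement, and confident regions
equal to the contig minus a 300 bp edge margin. The short-read profile emits
paired 150 bp reads (fragment ≈ 400 bp) with substitution-dominated errors
(default 1e-3, indels 1e-5); the long-read profile emits 5 kb single-end reads
with low substitution error and indel errors whose per-base rate is
multiplied by the homopolymer run length (capped at 8), plus an HP tag naming
the source haplotype.

Reads are emitted pre-aligned from their known simulation coordinates, with
CIGARs built during the haplotype walk, so no external aligner is required
and truth coordinates are exact by construction. This deliberately omits
alignment noise (mapping errors, soft clips, reference bias): passing tests
demonstrate the pipeline's correctness and trainability under known error
processes, not calling accuracy on real alignments. Identical configuration
and seed give byte-identical outputs.

## Training

The loss is per-allele binary cross-entropy on the clamped probabilities —
the natural objective for a Bernoulli allele status. A batch's loss is the
candidate-count-weighted mean of per-site losses, which makes heterogeneous
batches (different read depths and candidate counts per site) well defined;
the equality is asserted in the tests. Optimization uses Adam at LR 1e-3 with
no schedule or warmup (all configurable); one epoch is a full pass over the
shard sites in a seeded shuffled order; the selected checkpoint is the epoch
with the highest held-out per-allele accuracy. Held-out shards never
contribute gradients. Class weighting for the true/false imbalance is
available and defaults to 1.

## Problem sizes and evaluation scale

Desk-scale runs use a 100 kb contig at 30× short-read coverage (≈ 120
planted variants, ≈ 100 training sites), the reduced architecture, and 6
epochs; this trains in well under a minute on one CPU and reaches perfect
held-out SNV genotype concordance on error-free reads and ≥ 0.9 with 0.5%
substitution noise. The end-to-end acceptance run trains on the first 80 kb
and scores only the held-out final 20 kb, so no called site ever contributed
a gradient.

## Known limitations

* Whole-genome accuracy on real data is out of scope at desk scale; no claims
  are made beyond the synthetic error model.
* The caller consumes externally realigned/haplotagged input where available;
  it performs no internal local reassembly or indel realignment.
* Candidate recovery is bounded by the pileup: an allele spelled by no read
  cannot be called, and heavy soft-clipping is not modeled by the simulator.
* Probabilities are not calibrated against empirical allele frequencies; GQ
  derives from the event-space posterior of a trained model.
* gVCF output, joint multi-sample calling, and phased output genotypes are
  not implemented.
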