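# Methods

## The model

leafcall is a single-sample germline SNV and short-indel caller built around
one idea: instead of a hand-tuned error model, use membership in a large
known-variant database (dbSNP-style) as a weak supervision signal and let a
decision tree learned *on the sample itself* separate true variants from
artifacts. Training and calling happen in one pass over the same candidate
set (transductive labelling):

1. **Candidate generation.** A pileup over the aligned reads enumerates, at
   every covered locus, every observed non-reference allele — each
   substitution base, each distinct insertion sequence, each distinct
   deletion length. Candidates supported by fewer than `min_alt_reads`
   reads (default 2) or by less than `min_ratio` of the locus depth
   (default 0.05) are dropped. Indels are left-aligned against the
   reference and reduced to the minimal anchored representation, so that
   database lookup is exact-match on `(chrom, pos, ref, alt)`.
2. **Labelling.** Each candidate gets a 0/1 label: 1 if its normalized key
   is in the known-variant index, else 0. The index is an in-memory hash
   set, so lookup is O(1).
3. **Features.** Twelve per-candidate features summarize depth, base
   quality, mapping quality and strand balance (see the table in
   `leafcall/features.py`). "Effective" reads are those whose observation
   at the locus *is* the candidate allele; several features deliberately
   use all reads at the locus instead (worst mapping quality, poor-mapping
   fraction, mean alignment score, the strand contingency table).
4. **Tree.** A CART regression tree is trained on the labelled feature
   vectors with the squared-error criterion. Regression, not
   classification, because the object consumed downstream is the *mean*
   label of a leaf: candidates that share a leaf share a score, and a
   leaf's mean is an empirical estimate of the fraction of real variants
   among feature-similar candidates.
5. **Calling and genotyping.** A candidate is reported when its leaf mean
   meets the type-specific threshold — 0.8 for SNVs, 0.6 for indels
   (inclusive comparison; leaf means are ratios of small integers, so exact
   equality happens). Genotype is homozygous when the alt-allele effective
   depth strictly exceeds 10x the reference-allele effective depth at the
   locus, else heterozygous. Output is a VCFv4.2 file (QUAL = leaf mean x
   100; the raw leaf mean is kept in INFO/LQ) plus a plain-text tree audit
   file with one line per leaf: candidate count, leaf mean, and the
   root-to-leaf decision path.

The mechanism that lets the caller find variants *not* in the database is
leaf sharing: an unlabelled true variant has feature values like those of
labelled true variants, lands in a leaf dominated by them, and inherits a
high leaf mean.

## Feature notes and numerical choices

* **EBD scale.** Effective base depth uses raw phred integers (mapq x
  baseq summed for SNVs, mapq summed for indels). The tree is invariant to
  monotone transforms of each feature, so the scale is immaterial to the
  partition; no standardization is done.
* **EBD ratio denominator** includes the reference allele's EBD along with
  every alternative allele's. Without it, any locus with a single
  alternative allele would score 1.0 regardless of depth, and the feature
  would lose its power to flag random errors.
* **DeltaL.** Let k be the effective-read count and n the locus depth. The
  "ideal variant" likelihood is the better of the het model (allele
  fraction 1/2) and the hom model (per-read error eps):
  `L1 = max(n ln 1/2, k ln(1-eps) + (n-k) ln eps)`; the null model treats
  every effective read as an error: `L2 = k ln eps + (n-k) ln(1-eps)`.
  DeltaL = L1 - L2. eps is 1e-3 for indels; for SNVs it is derived from
  the mean effective base quality, `10^(-AveBQ/10)`, clamped to
  [1e-4, 0.25] to keep the logs finite and the null model meaningful.
* **Indel base quality** is fixed at 30 per effective read (no per-base
  quality exists for an event), so SumBQ for an indel is 30 x count.
* **3' offsets.** The pile-up site's distance from the read's sequencing
  end, a proxy for cycle-dependent error rate; VarPos is the *population*
  variance of these offsets over effective reads (0 for n <= 1).
* **Strand bias** is the uncorrected Pearson chi-square of the 2x2
  effective-by-strand table, with 0 returned for degenerate tables (any
  zero marginal).
* **Missing AS tags** contribute alignment score 0; mapq-0 reads are kept
  (two features exist precisely to measure poorly mapped reads), while
  duplicate-flagged, secondary, supplementary and unmapped records are
  skipped on input.

## Tree training

Greedy binary recursive splitting; candidate thresholds are midpoints
between consecutive distinct sorted feature values (with a fallback to the
lower value when the midpoint rounds onto the upper float, preserving the
train/predict partition identity); boundary values route left ("value >
threshold" is strict). Ties in impurity are broken by lowest feature index
then smallest threshold, and sorting is stable, so training is fully
deterministic for a fixed input order.

Stopping rules (none is dictated by the method itself, all are config):

* `max_depth` — default 14.
* `min_leaf` / `min_split` — defaults 200 / 400, sized for whole-genome
  candidate counts where leaves hold hundreds to thousands of candidates.
* `min_impurity_decrease` — default 0.01, in scikit-learn's convention
  (the split must lower total SSE by at least this fraction of the
  training-set size). On 0/1 labels, whose variance is at most 0.25, this
  demands each split explain >= 4% of the worst-case label variance. This
  is the regularizer that protects the transductive design: without it the
  tree will spend splits isolating individual label-0 candidates — exactly
  the held-out true variants the leaf-sharing mechanism is supposed to
  rescue. In our simulations the genuine error-separating split gains
  ~0.065 per sample while label-chasing splits gain < 0.003, so the
  threshold sits comfortably between the two regimes.

**Problem-size note.** The test suite and `scripts/acceptance.py` run the
pipeline on ~300-candidate simulated samples and pass `min_leaf=10,
min_split=20`; with the whole-genome defaults such samples cannot be split
at all and the method degenerates to a single leaf. Calling thresholds and
the genotype rule are identical at every scale.

## The synthetic data

`leafcall.simulate` generates a uniform random reference (one contig, GC
0.5), plants non-overlapping SNVs and 1-5 bp indels (het variants on one
random haplotype, hom on both, spaced >= 15 bp apart), and draws
single-end reads uniformly from the two haplotypes. Reads are emitted
pre-aligned at their true coordinates with exact CIGARs — the simulator
plays the aligner, since alignment is outside the caller's scope.
Substitution errors occur at `error_rate` per base; base qualities are
Normal(30, 3) clamped to [2, 41]; strand is Bernoulli(1/2); mapq is
constant 60 (a degradation flag can lower a fraction of reads); the
alignment score is `read_length - 5 x edit_distance`. The known-variant
file contains a seeded fraction of the truth set plus optional decoy
entries at non-variant positions; the withheld remainder is written to a
held-out list for generalization experiments.

Default conditions: 200 kb genome, 200 SNVs + 40 insertions + 40 deletions
at 60% het, 30x coverage of 100 bp reads, 0.1% error rate, complete
database.

What the simulation does **not** emulate — and hence what passing tests do
not show about real data: mis-mapping and reference bias (reads are placed
at their true positions), PCR duplicates and GC/coverage bias, paired-end
structure, quality-by-cycle decay, homopolymer-specific indel error modes,
and a database whose entries are imperfectly normalized. Real-data error
modes that enter through the aligner are invisible here, so the simulated
precision/recall numbers characterize the method's machinery, not its
field performance.

## Degenerate inputs and edge cases

* A locus whose quality-weighted evidence sums to zero (all mapq x baseq
  zero) has an undefined EBD ratio; the candidate is dropped with a
  warning.
* 'N' bases in reads contribute no observation; loci whose reference base
  is 'N' are skipped.
* An alignment cannot begin or end with an insertion; the simulator
  resamples read starts accordingly, and the pileup ignores an I/D at the
  very start of a read (no anchor exists).
* An indel normalized off the contig start is re-anchored on the following
  base with a warning.
* Multiple passing alt alleles at one locus are emitted as separate VCF
  lines; records carry FILTER=PASS only (failed candidates are omitted,
  not flagged).

## Known limitations

Single-sample only; no multi-nucleotide or block substitutions; no local
assembly, so indels in repetitive context inherit the pileup paradigm's
weaknesses; genotyping is the simple 10x depth-ratio rule, not a
population-based model; tree training buffers all candidates in memory
(an optional seeded reservoir subsample caps this at whole-genome scale).
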