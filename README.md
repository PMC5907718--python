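# leafcall

A fast single-sample germline SNV and short-indel caller that replaces the
usual hand-tuned error model with a decision tree learned *on the sample
being called*, using membership in a known-variant database (dbSNP-style)
as the supervision signal.

**Who it is for.** Anyone studying machine-learning approaches to variant
calling, or needing a compact, fully offline, end-to-end testbed for the
pileup → features → tree → calls workflow: the package ships a seeded
simulator that generates the reference, the aligned reads, the truth set
and a partial known-variant database, so every stage runs without
downloads.

## The method

At each covered locus the caller enumerates every observed non-reference
allele from the pileup (each base substitution, each insertion sequence,
each deletion length), dropping candidates below a support filter
(count ≥ 2 and ≥ 5% of depth by default). Each candidate gets

* a **label** q ∈ {0, 1}: whether its normalized `(chrom, pos, ref, alt)`
  key is in the known-variant database, and
* a **12-dimensional feature vector**: effective base depth
  (EBD = Σ mapq·baseq for SNVs, Σ mapq for indels) and its ratio to the
  locus total; a log-likelihood gap ΔL = L₁ − L₂ between the best ideal
  genotype model (allele fraction ½ or 1) and a pure-error binomial model;
  base-quality sums/means and the variance of 3′-end offsets; mapping
  statistics (mean effective mapq, worst locus mapq, fraction with
  mapq < 15, mean alignment score); and two strand-balance statistics —
  the binomial variance np(1−p) of effective-read strands and the Pearson
  χ² of the 2×2 effective-by-strand table,
  χ² = n(ad−bc)² / [(a+b)(c+d)(a+c)(b+d)].

A CART regression tree (squared-error splits) is trained on these labelled
vectors, and every candidate's label is replaced by the **mean label of its
leaf**. Candidates with leaf mean ≥ 0.8 (SNVs) or ≥ 0.6 (indels) are
called; genotype is 1/1 when alt effective depth exceeds 10× the reference
effective depth, else 0/1. Because training and prediction share one
candidate set, a true variant *absent* from the database still lands in a
leaf full of database-confirmed look-alikes and inherits a high score —
that leaf sharing is what makes the approach more than a database filter.

Outputs: a VCFv4.2 file (QUAL = leaf mean × 100, raw leaf mean in
INFO/LQ, FORMAT GT:DP) and a tree audit file with one leaf per line —
candidate count, leaf mean, then the root-to-leaf decision path.

## Worked example

```sh
python examples/02_call_variants.py
```

simulates a 200 kb diploid sample (200 SNVs + 40 ins + 40 del, 60% het,
30× coverage, 0.1% error rate, 10% of variants withheld from the
database), runs the caller, and prints:

```
candidates:       311 (label prevalence 0.810)
tree:             2 leaves, depth 1
calls:            200 SNVs, 79 indels
SNV recall/precision:   1.000 / 1.000
indel recall/precision: 0.988 / 1.000
genotype concordance:   1.000
held-out recall:        0.964 (n=28)
```

Reading this: 311 candidates survived the support filter, of which 81%
were in the database (the rest are sequencing-error artifacts plus the
withheld true variants). One split — on ΔL — separated artifacts from real
variants; all 280 planted variants but one indel were recovered with no
false positives, genotypes all correct, and 27 of the 28 variants
deliberately missing from the database were still called via leaf sharing.

The same pipeline is available from the shell:

```sh
leafcall-sim -o data --seed 7
leafcall -i data/reads.sam -d data/known.vcf -r data/reference/ -o sample \
         --min-leaf 10 --min-split 20
```

which writes `sample.vcf`, `sample.tree` and a `sample.json` run summary.
(`--min-leaf/--min-split` default to 200/400, sized for whole-genome
candidate counts; small simulations need proportionally smaller floors —
see `docs/methods.md`.)

## Layout

```
src/leafcall/      records, io_formats, candidates, features, cart,
                   calling, simulate, evaluate, pipeline, cli
tests/             unit, property and end-to-end suites (pytest)
examples/          narrative scripts, one per capability
docs/methods.md    the model, parameter choices and limitations
```
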