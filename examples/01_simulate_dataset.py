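"""Generate a small synthetic diploid sample and look at what was planted.

Writes a reference FASTA, a coordinate-sorted SAM, a truth VCF, a partial
known-variant VCF and a held-out list, all deterministic for the seed.
"""

from collections import Counter

from leafcall import SimConfig, simulate_dataset

config = SimConfig(
    seed=7,
    genome_length=50_000,
    n_snv=50,
    n_ins=10,
    n_del=10,
    coverage=30.0,
    dbsnp_fraction=0.9,  # 10% of planted variants withheld from the database
    decoy_dbsnp=20,      # database entries that are not real variants
)
res = simulate_dataset(config, "example_data")

types = Counter(v.vtype for v in res["truth"])
gts = Counter(v.genotype for v in res["truth"])
print(f"reads written:        {len(res['reads'])}")
print(f"planted variants:     {dict(types)} ({dict(gts)})")
print(f"held out of database: {len(res['heldout'])}")
print(f"files under example_data/: reference/chr1.fa, reads.sam, truth.vcf, known.vcf, heldout.tsv")
# The held-out variants are real but absent from the known-variant file;
# calling them back is the generalization test of the transductive design.
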