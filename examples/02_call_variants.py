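"""Run the full caller on a simulated sample and score it against the truth.

The pipeline: pileup -> candidate filter -> 12 features -> 0/1 database
labels -> CART tree -> leaf-mean scores -> thresholds -> genotypes -> VCF.
"""

from leafcall import SimConfig, TrainConfig, call_variants, compare_to_truth, heldout_recall, simulate_dataset

res = simulate_dataset(SimConfig(seed=7, dbsnp_fraction=0.9), "example_data_full")

summary = call_variants(
    res["alignments"],
    res["known_vcf"],
    res["reference_dir"],
    "example_data_full/sample",
    # leaf-size floors scaled to a few hundred candidates (whole-genome
    # defaults are 200/400; see docs/methods.md)
    train_config=TrainConfig(min_leaf=10, min_split=20),
)
print(f"candidates:       {summary['candidates']} (label prevalence {summary['label_prevalence']:.3f})")
print(f"tree:             {summary['leaves']} leaves, depth {summary['tree_depth']}")
print(f"calls:            {summary['calls_snv']} SNVs, {summary['calls_indel']} indels")

m = compare_to_truth("example_data_full/sample.vcf", res["truth_vcf"])
print(f"SNV recall/precision:   {m.snv_recall:.3f} / {m.snv_precision:.3f}")
print(f"indel recall/precision: {m.indel_recall:.3f} / {m.indel_precision:.3f}")
print(f"genotype concordance:   {m.genotype_concordance:.3f}")
hr, n = heldout_recall("example_data_full/sample.vcf", res["heldout_tsv"])
print(f"held-out recall:        {hr:.3f} (n={n})")
# held-out recall measures variants called despite being absent from the
# database: the leaf-sharing inference at the heart of the method.
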