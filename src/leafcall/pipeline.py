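"""End-to-end orchestration: alignments -> candidates -> features -> labels
-> tree -> leaf quals -> calls -> VCF + tree audit file.

Two passes over the candidate set (buffered in memory): the transductive
design needs every candidate labelled before the tree can be trained, and
the same candidates are then scored by the tree they trained.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional

import numpy as np

from . import calling, cart, io_formats
from .calling import CallConfig
from .candidates import (
    enumerate_candidates,
    expand_candidate_alleles,
    label_candidate,
    normalize_variant,
    pileup,
)
from .cart import TrainConfig
from .features import compute_feature_vector
from .records import SNV, CandidateVariant

logger = logging.getLogger(__name__)


def collect_candidates(
    alignment_path,
    reference_dir,
    chroms: List[str],
    known_index,
    min_ratio: float = 0.05,
    min_alt_reads: int = 2,
) -> List[CandidateVariant]:
    """Pass 1: pileup every chromosome, enumerate/filter/normalize/label
    candidates and compute their features."""
    candidates: List[CandidateVariant] = []
    for chrom in chroms:
        reference = io_formats.load_reference(reference_dir, chrom)
        reads = io_formats.read_alignments(alignment_path, region=(chrom, None, None))
        for column in pileup(reads, reference, chrom):
            if column.ref_base == "N":
                continue
            for cand in enumerate_candidates(column, min_ratio=min_ratio, min_alt_reads=min_alt_reads):
                try:
                    compute_feature_vector(cand, column)
                    pos, ref, alt = expand_candidate_alleles(cand, reference)
                    key = normalize_variant(chrom, pos, ref, alt, reference)
                except ValueError as exc:
                    logger.warning("dropping candidate at %s:%d: %s", chrom, column.pos, exc)
                    continue
                cand.pos, cand.ref_allele, cand.alt_allele = key[1], key[2], key[3]
                cand.dbsnp_qual = label_candidate(key, known_index)
                candidates.append(cand)
    return candidates


def call_variants(
    alignment_path,
    known_path,
    reference_dir,
    out_prefix,
    call_config: Optional[CallConfig] = None,
    train_config: Optional[TrainConfig] = None,
    min_ratio: float = 0.05,
    min_alt_reads: int = 2,
    chroms: Optional[List[str]] = None,
) -> dict:
    """Run the full caller; write <prefix>.vcf, <prefix>.tree and
    <prefix>.json (run summary); return the summary dict."""
    call_config = call_config or CallConfig()
    train_config = train_config or TrainConfig()
    reference_dir = Path(reference_dir)
    if chroms is None:
        chroms = sorted(p.stem for p in reference_dir.glob("*.fa"))
    if not chroms:
        raise FileNotFoundError(f"no <chrom>.fa files in {reference_dir}")

    known_index = io_formats.build_known_index(
        known_path, reference_provider=lambda c: io_formats.load_reference(reference_dir, c)
    )
    candidates = collect_candidates(
        alignment_path, reference_dir, chroms, known_index, min_ratio, min_alt_reads
    )
    if not candidates:
        raise ValueError("no candidate variants survived filtering; nothing to train on")

    X = np.vstack([c.features for c in candidates])
    y = np.array([c.dbsnp_qual for c in candidates], dtype=np.float64)
    tree = cart.train_tree(X, y, train_config)
    cart.assign_leaf_quals(candidates, tree)

    called = calling.filter_calls(candidates, call_config)
    calling.genotype_candidates(called, call_config)

    chrom_order = {c: i for i, c in enumerate(chroms)}
    called.sort(key=lambda c: (chrom_order[c.chrom], c.pos, c.ref_allele, c.alt_allele))
    contigs = {c: len(io_formats.load_reference(reference_dir, c)) for c in chroms}
    references = {c: io_formats.load_reference(reference_dir, c) for c in chroms}

    out_prefix = str(out_prefix)
    vcf_path = out_prefix + ".vcf"
    tree_path = out_prefix + ".tree"
    io_formats.write_vcf(
        (calling.to_vcf_record(c, references[c.chrom]) for c in called), vcf_path, contigs
    )
    io_formats.write_tree_file(tree, tree_path)

    summary = {
        "candidates": len(candidates),
        "label_prevalence": float(y.mean()),
        "leaves": sum(1 for _ in cart.iter_leaves(tree)),
        "tree_depth": cart.tree_depth(tree),
        "calls_snv": sum(1 for c in called if c.vtype == SNV),
        "calls_indel": sum(1 for c in called if c.vtype != SNV),
        "known_records": known_index.n_records,
        "known_skipped": known_index.n_skipped,
        "vcf": vcf_path,
        "tree": tree_path,
    }
    Path(out_prefix + ".json").write_text(json.dumps(summary, indent=2) + "\n")
    logger.info(
        "candidates=%d prevalence=%.3f leaves=%d calls: %d SNV / %d indel",
        summary["candidates"],
        summary["label_prevalence"],
        summary["leaves"],
        summary["calls_snv"],
        summary["calls_indel"],
    )
    return summary
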