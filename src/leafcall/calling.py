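"""Final calling: threshold leaf quals by variant type, genotype, build VCF records."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

from .records import SNV, CandidateVariant, VcfRecord

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class CallConfig:
    """Type-specific leaf-qual thresholds and the homozygosity depth ratio.

    A candidate is reported when its leaf qual meets its type's threshold
    (inclusive: leaf means are ratios of small integers, so exact equality
    with the threshold is common).  Genotype is homozygous when the alt
    effective depth strictly exceeds ``hom_ratio`` times the ref effective
    depth.
    """

    snp_threshold: float = 0.8
    indel_threshold: float = 0.6
    hom_ratio: float = 10.0


def filter_calls(candidates: List[CandidateVariant], config: CallConfig = None) -> List[CandidateVariant]:
    config = config or CallConfig()
    out = []
    for c in candidates:
        thr = config.snp_threshold if c.vtype == SNV else config.indel_threshold
        if c.leaf_qual >= thr:
            out.append(c)
    return out


def genotype_call(alt_ebd: float, ref_ebd: float, config: CallConfig = None) -> str:
    """"hom" iff alt effective depth > hom_ratio x ref effective depth, else "het"."""
    config = config or CallConfig()
    return "hom" if alt_ebd > config.hom_ratio * ref_ebd else "het"


def to_vcf_record(cand: CandidateVariant, reference: str) -> VcfRecord:
    """VCF record for a passed, genotyped candidate.

    The candidate's (pos, ref, alt) are already in normalized anchored form.
    At the pos = 1 contig edge an indel that lost its left anchor is
    re-anchored on the following base (with a warning).
    """
    pos, ref, alt = cand.pos, cand.ref_allele, cand.alt_allele
    if cand.vtype != SNV and pos < 1:
        logger.warning("indel at contig start; using following-base anchoring")
        pos = 1
        nxt = reference[len(ref) - 1] if len(ref) > 1 else reference[0]
        ref, alt = ref[1:] + nxt if len(ref) > 1 else nxt, alt[1:] + nxt if len(alt) > 1 else nxt
    return VcfRecord(
        chrom=cand.chrom,
        pos=pos,
        id=".",
        ref=ref,
        alt=alt,
        qual=round(cand.leaf_qual * 100.0, 2),
        filter="PASS",
        info={"LQ": cand.leaf_qual},
        genotype="0/1" if cand.genotype == "het" else "1/1",
        depth=cand.depth,
    )


def genotype_candidates(candidates: List[CandidateVariant], config: CallConfig = None) -> None:
    config = config or CallConfig()
    for c in candidates:
        c.genotype = genotype_call(c.alt_ebd, c.ref_ebd, config)
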