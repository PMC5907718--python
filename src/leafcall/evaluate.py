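"""Call-set evaluation against a simulated truth set.

Matching is by exact normalized (chrom, pos, ref, alt) key, the same
canonical form the caller and the simulator both emit, so no re-alignment
is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Tuple

from .io_formats import read_vcf_records
from .records import SNV


def _vtype(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return SNV
    return "INS" if len(alt) > len(ref) else "DEL"


def vcf_key_genotypes(path) -> Dict[tuple, str]:
    """Map (chrom, pos, ref, alt) -> genotype string ('0/1'/'1/1') from a VCF."""
    return {(r.chrom, r.pos, r.ref, r.alt): r.genotype for r in read_vcf_records(path)}


@dataclass
class CallSetMetrics:
    snv_recall: float
    snv_precision: float
    indel_recall: float
    indel_precision: float
    genotype_concordance: float
    n_truth_snv: int
    n_truth_indel: int
    n_called_snv: int
    n_called_indel: int


def compare_to_truth(called_vcf, truth_vcf) -> CallSetMetrics:
    called = vcf_key_genotypes(called_vcf)
    truth = vcf_key_genotypes(truth_vcf)

    def _counts(vt):
        t = {k for k in truth if _vtype(k[2], k[3]) == vt}
        c = {k for k in called if _vtype(k[2], k[3]) == vt}
        tp = t & c
        recall = len(tp) / len(t) if t else float("nan")
        precision = len(tp) / len(c) if c else float("nan")
        return t, c, tp, recall, precision

    t_s, c_s, tp_s, rec_s, prec_s = _counts(SNV)
    t_i = {k for k in truth if _vtype(k[2], k[3]) != SNV}
    c_i = {k for k in called if _vtype(k[2], k[3]) != SNV}
    tp_i = t_i & c_i
    rec_i = len(tp_i) / len(t_i) if t_i else float("nan")
    prec_i = len(tp_i) / len(c_i) if c_i else float("nan")

    tps = tp_s | tp_i
    concord = (
        sum(1 for k in tps if called[k] == truth[k]) / len(tps) if tps else float("nan")
    )
    return CallSetMetrics(
        snv_recall=rec_s,
        snv_precision=prec_s,
        indel_recall=rec_i,
        indel_precision=prec_i,
        genotype_concordance=concord,
        n_truth_snv=len(t_s),
        n_truth_indel=len(t_i),
        n_called_snv=len(c_s),
        n_called_indel=len(c_i),
    )


def heldout_recall(called_vcf, heldout_tsv) -> Tuple[float, int]:
    """Fraction of held-out (non-database) planted variants that were called."""
    called = vcf_key_genotypes(called_vcf)
    keys = []
    with open(heldout_tsv) as fh:
        next(fh)  # header
        for line in fh:
            chrom, pos, ref, alt, _gt = line.rstrip("\n").split("\t")
            keys.append((chrom, int(pos), ref, alt))
    if not keys:
        return float("nan"), 0
    hit = sum(1 for k in keys if k in called)
    return hit / len(keys), len(keys)
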