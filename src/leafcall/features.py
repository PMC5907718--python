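"""The 12 per-candidate features fed to the decision tree.

A read is "effective" for a candidate when its observation at the locus is
exactly the candidate allele (same base for an SNV, same inserted sequence or
deletion length for an indel).  Reads showing any other allele — including
the reference and other alternatives — are non-effective but still count in
the locus-wide denominators (WorMQ, PoorMQR, AveAS, the strand table).

Feature summary (fixed order, see :data:`leafcall.records.FEATURE_NAMES`):

==========  ==============================================================
Depth       effective base depth (EBD): sum over effective reads of
            mapq x baseq for SNVs, mapq alone for indels
Ratio       candidate EBD / sum of EBDs of every allele at the locus
            (reference included)
DeltaL      log-likelihood gap between the best "ideal variant" model
            (allele fraction 1/2 or 1) and a pure-error binomial model
SumBQ       sum of effective base qualities (fixed 30 per indel read)
AveBQ       SumBQ / effective-read count
VarPos      population variance of effective reads' 3' offsets
AveMQ       mean mapping quality of effective reads
WorMQ       minimum mapping quality over all reads at the locus
PoorMQR     fraction of all reads with mapping quality < 15
AveAS       mean alignment score over all reads (0 substituted when absent)
VarStr      np(1-p) with n = effective reads, p = forward-strand fraction
BiasStr     Pearson chi-square of the 2x2 effective-vs-strand table
==========  ==============================================================
"""

from __future__ import annotations

import math
from typing import List, Sequence

import numpy as np

from .records import (
    INDEL_BASE_QUAL,
    SNV,
    CandidateVariant,
    PileupColumn,
    ReadObservation,
    allele_vtype,
)

POOR_MAPQ_CUTOFF = 15
INDEL_EPS = 1e-3
SNV_EPS_MIN = 1e-4
SNV_EPS_MAX = 0.25


def compute_ebd(effective: Sequence[ReadObservation], vtype: str) -> float:
    """Effective base depth: sum(mapq * baseq) for SNVs, sum(mapq) for indels."""
    if vtype == SNV:
        return float(sum(o.mapq * o.base_qual for o in effective))
    return float(sum(o.mapq for o in effective))


def compute_ebd_ratio(cand_ebd: float, all_allele_ebds: Sequence[float]) -> float:
    total = float(sum(all_allele_ebds))
    if total <= 0:
        raise ValueError("locus has no quality-weighted evidence (all EBDs zero)")
    return cand_ebd / total


def compute_deltal(k_effective: int, n_cover: int, eps: float) -> float:
    """Log-likelihood gap between the best ideal-variant model and the error model.

    Under the variant hypothesis the allele fraction is 1/2 (het) or ~1 (hom,
    with per-read error ``eps``); the better of the two gives L1.  Under the
    null every effective read is an error: L2 = k*ln(eps) + (n-k)*ln(1-eps).
    Values near or below zero mark likely false positives.
    """
    if n_cover == 0:
        return 0.0
    k, n = k_effective, n_cover
    l_het = n * math.log(0.5)
    l_hom = k * math.log1p(-eps) + (n - k) * math.log(eps)
    l1 = max(l_het, l_hom)
    l2 = k * math.log(eps) + (n - k) * math.log1p(-eps)
    return l1 - l2


def compute_sumbq_avebq(effective: Sequence[ReadObservation], vtype: str):
    n = len(effective)
    if n == 0:
        return 0.0, 0.0
    if vtype == SNV:
        sumbq = float(sum(o.base_qual for o in effective))
    else:
        sumbq = float(INDEL_BASE_QUAL * n)
    return sumbq, sumbq / n


def compute_varpos(effective: Sequence[ReadObservation]) -> float:
    """Population variance of the effective reads' 3' offsets (0 if n <= 1)."""
    n = len(effective)
    if n <= 1:
        return 0.0
    offs = [o.offset3 for o in effective]
    mean = sum(offs) / n
    return sum((x - mean) ** 2 for x in offs) / n


def compute_mapping_features(effective: Sequence[ReadObservation], all_obs: Sequence[ReadObservation]):
    """(AveMQ over effective, WorMQ over all, PoorMQR over all, AveAS over all)."""
    n_all = len(all_obs)
    ave_mq = sum(o.mapq for o in effective) / len(effective) if effective else 0.0
    wor_mq = min(o.mapq for o in all_obs)
    poor = sum(1 for o in all_obs if o.mapq < POOR_MAPQ_CUTOFF) / n_all
    ave_as = sum(o.align_score for o in all_obs) / n_all
    return float(ave_mq), int(wor_mq), float(poor), float(ave_as)


def compute_varstr(effective: Sequence[ReadObservation]) -> float:
    """Binomial strand variance np(1-p); 0 when all effective reads share a strand."""
    n = len(effective)
    if n == 0:
        return 0.0
    p = sum(1 for o in effective if not o.is_reverse) / n
    return n * p * (1.0 - p)


def compute_biasstr(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square of the 2x2 table [[a, b], [c, d]].

    a/b: effective reads on the forward/reverse strand; c/d: non-effective.
    Returns 0 when any marginal is zero (degenerate table).
    """
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def _allele_ebds(column: PileupColumn) -> dict:
    groups: dict = {}
    for obs in column.observations:
        groups.setdefault(obs.allele, []).append(obs)
    return {allele: compute_ebd(obs, allele_vtype(allele)) for allele, obs in groups.items()}, groups


def compute_feature_vector(cand: CandidateVariant, column: PileupColumn) -> np.ndarray:
    """Populate all 12 features for one candidate at its pileup column.

    Deterministic and invariant to the order of observations.  Also fills the
    candidate's ``depth``, ``alt_ebd`` and ``ref_ebd`` bookkeeping fields
    (the latter two on a shared scale for the genotyper).
    """
    all_obs = column.observations
    ebds, groups = _allele_ebds(column)
    effective = groups.get(cand.alt_allele, [])
    if not effective:
        raise ValueError(f"candidate allele {cand.alt_allele!r} not observed at {cand.chrom}:{cand.pos}")

    vtype = cand.vtype
    depth = compute_ebd(effective, vtype)
    ratio = compute_ebd_ratio(ebds[cand.alt_allele], list(ebds.values()))
    sumbq, avebq = compute_sumbq_avebq(effective, vtype)
    if vtype == SNV:
        eps = min(max(10.0 ** (-avebq / 10.0), SNV_EPS_MIN), SNV_EPS_MAX)
    else:
        eps = INDEL_EPS
    deltal = compute_deltal(len(effective), len(all_obs), eps)
    varpos = compute_varpos(effective)
    ave_mq, wor_mq, poor, ave_as = compute_mapping_features(effective, all_obs)
    varstr = compute_varstr(effective)
    a = sum(1 for o in effective if not o.is_reverse)
    b = len(effective) - a
    fwd_all = sum(1 for o in all_obs if not o.is_reverse)
    c = fwd_all - a
    d = len(all_obs) - len(effective) - c
    biasstr = compute_biasstr(a, b, c, d)

    cand.depth = len(all_obs)
    cand.alt_ebd = depth
    ref_obs = groups.get(column.ref_base, [])
    # same scale as the candidate: mapq*baseq vs an SNV, mapq alone vs an indel
    if vtype == SNV:
        cand.ref_ebd = compute_ebd(ref_obs, vtype)
    else:
        # a read carrying an indel also shows its anchor base, so subtract
        # every indel carrier's mapq from the reference support
        carrier_mq = sum(o.mapq for o in all_obs if o.allele[0] in "+-")
        cand.ref_ebd = max(0.0, compute_ebd(ref_obs, vtype) - carrier_mq)

    vec = np.array(
        [depth, ratio, deltal, sumbq, avebq, varpos, ave_mq, wor_mq, poor, ave_as, varstr, biasstr],
        dtype=np.float64,
    )
    cand.features = vec
    return vec


def feature_table_rows(candidates: List[CandidateVariant]):
    """Rows for the optional per-candidate feature dump (TSV)."""
    from .records import FEATURE_NAMES

    header = ["chrom", "pos", "ref", "alt", "vtype", "qual", *FEATURE_NAMES]
    rows = [header]
    for c in candidates:
        rows.append(
            [c.chrom, str(c.pos), c.ref_allele, c.alt_allele, c.vtype, str(c.dbsnp_qual)]
            + [repr(float(v)) for v in c.features]
        )
    return rows
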