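"""Candidate generation: CIGAR-driven pileup, allele enumeration with a
depth-proportion filter, indel normalization and known-variant labeling.

The pileup walks each read's CIGAR once.  Matches contribute the base at the
reference position; an insertion immediately following position ``p``
contributes an ``INS`` observation anchored at ``p``; a deletion starting
after ``p`` contributes a ``DEL`` anchor at ``p`` and the deleted positions
receive no base from that read.  Soft-clipped bases never contribute.

The 3' offset stored with every observation is the distance of the pile-up
site from the read's sequencing (3') end in query coordinates; for a
reverse-strand read the 3' end is the leftmost query base as stored in the
alignment.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, List

from .records import (
    INDEL_BASE_QUAL,
    AlignedRead,
    CandidateVariant,
    PileupColumn,
    ReadObservation,
    allele_vtype,
)

logger = logging.getLogger(__name__)

_QUERY_OPS = frozenset("MIS=X")


def _read_observations(read: AlignedRead):
    """Yield (ref_pos, ReadObservation) for one read; positions 1-based."""
    qlen = len(read.seq)
    expected = sum(ln for op, ln in read.cigar if op in _QUERY_OPS)
    if expected != qlen:
        raise ValueError(
            f"CIGAR/sequence length mismatch for read {read.query_name!r}: "
            f"CIGAR consumes {expected}, sequence has {qlen}"
        )
    mapq = read.mapq
    rev = read.is_reverse
    score = read.align_score if read.align_score is not None else 0
    seq = read.seq
    quals = read.base_quals
    qpos = 0
    rpos = read.pos
    last = qlen - 1
    for op, length in read.cigar:
        if op in ("M", "=", "X"):
            for _ in range(length):
                base = seq[qpos]
                if base != "N":
                    off3 = qpos if rev else last - qpos
                    yield rpos, ReadObservation(base, quals[qpos], mapq, rev, off3, score)
                qpos += 1
                rpos += 1
        elif op == "I":
            if qpos > 0 and rpos > read.pos:  # an alignment cannot open with I
                anchor_q = qpos - 1
                off3 = anchor_q if rev else last - anchor_q
                yield rpos - 1, ReadObservation(
                    "+" + seq[qpos : qpos + length], INDEL_BASE_QUAL, mapq, rev, off3, score
                )
            qpos += length
        elif op == "D":
            if rpos > read.pos:
                anchor_q = qpos - 1
                off3 = anchor_q if rev else last - anchor_q
                yield rpos - 1, ReadObservation(f"-{length}", INDEL_BASE_QUAL, mapq, rev, off3, score)
            rpos += length
        elif op == "S":
            qpos += length
        elif op == "N":
            rpos += length
        # H and P consume nothing we track


def pileup(reads: Iterable[AlignedRead], reference: str, chrom: str) -> Iterator[PileupColumn]:
    """Stream pileup columns over every reference position covered by >= 1 read.

    Reads must arrive sorted by position; columns are emitted in increasing
    position order and freed as soon as no later read can touch them, so
    memory stays proportional to read length + local depth, not to file size.
    Reads whose CIGAR disagrees with their sequence length are skipped with a
    warning.
    """
    pending: dict = {}
    horizon = 0  # columns strictly below this can still gain observations

    for read in reads:
        flush_to = read.pos - 1  # insertion at read start may anchor at pos-1
        if flush_to > horizon:
            for pos in sorted(p for p in pending if p < flush_to):
                yield _make_column(chrom, pos, reference, pending.pop(pos))
            horizon = flush_to
        try:
            for pos, obs in _read_observations(read):
                pending.setdefault(pos, []).append(obs)
        except ValueError as exc:
            logger.warning("skipping read: %s", exc)
    for pos in sorted(pending):
        yield _make_column(chrom, pos, reference, pending[pos])


def _make_column(chrom, pos, reference, observations):
    ref_base = reference[pos - 1] if 0 < pos <= len(reference) else "N"
    return PileupColumn(chrom=chrom, pos=pos, ref_base=ref_base, observations=observations)


def enumerate_candidates(
    column: PileupColumn, min_ratio: float = 0.05, min_alt_reads: int = 2
) -> List[CandidateVariant]:
    """Enumerate non-reference allele classes at a column, filtered by support.

    Every distinct observed alternative allele (each base, each insertion
    sequence, each deletion length) is its own candidate; it is kept only if
    its supporting-read count is >= ``min_alt_reads`` and its fraction of the
    column's observations is >= ``min_ratio``.  The reference allele is never
    emitted.
    """
    total = len(column.observations)
    if total == 0:
        return []
    counts: dict = {}
    for obs in column.observations:
        counts[obs.allele] = counts.get(obs.allele, 0) + 1
    out = []
    for allele in sorted(counts):
        if allele == column.ref_base:
            continue
        n = counts[allele]
        if n < min_alt_reads or n / total < min_ratio:
            continue
        out.append(
            CandidateVariant(
                chrom=column.chrom,
                pos=column.pos,
                ref_allele=column.ref_base,
                alt_allele=allele,
                vtype=allele_vtype(allele),
            )
        )
    return out


def expand_candidate_alleles(cand: CandidateVariant, reference: str):
    """Raw VCF-style (pos, ref, alt) for a candidate prior to normalization.

    SNVs are already in final form.  Indels are anchored on the base before
    the event: an insertion of S at anchor p becomes (p, R, R+S); a deletion
    of L bases becomes (p, R + deleted bases, R), with R the anchor base.
    """
    allele = cand.alt_allele
    if cand.vtype == "SNV":
        return cand.pos, cand.ref_allele, allele
    anchor = reference[cand.pos - 1]
    if cand.vtype == "INS":
        return cand.pos, anchor, anchor + allele[1:]
    length = int(allele[1:])
    deleted = reference[cand.pos : cand.pos + length]
    return cand.pos, anchor + deleted, anchor


def normalize_variant(chrom: str, pos: int, ref_allele: str, alt_allele: str, reference: str):
    """Canonical (chrom, pos, ref, alt) key: trimmed, left-aligned, anchored.

    SNVs pass through unchanged.  Indels are shifted as far left as the
    reference allows and reduced to a minimal representation with a single
    shared anchor base.  Idempotent.  Raises ValueError if ``ref_allele``
    disagrees with the reference sequence, or if ref == alt.
    """
    ref = ref_allele.upper()
    alt = alt_allele.upper()
    if not ref or not alt:
        raise ValueError("empty allele")
    if ref == alt:
        raise ValueError(f"ref == alt at {chrom}:{pos} ({ref}); not a variant")
    if reference[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ValueError(
            f"REF {ref!r} does not match reference at {chrom}:{pos} "
            f"({reference[pos - 1 : pos - 1 + len(ref)]!r})"
        )
    if len(ref) == 1 and len(alt) == 1:
        return (chrom, pos, ref, alt)

    # right-trim shared suffix, extending left when an allele would empty out
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif ref[-1] == alt[-1] and pos > 1:
            prev = reference[pos - 2]
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
        else:
            break
    # left-trim shared prefix down to one anchor base
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if len(ref) > 1 and len(alt) > 1:
        # block substitution; keep as-is (outside this caller's emit path)
        return (chrom, pos, ref, alt)
    if pos < 1:
        raise ValueError(f"variant at {chrom}:{pos} ran off the contig start")
    return (chrom, pos, ref, alt)


def label_candidate(cand_key, index) -> int:
    """1 if the normalized candidate key is in the known-variant index, else 0."""
    return 1 if cand_key in index else 0
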