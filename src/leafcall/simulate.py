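"""Synthetic diploid WGS data: reference, planted truth set, simulated
pre-aligned reads and a partial known-variant database.

The simulator plays both sequencer and aligner: reads are drawn uniformly
from one of the two haplotypes and emitted at their true reference
coordinates with exact CIGARs derived from the planted indels, so alignment
itself stays out of scope.  Substitution errors, base-quality noise and
strand assignment are the stochastic layers; everything is driven by one
seeded generator, making every emitted file byte-identical across runs with
the same config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pysam

from .candidates import normalize_variant
from .records import DEL, INS, SNV, AlignedRead, VcfRecord
from .io_formats import write_vcf

_BASES = np.array(list("ACGT"))
_CIGAR_CODE = {"M": 0, "I": 1, "D": 2}


@dataclass(slots=True)
class SimConfig:
    """Study conditions for the simulated sample.

    Defaults describe a small but realistic desk-scale WGS experiment: a
    200 kb contig with 280 planted variants (60% heterozygous), 30x coverage
    of 100 bp single-end reads, a 0.1% substitution error rate and a fully
    covering known-variant database.
    """

    seed: int = 1
    chrom: str = "chr1"
    genome_length: int = 200_000
    n_snv: int = 200
    n_ins: int = 40
    n_del: int = 40
    het_fraction: float = 0.6
    coverage: float = 30.0
    read_length: int = 100
    error_rate: float = 0.001
    bq_mean: float = 30.0
    bq_sd: float = 3.0
    mapq_const: int = 60
    mapq_degrade_fraction: float = 0.0  # fraction of reads given a low random mapq
    dbsnp_fraction: float = 1.0
    decoy_dbsnp: int = 0
    max_indel: int = 5
    min_gap: int = 10  # minimum bp between planted events (beyond their spans)


@dataclass(slots=True)
class TruthVariant:
    chrom: str
    pos: int  # raw anchor position, 1-based
    vtype: str
    payload: str  # alt base (SNV), inserted seq (INS), or str(del length) (DEL)
    genotype: str  # "het" / "hom"
    haps: Tuple[bool, bool]
    key: tuple = ()  # normalized (chrom, pos, ref, alt), set at planting time


def simulate_reference(config: SimConfig, out_dir=None, rng=None) -> str:
    """Uniform random A/C/G/T sequence; optionally written as <chrom>.fa."""
    if config.genome_length < 10 * config.read_length:
        raise ValueError("genome_length must be at least 10x read_length")
    rng = rng or np.random.default_rng(config.seed)
    seq = "".join(_BASES[rng.integers(0, 4, size=config.genome_length)])
    if out_dir is not None:
        write_fasta(Path(out_dir) / f"{config.chrom}.fa", config.chrom, seq)
    return seq


def write_fasta(path, name: str, seq: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def plant_variants(reference: str, config: SimConfig, rng=None):
    """Place non-overlapping SNVs and 1-5 bp indels; build the two haplotypes.

    Returns ``(truth, haplotypes)`` where each haplotype is a pair
    ``(sequence, ref_index)`` with ``ref_index[i]`` the 0-based reference
    position of haplotype base i, or -1 for inserted bases.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_total = config.n_snv + config.n_ins + config.n_del
    positions = _spaced_positions(reference, config, rng, n_total)
    types = [SNV] * config.n_snv + [INS] * config.n_ins + [DEL] * config.n_del
    order = rng.permutation(n_total)
    truth: List[TruthVariant] = []
    for pos, t in zip(positions, (types[i] for i in order)):
        ref_base = reference[pos - 1]
        if t == SNV:
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            payload = alt
            raw = (pos, ref_base, alt)
        elif t == INS:
            ln = int(rng.integers(1, config.max_indel + 1))
            ins = "".join(_BASES[rng.integers(0, 4, size=ln)])
            payload = ins
            raw = (pos, ref_base, ref_base + ins)
        else:
            ln = int(rng.integers(1, config.max_indel + 1))
            payload = str(ln)
            raw = (pos, ref_base + reference[pos : pos + ln], ref_base)
        is_het = rng.random() < config.het_fraction
        if is_het:
            carrier = int(rng.integers(0, 2))
            haps = (carrier == 0, carrier == 1)
            gt = "het"
        else:
            haps = (True, True)
            gt = "hom"
        key = normalize_variant(config.chrom, raw[0], raw[1], raw[2], reference)
        truth.append(TruthVariant(config.chrom, pos, t, payload, gt, haps, key))
    truth.sort(key=lambda v: v.pos)
    keys = [v.key for v in truth]
    if len(set(keys)) != len(keys):
        raise ValueError("normalized truth keys collide; increase min_gap or genome_length")
    haplotypes = tuple(
        _build_haplotype(reference, [v for v in truth if v.haps[h]]) for h in range(2)
    )
    return truth, haplotypes


def _spaced_positions(reference: str, config: SimConfig, rng, n_needed: int) -> np.ndarray:
    lo = config.read_length
    hi = len(reference) - config.read_length - config.max_indel
    if hi <= lo:
        raise ValueError("genome too short for the requested read length")
    spacing = config.min_gap + config.max_indel
    pool_size = min(hi - lo, max(4 * n_needed, n_needed + 64))
    pool = np.sort(rng.choice(hi - lo, size=pool_size, replace=False) + lo)
    picked = []
    last = -(10**9)
    for p in pool:
        if p - last >= spacing:
            picked.append(int(p))
            last = p
            if len(picked) == n_needed:
                break
    if len(picked) < n_needed:
        raise ValueError(
            f"could not place {n_needed} variants with spacing {spacing}; "
            f"increase genome_length"
        )
    return np.array(picked)


def _build_haplotype(reference: str, events: List[TruthVariant]):
    seq_parts: List[str] = []
    idx_parts: List[np.ndarray] = []
    cur = 0  # 0-based reference cursor
    for ev in events:
        if ev.vtype == SNV:
            p0 = ev.pos - 1
            seq_parts.append(reference[cur:p0] + ev.payload)
            idx_parts.append(np.arange(cur, p0 + 1))
            cur = p0 + 1
        elif ev.vtype == INS:
            seq_parts.append(reference[cur : ev.pos] + ev.payload)
            idx_parts.append(np.concatenate([np.arange(cur, ev.pos), np.full(len(ev.payload), -1)]))
            cur = ev.pos
        else:
            ln = int(ev.payload)
            seq_parts.append(reference[cur : ev.pos])
            idx_parts.append(np.arange(cur, ev.pos))
            cur = ev.pos + ln
    seq_parts.append(reference[cur:])
    idx_parts.append(np.arange(cur, len(reference)))
    return "".join(seq_parts), np.concatenate(idx_parts)


def simulate_reads(
    reference: str,
    haplotypes,
    config: SimConfig,
    rng=None,
    sam_path=None,
) -> List[AlignedRead]:
    """Draw reads from random haplotypes; return them sorted by position.

    Each read gets an exact CIGAR from the haplotype-to-reference map,
    substitution errors at ``error_rate``, clamped-normal base qualities,
    a Bernoulli(0.5) strand, constant mapq and an alignment score of
    ``read_length - 5 * edit_distance``.  When ``sam_path`` is given the
    reads are also written as a coordinate-sorted SAM file.
    """
    rng = rng or np.random.default_rng(config.seed)
    L = config.read_length
    n_reads = int(round(config.coverage * config.genome_length / L))
    reads: List[AlignedRead] = []
    for i in range(n_reads):
        hap_i = int(rng.integers(0, 2))
        seq_h, idx_h = haplotypes[hap_i]
        for _ in range(64):
            start = int(rng.integers(0, len(seq_h) - L + 1))
            if idx_h[start] >= 0 and idx_h[start + L - 1] >= 0:
                break
        else:
            continue
        bases = list(seq_h[start : start + L])
        err = np.nonzero(rng.random(L) < config.error_rate)[0]
        for j in err:
            bases[j] = str(rng.choice([b for b in "ACGT" if b != bases[j]]))
        quals = np.clip(np.rint(rng.normal(config.bq_mean, config.bq_sd, size=L)), 2, 41).astype(int)
        is_rev = bool(rng.random() < 0.5)
        mapq = config.mapq_const
        if config.mapq_degrade_fraction > 0 and rng.random() < config.mapq_degrade_fraction:
            mapq = int(rng.integers(0, 15))
        ref_slice = idx_h[start : start + L]
        cigar, mismatches = _cigar_and_mismatches(bases, ref_slice, reference)
        indel_len = sum(ln for op, ln in cigar if op in ("I", "D"))
        edit = mismatches + indel_len
        reads.append(
            AlignedRead(
                query_name=f"r{i:06d}",
                chrom=config.chrom,
                pos=int(ref_slice[0]) + 1,
                cigar=cigar,
                mapq=mapq,
                seq="".join(bases),
                base_quals=list(quals),
                is_reverse=is_rev,
                align_score=L - 5 * edit,
            )
        )
    reads.sort(key=lambda r: (r.pos, r.query_name))
    if sam_path is not None:
        write_sam(reads, sam_path, config.chrom, config.genome_length)
    return reads


def _cigar_and_mismatches(bases, ref_slice, reference: str):
    cigar: List[list] = []
    mismatches = 0
    last_m_ref = None
    for i, r in enumerate(ref_slice):
        if r < 0:
            op = "I"
        else:
            if last_m_ref is not None and r > last_m_ref + 1:
                cigar.append(["D", int(r - last_m_ref - 1)])
            op = "M"
            last_m_ref = r
            if bases[i] != reference[r]:
                mismatches += 1
        if cigar and cigar[-1][0] == op:
            cigar[-1][1] += 1
        else:
            cigar.append([op, 1])
    return [(op, ln) for op, ln in cigar], mismatches


def write_sam(reads: List[AlignedRead], path, chrom: str, chrom_length: int) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": chrom_length}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.query_name
            a.flag = 16 if r.is_reverse else 0
            a.reference_id = 0
            a.reference_start = r.pos - 1
            a.mapping_quality = r.mapq
            a.cigartuples = [(_CIGAR_CODE[op], ln) for op, ln in r.cigar]
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.base_quals)
            )
            if r.align_score is not None:
                a.set_tag("AS", int(r.align_score), value_type="i")
            out.write(a)


def truth_vcf_records(truth: List[TruthVariant]) -> List[VcfRecord]:
    recs = []
    for v in sorted(truth, key=lambda t: t.key[1]):
        _, pos, ref, alt = v.key
        recs.append(
            VcfRecord(
                chrom=v.chrom,
                pos=pos,
                id=".",
                ref=ref,
                alt=alt,
                qual=None,
                genotype="0/1" if v.genotype == "het" else "1/1",
            )
        )
    return recs


def write_known_variants(
    truth: List[TruthVariant],
    config: SimConfig,
    reference: str,
    path,
    heldout_path=None,
    rng=None,
):
    """Write a dbSNP-like file containing a seeded fraction of the truth set
    plus decoy entries at non-variant positions; return the held-out truth.

    The held-out list (planted variants deliberately absent from the
    database) is what a generalization experiment evaluates.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_known = int(round(config.dbsnp_fraction * len(truth)))
    perm = rng.permutation(len(truth))
    known_idx = set(int(i) for i in perm[:n_known])
    known = [truth[i] for i in sorted(known_idx, key=lambda i: truth[i].key[1])]
    heldout = [truth[i] for i in range(len(truth)) if i not in known_idx]

    taken = {v.pos for v in truth}
    decoys = []
    lo, hi = config.read_length, len(reference) - config.read_length
    while len(decoys) < config.decoy_dbsnp:
        p = int(rng.integers(lo, hi))
        if any(abs(p - t) <= config.min_gap + config.max_indel for t in taken):
            continue
        ref_base = reference[p - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        decoys.append(VcfRecord(chrom=config.chrom, pos=p, id=".", ref=ref_base, alt=alt, qual=None, genotype="0/1"))
        taken.add(p)

    recs = [
        VcfRecord(chrom=v.chrom, pos=v.key[1], id=".", ref=v.key[2], alt=v.key[3], qual=None, genotype="0/1" if v.genotype == "het" else "1/1")
        for v in known
    ] + decoys
    recs.sort(key=lambda r: r.pos)
    write_vcf(recs, path, {config.chrom: len(reference)})
    if heldout_path is not None:
        with open(heldout_path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tgenotype\n")
            for v in sorted(heldout, key=lambda t: t.key[1]):
                fh.write(f"{v.key[0]}\t{v.key[1]}\t{v.key[2]}\t{v.key[3]}\t{v.genotype}\n")
    return heldout


def simulate_dataset(config: SimConfig, out_dir) -> dict:
    """Generate the full fixture: reference dir, reads.sam, truth.vcf,
    known.vcf and heldout.tsv under ``out_dir``.  Deterministic per seed."""
    out_dir = Path(out_dir)
    ref_dir = out_dir / "reference"
    ref_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    reference = simulate_reference(config, out_dir=ref_dir, rng=rng)
    truth, haplotypes = plant_variants(reference, config, rng=rng)
    sam_path = out_dir / "reads.sam"
    reads = simulate_reads(reference, haplotypes, config, rng=rng, sam_path=sam_path)
    truth_path = out_dir / "truth.vcf"
    write_vcf(truth_vcf_records(truth), truth_path, {config.chrom: len(reference)})
    known_path = out_dir / "known.vcf"
    heldout_path = out_dir / "heldout.tsv"
    heldout = write_known_variants(truth, config, reference, known_path, heldout_path, rng=rng)
    return {
        "reference": reference,
        "reference_dir": ref_dir,
        "alignments": sam_path,
        "truth_vcf": truth_path,
        "known_vcf": known_path,
        "heldout_tsv": heldout_path,
        "truth": truth,
        "heldout": heldout,
        "reads": reads,
        "config": config,
    }
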