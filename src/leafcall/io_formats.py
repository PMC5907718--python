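"""File-format frontier: alignments, reference FASTA, known-variant index,
VCF output and the tree audit file.

Everything that touches a standard format lives here; the rest of the
package works on plain in-memory records.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional

import pysam
from Bio import SeqIO

from .records import AlignedRead, VcfRecord

logger = logging.getLogger(__name__)

_CIGAR_OPS = "MIDNSHP=X"


class UnsortedInputError(ValueError):
    pass


def read_alignments(path, region: Optional[tuple] = None) -> Iterator[AlignedRead]:
    """Stream mapped reads from a coordinate-sorted SAM/BAM file.

    Unmapped, secondary, supplementary and duplicate-flagged records are
    skipped.  Raises :class:`UnsortedInputError` naming the first
    out-of-order record if the file is not coordinate-sorted.

    Parameters
    ----------
    region
        Optional ``(chrom, start, end)`` filter (1-based inclusive); reads
        overlapping the interval are yielded.  ``start``/``end`` may be None.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"alignment file not found: {path}")
    last = None  # (tid, pos) of previous kept-or-skipped mapped record
    with pysam.AlignmentFile(str(path), require_index=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            key = (rec.reference_id, rec.reference_start)
            if last is not None and key < last:
                raise UnsortedInputError(
                    f"input is not coordinate-sorted: read {rec.query_name!r} at "
                    f"{rec.reference_name}:{rec.reference_start + 1} follows a "
                    f"later position"
                )
            last = key
            if rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                continue
            if region is not None:
                chrom, start, end = region
                if rec.reference_name != chrom:
                    continue
                if start is not None and rec.reference_end < start:
                    continue
                if end is not None and rec.reference_start + 1 > end:
                    continue
            if rec.cigartuples is None or rec.query_sequence is None:
                continue
            quals = rec.query_qualities
            yield AlignedRead(
                query_name=rec.query_name,
                chrom=rec.reference_name,
                pos=rec.reference_start + 1,
                cigar=[(_CIGAR_OPS[op], ln) for op, ln in rec.cigartuples],
                mapq=rec.mapping_quality,
                seq=rec.query_sequence,
                base_quals=list(quals) if quals is not None else [0] * len(rec.query_sequence),
                is_reverse=rec.is_reverse,
                align_score=rec.get_tag("AS") if rec.has_tag("AS") else None,
            )


def load_reference(ref_dir, chrom: str) -> str:
    """Load one chromosome's sequence from ``<ref_dir>/<chrom>.fa`` (uppercased)."""
    ref_dir = Path(ref_dir)
    path = ref_dir / f"{chrom}.fa"
    if not path.exists():
        available = sorted(p.stem for p in ref_dir.glob("*.fa"))
        raise FileNotFoundError(
            f"no reference file for chromosome {chrom!r} in {ref_dir} "
            f"(available: {', '.join(available) or 'none'})"
        )
    record = next(SeqIO.parse(str(path), "fasta"))
    seq = str(record.seq).upper()
    if not seq:
        raise ValueError(f"empty reference sequence in {path}")
    return seq


def _minimal_representation(pos: int, ref: str, alt: str):
    """Trim shared suffix/prefix bases down to the anchored minimal form.

    Reference-free: does not left-align across repeats.  Used for known-
    variant entries when no reference is available (dbSNP-style input is
    left-aligned by convention).
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


class KnownVariantIndex:
    """Constant-time membership set of normalized (chrom, pos, ref, alt) keys."""

    def __init__(self):
        self._keys = set()
        self.n_records = 0
        self.n_skipped = 0

    def add(self, chrom: str, pos: int, ref: str, alt: str) -> None:
        self._keys.add((chrom, pos, ref.upper(), alt.upper()))

    def __contains__(self, key) -> bool:
        return tuple(key) in self._keys

    def __len__(self) -> int:
        return len(self._keys)


def build_known_index(path, reference_provider: Optional[Callable[[str], Optional[str]]] = None) -> KnownVariantIndex:
    """Build the known-variant membership index from a VCF-style file.

    Only CHROM/POS/REF/ALT are consulted; multi-allelic records are expanded
    into their biallelic parts.  Malformed lines are skipped with a warning
    count rather than aborting, so a minimal tab-split reader is used instead
    of a strict VCF parser.  ``.gz`` input is transparently decompressed.

    Parameters
    ----------
    reference_provider
        Optional ``chrom -> sequence`` callable; when given, every entry is
        fully normalized (left-aligned) against the reference.  Otherwise
        entries are reduced to minimal representation only, which assumes the
        input follows the usual left-aligned convention.
    """
    from .candidates import normalize_variant  # local import to avoid a cycle

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    index = KnownVariantIndex()
    ref_cache: dict = {}

    def get_ref(chrom):
        if reference_provider is None:
            return None
        if chrom not in ref_cache:
            try:
                ref_cache[chrom] = reference_provider(chrom)
            except Exception:
                ref_cache[chrom] = None
        return ref_cache[chrom]

    with opener(path, "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                if len(fields) < 5:
                    raise ValueError("fewer than 5 columns")
                chrom, pos, ref, alts = fields[0], int(fields[1]), fields[3].upper(), fields[4].upper()
                if not ref or any(b not in "ACGTN" for b in ref):
                    raise ValueError(f"bad REF {ref!r}")
                for alt in alts.split(","):
                    if not alt or alt in (".", "*") or any(b not in "ACGTN" for b in alt):
                        raise ValueError(f"bad ALT {alt!r}")
                    if ref == alt:
                        raise ValueError("REF == ALT")
                    seq = get_ref(chrom)
                    if seq is not None:
                        key = normalize_variant(chrom, pos, ref, alt, seq)
                    else:
                        npos, nref, nalt = _minimal_representation(pos, ref, alt)
                        key = (chrom, npos, nref, nalt)
                    index.add(*key)
                index.n_records += 1
            except (ValueError, IndexError) as exc:
                index.n_skipped += 1
                logger.warning("skipping malformed known-variant line: %s (%s)", line.rstrip()[:80], exc)
    return index


def _vcf_header(contigs: dict) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.info.add("LQ", 1, "Float", "Leaf mean known-variant label (calling score)")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Total read observations at the locus")
    header.add_sample("SAMPLE")
    return header


def write_vcf(records: Iterable[VcfRecord], path, contigs: dict) -> None:
    """Write VCFv4.2 with FORMAT GT:DP.  Records must be sorted by (chrom, pos).

    ``contigs`` maps chromosome name to length and fixes the sort order of
    chromosomes.
    """
    order = {c: i for i, c in enumerate(contigs)}
    header = _vcf_header(contigs)
    last = None
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in records:
            key = (order[r.chrom], r.pos)
            if last is not None and key < last:
                raise UnsortedInputError(f"VCF records out of order at {r.chrom}:{r.pos}")
            last = key
            rec = vf.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, r.alt),
                id=r.id if r.id not in (None, "") else None,
                qual=r.qual,
            )
            rec.filter.add(r.filter or "PASS")
            for k, v in r.info.items():
                rec.info[k] = v
            if r.genotype is not None:
                a0, a1 = r.genotype.split("/")
                rec.samples["SAMPLE"]["GT"] = (int(a0), int(a1))
            if r.depth is not None:
                rec.samples["SAMPLE"]["DP"] = r.depth
            vf.write(rec)


def read_vcf_records(path) -> list:
    """Parse a VCF back into VcfRecord objects (one per ALT allele)."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            sample = rec.samples["SAMPLE"] if "SAMPLE" in rec.samples else None
            gt = None
            dp = None
            if sample is not None:
                gt_t = sample.get("GT")
                if gt_t is not None and gt_t[0] is not None:
                    gt = "/".join(str(a) for a in gt_t)
                dp = sample.get("DP")
            for alt in rec.alts or ():
                out.append(
                    VcfRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        id=rec.id or ".",
                        ref=rec.ref,
                        alt=alt,
                        qual=rec.qual,
                        filter=";".join(rec.filter.keys()) or "PASS",
                        info=dict(rec.info),
                        genotype=gt,
                        depth=dp,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Tree audit file
# ---------------------------------------------------------------------------
#
# One line per leaf:  "<count> <mean_qual> [<Name>> <thr> | <Name><= <thr>]..."
# The condition tokens record the root-to-leaf decision path; ">" marks the
# branch where the Boolean test "value > threshold" is true, "<=" the branch
# where it is false.  Plain decimals only, no thousands separators.


def write_tree_file(tree, path) -> None:
    from .cart import Leaf  # local import to avoid a cycle

    lines = []

    def walk(node, tokens):
        if isinstance(node, Leaf):
            lines.append(" ".join([str(node.count), _fmt(node.mean_qual)] + tokens))
        else:
            walk(node.left, tokens + [f"{node.feature_name}<= {_fmt(node.threshold)}"])
            walk(node.right, tokens + [f"{node.feature_name}> {_fmt(node.threshold)}"])

    walk(tree, [])
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt(x: float) -> str:
    # shortest round-trip float repr; integers print without a trailing ".0"
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def parse_tree_file(path):
    """Rebuild a decision tree from its audit file.

    The reconstructed tree predicts identically to the one that was written.
    Raises ValueError with the offending line number on malformed input.
    """
    from .cart import Internal, Leaf  # local import to avoid a cycle

    paths = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        tokens = line.split()
        try:
            count = int(tokens[0])
            mean = float(tokens[1])
            conds = []
            rest = tokens[2:]
            if len(rest) % 2:
                raise ValueError("odd number of condition tokens")
            for name_tok, thr_tok in zip(rest[::2], rest[1::2]):
                if name_tok.endswith("<="):
                    conds.append((name_tok[:-2], float(thr_tok), False))
                elif name_tok.endswith(">"):
                    conds.append((name_tok[:-1], float(thr_tok), True))
                else:
                    raise ValueError(f"condition token {name_tok!r} lacks > or <=")
            paths.append((conds, Leaf(count=count, mean_qual=mean)))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed tree-file line {lineno}: {exc}") from exc

    def build(items, depth):
        if len(items) == 1 and not items[0][0]:
            return items[0][1]
        heads = {c[0][:2] for c, _ in items if c}
        if len(heads) != 1 or any(not c for c, _ in items):
            raise ValueError("inconsistent decision paths in tree file")
        (name, thr), = heads
        left = [(c[1:], leaf) for c, leaf in items if c[0][2] is False]
        right = [(c[1:], leaf) for c, leaf in items if c[0][2] is True]
        if not left or not right:
            raise ValueError(f"missing branch under condition {name} @ {thr}")
        return Internal(
            feature_name=name,
            threshold=thr,
            left=build(left, depth + 1),
            right=build(right, depth + 1),
        )

    if not paths:
        raise ValueError("empty tree file")
    return build(paths, 0)
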