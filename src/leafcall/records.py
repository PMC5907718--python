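"""Core record types shared across the caller.

Alleles observed at a pile-up site are encoded as short strings:

* ``"A"``/``"C"``/``"G"``/``"T"`` — a base call (SNV or reference support),
* ``"+SEQ"`` — an insertion of ``SEQ`` anchored immediately after the site,
* ``"-N"`` — a deletion of ``N`` reference bases starting after the site.

This keeps per-locus grouping cheap (plain dict keys) while remaining
readable in debug output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

#: Fixed feature order; also the column order of the feature matrix and the
#: names used in the serialized tree file.
FEATURE_NAMES = (
    "Depth",
    "Ratio",
    "DeltaL",
    "SumBQ",
    "AveBQ",
    "VarPos",
    "AveMQ",
    "WorMQ",
    "PoorMQR",
    "AveAS",
    "VarStr",
    "BiasStr",
)
FEATURE_INDEX = {name: i for i, name in enumerate(FEATURE_NAMES)}

SNV = "SNV"
INS = "INS"
DEL = "DEL"

#: Base quality assigned to indel observations (no per-base quality exists
#: for an inserted/deleted event; 30 is the conventional fixed value).
INDEL_BASE_QUAL = 30


def allele_vtype(allele: str) -> str:
    """Variant type implied by an encoded allele string."""
    if allele.startswith("+"):
        return INS
    if allele.startswith("-"):
        return DEL
    return SNV


@dataclass(slots=True)
class AlignedRead:
    """One mapped read, reduced to the fields the caller consumes."""

    query_name: str
    chrom: str
    pos: int  # 1-based leftmost reference coordinate
    cigar: list  # [(op, length)] with op in "MIDNSHP=X"
    mapq: int
    seq: str
    base_quals: list
    is_reverse: bool
    align_score: Optional[int] = None  # AS-tag semantics; None if absent


class ReadObservation(NamedTuple):
    """A single read's evidence at a single locus."""

    allele: str
    base_qual: int
    mapq: int
    is_reverse: bool
    offset3: int  # distance from the read's 3' sequencing end, query coords
    align_score: int  # 0 when the AS tag was absent


@dataclass(slots=True)
class PileupColumn:
    chrom: str
    pos: int  # 1-based
    ref_base: str
    observations: list  # of ReadObservation


@dataclass(slots=True)
class CandidateVariant:
    """A candidate (chrom, pos, ref, alt) with its label, features and call state."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    vtype: str
    dbsnp_qual: int = 0
    features: Optional[np.ndarray] = None  # length-12, FEATURE_NAMES order
    leaf_qual: float = 0.0
    genotype: str = ""  # "het" / "hom", set at calling time
    depth: int = 0  # total observations at the locus
    alt_ebd: float = 0.0  # effective base depth of the alt allele
    ref_ebd: float = 0.0  # same-scale effective base depth of the ref allele

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(slots=True)
class VcfRecord:
    chrom: str
    pos: int  # 1-based; for indels, the anchor base
    id: str
    ref: str
    alt: str
    qual: Optional[float]
    filter: str = "PASS"
    info: dict = field(default_factory=dict)
    genotype: Optional[str] = None  # "0/1" or "1/1"
    depth: Optional[int] = None
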