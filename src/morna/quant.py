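"""Small-RNA read quantification: trimming, locus allotment, window
classification, counting and RPMR normalization.

The scheme consumes *aligned* reads (alignment itself is upstream). Each
read is assigned to every pri-miR locus on the same chromosome and strand
whose hairpin interval lies within ``locus_distance`` nt (default 50); a
read near several loci is allotted evenly between them. Per locus, the read
is classified by strict containment in one of the four windows derived in
:mod:`morna.annotation` (miR windows take precedence over moR windows).
Weighted counts are normalized to RPMR — reads per million reads mapped to
the counted regions in the library — so per-library RPMR totals 1e6.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .annotation import (
    GenomicInterval,
    LocusIndex,
    PriMirLocus,
    QuantParams,
    RegionSet,
    build_locus_index,
    derive_regions,
)

logger = logging.getLogger(__name__)


class Category(enum.Enum):
    """Read category under the four-window counting scheme."""

    MIR5P = "MIR5P"
    MIR3P = "MIR3P"
    MOR5P = "MOR5P"
    MOR3P = "MOR3P"
    UNASSIGNED = "UNASSIGNED"


COUNTED_CATEGORIES = (Category.MIR5P, Category.MIR3P, Category.MOR5P, Category.MOR3P)


@dataclass(frozen=True)
class AlignedSegment:
    """One alignment of a small-RNA read."""

    read_id: str
    interval: GenomicInterval
    n_alignments: int = 1


@dataclass(frozen=True)
class LocusAssignment:
    read_id: str
    locus_id: str
    weight: float


@dataclass
class CountTable:
    """Weighted per-(locus, category) read counts for one library."""

    library_id: str
    counts: dict[tuple[str, Category], float] = field(default_factory=dict)

    def total(self) -> float:
        return sum(self.counts.values())


@dataclass
class RpmrTable:
    """Reads-per-million-region-reads normalization of a :class:`CountTable`."""

    library_id: str
    rpmr: dict[tuple[str, Category], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Read preprocessing
# ---------------------------------------------------------------------------


def trim_adapter(read_seq: str, adapter: str, min_overlap: int = 6) -> str:
    """Remove the 3' adapter from a read.

    Trims at the leftmost position where the adapter's first ``min_overlap``
    or more bases match exactly; a terminal partial adapter (read suffix
    equal to an adapter prefix of length >= ``min_overlap``) is also
    trimmed. Reads without a match are returned unchanged.
    """
    if not read_seq:
        raise ValueError("empty read")
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    # the leftmost occurrence of the adapter's first min_overlap bases also
    # covers full-adapter matches and terminal partial-adapter prefixes
    probe = adapter.upper()[:min_overlap]
    pos = read_seq.upper().find(probe)
    return read_seq[:pos] if pos != -1 else read_seq


def filter_insert(insert: str, params: QuantParams = QuantParams()) -> bool:
    """Keep an insert iff it is at least ``min_insert`` nt long."""
    return len(insert) >= params.min_insert


# ---------------------------------------------------------------------------
# Locus assignment and classification
# ---------------------------------------------------------------------------


def find_candidate_loci(
    segment: AlignedSegment,
    index: LocusIndex,
    params: QuantParams = QuantParams(),
) -> set[str]:
    """Same-strand loci whose hairpin interval is within ``locus_distance``
    nt (gap distance, boundary inclusive) of the alignment."""
    hits = index.query(segment.interval, distance=params.locus_distance)
    if not hits and segment.interval.chrom not in {
        l.interval.chrom for l in index.loci.values()
    }:
        logger.warning(
            "read %s maps to unknown chromosome %s",
            segment.read_id, segment.interval.chrom,
        )
    return hits


def allot_weights(read_id: str, candidates: Iterable[str]) -> list[LocusAssignment]:
    """Allot a read evenly between its candidate loci (weight 1/n each)."""
    cand = sorted(set(candidates))
    if not cand:
        return []
    w = 1.0 / len(cand)
    return [LocusAssignment(read_id, locus_id, w) for locus_id in cand]


def classify(segment: AlignedSegment, regions: RegionSet) -> Category:
    """Classify an alignment by strict containment in one locus's windows.

    Tested in order MIR5P, MIR3P, MOR5P, MOR3P; first containing window
    wins. A chrom/strand mismatch or no containing window yields
    ``UNASSIGNED``.
    """
    iv = segment.interval
    for cat, win in (
        (Category.MIR5P, regions.mir5p_win),
        (Category.MIR3P, regions.mir3p_win),
        (Category.MOR5P, regions.mor5p_win),
        (Category.MOR3P, regions.mor3p_win),
    ):
        if win is not None and win.contains(iv):
            return cat
    return Category.UNASSIGNED


def tabulate(
    classified: Iterable[tuple[LocusAssignment, Category]],
    library_id: str,
) -> CountTable:
    """Sum assignment weights into per-(locus, category) counts.

    ``UNASSIGNED`` pairs contribute nothing — a read allotted to a locus but
    contained in no window (e.g. a loop read) is excluded from both the
    numerators and the RPMR denominator.
    """
    table = CountTable(library_id)
    for assignment, cat in classified:
        if cat is Category.UNASSIGNED:
            continue
        key = (assignment.locus_id, cat)
        table.counts[key] = table.counts.get(key, 0.0) + assignment.weight
    return table


def normalize_rpmr(table: CountTable) -> RpmrTable:
    """Normalize counts to reads per million region-mapped reads."""
    total = table.total()
    if total <= 0:
        raise ValueError("no region-mapped reads")
    scale = 1e6 / total
    return RpmrTable(
        table.library_id,
        {key: count * scale for key, count in table.counts.items()},
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class QuantResult:
    counts: CountTable
    rpmr: Optional[RpmrTable]
    assignments: list[tuple[LocusAssignment, Category]]
    n_reads: int
    n_assigned_reads: int  # reads with >=1 candidate locus

    def summary(self) -> dict:
        per_cat: dict[str, float] = {c.value: 0.0 for c in COUNTED_CATEGORIES}
        for (_, cat), count in self.counts.counts.items():
            per_cat[cat.value] += count
        total = self.counts.total()
        return {
            "library": self.counts.library_id,
            "n_reads": self.n_reads,
            "n_reads_near_locus": self.n_assigned_reads,
            "region_mapped_weight": total,
            "fraction_region_mapped": total / self.n_reads if self.n_reads else 0.0,
            "per_category": per_cat,
        }


def quantify(
    segments: Sequence[AlignedSegment],
    loci: Sequence[PriMirLocus] | Mapping[str, PriMirLocus],
    params: QuantParams = QuantParams(),
    library_id: str = "library",
) -> QuantResult:
    """Run locus allotment + window classification + counting + RPMR.

    A read with several alignment records pools the candidate loci of all of
    them and is allotted evenly across the union. Per candidate locus, the
    read is classified using the first of its alignments (in input order)
    that put the locus in range.
    """
    if isinstance(loci, Mapping):
        loci = list(loci.values())
    index = build_locus_index(loci)
    regions = {locus.id: derive_regions(locus, params) for locus in loci}

    # group alignments by read, preserving input order
    by_read: dict[str, list[AlignedSegment]] = defaultdict(list)
    for seg in segments:
        by_read[seg.read_id].append(seg)

    classified: list[tuple[LocusAssignment, Category]] = []
    n_assigned = 0
    for read_id, segs in by_read.items():
        per_seg = [(seg, find_candidate_loci(seg, index, params)) for seg in segs]
        union: set[str] = set()
        for _, cand in per_seg:
            union |= cand
        if not union:
            continue
        n_assigned += 1
        for assignment in allot_weights(read_id, union):
            seg = next(s for s, cand in per_seg if assignment.locus_id in cand)
            classified.append((assignment, classify(seg, regions[assignment.locus_id])))

    counts = tabulate(classified, library_id)
    rpmr = normalize_rpmr(counts) if counts.counts else None
    return QuantResult(
        counts=counts, rpmr=rpmr, assignments=classified,
        n_reads=len(by_read), n_assigned_reads=n_assigned,
    )
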