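"""Pri-miR annotation model and the four miR/moR counting windows.

A pri-miR locus carries up to two mature arms (5p/3p). Around each arm the
quantification scheme defines two windows on the same strand:

* the **miR window** — the mature miR coordinates widened by ``mir_slack``
  (default 3 nt) on both sides;
* the **moR window** — the region extending ``mor_extent`` (default 35 nt)
  outward from the mature miR's 5'-terminal base (5p arm) or 3'-terminal
  base (3p arm), plus ``mir_slack`` + 1 nt into the miR itself.

Reads are later classified by strict containment in these windows. With the
defaults a same-arm miR/moR window pair overlaps by exactly 7 nt, so no
read of at least ``min_insert`` (14) nt can be contained in both.

Coordinates are 0-based half-open throughout; GFF3 (1-based inclusive) is
converted at the I/O boundary only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import gffutils
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True if ``other`` lies entirely within this interval (same chrom+strand)."""
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Number of bases separating the two intervals; 0 when they overlap
        or abut. None if on different chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.end <= other.start:
            return other.start - self.end
        if other.end <= self.start:
            return self.start - other.end
        return 0


@dataclass(frozen=True)
class MatureMir:
    """A mature miR arm."""

    name: str
    arm: str  # "5p" or "3p"
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise AnnotationError(f"arm must be '5p' or '3p', got {self.arm!r}")
        n = len(self.interval)
        if not 15 <= n <= 30:
            warnings.warn(
                f"mature miR {self.name!r} has unusual length {n} nt "
                "(typical mature miRs are 18-26 nt)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PriMirLocus:
    """A pri-miR with its annotated mature arms."""

    id: str
    interval: GenomicInterval
    mature_5p: Optional[MatureMir] = None
    mature_3p: Optional[MatureMir] = None

    def __post_init__(self) -> None:
        if self.mature_5p is None and self.mature_3p is None:
            raise AnnotationError(f"locus {self.id!r} has no mature arm")
        for mat in (self.mature_5p, self.mature_3p):
            if mat is not None and not self.interval.contains(mat.interval):
                raise AnnotationError(
                    f"mature {mat.name!r} does not lie within pri-miR {self.id!r} "
                    "on the same chrom/strand"
                )


@dataclass(frozen=True)
class QuantParams:
    """Window-geometry and filtering parameters of the counting scheme.

    All values in nucleotides. ``mir_slack`` widens the miR window on both
    sides; ``mor_extent`` is the outward reach of a moR window from the
    mature miR terminus; ``locus_distance`` is the maximum read-to-hairpin
    gap for locus assignment; ``min_insert`` is the minimum insert length
    kept after trimming.
    """

    mir_slack: int = 3
    mor_extent: int = 35
    locus_distance: int = 50
    min_insert: int = 14

    def __post_init__(self) -> None:
        for name in ("mir_slack", "mor_extent", "locus_distance", "min_insert"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.mir_slack * 2 + 1 >= self.min_insert:
            raise ValueError(
                "mir_slack*2 + 1 must be < min_insert so that no kept read "
                "can be contained in both a miR and a moR window"
            )


@dataclass(frozen=True)
class RegionSet:
    """The four derived counting windows of one locus (absent arm => absent windows)."""

    locus_id: str
    mir5p_win: Optional[GenomicInterval] = None
    mir3p_win: Optional[GenomicInterval] = None
    mor5p_win: Optional[GenomicInterval] = None
    mor3p_win: Optional[GenomicInterval] = None


def _clip0(chrom: str, start: int, end: int, strand: str) -> Optional[GenomicInterval]:
    start = max(start, 0)
    if start >= end:
        return None
    return GenomicInterval(chrom, start, end, strand)


def derive_regions(locus: PriMirLocus, params: QuantParams = QuantParams()) -> RegionSet:
    """Derive the four counting windows for a locus, strand-aware.

    For a mature arm at [s, e) the miR window is [s-slack, e+slack). The moR
    window sits on the 5' side of a 5p miR and on the 3' side of a 3p miR
    *in transcript orientation*, reaching ``mor_extent`` nt outward from the
    terminal base and ``mir_slack`` + 1 nt into the miR. Windows are clipped
    at position 0 and never trimmed to the pri-miR interval.
    """
    k = params.mir_slack
    m = params.mor_extent
    iv = locus.interval
    minus = iv.strand == "-"

    mir5p = mir3p = mor5p = mor3p = None
    if locus.mature_5p is not None:
        s, e = locus.mature_5p.interval.start, locus.mature_5p.interval.end
        mir5p = _clip0(iv.chrom, s - k, e + k, iv.strand)
        if minus:
            # 5' terminal base of a minus-strand 5p miR is the genomic end
            mor5p = _clip0(iv.chrom, e - k - 1, e + m, iv.strand)
        else:
            mor5p = _clip0(iv.chrom, s - m, s + k + 1, iv.strand)
    if locus.mature_3p is not None:
        s, e = locus.mature_3p.interval.start, locus.mature_3p.interval.end
        mir3p = _clip0(iv.chrom, s - k, e + k, iv.strand)
        if minus:
            mor3p = _clip0(iv.chrom, s - m, s + k + 1, iv.strand)
        else:
            mor3p = _clip0(iv.chrom, e - k - 1, e + m, iv.strand)
    return RegionSet(locus.id, mir5p_win=mir5p, mir3p_win=mir3p,
                     mor5p_win=mor5p, mor3p_win=mor3p)


# ---------------------------------------------------------------------------
# GFF3 parsing (miRBase dialect)
# ---------------------------------------------------------------------------

_PRI_TYPES = {"miRNA_primary_transcript", "pre_miRNA"}
_MATURE_TYPES = {"miRNA"}


def _feature_name(f: gffutils.Feature) -> str:
    for key in ("Name", "ID"):
        if key in f.attributes:
            return f.attributes[key][0]
    return f.id or ""


def _arm_from_name(name: str) -> Optional[str]:
    low = name.lower()
    if low.endswith("-5p") or low.endswith("_5p"):
        return "5p"
    if low.endswith("-3p") or low.endswith("_3p"):
        return "3p"
    return None


def parse_mirbase_gff(gff_text: str) -> list[PriMirLocus]:
    """Parse miRBase-style GFF3 text into pri-miR loci.

    Primary transcripts (``miRNA_primary_transcript``) and mature ``miRNA``
    records are linked through ``Derives_from`` or ``Parent``. Arms are taken
    from a ``-5p``/``-3p`` name suffix when present, otherwise assigned by
    position in transcript orientation (5'-most mature = 5p). Coordinates are
    converted from 1-based inclusive to 0-based half-open.
    """
    for lineno, line in enumerate(gff_text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationError(
                f"malformed GFF line {lineno}: expected 9 tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise AnnotationError(
                f"malformed GFF line {lineno}: non-numeric coordinates"
            ) from exc
        if start < 1 or end < start:
            raise AnnotationError(
                f"malformed GFF line {lineno}: invalid 1-based span {start}..{end}"
            )
    try:
        db = gffutils.create_db(
            gff_text, dbfn=":memory:", from_string=True,
            merge_strategy="create_unique", keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted error types
        raise AnnotationError(f"malformed GFF3: {exc}") from exc

    pris: dict[str, gffutils.Feature] = {}
    for f in db.all_features():
        if f.featuretype in _PRI_TYPES:
            pris[f.id] = f

    matures: dict[str, list[gffutils.Feature]] = {pid: [] for pid in pris}
    for f in db.all_features():
        if f.featuretype not in _MATURE_TYPES:
            continue
        parents = list(f.attributes.get("Derives_from", [])) or list(
            f.attributes.get("Parent", [])
        )
        parent = next((p for p in parents if p in pris), None)
        if parent is None:
            warnings.warn(
                f"mature miR record {_feature_name(f)!r} has no resolvable "
                "primary transcript; skipped",
                stacklevel=2,
            )
            continue
        matures[parent].append(f)

    loci = []
    for pid, pri in pris.items():
        strand = pri.strand
        iv = GenomicInterval(pri.seqid, pri.start - 1, pri.end, strand)
        arms: dict[str, MatureMir] = {}
        kids = matures[pid]
        named = {_arm_from_name(_feature_name(k)) for k in kids}
        use_names = named - {None} and None not in named and len(named) == len(kids) <= 2
        if not use_names:
            # fall back to transcript-orientation order: 5'-most mature = 5p
            kids = sorted(kids, key=lambda k: k.start, reverse=(strand == "-"))
        for i, kid in enumerate(kids):
            arm = _arm_from_name(_feature_name(kid)) if use_names else ("5p", "3p")[min(i, 1)]
            if arm in arms:
                warnings.warn(
                    f"locus {pid!r}: multiple {arm} matures; keeping the first",
                    stacklevel=2,
                )
                continue
            arms[arm] = MatureMir(
                name=_feature_name(kid), arm=arm,
                interval=GenomicInterval(kid.seqid, kid.start - 1, kid.end, kid.strand),
            )
        if not arms:
            logger.warning("pri-miR %s has no mature arms; skipped", pid)
            continue
        loci.append(
            PriMirLocus(
                id=_feature_name(pri) or pid, interval=iv,
                mature_5p=arms.get("5p"), mature_3p=arms.get("3p"),
            )
        )
    return loci


# ---------------------------------------------------------------------------
# Locus index
# ---------------------------------------------------------------------------


@dataclass
class LocusIndex:
    """Strand-aware interval index over pri-miR hairpin intervals.

    Supports "all loci within D nt (gap distance) of a query interval" in
    O(log n + hits) via per-(chrom, strand) interval trees.
    """

    loci: dict[str, PriMirLocus] = field(default_factory=dict)
    _trees: dict[tuple[str, str], IntervalTree] = field(default_factory=dict)

    def query(self, interval: GenomicInterval, distance: int = 0) -> set[str]:
        """Ids of same-chrom, same-strand loci whose pri-miR interval is
        within ``distance`` nt of ``interval`` (boundary inclusive)."""
        tree = self._trees.get((interval.chrom, interval.strand))
        if tree is None:
            return set()
        # pad by distance+1 (tree overlap is exclusive), then verify the gap
        hits = tree.overlap(interval.start - distance - 1, interval.end + distance + 1)
        out = set()
        for h in hits:
            gap = self.loci[h.data].interval.gap_to(interval)
            if gap is not None and gap <= distance:
                out.add(h.data)
        return out


def build_locus_index(loci: Iterable[PriMirLocus]) -> LocusIndex:
    """Build a :class:`LocusIndex`; duplicate locus ids are an error."""
    index = LocusIndex()
    for locus in loci:
        if locus.id in index.loci:
            raise AnnotationError(f"duplicate locus id {locus.id!r}")
        index.loci[locus.id] = locus
        key = (locus.interval.chrom, locus.interval.strand)
        index._trees.setdefault(key, IntervalTree()).addi(
            locus.interval.start, locus.interval.end, locus.id
        )
    return index


def regions_to_bed(loci: Iterable[PriMirLocus],
                   params: QuantParams = QuantParams()) -> Iterator[str]:
    """Yield BED6 lines (name = locusid:category) for all derived windows."""
    for locus in loci:
        rs = derive_regions(locus, params)
        for cat, win in (("MIR5P", rs.mir5p_win), ("MIR3P", rs.mir3p_win),
                         ("MOR5P", rs.mor5p_win), ("MOR3P", rs.mor3p_win)):
            if win is not None:
                yield f"{win.chrom}\t{win.start}\t{win.end}\t{locus.id}:{cat}\t0\t{win.strand}"
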