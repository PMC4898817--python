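"""Seeded synthetic-data generators for every pipeline input.

Each generator is a pure function of its config (one integer seed per
config; internal streams are derived as ``default_rng([seed, STREAM])``
with a fixed stream id per generator) and emits ground-truth labels so
recovery can be asserted exactly.

The read simulator inverts the classification rules: it draws each read's
interval uniformly among placements entirely inside its true category's
window, so the classifier must recover the truth label for every
single-locus read. Background reads are kept >= 100 nt from every hairpin.
UTRs are i.i.d.-uniform DNA with exact seed matches planted at a controlled
rate; DE tables draw fold changes and adjusted p-values from ranges that
strictly pass (regulated) or strictly fail (unchanged) the default
thresholds, so the intended class is reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .annotation import GenomicInterval, MatureMir, PriMirLocus, QuantParams
from .enrichment import DeRecord
from .quant import AlignedSegment, Category
from .seeds import SeedWindow, UtrRecord

_STREAM_ANNOTATION = 11
_STREAM_READS = 12
_STREAM_UTRS = 13
_STREAM_DE = 14

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


# ---------------------------------------------------------------------------
# Annotation + reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Library-scale small-RNA simulation settings.

    ``category_mix`` gives the probability that a read is a true member of
    each window class (or background); the default mix makes miRs dominant,
    moRs present but rare, and ~79% of reads region-assigned, echoing a
    typical small-RNA library from vascular smooth muscle cells.
    """

    seed: int = 0
    n_loci: int = 20
    chrom_length: int = 200_000
    chrom_name: str = "simchr"
    mature_len: tuple[int, int] = (20, 23)
    reads_per_library: int = 10_000
    category_mix: dict[str, float] = field(default_factory=lambda: {
        "MIR5P": 0.45, "MIR3P": 0.25, "MOR5P": 0.06, "MOR3P": 0.03,
        "BACKGROUND": 0.21,
    })
    read_len: tuple[int, int] = (18, 26)
    multi_locus_fraction: float = 0.0
    params: QuantParams = field(default_factory=QuantParams)

    def __post_init__(self) -> None:
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix must sum to 1, sums to {total}")
        if not 0.0 <= self.multi_locus_fraction <= 1.0:
            raise ValueError("multi_locus_fraction must be a probability")
        for lo, hi in (self.mature_len, self.read_len):
            if not 0 < lo <= hi:
                raise ValueError("ranges must be non-degenerate and positive")


@dataclass
class AnnotationBundle:
    """Genome + pri-miR loci emitted by :func:`gen_annotation`."""

    genome: str
    chrom_name: str
    loci: list[PriMirLocus]
    close_pairs: list[tuple[str, str]]  # locus-id pairs able to host multi-locus reads


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    category: Category
    locus_id: Optional[str]  # None for background
    multi_locus: bool = False


_LOOP_RANGE = (10, 21)
_MIN_SPACING = 200  # between hairpin intervals of unrelated loci
_PAIR_GAP = 60      # between hairpin intervals within a close pair


def gen_annotation(config: SimConfig) -> AnnotationBundle:
    """Place ``n_loci`` non-overlapping pri-miR hairpins on one chromosome.

    Each hairpin is mature5p + loop (>= 10 nt) + mature3p with a random
    strand. Unrelated hairpins are separated by >= 200 nt; when
    ``multi_locus_fraction`` > 0, roughly a quarter of the loci are laid out
    as plus-strand *close pairs* 60 nt apart so that reads can fall within
    50 nt of two hairpins (real miR clusters are similarly compact).
    """
    rng = _rng(config.seed, _STREAM_ANNOTATION)
    chrom = config.chrom_name
    n_pairs = max(1, config.n_loci // 4) if config.multi_locus_fraction > 0 else 0

    loci: list[PriMirLocus] = []
    close_pairs: list[tuple[str, str]] = []
    pos = 300  # leave room for clipped windows and background placement

    def make_locus(idx: int, start: int, strand: str) -> PriMirLocus:
        m5 = int(rng.integers(config.mature_len[0], config.mature_len[1] + 1))
        m3 = int(rng.integers(config.mature_len[0], config.mature_len[1] + 1))
        loop = int(rng.integers(*_LOOP_RANGE))
        end = start + m5 + loop + m3
        lid = f"sim-mir-{idx}"
        # genomic left arm is 5p on +, 3p on -
        left = GenomicInterval(chrom, start, start + m5, strand)
        right = GenomicInterval(chrom, end - m3, end, strand)
        arm5, arm3 = (left, right) if strand == "+" else (right, left)
        return PriMirLocus(
            id=lid,
            interval=GenomicInterval(chrom, start, end, strand),
            mature_5p=MatureMir(f"{lid}-5p", "5p", arm5),
            mature_3p=MatureMir(f"{lid}-3p", "3p", arm3),
        )

    idx = 0
    while idx < config.n_loci:
        in_pair = len(close_pairs) < n_pairs and idx + 1 < config.n_loci
        strand = "+" if in_pair else ("+" if rng.random() < 0.5 else "-")
        locus = make_locus(idx, pos, strand)
        loci.append(locus)
        idx += 1
        if in_pair:
            partner = make_locus(idx, locus.interval.end + _PAIR_GAP, "+")
            loci.append(partner)
            close_pairs.append((locus.id, partner.id))
            idx += 1
            pos = partner.interval.end
        else:
            pos = locus.interval.end
        pos += _MIN_SPACING + int(rng.integers(0, 200))
        if idx < config.n_loci and pos > config.chrom_length - 400:
            raise ValueError(
                f"cannot pack {config.n_loci} loci into chrom_length="
                f"{config.chrom_length}"
            )
    if loci[-1].interval.end + 300 > config.chrom_length:
        raise ValueError("chromosome too short for the requested loci")

    genome = _random_dna(rng, config.chrom_length)
    return AnnotationBundle(genome=genome, chrom_name=chrom, loci=loci,
                            close_pairs=close_pairs)


def _window_for(locus: PriMirLocus, category: Category,
                params: QuantParams) -> GenomicInterval:
    from .annotation import derive_regions

    rs = derive_regions(locus, params)
    win = {
        Category.MIR5P: rs.mir5p_win, Category.MIR3P: rs.mir3p_win,
        Category.MOR5P: rs.mor5p_win, Category.MOR3P: rs.mor3p_win,
    }[category]
    assert win is not None
    return win


def simulate_reads(
    config: SimConfig,
    annotation: AnnotationBundle,
) -> tuple[list[AlignedSegment], list[ReadTruth]]:
    """Draw ``reads_per_library`` reads according to ``category_mix``.

    Window reads are uniform over placements entirely inside the true
    window (lengths from ``read_len`` clipped to the window). Background
    reads are >= 100 nt from every hairpin. A ``multi_locus_fraction`` of
    reads is instead placed between a close pair of hairpins, inside the
    left locus's 3p-moR window and within 50 nt of both hairpins.
    """
    rng = _rng(config.seed, _STREAM_READS)
    params = config.params
    cats = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in cats])
    loci = annotation.loci
    by_id = {l.id: l for l in loci}
    chrom_len = config.chrom_length

    # background: complement of 100-nt halos around hairpins
    free: list[tuple[int, int]] = []
    cursor = 0
    for locus in sorted(loci, key=lambda l: l.interval.start):
        lo = locus.interval.start - 100
        if lo - cursor >= config.read_len[1]:
            free.append((cursor, lo))
        cursor = max(cursor, locus.interval.end + 100)
    if chrom_len - cursor >= config.read_len[1]:
        free.append((cursor, chrom_len))
    free_arr = np.array(free) if free else np.empty((0, 2), dtype=int)

    windows = {
        (l.id, Category[c]): _window_for(l, Category[c], params)
        for l in loci for c in cats if c != "BACKGROUND"
    }
    pair_left = [a for a, _ in annotation.close_pairs]

    segments: list[AlignedSegment] = []
    truths: list[ReadTruth] = []
    draws = rng.choice(len(cats), size=config.reads_per_library, p=probs)
    multi_flags = rng.random(config.reads_per_library) < config.multi_locus_fraction

    for i in range(config.reads_per_library):
        rid = f"read{i:06d}"
        cat_name = cats[draws[i]]
        if multi_flags[i] and pair_left and cat_name != "BACKGROUND":
            # place inside the left hairpin's 3p-moR window, in the gap
            left = by_id[pair_left[int(rng.integers(0, len(pair_left)))]]
            win = windows[(left.id, Category.MOR3P)]
            length = min(int(rng.integers(*_rl(config))), len(win))
            length = max(length, params.min_insert)
            start = int(rng.integers(win.start, win.end - length + 1))
            segments.append(AlignedSegment(
                rid, GenomicInterval(win.chrom, start, start + length, win.strand)))
            truths.append(ReadTruth(rid, Category.MOR3P, left.id, multi_locus=True))
            continue
        if cat_name == "BACKGROUND":
            length = int(rng.integers(*_rl(config)))
            spans = free_arr[:, 1] - free_arr[:, 0] - length
            ok = np.nonzero(spans > 0)[0]
            if ok.size == 0:
                raise ValueError("no room for background reads")
            j = int(ok[rng.integers(0, ok.size)])
            start = int(rng.integers(free_arr[j, 0], free_arr[j, 1] - length))
            strand = "+" if rng.random() < 0.5 else "-"
            segments.append(AlignedSegment(
                rid, GenomicInterval(config.chrom_name, start, start + length, strand)))
            truths.append(ReadTruth(rid, Category.UNASSIGNED, None))
            continue
        locus = loci[int(rng.integers(0, len(loci)))]
        category = Category[cat_name]
        win = windows[(locus.id, category)]
        length = min(int(rng.integers(*_rl(config))), len(win))
        start = int(rng.integers(win.start, win.end - length + 1))
        segments.append(AlignedSegment(
            rid, GenomicInterval(win.chrom, start, start + length, win.strand)))
        truths.append(ReadTruth(rid, category, locus.id))
    return segments, truths


def _rl(config: SimConfig) -> tuple[int, int]:
    return (config.read_len[0], config.read_len[1] + 1)


# ---------------------------------------------------------------------------
# UTRs + DE tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UtrSimConfig:
    """Settings for synthetic 3'UTR sets with planted seed matches."""

    seed: int = 0
    n_genes: int = 2000
    utr_len: tuple[int, int] = (200, 800)
    planted_window: Optional[SeedWindow] = None
    plant_rate: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 <= self.plant_rate <= 1.0:
            raise ValueError("plant_rate must be a probability")
        if self.utr_len[0] < 7:
            raise ValueError("UTRs must be at least 7 nt")


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    planted: bool
    plant_offset: Optional[int] = None


def gen_utrs(config: UtrSimConfig) -> tuple[list[UtrRecord], list[GeneTruth]]:
    """i.i.d.-uniform-base UTRs; a ``plant_rate`` fraction receive one exact
    seed match for ``planted_window`` written at a uniform offset."""
    rng = _rng(config.seed, _STREAM_UTRS)
    pattern = config.planted_window.pattern if config.planted_window else None
    utrs, truths = [], []
    lengths = rng.integers(config.utr_len[0], config.utr_len[1] + 1,
                           size=config.n_genes)
    planted = rng.random(config.n_genes) < config.plant_rate
    for i in range(config.n_genes):
        gid = f"gene{i:05d}"
        seq = _random_dna(rng, int(lengths[i]))
        offset = None
        if pattern is not None and planted[i]:
            offset = int(rng.integers(0, len(seq) - 6))
            seq = seq[:offset] + pattern + seq[offset + 7:]
        utrs.append(UtrRecord(gid, seq))
        truths.append(GeneTruth(gid, planted=bool(planted[i]) and pattern is not None,
                                plant_offset=offset))
    return utrs, truths


@dataclass(frozen=True)
class DeSimConfig:
    """Settings for synthetic DE tables with a planted down-regulation effect.

    Regulated genes draw |FC| and adj. p from ranges strictly inside the
    default cutoffs, unchanged genes from ranges strictly outside, so the
    intended class is recovered exactly by the thresholder.
    """

    seed: int = 0
    p_down_target: float = 0.5
    p_down_background: float = 0.05
    p_up: float = 0.05
    detected_rate: float = 0.9
    fc_magnitude: tuple[float, float] = (1.5, 4.0)
    fc_null: tuple[float, float] = (1.0, 1.25)
    adjp_regulated: tuple[float, float] = (1e-8, 1e-3)
    adjp_null: tuple[float, float] = (0.01, 0.9)

    def __post_init__(self) -> None:
        for p in (self.p_down_target, self.p_down_background, self.p_up,
                  self.detected_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.p_down_background + self.p_up > 1 or self.p_down_target + self.p_up > 1:
            raise ValueError("down + up probabilities exceed 1")
        if self.fc_magnitude[0] <= 1.3:
            raise ValueError("regulated fold changes must strictly exceed 1.3")
        if self.adjp_regulated[1] >= 0.002 or self.adjp_null[0] <= 0.002:
            raise ValueError("adj-p ranges must strictly pass/fail the 0.002 cutoff")


@dataclass(frozen=True)
class DeTruth:
    gene_id: str
    intended_class: str  # DOWN / UP / UNCHANGED / NOT_DETECTED


def gen_de_table(
    config: DeSimConfig,
    gene_truth: Sequence[GeneTruth],
) -> tuple[list[DeRecord], list[DeTruth]]:
    """Emit a DE record per gene: planted genes go DOWN with probability
    ``p_down_target``, others with ``p_down_background``; non-down genes go
    UP with ``p_up``; detection is Bernoulli(``detected_rate``)."""
    rng = _rng(config.seed, _STREAM_DE)
    records, truths = [], []
    for gt in gene_truth:
        detected = rng.random() < config.detected_rate
        p_down = config.p_down_target if gt.planted else config.p_down_background
        u = rng.random()
        if u < p_down:
            cls = "DOWN"
            fc = -float(rng.uniform(*config.fc_magnitude))
            adjp = float(rng.uniform(*config.adjp_regulated))
        elif u < p_down + config.p_up:
            cls = "UP"
            fc = float(rng.uniform(*config.fc_magnitude))
            adjp = float(rng.uniform(*config.adjp_regulated))
        else:
            cls = "UNCHANGED"
            mag = float(rng.uniform(*config.fc_null))
            fc = mag if rng.random() < 0.5 else -mag
            adjp = float(rng.uniform(*config.adjp_null))
        records.append(DeRecord(gt.gene_id, fc, adjp, detected=detected))
        truths.append(DeTruth(gt.gene_id, cls if detected else "NOT_DETECTED"))
    return records, truths


def with_seed(config, seed: int):
    """Copy any sim config with a replaced seed."""
    return replace(config, seed=seed)
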