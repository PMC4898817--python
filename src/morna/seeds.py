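"""Seed-window enumeration, 3'UTR seed-match scanning, and the bulged
sponge-site model.

For a small RNA of length L every 7-nt window at starts 1..L-6 (1-based) is
a candidate seed; the window at start 2 is the classic miR seed
(nucleotides 2-8). A window's *seed match* is the DNA reverse complement of
its 7-mer, searched as an exact substring on the sense strand of 3'UTRs.

A sponge binding site for a small RNA pairs its seed (nucleotides 1-8) and
its 3' terminus but bulges out the central nucleotides, which blocks
Ago2-mediated endonucleolytic cleavage while retaining binding: the site is
``anchor5 + bulge + anchor3`` where anchor5 is the reverse complement of
the RNA's 3'-terminal hexamer and anchor3 the reverse complement of its
5'-terminal octamer.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from . import constructs

_RNA_ALPHABET = set("ACGU")
_DNA_ALPHABET = set("ACGTN")


def revcomp_dna(seq: str) -> str:
    """Reverse complement, returned as DNA (U treated as T)."""
    return str(Seq(seq.upper().replace("U", "T")).reverse_complement())


@dataclass(frozen=True)
class SmallRnaSeq:
    """A small RNA sequence, 5'->3', RNA alphabet (T converted with warning)."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if "T" in seq:
            warnings.warn(
                f"{self.name}: DNA-style sequence supplied; converting T to U",
                stacklevel=2,
            )
            seq = seq.replace("T", "U")
        if len(seq) < 7:
            raise ValueError(f"{self.name}: small RNA must be >= 7 nt")
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.name}: non-RNA characters {sorted(bad)}")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SeedWindow:
    """A candidate 7-nt seed at 1-based offset ``start`` within the RNA."""

    start: int
    rna7: str
    width: int = 7

    def __post_init__(self) -> None:
        if len(self.rna7) != self.width or self.width != 7:
            raise ValueError("seed windows are exactly 7 nt")
        if self.start < 1:
            raise ValueError("window start is 1-based")

    @property
    def pattern(self) -> str:
        """DNA seed-match 7-mer (reverse complement of the window), 5'->3'."""
        return seed_match_pattern(self)


def enumerate_seed_windows(rna: SmallRnaSeq) -> list[SeedWindow]:
    """All L-6 candidate seed windows, ordered by start (1..L-6).

    The window at start 2 is the canonical seed (nucleotides 2-8).
    """
    length = len(rna)
    if length < 7:
        raise ValueError("sequence shorter than one seed window")
    return [SeedWindow(i + 1, rna.seq[i:i + 7]) for i in range(length - 6)]


def seed_match_pattern(window: SeedWindow) -> str:
    """The DNA 7-mer whose presence in a UTR constitutes a seed match."""
    return revcomp_dna(window.rna7)


@dataclass(frozen=True)
class UtrRecord:
    """A gene's 3'UTR on the sense strand (DNA, 5'->3')."""

    gene_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.gene_id}: empty UTR")
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"{self.gene_id}: non-DNA characters {sorted(bad)}")


@dataclass
class TargetSet:
    """Genes whose UTR carries >= 1 exact seed match for one window."""

    pattern: str
    hits: dict[str, list[int]] = field(default_factory=dict)
    window: Optional[SeedWindow] = None

    @property
    def genes(self) -> set[str]:
        return set(self.hits)


def find_matches(pattern: str, seq: str) -> list[int]:
    """All (possibly overlapping) 0-based offsets of ``pattern`` in ``seq``."""
    out = []
    pos = seq.find(pattern)
    while pos != -1:
        out.append(pos)
        pos = seq.find(pattern, pos + 1)
    return out


def scan_utrs(
    window: SeedWindow | str,
    utrs: Iterable[UtrRecord],
) -> TargetSet:
    """Exact sense-strand scan of UTRs for a window's seed-match 7-mer.

    Accepts a :class:`SeedWindow` or a DNA 7-mer pattern directly. ``N``
    never matches. Duplicate gene ids are an error (collapse transcripts to
    one UTR per gene upstream).
    """
    if isinstance(window, SeedWindow):
        pattern, win = window.pattern, window
    else:
        pattern, win = window.upper(), None
        if len(pattern) != 7 or set(pattern) - (_DNA_ALPHABET - {"N"}):
            raise ValueError(f"seed-match pattern must be a DNA 7-mer, got {pattern!r}")
    result = TargetSet(pattern=pattern, window=win)
    seen: set[str] = set()
    for utr in utrs:
        if utr.gene_id in seen:
            raise ValueError(f"duplicate gene id {utr.gene_id!r} in UTR set")
        seen.add(utr.gene_id)
        offsets = find_matches(pattern, utr.seq)
        if offsets:
            result.hits[utr.gene_id] = offsets
    return result


def common_region(windows: Sequence[SeedWindow]) -> str:
    """Longest substring shared by all windows' RNA 7-mers (leftmost and
    longest on ties) — the candidate core to disrupt when designing
    seed-mutant small RNAs."""
    if not windows:
        return ""
    first = windows[0].rna7
    others = [w.rna7 for w in windows[1:]]
    for width in range(len(first), 0, -1):
        for i in range(len(first) - width + 1):
            sub = first[i:i + width]
            if all(sub in o for o in others):
                return sub
    return ""


# ---------------------------------------------------------------------------
# Bulged sponge sites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpongeSiteModel:
    """A bulged decoy binding site: ``anchor5 + (bulge_len any bases) + anchor3``.

    anchor5 pairs the small RNA's 3' terminus, anchor3 its seed octamer;
    the unpaired bulge opposite the RNA's central nucleotides prevents
    Ago2 slicing.
    """

    anchor5: str
    anchor3: str
    bulge_len: int = 3

    def __post_init__(self) -> None:
        if not self.anchor5 or not self.anchor3:
            raise ValueError("sponge anchors must be non-empty")
        if self.bulge_len < 0:
            raise ValueError("bulge_len must be nonnegative")

    @classmethod
    def from_rna(
        cls,
        rna: SmallRnaSeq,
        tail_len: int = 6,
        seed_len: int = 8,
        bulge_len: int = 3,
    ) -> "SpongeSiteModel":
        """Derive anchors from a small RNA: anchor5 = revcomp of the last
        ``tail_len`` nt, anchor3 = revcomp of nucleotides 1..``seed_len``."""
        if len(rna) < tail_len + seed_len:
            raise ValueError("small RNA too short for the requested anchors")
        return cls(
            anchor5=revcomp_dna(rna.seq[-tail_len:]),
            anchor3=revcomp_dna(rna.seq[:seed_len]),
            bulge_len=bulge_len,
        )

    @property
    def regex(self) -> "re.Pattern[str]":
        return re.compile(
            re.escape(self.anchor5.upper())
            + f"[ACGTN]{{{self.bulge_len}}}"
            + re.escape(self.anchor3.upper())
        )


def count_sponge_sites(seq: str, model: SpongeSiteModel) -> int:
    """Number of non-overlapping bulged sites in ``seq``, scanning 5'->3'."""
    return sum(1 for _ in model.regex.finditer(seq.upper()))


def default_bulges(rna: SmallRnaSeq, n_sites: int, bulge_len: int = 3) -> list[str]:
    """A deterministic bulge palette avoiding the one filler that would
    restore perfect complementarity to the RNA's bulged-out positions."""
    forbidden = revcomp_dna(rna.seq[8:8 + bulge_len])
    if bulge_len == 3:
        palette = [b for b in constructs.SPONGE_BULGES if b != forbidden]
        extra = ("AAC", "AGG", "TAC", "TTG", "CAA", "GGA")
        palette += [b for b in extra if b != forbidden and b not in palette]
    else:
        palette = [(base * bulge_len) for base in "ACGT" if base * bulge_len != forbidden]
    return [palette[i % len(palette)] for i in range(n_sites)]


def build_sponge(
    rna: SmallRnaSeq,
    n_sites: int = 7,
    bulges: Optional[Sequence[str]] = None,
    linkers: Optional[Sequence[str]] = None,
    flanks: tuple[str, str] = (constructs.SPONGE_FLANK5, constructs.SPONGE_FLANK3),
    model: Optional[SpongeSiteModel] = None,
) -> str:
    """Assemble a sponge construct: flank5 + site1 + linker1 + ... + siteN + flank3.

    Each site follows :class:`SpongeSiteModel` derived from ``rna`` (unless
    an explicit model is given). With the default flanks the construct
    carries the XhoI and ApaI cloning hexamers. A bulge that restores
    perfect complementarity to the RNA's bulged-out central positions
    triggers a warning (such a site would permit Ago2 cleavage).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    model = model or SpongeSiteModel.from_rna(rna)
    if bulges is None:
        bulges = default_bulges(rna, n_sites, model.bulge_len)
    if linkers is None:
        linkers = [constructs.SPONGE_LINKERS[i % len(constructs.SPONGE_LINKERS)]
                   for i in range(n_sites - 1)]
    if len(bulges) != n_sites:
        raise ValueError(f"need {n_sites} bulges, got {len(bulges)}")
    if len(linkers) != n_sites - 1:
        raise ValueError(f"need {n_sites - 1} linkers, got {len(linkers)}")
    cleaving = revcomp_dna(rna.seq[8:8 + model.bulge_len])
    parts = [flanks[0]]
    for i in range(n_sites):
        bulge = bulges[i]
        if len(bulge) != model.bulge_len:
            raise ValueError(f"bulge {bulge!r} is not {model.bulge_len} nt")
        if bulge.upper() == cleaving:
            warnings.warn(
                f"bulge {bulge!r} restores perfect complementarity to the "
                "small RNA's central positions; the site may be cleaved",
                stacklevel=2,
            )
        parts.append(model.anchor5 + bulge + model.anchor3)
        if i < n_sites - 1:
            parts.append(linkers[i])
    parts.append(flanks[1])
    return "".join(parts)
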