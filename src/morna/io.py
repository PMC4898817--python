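"""Format readers and writers shared by all pipeline stages.

Conventions: TSV with headered columns and ``.`` for missing values; BED6
and all internal coordinates 0-based half-open; GFF3 1-based inclusive
(miRBase dialect) converted at this boundary; JSON reports carry a
``schema_version`` field.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GenomicInterval, PriMirLocus
from .enrichment import DeRecord, EnrichmentResult, OverlapSets, coerce_fold_change
from .quant import AlignedSegment, QuantResult, RpmrTable
from .seeds import TargetSet, UtrRecord

SCHEMA_VERSION = 1

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_utr_fasta(path: PathLike) -> list[UtrRecord]:
    """UTR FASTA: record id = gene id, description ignored."""
    return [UtrRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: PathLike) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path), "fasta",
    )


def read_fastq_seqs(path: PathLike) -> Iterable[tuple[str, str]]:
    """Yield (read id, sequence) from FASTQ, for the trim/filter stage."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq)


def write_genome_fasta(chrom_name: str, genome: str, path: PathLike) -> None:
    write_fasta([(chrom_name, genome)], path)


# ---------------------------------------------------------------------------
# GFF3 (miRBase dialect)
# ---------------------------------------------------------------------------


def loci_to_gff(loci: Iterable[PriMirLocus]) -> str:
    """Serialize loci as miRBase-style GFF3 (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for locus in loci:
        iv = locus.interval
        lines.append(
            f"{iv.chrom}\t.\tmiRNA_primary_transcript\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{iv.strand}\t.\tID={locus.id};Name={locus.id}"
        )
        for mat in (locus.mature_5p, locus.mature_3p):
            if mat is None:
                continue
            mi = mat.interval
            lines.append(
                f"{mi.chrom}\t.\tmiRNA\t{mi.start + 1}\t{mi.end}\t.\t{mi.strand}\t.\t"
                f"ID={mat.name};Name={mat.name};Derives_from={locus.id}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Alignments: SAM and BED6
# ---------------------------------------------------------------------------


def read_alignments_sam(path: PathLike) -> list[AlignedSegment]:
    """Read mapped records from SAM/BAM; strand from the reverse flag."""
    segments = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        counts: dict[str, int] = {}
        records = []
        for aln in fh:
            if aln.is_unmapped:
                continue
            records.append(aln)
            counts[aln.query_name] = counts.get(aln.query_name, 0) + 1
        for aln in records:
            segments.append(AlignedSegment(
                read_id=aln.query_name,
                interval=GenomicInterval(
                    aln.reference_name, aln.reference_start, aln.reference_end,
                    "-" if aln.is_reverse else "+",
                ),
                n_alignments=counts[aln.query_name],
            ))
    return segments


def write_alignments_sam(
    segments: Sequence[AlignedSegment],
    chrom_lengths: dict[str, int],
    path: PathLike,
    genome: Optional[str] = None,
) -> None:
    """Write alignments as headered plain-text SAM (CIGAR = full match)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in chrom_lengths.items()],
    }
    refs = {name: i for i, name in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for seg in segments:
            iv = seg.interval
            a = pysam.AlignedSegment(fh.header)
            a.query_name = seg.read_id
            a.flag = 16 if iv.strand == "-" else 0
            a.reference_id = refs[iv.chrom]
            a.reference_start = iv.start
            a.mapping_quality = 255
            a.cigarstring = f"{len(iv)}M"
            if genome is not None:
                a.query_sequence = genome[iv.start:iv.end]
            fh.write(a)


def read_alignments_bed(path: PathLike) -> list[AlignedSegment]:
    """BED6: chrom, start, end, read id, score (ignored), strand."""
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 needs 6 columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]),
                                     fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            segments.append(AlignedSegment(fields[3], iv))
    counts: dict[str, int] = {}
    for seg in segments:
        counts[seg.read_id] = counts.get(seg.read_id, 0) + 1
    return [
        AlignedSegment(s.read_id, s.interval, counts[s.read_id]) for s in segments
    ]


def write_alignments_bed(segments: Iterable[AlignedSegment], path: PathLike) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            iv = seg.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{seg.read_id}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def read_de_table(path: PathLike) -> list[DeRecord]:
    """Headered TSV with columns gene, fold_change, adj_p, detected.

    Ratio-style fold changes (all magnitudes in (0, 1] U [1, inf) with some
    0 < FC < 1) are detected and converted to the signed-magnitude
    convention with a warning. ``.`` marks missing values.
    """
    df = pd.read_csv(path, sep="\t", na_values=["."])
    required = {"gene", "fold_change", "adj_p", "detected"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing DE columns {sorted(missing)}")
    fc = df["fold_change"].astype(float)
    present = fc.dropna()
    if ((present > 0) & (present < 1)).any():
        warnings.warn(
            f"{path}: ratio-style fold changes detected (values in (0,1)); "
            "converting to signed magnitude convention",
            stacklevel=2,
        )
        fc = fc.map(lambda v: coerce_fold_change(v) if pd.notna(v) else v)
    records = []
    for i, row in df.iterrows():
        records.append(DeRecord(
            gene_id=str(row["gene"]),
            fold_change=None if pd.isna(fc.iloc[i]) else float(fc.iloc[i]),
            adj_p=None if pd.isna(row["adj_p"]) else float(row["adj_p"]),
            detected=_as_bool(row["detected"]),
        ))
    return records


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes", "y")
    return bool(value)


def write_de_table(records: Iterable[DeRecord], path: PathLike) -> None:
    rows = [
        {
            "gene": r.gene_id,
            "fold_change": "." if r.fold_change is None else r.fold_change,
            "adj_p": "." if r.adj_p is None else r.adj_p,
            "detected": int(r.detected),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def quant_tables(result: QuantResult) -> pd.DataFrame:
    """Long-format per-(locus, category) counts and RPMR."""
    rpmr = result.rpmr.rpmr if result.rpmr else {}
    rows = [
        {
            "library": result.counts.library_id,
            "locus": locus,
            "category": cat.value,
            "count": count,
            "rpmr": rpmr.get((locus, cat), 0.0),
        }
        for (locus, cat), count in sorted(
            result.counts.counts.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
        )
    ]
    return pd.DataFrame(
        rows, columns=["library", "locus", "category", "count", "rpmr"]
    )


def write_quant_output(result: QuantResult, outdir: PathLike) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    quant_tables(result).to_csv(outdir / "quant.tsv", sep="\t", index=False)
    report = {"schema_version": SCHEMA_VERSION, **result.summary()}
    (outdir / "summary.json").write_text(json.dumps(report, indent=2) + "\n")


def write_targets_tsv(target_sets: Iterable[TargetSet], path: PathLike) -> None:
    rows = []
    for ts in target_sets:
        start = ts.window.start if ts.window else "."
        for gene, offsets in sorted(ts.hits.items()):
            rows.append({
                "window_start": start, "pattern": ts.pattern, "gene": gene,
                "n_sites": len(offsets),
                "offsets": ",".join(map(str, offsets)),
            })
    pd.DataFrame(
        rows, columns=["window_start", "pattern", "gene", "n_sites", "offsets"]
    ).to_csv(path, sep="\t", index=False)


def read_targets_tsv(path: PathLike) -> dict[int, TargetSet]:
    """Inverse of :func:`write_targets_tsv`, keyed by window start."""
    df = pd.read_csv(path, sep="\t")
    out: dict[int, TargetSet] = {}
    for _, row in df.iterrows():
        start = int(row["window_start"])
        ts = out.setdefault(start, TargetSet(pattern=str(row["pattern"])))
        ts.hits[str(row["gene"])] = [int(x) for x in str(row["offsets"]).split(",")]
    return out


def enrichment_report(
    results: Sequence[EnrichmentResult],
    bonferroni_tails: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(results):
        rows.append({
            "window_start": r.window.start,
            "seed": r.window.rna7,
            "pattern": r.window.pattern,
            "n_detected": r.crosstab.n_detected,
            "k_down": r.crosstab.k_down,
            "k_up": r.crosstab.k_up,
            "k_unchanged": r.crosstab.k_unchanged,
            "null_p0": r.null_p0,
            "tail_prob": r.tail_prob,
            "bonferroni": bonferroni_tails[i] if bonferroni_tails else None,
        })
    return pd.DataFrame(rows)


def write_enrichment_report(
    results: Sequence[EnrichmentResult],
    outdir: PathLike,
    bonferroni_tails: Optional[Sequence[float]] = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = enrichment_report(results, bonferroni_tails)
    df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "windows": json.loads(df.to_json(orient="records")),
    }
    (outdir / "enrichment.json").write_text(json.dumps(payload, indent=2) + "\n")


def write_overlap_tsv(overlaps: OverlapSets, path: PathLike) -> None:
    rows = [
        {
            "gene": gene,
            "n_windows": len(wins),
            "windows": ",".join(map(str, sorted(wins))),
        }
        for gene, wins in sorted(overlaps.membership.items())
    ]
    pd.DataFrame(rows, columns=["gene", "n_windows", "windows"]).to_csv(
        path, sep="\t", index=False
    )


def read_text(path: PathLike) -> str:
    return Path(path).read_text()


def read_gff_loci(path: PathLike) -> list[PriMirLocus]:
    from .annotation import parse_mirbase_gff

    return parse_mirbase_gff(read_text(path))
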