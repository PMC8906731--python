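"""Readers and writers for the plain-text formats the pipeline touches.

All genomic files use 0-based, half-open coordinates (BED convention).
Supported formats: BED6 tag alignments, BED6/narrowPeak peak calls, an
extended peak table TSV carrying AUC and background AUC, bedGraph coverage,
a TSS/gene table TSV, expression TSV (gene_id plus ``condition:replicate``
RPKM columns), and the binary motif-hit matrix TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenomicInterval, Peak, SignalTrack, TagAlignment

logger = logging.getLogger(__name__)

PEAK_TABLE_COLUMNS = ["name", "chrom", "start", "end", "summit", "auc", "background_auc"]


# ---------------------------------------------------------------------------
# reads / intervals


def read_bed_reads(path: str | Path) -> list[TagAlignment]:
    """Read BED6 tag alignments; strand is required, name/score ignored."""
    reads: list[TagAlignment] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6 or parts[5] not in ("+", "-"):
                logger.warning("%s:%d: skipping record without a valid strand", path, ln)
                continue
            reads.append(TagAlignment(parts[0], int(parts[1]), int(parts[2]), parts[5]))
    return reads


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read plain intervals (first three BED columns)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed_intervals(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# peaks


def read_peaks(path: str | Path, signal_as_auc: bool = True) -> list[Peak]:
    """Read BED6 or narrowPeak peak calls.

    narrowPeak (10 columns): the summit is ``start + column-10 offset`` when
    the offset is >= 0, and column 7 (signalValue) is taken as the peak AUC
    when ``signal_as_auc`` is set. BED6 peaks get midpoint summits and, with
    ``signal_as_auc``, the score column as AUC.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else f"peak_{ln}"
            summit = None
            auc = 0.0
            if len(parts) >= 10:  # narrowPeak
                offset = int(parts[9])
                if offset >= 0:
                    summit = start + offset
                if signal_as_auc:
                    auc = float(parts[6])
            elif len(parts) >= 5 and signal_as_auc:
                auc = float(parts[4])
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), summit=summit, auc=auc, name=name)
            )
    return peaks


def write_narrowpeak(peaks: list[Peak], path: str | Path) -> None:
    """Write narrowPeak; signalValue carries the AUC, column 10 the summit offset."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.name}\t0\t.\t"
                f"{p.auc:.6g}\t-1\t-1\t{p.summit - p.interval.start}\n"
            )


def read_peak_table(path: str | Path) -> list[Peak]:
    """Read the extended peak table TSV (with AUC and background AUC)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PEAK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table {path} lacks columns: {sorted(missing)}")
    return [
        Peak(
            GenomicInterval(r.chrom, int(r.start), int(r.end)),
            summit=int(r.summit),
            auc=float(r.auc),
            background_auc=float(r.background_auc),
            name=str(r.name),
        )
        for r in df.itertuples(index=False)
    ]


def write_peak_table(peaks: list[Peak], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "name": [p.name for p in peaks],
            "chrom": [p.chrom for p in peaks],
            "start": [p.interval.start for p in peaks],
            "end": [p.interval.end for p in peaks],
            "summit": [p.summit for p in peaks],
            "auc": [p.auc for p in peaks],
            "background_auc": [p.background_auc for p in peaks],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# coverage tracks


def read_bedgraph(
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
    total_mapped_reads: int | None = None,
) -> SignalTrack:
    """Expand a bedGraph into a dense per-base track.

    Without ``chrom_lengths`` each chromosome's vector extends to the last
    covered base; queries past it read as zero.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    data: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        length = (
            chrom_lengths[chrom] if chrom_lengths and chrom in chrom_lengths
            else int(grp["end"].max())
        )
        vec = np.zeros(length, dtype=float)
        for s, e, v in zip(grp["start"].to_numpy(), grp["end"].to_numpy(), grp["value"].to_numpy()):
            vec[s : min(e, length)] = v
        data[chrom] = vec
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            data.setdefault(chrom, np.zeros(length, dtype=float))
    return SignalTrack(data=data, total_mapped_reads=total_mapped_reads)


def write_bedgraph(track: SignalTrack, path: str | Path, precision: int = 6) -> None:
    """Write a dense track as run-length-compressed bedGraph (zeros omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            vec = track.data[chrom]
            if len(vec) == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{round(float(v), precision):.{precision}g}\n")


# ---------------------------------------------------------------------------
# gene / expression tables


def read_tss_table(path: str | Path):
    """Read the TSS table TSV (gene_id, chrom, strand, tss) into GeneModels."""
    from .annotation import GeneModel

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    return [
        GeneModel(str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss))
        for r in df.itertuples(index=False)
    ]


def write_tss_table(genes, path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Expression TSV: gene_id column plus ``condition:replicate`` RPKM columns."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError(f"expression table {path} lacks a gene_id column")
    return df


def expression_sample_columns(df: pd.DataFrame) -> dict[str, list[str]]:
    """Group ``condition:replicate`` columns by condition label."""
    groups: dict[str, list[str]] = {}
    for col in df.columns:
        if ":" in col:
            groups.setdefault(col.split(":", 1)[0], []).append(col)
    return groups


def read_motif_hits(path: str | Path) -> pd.DataFrame:
    """Motif-hit matrix TSV: peak_id index, ``anchor_*`` flag columns, factor columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = [c for c in df.columns if not df[c].isin((0, 1)).all()]
    if bad:
        raise ValueError(f"non-binary columns in motif hit matrix: {bad}")
    return df.astype(int)
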