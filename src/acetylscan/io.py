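"""Readers and writers for the pipeline's on-disk formats.

Genomes travel as FASTA, tags as BED6 (chrom, pos, pos+1, sample, 0, strand;
0-based half-open), atlases as BED with the region id in the name column and
summit provenance in extra columns, matrices and truth tables as TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .atlas import RegionAtlas, RegionScoreMatrix
from .peaks import Peak, TagSet
from .synthetic import ExpressionMatrix, GenomeSequence


def write_fasta(genome: GenomeSequence, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(genome.sequences[c]), id=c, description="")
        for c in genome.chrom_names
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> GenomeSequence:
    names: list[str] = []
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
    return GenomeSequence(names, seqs)


def write_tags_bed(tags: TagSet, path: str | Path) -> None:
    df = tags.records
    bed = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 1,
            "name": tags.sample_id,
            "score": 0,
            "strand": df["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_tags_bed(path: str | Path, sample_id: str | None = None) -> TagSet:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    sid = sample_id or (str(bed["name"].iloc[0]) if len(bed) else "sample")
    records = pd.DataFrame(
        {"chrom": bed["chrom"], "pos": bed["start"].astype(int), "strand": bed["strand"]}
    )
    return TagSet(sid, records)


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    # columns 1-6 are standard BED; column 7 carries the summit coordinate
    rows = [
        (p.chrom, p.start, p.end, f"peak_{i}", p.height, ".", p.summit)
        for i, p in enumerate(peaks)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path: str | Path) -> list[Peak]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "height", "strand", "summit"],
        dtype={"chrom": str},
    )
    return [
        Peak(r.chrom, int(r.start), int(r.end), int(r.summit), int(r.height))
        for r in df.itertuples(index=False)
    ]


def write_atlas_bed(atlas: RegionAtlas, path: str | Path) -> None:
    df = atlas.regions
    bed = df[["chrom", "start", "end", "region_id", "source_height"]].copy()
    bed["strand"] = "."
    bed["source_sample"] = df["source_sample"]
    bed["source_summit"] = df["source_summit"]
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_atlas_bed(path: str | Path, width: int) -> RegionAtlas:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=[
            "chrom", "start", "end", "region_id", "source_height",
            "strand", "source_sample", "source_summit",
        ],
        dtype={"chrom": str, "region_id": str, "source_sample": str},
    )
    cols = [
        "chrom", "start", "end", "region_id",
        "source_sample", "source_summit", "source_height",
    ]
    return RegionAtlas(df[cols].reset_index(drop=True), width)


def write_score_matrix(scores: RegionScoreMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    scores.raw.to_csv(prefix.with_suffix(".raw.tsv"), sep="\t")
    scores.rpm.to_csv(prefix.with_suffix(".rpm.tsv"), sep="\t")
    scores.library_sizes.to_frame().to_csv(
        prefix.with_suffix(".libsizes.tsv"), sep="\t"
    )


def read_score_matrix(prefix: str | Path) -> RegionScoreMatrix:
    prefix = Path(prefix)
    raw = pd.read_csv(prefix.with_suffix(".raw.tsv"), sep="\t", index_col=0)
    rpm = pd.read_csv(prefix.with_suffix(".rpm.tsv"), sep="\t", index_col=0)
    libs = pd.read_csv(prefix.with_suffix(".libsizes.tsv"), sep="\t", index_col=0)[
        "library_size"
    ]
    return RegionScoreMatrix(raw, rpm, libs)


def write_expression(matrix: ExpressionMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    matrix.intensities.to_csv(prefix.with_suffix(".intensities.tsv"), sep="\t")
    matrix.detection.to_csv(prefix.with_suffix(".detection.tsv"), sep="\t")
    pd.Series(matrix.conditions, name="condition").to_csv(
        prefix.with_suffix(".conditions.tsv"), sep="\t"
    )


def read_expression(prefix: str | Path) -> ExpressionMatrix:
    prefix = Path(prefix)
    intensities = pd.read_csv(
        prefix.with_suffix(".intensities.tsv"), sep="\t", index_col=0
    )
    detection = pd.read_csv(
        prefix.with_suffix(".detection.tsv"), sep="\t", index_col=0
    )
    cond = pd.read_csv(prefix.with_suffix(".conditions.tsv"), sep="\t", index_col=0)[
        "condition"
    ].to_dict()
    return ExpressionMatrix(intensities, detection, cond)
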