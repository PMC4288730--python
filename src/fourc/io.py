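"""Plain-text I/O: FASTA, FASTQ, BED, BedGraph, viewpoint and fragment tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .digestion import FragmentMap
from .intervals import GenomicInterval
from .profile import ViewpointProfile, ViewpointSpec


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path, line_width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def read_fastq(path: str | Path):
    """Yield (id+description, sequence, quality) triples."""
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(reads, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(intervals, path: str | Path, names=None, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def write_bedgraph(fmap: FragmentMap, chrom: str, values: np.ndarray, path: str | Path, header: str | None = None) -> None:
    starts, ends = fmap.starts(chrom), fmap.ends(chrom)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for s, e, v in zip(starts, ends, values):
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", names=["chrom", "start", "end", "value"]
    )


def read_viewpoint_table(path: str | Path) -> list[ViewpointSpec]:
    """Tab-delimited viewpoint table: name, chrom, position, tag, tissue."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ViewpointSpec(str(r["name"]), str(r["chrom"]), int(r["position"]), str(r.get("tag", "") or ""), str(r.get("tissue", "") or ""))
        for _, r in df.iterrows()
    ]


def write_fragment_map(fmap: FragmentMap, path: str | Path) -> None:
    fmap.to_frame().to_csv(path, sep="\t", index=False)


def read_fragment_map(path: str | Path) -> FragmentMap:
    return FragmentMap.from_frame(pd.read_csv(path, sep="\t"))


def read_sam_positions(path: str | Path):
    """Yield (chrom, 0-based leftmost position) from a plain-text SAM file.

    Unmapped records (flag 0x4 or '*' reference) are skipped. Reads are
    assigned by their leftmost aligned coordinate regardless of strand.
    """
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4 or f[2] == "*" or int(f[1]) & 0x4:
                continue
            yield f[2], int(f[3]) - 1


def write_profile_tracks(profile: ViewpointProfile, out_dir: str | Path, prefix: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chrom = profile.chrom
    write_bedgraph(profile.fmap, chrom, profile.raw_counts, out / f"{prefix}.raw.bedgraph")
    if profile.normalized is not None:
        write_bedgraph(profile.fmap, chrom, profile.normalized, out / f"{prefix}.rpm.bedgraph")
    if profile.smoothed is not None:
        write_bedgraph(profile.fmap, chrom, profile.smoothed, out / f"{prefix}.smoothed.bedgraph")
    masked_iv = [
        GenomicInterval(chrom, int(s), int(e))
        for s, e, m in zip(profile.fmap.starts(chrom), profile.fmap.ends(chrom), profile.masked)
        if m
    ]
    write_bed(masked_iv, out / f"{prefix}.mask.bed")
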