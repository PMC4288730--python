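"""In-silico restriction digestion and read-to-fragment assignment.

A 4C library is built by a primary digest (NlaIII, CATG) that defines the
restriction-fragment coordinate system, followed by a secondary digest
(DpnII, GATC) used for circularization; fragments without an internal
secondary site are "blind" and quantify poorly. Both motifs are palindromic,
so forward-strand scanning finds every site.

Cuts are placed after the last motif base on the forward strand (CATG^):
NlaIII leaves CATG on the upstream fragment's 3' end, which keeps
motif-containing fragment ends identifiable. Any fixed convention works for
fragment-level counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

NLAIII = "CATG"
DPNII = "GATC"


def find_sites(sequence: str, motif: str) -> list[int]:
    """All exact forward-strand occurrences of ``motif`` (overlaps allowed).

    ``N`` never matches because matching is exact over A/C/G/T.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    seq = sequence.upper()
    motif = motif.upper()
    sites = []
    i = seq.find(motif)
    while i != -1:
        sites.append(i)
        i = seq.find(motif, i + 1)
    return sites


@dataclass(frozen=True)
class Fragment:
    """One restriction fragment; ``blind`` means no internal secondary site."""

    index: int
    interval: GenomicInterval
    has_secondary_site: bool = False

    @property
    def blind(self) -> bool:
        return not self.has_secondary_site

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def midpoint(self) -> float:
        return self.interval.midpoint


@dataclass
class FragmentMap:
    """Ordered restriction fragments tiling each chromosome.

    Stores per-chromosome boundary arrays for O(log n) read assignment;
    ``Fragment`` objects are materialized on demand.
    """

    primary_motif: str = NLAIII
    secondary_motif: str = DPNII
    genome: str = ""
    _starts: dict[str, np.ndarray] = field(default_factory=dict)
    _ends: dict[str, np.ndarray] = field(default_factory=dict)
    _secondary: dict[str, np.ndarray] = field(default_factory=dict)

    def add_chromosome(self, chrom: str, boundaries: np.ndarray) -> None:
        b = np.asarray(boundaries, dtype=np.int64)
        if b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must start at 0 and be strictly increasing")
        self._starts[chrom] = b[:-1]
        self._ends[chrom] = b[1:]
        self._secondary[chrom] = np.zeros(len(b) - 1, dtype=bool)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._starts)

    def n_fragments(self, chrom: str) -> int:
        return len(self._starts[chrom])

    def chrom_length(self, chrom: str) -> int:
        return int(self._ends[chrom][-1])

    def starts(self, chrom: str) -> np.ndarray:
        return self._starts[chrom]

    def ends(self, chrom: str) -> np.ndarray:
        return self._ends[chrom]

    def midpoints(self, chrom: str) -> np.ndarray:
        return (self._starts[chrom] + self._ends[chrom]) / 2

    def secondary(self, chrom: str) -> np.ndarray:
        return self._secondary[chrom]

    def fragment(self, chrom: str, index: int) -> Fragment:
        return Fragment(
            index,
            GenomicInterval(chrom, int(self._starts[chrom][index]), int(self._ends[chrom][index])),
            has_secondary_site=bool(self._secondary[chrom][index]),
        )

    def fragments(self, chrom: str) -> list[Fragment]:
        return [self.fragment(chrom, i) for i in range(self.n_fragments(chrom))]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chromosomes:
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": self._starts[chrom],
                        "end": self._ends[chrom],
                        "index": np.arange(self.n_fragments(chrom)),
                        "blind": ~self._secondary[chrom],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, primary_motif: str = NLAIII, secondary_motif: str = DPNII) -> "FragmentMap":
        fmap = cls(primary_motif=primary_motif, secondary_motif=secondary_motif)
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            boundaries = np.concatenate([sub["start"].to_numpy(), [sub["end"].iloc[-1]]])
            fmap.add_chromosome(str(chrom), boundaries)
            if "blind" in sub:
                fmap._secondary[str(chrom)] = ~sub["blind"].to_numpy(dtype=bool)
        return fmap


def digest(sequence: str, primary_motif: str = NLAIII, chrom: str = "chr", genome: str = "") -> FragmentMap:
    """Digest one chromosome sequence into a fragment map.

    Cut positions are (site offset + motif length); fragments are the
    intervals between consecutive cuts plus the chromosome ends. A sequence
    with no sites yields a single fragment.
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    cuts = [s + len(primary_motif) for s in find_sites(sequence, primary_motif)]
    boundaries = [0] + [c for c in cuts if 0 < c < n] + [n]
    fmap = FragmentMap(primary_motif=primary_motif, genome=genome)
    fmap.add_chromosome(chrom, np.array(sorted(set(boundaries)), dtype=np.int64))
    return fmap


def digest_fasta(records: dict[str, str], primary_motif: str = NLAIII, genome: str = "") -> FragmentMap:
    """Digest every record of a {name: sequence} mapping into one map."""
    fmap = FragmentMap(primary_motif=primary_motif, genome=genome)
    for chrom, seq in records.items():
        sub = digest(seq, primary_motif, chrom=chrom)
        fmap.add_chromosome(chrom, np.concatenate([sub.starts(chrom), [sub.ends(chrom)[-1]]]))
    return fmap


def annotate_secondary(fmap: FragmentMap, sequences: dict[str, str], secondary_motif: str = DPNII) -> FragmentMap:
    """Flag fragments containing >= 1 full secondary-motif occurrence.

    A motif straddling a fragment boundary counts for neither fragment
    (containment is by coordinates: the whole match must lie inside).
    """
    fmap.secondary_motif = secondary_motif
    for chrom, seq in sequences.items():
        if chrom not in fmap._starts:
            continue
        if len(seq) != fmap.chrom_length(chrom):
            raise ValueError(f"sequence length {len(seq)} != map length {fmap.chrom_length(chrom)} for {chrom}")
        sites = np.array(find_sites(seq, secondary_motif), dtype=np.int64)
        flags = np.zeros(fmap.n_fragments(chrom), dtype=bool)
        if sites.size:
            starts = fmap.starts(chrom)
            idx = np.searchsorted(starts, sites, side="right") - 1
            contained = sites + len(secondary_motif) <= fmap.ends(chrom)[idx]
            flags[np.unique(idx[contained])] = True
        fmap._secondary[chrom] = flags
    return fmap


def assign_read(position: tuple[str, int], fmap: FragmentMap) -> int:
    """Fragment index whose half-open interval contains the position (binary search)."""
    chrom, bp = position
    if chrom not in fmap._starts:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if not (0 <= bp < fmap.chrom_length(chrom)):
        raise ValueError(f"position {bp} outside {chrom} [0, {fmap.chrom_length(chrom)})")
    return int(np.searchsorted(fmap.starts(chrom), bp, side="right") - 1)
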