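"""From demultiplexed reads to a normalized, masked, smoothed 4C profile.

The processing order follows standard 4C practice: count reads per
restriction fragment, rescale by the library total on the viewpoint
chromosome times 10^6 (RPM normalization), mask viewpoint-proximal and
low-mappability fragments, then smooth with a running mean over a window of
adjacent fragments (default 11). Smoothing happens after normalization;
masked fragments are excluded from both the numerator and denominator of
each window so that artifactual zeros do not drag the local mean down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .digestion import FragmentMap, assign_read
from .intervals import GenomicInterval

RPM_SCALE = 1_000_000
DEFAULT_WINDOW = 11
DEFAULT_VIEWPOINT_RADIUS = 10_000


@dataclass(frozen=True)
class ViewpointSpec:
    """One 4C viewpoint: anchor position, inline barcode tag, tissue."""

    name: str
    chrom: str
    position: int
    tag: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.tag and not (3 <= len(self.tag) <= 6):
            raise ValueError(f"tag length must be 3-6 nt, got {len(self.tag)}")


def check_prefix_free(specs: list[ViewpointSpec]) -> None:
    """Reject tag sets where one tag is a prefix of another (ambiguous demux)."""
    tags = [s.tag for s in specs if s.tag]
    for i, a in enumerate(tags):
        for b in tags[i + 1 :]:
            if a.startswith(b) or b.startswith(a):
                raise ValueError(f"tags {a!r} and {b!r} are prefix-ambiguous")


def demultiplex(
    reads,
    specs: list[ViewpointSpec],
) -> tuple[dict[str, list[tuple[str, str, str]]], list[tuple[str, str, str]]]:
    """Assign reads to viewpoints by exact 5' tag prefix match.

    ``reads`` iterates (id, sequence, quality) triples. Returns per-viewpoint
    lists of tag-trimmed reads plus the unassigned remainder. Tags must be
    mutually prefix-free, so each read matches at most one spec; no mismatch
    tolerance is applied.
    """
    check_prefix_free(specs)
    by_tag = {s.tag: s.name for s in specs}
    lengths = sorted({len(t) for t in by_tag})
    assigned: dict[str, list[tuple[str, str, str]]] = {s.name: [] for s in specs}
    unassigned: list[tuple[str, str, str]] = []
    for rid, seq, qual in reads:
        for L in lengths:
            name = by_tag.get(seq[:L])
            if name is not None:
                assigned[name].append((rid, seq[L:], qual[L:] if qual else qual))
                break
        else:
            unassigned.append((rid, seq, qual))
    return assigned, unassigned


@dataclass
class ViewpointProfile:
    """Per-fragment 4C signal for one viewpoint on its chromosome."""

    viewpoint: ViewpointSpec
    fmap: FragmentMap
    raw_counts: np.ndarray
    normalized: np.ndarray | None = None
    masked: np.ndarray = field(default=None)  # type: ignore[assignment]
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.fmap.n_fragments(self.viewpoint.chrom)
        self.raw_counts = np.asarray(self.raw_counts)
        if len(self.raw_counts) != n:
            raise ValueError(f"raw_counts length {len(self.raw_counts)} != {n} fragments")
        if np.any(self.raw_counts < 0):
            raise ValueError("raw counts must be nonnegative")
        if self.masked is None:
            self.masked = np.zeros(n, dtype=bool)

    @property
    def chrom(self) -> str:
        return self.viewpoint.chrom

    @property
    def viewpoint_fragment(self) -> int:
        return assign_read((self.viewpoint.chrom, self.viewpoint.position), self.fmap)

    def midpoints(self) -> np.ndarray:
        return self.fmap.midpoints(self.chrom)


def count_per_fragment(positions, fmap: FragmentMap, chrom: str) -> np.ndarray:
    """Tally aligned (chrom, bp) positions per fragment of ``chrom``.

    Positions on other chromosomes are ignored (the count vector covers the
    viewpoint chromosome, where all normalization happens).
    """
    counts = np.zeros(fmap.n_fragments(chrom), dtype=np.int64)
    bps = np.array([bp for c, bp in positions if c == chrom], dtype=np.int64)
    if bps.size:
        idx = np.searchsorted(fmap.starts(chrom), bps, side="right") - 1
        np.add.at(counts, idx, 1)
    return counts


def rpm_normalize(profile: ViewpointProfile) -> ViewpointProfile:
    """Divide counts by the viewpoint-chromosome total and scale by 10^6."""
    total = int(profile.raw_counts.sum())
    if total <= 0:
        raise ValueError("cannot RPM-normalize: zero reads on the viewpoint chromosome")
    profile.normalized = profile.raw_counts.astype(float) / total * RPM_SCALE
    return profile


def mask_viewpoint(profile: ViewpointProfile, radius: int = DEFAULT_VIEWPOINT_RADIUS) -> ViewpointProfile:
    """Mask fragments whose midpoint lies within ``radius`` bp of the viewpoint fragment's midpoint.

    The viewpoint fragment itself is always masked: its signal is dominated
    by self-ligation and undigested products.
    """
    mids = profile.midpoints()
    vp_mid = mids[profile.viewpoint_fragment]
    profile.masked = profile.masked | (np.abs(mids - vp_mid) <= radius)
    profile.masked[profile.viewpoint_fragment] = True
    return profile


def mask_regions(profile: ViewpointProfile, exclusions: list[GenomicInterval]) -> ViewpointProfile:
    """Mask fragments overlapping (>= 1 bp) any exclusion interval (e.g. low mappability)."""
    starts = profile.fmap.starts(profile.chrom)
    ends = profile.fmap.ends(profile.chrom)
    for iv in exclusions:
        if iv.chrom != profile.chrom:
            continue
        profile.masked |= (starts < iv.end) & (iv.start < ends)
    return profile


def smooth(profile: ViewpointProfile, window: int = DEFAULT_WINDOW) -> ViewpointProfile:
    """Running mean of the normalized signal over ``window`` adjacent fragments.

    The window is centered, truncated at chromosome ends (mean over the
    fragments actually available), and masked fragments contribute to
    neither numerator nor denominator.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if profile.normalized is None:
        raise ValueError("normalize before smoothing")
    valid = (~profile.masked).astype(float)
    kernel = np.ones(window)
    num = np.convolve(profile.normalized * valid, kernel, mode="same")
    den = np.convolve(valid, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    profile.smoothed = sm
    return profile


def build_profile(
    viewpoint: ViewpointSpec,
    fmap: FragmentMap,
    raw_counts: np.ndarray,
    window: int = DEFAULT_WINDOW,
    viewpoint_radius: int = DEFAULT_VIEWPOINT_RADIUS,
    exclusions: list[GenomicInterval] | None = None,
) -> ViewpointProfile:
    """Convenience pipeline: normalize, mask, smooth."""
    profile = ViewpointProfile(viewpoint, fmap, raw_counts)
    rpm_normalize(profile)
    mask_viewpoint(profile, radius=viewpoint_radius)
    if exclusions:
        mask_regions(profile, exclusions)
    smooth(profile, window=window)
    return profile
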