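"""Derived structural statistics of a two-domain locus.

Given the primary interaction domains called from two adjacent viewpoints,
this module characterizes the region between them: the transition zone (the
overlap — typically a few tens of kb — where both domains reach), cumulative
left/right contact asymmetry around a viewpoint, the fraction of normalized
signal falling in named regions (e.g. an inverted segment and its 400-kb
flanks), and cross-allele domain comparisons after liftover.

Fragment membership in a region is midpoint-based throughout, the single
consistent rule used across the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .profile import DEFAULT_VIEWPOINT_RADIUS, ViewpointProfile
from .rearrangement import AlleleMap, lift_point_snapped
from .segmentation import InteractionDomain

DEFAULT_MERGE_FRACTION = 0.5
DEFAULT_FLANK = 400_000
#: Pseudocount (in normalized RPM units) guarding the log2 asymmetry ratio.
ASYMMETRY_EPSILON = 1.0


@dataclass
class TransitionZone:
    """Overlap, gap or merger between two primary interaction domains."""

    interval: GenomicInterval | None
    relation: str  # {"overlap", "gap", "merged"}
    source_domains: tuple[InteractionDomain, InteractionDomain]

    @property
    def width(self) -> int:
        return self.interval.length if self.interval else 0


def detect_transition_zone(
    dom_a: InteractionDomain,
    dom_b: InteractionDomain,
    merge_fraction: float = DEFAULT_MERGE_FRACTION,
) -> TransitionZone:
    """Classify the relation between two domains on one coordinate frame.

    Intersecting domains with Jaccard below ``merge_fraction`` yield an
    "overlap" transition zone (the intersection); disjoint domains yield a
    "gap"; a Jaccard at or above the threshold means the domains have
    effectively merged into one, as happens when the zone separating them is
    deleted.
    """
    a, b = dom_a.interval, dom_b.interval
    if a.chrom != b.chrom:
        raise ValueError("domains must share a coordinate frame")
    jac = a.jaccard(b)
    inter = a.intersect(b)
    if jac >= merge_fraction:
        return TransitionZone(inter if inter else a.union_span(b), "merged", (dom_a, dom_b))
    if inter is not None:
        return TransitionZone(inter, "overlap", (dom_a, dom_b))
    gap_start, gap_end = min(a.end, b.end), max(a.start, b.start)
    interval = GenomicInterval(a.chrom, gap_start, gap_end) if gap_start < gap_end else None
    return TransitionZone(interval, "gap", (dom_a, dom_b))


@dataclass
class AsymmetryCurve:
    """Cumulative normalized signal left/right of a viewpoint by distance."""

    viewpoint: str
    distances: np.ndarray
    cumulative_left: np.ndarray
    cumulative_right: np.ndarray
    exclusion_radius: int

    def log2_ratio(self, epsilon: float = ASYMMETRY_EPSILON) -> np.ndarray:
        """log2((right + eps)/(left + eps)); the pseudocount guards one-sided profiles."""
        return np.log2((self.cumulative_right + epsilon) / (self.cumulative_left + epsilon))


def cumulative_asymmetry(
    profile: ViewpointProfile,
    max_distance: int,
    step: int,
    exclusion_radius: int = DEFAULT_VIEWPOINT_RADIUS,
) -> AsymmetryCurve:
    """Cumulative normalized reads on each side of the viewpoint.

    At distance d, the left cumulative sums unmasked fragments with midpoint
    in (vp - d, vp - radius] and the right one sums (vp + radius, vp + d];
    fragments within the exclusion radius never contribute.
    """
    if profile.normalized is None:
        raise ValueError("profile must be normalized")
    mids = profile.midpoints()
    vp_mid = mids[profile.viewpoint_fragment]
    keep = ~profile.masked
    offsets = mids - vp_mid
    values = profile.normalized
    distances = np.arange(step, max_distance + 1, step)
    left = np.empty(len(distances))
    right = np.empty(len(distances))
    for i, d in enumerate(distances):
        lsel = keep & (offsets < -exclusion_radius) & (offsets >= -d)
        rsel = keep & (offsets > exclusion_radius) & (offsets <= d)
        left[i] = values[lsel].sum() if d > exclusion_radius else 0.0
        right[i] = values[rsel].sum() if d > exclusion_radius else 0.0
    return AsymmetryCurve(profile.viewpoint.name, distances, left, right, exclusion_radius)


@dataclass
class RegionSummary:
    """Percentage of normalized signal in each named region."""

    percentages: dict[str, float]
    totals: dict[str, float]
    exclusion_radius: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": list(self.percentages), "percent": list(self.percentages.values()),
             "normalized_sum": list(self.totals.values())}
        )


def region_fraction(
    profile: ViewpointProfile,
    regions: dict[str, GenomicInterval],
    exclusion_radius: int = DEFAULT_VIEWPOINT_RADIUS,
) -> RegionSummary:
    """Percent of normalized signal per region (midpoint membership, unmasked only).

    Percentages are taken over the listed regions, so a partition sums to
    100. Viewpoint-proximal fragments are excluded via the profile's mask.
    """
    if profile.normalized is None:
        raise ValueError("profile must be normalized")
    mids = profile.midpoints()
    keep = ~profile.masked
    totals = {}
    for name, iv in regions.items():
        sel = keep & (mids >= iv.start) & (mids < iv.end) if iv.chrom == profile.chrom else np.zeros_like(keep)
        totals[name] = float(profile.normalized[sel].sum())
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("no signal in any listed region")
    return RegionSummary({k: 100.0 * v / grand for k, v in totals.items()}, totals, exclusion_radius)


def flanking_regions(
    focus: GenomicInterval,
    flank: int = DEFAULT_FLANK,
    chrom_length: int | None = None,
) -> dict[str, GenomicInterval]:
    """Default region set for an engineered segment: the segment plus 400-kb flanks."""
    left_start = max(0, focus.start - flank)
    right_end = focus.end + flank
    if chrom_length is not None:
        right_end = min(right_end, chrom_length)
    return {
        "left_flank": GenomicInterval(focus.chrom, left_start, focus.start),
        "focus": focus,
        "right_flank": GenomicInterval(focus.chrom, focus.end, right_end),
    }


def lift_domain(amap: AlleleMap, domain: InteractionDomain) -> tuple[GenomicInterval, bool]:
    """Express a reference-frame domain in allele coordinates (span of lifted edges).

    Edges falling in deleted intervals snap to the nearest surviving position
    and the result is flagged.
    """
    a, snapped_a = lift_point_snapped(amap, domain.interval.start)
    b, snapped_b = lift_point_snapped(amap, domain.interval.end - 1)
    lo, hi = min(a, b), max(a, b)
    return GenomicInterval(amap.name, lo, hi + 1), snapped_a or snapped_b


def compare_alleles(
    domains_ref: list[InteractionDomain],
    domains_alt: list[InteractionDomain],
    amap: AlleleMap,
    merge_fraction: float = DEFAULT_MERGE_FRACTION,
) -> pd.DataFrame:
    """Per-viewpoint domain shifts between reference and rearranged allele.

    Reference domains are lifted into allele coordinates before comparison.
    Returns one row per viewpoint with signed start/end boundary shifts (bp)
    and the Jaccard between the lifted reference domain and the allele-called
    domain; plus one summary row per frame with the inter-viewpoint domain
    Jaccard and transition-zone relation.
    """
    by_name_alt = {d.viewpoint: d for d in domains_alt}
    rows = []
    for d_ref in domains_ref:
        d_alt = by_name_alt.get(d_ref.viewpoint)
        if d_alt is None:
            continue
        lifted, snapped = lift_domain(amap, d_ref)
        rows.append(
            {
                "viewpoint": d_ref.viewpoint,
                "start_shift_bp": d_alt.interval.start - lifted.start,
                "end_shift_bp": d_alt.interval.end - lifted.end,
                "jaccard_ref_vs_alt": lifted.jaccard(d_alt.interval),
                "edge_snapped": snapped,
            }
        )
    df = pd.DataFrame(rows)
    if len(domains_ref) >= 2:
        df.attrs["ref_pair_jaccard"] = domains_ref[0].jaccard(domains_ref[1])
        df.attrs["ref_tz_relation"] = detect_transition_zone(
            domains_ref[0], domains_ref[1], merge_fraction
        ).relation
    if len(domains_alt) >= 2:
        df.attrs["alt_pair_jaccard"] = domains_alt[0].jaccard(domains_alt[1])
        df.attrs["alt_tz_relation"] = detect_transition_zone(
            domains_alt[0], domains_alt[1], merge_fraction
        ).relation
    return df
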