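"""End-to-end convenience pipeline: simulate a locus, build profiles, call domains."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .digestion import FragmentMap
from .profile import (
    DEFAULT_VIEWPOINT_RADIUS,
    DEFAULT_WINDOW,
    ViewpointProfile,
    build_profile,
)
from .segmentation import (
    DEFAULT_BACKGROUND_DISTANCE,
    DEFAULT_KMAX,
    DEFAULT_PENALTY,
    DEFAULT_THRESHOLD_FACTOR,
    InteractionDomain,
    call_domain,
)
from .simulate import SimTruth, SyntheticLocusSpec, make_truth, simulate_counts, simulate_fragment_map
from .topology import TransitionZone, detect_transition_zone


@dataclass
class LocusResult:
    """Everything the pipeline produced for one simulated locus."""

    spec: SyntheticLocusSpec
    fmap: FragmentMap
    truth: SimTruth
    profiles: dict[str, ViewpointProfile]
    domains: dict[str, InteractionDomain]
    tz: TransitionZone | None


def analyze_locus(
    spec: SyntheticLocusSpec,
    seed: int | None = None,
    window: int = DEFAULT_WINDOW,
    viewpoint_radius: int = DEFAULT_VIEWPOINT_RADIUS,
    k_max: int = DEFAULT_KMAX,
    penalty: float = DEFAULT_PENALTY,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
    background_distance: int = DEFAULT_BACKGROUND_DISTANCE,
) -> LocusResult:
    """Simulate counts for every viewpoint and run the full calling pipeline.

    ``seed`` overrides the spec's seed for this run (replicate studies pass
    a different seed per replicate while keeping the locus fixed).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    fmap, _ = simulate_fragment_map(spec, rng)
    truth = make_truth(spec)
    profiles: dict[str, ViewpointProfile] = {}
    domains: dict[str, InteractionDomain] = {}
    for vp in spec.viewpoints:
        counts, mu = simulate_counts(spec, vp, fmap, rng)
        truth.expected[vp.name] = mu
        profiles[vp.name] = build_profile(
            vp, fmap, counts, window=window, viewpoint_radius=viewpoint_radius
        )
        domains[vp.name] = call_domain(
            profiles[vp.name],
            k_max=k_max,
            penalty=penalty,
            threshold_factor=threshold_factor,
            background_distance=background_distance,
        )
    tz = None
    if len(spec.viewpoints) >= 2:
        names = [vp.name for vp in spec.viewpoints]
        tz = detect_transition_zone(domains[names[0]], domains[names[1]])
    return LocusResult(spec, fmap, truth, profiles, domains, tz)


def planted_edge_fragments(result: LocusResult, viewpoint: str) -> tuple[int, int]:
    """Fragment indices (first, last) of the planted domain, midpoint membership."""
    interval = result.truth.domain_intervals[viewpoint]
    mids = result.fmap.midpoints(result.spec.chrom)
    inside = np.flatnonzero((mids >= interval.start) & (mids < interval.end))
    return int(inside[0]), int(inside[-1])


def called_edge_fragments(result: LocusResult, viewpoint: str) -> tuple[int, int]:
    """Fragment indices (first, last) of the called domain."""
    dom = result.domains[viewpoint].interval
    starts = result.fmap.starts(result.spec.chrom)
    ends = result.fmap.ends(result.spec.chrom)
    first = int(np.searchsorted(starts, dom.start, side="right") - 1)
    last = int(np.searchsorted(ends, dom.end, side="left"))
    return first, last
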