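"""Generative model of a two-domain locus separated by a transition zone.

The simulator emulates the qualitative features of a 4C contact profile over
a locus partitioned into two interaction domains by a narrow semi-permeable
transition zone (TZ): power-law distance decay from the viewpoint, elevated
contacts within the viewpoint's own domain, strongly reduced contacts across
the TZ, a TZ that itself contacts both sides (an "interaction sink"),
tissue-specific enhancer contact peaks, and overdispersed counts at fixed
sequencing depth.

Expected intensity of a fragment at midpoint distance d (kb) from the
viewpoint::

    mu = (1 + d)^(-alpha) * D * E

where D is beta when fragment and viewpoint share a domain, gamma when they
lie in different domains, and tau * (beta + gamma)/2 when either lies in the
TZ; E = 1 + the sum of Gaussian enhancer-peak amplitudes active in the
profiled tissue. Counts are a multinomial allocation of the library over
fragments with gamma-perturbed weights (dispersion phi), so the total read
count always equals the library size.

Engineered alleles are simulated by lifting the structural elements (TZ,
viewpoints, peaks, outer limits) into allele coordinates and re-deriving the
two domains from the lifted TZ: everything on one side of the TZ belongs to
one domain, bounded by the outer limits. Deleting the TZ therefore yields a
single merged domain spanning both outer limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .digestion import NLAIII, DPNII, FragmentMap
from .intervals import GenomicInterval
from .profile import ViewpointSpec
from .rearrangement import (
    AlleleMap,
    RearrangementEvent,
    build_allele_map,
    lift_interval,
    lift_point,
    lift_point_snapped,
)

MIN_FRAGMENT_LENGTH = 50
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class EnhancerPeak:
    """A tissue-specific contact peak (position, amplitude, tissue, width)."""

    position: int
    amplitude: float
    tissue: str
    width: int = 5_000  # Gaussian sigma in bp


@dataclass(frozen=True)
class SyntheticLocusSpec:
    """Generative parameters for a two-domain locus with a transition zone.

    The default geometry mirrors a ~0.7 Mb locus on a 1 Mb chromosome: two
    domains of ~360 kb meeting at a 20 kb TZ, viewpoints at the two "gene
    promoters" 300 kb apart straddling the TZ, and a heart-specific enhancer
    peak between the TZ and the second viewpoint. ``tz=None`` denotes a
    merged single-domain locus (the TZ has been deleted).
    """

    chrom: str = "chrS"
    length: int = 1_000_000
    mean_fragment: int = 3_000
    outer_left: int = 140_000
    outer_right: int = 840_000
    tz: GenomicInterval | None = GenomicInterval("chrS", 480_000, 500_000)
    alpha: float = 1.0
    beta: float = 5.0
    gamma: float = 0.2
    tau: float = 2.0
    phi: float = 0.1
    library_size: int = 1_000_000
    blind_fraction: float = 0.05
    peaks: tuple[EnhancerPeak, ...] = (EnhancerPeak(530_000, 3.0, "heart"),)
    viewpoints: tuple[ViewpointSpec, ...] = (
        ViewpointSpec("vpA", "chrS", 320_000, "ACGT", "heart"),
        ViewpointSpec("vpB", "chrS", 620_000, "TGCAC", "heart"),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 1 or not (0 < self.gamma < 1) or self.tau < 1 or self.phi < 0:
            raise ValueError("parameters out of range: need alpha>0, beta>1, 0<gamma<1, tau>=1, phi>=0")
        if self.tz is not None and not (0 <= self.outer_left < self.tz.start < self.tz.end < self.outer_right <= self.length):
            raise ValueError("need outer_left < tz < outer_right within the chromosome")

    @property
    def domain_a(self) -> GenomicInterval:
        """Left domain: outer limit to the TZ's far edge (the TZ belongs to both)."""
        end = self.tz.end if self.tz else self.outer_right
        return GenomicInterval(self.chrom, self.outer_left, end)

    @property
    def domain_b(self) -> GenomicInterval:
        start = self.tz.start if self.tz else self.outer_left
        return GenomicInterval(self.chrom, start, self.outer_right)

    def domain_of(self, position: float) -> str | None:
        """Exclusive domain membership used by the contact model: 'tz', 'A', 'B' or None."""
        if self.tz is not None and self.tz.start <= position < self.tz.end:
            return "tz"
        if self.tz is None:
            return "A" if self.outer_left <= position < self.outer_right else None
        if self.outer_left <= position < self.tz.start:
            return "A"
        if self.tz.end <= position < self.outer_right:
            return "B"
        return None


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset."""

    spec: SyntheticLocusSpec
    domain_intervals: dict[str, GenomicInterval]
    tz_interval: GenomicInterval | None
    expected: dict[str, np.ndarray] = field(default_factory=dict)  # per-viewpoint mu
    read_positions: dict[str, tuple[str, int]] = field(default_factory=dict)  # read id -> (chrom, bp)
    read_viewpoint: dict[str, str] = field(default_factory=dict)


def make_truth(spec: SyntheticLocusSpec) -> SimTruth:
    domains = {}
    for vp in spec.viewpoints:
        side = spec.domain_of(vp.position)
        if side == "B":
            domains[vp.name] = spec.domain_b
        elif side in ("A", "tz"):
            domains[vp.name] = spec.domain_a if side == "A" else spec.domain_a.union_span(spec.domain_b)
        else:
            domains[vp.name] = GenomicInterval(spec.chrom, spec.outer_left, spec.outer_right)
    return SimTruth(spec, domains, spec.tz)


def simulate_fragment_map(
    spec: SyntheticLocusSpec,
    rng: np.random.Generator | None = None,
    with_sequence: bool = False,
) -> tuple[FragmentMap, str | None]:
    """Draw a restriction-fragment map with exponential-like fragment lengths.

    With ``with_sequence=True`` a sequence is realized that digests back to
    exactly this map: the primary motif is planted immediately before every
    internal boundary, a secondary motif inside every non-blind fragment, and
    the filler alphabet {A, C} cannot form either motif.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if spec.mean_fragment >= spec.length:
        boundaries = np.array([0, spec.length], dtype=np.int64)
    else:
        mean_extra = max(spec.mean_fragment - MIN_FRAGMENT_LENGTH, 1)
        n_guess = int(spec.length / max(spec.mean_fragment, 1) * 2) + 10
        lengths = MIN_FRAGMENT_LENGTH + rng.exponential(mean_extra, size=n_guess).astype(np.int64)
        cuts = np.cumsum(lengths)
        cuts = cuts[cuts < spec.length - MIN_FRAGMENT_LENGTH]
        boundaries = np.concatenate([[0], cuts, [spec.length]])
    fmap = FragmentMap(primary_motif=NLAIII, secondary_motif=DPNII, genome=f"synthetic:{spec.chrom}")
    fmap.add_chromosome(spec.chrom, boundaries)
    n = fmap.n_fragments(spec.chrom)
    blind = rng.random(n) < spec.blind_fraction
    fmap._secondary[spec.chrom] = ~blind

    sequence = None
    if with_sequence:
        seq = _BASES[rng.integers(0, 2, size=spec.length)]  # A/C filler cannot form CATG or GATC
        starts, ends = fmap.starts(spec.chrom), fmap.ends(spec.chrom)
        for b in ends[:-1]:  # internal boundaries: plant CATG just upstream of the cut
            seq[b - 4 : b] = np.frombuffer(b"CATG", dtype=np.uint8)
        for i in range(n):
            if not blind[i]:
                mid = (starts[i] + ends[i]) // 2
                seq[mid : mid + 4] = np.frombuffer(b"GATC", dtype=np.uint8)
        sequence = seq.tobytes().decode()
    return fmap, sequence


def expected_intensity(
    spec: SyntheticLocusSpec,
    viewpoint: ViewpointSpec,
    midpoints: np.ndarray,
) -> np.ndarray:
    """Deterministic expected contact intensity per fragment midpoint."""
    mids = np.asarray(midpoints, dtype=float)
    d_kb = np.abs(mids - viewpoint.position) / 1000.0
    decay = (1.0 + d_kb) ** (-spec.alpha)

    vp_dom = spec.domain_of(viewpoint.position)
    frag_dom = np.array([spec.domain_of(m) for m in mids], dtype=object)
    tz_factor = spec.tau * (spec.beta + spec.gamma) / 2.0
    in_tz = (frag_dom == "tz") | (vp_dom == "tz")
    same = (frag_dom == vp_dom) & (frag_dom != None)  # noqa: E711
    D = np.where(in_tz, tz_factor, np.where(same, spec.beta, spec.gamma))

    E = np.ones_like(mids)
    for peak in spec.peaks:
        if peak.tissue == viewpoint.tissue:
            E += peak.amplitude * np.exp(-((mids - peak.position) ** 2) / (2.0 * peak.width**2))
    return decay * D * E


def simulate_counts(
    spec: SyntheticLocusSpec,
    viewpoint: ViewpointSpec,
    fmap: FragmentMap,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Overdispersed per-fragment counts for one viewpoint library.

    The library is allocated over fragments by a single multinomial draw
    with weights mu * Gamma(1/phi, phi) (unit-mean gamma), so the total is
    exactly the library size while per-fragment counts are overdispersed.
    Returns (counts, expected mu).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if spec.library_size < 1:
        raise ValueError("library size must be >= 1")
    mu = expected_intensity(spec, viewpoint, fmap.midpoints(spec.chrom))
    if not np.any(mu > 0):
        raise ValueError("all-zero expected intensity")
    w = mu.copy()
    if spec.phi > 0:
        w *= rng.gamma(1.0 / spec.phi, spec.phi, size=len(mu))
    counts = rng.multinomial(spec.library_size, w / w.sum())
    return counts.astype(np.int64), mu


def simulate_reads(
    spec: SyntheticLocusSpec,
    counts_by_viewpoint: dict[str, np.ndarray],
    fmap: FragmentMap,
    rng: np.random.Generator | None = None,
    read_length: int = 36,
) -> tuple[list[tuple[str, str, str]], SimTruth]:
    """One barcoded read per count: sequence = tag + random bases.

    The read's true genomic position (uniform within its fragment) is
    recorded in the truth tables and in the read id, so the demultiplex ->
    count round trip can be scored without an aligner.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    truth = make_truth(spec)
    by_name = {vp.name: vp for vp in spec.viewpoints}
    starts = fmap.starts(spec.chrom)
    lengths = fmap.ends(spec.chrom) - starts
    reads: list[tuple[str, str, str]] = []
    for name, counts in counts_by_viewpoint.items():
        vp = by_name[name]
        n_reads = int(np.sum(counts))
        if n_reads == 0:
            continue
        frag_idx = np.repeat(np.arange(len(counts)), counts)
        offsets = (rng.random(n_reads) * lengths[frag_idx]).astype(np.int64)
        positions = starts[frag_idx] + offsets
        body_len = max(read_length - len(vp.tag), 1)
        codes = _BASES[rng.integers(0, 4, size=(n_reads, body_len))]
        big = codes.tobytes()
        qual = "I" * (len(vp.tag) + body_len)
        for i in range(n_reads):
            rid = f"{name}.{i} pos={spec.chrom}:{positions[i]}"
            seq = vp.tag + big[i * body_len : (i + 1) * body_len].decode()
            reads.append((rid, seq, qual))
            short_id = rid.split()[0]
            truth.read_positions[short_id] = (spec.chrom, int(positions[i]))
            truth.read_viewpoint[short_id] = name
        truth.expected[name] = expected_intensity(spec, vp, fmap.midpoints(spec.chrom))
    order = rng.permutation(len(reads))
    return [reads[i] for i in order], truth


def read_position(read_id: str) -> tuple[str, int]:
    """Recover the true genomic position encoded in a simulated read id."""
    tag = read_id.split("pos=")[-1]
    chrom, bp = tag.split(":")
    return chrom, int(bp)


def simulate_allele(spec: SyntheticLocusSpec, events: list[RearrangementEvent]) -> tuple[SyntheticLocusSpec, AlleleMap]:
    """Express the locus spec in the coordinates of an engineered allele.

    Structural elements are lifted; the two domains are re-derived from the
    lifted TZ position rather than lifted wholesale, because domain identity
    is a consequence of which side of the TZ a sequence ends up on. If the
    TZ is deleted the allele becomes a single merged domain between the
    outer limits.
    """
    amap = build_allele_map(spec.length, events, name="allele", chrom=spec.chrom)

    new_viewpoints = []
    for vp in spec.viewpoints:
        res = lift_point(amap, vp.position)
        if res.deleted:
            raise ValueError(f"event deletes viewpoint {vp.name}")
        pos = ([im for im in res.images if im.copy_index == 0] or list(res.images))[0].position
        new_viewpoints.append(replace(vp, position=pos))

    new_tz: GenomicInterval | None = None
    if spec.tz is not None:
        pieces = [p for p in lift_interval(amap, spec.tz) if p.copy_index == 0]
        if pieces:
            lo = min(p.start for p in pieces)
            hi = max(p.end for p in pieces)
            new_tz = GenomicInterval(spec.chrom, lo, hi)

    left, _ = lift_point_snapped(amap, spec.outer_left)
    right, _ = lift_point_snapped(amap, spec.outer_right - 1)
    new_left, new_right = min(left, right), max(left, right) + 1

    new_peaks = []
    for peak in spec.peaks:
        res = lift_point(amap, peak.position)
        if res.deleted:
            continue
        pos = ([im for im in res.images if im.copy_index == 0] or list(res.images))[0].position
        new_peaks.append(replace(peak, position=pos))

    if new_tz is not None and not (new_left < new_tz.start and new_tz.end < new_right):
        raise ValueError("rearranged allele geometry is not representable as two flanked domains")

    allele_spec = replace(
        spec,
        length=amap.allele_length,
        outer_left=new_left,
        outer_right=new_right,
        tz=new_tz,
        viewpoints=tuple(new_viewpoints),
        peaks=tuple(new_peaks),
    )
    return allele_spec, amap
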