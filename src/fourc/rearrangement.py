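"""Coordinate algebra for engineered alleles.

An engineered allele (deletion, balanced inversion, tandem duplication) is
represented as an ordered list of oriented reference blocks. Points,
intervals and per-fragment signal tracks can be lifted from the reference
into allele coordinates and back, which is what lets 4C profiles of
rearranged alleles be replotted against the actual structure of the allele.

Events in one allele definition must be pairwise non-overlapping; nested or
composed events are rejected because every engineered allele modelled here
carries a single simple event and silent composition invites coordinate bugs.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import yaml

from .intervals import GenomicInterval, from_one_based

DELETION = "deletion"
INVERSION = "inversion"
TANDEM_DUPLICATION = "tandem_duplication"
_KINDS = (DELETION, INVERSION, TANDEM_DUPLICATION)

FORWARD = "+"
REVERSE = "-"


@dataclass(frozen=True)
class RearrangementEvent:
    """A single structural event rewriting one reference interval."""

    kind: str
    target: GenomicInterval

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown rearrangement kind {self.kind!r}; expected one of {_KINDS}")


@dataclass(frozen=True)
class Block:
    """One contiguous reference segment placed on the allele.

    ``ref_start``/``ref_end`` locate the segment on the reference;
    ``allele_start`` is its offset on the allele. ``orientation`` is '+' for
    a forward copy and '-' for a reversed one. ``copy_index`` is 0 for the
    original and 1 for the extra copy of a tandem duplication.
    """

    ref_start: int
    ref_end: int
    allele_start: int
    orientation: str = FORWARD
    copy_index: int = 0

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def allele_end(self) -> int:
        return self.allele_start + self.length


@dataclass
class AlleleMap:
    """Ordered, oriented reference blocks composing an engineered allele."""

    reference_length: int
    blocks: list[Block]
    name: str = "allele"
    chrom: str = "chr"
    _starts: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._starts = [b.allele_start for b in self.blocks]

    @property
    def allele_length(self) -> int:
        return self.blocks[-1].allele_end if self.blocks else 0

    def block_at_allele(self, allele_position: int) -> Block:
        if not (0 <= allele_position < self.allele_length):
            raise ValueError(f"allele position {allele_position} outside [0, {self.allele_length})")
        i = bisect_right(self._starts, allele_position) - 1
        return self.blocks[i]


@dataclass(frozen=True)
class LiftImage:
    """One image of a lifted point or interval on the allele."""

    start: int
    end: int  # == start + 1 for a point lift
    orientation: str
    copy_index: int

    @property
    def position(self) -> int:
        return self.start


@dataclass(frozen=True)
class LiftResult:
    images: tuple[LiftImage, ...]
    deleted: bool

    def __post_init__(self) -> None:
        if self.deleted != (len(self.images) == 0):
            raise ValueError("deleted flag must mirror an empty image list")


def _check_events(reference_length: int, events: list[RearrangementEvent]) -> list[RearrangementEvent]:
    for ev in events:
        if ev.target.start < 0 or ev.target.end > reference_length:
            raise ValueError(f"event {ev.kind} target {ev.target} outside reference [0, {reference_length})")
    ordered = sorted(events, key=lambda e: e.target.start)
    for a, b in zip(ordered, ordered[1:]):
        if a.target.end > b.target.start:
            raise ValueError(f"overlapping events: {a.kind} {a.target} and {b.kind} {b.target}")
    return ordered


def build_allele_map(
    reference_length: int,
    events: list[RearrangementEvent],
    name: str = "allele",
    chrom: str = "chr",
) -> AlleleMap:
    """Realize a set of non-overlapping events as an ordered block list.

    Each event rewrites exactly its own target interval: deletions drop it,
    inversions reverse it in place, tandem duplications append a second
    forward copy immediately after the original.
    """
    ordered = _check_events(reference_length, events)
    blocks: list[Block] = []
    ref_cursor = 0
    allele_cursor = 0

    def emit(ref_start: int, ref_end: int, orientation: str = FORWARD, copy_index: int = 0) -> None:
        nonlocal allele_cursor
        if ref_end > ref_start:
            blocks.append(Block(ref_start, ref_end, allele_cursor, orientation, copy_index))
            allele_cursor += ref_end - ref_start

    for ev in ordered:
        emit(ref_cursor, ev.target.start)
        if ev.kind == DELETION:
            pass
        elif ev.kind == INVERSION:
            emit(ev.target.start, ev.target.end, REVERSE)
        elif ev.kind == TANDEM_DUPLICATION:
            emit(ev.target.start, ev.target.end, FORWARD, 0)
            emit(ev.target.start, ev.target.end, FORWARD, 1)
        ref_cursor = ev.target.end
    emit(ref_cursor, reference_length)
    return AlleleMap(reference_length, blocks, name=name, chrom=chrom)


def lift_point(amap: AlleleMap, ref_position: int) -> LiftResult:
    """Map one reference position into allele coordinates.

    Returns every image (a tandem duplication yields two); a position inside
    a deleted interval returns ``deleted=True`` with no images.
    """
    if not (0 <= ref_position < amap.reference_length):
        raise ValueError(f"position {ref_position} outside reference [0, {amap.reference_length})")
    images = []
    for b in amap.blocks:
        if b.ref_start <= ref_position < b.ref_end:
            if b.orientation == FORWARD:
                pos = b.allele_start + (ref_position - b.ref_start)
            else:
                pos = b.allele_start + (b.ref_end - 1 - ref_position)
            images.append(LiftImage(pos, pos + 1, b.orientation, b.copy_index))
    return LiftResult(tuple(images), deleted=not images)


def lift_back(amap: AlleleMap, allele_position: int) -> tuple[int, str, int]:
    """Inverse lift: allele position -> (reference position, orientation, copy_index)."""
    b = amap.block_at_allele(allele_position)
    offset = allele_position - b.allele_start
    if b.orientation == FORWARD:
        ref = b.ref_start + offset
    else:
        ref = b.ref_end - 1 - offset
    return ref, b.orientation, b.copy_index


def lift_interval(amap: AlleleMap, ref_interval: GenomicInterval) -> list[LiftImage]:
    """Lift an interval; pieces spanning breakpoints are split.

    Returns the minimal set of allele intervals covering all non-deleted
    images, sorted by allele position. A reversed block yields a piece with
    '-' orientation whose allele span covers the reverse image.
    """
    if ref_interval.start < 0 or ref_interval.end > amap.reference_length:
        raise ValueError(f"interval {ref_interval} outside reference")
    pieces = []
    for b in amap.blocks:
        s = max(ref_interval.start, b.ref_start)
        e = min(ref_interval.end, b.ref_end)
        if s >= e:
            continue
        if b.orientation == FORWARD:
            pieces.append(LiftImage(b.allele_start + (s - b.ref_start), b.allele_start + (e - b.ref_start), FORWARD, b.copy_index))
        else:
            pieces.append(LiftImage(b.allele_start + (b.ref_end - e), b.allele_start + (b.ref_end - s), REVERSE, b.copy_index))
    return sorted(pieces, key=lambda p: (p.start, p.copy_index))


def lift_point_snapped(amap: AlleleMap, position: int) -> tuple[int, bool]:
    """Lift a point, snapping deleted positions to the nearest surviving one.

    Returns (allele position, snapped flag); copy-0 images are preferred.
    """
    position = min(max(position, 0), amap.reference_length - 1)
    res = lift_point(amap, position)
    if not res.deleted:
        primary = [im for im in res.images if im.copy_index == 0] or list(res.images)
        return primary[0].position, False
    for delta in range(1, amap.reference_length):
        for p in (position - delta, position + delta):
            if 0 <= p < amap.reference_length:
                res = lift_point(amap, p)
                if not res.deleted:
                    primary = [im for im in res.images if im.copy_index == 0] or list(res.images)
                    return primary[0].position, True
    raise ValueError("allele has no surviving reference sequence")


@dataclass(frozen=True)
class TrackElement:
    """One reordered track element in allele coordinates."""

    interval: GenomicInterval
    value: float
    orientation: str = FORWARD
    copy_index: int = 0
    split: bool = False  # True when the source element spanned a breakpoint


def reorder_track(
    amap: AlleleMap,
    track: list[tuple[GenomicInterval, float]],
    strict: bool = False,
) -> list[TrackElement]:
    """Reorder a per-fragment signal track into allele coordinates.

    Every non-deleted element appears once per copy with its value unchanged,
    sorted by allele position. An element spanning a breakpoint is split with
    the value carried to both parts and flagged (breakpoint fragments in a
    real 4C experiment are chimeric and unreliable); ``strict=True`` rejects
    such elements instead.
    """
    out: list[TrackElement] = []
    for interval, value in track:
        pieces = lift_interval(amap, interval)
        copy0_len = sum(p.end - p.start for p in pieces if p.copy_index == 0)
        n_copy0 = sum(1 for p in pieces if p.copy_index == 0)
        is_split = bool(pieces) and (n_copy0 > 1 or 0 < copy0_len < interval.length)
        if is_split and strict:
            raise ValueError(f"track element {interval} spans a rearrangement breakpoint")
        for p in pieces:
            out.append(
                TrackElement(
                    GenomicInterval(amap.name, p.start, p.end),
                    value,
                    p.orientation,
                    p.copy_index,
                    split=is_split,
                )
            )
    return sorted(out, key=lambda e: (e.interval.start, e.copy_index))


def load_allele_config(path: str) -> dict[str, list[RearrangementEvent]]:
    """Read allele definitions from a YAML file.

    One named section per allele; each event has fields kind/chrom/start/end
    with start/end in 1-based inclusive coordinates (converted on read).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    alleles: dict[str, list[RearrangementEvent]] = {}
    for name, events in raw.items():
        alleles[name] = [
            RearrangementEvent(ev["kind"], from_one_based(ev["chrom"], int(ev["start"]), int(ev["end"])))
            for ev in events
        ]
    return alleles
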