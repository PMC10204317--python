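"""Priority-ordered genomic region classification.

Partitions a reference genome into five region classes from four BED
tracks, assigning every base the highest-priority class covering it:

    satellite > tandem > repeat > lowmap > normal

(centromeric satellites, TRF tandem repeats, other repetitive elements,
low-mappability regions; the uncovered complement is "normal").  The
result tiles each chromosome exactly, with book-ended same-class
intervals merged after priority resolution.
"""

from __future__ import annotations

import heapq
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

__all__ = [
    "CLASS_PRIORITY",
    "RegionTrack",
    "RegionPartition",
    "classify_genome",
    "annotate_point",
    "class_fractions",
    "read_bed",
    "write_partition_bed",
]

# higher number = higher priority; "normal" is the absence of coverage
CLASS_PRIORITY: dict[str, int] = {
    "normal": 0,
    "lowmap": 1,
    "repeat": 2,
    "tandem": 3,
    "satellite": 4,
}


@dataclass
class RegionTrack:
    """One class's BED intervals: (chrom, start, end), 0-based half-open."""

    label: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in CLASS_PRIORITY or self.label == "normal":
            raise ValueError(
                f"track label must be one of satellite/tandem/repeat/lowmap, "
                f"got {self.label!r}"
            )
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
            if start < 0:
                raise ValueError(f"negative start {chrom}:{start}-{end}")


@dataclass
class RegionPartition:
    """Disjoint labeled intervals tiling each chromosome exactly."""

    chrom_lengths: dict[str, int]
    # per chromosome: sorted list of (start, end, label) tiling [0, length)
    intervals: dict[str, list[tuple[int, int, str]]]

    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)


def classify_genome(
    tracks: Iterable[RegionTrack], chrom_lengths: Mapping[str, int]
) -> RegionPartition:
    """Resolve overlapping tracks into a priority partition.

    Tracks may overlap arbitrarily; duplicate intervals are idempotent.
    Intervals extending past their chromosome are rejected rather than
    clipped — silent clipping hides upstream errors.
    """
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
    by_chrom: dict[str, list[tuple[int, int, int]]] = {c: [] for c in chrom_lengths}
    for track in tracks:
        prio = CLASS_PRIORITY[track.label]
        for chrom, start, end in track.intervals:
            if chrom not in chrom_lengths:
                raise ValueError(f"interval on unknown chromosome {chrom!r}")
            if end > chrom_lengths[chrom]:
                raise ValueError(
                    f"interval {chrom}:{start}-{end} exceeds chromosome length "
                    f"{chrom_lengths[chrom]}"
                )
            by_chrom[chrom].append((start, end, prio))

    label_of = {v: k for k, v in CLASS_PRIORITY.items()}
    partition: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, length in chrom_lengths.items():
        ivs = by_chrom[chrom]
        # boundary sweep: at each elementary interval take the max priority
        bounds = sorted({0, length, *(s for s, _, _ in ivs), *(e for _, e, _ in ivs)})
        starts = sorted(ivs)  # by start
        pieces: list[tuple[int, int, str]] = []
        active: list[tuple[int, int]] = []  # (-prio, end) heap
        si = 0
        for lo, hi in zip(bounds, bounds[1:]):
            while si < len(starts) and starts[si][0] <= lo:
                s, e, p = starts[si]
                heapq.heappush(active, (-p, e))
                si += 1
            while active and active[0][1] <= lo:
                heapq.heappop(active)
            prio = -active[0][0] if active else 0
            label = label_of[prio]
            if pieces and pieces[-1][2] == label and pieces[-1][1] == lo:
                pieces[-1] = (pieces[-1][0], hi, label)
            else:
                pieces.append((lo, hi, label))
        partition[chrom] = pieces
    return RegionPartition(chrom_lengths=dict(chrom_lengths), intervals=partition)


def annotate_point(partition: RegionPartition, chrom: str, pos: int) -> str:
    """Class label of the unique partition interval containing ``pos``."""
    if chrom not in partition.intervals:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if not 0 <= pos < partition.chrom_lengths[chrom]:
        raise IndexError(f"position {pos} outside {chrom} [0, {partition.chrom_lengths[chrom]})")
    pieces = partition.intervals[chrom]
    i = bisect_right([p[0] for p in pieces], pos) - 1
    return pieces[i][2]


def class_fractions(partition: RegionPartition) -> dict[str, float]:
    """Fraction of the genome in each class; fractions sum to 1."""
    total = sum(partition.chrom_lengths.values())
    lengths: dict[str, int] = {}
    for pieces in partition.intervals.values():
        for start, end, label in pieces:
            lengths[label] = lengths.get(label, 0) + (end - start)
    return {label: n / total for label, n in sorted(lengths.items())}


def read_bed(stream: TextIO, label: str) -> RegionTrack:
    intervals = []
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return RegionTrack(label=label, intervals=intervals)


def write_partition_bed(partition: RegionPartition, stream: TextIO) -> None:
    for chrom in partition.chromosomes():
        for start, end, label in partition.intervals[chrom]:
            stream.write(f"{chrom}\t{start}\t{end}\t{label}\n")
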