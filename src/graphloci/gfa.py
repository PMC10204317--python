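"""In-memory pangenome graph model with GFA1/rGFA readers and writers.

The graph holds three record kinds: segments (nodes carrying sequence,
optionally tagged with their assembly of origin, offset and rank as in
minigraph's rGFA dialect), links (blunt-ended edges), and paths (named
assembly walks, GFA P-lines).  W-lines are accepted on input and converted
to paths; they are never written back.

All coordinates are 0-based, half-open.  rGFA ``SO`` offsets are treated as
0-based, matching minigraph.  Sequences are uppercased at parse time:
soft-masking is metadata that plays no role in graph coordinates.
"""

from __future__ import annotations

import gzip
import io
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, TextIO

__all__ = [
    "Segment",
    "Link",
    "Path",
    "Graph",
    "PositionIndex",
    "GFAParseError",
    "GraphIntegrityError",
    "parse_gfa",
    "write_gfa",
    "path_sequence",
    "build_position_index",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


class GFAParseError(ValueError):
    """Malformed GFA record; the message names the offending line number."""


class GraphIntegrityError(ValueError):
    """A record references a segment or path that does not exist."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Segment:
    """A graph node: an identifier plus its DNA sequence.

    ``origin``/``offset``/``rank`` mirror rGFA's SN/SO/SR tags.  Rank 0
    marks reference-backbone segments; their origin names the reference
    contig (PanSN-style, e.g. ``ref#0#chr1``).
    """

    id: str
    sequence: str
    origin: str | None = None
    offset: int | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"segment {self.id!r} has empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"segment {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Link:
    """A blunt-ended edge between two oriented segment ends."""

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str

    def __post_init__(self) -> None:
        if self.from_orient not in "+-" or self.to_orient not in "+-":
            raise ValueError("link orientation must be + or -")


@dataclass
class Path:
    """A named walk: an ordered list of (segment id, orientation) steps."""

    name: str
    steps: list[tuple[str, str]] = field(default_factory=list)


class Graph:
    """Segments, links and named assembly paths with referential integrity."""

    def __init__(self) -> None:
        self.segments: dict[str, Segment] = {}
        self.links: set[Link] = set()
        self.paths: dict[str, Path] = {}

    # -- construction -----------------------------------------------------
    def add_segment(self, segment: Segment) -> None:
        if segment.id in self.segments:
            raise GraphIntegrityError(f"duplicate segment id {segment.id!r}")
        self.segments[segment.id] = segment

    def add_link(self, link: Link) -> None:
        for sid in (link.from_id, link.to_id):
            if sid not in self.segments:
                raise GraphIntegrityError(f"link references missing segment {sid!r}")
        self.links.add(link)

    def add_path(self, path: Path) -> None:
        if path.name in self.paths:
            raise GraphIntegrityError(f"duplicate path name {path.name!r}")
        for sid, _ in path.steps:
            if sid not in self.segments:
                raise GraphIntegrityError(
                    f"path {path.name!r} references missing segment {sid!r}"
                )
        self.paths[path.name] = path

    def has_link(self, a: str, ao: str, b: str, bo: str) -> bool:
        """True if steps (a,ao) -> (b,bo) are joined by a link, either way round."""
        flip = {"+": "-", "-": "+"}
        return (
            Link(a, ao, b, bo) in self.links
            or Link(b, flip[bo], a, flip[ao]) in self.links
        )

    def validate_path_links(self, path: Path) -> None:
        for (a, ao), (b, bo) in zip(path.steps, path.steps[1:]):
            if not self.has_link(a, ao, b, bo):
                raise GraphIntegrityError(
                    f"path {path.name!r}: steps {a}{ao} -> {b}{bo} not linked"
                )

    def stats(self) -> dict[str, int]:
        return {
            "segments": len(self.segments),
            "links": len(self.links),
            "paths": len(self.paths),
            "path_steps": sum(len(p.steps) for p in self.paths.values()),
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return (
            self.segments == other.segments
            and self.links == other.links
            and self.paths == other.paths
        )


# -- parsing ---------------------------------------------------------------

def _parse_tags(fields: Iterable[str], lineno: int) -> dict[str, str | int]:
    tags: dict[str, str | int] = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) != 3:
            raise GFAParseError(f"line {lineno}: malformed tag {f!r}")
        name, typ, value = parts
        if typ == "i":
            try:
                tags[name] = int(value)
            except ValueError as exc:
                raise GFAParseError(
                    f"line {lineno}: tag {name} not an integer: {value!r}"
                ) from exc
        else:
            tags[name] = value
    return tags


def _parse_oriented(token: str, lineno: int) -> tuple[str, str]:
    if len(token) < 2 or token[-1] not in "+-":
        raise GFAParseError(f"line {lineno}: malformed oriented segment {token!r}")
    return token[:-1], token[-1]


def _parse_walk(walk: str, lineno: int) -> list[tuple[str, str]]:
    """Parse a W-line walk string like ``>s1<s2`` into P-line style steps."""
    steps: list[tuple[str, str]] = []
    i = 0
    while i < len(walk):
        ch = walk[i]
        if ch not in "><":
            raise GFAParseError(f"line {lineno}: malformed walk at {walk[i:]!r}")
        j = i + 1
        while j < len(walk) and walk[j] not in "><":
            j += 1
        steps.append((walk[i + 1 : j], ">" if ch == ">" else "<"))
        i = j
    return [(sid, "+" if o == ">" else "-") for sid, o in steps]


def _open_text(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    data = open(source, "rb").read(2)
    if data == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(source, "rb"))
    return open(source, "rt")


def parse_gfa(source) -> Graph:
    """Parse GFA1/rGFA text into a :class:`Graph`.

    ``source`` may be a path (gzip-transparent) or an open text stream.
    S, L, P and W lines are interpreted; other line types are ignored.
    Links must be blunt (overlap ``0M`` or ``*``).
    """
    stream = _open_text(source)
    graph = Graph()
    pending_links: list[tuple[int, Link, str]] = []
    pending_paths: list[tuple[int, Path]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        kind = fields[0]
        if kind == "S":
            if len(fields) < 3:
                raise GFAParseError(f"line {lineno}: S line needs id and sequence")
            tags = _parse_tags(fields[3:], lineno)
            try:
                seg = Segment(
                    id=fields[1],
                    sequence=fields[2],
                    origin=tags.get("SN"),  # type: ignore[arg-type]
                    offset=tags.get("SO"),  # type: ignore[arg-type]
                    rank=tags.get("SR"),  # type: ignore[arg-type]
                )
            except ValueError as exc:
                raise GFAParseError(f"line {lineno}: {exc}") from exc
            graph.add_segment(seg)
        elif kind == "L":
            if len(fields) < 6:
                raise GFAParseError(f"line {lineno}: L line needs 5 fields")
            overlap = fields[5]
            if overlap not in ("0M", "*"):
                raise GFAParseError(
                    f"line {lineno}: only blunt links supported, got overlap {overlap!r}"
                )
            if fields[2] not in "+-" or fields[4] not in "+-":
                raise GFAParseError(f"line {lineno}: bad link orientation")
            pending_links.append(
                (lineno, Link(fields[1], fields[2], fields[3], fields[4]), overlap)
            )
        elif kind == "P":
            if len(fields) < 3:
                raise GFAParseError(f"line {lineno}: P line needs name and steps")
            steps = [
                _parse_oriented(tok, lineno) for tok in fields[2].split(",") if tok
            ]
            pending_paths.append((lineno, Path(fields[1], steps)))
        elif kind == "W":
            if len(fields) < 7:
                raise GFAParseError(f"line {lineno}: W line needs 6 fields")
            name = "#".join(fields[1:4])
            pending_paths.append((lineno, Path(name, _parse_walk(fields[6], lineno))))
        # H and unknown line types: preserved-but-ignored
    for lineno, link, _ in pending_links:
        try:
            graph.add_link(link)
        except GraphIntegrityError as exc:
            raise GraphIntegrityError(f"line {lineno}: {exc}") from exc
    for lineno, path in pending_paths:
        try:
            graph.add_path(path)
        except GraphIntegrityError as exc:
            raise GraphIntegrityError(f"line {lineno}: {exc}") from exc
    return graph


def write_gfa(graph: Graph, stream: TextIO | None = None) -> str:
    """Serialize a graph as GFA1 text in canonical order.

    Segments sorted by id, links lexicographically, paths by name, so that
    ``parse_gfa(write_gfa(g))`` reproduces ``g`` exactly.
    """
    out = stream if stream is not None else io.StringIO()
    out.write("H\tVN:Z:1.0\n")
    for sid in sorted(graph.segments):
        seg = graph.segments[sid]
        fields = ["S", seg.id, seg.sequence]
        if seg.origin is not None:
            fields.append(f"SN:Z:{seg.origin}")
        if seg.offset is not None:
            fields.append(f"SO:i:{seg.offset}")
        if seg.rank is not None:
            fields.append(f"SR:i:{seg.rank}")
        out.write("\t".join(fields) + "\n")
    for link in sorted(
        graph.links, key=lambda l: (l.from_id, l.from_orient, l.to_id, l.to_orient)
    ):
        out.write(
            f"L\t{link.from_id}\t{link.from_orient}\t{link.to_id}"
            f"\t{link.to_orient}\t0M\n"
        )
    for name in sorted(graph.paths):
        path = graph.paths[name]
        steps = ",".join(f"{sid}{o}" for sid, o in path.steps)
        out.write(f"P\t{name}\t{steps}\t*\n")
    if stream is None:
        return out.getvalue()  # type: ignore[union-attr]
    return ""


# -- path sequence and position indexing -----------------------------------

def path_sequence(graph: Graph, path: Path | str) -> str:
    """Concatenate step sequences along a path.

    Steps with ``-`` orientation contribute the reverse complement.
    """
    if isinstance(path, str):
        if path not in graph.paths:
            raise KeyError(f"unknown path {path!r}")
        path = graph.paths[path]
    parts: list[str] = []
    for sid, orient in path.steps:
        seg = graph.segments.get(sid)
        if seg is None:
            raise GraphIntegrityError(f"path step references missing segment {sid!r}")
        parts.append(seg.sequence if orient == "+" else reverse_complement(seg.sequence))
    return "".join(parts)


class PositionIndex:
    """Bidirectional path-position index.

    Maps a 0-based path coordinate to (step index, within-step offset) and a
    segment id to every (step index, path start coordinate, orientation)
    occurrence on the path — the machinery behind odgi-position-style
    coordinate translation between assembly paths.
    """

    def __init__(self, graph: Graph, path: Path):
        self.path_name = path.name
        self.steps = list(path.steps)
        starts: list[int] = []
        pos = 0
        occ: dict[str, list[tuple[int, int, str]]] = {}
        for i, (sid, orient) in enumerate(self.steps):
            seg = graph.segments.get(sid)
            if seg is None:
                raise GraphIntegrityError(
                    f"path {path.name!r} references missing segment {sid!r}"
                )
            starts.append(pos)
            occ.setdefault(sid, []).append((i, pos, orient))
            pos += len(seg)
        self._starts = starts
        self._lengths = [len(graph.segments[sid]) for sid, _ in self.steps]
        self._occurrences = occ
        self.total_length = pos

    def locate(self, coordinate: int) -> tuple[int, int]:
        """Path coordinate -> (step index, within-step offset)."""
        if not 0 <= coordinate < self.total_length:
            raise IndexError(
                f"coordinate {coordinate} outside path {self.path_name!r} "
                f"[0, {self.total_length})"
            )
        i = bisect_right(self._starts, coordinate) - 1
        return i, coordinate - self._starts[i]

    def coordinate(self, step_index: int, offset: int = 0) -> int:
        """(step index, within-step offset) -> path coordinate."""
        if not 0 <= step_index < len(self.steps):
            raise IndexError(f"step index {step_index} out of range")
        if not 0 <= offset < self._lengths[step_index]:
            raise IndexError(f"offset {offset} outside step {step_index}")
        return self._starts[step_index] + offset

    def step_start(self, step_index: int) -> int:
        return self._starts[step_index]

    def step_length(self, step_index: int) -> int:
        return self._lengths[step_index]

    def occurrences(self, segment_id: str) -> list[tuple[int, int, str]]:
        """Segment id -> list of (step index, path start coordinate, orientation)."""
        return list(self._occurrences.get(segment_id, []))


def build_position_index(graph: Graph, path_name: str) -> PositionIndex:
    if path_name not in graph.paths:
        raise KeyError(f"unknown path {path_name!r}")
    return PositionIndex(graph, graph.paths[path_name])
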