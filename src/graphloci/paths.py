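"""Assembly-path reconstruction for SV-level rGFA graphs.

SV-level graphs (minigraph-style) carry no P-lines of their own.  Each
assembly's walk can nevertheless be recovered from per-assembly bubble-call
records: the walk follows the rank-0 reference backbone and, inside each
bubble, substitutes the assembly's called traversal for the reference
interior.  A MISSING call (the assembly's route through the bubble is
unknown, e.g. the region is unassembled) breaks the path into fragments
rather than fabricating a route through the reference allele.

The call-record dialect is a TSV with columns
``chrom  start  end  source  sink  traversal`` where ``start``/``end`` are
0-based half-open reference coordinates of the bubble interior, ``source``/
``sink`` are the flanking backbone segment ids, and ``traversal`` is a
``>s1>s4``-style oriented walk (``.`` for MISSING, empty string for a
deletion allele that connects source directly to sink).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

from .gfa import Graph, GraphIntegrityError, Path

__all__ = [
    "BubbleCallRecord",
    "CongruenceReport",
    "BackboneError",
    "reference_backbone",
    "reconstruct_path",
    "congruence",
    "parse_calls",
    "write_calls",
]

MISSING = None


class BackboneError(ValueError):
    """Rank-0 segments do not tile the chromosome contiguously."""


@dataclass
class BubbleCallRecord:
    """One assembly's traversal of one reference-anchored bubble."""

    chrom: str
    start: int
    end: int
    source: str
    sink: str
    traversal: list[tuple[str, str]] | None  # None = MISSING

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"bubble start {self.start} > end {self.end}")

    @property
    def missing(self) -> bool:
        return self.traversal is None


@dataclass
class CongruenceReport:
    """Does an assembly's path traverse the nodes it contributed?"""

    assembly: str
    own_nodes: int
    untraversed_own_nodes: int
    warning: str | None = None

    @property
    def incongruence_rate(self) -> float:
        if self.own_nodes == 0:
            return 0.0
        return self.untraversed_own_nodes / self.own_nodes


def _format_traversal(traversal: list[tuple[str, str]] | None) -> str:
    if traversal is None:
        return "."
    if not traversal:
        return ""
    return "".join((">" if o == "+" else "<") + sid for sid, o in traversal)


def _parse_traversal(text: str) -> list[tuple[str, str]] | None:
    if text == ".":
        return None
    if text in ("", "*"):
        return []
    steps: list[tuple[str, str]] = []
    i = 0
    while i < len(text):
        if text[i] not in "><":
            raise ValueError(f"malformed traversal {text!r}")
        j = i + 1
        while j < len(text) and text[j] not in "><":
            j += 1
        steps.append((text[i + 1 : j], "+" if text[i] == ">" else "-"))
        i = j
    return steps


def parse_calls(stream: TextIO) -> list[BubbleCallRecord]:
    records = []
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"call record needs 6 columns: {line!r}")
        records.append(
            BubbleCallRecord(
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                source=fields[3],
                sink=fields[4],
                traversal=_parse_traversal(fields[5]),
            )
        )
    return records


def write_calls(records: Iterable[BubbleCallRecord], stream: TextIO) -> None:
    for r in records:
        stream.write(
            f"{r.chrom}\t{r.start}\t{r.end}\t{r.source}\t{r.sink}\t"
            f"{_format_traversal(r.traversal)}\n"
        )


def reference_backbone(graph: Graph, ref_label: str) -> Path:
    """Order the rank-0 segments of one reference contig into a path.

    Segments must carry rGFA SO offsets that tile the contig contiguously;
    the first discontinuity (gap or overlap) raises :class:`BackboneError`.
    """
    segs = [
        s
        for s in graph.segments.values()
        if s.rank == 0 and s.origin == ref_label
    ]
    if not segs:
        raise BackboneError(f"no rank-0 segments with origin {ref_label!r}")
    for s in segs:
        if s.offset is None:
            raise BackboneError(f"rank-0 segment {s.id!r} lacks an SO offset")
    segs.sort(key=lambda s: s.offset)  # type: ignore[arg-type, return-value]
    expected = segs[0].offset
    for s in segs:
        if s.offset != expected:
            kind = "gap" if s.offset > expected else "overlap"  # type: ignore[operator]
            raise BackboneError(
                f"backbone {kind} of {abs(s.offset - expected)} bp "  # type: ignore[operator]
                f"before segment {s.id!r} (expected offset {expected})"
            )
        expected += len(s)  # type: ignore[operator]
    return Path(name=ref_label, steps=[(s.id, "+") for s in segs])


def reconstruct_path(
    graph: Graph,
    backbone: Path,
    calls: list[BubbleCallRecord],
    assembly: str,
) -> list[Path]:
    """Rebuild an assembly's walk from its bubble calls.

    Walks the backbone; inside each called bubble the reference interior is
    replaced by the called traversal.  MISSING traversals close the current
    fragment at the bubble source and open a new one at the sink.  Returns
    fragments named ``<assembly>#frag<k>``.
    """
    step_index = {sid: i for i, (sid, _) in enumerate(backbone.steps)}
    ordered = sorted(calls, key=lambda c: c.start)
    prev_end = None
    for call in ordered:
        if prev_end is not None and call.start < prev_end:
            raise ValueError(
                f"overlapping bubble calls at {call.chrom}:{call.start}"
            )
        prev_end = call.end
        for name, sid in (("source", call.source), ("sink", call.sink)):
            if sid not in step_index:
                raise GraphIntegrityError(
                    f"bubble {name} segment {sid!r} not on the backbone"
                )
        if step_index[call.source] >= step_index[call.sink]:
            raise GraphIntegrityError(
                f"bubble source {call.source!r} not upstream of sink {call.sink!r} "
                "on the backbone (inverted bubbles are rejected)"
            )

    fragments: list[list[tuple[str, str]]] = []
    current: list[tuple[str, str]] = []
    cursor = 0  # next backbone step to emit

    def close_fragment() -> None:
        nonlocal current
        if current:
            fragments.append(current)
        current = []

    for call in ordered:
        src_i, sink_i = step_index[call.source], step_index[call.sink]
        current.extend(backbone.steps[cursor : src_i + 1])
        if call.missing:
            close_fragment()
        else:
            trav = call.traversal or []
            for sid, _ in trav:
                if sid not in graph.segments:
                    raise GraphIntegrityError(
                        f"traversal references missing segment {sid!r}"
                    )
            walk = [backbone.steps[src_i], *trav, backbone.steps[sink_i]]
            for (a, ao), (b, bo) in zip(walk, walk[1:]):
                if not graph.has_link(a, ao, b, bo):
                    raise GraphIntegrityError(
                        f"bubble traversal at {call.chrom}:{call.start} does not "
                        f"attach: {a}{ao} -> {b}{bo} not linked"
                    )
            current.extend(trav)
        cursor = sink_i
    current.extend(backbone.steps[cursor:])
    close_fragment()
    return [
        Path(name=f"{assembly}#frag{k}", steps=steps)
        for k, steps in enumerate(fragments)
    ]


def congruence(graph: Graph, paths: list[Path], assembly: str) -> CongruenceReport:
    """Count the assembly's own (rank > 0) nodes absent from its paths.

    Counts segment identity only, not traversal multiplicity.
    """
    own = {
        sid
        for sid, seg in graph.segments.items()
        if seg.origin == assembly and (seg.rank is None or seg.rank > 0)
    }
    traversed = {sid for p in paths for sid, _ in p.steps}
    untraversed = own - traversed
    warning = None
    if not own:
        warning = f"assembly {assembly!r} contributed no nodes; rate defined as 0"
    return CongruenceReport(
        assembly=assembly,
        own_nodes=len(own),
        untraversed_own_nodes=len(untraversed),
        warning=warning,
    )
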