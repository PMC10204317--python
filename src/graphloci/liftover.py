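"""Tandem-repeat catalogue filtering and graph-mediated coordinate liftover.

A TR catalogue (TRF-style, pre-parsed) is first filtered to loci with
motif length in [10, 100] bp and array length in [50 bp, 10 kb] that are
not covered >= 50% by any single repeat element (the per-pair semantics of
``bedtools intersect -v -f 0.5``).

Each retained reference interval is then translated into every assembly's
coordinate frame through the graph, by one of two routes:

* **exact** (base-level graphs, pggb/cactus style): both paths embed the
  locus, so the interval is re-anchored on segments shared between the
  reference and target paths — the odgi-position style of translation.
* **bubble** (SV-level graphs, minigraph style): only bubbles carry
  assembly coordinates, so the target interval is approximated from the
  called bubble traversal lengths plus the reference offsets of the TR
  relative to the bubble flanks.  Loci overlapping no bubble cannot be
  examined at all.

Anchors for exact translation are chosen strictly outside the repeat
interval and expanded outward up to ``flank`` bp when the nearest anchor
is repetitive on the target path: anchor segments inside a repeat array
recur on cyclic paths and produce the grossly mistranslated intervals
seen when lifting through tangled graph regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .gfa import Graph, PositionIndex
from .paths import BubbleCallRecord

__all__ = [
    "TRLocus",
    "LiftoverResult",
    "MIN_MOTIF",
    "MAX_MOTIF",
    "MIN_ARRAY",
    "MAX_ARRAY",
    "filter_tr_catalog",
    "translate_interval_exact",
    "translate_interval_bubble",
    "read_tr_catalog",
    "write_liftover_tsv",
]

MIN_MOTIF, MAX_MOTIF = 10, 100
MIN_ARRAY, MAX_ARRAY = 50, 10_000


@dataclass(frozen=True)
class TRLocus:
    """A reference tandem-repeat interval with its repeat motif."""

    chrom: str
    start: int
    end: int
    motif: str
    ref_copy_estimate: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class LiftoverResult:
    """Where one TR locus lands on one assembly's path.

    status: ``exact`` (unique shared anchors), ``anchored`` (chosen among
    candidates or approximated through bubbles), ``ambiguous`` (no single
    best placement), ``failed`` (anchor or bubble absent).  ``size_delta``
    is target length minus reference length; grossly inflated values
    diagnose mistranslation through repetitive anchors.
    """

    locus: TRLocus
    assembly: str
    status: str
    target_start: int | None = None
    target_end: int | None = None
    orientation: str = "+"
    anchors: dict = field(default_factory=dict)
    reason: str | None = None
    # bubble-mode splice plan: ('ref', start, end) and ('segs', [(id, orient), ...])
    splice_plan: list[tuple] | None = None

    def __post_init__(self) -> None:
        if self.status in ("exact", "anchored") and self.splice_plan is None:
            if self.target_start is None or self.target_end is None:
                raise ValueError(f"status {self.status} requires a target interval")
            if self.target_start >= self.target_end:
                raise ValueError("target interval must be non-empty")

    @property
    def ok(self) -> bool:
        return self.status in ("exact", "anchored")

    @property
    def target_length(self) -> int | None:
        if self.target_start is None or self.target_end is None:
            return None
        return self.target_end - self.target_start

    @property
    def size_delta(self) -> int | None:
        tl = self.target_length
        if tl is None:
            return None
        return tl - self.locus.length


# -- catalogue filtering ---------------------------------------------------

def filter_tr_catalog(
    trs: Iterable[TRLocus],
    repeat_elements: Sequence[tuple[str, int, int]] = (),
) -> tuple[list[TRLocus], dict[str, str]]:
    """Apply motif/array bounds and the single-feature 50% overlap exclusion.

    Returns (retained loci, rejection reason per rejected locus id).  A TR
    is excluded when any *single* repeat-element interval covers >= 50% of
    it — cumulative coverage by several smaller elements does not exclude.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in repeat_elements:
        by_chrom.setdefault(chrom, []).append((start, end))
    for ivs in by_chrom.values():
        ivs.sort()

    retained: list[TRLocus] = []
    rejected: dict[str, str] = {}
    for tr in trs:
        if not MIN_MOTIF <= len(tr.motif) <= MAX_MOTIF:
            rejected[tr.id] = f"motif length {len(tr.motif)} outside [{MIN_MOTIF}, {MAX_MOTIF}]"
            continue
        if not MIN_ARRAY <= tr.length <= MAX_ARRAY:
            rejected[tr.id] = f"array length {tr.length} outside [{MIN_ARRAY}, {MAX_ARRAY}]"
            continue
        hit = None
        for s, e in by_chrom.get(tr.chrom, []):
            if s >= tr.end:
                break
            overlap = min(e, tr.end) - max(s, tr.start)
            if overlap * 2 >= tr.length and overlap > 0:
                hit = (s, e, overlap)
                break
        if hit is not None:
            s, e, overlap = hit
            rejected[tr.id] = (
                f"repeat element {tr.chrom}:{s}-{e} covers "
                f"{100 * overlap / tr.length:.0f}% of locus"
            )
            continue
        retained.append(tr)
    return retained, rejected


# -- exact (path-position) translation -------------------------------------

def _anchor_candidates(
    ref_index: PositionIndex, boundary: int, flank: int, side: str
) -> list[tuple[int, int]]:
    """Backbone steps usable as anchors on one side of the locus.

    Returns (step index, signed reference distance from the anchor's
    alignment point to the boundary), nearest first.  ``side`` 'left'
    walks from the step containing ``boundary - 1`` outward to lower
    coordinates; 'right' from the step containing ``boundary`` upward.
    Candidates stop once the anchor's near edge is more than ``flank`` bp
    from the boundary.
    """
    candidates: list[tuple[int, int]] = []
    if side == "left":
        if boundary <= 0:
            return candidates
        step, _ = ref_index.locate(boundary - 1)
        while step >= 0:
            start = ref_index.step_start(step)
            near_edge = start + ref_index.step_length(step)  # anchor's right edge
            if boundary - near_edge > flank:
                break
            candidates.append((step, boundary - start))
            step -= 1
    else:
        if boundary >= ref_index.total_length:
            return candidates
        step, _ = ref_index.locate(boundary)
        while step < len(ref_index.steps):
            start = ref_index.step_start(step)
            if start - boundary > flank:
                break
            candidates.append((step, boundary - start))
            step += 1
    return candidates


def translate_interval_exact(
    graph: Graph,
    ref_index: PositionIndex,
    target_index: PositionIndex,
    locus: TRLocus,
    flank: int = 500,
) -> LiftoverResult:
    """Translate a reference interval onto another path via shared segments.

    The boundary positions are expressed as offsets within anchor segments
    on the reference path; the same offsets applied to the anchors'
    occurrences on the target path give the translated interval.  Among
    orientation-consistent anchor occurrence pairs the minimal positive
    span wins; a tie is ambiguous, a missing anchor is a failure.
    """
    assembly = target_index.path_name
    if locus.end > ref_index.total_length or locus.start < 0:
        raise ValueError(
            f"locus {locus.id} outside reference path [0, {ref_index.total_length})"
        )
    left = _anchor_candidates(ref_index, locus.start, flank, "left")
    right = _anchor_candidates(ref_index, locus.end, flank, "right")
    if not left or not right:
        return LiftoverResult(
            locus, assembly, "failed", reason="locus at path end; no flanking anchor"
        )

    def occurrences(cands):
        out = []
        for step, dist in cands:
            sid, ref_orient = ref_index.steps[step]
            occ = target_index.occurrences(sid)
            out.append((step, dist, sid, ref_orient, occ))
        return out

    left_occ = occurrences(left)
    right_occ = occurrences(right)
    if all(not occ for *_, occ in left_occ) or all(not occ for *_, occ in right_occ):
        return LiftoverResult(
            locus, assembly, "failed",
            reason="anchor segment absent from target path",
        )

    # nearest anchors with at least one target occurrence
    def first_present(cands):
        for entry in cands:
            if entry[4]:
                return entry
        return None

    lsel = first_present(left_occ)
    rsel = first_present(right_occ)
    assert lsel is not None and rsel is not None
    lstep, ldist, lsid, lrefo, loccs = lsel
    rstep, rdist, rsid, rrefo, roccs = rsel

    def project(dist, seg_len, ref_orient, occ_start, occ_orient):
        """Map a reference boundary (anchor start + dist along the reference
        path) onto the target path through one occurrence of the anchor."""
        if ref_orient == occ_orient:
            return occ_start + dist, "+"
        # anchor occurs flipped on target: offsets mirror within the segment
        return occ_start + seg_len - dist, "-"

    lseg_len = ref_index.step_length(lstep)
    rseg_len = ref_index.step_length(rstep)
    pairs = []
    for _, lo_start, lo_orient in loccs:
        lpos, lrel = project(ldist, lseg_len, lrefo, lo_start, lo_orient)
        for _, ro_start, ro_orient in roccs:
            rpos, rrel = project(rdist, rseg_len, rrefo, ro_start, ro_orient)
            if lrel != rrel:
                continue  # inconsistent relative orientation
            start, end = (lpos, rpos) if lrel == "+" else (rpos, lpos)
            if start < end:
                pairs.append((end - start, start, end, lrel))
    if not pairs:
        return LiftoverResult(
            locus, assembly, "failed",
            reason="no orientation-consistent anchor pair on target path",
        )
    pairs.sort()
    best = pairs[0]
    unique_anchors = len(loccs) == 1 and len(roccs) == 1
    exact_anchors = lstep == left[0][0] and rstep == right[0][0]
    if len(pairs) > 1 and pairs[1][0] == best[0]:
        return LiftoverResult(
            locus, assembly, "ambiguous",
            reason="multiple equally spanning anchor placements",
            anchors={"left": lsid, "right": rsid},
        )
    status = "exact" if (unique_anchors and exact_anchors) else "anchored"
    _, start, end, orient = best
    return LiftoverResult(
        locus,
        assembly,
        status,
        target_start=start,
        target_end=end,
        orientation=orient,
        anchors={
            "left": lsid,
            "right": rsid,
            "left_flank_used": max(0, locus.start - (ref_index.step_start(lstep) + lseg_len)),
            "right_flank_used": max(0, ref_index.step_start(rstep) - locus.end),
        },
    )


# -- bubble-anchored (SV-level) translation --------------------------------

def translate_interval_bubble(
    graph: Graph,
    backbone,
    calls: list[BubbleCallRecord],
    locus: TRLocus,
    assembly: str = "",
) -> LiftoverResult:
    """Approximate a TR interval on an assembly from its bubble calls.

    SV-level graphs expose assembly coordinates only at bubbles, so a TR
    is examinable only where it overlaps one: the reference interior of
    each spanned bubble is replaced by the called traversal, and flanking
    reference offsets carry over unchanged.  Several spanned bubbles are
    merged with the intervening reference.  The result is a splice plan
    (reference pieces + traversal segments) from which the target sequence
    and length follow; the coordinates are approximate by construction,
    hence at best status ``anchored``.
    """
    overlapping = sorted(
        (c for c in calls if c.chrom == locus.chrom and c.start < locus.end and c.end > locus.start),
        key=lambda c: c.start,
    )
    if not overlapping:
        return LiftoverResult(locus, assembly, "failed", reason="no bubble overlap")
    if any(c.missing for c in overlapping):
        return LiftoverResult(
            locus, assembly, "failed", reason="MISSING traversal in spanned bubble"
        )
    plan: list[tuple] = []
    target_len = 0
    cursor = min(locus.start, overlapping[0].start)
    span_start = cursor
    for call in overlapping:
        if call.start > cursor:
            plan.append(("ref", cursor, call.start))
            target_len += call.start - cursor
        trav = call.traversal or []
        plan.append(("segs", list(trav)))
        target_len += sum(len(graph.segments[sid]) for sid, _ in trav)
        cursor = call.end
    span_end = max(locus.end, cursor)
    if span_end > cursor:
        plan.append(("ref", cursor, span_end))
        target_len += span_end - cursor
    # trim the plan's reference overhang back to the locus itself: the TR may
    # start after span_start / end before span_end only within ref pieces
    lead = locus.start - span_start
    tail = span_end - locus.end
    target_start = lead
    target_end = target_len - tail
    if target_start >= target_end:
        return LiftoverResult(
            locus, assembly, "failed", reason="deletion allele removes the locus"
        )
    status = "anchored"
    return LiftoverResult(
        locus,
        assembly,
        status,
        target_start=target_start,
        target_end=target_end,
        anchors={
            "bubbles": [(c.start, c.end) for c in overlapping],
            "span": (span_start, span_end),
        },
        splice_plan=plan,
    )


def splice_sequence(graph: Graph, ref_sequence: str, result: LiftoverResult) -> str:
    """Materialize the target subsequence of a bubble-anchored liftover."""
    if result.splice_plan is None:
        raise ValueError("result has no splice plan (not a bubble liftover)")
    from .gfa import reverse_complement

    parts: list[str] = []
    for piece in result.splice_plan:
        if piece[0] == "ref":
            _, s, e = piece
            parts.append(ref_sequence[s:e])
        else:
            for sid, orient in piece[1]:
                seq = graph.segments[sid].sequence
                parts.append(seq if orient == "+" else reverse_complement(seq))
    full = "".join(parts)
    return full[result.target_start : result.target_end]


# -- I/O -------------------------------------------------------------------

def read_tr_catalog(stream: TextIO) -> list[TRLocus]:
    """TSV: chrom, start, end, motif[, copy_estimate]."""
    loci = []
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        copy = float(fields[4]) if len(fields) > 4 else 0.0
        loci.append(
            TRLocus(fields[0], int(fields[1]), int(fields[2]), fields[3].upper(), copy)
        )
    return loci


def write_liftover_tsv(results: Iterable[LiftoverResult], stream: TextIO) -> None:
    stream.write("locus\tassembly\ttarget_start\ttarget_end\tstatus\tsize_delta\n")
    for r in results:
        ts = "" if r.target_start is None else r.target_start
        te = "" if r.target_end is None else r.target_end
        sd = "" if r.size_delta is None else r.size_delta
        stream.write(f"{r.locus.id}\t{r.assembly}\t{ts}\t{te}\t{r.status}\t{sd}\n")
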