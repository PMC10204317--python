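"""Bounded-error repeat-motif counting and per-locus genotyping.

Copy numbers are counted by scanning the lifted per-assembly sequence for
non-overlapping occurrences of the repeat motif, each occurrence allowed
an edit-distance budget of ``floor(max_error_rate * |motif|)`` —
substitutions, insertions and deletions between repeat units are expected
in real arrays, and a 25% per-unit error rate absorbs them without
collapsing distinct motifs.

The scan is greedy left-to-right: at each position the shortest window
matching the motif within budget is taken (ties cannot arise — windows at
one start differ in length), the counter increments, and the scan resumes
after the matched window; with no match the scan advances one base.  This
makes the count deterministic and monotone: appending one clean motif
copy to any sequence adds exactly one occurrence.

A locus is *genotypable* when every assembly has a resolvable path through
the local graph (liftover status exact or anchored), and a *VNTR* when it
is genotypable and at least one assembly's count differs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gfa import Graph, PositionIndex, path_sequence, reverse_complement
from .liftover import LiftoverResult, TRLocus, splice_sequence

__all__ = [
    "MotifMatchParams",
    "TRGenotype",
    "count_motif",
    "motif_is_degenerate",
    "genotype_locus",
]

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class MotifMatchParams:
    """Error model for motif occurrence matching.

    ``max_error_rate`` is the tolerated edit fraction per occurrence; the
    per-occurrence budget is ``floor(rate * |motif|)`` edits.  Occurrences
    never overlap.
    """

    max_error_rate: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.max_error_rate < 0.5:
            raise ValueError("max_error_rate must be in [0, 0.5)")

    def budget(self, motif: str) -> int:
        return math.floor(self.max_error_rate * len(motif))


@dataclass
class TRGenotype:
    """Per-assembly copy counts at one TR locus."""

    locus: TRLocus
    counts: dict[str, int | None] = field(default_factory=dict)  # None = no-call
    statuses: dict[str, str] = field(default_factory=dict)

    @property
    def genotypable(self) -> bool:
        return bool(self.statuses) and all(
            s in ("exact", "anchored") for s in self.statuses.values()
        )

    @property
    def is_vntr(self) -> bool:
        if not self.genotypable:
            return False
        values = {c for c in self.counts.values() if c is not None}
        return len(values) >= 2


def _shortest_match(seq_codes: np.ndarray, motif_codes: np.ndarray, budget: int) -> int | None:
    """Length of the shortest prefix of ``seq_codes`` within edit distance
    ``budget`` of the motif, or None.

    One DP over the motif (rows) x window prefix (columns) rectangle; the
    final row holds dist(motif, window[:w]) for every w, so the smallest
    admissible w falls out directly.  The window need never exceed
    |motif| + budget (longer prefixes cost more than budget deletions).
    """
    m = len(motif_codes)
    wmax = min(len(seq_codes), m + budget)
    if wmax < m - budget:
        return None
    window = seq_codes[:wmax]
    j_idx = np.arange(wmax + 1, dtype=np.int32)
    prev = j_idx.copy()  # dist("", window[:j])
    cur = np.empty(wmax + 1, dtype=np.int32)
    for i in range(1, m + 1):
        cur[0] = i
        # substitution / match and deletion of a window base
        cur[1:] = np.minimum(
            prev[:-1] + (window != motif_codes[i - 1]), prev[1:] + 1
        )
        # insertion relaxation cur[j] <= cur[j-1] + 1, via prefix-min trick
        cur[:] = np.minimum.accumulate(cur - j_idx) + j_idx
        prev, cur = cur, prev
    hits = np.nonzero(prev <= budget)[0]
    for w in hits:
        if w >= 1:
            return int(w)
    return None


_ENCODE = {c: i for i, c in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    # sequence N -> 8, motif N -> 9 (see count_motif): N never matches anything
    return np.array([_ENCODE.get(c, 8) for c in seq], dtype=np.int8)


def count_motif(sequence: str, motif: str, params: MotifMatchParams | None = None) -> int:
    """Count non-overlapping motif occurrences within the edit budget."""
    params = params or MotifMatchParams()
    sequence = sequence.upper()
    motif = motif.upper()
    if not motif:
        raise ValueError("motif must be non-empty")
    bad = (set(sequence) | set(motif)) - _VALID
    if bad:
        raise ValueError(f"non-ACGTN characters: {sorted(bad)}")
    budget = params.budget(motif)
    seq_codes = _encode(sequence)
    motif_codes = np.array([_ENCODE.get(c, 9) for c in motif], dtype=np.int8)
    count = 0
    i = 0
    n = len(sequence)
    min_w = max(1, len(motif) - budget)
    while i + min_w <= n:
        w = _shortest_match(seq_codes[i:], motif_codes, budget)
        if w is None:
            i += 1
        else:
            count += 1
            i += w
    return count


def motif_is_degenerate(motif: str, params: MotifMatchParams | None = None) -> bool:
    """True when the motif is approximately periodic with period < |motif|/2.

    Checked as the Hamming distance between the motif and its rotations by
    less than half its length: an AT-repeat rotated by its period is
    identical, while a random motif mismatches about three quarters of its
    positions.  (Edit distance is useless here: any string is within
    ``2*s`` edits of its own shift by ``s``.)  Degenerate motifs make
    occurrence boundaries ill-defined; counts on them are reported but
    should be flagged.
    """
    params = params or MotifMatchParams()
    budget = params.budget(motif)
    m = len(motif)
    doubled = motif + motif
    for shift in range(1, (m + 1) // 2):
        rotated = doubled[shift : shift + m]
        hamming = sum(a != b for a, b in zip(motif, rotated))
        if hamming <= budget:
            return True
    return False


def _edit_distance(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def genotype_locus(
    graph: Graph,
    locus: TRLocus,
    liftovers: list[LiftoverResult],
    params: MotifMatchParams | None = None,
    ref_sequence: str | None = None,
) -> TRGenotype:
    """Count motif copies on every assembly with a resolved liftover.

    Exact liftovers slice the target path sequence (reverse-complemented
    back to the reference strand when the locus lifted over inverted);
    bubble liftovers splice reference flanks with traversal segments.
    Failed or ambiguous liftovers become no-calls.
    """
    params = params or MotifMatchParams()
    genotype = TRGenotype(locus=locus)
    for res in liftovers:
        genotype.statuses[res.assembly] = res.status
        if not res.ok:
            genotype.counts[res.assembly] = None
            continue
        if res.splice_plan is not None:
            if ref_sequence is None:
                raise ValueError("bubble liftovers need the reference sequence")
            seq = splice_sequence(graph, ref_sequence, res)
        else:
            full = path_sequence(graph, res.assembly)
            seq = full[res.target_start : res.target_end]
            if res.orientation == "-":
                seq = reverse_complement(seq)
        genotype.counts[res.assembly] = count_motif(seq, locus.motif, params)
    return genotype
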