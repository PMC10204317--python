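"""Deterministic synthetic reference/assembly/graph generator with truth.

Emulates the study design of assembly-based pangenome analysis at desk
scale: a random reference chromosome with planted tandem-repeat arrays,
plus pseudo-assemblies derived from it by imposing known variation — TR
copy-number changes, SNPs, small indels and structural variants — so that
every downstream stage (graph construction, path reconstruction, region
classification, liftover, genotyping) can be checked against exact truth.

Variants are planted non-overlapping within and across assemblies and at
least 1 kb from chromosome ends, so graph construction is exact
bookkeeping rather than alignment: each variant becomes one bubble whose
breakpoints are shared by all paths.  Two graph flavours are built from
the same truth:

* **base** level: one bubble per planted variant of any size; each
  assembly gets a true P-line and the graph losslessly re-encodes every
  assembly sequence (pggb/cactus style);
* **sv** level: bubbles only for variants whose allele lengths differ by
  >= 50 bp, plus per-assembly bubble-call records (minigraph style);
  sub-50 bp variation is deliberately invisible in this flavour.

TR arrays are ``motif x count`` with optional per-unit substitution noise
kept below the counting error budget, so planted copy numbers remain the
unambiguous truth for the counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .gfa import Graph, Link, Path, Segment
from .genotype import MotifMatchParams, count_motif, motif_is_degenerate
from .liftover import TRLocus
from .paths import BubbleCallRecord

__all__ = [
    "SimulationSpec",
    "AssemblyPlan",
    "PlantedVariant",
    "TruthSet",
    "default_spec",
    "simulate",
    "build_graph",
    "SV_THRESHOLD",
]

SV_THRESHOLD = 50  # bp; allele-length difference that forms an SV-level bubble
_EDGE_MARGIN = 1_000  # planted features stay this far from chromosome ends
_FEATURE_GAP = 10  # minimum bp between planted features (keeps bubbles apart)
_BASES = np.array(list("ACGT"))


@dataclass
class AssemblyPlan:
    """Edit plan for one pseudo-assembly, in reference coordinates."""

    name: str
    snp_count: int = 40
    small_indel_count: int = 8
    sv_insertion_count: int = 2
    sv_deletion_count: int = 2
    small_indel_max: int = 20
    sv_size_range: tuple[int, int] = (50, 300)
    motif_noise_rate: float = 0.2  # per-unit probability of one substitution
    tr_change_prob: float = 0.65  # per-locus probability of a copy-number delta


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic chromosome.

    Defaults are the desk-scale conditions used throughout the test
    suite: one 200 kb chromosome, five assemblies, twenty TR loci with
    reference copy numbers 4-60, seed 7.
    """

    seed: int = 7
    chrom: str = "chr1"
    chrom_length: int = 200_000
    n_tr_loci: int = 20
    motif_length_range: tuple[int, int] = (10, 24)
    ref_copy_range: tuple[int, int] = (4, 60)
    assemblies: list[AssemblyPlan] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.assemblies:
            self.assemblies = [AssemblyPlan(name=f"asm{c}") for c in "ABCDE"]


@dataclass
class PlantedVariant:
    """A replacement edit: reference [start, end) becomes ``alt``."""

    kind: str  # snp | ins | del | tr
    start: int
    end: int
    alt: str
    assembly: str
    tr_index: int | None = None

    @property
    def size_delta(self) -> int:
        return len(self.alt) - (self.end - self.start)

    @property
    def is_sv(self) -> bool:
        return abs(self.size_delta) >= SV_THRESHOLD


@dataclass
class TruthSet:
    """Complete ground truth of one simulation."""

    spec: SimulationSpec
    reference: str
    assemblies: dict[str, str]
    variants: dict[str, list[PlantedVariant]]  # per assembly, sorted by start
    tr_loci: list[TRLocus]  # reference-frame catalogue (copy estimate = truth)
    tr_counts: dict[str, dict[str, int]]  # locus id -> assembly -> true count
    tr_intervals: dict[str, dict[str, tuple[int, int]]]  # assembly-frame arrays

    @property
    def assembly_names(self) -> list[str]:
        return [p.name for p in self.spec.assemblies]


def default_spec(seed: int = 7) -> SimulationSpec:
    return SimulationSpec(seed=seed)


# -- simulation ------------------------------------------------------------

def _random_motif(rng: np.random.Generator, length: int) -> str:
    params = MotifMatchParams()
    for _ in range(100):
        motif = "".join(rng.choice(_BASES, size=length))
        # non-degenerate and operationally clean: a pure array counts exactly
        if not motif_is_degenerate(motif, params) and count_motif(motif * 5, motif, params) == 5:
            return motif
    raise RuntimeError("could not draw a non-degenerate motif")


def _noisy_array(rng: np.random.Generator, motif: str, count: int, rate: float) -> str:
    """``count`` units, each with at most one mid-unit substitution.

    Edits stay away from unit boundaries and well inside the 25% counting
    budget, so the planted copy number is recoverable exactly.
    """
    m = len(motif)
    units = []
    for _ in range(count):
        unit = motif
        if rate > 0 and rng.random() < rate:
            pos = int(rng.integers(2, m - 2))
            old = unit[pos]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            unit = unit[:pos] + new + unit[pos + 1 :]
        units.append(unit)
    return "".join(units)


class _Placer:
    """Non-overlapping feature placement with a minimum inter-feature gap."""

    def __init__(self, rng: np.random.Generator, chrom_length: int):
        self.rng = rng
        self.length = chrom_length
        self.occupied: list[tuple[int, int]] = []

    def place(self, feature_length: int) -> int:
        lo = _EDGE_MARGIN
        hi = self.length - _EDGE_MARGIN - max(feature_length, 1)
        if hi <= lo:
            raise ValueError("chromosome too short for the requested features")
        for _ in range(2_000):
            start = int(self.rng.integers(lo, hi))
            end = start + max(feature_length, 1)
            if all(
                end + _FEATURE_GAP <= s or e + _FEATURE_GAP <= start
                for s, e in self.occupied
            ):
                self.occupied.append((start, end))
                return start
        raise ValueError("could not place feature without overlap; reduce density")


def _draw_tr_delta(
    rng: np.random.Generator, motif_len: int, ref_count: int, change_prob: float
) -> int:
    """TR copy-number change for one assembly at one locus.

    Mix of: no change, +/-1 unit (sub-SV, invisible at SV level), and an
    SV-sized change of at least ceil(50/|motif|) units.
    """
    r = rng.random()
    if r >= change_prob:
        return 0
    if r < change_prob * 0.23:
        return int(rng.choice([-1, 1])) if ref_count > 2 else 1
    sv_units = -(-SV_THRESHOLD // motif_len)  # ceil
    magnitude = int(rng.integers(sv_units, sv_units + 7))
    if rng.random() < 0.5 and ref_count - magnitude >= 1:
        return -magnitude
    return magnitude


def simulate(spec: SimulationSpec) -> TruthSet:
    """Generate reference, assemblies and complete truth, deterministically."""
    rng = np.random.default_rng(spec.seed)
    placer = _Placer(rng, spec.chrom_length)

    # reference TR catalogue
    loci_plan: list[tuple[int, str, int]] = []  # (start, motif, ref_count)
    for _ in range(spec.n_tr_loci):
        mlen = int(rng.integers(spec.motif_length_range[0], spec.motif_length_range[1] + 1))
        motif = _random_motif(rng, mlen)
        count = int(rng.integers(spec.ref_copy_range[0], spec.ref_copy_range[1] + 1))
        start = placer.place(mlen * count)
        loci_plan.append((start, motif, count))
    loci_plan.sort()

    # reference sequence with planted clean arrays
    ref = rng.choice(_BASES, size=spec.chrom_length)
    for start, motif, count in loci_plan:
        array = np.array(list(motif * count))
        ref[start : start + len(array)] = array
    reference = "".join(ref)

    tr_loci = [
        TRLocus(spec.chrom, start, start + len(motif) * count, motif, float(count))
        for start, motif, count in loci_plan
    ]

    # per-assembly edit plans
    variants: dict[str, list[PlantedVariant]] = {}
    tr_counts: dict[str, dict[str, int]] = {t.id: {} for t in tr_loci}
    for plan in spec.assemblies:
        edits: list[PlantedVariant] = []
        for idx, locus in enumerate(tr_loci):
            ref_count = int(locus.ref_copy_estimate)
            delta = _draw_tr_delta(
                rng, len(locus.motif), ref_count, plan.tr_change_prob
            )
            count = ref_count + delta
            tr_counts[locus.id][plan.name] = count
            noisy = plan.motif_noise_rate > 0 and rng.random() < 0.8
            if delta == 0 and not noisy:
                continue  # assembly keeps the reference allele verbatim
            alt = _noisy_array(
                rng, locus.motif, count, plan.motif_noise_rate if noisy else 0.0
            )
            edits.append(
                PlantedVariant("tr", locus.start, locus.end, alt, plan.name, idx)
            )
        for _ in range(plan.snp_count):
            pos = placer.place(1)
            old = reference[pos]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            edits.append(PlantedVariant("snp", pos, pos + 1, new, plan.name))
        for _ in range(plan.small_indel_count):
            size = int(rng.integers(1, plan.small_indel_max + 1))
            if rng.random() < 0.5:
                pos = placer.place(0)
                ins = "".join(rng.choice(_BASES, size=size))
                edits.append(PlantedVariant("ins", pos, pos, ins, plan.name))
            else:
                pos = placer.place(size)
                edits.append(PlantedVariant("del", pos, pos + size, "", plan.name))
        lo, hi = plan.sv_size_range
        for _ in range(plan.sv_insertion_count):
            size = int(rng.integers(lo, hi + 1))
            pos = placer.place(0)
            ins = "".join(rng.choice(_BASES, size=size))
            edits.append(PlantedVariant("ins", pos, pos, ins, plan.name))
        for _ in range(plan.sv_deletion_count):
            size = int(rng.integers(lo, hi + 1))
            pos = placer.place(size)
            edits.append(PlantedVariant("del", pos, pos + size, "", plan.name))
        edits.sort(key=lambda v: (v.start, v.end))
        variants[plan.name] = edits

    # materialize assembly sequences and assembly-frame TR intervals
    assemblies: dict[str, str] = {}
    tr_intervals: dict[str, dict[str, tuple[int, int]]] = {t.id: {} for t in tr_loci}
    for plan in spec.assemblies:
        parts: list[str] = []
        cursor = 0
        for v in variants[plan.name]:
            parts.append(reference[cursor : v.start])
            parts.append(v.alt)
            cursor = v.end
        parts.append(reference[cursor:])
        assemblies[plan.name] = "".join(parts)
        for locus in tr_loci:
            shift = sum(
                v.size_delta for v in variants[plan.name] if v.end <= locus.start
            )
            own = next(
                (
                    v
                    for v in variants[plan.name]
                    if v.kind == "tr" and v.start == locus.start
                ),
                None,
            )
            length = len(own.alt) if own is not None else locus.length
            tr_intervals[locus.id][plan.name] = (
                locus.start + shift,
                locus.start + shift + length,
            )

    truth = TruthSet(
        spec=spec,
        reference=reference,
        assemblies=assemblies,
        variants=variants,
        tr_loci=tr_loci,
        tr_counts=tr_counts,
        tr_intervals=tr_intervals,
    )
    _verify_truth(truth)
    return truth


def _verify_truth(truth: TruthSet) -> None:
    """Internal invariant: replaying each edit plan reproduces the assembly."""
    for name, seq in truth.assemblies.items():
        expected_len = len(truth.reference) + sum(
            v.size_delta for v in truth.variants[name]
        )
        if len(seq) != expected_len:
            raise AssertionError(f"assembly {name}: edit bookkeeping broken")
        for locus in truth.tr_loci:
            s, e = truth.tr_intervals[locus.id][name]
            if not 0 <= s < e <= len(seq):
                raise AssertionError(f"TR interval out of range for {name}")


# -- graph construction ----------------------------------------------------

def build_graph(
    truth: TruthSet, level: str = "base", ref_label: str = "ref"
) -> tuple[Graph, dict[str, list[BubbleCallRecord]]]:
    """Build a pangenome graph (and SV-level call records) from truth.

    ``level='base'`` includes every planted variant as a bubble and adds a
    true P-line per assembly (lossless).  ``level='sv'`` includes only
    variants with allele-length difference >= 50 bp and returns truthful
    per-assembly :class:`BubbleCallRecord` lists instead of relying on the
    graph's own paths.
    """
    if level not in ("base", "sv"):
        raise ValueError("level must be 'base' or 'sv'")
    chrom = truth.spec.chrom
    selected: list[PlantedVariant] = []
    for name in truth.assembly_names:
        for v in truth.variants[name]:
            if level == "base" or v.is_sv:
                selected.append(v)
    selected.sort(key=lambda v: (v.start, v.end, v.assembly))

    breakpoints = sorted({0, len(truth.reference), *(v.start for v in selected), *(v.end for v in selected)})
    graph = Graph()
    ref_pieces: list[tuple[int, int, str]] = []  # (start, end, segment id)
    for i, (lo, hi) in enumerate(zip(breakpoints, breakpoints[1:])):
        sid = f"r{i}"
        graph.add_segment(
            Segment(sid, truth.reference[lo:hi], origin=ref_label, offset=lo, rank=0)
        )
        ref_pieces.append((lo, hi, sid))
    for a, b in zip(ref_pieces, ref_pieces[1:]):
        graph.add_link(Link(a[2], "+", b[2], "+"))

    piece_ending_at = {end: sid for _, end, sid in ref_pieces}
    piece_starting_at = {start: sid for start, _, sid in ref_pieces}
    interior = {
        (s, e): [sid for ps, pe, sid in ref_pieces if s <= ps and pe <= e]
        for s, e in {(v.start, v.end) for v in selected}
    }

    alt_segment: dict[int, str | None] = {}
    for k, v in enumerate(selected):
        if not v.alt:
            alt_segment[k] = None
            graph.add_link(
                Link(piece_ending_at[v.start], "+", piece_starting_at[v.end], "+")
            )
            continue
        sid = f"v{k}"
        graph.add_segment(Segment(sid, v.alt, origin=v.assembly, rank=1))
        graph.add_link(Link(piece_ending_at[v.start], "+", sid, "+"))
        graph.add_link(Link(sid, "+", piece_starting_at[v.end], "+"))
        alt_segment[k] = sid

    # reference path over all pieces
    ref_path = Path(ref_label, [(sid, "+") for _, _, sid in ref_pieces])
    graph.add_path(ref_path)

    variant_index = {(v.assembly, v.start, v.end): k for k, v in enumerate(selected)}

    # per-assembly paths: walk pieces, substituting the assembly's own bubbles
    for name in truth.assembly_names:
        own = [
            v
            for v in truth.variants[name]
            if (name, v.start, v.end) in variant_index
        ]
        steps: list[tuple[str, str]] = []
        cursor = 0
        pi = 0
        for v in own:
            while ref_pieces[pi][1] <= v.start:
                steps.append((ref_pieces[pi][2], "+"))
                pi += 1
            k = variant_index[(name, v.start, v.end)]
            if alt_segment[k] is not None:
                steps.append((alt_segment[k], "+"))
            while pi < len(ref_pieces) and ref_pieces[pi][1] <= v.end:
                pi += 1
        steps.extend((sid, "+") for _, _, sid in ref_pieces[pi:])
        graph.add_path(Path(name, steps))

    calls: dict[str, list[BubbleCallRecord]] = {n: [] for n in truth.assembly_names}
    if level == "sv":
        # variants from different assemblies at one interval form a single
        # multi-allelic bubble: one call record per assembly per interval
        owners: dict[tuple[int, int], dict[str, int]] = {}
        for k, v in enumerate(selected):
            owners.setdefault((v.start, v.end), {})[v.assembly] = k
        for (s, e), by_assembly in sorted(owners.items()):
            src = piece_ending_at[s]
            snk = piece_starting_at[e]
            for name in truth.assembly_names:
                if name in by_assembly:
                    sid = alt_segment[by_assembly[name]]
                    trav = [] if sid is None else [(sid, "+")]
                else:
                    trav = [(pid, "+") for pid in interior[(s, e)]]
                calls[name].append(BubbleCallRecord(chrom, s, e, src, snk, trav))
        for recs in calls.values():
            recs.sort(key=lambda c: c.start)
    return graph, calls


# -- plain-text export -----------------------------------------------------

def write_fasta(sequences: dict[str, str], stream, width: int = 80) -> None:
    for name, seq in sequences.items():
        stream.write(f">{name}\n")
        for i in range(0, len(seq), width):
            stream.write(seq[i : i + width] + "\n")


def write_truth_counts(truth: TruthSet, stream) -> None:
    names = truth.assembly_names
    stream.write("locus\tmotif\tref_count\t" + "\t".join(names) + "\n")
    for locus in truth.tr_loci:
        counts = truth.tr_counts[locus.id]
        stream.write(
            f"{locus.id}\t{locus.motif}\t{int(locus.ref_copy_estimate)}\t"
            + "\t".join(str(counts[n]) for n in names)
            + "\n"
        )
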