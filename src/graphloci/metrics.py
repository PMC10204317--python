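"""Cross-method concordance statistics, count-derived trees, graph-alignment
summaries and the allelic-imbalance exact binomial test.

Copy-number matrices from different pangenome methods (rows = loci,
columns = assemblies, NaN = missing) are compared three ways: locus-level
agreement categories (identical counts in all methods / in at least two /
in none), per-assembly squared Pearson and Spearman correlations, and
neighbour-joining trees built from pairwise Manhattan distances of the
count vectors — assemblies with similar repeat-length profiles cluster
together, recapitulating their phylogeny.

GAF (graph alignment format) records are summarized into an edit rate
(total edit distance over total aligned block length) and a query
coverage (aligned query bases over total query length; > 100% signals
multiple equally scored alignments).

Allelic imbalance at a heterozygous site is tested with the exact
two-sided binomial test against a 50:50 null, the same minlike rule as R's
``binom.test``: the p-value sums the probabilities of all outcomes no more
likely than the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, TextIO

import numpy as np
import pandas as pd
from scipy import stats

from .regions import RegionPartition, annotate_point

__all__ = [
    "GafRecord",
    "AgreementSummary",
    "GafSummary",
    "agreement_summary",
    "correlation",
    "count_tree",
    "parse_gaf",
    "gaf_summary",
    "binom_imbalance",
]


# -- count-matrix concordance ----------------------------------------------

@dataclass
class AgreementSummary:
    """Locus agreement categories over commonly genotyped loci."""

    n_common: int
    identical_in_all: int
    identical_in_at_least_two: int
    identical_in_none: int

    def as_dict(self) -> dict[str, int]:
        return {
            "common_loci": self.n_common,
            "identical_in_all": self.identical_in_all,
            "identical_in_at_least_two": self.identical_in_at_least_two,
            "identical_in_none": self.identical_in_none,
        }


def _common_complete(matrices: Mapping[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Restrict all matrices to shared loci/assemblies with no missing value."""
    methods = list(matrices)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    loci = matrices[methods[0]].index
    cols = matrices[methods[0]].columns
    for m in methods[1:]:
        loci = loci.intersection(matrices[m].index)
        cols = cols.intersection(matrices[m].columns)
    sub = {m: matrices[m].loc[loci, cols] for m in methods}
    complete = pd.Series(True, index=loci)
    for m in methods:
        complete &= sub[m].notna().all(axis=1)
    return {m: sub[m].loc[complete] for m in methods}


def agreement_summary(matrices: Mapping[str, pd.DataFrame]) -> AgreementSummary:
    """Categorize loci by cross-method count identity.

    A locus is *identical* for a method pair iff every assembly's counts
    match exactly.  Only loci genotyped (non-missing) by every method in
    every assembly enter the categories.
    """
    sub = _common_complete(matrices)
    methods = list(sub)
    n = len(next(iter(sub.values())))
    if n == 0:
        return AgreementSummary(0, 0, 0, 0)
    pair_identical = []
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            pair_identical.append((sub[a] == sub[b]).all(axis=1))
    agree = pd.concat(pair_identical, axis=1)
    n_pairs_agree = agree.sum(axis=1)
    in_all = int((n_pairs_agree == agree.shape[1]).sum())
    in_two = int((n_pairs_agree >= 1).sum())
    return AgreementSummary(
        n_common=n,
        identical_in_all=in_all,
        identical_in_at_least_two=in_two,
        identical_in_none=n - in_two,
    )


def correlation(x, y, kind: str = "pearson") -> float:
    """Squared Pearson or Spearman correlation with pairwise deletion.

    Spearman uses average ranks for ties.  Constant vectors have no
    defined correlation and raise rather than returning 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired non-missing values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    if kind == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif kind == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown correlation kind {kind!r}")
    return float(r**2)


def count_tree(matrix: pd.DataFrame) -> str:
    """Neighbour-joining Newick tree from assembly count vectors.

    Distance between two assemblies is the Manhattan distance of their
    count vectors over loci genotyped in both, divided by the number of
    shared loci.  Assemblies are processed in name order (deterministic
    tie-breaking); all-missing assemblies are dropped with a warning;
    negative NJ branch lengths are clamped to zero.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    cols = sorted(matrix.columns)
    usable = []
    for c in cols:
        if matrix[c].notna().any():
            usable.append(c)
        else:
            warnings.warn(f"assembly {c!r} has no counts; excluded from tree")
    if len(usable) < 3:
        raise ValueError("need at least 3 assemblies with counts")
    k = len(usable)
    dm = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a = matrix[usable[i]].to_numpy(dtype=float)
            b = matrix[usable[j]].to_numpy(dtype=float)
            keep = ~(np.isnan(a) | np.isnan(b))
            if not keep.any():
                raise ValueError(
                    f"assemblies {usable[i]!r} and {usable[j]!r} share no loci"
                )
            d = np.abs(a[keep] - b[keep]).sum() / keep.sum()
            dm[i, j] = dm[j, i] = d
    tree = nj(DistanceMatrix(dm, ids=usable))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


# -- GAF summaries ---------------------------------------------------------

@dataclass
class GafRecord:
    """One graph-alignment record (GAF line)."""

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    path: str = "*"
    matches: int = 0
    block_length: int = 0
    edit_distance: int | None = None  # NM tag

    def __post_init__(self) -> None:
        if not 0 <= self.query_start <= self.query_end <= self.query_length:
            raise ValueError(
                f"bad query interval {self.query_start}-{self.query_end} "
                f"on {self.query_name!r} (length {self.query_length})"
            )
        if self.matches > self.block_length:
            raise ValueError("residue matches exceed alignment block length")


@dataclass
class GafSummary:
    """Edit rate and query coverage for one group of GAF records."""

    n_records: int
    total_block: int
    total_edit: int
    aligned_query_bases: int
    total_query_bases: int
    records_without_nm: int = 0

    @property
    def edit_rate(self) -> float:
        return self.total_edit / self.total_block if self.total_block else 0.0

    @property
    def query_coverage(self) -> float:
        if self.total_query_bases == 0:
            return 0.0
        return self.aligned_query_bases / self.total_query_bases


def parse_gaf(stream: TextIO) -> list[GafRecord]:
    records = []
    for raw in stream:
        line = raw.rstrip("\n")
        if not line:
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ValueError(f"GAF record needs >= 12 columns: {line!r}")
        nm = None
        for tag in f[12:]:
            if tag.startswith("NM:i:"):
                nm = int(tag[5:])
        records.append(
            GafRecord(
                query_name=f[0],
                query_length=int(f[1]),
                query_start=int(f[2]),
                query_end=int(f[3]),
                path=f[5],
                matches=int(f[9]),
                block_length=int(f[10]),
                edit_distance=nm,
            )
        )
    return records


def _group_of_record(
    rec: GafRecord,
    partition: RegionPartition | None,
    group_by: Callable[[GafRecord], str] | None,
) -> str:
    if group_by is not None:
        return group_by(rec)
    if partition is not None:
        # query names of the form "chrom:start-end" (region-split fasta);
        # grouped by the class at the query's reference start
        name = rec.query_name
        chrom, _, span = name.rpartition(":")
        start = int(span.split("-")[0])
        return annotate_point(partition, chrom, start)
    return "all"


def gaf_summary(
    records: Iterable[GafRecord],
    partition: RegionPartition | None = None,
    group_by: Callable[[GafRecord], str] | None = None,
) -> dict[str, GafSummary]:
    """Aggregate edit rate and query coverage, optionally per region class.

    Edit rate = sum(NM) / sum(block length): unaligned sequence lowers
    coverage but not the edit rate.  Coverage counts each distinct query's
    length once in the denominator, so multiple alignments of one query
    can push coverage past 100%.  Records lacking an NM tag contribute to
    coverage only and are flagged in ``records_without_nm``.
    """
    groups: dict[str, GafSummary] = {}
    seen_queries: dict[str, set[str]] = {}
    for rec in records:
        g = _group_of_record(rec, partition, group_by)
        if g not in groups:
            groups[g] = GafSummary(0, 0, 0, 0, 0)
            seen_queries[g] = set()
        s = groups[g]
        s.n_records += 1
        s.aligned_query_bases += rec.query_end - rec.query_start
        if rec.query_name not in seen_queries[g]:
            seen_queries[g].add(rec.query_name)
            s.total_query_bases += rec.query_length
        if rec.edit_distance is None:
            s.records_without_nm += 1
        else:
            s.total_edit += rec.edit_distance
            s.total_block += rec.block_length
    return groups


# -- allelic imbalance -----------------------------------------------------

def binom_imbalance(k: int, n: int) -> float:
    """Two-sided exact binomial p-value against a 50:50 null.

    Sums the probabilities of all outcomes whose probability does not
    exceed that of the observed ``k`` (the R ``binom.test`` definition).
    """
    if n < 1:
        raise ValueError("need at least one trial")
    if not 0 <= k <= n:
        raise ValueError(f"successes {k} outside [0, {n}]")
    return float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
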