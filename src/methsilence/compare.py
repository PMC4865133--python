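"""DMR-set comparison: shared/specific partition, enrichment, composition.

Two regions are considered overlapping only when their overlap strictly
exceeds ``min_overlap`` base pairs (default 50). Overlap enrichment uses the
upper tail of the hypergeometric distribution; the universe size is always an
explicit argument, never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .io import FEATURE_KINDS

# tie-break priority for composition assignment
_KIND_PRIORITY = {"TE": 0, "gene": 1, "other": 2}


@dataclass(frozen=True, slots=True)
class DMROverlapPartition:
    shared_a: tuple
    specific_a: tuple
    shared_b: tuple
    specific_b: tuple
    pairs: tuple  # (a_region, b_region, overlap_bp), overlap strictly > min_overlap


@dataclass(frozen=True, slots=True)
class CompositionSummary:
    """Counts and percentages of a region set over gene/TE/other locations."""

    counts: dict
    percentages: dict
    n: int

    @property
    def empty(self) -> bool:
        return self.n == 0


def overlap_bp(a, b) -> int:
    """Base pairs shared by two 0-based half-open regions on the same chromosome."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _trees(regions) -> dict:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
    return trees


def classify_overlap(
    dmrs_a: Sequence, dmrs_b: Sequence, min_overlap: int = 50
) -> DMROverlapPartition:
    """Partition two region sets into shared and specific.

    A region of one set is shared iff some region of the other set overlaps it
    by strictly more than ``min_overlap`` bp. Every qualifying pair is listed
    once, as (a, b, overlap_bp).
    """
    trees_b = _trees(dmrs_b)
    shared_a, specific_a = [], []
    shared_b_set = set()
    pairs = []
    for a in dmrs_a:
        tree = trees_b.get(a.chrom)
        hit = False
        if tree is not None:
            for iv in sorted(tree.overlap(a.start, a.end)):
                o = min(a.end, iv.end) - max(a.start, iv.begin)
                if o > min_overlap:
                    hit = True
                    pairs.append((a, iv.data, o))
                    shared_b_set.add(id(iv.data))
        (shared_a if hit else specific_a).append(a)
    shared_b = [b for b in dmrs_b if id(b) in shared_b_set]
    specific_b = [b for b in dmrs_b if id(b) not in shared_b_set]
    return DMROverlapPartition(
        tuple(shared_a), tuple(specific_a), tuple(shared_b), tuple(specific_b), tuple(pairs)
    )


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent arguments: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    return float(hypergeom.sf(k - 1, N, K, n))


def genomic_composition(dmrs: Sequence, features: Sequence) -> CompositionSummary:
    """Assign each region to gene, TE, or other by maximal base-pair overlap.

    Overlap with each kind is the region's coverage by the union of that
    kind's features; unannotated space counts toward "other". Ties break
    TE > gene > other. Percentages are over the region count; an empty region
    set yields an empty (flagged) summary.
    """
    kind_trees = {
        kind: _trees([f for f in features if f.kind == kind]) for kind in ("gene", "TE")
    }
    counts = {k: 0 for k in FEATURE_KINDS}
    for d in dmrs:
        length = d.end - d.start
        cov = {}
        for kind, trees in kind_trees.items():
            tree = trees.get(d.chrom)
            cov[kind] = _covered_bp(d, tree) if tree is not None else 0
        # space not annotated as gene or TE; annotated kinds may overlap each
        # other, so clamp at zero
        cov["other"] = max(0, length - _covered_union(d, kind_trees))
        best = max(cov, key=lambda k: (cov[k], -_KIND_PRIORITY[k]))
        counts[best] += 1
    n = len(dmrs)
    percentages = {k: (100.0 * c / n if n else 0.0) for k, c in counts.items()}
    return CompositionSummary(counts=counts, percentages=percentages, n=n)


def _covered_bp(region, tree: IntervalTree) -> int:
    segs = sorted(
        (max(region.start, iv.begin), min(region.end, iv.end))
        for iv in tree.overlap(region.start, region.end)
    )
    return _union_len(segs)


def _covered_union(region, kind_trees) -> int:
    segs = []
    for trees in kind_trees.values():
        tree = trees.get(region.chrom)
        if tree is None:
            continue
        segs.extend(
            (max(region.start, iv.begin), min(region.end, iv.end))
            for iv in tree.overlap(region.start, region.end)
        )
    return _union_len(sorted(segs))


def _union_len(sorted_segs) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted_segs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total
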