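"""Feature-level methylation: TE bodies, 1-kb promoters, class filters, t-tests.

Levels are weighted: pooled methylated reads over pooled total reads across
the sites of a feature, per context and for all contexts combined, counting
only sites with at least ``min_coverage`` reads. A context with no qualifying
reads has an undefined level (None), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .io import CONTEXTS, GenomicFeature


@dataclass(frozen=True, slots=True)
class PromoterInterval:
    """1-kb (by default) region upstream of a gene's 5' end on its strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True, slots=True)
class FeatureMethylation:
    feature_id: str
    genotype: str
    m: dict  # context -> pooled methylated reads
    u: dict

    def counts(self, context: str = "total") -> tuple[int, int]:
        if context == "total":
            return sum(self.m.values()), sum(self.u.values())
        return self.m.get(context, 0), self.u.get(context, 0)

    def level(self, context: str = "total") -> float | None:
        m, u = self.counts(context)
        return m / (m + u) if m + u > 0 else None

    @property
    def defined(self) -> bool:
        return self.level("total") is not None


def promoter_region(
    gene: GenomicFeature, promoter_len: int = 1000, chrom_len: int | None = None
) -> PromoterInterval:
    """The promoter abuts the gene's 5' end: upstream of start for '+' genes,
    downstream of end for '-' genes; truncated at chromosome bounds."""
    if gene.kind != "gene":
        raise ValueError(f"{gene.feature_id}: promoter defined only for genes")
    if gene.strand == "+":
        start, end = max(0, gene.start - promoter_len), gene.start
    elif gene.strand == "-":
        start = gene.end
        end = gene.end + promoter_len
        if chrom_len is not None:
            end = min(end, chrom_len)
    else:
        raise ValueError(f"{gene.feature_id}: promoter undefined without strand")
    if start >= end:
        raise ValueError(f"{gene.feature_id}: promoter collapses at chromosome bound")
    return PromoterInterval(gene.feature_id, gene.chrom, start, end, gene.strand)


def feature_methylation_level(
    sites, interval, min_coverage: int = 5, genotype: str = ""
) -> FeatureMethylation:
    """Pooled per-context levels of one interval (feature or promoter)."""
    fid = getattr(interval, "feature_id", None) or getattr(interval, "gene_id", "")
    m = {c: 0 for c in CONTEXTS}
    u = {c: 0 for c in CONTEXTS}
    for s in sites:
        if s.chrom != interval.chrom or not (interval.start <= s.start < interval.end):
            continue
        if s.coverage < min_coverage:
            continue
        m[s.context] += s.count_meth
        u[s.context] += s.count_unmeth
    m = {c: v for c, v in m.items() if v or u[c]}
    u = {c: u[c] for c in m}
    return FeatureMethylation(fid, genotype, m, u)


def feature_methylation_table(
    sites, intervals: Sequence, min_coverage: int = 5, genotype: str = ""
) -> dict[str, FeatureMethylation]:
    """Vectorized pooled levels for many intervals at once.

    Intervals may overlap (promoters can extend over neighboring features);
    each is evaluated independently against the same site set.
    """
    df = sites if isinstance(sites, pd.DataFrame) else pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "context": [s.context for s in sites],
            "count_meth": [s.count_meth for s in sites],
            "count_unmeth": [s.count_unmeth for s in sites],
        }
    )
    if not df.empty:
        df = df[(df["count_meth"] + df["count_unmeth"]) >= min_coverage]
    by_chrom = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        by_chrom[chrom] = (
            grp["pos"].to_numpy() - 1,
            grp["context"].to_numpy(),
            grp["count_meth"].to_numpy(),
            grp["count_unmeth"].to_numpy(),
        )
    out = {}
    for iv in intervals:
        fid = getattr(iv, "feature_id", None) or getattr(iv, "gene_id", "")
        m: dict[str, int] = {}
        u: dict[str, int] = {}
        data = by_chrom.get(iv.chrom)
        if data is not None:
            starts, ctx, cm, cu = data
            lo, hi = np.searchsorted(starts, [iv.start, iv.end])
            for c in CONTEXTS:
                mask = ctx[lo:hi] == c
                if mask.any():
                    m[c] = int(cm[lo:hi][mask].sum())
                    u[c] = int(cu[lo:hi][mask].sum())
        out[fid] = FeatureMethylation(fid, genotype, m, u)
    return out


THRESHOLDS = {"TE": 0.20, "gene-promoter": 0.05}


def filter_methylated_features(
    levels: Mapping[str, float | None], kind: str, threshold: float | None = None
) -> set[str]:
    """Ids whose total-cytosine level strictly exceeds the class threshold
    (>20% for TE bodies, >5% for gene promoters). Undefined levels are
    excluded."""
    if threshold is None:
        try:
            threshold = THRESHOLDS[kind]
        except KeyError:
            raise ValueError(f"kind must be one of {sorted(THRESHOLDS)}, got {kind!r}") from None
    return {fid for fid, lv in levels.items() if lv is not None and lv > threshold}


class TTestOutcome(NamedTuple):
    t: float
    p: float
    stars: str  # "", "*", or "**"
    degenerate: bool  # both groups had zero within-group variance


def group_ttest(levels_group1: Sequence[float], levels_group2: Sequence[float]) -> TTestOutcome:
    """Welch two-sample t-test, two-sided, with significance stars at 0.05/0.01."""
    g1 = np.asarray(levels_group1, dtype=float)
    g2 = np.asarray(levels_group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 values")
    degenerate = g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0
    if degenerate:
        # zero within-group variance: t-test undefined; report the p -> 0 or
        # p = 1 limit depending on whether the means differ
        if g1.mean() == g2.mean():
            t, p = 0.0, 1.0
        else:
            t, p = float("inf") if g2.mean() < g1.mean() else float("-inf"), 0.0
    else:
        res = ttest_ind(g1, g2, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
    stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
    return TTestOutcome(t, p, stars, degenerate)


def methylation_delta_table(
    genotype_levels: Mapping[str, Mapping[str, FeatureMethylation]],
    reference_genotype: str,
) -> pd.DataFrame:
    """Per-feature, per-context level differences vs the reference genotype.

    Returns a tidy frame (feature_id, genotype, context, level, ref_level,
    delta); the reference rows have delta 0 by construction and are omitted.
    Undefined levels propagate as NaN.
    """
    if reference_genotype not in genotype_levels:
        raise ValueError(f"reference genotype {reference_genotype!r} missing")
    ref = genotype_levels[reference_genotype]
    rows = []
    for genotype, levels in genotype_levels.items():
        if genotype == reference_genotype:
            continue
        for fid, fm in levels.items():
            ref_fm = ref.get(fid)
            for context in CONTEXTS + ("total",):
                lv = fm.level(context)
                rv = ref_fm.level(context) if ref_fm is not None else None
                delta = lv - rv if lv is not None and rv is not None else np.nan
                rows.append(
                    {
                        "feature_id": fid,
                        "genotype": genotype,
                        "context": context,
                        "level": np.nan if lv is None else lv,
                        "ref_level": np.nan if rv is None else rv,
                        "delta": delta,
                    }
                )
    return pd.DataFrame(rows)
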