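"""Differential-expression decision rule and target-set classification.

A feature is called up-regulated in the test genotype when the fold change of
normalized read counts exceeds ``fc_min`` (default 2) and a two-sided Fisher
exact test of (feature count vs rest of library) across the two genotypes
gives p < ``alpha`` (default 0.01). Down-regulation is the mirrored rule
(fold < 1/fc_min). Normalization scales counts to the smaller library's
total; a pseudocount enters the fold change only, never the exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .compare import hypergeometric_upper_tail
from .dmr import fisher_exact_two_sided


@dataclass(frozen=True, slots=True)
class ExpressionRecord:
    feature_id: str
    count_a: int
    count_b: int
    norm_a: float
    norm_b: float
    fold_change: float  # (norm_b + c0) / (norm_a + c0)
    p: float
    call: str  # up | down | unchanged


@dataclass(frozen=True, slots=True)
class TargetPartition:
    common: tuple
    specific_a: tuple
    specific_b: tuple


def call_differential_expression(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    lib_a: int,
    lib_b: int,
    fc_min: float = 2.0,
    alpha: float = 0.01,
    pseudocount: float = 0.5,
) -> list[ExpressionRecord]:
    """Apply the fold-change + Fisher rule per feature (B tested against A).

    ``counts_a`` and ``counts_b`` must cover the same feature ids; library
    totals must be positive and at least as large as any feature count.
    """
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    if set(counts_a) != set(counts_b):
        raise ValueError("feature id sets differ between genotypes")
    scale = min(lib_a, lib_b)
    records = []
    for fid in sorted(counts_a):
        ca, cb = int(counts_a[fid]), int(counts_b[fid])
        if ca < 0 or cb < 0:
            raise ValueError(f"negative count at {fid}")
        if ca > lib_a or cb > lib_b:
            raise ValueError(f"count exceeds library total at {fid}")
        na = ca * scale / lib_a
        nb = cb * scale / lib_b
        fold = (nb + pseudocount) / (na + pseudocount)
        p = fisher_exact_two_sided(ca, lib_a - ca, cb, lib_b - cb)
        if fold > fc_min and p < alpha:
            call = "up"
        elif fold < 1.0 / fc_min and p < alpha:
            call = "down"
        else:
            call = "unchanged"
        records.append(ExpressionRecord(fid, ca, cb, na, nb, fold, p, call))
    return records


def partition_targets(up_a, up_b) -> TargetPartition:
    """Venn partition of two up-regulated id sets, ordered by feature id."""
    a, b = set(up_a), set(up_b)
    return TargetPartition(
        common=tuple(sorted(a & b)),
        specific_a=tuple(sorted(a - b)),
        specific_b=tuple(sorted(b - a)),
    )


def set_enrichment(common_size: int, up_a_size: int, up_b_size: int, universe: int) -> float:
    """Hypergeometric upper-tail p for the observed co-up-regulation count."""
    return hypergeometric_upper_tail(common_size, up_a_size, up_b_size, universe)


def records_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "count_a": [r.count_a for r in records],
            "count_b": [r.count_b for r in records],
            "norm_a": [r.norm_a for r in records],
            "norm_b": [r.norm_b for r in records],
            "fold_change": [r.fold_change for r in records],
            "p": [r.p for r in records],
            "call": [r.call for r in records],
        }
    )
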