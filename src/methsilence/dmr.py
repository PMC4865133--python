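"""Windowed differential-methylation calling.

The procedure: pool per-site read counts into fixed 50-bp windows anchored at
coordinate 0 of each chromosome (only sites with at least five-fold coverage
contribute), compute the weighted methylation level of each window in each
genotype (pooled methylated reads over pooled total reads), retain windows
whose levels differ by at least 10 percentage points with a two-sided Fisher
exact p below 0.01, and chain retained windows of the same direction into
differentially methylated regions (DMRs) whenever the gap between consecutive
windows is at most 50 bp.

All thresholds are parameters; the values above are the defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from .io import CONTEXTS

CONTEXT_MODES = CONTEXTS + ("total",)


class GridMismatchError(ValueError):
    """Window grids from the two genotypes do not align."""


@dataclass(frozen=True, slots=True)
class MethylationWindow:
    """Pooled methylation counts for one fixed-width window.

    ``m``/``u``/``n_sites`` map context -> pooled methylated reads, pooled
    unmethylated reads, and number of qualifying sites. The weighted level for
    a context (or for "total", all contexts pooled) is undefined when no reads
    qualify, in which case :meth:`level` returns None.
    """

    chrom: str
    start: int
    end: int
    m: dict
    u: dict
    n_sites: dict

    def counts(self, context: str = "total") -> tuple[int, int]:
        if context == "total":
            return sum(self.m.values()), sum(self.u.values())
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        return self.m.get(context, 0), self.u.get(context, 0)

    def level(self, context: str = "total") -> float | None:
        m, u = self.counts(context)
        return m / (m + u) if m + u > 0 else None


@dataclass(frozen=True, slots=True)
class DifferentialWindow:
    """A window retained by the |delta| and Fisher-p thresholds.

    ``delta`` = level(B) - level(A) on the tested context set; direction is
    hypo when the test genotype lost methylation.
    """

    window_a: MethylationWindow
    window_b: MethylationWindow
    context: str
    delta: float
    p: float

    @property
    def chrom(self) -> str:
        return self.window_a.chrom

    @property
    def start(self) -> int:
        return self.window_a.start

    @property
    def end(self) -> int:
        return self.window_a.end

    @property
    def direction(self) -> str:
        return "hypo" if self.delta < 0 else "hyper"


@dataclass(frozen=True, slots=True)
class DMR:
    """A run of same-direction differential windows with gaps <= max_gap."""

    chrom: str
    start: int
    end: int
    direction: str
    n_windows: int
    delta_total: float
    p_min: float
    windows: tuple = field(default=())


def _sites_frame(sites) -> pd.DataFrame:
    if isinstance(sites, pd.DataFrame):
        return sites
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "context": [s.context for s in sites],
            "count_meth": [s.count_meth for s in sites],
            "count_unmeth": [s.count_unmeth for s in sites],
        }
    )


def compute_window_methylation(
    sites, window_size: int = 50, min_coverage: int = 5
) -> list[MethylationWindow]:
    """Pool qualifying sites into non-overlapping windows on a 0-anchored grid.

    ``sites`` is a sequence of cytosine records (or an equivalent DataFrame
    with columns chrom, pos, context, count_meth, count_unmeth; pos 1-based).
    Only sites with coverage >= ``min_coverage`` contribute; grid cells with no
    qualifying site produce no window. Windows are returned sorted by
    (chrom, start).
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    if min_coverage < 0:
        raise ValueError(f"min_coverage must be >= 0, got {min_coverage}")
    df = _sites_frame(sites)
    if df.empty:
        return []
    df = df[(df["count_meth"] + df["count_unmeth"]) >= min_coverage]
    if df.empty:
        return []
    win = (df["pos"] - 1) // window_size
    agg = (
        df.groupby([df["chrom"], win.rename("win"), df["context"]], sort=True)
        .agg(m=("count_meth", "sum"), u=("count_unmeth", "sum"), n=("pos", "size"))
        .reset_index()
    )
    windows = []
    for (chrom, w), grp in agg.groupby(["chrom", "win"], sort=True):
        windows.append(
            MethylationWindow(
                chrom=chrom,
                start=int(w) * window_size,
                end=(int(w) + 1) * window_size,
                m=dict(zip(grp["context"], grp["m"].astype(int))),
                u=dict(zip(grp["context"], grp["u"].astype(int))),
                n_sites=dict(zip(grp["context"], grp["n"].astype(int))),
            )
        )
    return windows


def fisher_exact_two_sided(m_a: int, u_a: int, m_b: int, u_b: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[m_a, u_a], [m_b, u_b]].

    Uses the point-probability rule (sum of hypergeometric probabilities of
    tables as or less probable than the observed one). The degenerate all-zero
    table has no defined test; p = 1 is returned with a warning.
    """
    for v in (m_a, u_a, m_b, u_b):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if m_a + u_a + m_b + u_b == 0:
        warnings.warn("Fisher test on an all-zero table; returning p = 1", stacklevel=2)
        return 1.0
    return float(_scipy_fisher([[m_a, u_a], [m_b, u_b]]).pvalue)


def call_differential_windows(
    windows_a: Sequence[MethylationWindow],
    windows_b: Sequence[MethylationWindow],
    delta_min: float = 0.10,
    alpha: float = 0.01,
    context_mode: str = "total",
) -> list[DifferentialWindow]:
    """Test windows present in both genotypes; retain |delta| >= delta_min and
    p < alpha on the pooled counts of the chosen context set.

    The |delta| filter is applied first so the exact test runs only on windows
    that could be retained. Windows are matched by (chrom, start); a matched
    pair with differing widths raises :class:`GridMismatchError`.
    """
    if context_mode not in CONTEXT_MODES:
        raise ValueError(f"context_mode must be one of {CONTEXT_MODES}, got {context_mode!r}")
    index_b = {(w.chrom, w.start): w for w in windows_b}
    out: list[DifferentialWindow] = []
    for wa in windows_a:
        wb = index_b.get((wa.chrom, wa.start))
        if wb is None:
            continue
        if wb.end != wa.end:
            raise GridMismatchError(
                f"window {wa.chrom}:{wa.start} has width {wa.end - wa.start} in A "
                f"but {wb.end - wb.start} in B"
            )
        la = wa.level(context_mode)
        lb = wb.level(context_mode)
        if la is None or lb is None:
            continue
        delta = lb - la
        if abs(delta) < delta_min:
            continue
        ma, ua = wa.counts(context_mode)
        mb, ub = wb.counts(context_mode)
        p = fisher_exact_two_sided(ma, ua, mb, ub)
        if p < alpha:
            out.append(DifferentialWindow(wa, wb, context_mode, delta, p))
    out.sort(key=lambda w: (w.chrom, w.start))
    return out


def merge_windows(
    diff_windows: Iterable[DifferentialWindow], max_gap: int = 50
) -> list[DMR]:
    """Chain same-chromosome, same-direction windows into DMRs.

    Consecutive windows merge when next.start - prev.end <= max_gap; hypo and
    hyper chains never mix. ``delta_total`` is recomputed from the pooled
    counts of the constituent windows (on their shared context set) and
    ``p_min`` is the smallest window p.
    """
    by_key: dict[tuple[str, str], list[DifferentialWindow]] = {}
    for w in diff_windows:
        by_key.setdefault((w.chrom, w.direction), []).append(w)

    dmrs: list[DMR] = []
    for (chrom, direction), group in by_key.items():
        group.sort(key=lambda w: w.start)
        chain: list[DifferentialWindow] = []
        for w in group:
            if chain and w.start - chain[-1].end <= max_gap:
                chain.append(w)
            else:
                if chain:
                    dmrs.append(_finalize(chrom, direction, chain))
                chain = [w]
        if chain:
            dmrs.append(_finalize(chrom, direction, chain))
    dmrs.sort(key=lambda d: (d.chrom, d.start, d.direction))
    return dmrs


def _finalize(chrom: str, direction: str, chain: list[DifferentialWindow]) -> DMR:
    context = chain[0].context
    ma = ua = mb = ub = 0
    for w in chain:
        a_m, a_u = w.window_a.counts(context)
        b_m, b_u = w.window_b.counts(context)
        ma += a_m
        ua += a_u
        mb += b_m
        ub += b_u
    delta_total = mb / (mb + ub) - ma / (ma + ua)
    return DMR(
        chrom=chrom,
        start=chain[0].start,
        end=chain[-1].end,
        direction=direction,
        n_windows=len(chain),
        delta_total=delta_total,
        p_min=min(w.p for w in chain),
        windows=tuple(chain),
    )


def call_dmrs(
    sites_a,
    sites_b,
    window_size: int = 50,
    min_coverage: int = 5,
    delta_min: float = 0.10,
    alpha: float = 0.01,
    max_gap: int = 50,
    context_mode: str = "total",
) -> list[DMR]:
    """End-to-end: windows in each genotype, differential test, merge."""
    wa = compute_window_methylation(sites_a, window_size, min_coverage)
    wb = compute_window_methylation(sites_b, window_size, min_coverage)
    diff = call_differential_windows(wa, wb, delta_min, alpha, context_mode)
    return merge_windows(diff, max_gap)
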