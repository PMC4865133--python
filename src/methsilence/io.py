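"""Readers and writers for on-disk formats.

All TSVs are tab-delimited; lines starting with ``#`` are skipped. Internally
every interval is 0-based half-open; only the file boundary converts:
cytosine-report positions and GFF3 coordinates are 1-based on disk, BED is
already 0-based half-open.

Chromosome names are compared as exact strings. A rename mapping can be passed
to any reader to reconcile conventions such as ``Chr1`` vs ``1``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

CONTEXTS = ("CG", "CHG", "CHH")
FEATURE_KINDS = ("gene", "TE", "other")

SCORE_CAP = 300.0  # -log10(p) cap in DMR BED output


class ReportParseError(ValueError):
    """A line of an input file could not be parsed."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


class ValidationError(ValueError):
    """Parsed content violates a contract (negative count, duplicate site...)."""


@dataclass(frozen=True, slots=True)
class CytosineSiteRecord:
    """One cytosine position from a Bismark-style cytosine report.

    ``pos`` is kept 1-based exactly as in the source file; ``start`` exposes
    the 0-based coordinate used internally.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    count_meth: int
    count_unmeth: int

    @property
    def start(self) -> int:
        return self.pos - 1

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth


@dataclass(frozen=True, slots=True)
class GenomicFeature:
    """A gene, transposable element, or uncharacterized interval.

    Coordinates are 0-based half-open; ``strand`` is '+', '-' or '.'.
    """

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"feature {self.feature_id}: start {self.start} >= end {self.end}"
            )
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"feature {self.feature_id}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_cytosine_report(
    path, rename: Mapping[str, str] | None = None
) -> list[CytosineSiteRecord]:
    """Read a cytosine report: chrom, pos(1-based), strand, meth, unmeth, context.

    An optional 7th trinucleotide column is ignored. Raises
    :class:`ReportParseError` on malformed lines and :class:`ValidationError`
    on negative counts or duplicated (chrom, pos, strand) sites.
    """
    records: list[CytosineSiteRecord] = []
    seen: set[tuple[str, int, str]] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ReportParseError(path, lineno, f"expected >=6 columns, got {len(fields)}")
        chrom, pos_s, strand, m_s, u_s, context = fields[:6]
        if rename:
            chrom = rename.get(chrom, chrom)
        try:
            pos = int(pos_s)
            m = int(m_s)
            u = int(u_s)
        except ValueError as exc:
            raise ReportParseError(path, lineno, f"non-integer field: {exc}") from None
        if strand not in ("+", "-"):
            raise ReportParseError(path, lineno, f"unknown strand {strand!r}")
        if context not in CONTEXTS:
            raise ReportParseError(path, lineno, f"unknown context {context!r}")
        if pos < 1:
            raise ReportParseError(path, lineno, f"position {pos} is not 1-based")
        if m < 0 or u < 0:
            raise ValidationError(f"{path}:{lineno}: negative read count")
        key = (chrom, pos, strand)
        if key in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate site {key}")
        seen.add(key)
        records.append(CytosineSiteRecord(chrom, pos, strand, context, m, u))
    return records


def write_cytosine_report(records: Iterable[CytosineSiteRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.count_meth}\t{r.count_unmeth}\t{r.context}\n"
            )


_TE_NAME = re.compile(r"TE", re.IGNORECASE)


def infer_kind_from_name(name: str) -> str:
    """Default BED name rule: names containing 'TE' (e.g. AT1TE45510) are TEs,
    everything else is a gene."""
    return "TE" if _TE_NAME.search(name) else "gene"


def _kind_from_gff_type(gff_type: str) -> str:
    if gff_type == "gene":
        return "gene"
    if gff_type.startswith("transposable_element"):
        return "TE"
    return "other"


_GFF_ID = re.compile(r"(?:^|;)ID=([^;]+)")


def read_features(
    path,
    dialect: str = "gff3",
    bed_kind_rule: Callable[[str], str] = infer_kind_from_name,
    rename: Mapping[str, str] | None = None,
) -> list[GenomicFeature]:
    """Read an annotation as GFF3 (1-based inclusive) or BED (0-based half-open).

    All coordinates are normalized to 0-based half-open. GFF3 kind comes from
    the type column (gene -> gene, transposable_element* -> TE, else other);
    BED kind comes from a 7th column when present, else from ``bed_kind_rule``
    applied to the name.
    """
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    features: list[GenomicFeature] = []
    seen_ids: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if dialect == "gff3":
            if len(fields) < 9:
                raise ReportParseError(path, lineno, f"expected 9 GFF3 columns, got {len(fields)}")
            chrom, _src, gff_type, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            try:
                start = int(start_s) - 1  # 1-based inclusive -> 0-based half-open
                end = int(end_s)
            except ValueError:
                raise ReportParseError(path, lineno, "non-integer coordinate") from None
            m = _GFF_ID.search(attrs)
            fid = m.group(1) if m else f"{gff_type}_{lineno}"
            kind = _kind_from_gff_type(gff_type)
        else:
            if len(fields) < 4:
                raise ReportParseError(path, lineno, f"expected >=4 BED columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError:
                raise ReportParseError(path, lineno, "non-integer coordinate") from None
            fid = fields[3]
            strand = fields[5] if len(fields) >= 6 else "."
            kind = fields[6] if len(fields) >= 7 else bed_kind_rule(fid)
        if rename:
            chrom = rename.get(chrom, chrom)
        if strand not in ("+", "-", "."):
            raise ReportParseError(path, lineno, f"unknown strand {strand!r}")
        if fid in seen_ids:
            raise ValidationError(f"{path}:{lineno}: duplicate feature id {fid!r}")
        seen_ids.add(fid)
        features.append(GenomicFeature(fid, chrom, start, end, strand, kind))
    return features


def write_features(features: Iterable[GenomicFeature], path) -> None:
    """Write features as BED6+1 (7th column = kind); round-trips through
    :func:`read_features` with dialect 'bed'."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\t{f.kind}\n")


def write_gff3(features: Iterable[GenomicFeature], path) -> None:
    """Write gene/TE features as a minimal GFF3 (1-based inclusive on disk)."""
    type_of = {"gene": "gene", "TE": "transposable_element", "other": "region"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.chrom}\tmethsilence\t{type_of[f.kind]}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.feature_id}\n"
            )


def write_dmrs(dmrs: Sequence, path) -> None:
    """Write DMRs as BED6+3: chrom, start, end, name, score, strand, delta_total,
    n_windows, direction.

    Score is -log10(p_min) capped at 300; name is ``<direction>_<rank>`` after
    the deterministic (chrom, start) sort.
    """
    ordered = sorted(dmrs, key=lambda d: (d.chrom, d.start, d.end))
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\tscore\tstrand\tdelta_total\tn_windows\tdirection\n"
        )
        for i, d in enumerate(ordered, start=1):
            score = SCORE_CAP if d.p_min <= 0 else min(SCORE_CAP, -math.log10(d.p_min))
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.direction}_{i}\t{score:.6g}\t.\t"
                f"{d.delta_total:.6g}\t{d.n_windows}\t{d.direction}\n"
            )


def read_dmrs(path) -> list:
    """Read a DMR BED6+3 written by :func:`write_dmrs`.

    The per-window detail is not stored on disk, so the returned DMRs carry an
    empty window tuple; ``p_min`` is reconstructed from the score column.
    """
    from .dmr import DMR  # local import: dmr builds on io's record types

    dmrs = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 9:
            raise ReportParseError(path, lineno, f"expected 9 columns, got {len(fields)}")
        chrom, start_s, end_s, _name, score_s, _strand, delta_s, nwin_s, direction = fields[:9]
        try:
            start, end = int(start_s), int(end_s)
            score = float(score_s)
            delta = float(delta_s)
            n_windows = int(nwin_s)
        except ValueError:
            raise ReportParseError(path, lineno, "malformed numeric field") from None
        if direction not in ("hypo", "hyper"):
            raise ReportParseError(path, lineno, f"unknown direction {direction!r}")
        dmrs.append(
            DMR(
                chrom=chrom,
                start=start,
                end=end,
                direction=direction,
                n_windows=n_windows,
                delta_total=delta,
                p_min=10.0 ** (-score),
                windows=(),
            )
        )
    return dmrs


def to_zero_based(pos_1based: int) -> int:
    return pos_1based - 1


def to_one_based(start_0based: int) -> int:
    return start_0based + 1
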